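"""Plate-based RNAi viability screen statistics.

A 384-well screen plate has 16 lettered rows (A-P) and 24 numbered
columns; the outermost columns (1, 2, 23, 24 by default) hold controls.
Raw luminescence is normalized on the log2 scale by removing a smooth
spatial surface fitted on sample wells only, z-scored against robust
location/scale estimates of the library-wide sample distribution, and
wells at least ``threshold_sd`` robust standard deviations from the
library median are called hits (the three-sigma rule). The robust SD is
Huber's Proposal 2 estimate with the data winsorized at ``k = 1.5``
scale units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateLayoutError,
    EmptyResultWarning,
    InputError,
    NonConvergenceError,
    UnstableScaleWarning,
    ZeroScaleError,
    ZeroSpreadError,
)

WELL_COLUMNS = ["plate", "row", "col", "gene", "well_type", "condition", "signal"]
WELL_TYPES = {"sample", "control", "empty"}
#: normal-consistency factor for the median absolute deviation
MAD_SCALE = 1.4826022185056018


@dataclass
class PlateSet:
    """Grid-addressed raw screen signals with well roles and conditions.

    ``wells`` is a long-format frame with columns ``plate``, ``row``
    (1-16), ``col`` (1-24), ``gene``, ``well_type`` (sample / control /
    empty), ``condition`` and ``signal`` (raw luminescence, > 0 for
    non-empty wells).
    """

    wells: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise InputError(f"plate table missing columns: {missing}")
        w = self.wells
        bad_types = set(w["well_type"]) - WELL_TYPES
        if bad_types:
            raise InputError(f"unknown well_type values: {sorted(bad_types)}")
        if not w["row"].between(1, 16).all():
            raise InputError("row indices must be in 1..16")
        if not w["col"].between(1, 24).all():
            raise InputError("column indices must be in 1..24")
        addr = w[["plate", "row", "col", "condition"]]
        if addr.duplicated().any():
            dup = addr[addr.duplicated()].iloc[0]
            raise InputError(
                f"duplicate well address: plate={dup['plate']} "
                f"row={dup['row']} col={dup['col']} condition={dup['condition']}"
            )
        nonempty = w[w["well_type"] != "empty"]
        sig = nonempty["signal"].to_numpy(float)
        if not np.all(np.isfinite(sig)) or np.any(sig <= 0):
            raise InputError("raw signal must be finite and > 0 for non-empty wells")
        for plate, grp in w.groupby("plate"):
            if not (grp["well_type"] == "sample").any():
                raise InputError(f"plate {plate!r} has no sample wells")

    @property
    def plates(self):
        return sorted(self.wells["plate"].unique())

    @property
    def conditions(self):
        return sorted(self.wells["condition"].unique())


@dataclass
class NormalizedScreen:
    """Per-well normalized (log2) signals plus fit metadata.

    ``wells`` carries one record per non-empty input well with a
    ``normalized`` column; ``meta`` maps (plate, condition) to the
    surface-fit parameters used.
    """

    wells: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class RobustScale:
    """Huber Proposal 2 simultaneous location/scale estimate."""

    mu: float
    sigma: float
    k: float
    iterations: int
    converged: bool


def _quadratic_design(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    # centred coordinates keep the design well conditioned
    rc_ = (r - 8.5) / 7.5
    cc_ = (c - 12.5) / 11.5
    return np.column_stack(
        [np.ones_like(rc_), rc_, cc_, rc_ * rc_, cc_ * cc_, rc_ * cc_]
    )


def _fit_polynomial_surface(fit_rc, fit_y, eval_rc, trim_sd: float = 3.5):
    """OLS tensor-quadratic surface with one outlier-trimming pass.

    Wells whose initial residual exceeds ``trim_sd`` robust SDs are
    dropped before the final fit, so strong biological effects (hits)
    do not steer the artifact surface. The final fit is an orthogonal
    projection of the kept wells, which makes normalization idempotent.
    """
    X = _quadratic_design(fit_rc[:, 0], fit_rc[:, 1])
    beta, *_ = np.linalg.lstsq(X, fit_y, rcond=None)
    resid = fit_y - X @ beta
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= trim_sd * mad * MAD_SCALE
        if keep.sum() >= max(10, X.shape[1] + 1) and not keep.all():
            beta, *_ = np.linalg.lstsq(X[keep], fit_y[keep], rcond=None)
    Xe = _quadratic_design(eval_rc[:, 0], eval_rc[:, 1])
    return Xe @ beta, X @ beta, beta


def _fit_loess_surface(fit_rc, fit_y, eval_rc, span):
    """Tricube-weighted local linear regression on the plate grid."""
    n = len(fit_y)
    kq = max(5, int(np.ceil(span * n)))

    def predict(points):
        out = np.empty(len(points))
        for i, (r0, c0) in enumerate(points):
            d = np.hypot(fit_rc[:, 0] - r0, fit_rc[:, 1] - c0)
            idx = np.argpartition(d, kq - 1)[:kq]
            dmax = d[idx].max()
            w = (1.0 - np.minimum(d[idx] / max(dmax, 1e-12), 1.0) ** 3) ** 3
            X = np.column_stack([np.ones(kq), fit_rc[idx, 0], fit_rc[idx, 1]])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], fit_y[idx] * sw, rcond=None)
            out[i] = beta @ [1.0, r0, c0]
        return out

    return predict(eval_rc), predict(fit_rc), None


def loess_normalize(
    plates: PlateSet,
    span: float = 0.7,
    excluded_columns=(1, 2, 23, 24),
    log2_scale: bool = True,
    surface: str = "polynomial",
) -> NormalizedScreen:
    """Remove smooth spatial plate artifacts, fitted on sample wells only.

    A surface over (row, column) is fitted per plate and per condition
    using sample wells outside ``excluded_columns`` (the control lines),
    then subtracted from every non-empty well after re-centring so the
    plate median of the fitted wells is preserved. ``surface`` selects
    the model: ``"polynomial"`` (default) is an OLS tensor-quadratic fit
    — a projection, so normalization is idempotent — while ``"loess"``
    is classic tricube local linear regression with neighbourhood
    fraction ``span``.
    """
    if not (0 < span <= 1):
        raise InputError(f"span must be in (0, 1], got {span}")
    if surface not in ("polynomial", "loess"):
        raise InputError(f"unknown surface model {surface!r}")
    excluded = set(excluded_columns)

    w = plates.wells[plates.wells["well_type"] != "empty"].copy()
    y_all = np.log2(w["signal"].to_numpy(float)) if log2_scale else w[
        "signal"
    ].to_numpy(float)
    w["normalized"] = np.nan
    meta = {}

    for (plate, cond), grp in w.groupby(["plate", "condition"], sort=False):
        is_fit = (grp["well_type"] == "sample") & (~grp["col"].isin(excluded))
        if not is_fit.any():
            raise DegenerateLayoutError(
                f"plate {plate!r} condition {cond!r}: every sample well lies "
                f"in excluded columns {sorted(excluded)}"
            )
        if is_fit.sum() < 10:
            raise DegenerateLayoutError(
                f"plate {plate!r} condition {cond!r}: only {int(is_fit.sum())} "
                "sample wells outside excluded columns (need >= 10)"
            )
        pos = w.index.get_indexer(grp.index)
        y = y_all[pos]
        rc = grp[["row", "col"]].to_numpy(float)
        fit_rc, fit_y = rc[is_fit.to_numpy()], y[is_fit.to_numpy()]
        if surface == "polynomial":
            fitted, fitted_at_fit, beta = _fit_polynomial_surface(fit_rc, fit_y, rc)
        else:
            fitted, fitted_at_fit, beta = _fit_loess_surface(fit_rc, fit_y, rc, span)
        centre = np.median(fitted_at_fit)
        w.iloc[pos, w.columns.get_loc("normalized")] = y - (fitted - centre)
        meta[(plate, cond)] = {
            "surface": surface,
            "span": span,
            "excluded_columns": sorted(excluded),
            "n_fit_wells": int(is_fit.sum()),
            "coefficients": None if beta is None else beta.tolist(),
        }
    return NormalizedScreen(wells=w, meta=meta)


def robust_z(values, name: str = "values") -> np.ndarray:
    """Robust z-scores: (x - median) / (1.4826 * MAD)."""
    x = np.asarray(values, float)
    if x.size < 3:
        raise InputError(f"robust_z needs >= 3 values in {name}, got {x.size}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ZeroSpreadError(f"MAD of {name} is zero; z-scores undefined")
    return (x - med) / (mad * MAD_SCALE)


def huber_consistency_beta(k: float) -> float:
    """E[min(|Z|, k)^2] for standard normal Z (scale-consistency factor)."""
    return (
        2 * stats.norm.cdf(k)
        - 1
        - 2 * k * stats.norm.pdf(k)
        + 2 * k * k * stats.norm.sf(k)
    )


def huber_proposal2(
    values, k: float = 1.5, tol: float = 1e-8, max_iter: int = 200
) -> RobustScale:
    """Simultaneous Huber location/scale (Proposal 2) by fixed-point iteration.

    At each step the data are winsorized at ``mu +/- k*sigma``; the new
    location is the mean of the winsorized values and the new scale
    satisfies ``sigma^2 = sum((win - mu)^2) / (n * beta(k))`` with
    ``beta(k) = E[min(|Z|, k)^2]`` keeping the estimate consistent for
    the normal SD. Iteration stops when both parameters move < ``tol``.
    """
    x = np.asarray(values, float)
    if x.size < 4:
        raise InputError(f"huber_proposal2 needs >= 4 values, got {x.size}")
    if np.ptp(x) == 0:
        raise ZeroScaleError("all values identical; scale is zero")
    beta = huber_consistency_beta(k)
    mu = float(np.median(x))
    sigma = float(np.median(np.abs(x - mu)) * MAD_SCALE)
    if sigma == 0:
        sigma = float(np.std(x))
    n = x.size
    for it in range(1, max_iter + 1):
        lo, hi = mu - k * sigma, mu + k * sigma
        wx = np.clip(x, lo, hi)
        mu_new = float(wx.mean())
        sigma_new = float(np.sqrt(np.sum((wx - mu_new) ** 2) / (n * beta)))
        done = abs(mu_new - mu) < tol and abs(sigma_new - sigma) < tol
        mu, sigma = mu_new, sigma_new
        if done:
            return RobustScale(mu, sigma, k, it, True)
    raise NonConvergenceError(
        f"Huber Proposal 2 did not converge in {max_iter} iterations",
        last_iterate=RobustScale(mu, sigma, k, max_iter, False),
    )


def call_hits(
    normalized: NormalizedScreen,
    threshold_sd: float = 3.0,
    scope: str = "library",
) -> pd.DataFrame:
    """Three-sigma hit calling against the library-wide sample distribution.

    Per condition (and per plate when ``scope="plate"``), the median of
    all normalized sample wells and the Huber Proposal 2 SD of the same
    distribution define the hit rule: a well is a hit iff its value is
    at least ``threshold_sd * sigma`` from the median (boundary
    inclusive); direction is anti-proliferative below the median,
    pro-proliferative above.
    """
    if scope not in ("library", "plate"):
        raise InputError(f"scope must be 'library' or 'plate', got {scope!r}")
    w = normalized.wells
    samples = w[w["well_type"] == "sample"]
    keys = ["condition"] if scope == "library" else ["plate", "condition"]
    out = []
    for key, grp in samples.groupby(keys, sort=False):
        vals = grp["normalized"].to_numpy(float)
        if vals.size < 50:
            warnings.warn(
                f"only {vals.size} sample wells for {key}; scale estimate "
                "may be unstable",
                UnstableScaleWarning,
                stacklevel=2,
            )
        med = float(np.median(vals))
        sigma = huber_proposal2(vals).sigma
        z = robust_z(vals, name=f"normalized sample wells {key}")
        dev = vals - med
        hit = np.abs(dev) >= threshold_sd * sigma
        direction = np.where(
            hit & (dev < 0),
            "anti-proliferative",
            np.where(hit & (dev > 0), "pro-proliferative", "none"),
        )
        tab = pd.DataFrame(
            {
                "gene": grp["gene"].to_numpy(),
                "condition": grp["condition"].to_numpy(),
                "value": vals,
                "z": z,
                "hit": hit,
                "direction": direction,
            }
        )
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def differential_response(
    hits_induced: pd.DataFrame,
    hits_uninduced: pd.DataFrame,
    delta_threshold: float = 2.0,
) -> pd.DataFrame:
    """Condition dependence of knockdown response: delta z between conditions.

    Returns one row per gene present in both hit tables with
    ``delta_z = z_induced - z_uninduced`` and a flag where
    ``|delta_z| >= delta_threshold``.
    """
    a = hits_induced.set_index("gene")
    b = hits_uninduced.set_index("gene")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        warnings.warn(
            "hit tables share no genes; differential response is empty",
            EmptyResultWarning,
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["gene", "z_induced", "z_uninduced", "delta_z", "condition_dependent"]
        )
    dz = a.loc[shared, "z"].to_numpy(float) - b.loc[shared, "z"].to_numpy(float)
    return pd.DataFrame(
        {
            "gene": shared.to_numpy(),
            "z_induced": a.loc[shared, "z"].to_numpy(float),
            "z_uninduced": b.loc[shared, "z"].to_numpy(float),
            "delta_z": dz,
            "condition_dependent": np.abs(dz) >= delta_threshold,
        }
    )
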