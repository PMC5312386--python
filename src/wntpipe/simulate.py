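"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its parameters and seed and emits
data in exactly the shapes the analysis modules consume: 384-well
screen plates with smooth spatial artifacts, edge control columns and
spiked gene effects in two induction conditions; per-contrast
differential-expression tables driven by planted regulator activity
states; and a tumour cohort (default 478 samples, minority
MYCN-amplified) whose signature-gene expression is coupled to a latent
regulator activity and to MYCN expression, with proportional-hazards
survival and uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .itr import RegulatorNetwork
from .screen import PlateSet
from .signature import Signature

N_ROWS, N_COLS = 16, 24


@dataclass
class ScreenTruth:
    """Planted spike effects (sigma units, signed) and surface parameters."""

    spikes: dict  # (gene, condition) -> effect in sigma units
    surfaces: dict = field(default_factory=dict)  # (plate, condition) -> coeffs
    noise_sd: float = 0.0


@dataclass
class CohortTruth:
    """Planted cohort structure: latent activity, hazard ratio, couplings."""

    activity: pd.Series
    hazard_ratio_per_unit: float
    mycn_b1: pd.Series
    directions: pd.Series


def _surface(rows, cols, coeffs):
    rc_ = (rows - 8.5) / 7.5
    cc_ = (cols - 12.5) / 11.5
    a1, a2, a3, a4, a5 = coeffs[:5]
    offset = coeffs[5] if len(coeffs) > 5 else 0.0
    return (
        a1 * rc_ + a2 * cc_ + a3 * rc_ * cc_ + a4 * rc_**2 + a5 * cc_**2 - offset
    )


def simulate_screen(
    n_genes: int = 2000,
    gradient_amplitude: float = 1.0,
    noise_sd: float = 0.3,
    spikes=None,
    conditions=("uninduced", "induced"),
    baseline: float = 10.0,
    control_columns=(1, 2, 23, 24),
    n_plates: int | None = None,
    seed: int = 0,
):
    """Simulate a pooled-siRNA viability screen on 384-well plates.

    Sample wells fill the columns outside ``control_columns`` plate by
    plate; log2 signal = baseline + planted low-order polynomial
    surface (coefficients ~ U(-1, 1) scaled by ``gradient_amplitude``)
    + gene spike effect + N(0, noise_sd). ``spikes`` is a list of
    ``(gene, condition, effect)`` with the effect in units of
    ``noise_sd`` (so -6 plants a well six SDs below baseline). Control
    wells sit at the constant baseline.

    Returns ``(PlateSet, ScreenTruth)``.
    """
    rng = np.random.default_rng(seed)
    control_columns = sorted(set(control_columns))
    sample_cols = [c for c in range(1, N_COLS + 1) if c not in control_columns]
    per_plate = N_ROWS * len(sample_cols)
    needed = int(np.ceil(n_genes / per_plate))
    if n_plates is None:
        n_plates = needed
    elif n_plates * per_plate < n_genes:
        raise InputError(
            f"{n_genes} genes exceed capacity of {n_plates} plates "
            f"({per_plate} sample wells each)"
        )
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    spike_map = {}
    for gene, cond, eff in spikes or []:
        if gene not in set(genes):
            raise InputError(f"spiked gene {gene!r} not on the plates")
        spike_map[(gene, cond)] = float(eff)

    # arrayed library layout: genes scattered over sample wells by a
    # seeded permutation, identical in both induction conditions
    slots = [
        (f"P{p:02d}", row, col)
        for p in range(1, n_plates + 1)
        for col in sample_cols
        for row in range(1, N_ROWS + 1)
    ]
    layout = {}
    for gene, slot_idx in zip(genes, rng.permutation(len(slots))[:n_genes]):
        layout[slots[slot_idx]] = gene

    # pre-evaluate the surface basis over sample wells so each planted
    # surface can be centred: artifacts are spatial, not plate offsets
    grid_r, grid_c = np.meshgrid(
        np.arange(1, N_ROWS + 1, dtype=float),
        np.asarray(sample_cols, dtype=float),
        indexing="ij",
    )

    records = []
    surfaces = {}
    for p in range(1, n_plates + 1):
        plate = f"P{p:02d}"
        for cond in conditions:
            coeffs = rng.uniform(-1, 1, 5) * gradient_amplitude
            offset = float(np.median(_surface(grid_r, grid_c, coeffs)))
            coeffs = np.append(coeffs, offset)
            surfaces[(plate, cond)] = coeffs.tolist()
            for col in range(1, N_COLS + 1):
                for row in range(1, N_ROWS + 1):
                    if col in control_columns:
                        records.append(
                            (plate, row, col, "CTRL", "control", cond,
                             2.0**baseline)
                        )
                        continue
                    gene = layout.get((plate, row, col))
                    if gene is None:
                        records.append(
                            (plate, row, col, "", "empty", cond, np.nan)
                        )
                        continue
                    log2sig = (
                        baseline
                        + _surface(float(row), float(col), coeffs)
                        + spike_map.get((gene, cond), 0.0) * noise_sd
                        + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    )
                    records.append(
                        (plate, row, col, gene, "sample", cond, 2.0**log2sig)
                    )
    wells = pd.DataFrame(
        records,
        columns=["plate", "row", "col", "gene", "well_type", "condition", "signal"],
    )
    return PlateSet(wells=wells), ScreenTruth(
        spikes=spike_map, surfaces=surfaces, noise_sd=noise_sd
    )


def random_network(
    n_regulators: int = 10,
    targets_per_regulator: int = 20,
    frac_unknown_sign: float = 0.1,
    seed: int = 0,
) -> RegulatorNetwork:
    """A synthetic signed, weighted regulator->target prior.

    Target pools are disjoint across regulators; edge signs are +/-1
    with a ``frac_unknown_sign`` fraction left unknown (NaN) and
    weights ~ U(0.5, 1.5).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_regulators):
        reg = f"REG{r + 1:03d}"
        for t in range(targets_per_regulator):
            sign = rng.choice([-1.0, 1.0])
            if rng.random() < frac_unknown_sign:
                sign = np.nan
            rows.append(
                (reg, f"T{r + 1:03d}_{t + 1:03d}", sign, rng.uniform(0.5, 1.5))
            )
    return RegulatorNetwork(
        edges=pd.DataFrame(rows, columns=["regulator", "target", "sign", "weight"])
    )


def simulate_contrasts(
    network: RegulatorNetwork,
    activity: dict,
    effect_mu: float = 2.0,
    noise_sd: float = 0.5,
    background_de_rate: float = 0.05,
    n_null_genes: int = 500,
    de_threshold: float = 0.05,
    seed: int = 0,
):
    """Differential-expression tables driven by planted regulator states.

    ``activity`` maps contrast id -> {regulator: state} with state in
    {-1, 0, +1}. Targets of an active regulator (with known edge sign)
    shift by state*sign*effect_mu; everything else is N(0, noise_sd).
    Adjusted p-values are assigned rank-consistently with |log2FC| so
    that ~``background_de_rate`` of non-target genes pass
    ``de_threshold``.

    Returns ``(tables, truth)``: a dict contrast -> DE DataFrame
    (columns contrast, gene, log2fc, padj) and a dict contrast ->
    {gene: planted direction}.
    """
    if effect_mu <= 0:
        raise InputError(f"effect_mu must be > 0, got {effect_mu}")
    unknown = set().union(*(set(a) for a in activity.values())) - set(
        network.regulators
    )
    if unknown:
        raise InputError(f"activity names regulators absent from network: "
                         f"{sorted(unknown)}")
    rng = np.random.default_rng(seed)
    universe = sorted(set(network.edges["target"])) + [
        f"NULL{i + 1:05d}" for i in range(n_null_genes)
    ]
    n = len(universe)
    tables, truth = {}, {}
    for contrast, states in activity.items():
        shift = pd.Series(0.0, index=universe)
        planted = {}
        for reg, state in states.items():
            if state == 0:
                continue
            edges = network.targets_of(reg)
            known = edges[np.isfinite(edges["sign"].astype(float))]
            for t, s in zip(known["target"], known["sign"].astype(float)):
                d = state * s
                shift[t] += d * effect_mu
                planted[t] = int(np.sign(planted.get(t, 0) + d))
        lfc = shift.to_numpy() + rng.normal(0.0, noise_sd, n)
        absl = np.abs(lfc)
        nontarget = ~np.isin(universe, list(planted))
        cut = (
            np.quantile(absl[nontarget], 1.0 - background_de_rate)
            if nontarget.any()
            else np.inf
        )
        order = np.argsort(-absl, kind="stable")
        m = max(int(np.sum(absl >= cut)), 1)
        padj = np.empty(n)
        ranks = np.empty(n, int)
        ranks[order] = np.arange(1, n + 1)
        in_top = ranks <= m
        padj[in_top] = de_threshold * ranks[in_top] / m
        padj[~in_top] = de_threshold + (1 - de_threshold) * (
            ranks[~in_top] - m
        ) / max(n - m, 1)
        tables[contrast] = pd.DataFrame(
            {"contrast": contrast, "gene": universe, "log2fc": lfc, "padj": padj}
        )
        truth[contrast] = planted
    return tables, truth


def simulate_cohort(
    signature: Signature,
    n_samples: int = 478,
    frac_amplified: float = 0.2,
    activity_effect: float = 1.0,
    mycn_coupling: float = 1.0,
    noise_sd: float = 0.5,
    hazard_ratio_per_unit: float = 3.0,
    censor_rate: float = 0.3,
    frac_active_nonamp: float = 0.05,
    n_extra_genes: int = 200,
    two_probe_frac: float = 0.5,
    weibull_shape: float = 1.0,
    baseline_median_days: float = 1500.0,
    seed: int = 0,
):
    """Simulate a tumour cohort with a latent regulator-activity group.

    The latent activity is 1 in every MYCN-amplified sample plus a
    ``frac_active_nonamp`` fraction of non-amplified ones, 0 elsewhere.
    MYCN log2 expression is drawn higher in amplified samples; each
    signature gene's probe value is

        direction * activity * activity_effect + b1 * MYCN + noise,

    with per-gene b1 = ``mycn_coupling`` * U(0.5, 1.5). Survival times
    follow a proportional-hazards Weibull (exponential by default) with
    hazard ratio ``hazard_ratio_per_unit`` per activity unit; uniform
    censoring is calibrated to ~``censor_rate``.

    Returns ``(expr, probe_map, clinical, truth)``.
    """
    if not (0 < frac_amplified < 1):
        raise InputError(f"frac_amplified must be in (0, 1), got {frac_amplified}")
    if signature.genes.empty:
        raise InputError("signature is empty")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    n_amp = int(round(frac_amplified * n_samples))
    amp = np.zeros(n_samples, int)
    amp[rng.permutation(n_samples)[:n_amp]] = 1
    mycn = np.where(amp == 1, rng.normal(11.0, 1.0, n_samples),
                    rng.normal(8.0, 1.0, n_samples))
    activity = amp.astype(float).copy()
    nonamp_idx = np.flatnonzero(amp == 0)
    extra = nonamp_idx[rng.random(len(nonamp_idx)) < frac_active_nonamp]
    activity[extra] = 1.0

    sig = signature.genes
    genes = list(sig["gene"])
    directions = sig["direction"].to_numpy(float)
    b1 = mycn_coupling * rng.uniform(0.5, 1.5, len(genes))
    rows, row_ids, map_probe, map_gene = [], [], [], []
    for j, g in enumerate(genes):
        mean = (
            directions[j] * activity * activity_effect
            + b1[j] * mycn
            + rng.normal(7.0, 1.0)
        )
        n_probes = 2 if rng.random() < two_probe_frac else 1
        for k in range(n_probes):
            pid = f"{g}_p{k + 1}"
            rows.append(mean + rng.normal(0.0, noise_sd, n_samples))
            row_ids.append(pid)
            map_probe.append(pid)
            map_gene.append(g)
    for i in range(n_extra_genes):
        g = f"BG{i + 1:04d}"
        rows.append(rng.normal(7.0, 1.0) + rng.normal(0.0, noise_sd, n_samples))
        row_ids.append(f"{g}_p1")
        map_probe.append(f"{g}_p1")
        map_gene.append(g)
    expr = pd.DataFrame(np.vstack(rows), index=row_ids, columns=samples)
    probe_map = pd.Series(map_gene, index=map_probe, name="gene")

    log_hr = np.log(hazard_ratio_per_unit)
    lam0 = np.log(2.0) / baseline_median_days**weibull_shape
    haz = lam0 * np.exp(log_hr * activity)
    T = (rng.exponential(1.0, n_samples) / haz) ** (1.0 / weibull_shape)
    if censor_rate <= 0:
        time, event = T, np.ones(n_samples, int)
    else:
        C = _calibrate_uniform_censor(T, censor_rate)
        U = rng.uniform(0.0, C, n_samples)
        event = (T <= U).astype(int)
        time = np.minimum(T, U)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time_days": np.maximum(time, 1e-3),
            "event": event,
            "mycn_amp": amp,
            "mycn_expr": mycn,
        }
    )
    truth = CohortTruth(
        activity=pd.Series(activity, index=samples, name="activity"),
        hazard_ratio_per_unit=hazard_ratio_per_unit,
        mycn_b1=pd.Series(b1, index=genes, name="b1"),
        directions=pd.Series(directions, index=genes, name="direction"),
    )
    return expr, probe_map, clinical, truth


def _calibrate_uniform_censor(T: np.ndarray, target: float) -> float:
    """Upper bound C of U(0, C) censoring giving ~target censored fraction.

    The expected censored fraction given the drawn event times is
    mean(min(T/C, 1)), monotone decreasing in C; solved by bisection.
    """
    lo, hi = 1e-9, float(T.max()) * 2

    def f(C):
        return float(np.mean(np.minimum(T / C, 1.0)))

    while f(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
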