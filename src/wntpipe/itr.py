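"""Inferred-transcriptional-regulator (ITR) scoring.

A candidate upstream regulator is scored against a differential-
expression result in two ways: a right-tail hypergeometric p-value for
the overlap between its known targets and the DE gene set, and an
activation z-score measuring direction concordance,

    z = sum(w_i * x_i) / sqrt(sum(w_i^2)),

where x_i = +1 when the edge's predicted regulation sign matches the
observed fold-change direction under the regulator-active hypothesis
and -1 when it contradicts it. |z| >= 2 conventionally labels the
regulator activated (z positive) or inhibited (z negative). The
regulator->target network is user-supplied; no proprietary knowledge
base is reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultWarning, InputError

NETWORK_COLUMNS = ["regulator", "target", "sign", "weight"]


@dataclass
class RegulatorNetwork:
    """Signed, weighted regulator->target edges (the ITR prior).

    ``edges`` has columns ``regulator``, ``target``, ``sign`` (+1, -1 or
    NaN for unknown) and ``weight`` (>= 0).
    """

    edges: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in NETWORK_COLUMNS if c not in self.edges.columns]
        if missing:
            raise InputError(f"network missing columns: {missing}")
        e = self.edges
        if e[["regulator", "target"]].duplicated().any():
            dup = e[e[["regulator", "target"]].duplicated()].iloc[0]
            raise InputError(
                f"duplicate edge {dup['regulator']!r} -> {dup['target']!r}"
            )
        w = e["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise InputError("edge weights must be finite and >= 0")
        s = e["sign"].to_numpy(float)
        known = s[np.isfinite(s)]
        if not np.all(np.isin(known, [-1.0, 1.0])):
            raise InputError("edge signs must be +1, -1 or NaN (unknown)")

    @property
    def regulators(self):
        return sorted(self.edges["regulator"].unique())

    def targets_of(self, regulator) -> pd.DataFrame:
        return self.edges[self.edges["regulator"] == regulator]


def overlap_pvalue(targets, de_genes, background) -> float:
    """Right-tail hypergeometric p for the target / DE-set overlap.

    Probability of drawing at least ``|targets & de_genes|`` of the
    ``|targets|`` marked genes when ``|de_genes|`` genes are drawn
    without replacement from ``background``.
    """
    targets, de_genes, background = set(targets), set(de_genes), set(background)
    if not background:
        raise InputError("background gene set is empty")
    if not targets <= background or not de_genes <= background:
        stray = (targets | de_genes) - background
        raise InputError(f"genes outside background: {sorted(stray)[:5]}")
    if not targets or not de_genes:
        warnings.warn("empty target or DE set; overlap p = 1", EmptyResultWarning,
                      stacklevel=2)
        return 1.0
    k = len(targets & de_genes)
    return float(stats.hypergeom.sf(k - 1, len(background), len(targets),
                                    len(de_genes)))


def activation_zscore(signs, weights, observed_directions) -> float | None:
    """Direction-concordance z of one regulator's DE-overlapping targets.

    ``signs``/``weights`` are the regulator's edges (aligned arrays;
    sign NaN = unknown), ``observed_directions`` the matching observed
    fold-change directions (+1/-1, 0 or NaN when the target is not DE).
    Returns None (undetermined) when no edge is usable.
    """
    s = np.asarray(signs, float)
    w = np.asarray(weights, float)
    d = np.asarray(observed_directions, float)
    usable = np.isfinite(s) & np.isfinite(d) & (d != 0) & (w > 0)
    if not usable.any():
        return None
    x = s[usable] * d[usable]  # +1 concordant, -1 discordant
    wu = w[usable]
    return float(np.sum(wu * x) / np.sqrt(np.sum(wu * wu)))


def _state_of(z: float | None, z_cutoff: float) -> str:
    if z is None:
        return "undetermined"
    if z >= z_cutoff:
        return "activated"
    if z <= -z_cutoff:
        return "inhibited"
    return "undetermined"


def infer_regulators(
    network: RegulatorNetwork,
    de: pd.DataFrame,
    contrast: str | None = None,
    de_threshold: float = 0.05,
    z_cutoff: float = 2.0,
    background=None,
) -> pd.DataFrame:
    """Score every network regulator against one DE table.

    ``de`` needs columns ``gene``, ``log2fc``, ``padj`` (plus optional
    ``contrast``). The DE set is ``padj <= de_threshold``; the
    background defaults to all genes in the DE table (the measured
    universe). Regulators are ranked by overlap p, ties broken by |z|
    (descending) then regulator id.
    """
    for col in ("gene", "log2fc", "padj"):
        if col not in de.columns:
            raise InputError(f"DE table missing column {col!r}")
    if contrast is None:
        contrast = str(de["contrast"].iloc[0]) if "contrast" in de.columns else "contrast"
    background = set(de["gene"]) if background is None else set(background)
    de_pass = de[de["padj"] <= de_threshold]
    de_genes = set(de_pass["gene"])
    direction = dict(zip(de_pass["gene"], np.sign(de_pass["log2fc"])))
    if not de_genes:
        warnings.warn(f"no genes pass padj <= {de_threshold}; empty ITR result",
                      EmptyResultWarning, stacklevel=2)

    rows = []
    for reg in network.regulators:
        edges = network.targets_of(reg)
        in_bg = edges[edges["target"].isin(background)]
        targets = set(in_bg["target"])
        contributing = sorted(targets & de_genes)
        p = (
            overlap_pvalue(targets, de_genes, background)
            if targets and de_genes
            else 1.0
        )
        z = activation_zscore(
            in_bg["sign"].to_numpy(float),
            in_bg["weight"].to_numpy(float),
            np.array([direction.get(t, np.nan) for t in in_bg["target"]]),
        )
        rows.append(
            {
                "regulator": reg,
                "contrast": contrast,
                "overlap": len(contributing),
                "p": p,
                "z": np.nan if z is None else z,
                "state": _state_of(z, z_cutoff),
                "contributing_genes": contributing,
                "contributing_directions": [int(direction[g]) for g in contributing],
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        order = res.assign(
            _absz=res["z"].abs().fillna(-1.0)
        ).sort_values(["p", "_absz", "regulator"], ascending=[True, False, True])
        res = res.loc[order.index].reset_index(drop=True)
        res["rank"] = np.arange(1, len(res) + 1)
    return res


def rank_regulators_binary(
    network: RegulatorNetwork, bound_genes, background
) -> pd.DataFrame:
    """Rank regulators by target overlap with a direction-less gene set.

    Used for e.g. ChIP-derived bound-gene lists: only the hypergeometric
    overlap p is computed; the activation z is undefined.
    """
    bound_genes, background = set(bound_genes), set(background)
    if not bound_genes <= background:
        raise InputError("bound genes must lie within the background")
    rows = []
    for reg in network.regulators:
        targets = set(network.targets_of(reg)["target"]) & background
        contributing = sorted(targets & bound_genes)
        p = (
            overlap_pvalue(targets, bound_genes, background)
            if targets and bound_genes
            else 1.0
        )
        rows.append(
            {
                "regulator": reg,
                "overlap": len(contributing),
                "p": p,
                "z": np.nan,
                "state": "undetermined",
                "contributing_genes": contributing,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res = res.sort_values(["p", "regulator"]).reset_index(drop=True)
        res["rank"] = np.arange(1, len(res) + 1)
    return res
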