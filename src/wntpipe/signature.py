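"""Regulator gene-signature construction and MYCN-corrected cohort analysis.

The beta-catenin activity signature is built from the genes that
contributed to calling the regulator an ITR in each cell-line contrast,
keeping genes supported by at least ``min_contrasts`` contrasts. Tumour
expression is corrected for MYCN expression by a per-probe linear model
(MYCN log2 expression + amplification status as covariates), removing
only the expression-level effect, in the manner of limma-style batch
effect removal. Samples are then split into Signature(+) / Signature(-)
groups by two-way hierarchical clustering of the standardized signature
probes, and separation of MYCN-amplified (MNA) from non-amplified
tumours is quantified with a one-way ANOVA F on the per-sample
signature score plus per-probe tests with Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import CoverageError, InputError


@dataclass
class Signature:
    """Gene list with expected regulation direction and contrast support.

    ``genes`` has columns ``gene``, ``direction`` (+1, -1 or 0 for
    unknown) and ``support`` (number of contrasts the gene contributed
    to).
    """

    regulator: str
    genes: pd.DataFrame

    def __post_init__(self):
        for col in ("gene", "direction", "support"):
            if col not in self.genes.columns:
                raise InputError(f"signature table missing column {col!r}")
        if self.genes["gene"].duplicated().any():
            raise InputError("duplicate genes in signature")

    def directions(self) -> dict:
        return dict(zip(self.genes["gene"], self.genes["direction"]))


@dataclass
class CorrectionModel:
    """Per-row linear fit y = b0 + b1*mycn_expr + b2*amp.

    ``coefficients`` is indexed by expression row id with columns
    ``b0``, ``b1``, ``b2`` and ``partial_r2`` (RSS reduction of the
    MYCN-expression term relative to the amplification-only model).
    """

    coefficients: pd.DataFrame
    mycn_mean: float


@dataclass
class GroupAssignment:
    """Signature(+)/Signature(-) sample groups with per-sample scores."""

    labels: pd.Series
    scores: pd.Series
    linkage: np.ndarray = field(repr=False, default=None)


def build_signature(
    itr_results: pd.DataFrame, regulator: str, min_contrasts: int = 2
) -> Signature:
    """Union of a regulator's contributing genes across contrasts.

    Keeps genes contributing in at least ``min_contrasts`` contrasts;
    the expected direction is the majority observed DE direction across
    supporting contrasts (0 = unknown on a tie).
    """
    res = itr_results[itr_results["regulator"] == regulator]
    if res.empty:
        raise InputError(f"regulator {regulator!r} absent from ITR results")
    if res["contrast"].nunique() < 2:
        raise InputError(
            f"need >= 2 scored contrasts for {regulator!r}, "
            f"got {res['contrast'].nunique()}"
        )
    support: dict = {}
    dirsum: dict = {}
    for _, row in res.iterrows():
        dirs = row.get("contributing_directions")
        genes = row["contributing_genes"]
        if dirs is None or (isinstance(dirs, float) and np.isnan(dirs)):
            dirs = [0] * len(genes)
        for g, d in zip(genes, dirs):
            support[g] = support.get(g, 0) + 1
            dirsum[g] = dirsum.get(g, 0) + d
    kept = sorted(g for g, s in support.items() if s >= min_contrasts)
    table = pd.DataFrame(
        {
            "gene": kept,
            "direction": [int(np.sign(dirsum[g])) for g in kept],
            "support": [support[g] for g in kept],
        }
    )
    return Signature(regulator=regulator, genes=table)


def fit_mycn_model(
    expr: pd.DataFrame, mycn_expr: pd.Series, amp_status: pd.Series
) -> CorrectionModel:
    """Per-row OLS of expression on MYCN expression and amplification.

    ``expr`` is rows (probes/genes) x samples; ``mycn_expr`` (log2) and
    ``amp_status`` (0/1) are indexed by sample. Reports the partial R^2
    of the MYCN-expression covariate per row.
    """
    samples = expr.columns
    mycn = mycn_expr.loc[samples].to_numpy(float)
    amp = amp_status.loc[samples].to_numpy(float)
    n = len(samples)
    if n < 10:
        raise InputError(f"need >= 10 samples, got {n}")
    if len(np.unique(amp)) < 2:
        raise InputError("both amplification classes must be present")
    if np.ptp(mycn) == 0:
        raise InputError("MYCN expression is constant")

    X = np.column_stack([np.ones(n), mycn, amp])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(
            f"MYCN expression and amplification nearly collinear "
            f"(condition number {cond:.2g}); coefficients unstable",
            UserWarning,
            stacklevel=2,
        )
    Y = expr.to_numpy(float).T  # samples x rows
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss_full = np.sum(resid**2, axis=0)

    X0 = X[:, [0, 2]]  # amplification-only model
    beta0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
    rss_red = np.sum((Y - X0 @ beta0) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        partial_r2 = np.where(rss_red > 0, (rss_red - rss_full) / rss_red, 0.0)
    partial_r2 = np.clip(partial_r2, 0.0, 1.0)

    # constant rows carry no signal: zero out their covariate effects
    const = np.ptp(Y, axis=0) == 0
    beta[1, const] = 0.0
    beta[2, const] = 0.0
    partial_r2[const] = 0.0

    coef = pd.DataFrame(
        {"b0": beta[0], "b1": beta[1], "b2": beta[2], "partial_r2": partial_r2},
        index=expr.index,
    )
    return CorrectionModel(coefficients=coef, mycn_mean=float(mycn.mean()))


def correct_matrix(
    expr: pd.DataFrame, model: CorrectionModel, mycn_expr: pd.Series
) -> pd.DataFrame:
    """Remove the MYCN-expression effect, retaining the amplification effect.

    corrected = y - b1 * (mycn_expr - mean(mycn_expr)); centring keeps
    the overall expression level of each row unchanged.
    """
    if not expr.index.equals(model.coefficients.index):
        raise InputError("correction model was fitted on different rows")
    missing = [s for s in expr.columns if s not in mycn_expr.index]
    if missing:
        raise InputError(f"samples without MYCN expression: {missing[:5]}")
    mycn = mycn_expr.loc[expr.columns].to_numpy(float)
    b1 = model.coefficients["b1"].to_numpy(float)
    centred = mycn - model.mycn_mean
    return expr - np.outer(b1, centred)


def signature_scores(
    expr: pd.DataFrame, signature: Signature, probe_map: pd.Series | None = None
) -> pd.Series:
    """Per-sample signature score: mean direction-aligned standardized expression.

    Probes of unknown-direction genes do not enter the score.
    """
    sub, directions = _signature_submatrix(expr, signature, probe_map)
    z = _standardize_rows(sub)
    directed = directions != 0
    if not directed.any():
        return pd.Series(0.0, index=expr.columns, name="signature_score")
    score = (z.to_numpy(float)[directed] * directions[directed, None]).mean(axis=0)
    return pd.Series(score, index=expr.columns, name="signature_score")


def _signature_submatrix(expr, signature, probe_map):
    if probe_map is None:
        probe_gene = pd.Series(expr.index, index=expr.index)
    else:
        probe_gene = probe_map
    sig_genes = set(signature.genes["gene"])
    probes = [p for p in expr.index if probe_gene.get(p) in sig_genes]
    found_genes = {probe_gene.get(p) for p in probes}
    missing = sorted(sig_genes - found_genes)
    if len(probes) < 2:
        raise CoverageError(
            f"only {len(probes)} signature probes found in matrix; "
            f"missing genes: {missing}",
            missing=missing,
        )
    dirmap = signature.directions()
    directions = np.array([dirmap[probe_gene[p]] for p in probes], int)
    return expr.loc[probes], directions


def _standardize_rows(sub: pd.DataFrame) -> pd.DataFrame:
    vals = sub.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=sub.index, columns=sub.columns)


def cluster_signature(
    expr: pd.DataFrame,
    signature: Signature,
    probe_map: pd.Series | None = None,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> GroupAssignment:
    """Two-way split of samples on standardized signature probes.

    Agglomerative hierarchical clustering of samples (default Ward on
    Euclidean distances) cut at the top merge; the group with the
    higher mean signature score is labelled ``signature_plus``, making
    the polarity reproducible across runs.
    """
    if expr.shape[1] < 4:
        raise InputError(f"need >= 4 samples to cluster, got {expr.shape[1]}")
    sub, _ = _signature_submatrix(expr, signature, probe_map)
    z = _standardize_rows(sub)
    data = z.to_numpy(float).T  # samples x probes
    Z = hierarchy.linkage(pdist(data, metric=metric), method=linkage)
    labels_num = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    scores = signature_scores(expr, signature, probe_map)
    means = {g: scores[labels_num == g].mean() for g in np.unique(labels_num)}
    plus = max(means, key=means.get)
    labels = pd.Series(
        np.where(labels_num == plus, "signature_plus", "signature_minus"),
        index=expr.columns,
        name="group",
    )
    return GroupAssignment(labels=labels, scores=scores, linkage=Z)


def mna_separation_test(
    scores: pd.Series,
    amp_status: pd.Series,
    expr: pd.DataFrame | None = None,
    alpha: float = 0.05,
):
    """MNA vs non-MNA separation: score ANOVA plus per-probe DE flags.

    Returns ``(F, p, probe_table)``: the one-way ANOVA F (df 1, n-2) of
    the per-sample signature score by amplification status, and — when
    ``expr`` is given — per-probe two-sample t tests with
    Benjamini-Hochberg adjusted p-values and a ``significant`` flag at
    ``p_adj < alpha``.
    """
    amp = amp_status.loc[scores.index].astype(int)
    g0, g1 = scores[amp == 0], scores[amp == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise InputError(
            f"each amplification class needs >= 2 samples "
            f"(got {len(g0)} and {len(g1)})"
        )
    F, p = stats.f_oneway(g0.to_numpy(float), g1.to_numpy(float))
    probe_table = None
    if expr is not None:
        vals = expr.to_numpy(float)
        a = vals[:, (amp == 1).to_numpy()]
        b = vals[:, (amp == 0).to_numpy()]
        t, praw = stats.ttest_ind(a, b, axis=1)
        _, padj, _, _ = multipletests(praw, method="fdr_bh")
        probe_table = pd.DataFrame(
            {
                "t": t,
                "p": praw,
                "p_adj": padj,
                "significant": padj < alpha,
            },
            index=expr.index,
        )
    return float(F), float(p), probe_table
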