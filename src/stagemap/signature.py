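"""Derivation of monotone disease-progression gene signatures.

A cohort spans five ordinal stages (healthy marrow, three progression-risk
strata, overt leukemia).  Per gene, a one-way fixed-effects ANOVA across the
stages gives an omnibus p-value, moderated by Benjamini–Hochberg FDR; the
least-squares means of each stage (plain group means in this one-factor
design) give four adjacent-stage log2 fold changes.  Genes passing the FDR
gate whose four adjacent fold changes are all strictly positive (or all
strictly negative) form the consistently increasing / decreasing lists —
strict adjacent monotonicity of the five stage means implies monotonicity of
every pairwise stage comparison.  The top-d of each list, ranked by p-value,
are combined into nested signed-rank query signatures for connectivity
mapping.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, ExpressionMatrix, GeneSignature, SampleAnnotation

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS: tuple[int, ...] = (10, 20, 30, 40, 50)

# Sums of squares below this (relative) floor are treated as exactly zero:
# a gene constant across all samples is reported as F = 0, p = 1, and a gene
# with zero within-group scatter but distinct group means as F = inf, p = 0.
_ZERO_SS_ATOL_FACTOR = 64.0


def _group_column_indices(X: ExpressionMatrix, ann: SampleAnnotation) -> list[np.ndarray]:
    cols = pd.Index(X.sample_ids)
    out = []
    for g in ann.group_order:
        idx = cols.get_indexer(ann.samples_in(g))
        if (idx < 0).any():
            raise ConfigurationError(f"samples of group {g!r} missing from expression matrix")
        out.append(idx)
    return out


def anova_per_gene(X: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across stages, vectorized over genes.

    Returns a DataFrame indexed by gene id with columns ``F`` and ``p``.
    A gene with zero between- and within-group variance gets F = 0, p = 1.
    """
    groups = _group_column_indices(X, ann)
    if len(groups) < 2:
        raise ConfigurationError("anova_per_gene: need >= 2 groups")
    V = X.values.to_numpy(dtype=float)
    n_total = sum(len(g) for g in groups)
    k = len(groups)

    group_means = np.column_stack([V[:, idx].mean(axis=1) for idx in groups])  # G x k
    counts = np.array([len(idx) for idx in groups], dtype=float)
    grand = (group_means * counts).sum(axis=1) / n_total

    ssb = (counts * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(V.shape[0])
    for j, idx in enumerate(groups):
        ssw += ((V[:, idx] - group_means[:, [j]]) ** 2).sum(axis=1)

    eps = np.finfo(float).eps
    atol = n_total * (_ZERO_SS_ATOL_FACTOR * eps * (1.0 + np.abs(grand))) ** 2
    ssb = np.where(ssb <= atol, 0.0, ssb)
    ssw = np.where(ssw <= atol, 0.0, ssw)

    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    F = np.where((ssw == 0) & (ssb == 0), 0.0, F)
    F = np.where((ssw == 0) & (ssb > 0), np.inf, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w))
    p = np.where((ssw == 0) & (ssb == 0), 1.0, p)
    return pd.DataFrame({"F": F, "p": p}, index=X.values.index)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1 or np.isnan(p).any()):
        raise ConfigurationError("bh_fdr: p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def stage_means(X: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Least-squares means per stage (group means in a one-factor design)."""
    groups = _group_column_indices(X, ann)
    V = X.values.to_numpy(dtype=float)
    M = np.column_stack([V[:, idx].mean(axis=1) for idx in groups])
    return pd.DataFrame(M, index=X.values.index, columns=list(ann.group_order))


def adjacent_fold_changes(X: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Signed log2 fold changes for each adjacent ordered stage pair.

    Fold change of pair (g_k, g_{k+1}) is mean(g_{k+1}) - mean(g_k) on the
    log2 scale, so columns ``fc1..fc{K-1}`` for K ordered stages.
    """
    if len(ann.group_order) < 2:
        raise ConfigurationError("adjacent_fold_changes: need >= 2 ordered stages")
    M = stage_means(X, ann).to_numpy()
    fc = np.diff(M, axis=1)
    cols = [f"fc{i+1}" for i in range(fc.shape[1])]
    return pd.DataFrame(fc, index=X.values.index, columns=cols)


def differential_analysis(X: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Full per-gene differential table: F, p, BH q, adjacent fold changes, trend.

    ``trend`` is +1 when every adjacent fold change is strictly positive, -1
    when all strictly negative, 0 otherwise.  ``span`` (mean of the last stage
    minus the first) is carried for deterministic tie-breaking when ranking.
    """
    res = anova_per_gene(X, ann)
    res["q"] = bh_fdr(res["p"].to_numpy())
    fc = adjacent_fold_changes(X, ann)
    fcv = fc.to_numpy()
    trend = np.where((fcv > 0).all(axis=1), 1, np.where((fcv < 0).all(axis=1), -1, 0))
    out = pd.concat([res, fc], axis=1)
    out["trend"] = trend
    out["span"] = fcv.sum(axis=1)
    out.index.name = "gene_id"
    return out


def monotone_filter(diff: pd.DataFrame, q_threshold: float = 0.05) -> tuple[list[str], list[str]]:
    """Consistently increasing / decreasing gene lists, sorted by ascending p.

    A gene qualifies when its BH q-value is <= ``q_threshold`` and its
    adjacent fold changes are all strictly positive (increasing) or all
    strictly negative (decreasing).  Ties in p break by larger absolute span
    (first-to-last stage mean difference), then lexicographic gene id.
    """
    passing = diff[diff["q"] <= q_threshold].reset_index()

    def _sorted_ids(sub: pd.DataFrame) -> list[str]:
        order = sub.assign(_abs_span=sub["span"].abs()).sort_values(
            by=["p", "_abs_span", "gene_id"], ascending=[True, False, True]
        )
        return list(order["gene_id"])

    return (
        _sorted_ids(passing[passing["trend"] == 1]),
        _sorted_ids(passing[passing["trend"] == -1]),
    )


def restrict_universe(gene_lists: Sequence[Sequence[str]], universe: Iterable[str]) -> list[list[str]]:
    """Drop genes absent from ``universe`` from each list, preserving order."""
    uni = set(universe)
    if not uni:
        raise ConfigurationError("restrict_universe: universe must be nonempty")
    out = []
    for lst in gene_lists:
        kept = [g for g in lst if g in uni]
        if lst and not kept:
            logger.warning("restrict_universe: a gene list became empty after restriction")
        out.append(kept)
    return out


def build_signatures(
    increasing: Sequence[str],
    decreasing: Sequence[str],
    depths: Sequence[int] = DEFAULT_DEPTHS,
) -> list[GeneSignature]:
    """Nested signed-rank signatures from the ranked gene lists.

    For each depth d the top-d increasing genes get ranks +d (most
    significant) down to +1, and the top-d decreasing genes -d down to -1, so
    a depth-d signature has 2d genes and shallower signatures are subsets of
    deeper ones.  Depths exceeding either list length are skipped with a
    warning.
    """
    sigs = []
    for d in sorted(set(int(d) for d in depths)):
        if d < 1:
            raise ConfigurationError("build_signatures: depths must be >= 1")
        if len(increasing) < d or len(decreasing) < d:
            logger.warning("build_signatures: depth %d exceeds list lengths (%d up, %d down); skipped",
                           d, len(increasing), len(decreasing))
            continue
        entries = [(increasing[i], d - i) for i in range(d)]
        entries += [(decreasing[i], -(d - i)) for i in range(d)]
        sigs.append(GeneSignature(entries=entries, signature_id=f"top{d}"))
    return sigs
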