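"""Statistically significant connectivity mapping.

A query signature is an ordered list of genes with signed integer ranks q_i
(sign = direction of regulation, magnitude = extremity).  A reference profile
assigns every gene g of a common universe of size N a signed rank r(g) whose
magnitudes are a permutation of {1..N}.  The connection strength is the
normalized signed-rank inner product

    c = sum_i q_i * r(g_i) / max_score,
    max_score = sum_k |q|_(k) * (N - k + 1),

where |q|_(1) >= |q|_(2) >= ... are the sorted signature rank magnitudes, so
c lies in [-1, 1] and reaches +1 exactly when the signature genes occupy the
top reference positions with matching signs and magnitude order.  Negative
connections mark perturbagens whose expression response opposes the query
pattern — candidate inhibitors of the queried disease process.

Significance comes from a permutation null: random signatures of the same
length, drawn by sampling distinct genes uniformly from the universe and
assigning them the observed signed-rank multiset in random order, are scored
against the reference set; the two-sided empirical p-value is
(#{|c_rand| >= |c_obs|} + 1) / (K + 1).  The per-analysis significance cutoff
is set by an accepted number of false positives per analysis divided by the
number of reference profiles compared.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    GeneSignature,
    MissingGenesError,
    RefSet,
    ReferenceProfile,
    child_seed,
)

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 10_000
_CHUNK_ROWS = 2048


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

def build_reference_profile(
    stats: Mapping[str, float],
    instance_id: str,
    perturbagen: str,
    cell_line: str,
    dose: str | None = None,
    universe: Sequence[str] | None = None,
) -> ReferenceProfile:
    """Convert per-gene differential statistics into a signed-rank profile.

    Genes are ranked by |statistic| descending: the most extreme gene gets
    magnitude N, the least extreme magnitude 1; each gene's rank carries the
    sign of its statistic.  Ties in |statistic| break lexicographically by
    gene id; zero statistics sort last (smallest magnitudes) and take
    positive sign.
    """
    if universe is None:
        universe = sorted(stats)
    missing = [g for g in universe if g not in stats]
    if missing:
        raise MissingGenesError(missing, context=f"stats for instance {instance_id}")
    values = np.array([float(stats[g]) for g in universe])
    if not np.isfinite(values).all():
        raise ConfigurationError(f"build_reference_profile: non-finite statistic in {instance_id}")

    n = len(universe)
    # primary key |stat| descending, ties by gene id ascending; zeros sort last
    order = np.lexsort((np.asarray(universe, dtype=object), -np.abs(values)))
    mags = n - np.arange(n)
    vals_sorted = values[order]
    signs = np.where(vals_sorted > 0, 1, np.where(vals_sorted < 0, -1, 1))
    signed = np.empty(n, dtype=np.int64)
    signed[order] = signs * mags
    ranks = pd.Series(signed, index=list(universe))
    return ReferenceProfile(
        instance_id=instance_id, perturbagen=perturbagen, cell_line=cell_line,
        dose=dose, signed_ranks=ranks,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def max_connection_score(rank_magnitudes: Sequence[int] | np.ndarray, n_universe: int) -> float:
    """Largest achievable |raw score| for a signature over a size-N universe."""
    mags = np.sort(np.abs(np.asarray(rank_magnitudes, dtype=float)))[::-1]
    if len(mags) > n_universe:
        raise ConfigurationError("max_connection_score: signature longer than universe")
    top = n_universe - np.arange(len(mags))
    return float((mags * top).sum())


def connection_score(
    sig: GeneSignature,
    ref: ReferenceProfile,
    drop_missing: bool = False,
) -> tuple[float, float]:
    """Raw and normalized connection score of a signature against one profile.

    Missing signature genes raise :class:`MissingGenesError` unless
    ``drop_missing`` is set, in which case they are logged, dropped, and the
    normalizing maximum recomputed over the remaining ranks.
    """
    r = ref.signed_ranks
    present = [(g, q) for g, q in sig.entries if g in r.index]
    missing = [g for g, _ in sig.entries if g not in r.index]
    if missing:
        if not drop_missing:
            raise MissingGenesError(missing, context=f"profile {ref.instance_id}")
        logger.warning("connection_score: dropping %d missing genes from %s", len(missing), sig.signature_id)
    if not present:
        raise ConfigurationError("connection_score: no signature genes in the universe")
    q = np.array([qi for _, qi in present], dtype=float)
    rv = r.loc[[g for g, _ in present]].to_numpy(dtype=float)
    raw = float((q * rv).sum())
    max_score = max_connection_score(q, len(r))
    return raw, raw / max_score


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _count_extreme_random(
    q: np.ndarray,
    rank_matrix: np.ndarray,
    abs_obs_raw: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    randomize_signs: bool = False,
) -> np.ndarray:
    """#{random signatures with |raw| >= |raw_obs|}, per reference instance.

    Random signatures keep the observed signed-rank multiset ``q`` and draw m
    distinct genes uniformly from the universe, assigning the multiset in
    random order.  Products of integer ranks are exact in float64, so ties
    with the observed score count exactly.
    """
    m = len(q)
    n_inst, n_uni = rank_matrix.shape
    if m >= n_uni:
        raise ConfigurationError("permutation null: signature length must be < universe size")
    counts = np.zeros(n_inst, dtype=np.int64)
    Rt = rank_matrix.T.astype(float)
    done = 0
    while done < n_permutations:
        b = min(_CHUNK_ROWS, n_permutations - done)
        keys = rng.random((b, n_uni))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        qperm = rng.permuted(np.tile(q.astype(float), (b, 1)), axis=1)
        if randomize_signs:
            qperm *= rng.choice([-1.0, 1.0], size=qperm.shape)
        Q = np.zeros((b, n_uni))
        np.put_along_axis(Q, idx, qperm, axis=1)
        raw = Q @ Rt
        counts += (np.abs(raw) >= abs_obs_raw[None, :]).sum(axis=0)
        done += b
    return counts


def _signature_child_seed(master_seed: int, signature_id: str) -> np.random.SeedSequence:
    # CRC32 of the id keeps the null draw independent of iteration order
    return child_seed(master_seed, zlib.crc32(signature_id.encode()))


def permutation_pvalue(
    sig: GeneSignature,
    ref: ReferenceProfile | RefSet,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    randomize_signs: bool = False,
) -> float | pd.Series:
    """Two-sided empirical permutation p-value(s) for a signature.

    Against a single profile, returns one float; against a reference set,
    returns a Series of p-values indexed by instance id (one shared set of
    random signatures, as the null depends only on the signature length and
    rank multiset).  p = (#{|c_rand| >= |c_obs|} + 1) / (K + 1), never zero.
    """
    if n_permutations < 1:
        raise ConfigurationError("permutation_pvalue: n_permutations must be >= 1")
    single = isinstance(ref, ReferenceProfile)
    refset = RefSet(gene_universe=list(ref.signed_ranks.index), profiles=[ref]) if single else ref
    q = sig.ranks.astype(float)
    R = refset.rank_matrix()
    pos = pd.Index(refset.gene_universe).get_indexer(sig.genes)
    if (pos < 0).any():
        raise MissingGenesError([g for g, i in zip(sig.genes, pos) if i < 0], context="refset universe")
    obs_raw = R[:, pos] @ q
    rng = np.random.default_rng(_signature_child_seed(seed, sig.signature_id))
    counts = _count_extreme_random(q, R, np.abs(obs_raw), n_permutations, rng, randomize_signs)
    p = (counts + 1) / (n_permutations + 1)
    if single:
        return float(p[0])
    return pd.Series(p, index=[prof.instance_id for prof in refset.profiles])


# ---------------------------------------------------------------------------
# significance threshold and batch connection
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPolicy:
    """Expected-false-positive significance policy.

    The p-value cutoff is the accepted number of false positives per analysis
    divided by the number of comparisons (reference profiles) made.
    """

    false_positives_per_analysis: float = 1.0
    n_comparisons: int = 1

    def validate(self) -> None:
        if self.n_comparisons < 1:
            raise ConfigurationError("ThresholdPolicy: n_comparisons must be >= 1")
        if not (0 < self.false_positives_per_analysis <= self.n_comparisons):
            raise ConfigurationError("ThresholdPolicy: cutoff must lie in (0, 1]")


def significance_threshold(policy: ThresholdPolicy) -> tuple[float, float]:
    """P-value cutoff and its -log10 form for a threshold policy."""
    policy.validate()
    cutoff = policy.false_positives_per_analysis / policy.n_comparisons
    return cutoff, float(-np.log10(cutoff))


def connect_all(
    signatures: Sequence[GeneSignature],
    refset: RefSet,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    policy: ThresholdPolicy | None = None,
    randomize_signs: bool = False,
) -> pd.DataFrame:
    """Score every signature against every reference instance.

    Returns one row per (signature, instance) with the normalized score, the
    permutation p-value, its -log10 form, and the significance call at the
    policy cutoff, sorted by ascending p-value.  Reproducible for a fixed
    master seed regardless of signature order.
    """
    if policy is None:
        policy = ThresholdPolicy(false_positives_per_analysis=1.0, n_comparisons=len(refset))
    cutoff, _ = significance_threshold(policy)
    R = refset.rank_matrix()
    uni_index = pd.Index(refset.gene_universe)
    n_uni = len(uni_index)

    frames = []
    for sig in signatures:
        q = sig.ranks.astype(float)
        pos = uni_index.get_indexer(sig.genes)
        if (pos < 0).any():
            raise MissingGenesError([g for g, i in zip(sig.genes, pos) if i < 0], context="refset universe")
        obs_raw = R[:, pos] @ q
        max_score = max_connection_score(q, n_uni)
        scores = obs_raw / max_score
        rng = np.random.default_rng(_signature_child_seed(seed, sig.signature_id))
        counts = _count_extreme_random(q, R, np.abs(obs_raw), n_permutations, rng, randomize_signs)
        p = (counts + 1) / (n_permutations + 1)
        frames.append(
            pd.DataFrame(
                {
                    "signature_id": sig.signature_id,
                    "instance_id": [prof.instance_id for prof in refset.profiles],
                    "perturbagen": [prof.perturbagen for prof in refset.profiles],
                    "cell_line": [prof.cell_line for prof in refset.profiles],
                    "score": scores,
                    "p_value": p,
                    "neg_log10_p": -np.log10(p),
                    "significant": p <= cutoff,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["p_value", "signature_id", "instance_id"], kind="mergesort").reset_index(drop=True)


def select_hits(
    results: pd.DataFrame,
    min_signatures: int = 2,
    direction: str = "negative",
) -> pd.DataFrame:
    """Perturbagen-level hit table from per-instance connection results.

    A hit is a perturbagen with significant connections of the required sign
    for at least ``min_signatures`` distinct signatures.  Reports connection
    and signature counts, the best p-value, and the mean score.
    """
    if results.empty:
        raise ConfigurationError("select_hits: results table is empty")
    if direction not in ("negative", "positive"):
        raise ConfigurationError("select_hits: direction must be 'negative' or 'positive'")
    sign_ok = results["score"] < 0 if direction == "negative" else results["score"] > 0
    sub = results[results["significant"] & sign_ok]
    if sub.empty:
        return pd.DataFrame(
            columns=["perturbagen", "n_connections", "n_signatures", "best_p", "mean_score"]
        )
    agg = (
        sub.groupby("perturbagen")
        .agg(
            n_connections=("instance_id", "size"),
            n_signatures=("signature_id", "nunique"),
            best_p=("p_value", "min"),
            mean_score=("score", "mean"),
        )
        .reset_index()
    )
    hits = agg[agg["n_signatures"] >= min_signatures]
    return hits.sort_values(["best_p", "perturbagen"], kind="mergesort").reset_index(drop=True)
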