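"""Connectivity scoring, permutation null, thresholds, and hit selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stagemap import (
    ConfigurationError,
    GeneSignature,
    MissingGenesError,
    RefSet,
    ReferenceProfile,
    ThresholdPolicy,
    build_reference_profile,
    connect_all,
    connection_score,
    max_connection_score,
    permutation_pvalue,
    select_hits,
    significance_threshold,
    simulate_refset,
    RefSetSpec,
)


def make_profile(signed, instance_id="i0", perturbagen="cmpd", cell_line="HL-60"):
    return ReferenceProfile(
        instance_id=instance_id, perturbagen=perturbagen, cell_line=cell_line,
        signed_ranks=pd.Series(signed),
    )


class TestBuildReferenceProfile:
    def test_hand_sorted_example(self):
        stats = {"A": 2.0, "B": -1.5, "E": 1.0, "C": 0.5, "D": -0.1}
        prof = build_reference_profile(stats, "i", "x", "HL-60")
        assert dict(prof.signed_ranks) == {"A": 5, "B": -4, "E": 3, "C": 2, "D": -1}

    def test_all_negative_stats(self):
        stats = {f"g{i}": -float(i + 1) for i in range(6)}
        prof = build_reference_profile(stats, "i", "x", "")
        ranks = prof.signed_ranks
        assert (ranks < 0).all()
        assert np.array_equal(np.sort(-ranks.to_numpy()), np.arange(1, 7))

    def test_negated_stats_negate_ranks(self):
        rng = np.random.default_rng(2)
        stats = {f"g{i}": v for i, v in enumerate(rng.normal(size=20))}
        p1 = build_reference_profile(stats, "i", "x", "")
        p2 = build_reference_profile({g: -v for g, v in stats.items()}, "i", "x", "")
        assert (p1.signed_ranks == -p2.signed_ranks).all()

    def test_zero_stats_positive_smallest_magnitudes(self):
        stats = {"A": 3.0, "B": 0.0, "C": 0.0, "D": -2.0}
        prof = build_reference_profile(stats, "i", "x", "")
        assert dict(prof.signed_ranks) == {"A": 4, "D": -3, "B": 2, "C": 1}

    def test_missing_gene_listed(self):
        with pytest.raises(MissingGenesError, match="B"):
            build_reference_profile({"A": 1.0}, "i", "x", "", universe=["A", "B"])


class TestConnectionScore:
    def test_perfect_match_scores_one(self):
        prof = make_profile({"A": 5, "B": -4, "C": 3, "D": 2, "E": 1})
        sig = GeneSignature(entries=[("A", 1)], signature_id="s")
        _, c = connection_score(sig, prof)
        assert c == pytest.approx(1.0, abs=1e-15)

    def test_antisymmetry(self):
        prof = make_profile({"A": 5, "B": -4, "C": 3, "D": 2, "E": 1})
        sig = GeneSignature(entries=[("A", 1)], signature_id="s")
        _, c_neg = connection_score(sig.negated(), prof)
        assert c_neg == pytest.approx(-1.0, abs=1e-15)

    def test_hand_arithmetic_example(self):
        """raw = 2*2 + (-1)*3 = 1; max = 2*5 + 1*4 = 14; c = 1/14."""
        prof = make_profile({"A": 5, "B": -4, "E": 3, "C": 2, "D": -1})
        sig = GeneSignature(entries=[("C", 2), ("E", -1)], signature_id="s")
        raw, c = connection_score(sig, prof)
        assert raw == pytest.approx(1.0)
        assert c == pytest.approx(1.0 / 14.0, abs=1e-15)

    def test_extremal_configuration_negative_one(self):
        # signature genes occupy top positions with opposing signs, ordered
        prof = make_profile({"A": -6, "B": 5, "C": 4, "D": 3, "E": -2, "F": 1})
        sig = GeneSignature(entries=[("A", 2), ("B", -1)], signature_id="s")
        _, c = connection_score(sig, prof)
        assert c == pytest.approx(-1.0, abs=1e-15)

    def test_non_signature_gene_permutation_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        mags = rng.permutation(np.arange(1, 21))
        signs = rng.choice([-1, 1], size=20)
        ranks = dict(zip(genes, mags * signs))
        sig = GeneSignature(entries=[("g0", 2), ("g1", 1), ("g2", -1)], signature_id="s")
        _, c1 = connection_score(sig, make_profile(ranks))
        # permute the identities of the non-signature genes only
        others = genes[3:]
        shuffled = list(rng.permutation(others))
        remap = dict(zip(others, shuffled))
        ranks2 = {remap.get(g, g): r for g, r in ranks.items()}
        _, c2 = connection_score(sig, make_profile(ranks2))
        assert c2 == pytest.approx(c1, abs=1e-15)

    def test_missing_gene_raises_unless_dropped(self):
        prof = make_profile({"A": 2, "B": -1})
        sig = GeneSignature(entries=[("A", 2), ("Z", 1)], signature_id="s")
        with pytest.raises(MissingGenesError, match="Z"):
            connection_score(sig, prof)
        raw, c = connection_score(sig, prof, drop_missing=True)
        assert raw == pytest.approx(4.0) and c == pytest.approx(1.0)

    def test_bound_holds_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            genes = [f"g{i}" for i in range(n)]
            ranks = dict(zip(genes, rng.permutation(np.arange(1, n + 1)) * rng.choice([-1, 1], n)))
            m = int(rng.integers(1, min(4, n)))
            chosen = list(rng.choice(genes, size=m, replace=False))
            qm = rng.permutation(np.arange(1, m + 1))
            qs = rng.choice([-1, 1], m)
            # rebuild a valid contiguous signed-rank multiset
            pos = sorted([int(v) for v, s in zip(qm, qs) if s > 0], reverse=True)
            neg = sorted([int(v) for v, s in zip(qm, qs) if s < 0], reverse=True)
            entries = [(chosen[i], r) for i, r in enumerate(
                [p for p in range(len(pos), 0, -1)] + [-p for p in range(len(neg), 0, -1)])]
            sig = GeneSignature(entries=entries, signature_id="s")
            _, c = connection_score(sig, make_profile(ranks))
            assert abs(c) <= 1.0 + 1e-12


def exact_permutation_pvalue(sig, prof):
    """Enumerate every ordered assignment of the signature's ranks to distinct genes."""
    genes = list(prof.signed_ranks.index)
    q = [r for _, r in sig.entries]
    m = len(q)
    obs_raw, _ = connection_score(sig, prof)
    scores = []
    for combo in itertools.permutations(genes, m):
        scores.append(sum(qi * prof.signed_ranks[g] for qi, g in zip(q, combo)))
    scores = np.array(scores, dtype=float)
    return (np.abs(scores) >= abs(obs_raw)).mean()


class TestPermutationPvalue:
    def test_enumeration_oracle_small_universe(self):
        """N=5, m=2, ranks {+2,-1}: Monte-Carlo p within 3 binomial SDs of exact."""
        prof = make_profile({"A": 5, "B": -4, "E": 3, "C": 2, "D": -1})
        sig = GeneSignature(entries=[("C", 2), ("E", -1)], signature_id="s")
        p_exact = exact_permutation_pvalue(sig, prof)
        K = 10_000
        p_mc = permutation_pvalue(sig, prof, n_permutations=K, seed=123)
        sd = np.sqrt(p_exact * (1 - p_exact) / K)
        assert abs(p_mc - p_exact) <= 3 * sd + 2 / K

    def test_p_has_positive_floor(self):
        prof = make_profile({f"g{i}": r for i, r in enumerate([10, -9, 8, 7, -6, 5, 4, 3, 2, 1])})
        sig = GeneSignature(entries=[("g0", 1)], signature_id="s")
        p = permutation_pvalue(sig, prof, n_permutations=100, seed=0)
        assert p >= 1 / 101

    def test_deterministic_given_seed(self):
        refset, _ = simulate_refset(RefSetSpec(n_instances=10, n_genes_universe=40, seed=6))
        sig = GeneSignature(
            entries=[(g, r) for g, r in zip(refset.gene_universe[:4], [2, 1, -2, -1])],
            signature_id="s",
        )
        p1 = permutation_pvalue(sig, refset, n_permutations=500, seed=11)
        p2 = permutation_pvalue(sig, refset, n_permutations=500, seed=11)
        assert (p1 == p2).all()

    def test_two_sided_p_unchanged_under_negation(self):
        refset, _ = simulate_refset(RefSetSpec(n_instances=5, n_genes_universe=30, seed=2))
        sig = GeneSignature(
            entries=[(g, r) for g, r in zip(refset.gene_universe[:3], [2, 1, -1])],
            signature_id="s",
        )
        # same signature_id -> same random draws; negation flips every score's
        # sign but |obs| and the |random| null are unchanged, so p is identical
        neg = GeneSignature(entries=[(g, -r) for g, r in sig.entries], signature_id="s")
        p1 = permutation_pvalue(sig, refset, n_permutations=400, seed=5)
        p2 = permutation_pvalue(neg, refset, n_permutations=400, seed=5)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_signature_as_long_as_universe_rejected(self):
        prof = make_profile({"A": 2, "B": -1})
        sig = GeneSignature(entries=[("A", 2), ("B", -1)], signature_id="s")
        with pytest.raises(ConfigurationError):
            permutation_pvalue(sig, prof, n_permutations=10, seed=0)


class TestThreshold:
    def test_printed_cutoff_two_sig_figs(self):
        cutoff, neg = significance_threshold(ThresholdPolicy(1.0, 3730))
        assert cutoff == pytest.approx(0.00027, abs=5e-6)  # ~0.00027 at 2 s.f.
        assert neg == pytest.approx(3.572, abs=5e-4)  # 3.572 at 3 d.p.

    def test_single_comparison(self):
        cutoff, neg = significance_threshold(ThresholdPolicy(1.0, 1))
        assert cutoff == 1.0 and neg == 0.0

    def test_invalid_comparisons_rejected(self):
        with pytest.raises(ConfigurationError):
            significance_threshold(ThresholdPolicy(1.0, 0))


@pytest.fixture(scope="module")
def small_run():
    refset, _ = simulate_refset(RefSetSpec(n_instances=30, n_genes_universe=60, seed=21))
    genes = refset.gene_universe
    sigs = [
        GeneSignature(entries=[(genes[0], 2), (genes[1], 1), (genes[2], -2), (genes[3], -1)],
                      signature_id="sigA"),
        GeneSignature(entries=[(genes[4], 1), (genes[5], -1)], signature_id="sigB"),
    ]
    res = connect_all(sigs, refset, n_permutations=300, seed=3)
    return sigs, refset, res


class TestConnectAllAndHits:

    def test_cardinality_and_schema(self, small_run):
        sigs, refset, res = small_run
        assert len(res) == len(sigs) * len(refset)
        assert {"signature_id", "instance_id", "perturbagen", "cell_line",
                "score", "p_value", "neg_log10_p", "significant"} <= set(res.columns)
        assert (res["p_value"].sort_values().values == res["p_value"].values).all()

    def test_reproducible_regardless_of_signature_order(self, small_run):
        sigs, refset, res = small_run
        res2 = connect_all(list(reversed(sigs)), refset, n_permutations=300, seed=3)
        merged = res.merge(res2, on=["signature_id", "instance_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["p_value_a"], merged["p_value_b"])
        assert np.allclose(merged["score_a"], merged["score_b"])

    def _results_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["signature_id", "instance_id", "perturbagen", "cell_line",
                           "score", "p_value", "significant"],
        )

    def test_hit_requires_min_signatures(self):
        rows = [
            ["s1", "i1", "drugX", "HL-60", -0.5, 0.0001, True],
            ["s2", "i1", "drugX", "HL-60", -0.4, 0.0002, True],
            ["s1", "i2", "drugY", "HL-60", -0.5, 0.0001, True],
        ]
        hits = select_hits(self._results_frame(rows))
        assert list(hits["perturbagen"]) == ["drugX"]
        assert hits.loc[0, "n_signatures"] == 2

    def test_positive_scores_excluded_under_negative_direction(self):
        rows = [["s%d" % i, "i%d" % i, "drugZ", "HL-60", 0.9, 0.0001, True] for i in range(5)]
        hits = select_hits(self._results_frame(rows), direction="negative")
        assert hits.empty
        hits_pos = select_hits(self._results_frame(rows), direction="positive")
        assert list(hits_pos["perturbagen"]) == ["drugZ"]

    def test_insignificant_connections_never_count(self):
        rows = [
            ["s1", "i1", "drugW", "HL-60", -0.5, 0.2, False],
            ["s2", "i2", "drugW", "HL-60", -0.5, 0.3, False],
        ]
        assert select_hits(self._results_frame(rows)).empty


class TestNullCalibrationSmall:
    def test_null_pvalues_pass_ks_uniformity(self):
        """All-null refset: permutation p-values are uniform (scaled-down check)."""
        from scipy import stats

        refset, _ = simulate_refset(RefSetSpec(n_instances=300, n_genes_universe=200, seed=31))
        genes = refset.gene_universe
        sig = GeneSignature(
            entries=[(genes[i], 10 - i) for i in range(10)]
            + [(genes[10 + i], -(10 - i)) for i in range(10)],
            signature_id="null_query",
        )
        p = permutation_pvalue(sig, refset, n_permutations=2000, seed=77)
        ks = stats.kstest(p.to_numpy(), "uniform")
        assert ks.pvalue > 0.01
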