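import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from kinact.inference import (
    InferenceConfig,
    binary_call,
    draw_random_experiments,
    enrich,
    estimate_fpr,
    hypergeom_tail,
    mw_aggregate,
    run_kstar,
)
from kinact.reference import BIAS_CLASSES, EvidenceSet
from kinact import synthetic


def exact_hypergeom_tail(k, n, K, N):
    """Independent oracle: exact integer-arithmetic upper tail."""
    numerator = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    )
    return numerator / math.comb(N, n)


class TestHypergeomTail:
    def test_zero_observed_gives_one(self):
        assert hypergeom_tail(0, 5, 4, 10) == 1.0

    def test_small_instance_against_enumeration(self):
        # P(X >= 2) for N=10, K=4, n=5 is 186/252
        assert hypergeom_tail(2, 5, 4, 10) == pytest.approx(186 / 252, abs=1e-12)

    def test_forced_saturation(self):
        assert hypergeom_tail(6, 6, 6, 6) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n,K,N", [(6, 5, 4, 10), (2, 5, 11, 10), (1, 11, 4, 10)])
    def test_inconsistent_counts_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            hypergeom_tail(k, n, K, N)

    def test_monotone_in_k(self):
        ps = [hypergeom_tail(k, 8, 5, 20) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrich:
    def test_disjoint_evidence_gives_all_ones(self, small_ensemble, small_proteome):
        outside = sorted(set(small_proteome.background("Y")) - small_ensemble.union_sites)
        assert len(outside) >= 5
        ev = EvidenceSet.from_sites("out", outside[:5], "Y", small_proteome)
        table = enrich(ev, small_ensemble, small_proteome)
        assert (table.pvals.to_numpy() == 1.0).all()
        assert (table.k_obs.to_numpy() == 0).all()

    def test_matches_exact_enumeration_oracle(self, small_ensemble, small_proteome):
        union = sorted(small_ensemble.union_sites)
        ev = EvidenceSet.from_sites("mix", union[:30], "Y", small_proteome)
        table = enrich(ev, small_ensemble, small_proteome)
        N, n = table.N, table.n
        for kinase in table.kinases[:2]:
            for col in table.pvals.columns[:2]:
                k = int(table.k_obs.loc[kinase, col])
                K = len(small_ensemble.networks[col].membership[kinase])
                expected = 1.0 if k == 0 else exact_hypergeom_tail(k, n, K, N)
                assert table.pvals.loc[kinase, col] == pytest.approx(expected, abs=1e-12)

    def test_evidence_outside_background_rejected(self, small_ensemble, small_proteome):
        ev = EvidenceSet("none", frozenset({"FAKE_Y1"}), "Y", 0)
        with pytest.raises(ValueError):
            enrich(ev, small_ensemble, small_proteome)

    def test_member_swap_never_increases_p(self, small_ensemble, small_proteome):
        # replacing a non-member evidence site by a member site (n fixed)
        # cannot make the kinase's p-value larger
        kinase = small_ensemble.kinases[0]
        members = sorted(small_ensemble.networks[0].membership[kinase])
        non_members = sorted(
            set(small_proteome.background("Y"))
            - small_ensemble.networks[0].membership[kinase]
        )
        base = non_members[:20]
        ev0 = EvidenceSet.from_sites("a", base, "Y", small_proteome)
        p0 = enrich(ev0, small_ensemble, small_proteome).pvals.loc[kinase, 0]
        ev1 = EvidenceSet.from_sites("b", base[:-1] + [members[0]], "Y", small_proteome)
        p1 = enrich(ev1, small_ensemble, small_proteome).pvals.loc[kinase, 0]
        assert p1 <= p0


class TestRandomExperiments:
    def test_class_profile_preserved_in_every_draw(self, small_proteome):
        background = sorted(small_proteome.background("Y"))
        ev = EvidenceSet.from_sites("e", background[::7][:40], "Y", small_proteome)
        rand = draw_random_experiments(ev, small_proteome, n_random=25, seed=5)
        assert len(rand) == 25
        for draw in rand.draws:
            profile = {c: 0 for c in BIAS_CLASSES}
            for s in draw.sites:
                profile[small_proteome.bias_class(s)] += 1
            assert profile == rand.class_profile
            assert len(draw.sites) == len(ev.sites)

    def test_background_equals_evidence_forces_identity(self, toy_proteome):
        ev = EvidenceSet.from_sites("all", toy_proteome.sites, "Y", toy_proteome)
        rand = draw_random_experiments(ev, toy_proteome, n_random=5, seed=0)
        for draw in rand.draws:
            assert draw.sites == ev.sites

    def test_within_class_inclusion_is_uniform(self, small_proteome):
        background = sorted(small_proteome.background("Y"))
        rng = np.random.default_rng(0)
        ev = EvidenceSet.from_sites(
            "e", rng.choice(background, 60, replace=False), "Y", small_proteome
        )
        n_random = 150
        rand = draw_random_experiments(ev, small_proteome, n_random=n_random, seed=1)
        low_pool = [s for s in background if small_proteome.bias_class(s) == "low"]
        target = rand.class_profile["low"] / len(low_pool)
        counts = {s: 0 for s in low_pool}
        for draw in rand.draws:
            for s in draw.sites:
                if s in counts:
                    counts[s] += 1
        freqs = np.array(list(counts.values())) / n_random
        se = math.sqrt(target * (1 - target) / n_random)
        # each draw takes exactly the class quota, so the mean is exact ...
        assert freqs.mean() == pytest.approx(target, abs=1e-12)
        # ... and individual sites fluctuate binomially around it
        within = np.abs(freqs - target) <= 3 * se
        assert within.mean() >= 0.95

    def test_out_of_background_evidence_dropped_from_profile(self, toy_proteome):
        ev = EvidenceSet.from_sites(
            "e", set(list(toy_proteome.sites)[:4]) | {"FAKE_Y1"}, "Y", toy_proteome
        )
        rand = draw_random_experiments(ev, toy_proteome, n_random=3, seed=0)
        assert sum(rand.class_profile.values()) == 4
        for draw in rand.draws:
            assert len(draw.sites) == 4


def brute_force_mw_less(x, y):
    """Rank-sum permutation oracle, independent of the package implementation."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = rankdata(pooled, method="average")
    obs = ranks[:nx].sum()
    count = total = 0
    for comb in combinations(range(len(pooled)), nx):
        total += 1
        if ranks[list(comb)].sum() <= obs + 1e-9:
            count += 1
    return count / total


class TestMannWhitneyAggregation:
    def test_canonical_exact_case(self):
        p, score = mw_aggregate([0.01, 0.02, 0.03], [0.2, 0.3, 0.4])
        assert p == pytest.approx(1 / 20, abs=1e-12)
        assert score == pytest.approx(-math.log10(1 / 20), abs=1e-12)

    def test_identical_multisets_not_significant(self):
        p, _ = mw_aggregate([0.5, 0.7], [0.5, 0.7])
        assert p >= 0.5

    def test_wrong_direction_not_significant(self):
        p, _ = mw_aggregate([1.0, 1.0, 1.0], [0.1, 0.2, 1.0])
        assert p >= 0.5

    def test_all_constant_ones_well_defined(self):
        p, _ = mw_aggregate([1.0] * 5, [1.0] * 8)
        assert 0.5 <= p <= 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.uniform(0, 1, rng.integers(2, 6)), 1)  # ties likely
        y = np.round(rng.uniform(0, 1, rng.integers(2, 7)), 1)
        p, _ = mw_aggregate(x, y)
        assert p == pytest.approx(brute_force_mw_less(x, y), abs=1e-12)

    def test_large_sample_uses_asymptotic_and_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 50)
        y = rng.uniform(0, 1, 500)
        p, _ = mw_aggregate(x, y)
        expected = mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert p == pytest.approx(expected, rel=1e-12)


class TestFprAndProfile:
    def test_extreme_real_p_bounds_fpr(self):
        rng = np.random.default_rng(0)
        tensor = rng.uniform(0.2, 1.0, size=(30, 10, 1))
        kinases = ["K1"]
        tiny = pd.Series({"K1": 1e-30})
        fpr0 = estimate_fpr(tiny, tensor, kinases, n_decoys=20)
        assert fpr0["K1"] == 0.0
        ones = pd.Series({"K1": 1.0})
        fpr1 = estimate_fpr(ones, tensor, kinases, n_decoys=20)
        assert fpr1["K1"] == 1.0

    def test_too_many_decoys_rejected(self):
        tensor = np.ones((5, 3, 1))
        with pytest.raises(ValueError):
            estimate_fpr(pd.Series({"K": 0.5}), tensor, ["K"], n_decoys=5)

    def test_run_kstar_deterministic_and_consistent(
        self, small_spec, small_proteome, small_network, small_ensemble
    ):
        ev = synthetic.gen_experiment(
            small_spec, small_proteome, small_network, size=40, seed=21
        )
        cfg = InferenceConfig(n_random=30, n_decoys=20, seed=9)
        a = run_kstar(ev, small_ensemble, small_proteome, cfg)
        b = run_kstar(ev, small_ensemble, small_proteome, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        for kinase in a.table.index:
            assert a.table.loc[kinase, "score"] == -math.log10(a.table.loc[kinase, "mw_p"])
        assert list(a.table.index) == small_ensemble.kinases

    def test_planted_kinase_ranks_first(
        self, small_spec, small_proteome, small_network, small_ensemble
    ):
        ev = synthetic.gen_experiment(
            small_spec, small_proteome, small_network, size=40, seed=5
        )
        cfg = InferenceConfig(n_random=40, n_decoys=30, seed=2)
        profile = run_kstar(ev, small_ensemble, small_proteome, cfg)
        assert profile.table["score"].idxmax() == small_spec.planted[0]

    def test_zero_coverage_kinases_still_scored(self, small_proteome, small_ensemble):
        outside = sorted(
            set(small_proteome.background("Y")) - small_ensemble.union_sites
        )[:10]
        ev = EvidenceSet.from_sites("out", outside, "Y", small_proteome)
        cfg = InferenceConfig(n_random=20, n_decoys=10, seed=0)
        profile = run_kstar(ev, small_ensemble, small_proteome, cfg)
        assert profile.table["mw_p"].notna().all()
        assert (profile.table["mw_p"] >= 0.5).all()


class TestBinaryCall:
    def _profile(self, fpr, score):
        from kinact.inference import ActivityProfile

        table = pd.DataFrame(
            {
                "mw_p": 10.0 ** -np.asarray(score),
                "score": score,
                "fpr": fpr,
                "median_hypergeom_p": 0.5,
                "n_evidence": 10,
            },
            index=list("AB"),
        )
        return ActivityProfile(table, "x", 10, 100)

    def test_fpr_rule(self):
        p = self._profile([0.01, 0.2], [5.0, 1.0])
        assert binary_call(p, "fpr05") == {"A"}

    def test_score_rule(self):
        p = self._profile([0.0, 0.0], [3.2, 2.9])
        assert binary_call(p, "score3") == {"A"}

    def test_unknown_rule_rejected(self):
        p = self._profile([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            binary_call(p, "alpha99")
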