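import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from atollconnect import popgen
from atollconnect.genotypes import MISSING

from conftest import hwe_matrix, make_matrix
from wc_oracle import wc_theta_oracle


def _theta(matrix, demes):
    a, b, c, valid = popgen.weir_cockerham_components(
        [matrix.genotypes[np.asarray(demes) == d] for d in sorted(set(demes))]
    )
    return a[valid].sum() / (a + b + c)[valid].sum()


class TestWeirCockerham:
    def test_fixed_difference_gives_exactly_one(self):
        g = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)])
        demes = ["A"] * 5 + ["B"] * 5
        m = make_matrix(g, demes=demes)
        res = popgen.pairwise_fst(m, "deme", n_boot=200, seed=0)[0]
        assert res.fst == 1.0
        assert res.significant

    def test_null_split_not_significant(self, rng):
        m = hwe_matrix(rng, 60, 300, freq_range=(0.1, 0.9))
        labels = np.array(["X"] * 30 + ["Y"] * 30)
        rng.shuffle(labels)
        res = popgen.pairwise_fst(m, labels, n_boot=1000, seed=1)[0]
        assert not res.significant
        assert abs(res.fst) < 0.01

    @given(
        arrays(np.int16, (4, 5), elements=st.integers(0, 2)),
        st.integers(0, 2**16),
    )
    @settings(max_examples=50)
    def test_matches_brute_force_oracle(self, g, salt):
        """Vectorized theta equals the loop-based oracle on tiny instances."""
        # salt perturbs a couple of entries toward missing
        g = g.copy()
        if salt % 3 == 0:
            g[salt % 4, salt % 5] = MISSING
        blocks = [g[:2].tolist(), g[2:].tolist()]
        expected = wc_theta_oracle(blocks)
        a, b, c, valid = popgen.weir_cockerham_components([g[:2], g[2:]])
        denom = (a + b + c)[valid].sum()
        if np.isnan(expected):
            assert denom == 0 or not valid.any()
        else:
            assert a[valid].sum() / denom == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_relabeling(self, rng):
        m = hwe_matrix(rng, 20, 50, demes=["A"] * 10 + ["B"] * 10)
        flipped = make_matrix(2 - m.genotypes, demes=["A"] * 10 + ["B"] * 10)
        r1 = popgen.pairwise_fst(m, "deme", n_boot=50, seed=2)[0]
        r2 = popgen.pairwise_fst(flipped, "deme", n_boot=50, seed=2)[0]
        assert r1.fst == pytest.approx(r2.fst, abs=1e-12)

    def test_invariant_to_individual_order(self, rng):
        demes = ["A"] * 10 + ["B"] * 10
        m = hwe_matrix(rng, 20, 50, demes=demes)
        perm = rng.permutation(20)
        r1 = popgen.pairwise_fst(m, "deme", n_boot=50, seed=3)[0]
        r2 = popgen.pairwise_fst(m.subset(individuals=perm), "deme", n_boot=50, seed=3)[0]
        assert r1.fst == pytest.approx(r2.fst, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        m = hwe_matrix(rng, 40, 400, demes=["A"] * 20 + ["B"] * 20)
        res = popgen.pairwise_fst(m, "deme", n_boot=1000, seed=4)[0]
        assert res.ci_low <= res.fst <= res.ci_high


class TestRelativeHeterozygosity:
    def test_simple_arithmetic(self):
        g = np.zeros((2, 10))
        g[0, :3] = 1  # 3 het calls
        g[1, :] = 2  # keeps every locus polymorphic
        m = make_matrix(g)
        rh = popgen.relative_heterozygosity(m)
        assert rh.iloc[0] == pytest.approx(0.3)

    def test_all_homozygous_gives_zero(self):
        g = np.array([[0, 2, 0], [2, 0, 2]])
        m = make_matrix(g)
        assert (popgen.relative_heterozygosity(m) == 0).all()

    def test_monomorphic_matrix_errors(self):
        m = make_matrix(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            popgen.relative_heterozygosity(m)

    def test_hwe_mean_near_half(self, rng):
        m = hwe_matrix(rng, 50, 5000, freq_range=(0.5, 0.5))
        assert abs(popgen.relative_heterozygosity(m).mean() - 0.5) < 0.02


class TestPopDiversity:
    def test_all_heterozygous_gives_negative_fis(self):
        m = make_matrix(np.ones((6, 20)))
        d = popgen.pop_diversity(m, np.array(["g"] * 6), n_perm=99, seed=0)[0]
        assert d.ho == 1.0
        assert d.fis < 0
        assert d.significant

    def test_hwe_fis_near_zero(self, rng):
        m = hwe_matrix(rng, 80, 1000)
        d = popgen.pop_diversity(m, np.array(["g"] * 80), n_perm=199, seed=1)[0]
        assert abs(d.fis) < 0.02

    def test_inbred_cohort_fis_recovered(self, rng):
        F = 0.3
        p = rng.uniform(0.1, 0.9, 2000)
        ibd = rng.random((100, 2000)) < F
        shared = rng.binomial(1, p, size=(100, 2000))
        outbred = rng.binomial(1, p, size=(100, 2000)) + rng.binomial(
            1, p, size=(100, 2000)
        )
        g = np.where(ibd, 2 * shared, outbred)
        m = make_matrix(g)
        d = popgen.pop_diversity(m, np.array(["g"] * 100), n_perm=99, seed=2)[0]
        assert d.fis == pytest.approx(0.3, abs=0.05)
        assert d.significant

    def test_null_rejection_rate_calibrated(self):
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            m = hwe_matrix(r, 40, 300)
            d = popgen.pop_diversity(m, np.array(["g"] * 40), n_perm=99, seed=seed)[0]
            hits += d.fis_pvalue < 0.05
        assert hits / n_rep <= 0.2


class TestRelatednessAjk:
    def test_parent_offspring_near_half(self, rng):
        L = 5000
        p = rng.uniform(0.1, 0.9, L)
        parents = rng.binomial(2, p, size=(40, L)).astype(np.int16)
        kids = np.empty_like(parents[:20])
        for i in range(20):
            pa, pb = parents[2 * i], parents[2 * i + 1]
            kids[i] = rng.binomial(1, pa / 2.0) + rng.binomial(1, pb / 2.0)
        m = make_matrix(np.vstack([parents, kids]))
        ajk = popgen.relatedness_ajk(m, freq_source=p).to_numpy()
        po = np.mean([ajk[2 * i, 40 + i] for i in range(20)])
        assert po == pytest.approx(0.5, abs=0.05)

    def test_relabeling_invariance(self, rng):
        m = hwe_matrix(rng, 15, 200)
        a1 = popgen.relatedness_ajk(m).to_numpy()
        a2 = popgen.relatedness_ajk(make_matrix(2 - m.genotypes)).to_numpy()
        assert np.allclose(a1, a2, atol=1e-10)

    def test_fixed_loci_excluded_and_error_when_all_fixed(self):
        g = np.array([[0, 1], [0, 1], [0, 0]])
        a = popgen.relatedness_ajk(make_matrix(g))
        assert np.isfinite(a.to_numpy()).all()
        with pytest.raises(ValueError):
            popgen.relatedness_ajk(make_matrix(np.zeros((3, 4))))


class TestIndividualInbreeding:
    def test_hwe_null_covered_by_ci(self, rng):
        m = hwe_matrix(rng, 30, 1500)
        res = popgen.individual_inbreeding(m, n_boot=300, seed=0)
        covers = (res["ci_low"] <= 0) & (0 <= res["ci_high"])
        assert covers.mean() >= 0.85
        assert abs(res["fhat"].mean()) < 0.02

    def test_inbred_mean_recovered(self, rng):
        F = 0.35
        p = rng.uniform(0.1, 0.9, 2000)
        ibd = rng.random((60, 2000)) < F
        shared = rng.binomial(1, p, size=(60, 2000))
        g = np.where(
            ibd,
            2 * shared,
            rng.binomial(1, p, size=(60, 2000)) + rng.binomial(1, p, size=(60, 2000)),
        )
        res = popgen.individual_inbreeding(make_matrix(g), n_boot=200, seed=1)
        assert res["fhat"].mean() == pytest.approx(0.35, abs=0.05)

    def test_monomorphic_loci_do_not_move_estimate(self, rng):
        m = hwe_matrix(rng, 10, 500)
        res1 = popgen.individual_inbreeding(m, n_boot=50, seed=2)
        padded = np.hstack([m.genotypes, np.zeros((10, 100), dtype=np.int16)])
        res2 = popgen.individual_inbreeding(make_matrix(padded), n_boot=50, seed=2)
        assert np.allclose(res1["fhat"], res2["fhat"])


class TestGroupHeterozygosityTest:
    def test_hand_computed_kruskal_wallis(self):
        """3 groups of 3 untied values: H = 7.2 by the rank formula."""
        values = np.arange(1.0, 10.0)
        labels = np.repeat(["a", "b", "c"], 3)
        p, posthoc = popgen.group_heterozygosity_test(values, labels)
        assert p == pytest.approx(stats.chi2.sf(7.2, df=2))
        # Dunn z for a vs b: (2 - 5) / sqrt(7.5 * 2/3)
        z_ab = posthoc.set_index(["group_a", "group_b"]).loc[("a", "b"), "z"]
        assert z_ab == pytest.approx(-3 / np.sqrt(5))

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        p, _ = popgen.group_heterozygosity_test(
            np.concatenate([a, b]), np.repeat(["a", "b"], 30)
        )
        assert p < 1e-3

    def test_constant_values_return_one(self):
        p, posthoc = popgen.group_heterozygosity_test(
            np.ones(12), np.repeat(["a", "b", "c"], 4)
        )
        assert p == 1.0
        assert posthoc.empty

    def test_null_calibration(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            vals = r.normal(size=30)
            p, _ = popgen.group_heterozygosity_test(vals, np.repeat(["a", "b", "c"], 10))
            hits += p < 0.05
        assert hits / 40 <= 0.15


def _fmodel_matrix(seed, n_loci=300, n_pops=6, n_per=30, spike=0, spike_f=0.4):
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, n_loci)
    F = np.full(n_loci, 0.03)
    F[:spike] = spike_f
    blocks = []
    for _ in range(n_pops):
        scale = (1 - F) / F
        pj = np.clip(rng.beta(p_anc * scale, (1 - p_anc) * scale), 1e-6, 1 - 1e-6)
        blocks.append(rng.binomial(2, pj, size=(n_per, n_loci)))
    demes = np.repeat([f"d{j}" for j in range(n_pops)], n_per)
    return make_matrix(np.vstack(blocks), demes=list(demes))


class TestOutlierScan:
    def test_neutral_data_unflagged(self):
        m = _fmodel_matrix(seed=1)
        res = popgen.outlier_scan(m, "deme", n_burn=500, n_iter=1500, thin=5, seed=2)
        assert res.flagged.sum() == 0

    def test_spiked_loci_rank_highest(self):
        m = _fmodel_matrix(seed=3, n_loci=300, spike=5)
        res = popgen.outlier_scan(m, "deme", n_burn=500, n_iter=1500, thin=5, seed=4)
        top5 = set(np.argsort(res.posterior_inclusion)[-5:])
        assert len(top5 & set(range(5))) >= 3
        flagged = np.flatnonzero(res.flagged)
        assert set(flagged) <= set(range(5))
        # divergent loci carry positive locus effects
        assert (res.alpha[list(top5 & set(range(5)))] > 0).all()

    def test_neutral_subset_bookkeeping(self):
        m = _fmodel_matrix(seed=5, n_loci=100, spike=3, spike_f=0.6)
        res = popgen.outlier_scan(m, "deme", n_burn=300, n_iter=900, thin=3, seed=6)
        neutral = res.neutral_loci()
        assert len(neutral) == m.n_loci - res.flagged.sum()
        sub = m.subset(loci=neutral)
        assert sub.n_loci == len(neutral)
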