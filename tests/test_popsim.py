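import numpy as np
import pytest
from scipy import stats

from atollconnect import popgen, popsim

from conftest import make_matrix


def one_deme_config(**kw):
    base = dict(
        n_demes=1,
        deme_labels=["A"],
        cluster_of_deme={"A": "cluster2"},
        n_individuals_per_deme=[50],
        divergence_F_per_deme=[0.0],
        cluster_F=0.0,
        n_loci=1000,
        missing_rate=0.0,
        seed=0,
    )
    base.update(kw)
    return popsim.PopSimConfig(**base)


class TestDemeFrequencies:
    def test_no_drift_limit_equals_ancestral(self):
        cfg = one_deme_config()
        freqs = popsim.simulate_deme_frequencies(cfg)
        assert np.allclose(freqs["A"], freqs["ancestral"])

    def test_beta_mean_preserves_ancestral_frequency(self):
        cfg = one_deme_config(
            ancestral_freq_range=(0.5, 0.5),
            divergence_F_per_deme=[0.1],
            n_loci=10_000,
        )
        freqs = popsim.simulate_deme_frequencies(cfg)
        assert abs(freqs["A"].mean() - 0.5) < 0.01

    def test_degenerate_drift_rejected(self):
        with pytest.raises(ValueError):
            one_deme_config(divergence_F_per_deme=[1.0])

    def test_between_cluster_divergence_exceeds_within(self):
        """Hierarchical draws give larger F_ST across clusters than within."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = popsim.PopSimConfig(
                n_demes=4,
                deme_labels=["A1", "A2", "B1", "B2"],
                cluster_of_deme={"A1": "c1", "A2": "c1", "B1": "c2", "B2": "c2"},
                n_individuals_per_deme=[30] * 4,
                divergence_F_per_deme=[0.005] * 4,
                cluster_F=0.05,
                n_loci=2000,
                missing_rate=0.0,
                seed=seed,
            )
            rng = np.random.default_rng(seed)
            freqs = popsim.simulate_deme_frequencies(cfg, rng)
            m = popsim.simulate_genotypes(freqs, cfg, rng)
            groups = m.groups("deme")

            def theta(a, b):
                ca, cb, cc, valid = popgen.weir_cockerham_components(
                    [m.genotypes[groups[a]], m.genotypes[groups[b]]]
                )
                return ca[valid].sum() / (ca + cb + cc)[valid].sum()

            between = np.mean([theta("A1", "B1"), theta("A2", "B2")])
            within = np.mean([theta("A1", "A2"), theta("B1", "B2")])
            wins += between > within
        assert wins == n_seeds


class TestGenotypes:
    def test_hwe_heterozygosity_at_half(self):
        cfg = one_deme_config(ancestral_freq_range=(0.5, 0.5), n_loci=10_000)
        m, _ = popsim.simulate_dataset(cfg)
        ho = (m.genotypes == 1).mean()
        assert abs(ho - 0.5) < 0.02

    def test_missing_rate_matches_target(self):
        cfg = one_deme_config(
            n_individuals_per_deme=[200], n_loci=2000, missing_rate=0.1
        )
        freqs = popsim.simulate_deme_frequencies(cfg)
        m = popsim.simulate_genotypes(freqs, cfg)
        assert abs(m.missing_fraction() - 0.10) < 0.01

    def test_fixed_frequency_rejected(self):
        cfg = one_deme_config()
        freqs = popsim.simulate_deme_frequencies(cfg)
        freqs["A"] = 1.0
        with pytest.raises(ValueError):
            popsim.simulate_genotypes(freqs, cfg)

    def test_hwe_chi_square_goodness_of_fit(self):
        """Genotype counts within a deme stay consistent with HWE."""
        cfg = one_deme_config(
            n_individuals_per_deme=[300],
            n_loci=1000,
            ancestral_freq_range=(0.3, 0.7),
        )
        m, freqs = popsim.simulate_dataset(cfg)
        p = freqs["A"].to_numpy()
        counts = np.stack([(m.genotypes == k).sum(axis=0) for k in (0, 1, 2)])
        n = m.n_individuals
        expected = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=0)
        reject = chi2 > stats.chi2.ppf(0.99, df=2)
        assert reject.mean() <= 0.05

    def test_determinism(self):
        a, _ = popsim.simulate_dataset(popsim.PopSimConfig(seed=5, n_loci=100))
        b, _ = popsim.simulate_dataset(popsim.PopSimConfig(seed=5, n_loci=100))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.depth, b.depth)


class TestSRS:
    def _adults(self, seed=0, n=60):
        cfg = one_deme_config(
            n_individuals_per_deme=[n], n_loci=2000, seed=seed
        )
        adults, freqs = popsim.simulate_dataset(cfg)
        return adults, freqs["A"].to_numpy()

    def test_two_parents_make_full_sibs(self):
        adults, p = self._adults()
        coh = popsim.simulate_srs_spat_cohort(
            adults, 2, 30, np.random.default_rng(1), parent_freqs=p
        )
        ajk = popgen.relatedness_ajk(coh, freq_source=p)
        assert abs(popgen.mean_offdiagonal(ajk) - 0.5) < 0.05

    def test_same_sex_subset_raises(self):
        adults, _ = self._adults()
        adults.individual_meta["sex"] = "M"
        with pytest.raises(ValueError, match="no_compatible_pair"):
            popsim.simulate_srs_spat_cohort(adults, 5, 10, np.random.default_rng(0))

    def test_few_parents_inflate_relatedness(self):
        """5-parent cohorts beat all-parent cohorts on mean Ajk, paired seeds."""
        wins = 0
        for seed in range(5):
            adults, p = self._adults(seed=seed)
            rng = np.random.default_rng(seed + 100)
            few = popsim.simulate_srs_spat_cohort(adults, 5, 30, rng, parent_freqs=p)
            many = popsim.simulate_srs_spat_cohort(
                adults, adults.n_individuals, 30, rng, parent_freqs=p
            )
            a_few = popgen.mean_offdiagonal(popgen.relatedness_ajk(few, p))
            a_many = popgen.mean_offdiagonal(popgen.relatedness_ajk(many, p))
            wins += a_few > a_many
        assert wins == 5

    def test_spat_metadata(self):
        adults, _ = self._adults()
        coh = popsim.simulate_srs_spat_cohort(
            adults, 4, 10, np.random.default_rng(3), cohort_label="c9"
        )
        meta = coh.individual_meta
        assert (meta["stock"] == "spat").all()
        assert (meta["sex"] == "undetermined").all()
        assert (meta["cohort"] == "c9").all()


class TestProtandry:
    def test_anchor_values(self):
        s = popsim.ProtandrySchedule()
        assert s.female_fraction(1.0) == 0.0
        assert s.female_fraction(6.0) == pytest.approx(0.27)
        assert s.female_fraction(10.0) == pytest.approx(0.41)
        # linear interpolation between anchors
        assert s.female_fraction(3.5) == pytest.approx(0.135)

    def test_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            popsim.ProtandrySchedule(anchor_ages=(1, 6), female_fractions=(0.4, 0.2))


class TestDemography:
    def test_stock_age_and_sex_patterns(self):
        cfg = popsim.PopSimConfig(n_individuals_per_deme=[30] * 12, seed=42)
        m, _ = popsim.simulate_dataset(cfg)
        meta = m.individual_meta
        exploited = meta[meta["stock"] == "exploited"]
        assert (exploited["age"] <= 6.0).all()
        ne = meta[meta["deme"].isin(["N5", "N6", "N7"])]
        assert (ne["age"] >= 8.0).all()
        # directional sex-ratio property: young farms male-biased, old NE not
        for deme, grp in exploited.groupby("deme"):
            sexed = grp[grp["sex"].isin(["M", "F"])]
            assert (sexed["sex"] == "F").mean() <= 0.44
        ne_sexed = ne[ne["sex"].isin(["M", "F"])]
        assert (ne_sexed["sex"] == "F").mean() >= 0.38

    def test_lengths_clipped_and_spats_exempt(self):
        cfg = popsim.PopSimConfig(seed=3, n_loci=50)
        adults, _ = popsim.simulate_dataset(cfg)
        lengths = adults.individual_meta["length_cm"]
        assert lengths.between(6.0, 20.0).all()
        coh = popsim.simulate_srs_spat_cohort(
            adults, 5, 5, np.random.default_rng(0)
        )
        assert coh.individual_meta["length_cm"].isna().all()
        assert coh.individual_meta["age"].eq(0.0).all()
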