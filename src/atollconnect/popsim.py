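"""Synthetic genotypes, demography and spat cohorts for a two-cluster lagoon.

The generator emulates the statistical structure the downstream analysis
assumes for a farmed atoll lagoon: two weakly diverged genetic clusters
(northeastern natural sites versus southwestern natural + exploited sites),
protandrous sex ratios (young exploited stocks male-biased, old natural
stocks female-biased), sweepstakes reproductive success (SRS) spat cohorts
descended from a handful of parents, and per-genotype sequencing depth and
missingness so that the variant filters have something to act on.

Population divergence follows the Balding-Nichols F-model: each locus has an
ancestral frequency ``p``; a cluster-level frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with the between-cluster drift ``F``; deme
frequencies are drawn around their cluster frequency with a (smaller)
within-cluster ``F``.  Genotypes are Hardy-Weinberg binomial draws within
demes; loci are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PopSimConfig",
    "ProtandrySchedule",
    "DemographyRules",
    "simulate_deme_frequencies",
    "simulate_genotypes",
    "simulate_srs_spat_cohort",
    "assign_demography",
    "simulate_dataset",
]

_DEFAULT_DEMES = ["N2", "N3", "N4", "N5", "N6", "N7", "E1", "E2", "E3", "E4", "E5", "E6"]
_NE_DEMES = ("N5", "N6", "N7")


def _default_clusters() -> dict[str, str]:
    return {d: ("cluster1" if d in _NE_DEMES else "cluster2") for d in _DEFAULT_DEMES}


@dataclass
class PopSimConfig:
    """Parameters of the two-cluster F-model simulation.

    ``cluster_F`` is the between-cluster drift; ``divergence_F_per_deme`` the
    within-cluster drift of each deme around its cluster frequency (default
    10x smaller than ``cluster_F``).
    """

    n_demes: int = len(_DEFAULT_DEMES)
    deme_labels: list[str] = field(default_factory=lambda: list(_DEFAULT_DEMES))
    cluster_of_deme: dict[str, str] = field(default_factory=_default_clusters)
    n_individuals_per_deme: list[int] = field(
        default_factory=lambda: [20] * len(_DEFAULT_DEMES)
    )
    n_loci: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    cluster_F: float = 0.05
    divergence_F_per_deme: list[float] = field(
        default_factory=lambda: [0.005] * len(_DEFAULT_DEMES)
    )
    srs_n_parents: int = 5
    mean_depth: float = 40.0
    dispersion: float = 5.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.deme_labels) != self.n_demes:
            raise ValueError("deme_labels length != n_demes")
        if len(self.n_individuals_per_deme) != self.n_demes:
            raise ValueError("n_individuals_per_deme length != n_demes")
        if len(self.divergence_F_per_deme) != self.n_demes:
            raise ValueError("divergence_F_per_deme length != n_demes")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie in (0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.srs_n_parents < 2:
            raise ValueError("srs_n_parents must be >= 2")
        for f in [self.cluster_F, *self.divergence_F_per_deme]:
            if not 0.0 <= f < 1.0:
                raise ValueError("drift F must be in [0, 1); F = 1 is degenerate")
        for d in self.deme_labels:
            if d not in self.cluster_of_deme:
                raise ValueError(f"deme {d} has no cluster assignment")


@dataclass
class ProtandrySchedule:
    """Female fraction as a function of age for a protandrous hermaphrodite.

    Defaults: 0% females at age 1, 27% at age 6, 41% from age 8 onward, with
    linear interpolation between anchors and constant extrapolation outside.
    """

    anchor_ages: tuple[float, ...] = (1.0, 6.0, 8.0)
    female_fractions: tuple[float, ...] = (0.0, 0.27, 0.41)

    def __post_init__(self) -> None:
        if len(self.anchor_ages) != len(self.female_fractions):
            raise ValueError("anchor lengths differ")
        if np.any(np.diff(self.anchor_ages) <= 0):
            raise ValueError("anchor ages must increase")
        fr = np.asarray(self.female_fractions)
        if np.any(np.diff(fr) < 0) or np.any((fr < 0) | (fr > 1)):
            raise ValueError("female fractions must be non-decreasing in [0, 1]")

    def female_fraction(self, age: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(age, dtype=float), self.anchor_ages, self.female_fractions)


@dataclass
class DemographyRules:
    """Age ranges per stock group and the age -> shell-length curve.

    Exploited animals are grafted around age 3 and killed between the pearl
    harvest (4.5 y) and a second-graft harvest (6 y), so their ages truncate
    at ``exploited_age_range[1]``.  The length curve is von Bertalanffy-like
    with multiplicative lognormal noise, clipped to the 6-20 cm dorso-ventral
    sampling window for adults.
    """

    exploited_age_range: tuple[float, float] = (2.0, 6.0)
    natural_ne_age_range: tuple[float, float] = (8.0, 16.0)
    natural_sw_age_range: tuple[float, float] = (2.0, 16.0)
    undetermined_prob_exploited: float = 0.1
    length_linf_cm: float = 19.5
    length_k: float = 0.35
    length_t0: float = -0.5
    length_cv: float = 0.07
    length_clip_cm: tuple[float, float] = (6.0, 20.0)

    def mean_length(self, age: np.ndarray) -> np.ndarray:
        return self.length_linf_cm * (1.0 - np.exp(-self.length_k * (age - self.length_t0)))


# ----------------------------------------------------------------------
# frequency and genotype simulation
# ----------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw drifted frequencies around ``p`` with inbreeding-like variance f."""
    if f == 0.0:
        return p.copy()
    if f >= 1.0:
        raise ValueError("F = 1 is degenerate")
    scale = (1.0 - f) / f
    out = rng.beta(p * scale, (1.0 - p) * scale)
    eps = 1e-6
    return np.clip(out, eps, 1.0 - eps)


def simulate_deme_frequencies(
    config: PopSimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate per-deme allele frequencies under the hierarchical F-model.

    Returns a ``(n_loci, n_demes)`` frame (columns = deme labels) with an
    ``ancestral`` column appended.  Demes of the same cluster share one
    intermediate cluster-level draw, so between-cluster divergence exceeds
    within-cluster divergence whenever ``cluster_F`` dominates the per-deme F.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)

    clusters = sorted(set(config.cluster_of_deme[d] for d in config.deme_labels))
    p_cluster = {c: _balding_nichols(rng, p_anc, config.cluster_F) for c in clusters}

    cols = {}
    for deme, f in zip(config.deme_labels, config.divergence_F_per_deme):
        base = p_cluster[config.cluster_of_deme[deme]]
        cols[deme] = _balding_nichols(rng, base, f)
    cols["ancestral"] = p_anc
    return pd.DataFrame(cols)


def _locus_meta(n_loci: int, rng: np.random.Generator, loci_per_scaffold: int = 100) -> pd.DataFrame:
    scaff = np.arange(n_loci) // loci_per_scaffold
    pos_within = np.arange(n_loci) % loci_per_scaffold
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    return pd.DataFrame(
        {
            "scaffold": [f"scaffold{s + 1}" for s in scaff],
            "pos": (pos_within + 1) * 100,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "is_complex": np.zeros(n_loci, dtype=bool),
        }
    )


def _depth_and_missing(
    rng: np.random.Generator, shape: tuple[int, int], config: PopSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    k = config.dispersion
    p_nb = k / (k + config.mean_depth)
    depth = rng.negative_binomial(k, p_nb, size=shape).astype(np.int32)
    miss = rng.random(shape) < config.missing_rate
    return depth, miss


def simulate_genotypes(
    freqs: pd.DataFrame,
    config: PopSimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw HWE genotypes per deme plus negative-binomial depth and missingness."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    p = freqs[config.deme_labels].to_numpy()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("deme frequencies must lie strictly in (0, 1)")

    blocks, meta_rows = [], []
    for j, (deme, n_ind) in enumerate(zip(config.deme_labels, config.n_individuals_per_deme)):
        g = rng.binomial(2, p[:, j], size=(n_ind, config.n_loci)).astype(np.int16)
        blocks.append(g)
        stock = "exploited" if deme.startswith("E") else "natural"
        for i in range(n_ind):
            meta_rows.append(
                {
                    "id": f"{deme}_{i + 1:03d}",
                    "deme": deme,
                    "stock": stock,
                    "age": np.nan,
                    "sex": "undetermined",
                    "length_cm": np.nan,
                    "cohort": "",
                }
            )
    genotypes = np.vstack(blocks)
    depth, miss = _depth_and_missing(rng, genotypes.shape, config)
    genotypes[miss] = MISSING
    return GenotypeMatrix(
        genotypes=genotypes,
        depth=depth,
        locus_meta=_locus_meta(config.n_loci, rng),
        individual_meta=pd.DataFrame(meta_rows),
    )


# ----------------------------------------------------------------------
# sweepstakes reproductive success
# ----------------------------------------------------------------------

def simulate_srs_spat_cohort(
    parents: GenotypeMatrix,
    n_parents: int,
    n_offspring: int,
    rng: np.random.Generator,
    cohort_label: str = "spat1",
    parent_freqs: np.ndarray | None = None,
    require_both_sexes: bool = True,
    max_attempts: int = 200,
) -> GenotypeMatrix:
    """Mendelian spat cohort parented by a small subset of the adult pool.

    A subset of ``n_parents`` adults is drawn (redrawn until it contains at
    least one male and one female, bounded by ``max_attempts``); each
    offspring picks a random sire/dam pair within the subset and inherits one
    allele per parent per locus.  Missing parental genotypes fall back to a
    draw from ``parent_freqs`` (default: frequencies of the parent pool).
    """
    if n_parents < 2:
        raise ValueError("n_parents must be >= 2")
    if n_parents > parents.n_individuals:
        raise ValueError("n_parents exceeds available adults")

    sexes = parents.individual_meta["sex"].to_numpy()
    for _ in range(max_attempts):
        subset = rng.choice(parents.n_individuals, size=n_parents, replace=False)
        sub_sex = sexes[subset]
        males = subset[sub_sex == "M"]
        females = subset[sub_sex == "F"]
        if not require_both_sexes or (len(males) > 0 and len(females) > 0):
            if not require_both_sexes:
                males = females = subset
            break
    else:
        raise ValueError("no_compatible_pair: could not draw a subset with both sexes")

    if parent_freqs is None:
        parent_freqs = np.nan_to_num(parents.allele_frequencies(), nan=0.5)
    parent_freqs = np.clip(parent_freqs, 1e-9, 1 - 1e-9)

    L = parents.n_loci

    def _gamete(parent_idx: int) -> np.ndarray:
        g = parents.genotypes[parent_idx].astype(float)
        miss = g == MISSING
        prob = np.where(miss, parent_freqs, g / 2.0)
        return rng.binomial(1, prob)

    offspring = np.empty((n_offspring, L), dtype=np.int16)
    sires = rng.choice(males, size=n_offspring)
    dams = rng.choice(females, size=n_offspring)
    for i in range(n_offspring):
        offspring[i] = _gamete(sires[i]) + _gamete(dams[i])

    source_demes = sorted(set(parents.individual_meta["deme"].iloc[subset]))
    meta = pd.DataFrame(
        {
            "id": [f"{cohort_label}_{i + 1:03d}" for i in range(n_offspring)],
            "deme": "|".join(source_demes),
            "stock": "spat",
            "age": 0.0,
            "sex": "undetermined",  # spats cannot be sexed
            "length_cm": np.nan,
            "cohort": cohort_label,
        }
    )
    depth = np.full(offspring.shape, -1, dtype=np.int32)
    return GenotypeMatrix(
        genotypes=offspring,
        depth=depth,
        locus_meta=parents.locus_meta.copy(),
        individual_meta=meta,
    )


# ----------------------------------------------------------------------
# demography
# ----------------------------------------------------------------------

def draw_sexes(
    ages: np.ndarray, schedule: ProtandrySchedule, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli female draw from the protandry schedule; males otherwise."""
    pf = schedule.female_fraction(ages)
    female = rng.random(len(ages)) < pf
    return np.where(female, "F", "M")


def assign_demography(
    matrix: GenotypeMatrix,
    schedule: ProtandrySchedule | None = None,
    rules: DemographyRules | None = None,
    rng: np.random.Generator | None = None,
    cluster_of_deme: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Fill ages, sexes and shell lengths in the individual metadata.

    Ages are drawn uniformly per stock group (exploited: young, truncated at
    the kill age; NE natural: old; SW natural: mixed); sex follows the
    protandry schedule; exploited individuals are recorded ``undetermined``
    with a configurable probability (unreadable gonad biopsies).  Spats are
    exempt from all three.
    """
    schedule = schedule or ProtandrySchedule()
    rules = rules or DemographyRules()
    rng = np.random.default_rng(0) if rng is None else rng
    cluster_of_deme = cluster_of_deme or _default_clusters()

    out = matrix.copy()
    meta = out.individual_meta
    stock = meta["stock"].to_numpy()
    deme = meta["deme"].to_numpy()
    n = len(meta)

    ages = np.full(n, np.nan)
    for i in range(n):
        if stock[i] == "spat":
            continue
        if stock[i] == "exploited":
            lo, hi = rules.exploited_age_range
        elif cluster_of_deme.get(deme[i]) == "cluster1":
            lo, hi = rules.natural_ne_age_range
        else:
            lo, hi = rules.natural_sw_age_range
        ages[i] = rng.uniform(lo, hi)

    adult = stock != "spat"
    sexes = np.asarray(meta["sex"], dtype=object)
    sexes[adult] = draw_sexes(ages[adult], schedule, rng)
    undet = adult & (stock == "exploited") & (
        rng.random(n) < rules.undetermined_prob_exploited
    )
    sexes[undet] = "undetermined"

    lengths = np.full(n, np.nan)
    noise = rng.lognormal(mean=0.0, sigma=rules.length_cv, size=n)
    lengths[adult] = np.clip(
        rules.mean_length(ages[adult]) * noise[adult], *rules.length_clip_cm
    )

    meta["age"] = ages
    meta["sex"] = sexes
    meta["length_cm"] = lengths
    return out


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------

def simulate_dataset(
    config: PopSimConfig | None = None,
    schedule: ProtandrySchedule | None = None,
    rules: DemographyRules | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate adults with demography; returns (matrix, deme frequencies)."""
    config = config or PopSimConfig()
    rng = np.random.default_rng(config.seed)
    freqs = simulate_deme_frequencies(config, rng)
    adults = simulate_genotypes(freqs, config, rng)
    adults = assign_demography(
        adults, schedule, rules, rng, cluster_of_deme=config.cluster_of_deme
    )
    return adults, freqs


def write_metadata_csv(matrix: GenotypeMatrix, path: str) -> None:
    matrix.individual_meta.to_csv(path, index=False)
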