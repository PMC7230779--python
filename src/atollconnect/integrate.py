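"""Confront modelled connectivity with genetic spat assignment; run the pipeline.

``aggregate_connectivity`` folds release sources into stock groups;
``cohort_fit`` scores each weekly cohort's connectivity matrix against the
observed per-collector composition of genetically assigned spats (multinomial
log-likelihood with a pseudocount by default, cosine similarity as a
sensitivity mode) and names the best-fitting cohort.  ``run_pipeline``
orchestrates the whole study on synthetic data: simulate genotypes and spat
cohorts, filter and impute, compute population statistics, cluster and
assign spats, build the flow field, run the larval transport, and score the
cohorts; every stage is driven by one master seed and all artifacts land in
a run directory with a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dispersal, lagoonflow, popgen, popsim, structure, variants
from .dispersal import CollectorSpec, ConnectivityMatrix, ReleaseSpec
from .genotypes import GenotypeMatrix, concatenate_individuals

__all__ = [
    "StockAggregation",
    "CohortFitResult",
    "MasterConfig",
    "aggregate_connectivity",
    "cohort_fit",
    "run_pipeline",
]

# stylized site positions (m) inside the default elliptical lagoon;
# NE natural sites sit in the northeastern cell, SW natural in the southwest,
# farms (E) scattered, collectors (C) at the usual collecting grounds.
DEFAULT_SOURCE_POSITIONS: dict[str, tuple[float, float]] = {
    "N1": (-2500.0, 500.0),
    "N2": (-3500.0, -1200.0),
    "N3": (-4200.0, -300.0),
    "N4": (-4600.0, -1100.0),
    "N5": (1800.0, 1200.0),
    "N6": (3300.0, 900.0),
    "N7": (4400.0, 300.0),
    "E1": (-2000.0, -900.0),
    "E2": (-800.0, 1200.0),
    "E3": (-2800.0, -1700.0),
    "E4": (500.0, -1300.0),
    "E5": (2500.0, -900.0),
    "E6": (-3600.0, -1700.0),
}

DEFAULT_COLLECTOR_POSITIONS: dict[str, tuple[float, float]] = {
    "C1": (-2200.0, -500.0),
    "C2": (600.0, -300.0),
    "C3": (-500.0, 800.0),
    "C4": (2000.0, -400.0),
    "C5": (-3800.0, -800.0),
}

NE_SOURCES = ("N5", "N6", "N7")


def _default_stock_map() -> dict[str, str]:
    m = {s: "NE-natural" for s in NE_SOURCES}
    m.update({s: "SW-natural" for s in ("N1", "N2", "N3", "N4")})
    m.update({f"E{i}": "exploited" for i in range(1, 7)})
    return m


def _default_cluster_map() -> dict[str, str]:
    """Two-group map matching what genetic assignment can resolve."""
    return {s: ("cluster1" if s in NE_SOURCES else "cluster2") for s in _default_stock_map()}


@dataclass
class StockAggregation:
    """Source -> group map; every source must be mapped exactly once."""

    mapping: dict[str, str] = field(default_factory=_default_stock_map)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen

    @classmethod
    def clusters(cls) -> "StockAggregation":
        return cls(mapping=_default_cluster_map())


def aggregate_connectivity(
    counts: np.ndarray | pd.DataFrame,
    source_labels: list[str],
    collector_labels: list[str],
    agg: StockAggregation | None = None,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-sum a source x collector matrix into stock groups.

    Returns ``(group_counts, proportions)``; proportions are per collector
    with an additive pseudocount so empty collectors stay defined.
    """
    agg = agg or StockAggregation()
    counts = np.asarray(counts, dtype=float)
    unmapped = [s for s in source_labels if s not in agg.mapping]
    if unmapped:
        raise ValueError(f"unmapped sources: {unmapped}")
    groups = agg.groups
    out = np.zeros((len(groups), len(collector_labels)))
    for i, s in enumerate(source_labels):
        out[groups.index(agg.mapping[s])] += counts[i]
    group_counts = pd.DataFrame(out, index=groups, columns=collector_labels)
    smoothed = group_counts + pseudocount
    proportions = smoothed / smoothed.sum(axis=0)
    return group_counts, proportions


@dataclass
class CohortFitResult:
    scores: np.ndarray  # per-cohort score (higher is better)
    best_cohort: int
    tie: bool
    predicted_vs_observed: pd.DataFrame
    mode: str

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cohort": np.arange(len(self.scores)), "score": self.scores}
        )


def cohort_fit(
    observed: pd.DataFrame,
    connectivity: ConnectivityMatrix,
    agg: StockAggregation | None = None,
    pseudocount: float = 0.5,
    mode: str = "multinomial",
) -> CohortFitResult:
    """Score each cohort's matrix against observed spat assignment counts.

    ``observed`` is a collectors x groups count table (hard genetic
    assignments of collected spats).  The default score is the multinomial
    log-likelihood of the observed group counts under the cohort's predicted
    per-collector group proportions; ``mode="cosine"`` scores the mean
    cosine similarity of count vectors instead.  Collectors with zero
    observed spats contribute nothing.  Ties resolve to the smallest cohort
    index and are flagged.
    """
    agg = agg or StockAggregation.clusters()
    if mode not in ("multinomial", "cosine"):
        raise ValueError(f"unknown fit mode {mode!r}")
    groups = agg.groups
    obs = observed.reindex(columns=groups, fill_value=0.0)
    scores = np.zeros(connectivity.n_cohorts)
    for c in range(connectivity.n_cohorts):
        _, prop = aggregate_connectivity(
            connectivity.counts[c],
            connectivity.source_labels,
            connectivity.collector_labels,
            agg,
            pseudocount,
        )
        total = 0.0
        for col in obs.index:
            counts = obs.loc[col].to_numpy(dtype=float)
            if counts.sum() == 0 or col not in prop.columns:
                continue
            p = prop[col].to_numpy()
            if mode == "multinomial":
                total += float((counts * np.log(p)).sum())
            else:
                num = float((counts * p).sum())
                den = np.linalg.norm(counts) * np.linalg.norm(p)
                total += num / den if den > 0 else 0.0
        scores[c] = total
    best = int(np.argmax(scores))
    tie = bool(np.sum(np.isclose(scores, scores[best], rtol=0, atol=1e-12)) > 1)

    _, best_prop = aggregate_connectivity(
        connectivity.counts[best],
        connectivity.source_labels,
        connectivity.collector_labels,
        agg,
        pseudocount,
    )
    obs_prop = obs.div(obs.sum(axis=1).replace(0, np.nan), axis=0)
    pred_vs_obs = pd.concat(
        {"observed": obs_prop, "predicted": best_prop.T.reindex(obs.index)}, axis=1
    )
    return CohortFitResult(
        scores=scores, best_cohort=best, tie=tie,
        predicted_vs_observed=pred_vs_obs, mode=mode,
    )


# ----------------------------------------------------------------------
# master configuration and pipeline
# ----------------------------------------------------------------------

@dataclass
class SpatScenario:
    """How synthetic spat cohorts are parented and spread over collectors."""

    parent_demes: tuple[str, ...] = NE_SOURCES
    n_cohorts: int = 2
    n_spats_per_cohort: int = 20
    n_parents: int = 5


@dataclass
class MasterConfig:
    seed: int = 0
    popsim: popsim.PopSimConfig = field(default_factory=popsim.PopSimConfig)
    spats: SpatScenario = field(default_factory=SpatScenario)
    filters: variants.FilterConfig = field(default_factory=variants.FilterConfig)
    fst_n_boot: int = 5000
    fis_n_perm: int = 199
    run_outlier_scan: bool = True
    outlier_n_burn: int = 1000
    outlier_n_iter: int = 2000
    outlier_thin: int = 5
    k_max: int = 6
    n_pca: int | None = None
    flow: lagoonflow.FlowConfig = field(
        default_factory=lambda: lagoonflow.FlowConfig(n_hours=14 * 168 + 25 * 24 + 24)
    )
    n_larvae_per_release: int = 150
    n_cohorts: int = 15
    dt_hours: float = 0.5
    census_mode: str = "first_entry"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def manifest_hash(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o).__name__)

        text = json.dumps(self.to_dict(), sort_keys=True, default=_default)
        return hashlib.sha256(text.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str) -> "MasterConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {
            "popsim": popsim.PopSimConfig,
            "spats": SpatScenario,
            "filters": variants.FilterConfig,
            "flow": lagoonflow.FlowConfig,
        }
        for key, val in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class PipelineResult:
    outdir: Path
    adults: GenotypeMatrix
    spats: GenotypeMatrix
    diversity: list
    fst: list
    cluster_model: structure.ClusterModel
    ne_cluster: object
    spat_membership: pd.DataFrame
    spat_assignments: np.ndarray
    connectivity: ConnectivityMatrix
    fit: CohortFitResult
    manifest: dict


def _female_ratio(meta: pd.DataFrame) -> pd.Series:
    sexed = meta[meta["sex"].isin(["M", "F"])]
    return sexed.groupby("deme")["sex"].apply(lambda s: float((s == "F").mean()))


def run_pipeline(config: MasterConfig | None = None, outdir: str | Path = "run") -> PipelineResult:
    """End-to-end synthetic study; writes all stage artifacts into ``outdir``."""
    config = config or MasterConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    stage_seed = {
        name: int(s)
        for name, s in zip(
            ["sim", "srs", "impute", "fst", "fis", "outlier", "cluster", "flow", "disp", "alloc"],
            master.integers(0, 2**31 - 1, size=10),
        )
    }

    # --- 1. simulate adults and spat cohorts -------------------------------
    sim_cfg = dataclasses.replace(config.popsim, seed=stage_seed["sim"])
    adults, freqs = popsim.simulate_dataset(sim_cfg)
    srs_rng = np.random.default_rng(stage_seed["srs"])
    parent_rows = np.flatnonzero(
        adults.individual_meta["deme"].isin(config.spats.parent_demes).to_numpy()
    )
    parent_pool = adults.subset(individuals=parent_rows)
    spat_cohorts = [
        popsim.simulate_srs_spat_cohort(
            parent_pool,
            n_parents=config.spats.n_parents,
            n_offspring=config.spats.n_spats_per_cohort,
            rng=srs_rng,
            cohort_label=f"spat{c + 1}",
        )
        for c in range(config.spats.n_cohorts)
    ]
    everyone = concatenate_individuals([adults, *spat_cohorts])
    variants.write_vcf(everyone, str(outdir / "sim.vcf"))
    everyone.individual_meta.to_csv(outdir / "meta.csv", index=False)

    # --- 2. filter + impute -------------------------------------------------
    filtered, report = variants.apply_filters(everyone, config.filters)
    report.to_json(str(outdir / "filter_report.json"))
    imputed = variants.impute_missing(filtered, grouping="deme", seed=stage_seed["impute"])

    is_spat = (imputed.individual_meta["stock"] == "spat").to_numpy()
    adults_f = imputed.subset(individuals=np.flatnonzero(~is_spat))
    spats_f = imputed.subset(individuals=np.flatnonzero(is_spat))

    # --- 3. outlier scan on adult demes, restrict to neutral loci ----------
    if config.run_outlier_scan:
        scan = popgen.outlier_scan(
            adults_f,
            grouping="deme",
            n_burn=config.outlier_n_burn,
            n_iter=config.outlier_n_iter,
            thin=config.outlier_thin,
            seed=stage_seed["outlier"],
        )
        pd.DataFrame(
            {
                "scaffold": adults_f.locus_meta["scaffold"],
                "pos": adults_f.locus_meta["pos"],
                "alpha": scan.alpha,
                "posterior_inclusion": scan.posterior_inclusion,
                "flagged": scan.flagged,
            }
        ).to_csv(outdir / "outlier_report.csv", index=False)
        neutral = scan.neutral_loci()
        adults_f = adults_f.subset(loci=neutral)
        spats_f = spats_f.subset(loci=neutral)

    # --- 4. population statistics ------------------------------------------
    diversity = popgen.pop_diversity(
        adults_f, "deme", n_perm=config.fis_n_perm, seed=stage_seed["fis"]
    )
    ratio = _female_ratio(adults_f.individual_meta)
    pd.DataFrame(
        [
            {
                "pop": d.pop,
                "n": d.n,
                "Ho": round(d.ho, 4),
                "He": round(d.he, 4),
                "Fis": round(d.fis, 4),
                "Fis_signif": d.significant,
                "female_ratio": round(float(ratio.get(d.pop, np.nan)), 3),
            }
            for d in diversity
        ]
    ).to_csv(outdir / "table1_diversity.csv", index=False)

    fst = popgen.pairwise_fst(
        adults_f, "deme", n_boot=config.fst_n_boot, seed=stage_seed["fst"]
    )
    popgen.fst_table(fst).to_csv(outdir / "fst_matrix.csv")
    popgen.relatedness_ajk(adults_f).to_csv(outdir / "relatedness.csv")

    # --- 5. clustering + spat assignment ------------------------------------
    pc, fc, model = structure.fit_structure(
        adults_f, k_max=config.k_max, seed=stage_seed["cluster"], n_pca=config.n_pca
    )
    fc.aic_by_k.to_csv(outdir / "aic_by_k.csv", index=False)
    pd.DataFrame(
        {"id": adults_f.individual_meta["id"], "cluster": fc.assignments}
    ).to_csv(outdir / "assignments.csv", index=False)
    model.membership_by_site(adults_f.individual_meta["deme"].to_numpy()).to_csv(
        outdir / "composition_by_site.csv"
    )

    # which cluster is the NE one: majority label among NE-deme adults
    ne_demes = [d for d, c in config.popsim.cluster_of_deme.items() if c == "cluster1"]
    ne_rows = adults_f.individual_meta["deme"].isin(ne_demes).to_numpy()
    ne_labels, ne_counts = np.unique(fc.assignments[ne_rows], return_counts=True)
    ne_cluster = ne_labels[np.argmax(ne_counts)]

    spat_membership, spat_hard = structure.assign_spats(model, spats_f)
    spat_membership.to_csv(outdir / "spat_membership.csv")

    # --- 6. flow + dispersal -------------------------------------------------
    flow_cfg = dataclasses.replace(config.flow, seed=stage_seed["flow"])
    field_ = lagoonflow.build_flow_field(flow_cfg)
    releases = ReleaseSpec(
        sources=dict(DEFAULT_SOURCE_POSITIONS),
        n_larvae_per_release=config.n_larvae_per_release,
        cohort_start_hours=tuple(168.0 * i for i in range(config.n_cohorts)),
    )
    collectors = CollectorSpec(collectors=dict(DEFAULT_COLLECTOR_POSITIONS))
    params = dispersal.AdvectionParams(dt_hours=config.dt_hours)
    conn, tallies = dispersal.run_dispersal(
        releases, collectors, field_, params, seed=stage_seed["disp"],
        census_mode=config.census_mode,
    )
    for c in range(conn.n_cohorts):
        conn.cohort_frame(c).to_csv(outdir / f"connectivity_cohort{c + 1:02d}.csv")
    conn.cumulated_frame().to_csv(outdir / "connectivity_cumulated.csv")

    # --- 7. confrontation ----------------------------------------------------
    # spats are physically spread over collectors (round-robin by default);
    # the observed table counts hard genetic assignments per collector
    alloc_rng = np.random.default_rng(stage_seed["alloc"])
    collector_names = list(collectors.collectors)
    spat_collector = np.array(
        [collector_names[i % len(collector_names)] for i in range(spats_f.n_individuals)]
    )
    alloc_rng.shuffle(spat_collector)
    agg = StockAggregation.clusters()
    group_of_cluster = {
        ne_cluster: "cluster1",
    }
    obs_groups = [
        group_of_cluster.get(lbl, "cluster2") for lbl in spat_hard
    ]
    observed = (
        pd.DataFrame({"collector": spat_collector, "group": obs_groups})
        .value_counts()
        .unstack(fill_value=0)
        .reindex(index=collector_names, columns=agg.groups, fill_value=0)
    )
    fit = cohort_fit(observed, conn, agg)
    fit.scores_frame().to_csv(outdir / "cohort_scores.csv", index=False)
    fit.predicted_vs_observed.to_csv(outdir / "predicted_vs_observed.csv")
    with open(outdir / "best_cohort.json", "w") as fh:
        json.dump({"best_cohort": fit.best_cohort, "tie": fit.tie}, fh)

    manifest = {
        "config_hash": config.manifest_hash(),
        "master_seed": config.seed,
        "stage_seeds": stage_seed,
        "n_loci_retained": int(adults_f.n_loci),
        "n_adults": int(adults_f.n_individuals),
        "n_spats": int(spats_f.n_individuals),
        "best_k": int(fc.best_k),
        "best_cohort": int(fit.best_cohort),
        "particle_tallies": tallies,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        outdir=outdir,
        adults=adults_f,
        spats=spats_f,
        diversity=diversity,
        fst=fst,
        cluster_model=model,
        ne_cluster=ne_cluster,
        spat_membership=spat_membership,
        spat_assignments=spat_hard,
        connectivity=conn,
        fit=fit,
        manifest=manifest,
    )
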