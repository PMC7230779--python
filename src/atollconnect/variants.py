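"""VCF input/output, genotype/locus/individual filtering, and imputation.

The filter cascade mirrors a GBS post-calling workflow, in order:

1. genotypes with depth below ``min_genotype_depth`` are set to missing;
2. loci that are not biallelic single-base SNPs are dropped;
3. loci flagged as "complex events" by the caller are dropped;
4. loci with minor allele frequency strictly below ``min_maf`` (computed on
   non-missing genotypes after step 1) are dropped;
5. loci whose missing fraction strictly exceeds ``max_locus_missing`` are
   dropped;
6. individuals whose missing fraction on the surviving loci strictly exceeds
   ``max_individual_missing`` are dropped.

Boundary values survive each threshold.  Missing genotypes are imputed by a
seeded within-group binomial draw from the group allele frequency (a
deterministic, model-free stand-in for learned imputation; downstream
statistics are insensitive to the substitution at these missingness levels).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "AllFilteredError",
    "read_vcf",
    "write_vcf",
    "apply_filters",
    "impute_missing",
]


@dataclass
class FilterConfig:
    min_genotype_depth: int = 10
    biallelic_snps_only: bool = True
    min_maf: float = 0.01
    max_locus_missing: float = 0.10
    drop_complex_events: bool = True
    max_individual_missing: float = 0.15

    def __post_init__(self) -> None:
        if self.min_genotype_depth < 0:
            raise ValueError("min_genotype_depth must be >= 0")
        for frac in (self.min_maf, self.max_locus_missing, self.max_individual_missing):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class FilterReport:
    """Bookkeeping of what each stage removed, in application order."""

    n_loci_in: int = 0
    n_individuals_in: int = 0
    genotypes_masked_low_depth: int = 0
    loci_dropped_not_biallelic_snp: int = 0
    loci_dropped_complex: int = 0
    loci_dropped_maf: int = 0
    loci_dropped_missing: int = 0
    individuals_dropped_missing: int = 0
    n_loci_out: int = 0
    n_individuals_out: int = 0
    missing_fraction_out: float = 0.0
    notes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        dropped = (
            self.loci_dropped_not_biallelic_snp
            + self.loci_dropped_complex
            + self.loci_dropped_maf
            + self.loci_dropped_missing
        )
        assert self.n_loci_in - dropped == self.n_loci_out
        assert (
            self.n_individuals_in - self.individuals_dropped_missing
            == self.n_individuals_out
        )

    def to_json(self, path: str | None = None) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __str__(self) -> str:  # human-readable log
        lines = [
            f"input: {self.n_individuals_in} individuals x {self.n_loci_in} loci",
            f"genotypes masked (depth): {self.genotypes_masked_low_depth}",
            f"loci dropped, not biallelic SNP: {self.loci_dropped_not_biallelic_snp}",
            f"loci dropped, complex event: {self.loci_dropped_complex}",
            f"loci dropped, MAF: {self.loci_dropped_maf}",
            f"loci dropped, missingness: {self.loci_dropped_missing}",
            f"individuals dropped, missingness: {self.individuals_dropped_missing}",
            f"output: {self.n_individuals_out} individuals x {self.n_loci_out} loci "
            f"({100 * self.missing_fraction_out:.2f}% missing)",
        ]
        return "\n".join(lines + self.notes)


class AllFilteredError(RuntimeError):
    """Raised when a filter stage leaves no loci or no individuals."""

    def __init__(self, stage: str, report: FilterReport):
        super().__init__(f"all_filtered at stage '{stage}'\n{report}")
        self.stage = stage
        self.report = report


# ----------------------------------------------------------------------
# VCF I/O (pysam)
# ----------------------------------------------------------------------

_COMPLEX_TYPES = {"complex", "mnp", "ins", "del", "indel"}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as VCF 4.2 with GT and DP per genotype."""
    header = pysam.VariantHeader()
    for scaffold, grp in matrix.locus_meta.groupby("scaffold", sort=False):
        header.contigs.add(str(scaffold), length=int(grp["pos"].max()) + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.info.add("TYPE", 1, "String", "Variant type annotation")
    sample_ids = [str(s) for s in matrix.individual_meta["id"]]
    for s in sample_ids:
        header.add_sample(s)

    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    has_depth = matrix.has_depth
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, row in matrix.locus_meta.iterrows():
            alts = tuple(str(row["alt"]).split(","))
            rec = out.new_record(
                contig=str(row["scaffold"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), *alts),
            )
            rec.info["TYPE"] = "complex" if bool(row["is_complex"]) else "snp"
            for i, s in enumerate(sample_ids):
                code = int(matrix.genotypes[i, j])
                rec.samples[s]["GT"] = gt_map.get(code, (None, None))
                if has_depth:
                    rec.samples[s]["DP"] = int(matrix.depth[i, j])
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF 4.x with GT (DP optional) into a :class:`GenotypeMatrix`.

    Multiallelic records are retained and flagged for the filter stage; the
    genotype code then counts non-reference alleles.  Ploidy other than 2 is
    an error.  Absent DP yields depth ``-1`` throughout (the depth filter is
    then skipped with a warning).
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        genotypes, depths, loci = [], [], []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            info_type = rec.info.get("TYPE", None)
            if isinstance(info_type, tuple):
                info_type = info_type[0]
            if info_type is not None:
                is_complex = str(info_type).lower() in _COMPLEX_TYPES
            else:
                is_complex = len(rec.ref) != 1 or any(len(a) != 1 for a in alts)
            loci.append(
                {
                    "scaffold": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": ",".join(alts),
                    "is_complex": is_complex,
                }
            )
            grow, drow = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None:
                    alleles = (None, None)
                if len(alleles) != 2:
                    raise ValueError(
                        f"ploidy != 2 at {rec.chrom}:{rec.pos} sample {s}"
                    )
                if any(a is None for a in alleles):
                    grow.append(MISSING)
                else:
                    grow.append(sum(1 for a in alleles if a > 0))
                dp = call.get("DP", None)
                drow.append(-1 if dp is None else int(dp))
            genotypes.append(grow)
            depths.append(drow)

    locus_meta = pd.DataFrame(loci)
    meta = pd.DataFrame(
        {
            "id": samples,
            "deme": "",
            "stock": "",
            "age": np.nan,
            "sex": "",
            "length_cm": np.nan,
            "cohort": "",
        }
    )
    g = np.asarray(genotypes, dtype=np.int16).T if genotypes else np.zeros((len(samples), 0), np.int16)
    d = np.asarray(depths, dtype=np.int32).T if depths else np.zeros((len(samples), 0), np.int32)
    return GenotypeMatrix(genotypes=g, depth=d, locus_meta=locus_meta, individual_meta=meta)


def attach_metadata(matrix: GenotypeMatrix, meta_csv: str) -> GenotypeMatrix:
    """Join a metadata CSV (by ``id``) onto the individual table."""
    meta = pd.read_csv(meta_csv, dtype={"id": str})
    out = matrix.copy()
    merged = out.individual_meta[["id"]].merge(meta, on="id", how="left")
    if merged["deme"].isna().any():
        missing = merged.loc[merged["deme"].isna(), "id"].tolist()
        raise ValueError(f"metadata missing for individuals: {missing[:5]}")
    out.individual_meta = merged
    return out


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def _is_biallelic_snp(locus_meta: pd.DataFrame) -> np.ndarray:
    single_alt = ~locus_meta["alt"].astype(str).str.contains(",")
    snp = (locus_meta["ref"].astype(str).str.len() == 1) & (
        locus_meta["alt"].astype(str).str.len() == 1
    )
    return (single_alt & snp).to_numpy()


def apply_filters(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the six-stage filter cascade; see the module docstring for order."""
    config = config or FilterConfig()
    report = FilterReport(
        n_loci_in=matrix.n_loci, n_individuals_in=matrix.n_individuals
    )
    report.notes.append(
        "MAF computed on non-missing genotypes after depth masking"
    )
    work = matrix.copy()

    # 1. depth masking
    if work.has_depth:
        low = (work.depth >= 0) & (work.depth < config.min_genotype_depth) & (
            work.genotypes != MISSING
        )
        report.genotypes_masked_low_depth = int(low.sum())
        work.genotypes[low] = MISSING
    else:
        warnings.warn("no DP field present; depth filter skipped")
        report.notes.append("depth filter skipped: no DP in input")

    keep = np.ones(work.n_loci, dtype=bool)

    # 2. biallelic SNPs only
    if config.biallelic_snps_only:
        ok = _is_biallelic_snp(work.locus_meta)
        report.loci_dropped_not_biallelic_snp = int((keep & ~ok).sum())
        keep &= ok
        if not keep.any():
            raise AllFilteredError("biallelic_snp", report)

    # 3. complex events
    if config.drop_complex_events:
        cx = work.locus_meta["is_complex"].to_numpy(dtype=bool)
        report.loci_dropped_complex = int((keep & cx).sum())
        keep &= ~cx
        if not keep.any():
            raise AllFilteredError("complex", report)

    # 4. minor allele frequency
    p = work.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    maf_fail = np.isnan(maf) | (maf < config.min_maf)
    report.loci_dropped_maf = int((keep & maf_fail).sum())
    keep &= ~maf_fail
    if not keep.any():
        raise AllFilteredError("maf", report)

    # 5. locus missingness
    miss_frac = work.missing_mask.mean(axis=0)
    miss_fail = miss_frac > config.max_locus_missing
    report.loci_dropped_missing = int((keep & miss_fail).sum())
    keep &= ~miss_fail
    if not keep.any():
        raise AllFilteredError("locus_missing", report)

    work = work.subset(loci=np.flatnonzero(keep))

    # 6. individual missingness, on surviving loci
    ind_miss = work.missing_mask.mean(axis=1)
    keep_ind = ind_miss <= config.max_individual_missing
    report.individuals_dropped_missing = int((~keep_ind).sum())
    if not keep_ind.any():
        raise AllFilteredError("individual_missing", report)
    work = work.subset(individuals=np.flatnonzero(keep_ind))

    report.n_loci_out = work.n_loci
    report.n_individuals_out = work.n_individuals
    report.missing_fraction_out = work.missing_fraction()
    report.validate()
    return work, report


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

def impute_missing(
    matrix: GenotypeMatrix,
    grouping: str | np.ndarray = "deme",
    seed: int = 0,
) -> GenotypeMatrix:
    """Impute missing genotypes by binomial draws from within-group frequencies.

    Each missing genotype is drawn ``Binomial(2, p_hat)`` with ``p_hat`` the
    non-missing alternate-allele frequency of that individual's group at that
    locus, falling back to the global frequency when the group has no call.
    Imputed entries are flagged in ``matrix.imputed``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    if isinstance(grouping, str):
        labels = out.individual_meta[grouping].astype(str).to_numpy()
    else:
        labels = np.asarray(grouping, dtype=str)
        if len(labels) != out.n_individuals:
            raise ValueError("grouping length mismatch")

    global_p = np.nan_to_num(out.allele_frequencies(), nan=0.5)
    miss = out.missing_mask
    imputed = np.zeros_like(miss)
    for label in pd.unique(labels):
        rows = np.flatnonzero(labels == label)
        sub = out.genotypes[rows]
        g = np.ma.masked_equal(sub, MISSING)
        with np.errstate(invalid="ignore"):
            p_grp = g.mean(axis=0).filled(np.nan) / 2.0
        p_grp = np.where(np.isnan(p_grp), global_p, p_grp)
        m = miss[rows]
        if not m.any():
            continue
        draws = rng.binomial(2, np.broadcast_to(p_grp, sub.shape)[m])
        sub = sub.copy()
        sub[m] = draws.astype(np.int16)
        out.genotypes[rows] = sub
        imputed[rows] = m
    out.imputed = imputed
    return out
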