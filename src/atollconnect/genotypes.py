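"""Diploid genotype matrix container shared by every genetic stage.

Genotypes are coded as the count of the alternate allele (0, 1, 2) with
``MISSING`` (-1) for uncalled genotypes.  Per-genotype sequencing depth is
carried alongside, together with per-locus metadata (scaffold, position,
alleles, caller flags) and per-individual metadata (site, stock class, age,
sex, shell length, cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: columns required in ``locus_meta``
LOCUS_COLUMNS = ("scaffold", "pos", "ref", "alt", "is_complex")
#: columns required in ``individual_meta``
INDIVIDUAL_COLUMNS = ("id", "deme", "stock", "age", "sex", "length_cm", "cohort")

STOCKS = ("exploited", "natural", "spat")


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype codes with depth and metadata.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` integer array of alternate-allele counts;
        ``MISSING`` marks uncalled genotypes.
    depth
        Same shape, non-negative read depth per genotype.  ``-1`` throughout
        when the source VCF carried no DP field.
    locus_meta
        One row per locus with at least :data:`LOCUS_COLUMNS`.  ``alt`` holds
        a comma-joined string for multi-allelic records (kept by the reader,
        handled by the filter stage).
    individual_meta
        One row per individual with at least :data:`INDIVIDUAL_COLUMNS`.
    """

    genotypes: np.ndarray
    depth: np.ndarray
    locus_meta: pd.DataFrame
    individual_meta: pd.DataFrame
    imputed: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.genotypes.shape != self.depth.shape:
            raise ValueError("genotypes and depth shapes differ")
        if len(self.locus_meta) != self.n_loci:
            raise ValueError("locus_meta length != number of loci")
        if len(self.individual_meta) != self.n_individuals:
            raise ValueError("individual_meta length != number of individuals")
        self.locus_meta = self.locus_meta.reset_index(drop=True)
        self.individual_meta = self.individual_meta.reset_index(drop=True)
        self._check_positions()

    def _check_positions(self) -> None:
        for _, grp in self.locus_meta.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within scaffold")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    @property
    def has_depth(self) -> bool:
        return bool(np.any(self.depth >= 0))

    def missing_fraction(self) -> float:
        if self.genotypes.size == 0:
            return 0.0
        return float(self.missing_mask.mean())

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus from non-missing calls.

        Loci with no calls return ``nan``.
        """
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            freq = g.mean(axis=0).filled(np.nan) / 2.0
        return freq

    def polymorphic_mask(self) -> np.ndarray:
        p = self.allele_frequencies()
        with np.errstate(invalid="ignore"):
            return (p > 0) & (p < 1)

    # ------------------------------------------------------------------
    def subset(
        self,
        individuals: np.ndarray | None = None,
        loci: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual/locus indices."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(ind, loc)].copy(),
            depth=self.depth[np.ix_(ind, loc)].copy(),
            locus_meta=self.locus_meta.iloc[loc].copy(),
            individual_meta=self.individual_meta.iloc[ind].copy(),
            imputed=None if self.imputed is None else self.imputed[np.ix_(ind, loc)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()

    def groups(self, by: str = "deme") -> dict[str, np.ndarray]:
        """Map group label -> individual index array, in order of appearance."""
        col = self.individual_meta[by]
        out: dict[str, np.ndarray] = {}
        for label in col[~col.isna()].unique():
            out[str(label)] = np.flatnonzero((col == label).to_numpy())
        return out


def concatenate_individuals(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices sharing an identical locus panel along individuals."""
    first = matrices[0]
    for m in matrices[1:]:
        if len(m.locus_meta) != len(first.locus_meta) or not np.array_equal(
            m.locus_meta["pos"].to_numpy(), first.locus_meta["pos"].to_numpy()
        ):
            raise ValueError("locus panels differ between matrices")
    return GenotypeMatrix(
        genotypes=np.vstack([m.genotypes for m in matrices]),
        depth=np.vstack([m.depth for m in matrices]),
        locus_meta=first.locus_meta.copy(),
        individual_meta=pd.concat(
            [m.individual_meta for m in matrices], ignore_index=True
        ),
    )
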