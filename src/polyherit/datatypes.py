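"""Core in-memory containers shared across the pipeline.

The universal substrate is :class:`CohortData`: an individuals x SNPs dosage
matrix plus per-SNP metadata and an optional binary phenotype / covariate
table.  Genomic fixtures (gene models, per-cell-type peak tracks, a PPI edge
list, conservation scores) live in :class:`GenomeFixture`.

Coordinate conventions
----------------------
* SNP positions are 1-based (as in VCF / summary-statistic tables).
* All intervals (genes, coding subintervals, peaks) are 0-based half-open,
  BED style.  Conversions happen inside the functions that mix the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical column order of a SNP metadata table
SNP_TABLE_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "freq", "info"]

#: the three mutually exclusive genomic compartments
COMPARTMENTS = ("genic_coding", "genic_noncoding", "intergenic")


@dataclass
class CohortData:
    """Dosage matrix with SNP metadata and phenotype/covariates.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` array with values in ``[0, 2]``; ``NaN``
        encodes a missing call.
    snp_table
        One row per SNP with columns :data:`SNP_TABLE_COLUMNS`.
    phenotype
        Optional binary (0/1) disease status per individual.
    covariates
        Optional ``(n_individuals, k)`` numeric covariate matrix.
    """

    dosages: np.ndarray
    snp_table: pd.DataFrame
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        if len(self.snp_table) != self.dosages.shape[1]:
            raise ValueError(
                f"snp_table has {len(self.snp_table)} rows but dosage matrix "
                f"has {self.dosages.shape[1]} columns"
            )
        missing = [c for c in SNP_TABLE_COLUMNS if c not in self.snp_table.columns]
        if missing:
            raise ValueError(f"snp_table lacks required columns: {missing}")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype)
            if len(self.phenotype) != self.dosages.shape[0]:
                raise ValueError("phenotype length does not match individuals")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.dosages.shape[0]:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.dosages.shape[0]:
                raise ValueError("covariates do not match number of individuals")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.dosages.shape[0])
        else:
            self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_indices(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given SNP ids (raises on unknown ids)."""
        lookup = pd.Index(self.snp_table["snp"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            bad = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not present in cohort: {bad[:5]}")
        return idx

    def subset_snps(self, mask_or_ids) -> "CohortData":
        """New cohort restricted to a boolean mask / index array / id list."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif arr.dtype.kind in "iu":
            idx = arr
        else:
            idx = self.snp_indices(arr)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            snp_table=self.snp_table.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, idx) -> "CohortData":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            sample_ids=self.sample_ids[idx],
        )


@dataclass
class GeneModel:
    """A gene interval with strand and coding subintervals (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    coding: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for s, e in self.coding:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: coding subinterval [{s},{e}) not nested "
                    f"within gene bounds [{self.start},{self.end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based), strand-aware."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (0-based), strand-aware."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeFixture:
    """Synthetic stand-in for gene models, regulatory tracks and a PPI graph.

    ``peak_tracks[mark][cell_type]`` is a ``(k, 2)`` integer array of merged,
    sorted, half-open peak intervals.  ``conservation`` is a per-SNP score
    aligned with the cohort's SNP order.
    """

    gene_models: list[GeneModel]
    peak_tracks: dict[str, dict[str, np.ndarray]]
    ppi_edges: list[tuple[str, str]]
    conservation: np.ndarray | None = None
    genome_length: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.ppi_edges:
            if a == b:
                raise ValueError(f"PPI self-loop on {a}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate PPI edge {a}-{b}")
            seen.add(key)

    @property
    def cell_types(self) -> list[str]:
        for tracks in self.peak_tracks.values():
            return sorted(tracks)
        return []

    @property
    def marks(self) -> list[str]:
        return sorted(self.peak_tracks)


@dataclass
class CompartmentAssignment:
    """Exclusive compartment label per SNP at a given genic window size."""

    labels: pd.Series  # index: snp id, values in COMPARTMENTS
    window_kb: float

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {bad}")

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(COMPARTMENTS, fill_value=0)

    def snps_in(self, compartment: str) -> list[str]:
        if compartment not in COMPARTMENTS:
            raise KeyError(compartment)
        return list(self.labels.index[self.labels == compartment])


@dataclass
class LocusSet:
    """A lead GWAS SNP plus its LD tags at ``r2 >= r2_threshold``."""

    lead: str
    tags: dict[str, float]  # tag snp id -> r2 with the lead
    r2_threshold: float

    def __post_init__(self) -> None:
        self.tags.setdefault(self.lead, 1.0)
        low = {s: r for s, r in self.tags.items() if r < self.r2_threshold - 1e-12}
        if low:
            raise ValueError(f"tags below r2 threshold in locus {self.lead}: {low}")

    @property
    def snps(self) -> list[str]:
        return list(self.tags)
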