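"""SNP annotation: genomic compartments, regulatory-mark overlap, LD loci.

Compartments are exclusive with precedence coding > genic noncoding >
intergenic.  A SNP is "genic" if it falls within a gene body or within
``window_kb`` of the gene bounds, boundary inclusive: a SNP exactly
``window_kb`` bases from the outermost gene base still counts as genic.

Coordinate rule: all intervals are half-open ``[start, end)`` and a SNP at
position ``p`` overlaps an interval iff ``start <= p < end`` — positions are
compared directly on the interval axis, so the last covered position of a
peak ``[4000, 6000)`` is 5999.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import CohortData, CompartmentAssignment, GeneModel, LocusSet

logger = logging.getLogger(__name__)


def _merge(iv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted, merged interval set -> (starts, ends)."""
    if len(iv) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    iv = np.asarray(iv)
    order = np.argsort(iv[:, 0], kind="stable")
    iv = iv[order]
    starts, ends = [int(iv[0, 0])], [int(iv[0, 1])]
    for s, e in iv[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], int(e))
        else:
            starts.append(int(s))
            ends.append(int(e))
    return np.array(starts), np.array(ends)


def _points_in_intervals(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of 0-based points in a merged half-open interval set."""
    if len(starts) == 0:
        return np.zeros(len(pos0), dtype=bool)
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos0), dtype=bool)
    out[ok] = pos0[ok] < ends[idx[ok]]
    return out


def classify_compartments(
    snp_table: pd.DataFrame,
    gene_models: list[GeneModel],
    window_kb: float = 10.0,
) -> CompartmentAssignment:
    """Exclusive genic_coding / genic_noncoding / intergenic label per SNP.

    SNPs on chromosomes absent from the gene models are intergenic (logged,
    not an error).
    """
    w = int(window_kb * 1000)
    coding_by_chrom: dict[str, np.ndarray] = {}
    genic_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {g.chrom for g in gene_models}:
        genes = [g for g in gene_models if g.chrom == chrom]
        coding = [c for g in genes for c in g.coding]
        coding_by_chrom[chrom] = np.array(coding) if coding else np.empty((0, 2))
        genic_by_chrom[chrom] = np.array([[max(0, g.start - w), g.end + w] for g in genes])

    labels = np.full(len(snp_table), "intergenic", dtype=object)
    for chrom, grp in snp_table.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy()
        loc = snp_table.index.get_indexer(grp.index)
        if chrom not in genic_by_chrom:
            if gene_models:
                logger.info("chromosome %s absent from gene models; SNPs set intergenic", chrom)
            continue
        cs, ce = _merge(coding_by_chrom[chrom])
        gs, ge = _merge(genic_by_chrom[chrom])
        in_coding = _points_in_intervals(pos0, cs, ce)
        in_genic = _points_in_intervals(pos0, gs, ge)
        labels[loc[in_coding]] = "genic_coding"
        labels[loc[in_genic & ~in_coding]] = "genic_noncoding"
    return CompartmentAssignment(
        labels=pd.Series(labels, index=snp_table["snp"].to_numpy(), name="compartment"),
        window_kb=window_kb,
    )


def overlap_marks(
    snp_table: pd.DataFrame,
    peak_tracks: dict[str, dict[str, np.ndarray]],
) -> pd.DataFrame:
    """Binary SNP x (mark, cell type) membership matrix.

    ``peak_tracks[mark][cell_type]`` are half-open intervals; membership is 1
    iff the SNP's 0-based position lies inside at least one peak.  Unsorted
    tracks are sorted (and merged) internally with a warning.
    """
    pos0 = snp_table["pos"].to_numpy()
    cols = {}
    for mark, tracks in peak_tracks.items():
        for ct, iv in tracks.items():
            iv = np.asarray(iv).reshape(-1, 2)
            if len(iv) > 1 and not (np.diff(iv[:, 0]) >= 0).all():
                warnings.warn(f"peak track {mark}/{ct} unsorted; sorting internally")
            starts, ends = _merge(iv)
            cols[(mark, ct)] = _points_in_intervals(pos0, starts, ends)
    out = pd.DataFrame(cols, index=snp_table["snp"].to_numpy())
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["mark", "cell_type"])
    return out


def ld_expand(
    leads: list[str],
    cohort: CohortData,
    r2_threshold: float = 0.8,
    drop_failed: bool = False,
) -> list[LocusSet]:
    """Expand each lead SNP to its locus: all same-chromosome SNPs with
    dosage-r2 >= threshold.

    A monomorphic lead has undefined correlation: raises by default, or drops
    the lead with a report when ``drop_failed`` is set (mirroring query SNPs
    dropped for matching failure).
    """
    snp = cohort.snp_table
    x = cohort.dosages
    sd = x.std(axis=0)
    centered = x - x.mean(axis=0)
    loci = []
    for lead in leads:
        j = int(cohort.snp_indices([lead])[0])
        if sd[j] == 0:
            if drop_failed:
                logger.warning("lead %s monomorphic; dropped from LD expansion", lead)
                continue
            raise ValueError(f"lead SNP {lead} is monomorphic; r2 undefined")
        same_chrom = (snp["chrom"] == snp["chrom"].iloc[j]).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (centered.T @ centered[:, j]) / (len(x) * sd * sd[j])
        r2 = np.square(r)
        r2[~same_chrom] = 0.0
        r2[sd == 0] = 0.0
        hits = np.flatnonzero(r2 >= r2_threshold)
        tags = {snp["snp"].iloc[k]: float(r2[k]) for k in hits}
        tags[lead] = 1.0
        loci.append(LocusSet(lead=lead, tags=tags, r2_threshold=r2_threshold))
    return loci


def map_loci_to_genes(
    loci: list[LocusSet],
    gene_models: list[GeneModel],
    snp_table: pd.DataFrame,
    upstream_kb: float = 110.0,
    downstream_kb: float = 40.0,
) -> dict[str, set[str]]:
    """Assign genes to loci via strand-oriented regulatory windows.

    A gene belongs to a locus iff any lead/tag SNP lies within
    [TSS - upstream_kb, TES + downstream_kb], flipped for minus-strand genes;
    window boundaries are inclusive on both sides (a SNP exactly
    ``upstream_kb`` from the TSS is included).
    """
    up = int(upstream_kb * 1000)
    down = int(downstream_kb * 1000)
    pos_by_snp = dict(zip(snp_table["snp"], snp_table["pos"]))
    chrom_by_snp = dict(zip(snp_table["snp"], snp_table["chrom"]))
    windows = []
    for g in gene_models:
        first, last = g.start, g.end - 1  # outermost covered positions
        if g.strand == "+":
            lo, hi = first - up, last + down
        else:
            lo, hi = first - down, last + up
        windows.append((g.chrom, lo, hi, g.gene_id))

    out: dict[str, set[str]] = {}
    for locus in loci:
        genes: set[str] = set()
        positions = [
            (chrom_by_snp[s], pos_by_snp[s]) for s in locus.snps if s in pos_by_snp
        ]
        for chrom, lo, hi, gid in windows:
            if any(c == chrom and lo <= p <= hi for c, p in positions):
                genes.add(gid)
        out[locus.lead] = genes
    return out
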