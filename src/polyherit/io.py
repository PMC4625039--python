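"""Plain-text interchange: TSV dosages, BED tracks, GRM triples, YAML config."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CohortData, GeneModel
from .heritability import GRM
from .synthetic import SimulationConfig


def write_cohort(cohort: CohortData, prefix: str | Path) -> None:
    """Write dosages (individuals x SNPs), SNP table and phenotype as TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dos = pd.DataFrame(cohort.dosages, columns=cohort.snp_table["snp"])
    dos.insert(0, "sample_id", cohort.sample_ids)
    dos.to_csv(f"{prefix}.dosages.tsv", sep="\t", index=False)
    cohort.snp_table.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
    if cohort.phenotype is not None:
        pd.DataFrame(
            {"sample_id": cohort.sample_ids, "phenotype": cohort.phenotype}
        ).to_csv(f"{prefix}.phen.tsv", sep="\t", index=False)


def read_cohort(prefix: str | Path) -> CohortData:
    prefix = Path(prefix)
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    sample_ids = dos.pop("sample_id").to_numpy()
    snp = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
    phen = None
    phen_path = Path(f"{prefix}.phen.tsv")
    if phen_path.exists():
        phen = pd.read_csv(phen_path, sep="\t")["phenotype"].to_numpy()
    return CohortData(dosages=dos.to_numpy(), snp_table=snp, phenotype=phen, sample_ids=sample_ids)


def write_bed3(intervals: np.ndarray, path: str | Path, chrom: str = "1") -> None:
    with open(path, "w") as fh:
        for s, e in np.asarray(intervals).reshape(-1, 2):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_bed3(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[1, 2])
    return df.to_numpy(dtype=int)


def write_genes_bed12(genes: list[GeneModel], path: str | Path) -> None:
    """Gene models as BED12 (coding subintervals as blocks)."""
    with open(path, "w") as fh:
        for g in genes:
            blocks = sorted(g.coding) or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - g.start) for s, _ in blocks)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{blocks[0][0]}\t{blocks[-1][1]}\t0\t{len(blocks)}\t{sizes},\t{starts},\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            coding = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                GeneModel(gene_id=f[3], chrom=f[0], start=start, end=int(f[2]),
                          strand=f[5], coding=coding)
            )
    return genes


def write_ppi(edges: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.to_numpy()]


def write_grm(grm: GRM, prefix: str | Path) -> None:
    """Indexed lower-triangle text format (1-based pair, SNP count, value)."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{grm.n_snps}\t{grm.matrix[j, k]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for i in grm.ids:
            fh.write(f"{i}\n")


def read_grm(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = np.array([line.strip() for line in open(f"{prefix}.grm.id")])
    n = len(ids)
    a = np.zeros((n, n))
    m = 0
    with open(f"{prefix}.grm.txt") as fh:
        for line in fh:
            j, k, m, v = line.split("\t")
            j, k = int(j) - 1, int(k) - 1
            a[j, k] = a[k, j] = float(v)
    return GRM(matrix=a, n_snps=int(m), ids=ids)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("maf_range",):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
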