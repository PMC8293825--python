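"""Reading and writing genotype/phenotype tables.

Two genotype formats are supported: a plain tab-delimited individuals x
SNPs dosage matrix (header row of SNP ids, first column the individual
id, values in [0, 2]) and VCF (GT or DS fields converted to additive
dosage).  Phenotypes are two-column tab-delimited (id, value).  Ids are
joined strictly; mismatches are fatal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def read_genotypes_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (dosage matrix, individual ids, snp ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    G = df.to_numpy(dtype=float)
    if np.isnan(G).any():
        raise ValueError(f"{path}: missing dosage values are not supported")
    if G.size and (G.min() < 0 or G.max() > 2):
        raise ValueError(f"{path}: dosages must lie in [0, 2]")
    return G, [str(i) for i in df.index], [str(c) for c in df.columns]


def write_genotypes_tsv(path, G: np.ndarray, individual_ids, snp_ids) -> None:
    pd.DataFrame(G, index=list(individual_ids), columns=list(snp_ids)).to_csv(
        path, sep="\t", index_label="individual"
    )


def read_genotypes_vcf(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Additive dosages from a VCF: DS field when present, else GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snp_ids, columns = [], []
    for var in vcf:
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gts = np.asarray(var.genotype.array())[:, :2]
            if (gts < 0).any():
                raise ValueError(f"{path}: missing genotype at {sid}")
            ds = gts.sum(axis=1).astype(float)
        snp_ids.append(sid)
        columns.append(ds)
    vcf.close()
    if not columns:
        raise ValueError(f"{path}: no variants found")
    return np.column_stack(columns), individuals, snp_ids


def write_genotypes_vcf(path, G: np.ndarray, individual_ids, snp_ids) -> None:
    """Minimal uncompressed VCF with hard GT calls (dosages rounded)."""
    individual_ids = list(individual_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, sid in enumerate(snp_ids):
            calls = [gt_map[int(round(v))] for v in G[:, j]]
            fh.write(
                f"1\t{j + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_phenotype_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-delimited columns (id, value)")
    # tolerate an optional header line
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    values = df.iloc[:, 1].astype(float).to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing phenotype values are not supported")
    return values, [str(i) for i in df.iloc[:, 0]]


def write_phenotype_tsv(path, y: np.ndarray, individual_ids) -> None:
    pd.DataFrame({"individual": list(individual_ids), "value": y}).to_csv(
        path, sep="\t", index=False, header=False
    )


def join_genotypes_phenotype(
    G: np.ndarray,
    genotype_ids: Sequence[str],
    y: np.ndarray,
    phenotype_ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Strictly align genotype rows with phenotype entries by id."""
    gpos = {str(i): k for k, i in enumerate(genotype_ids)}
    missing = [str(i) for i in phenotype_ids if str(i) not in gpos]
    extra = [str(i) for i in genotype_ids if str(i) not in set(map(str, phenotype_ids))]
    if missing or extra:
        raise ValueError(
            "genotype/phenotype id mismatch: "
            f"{len(missing)} phenotype ids without genotypes "
            f"(e.g. {missing[:3]}), {len(extra)} genotype ids without "
            f"phenotypes (e.g. {extra[:3]})"
        )
    order = [gpos[str(i)] for i in phenotype_ids]
    return G[order], np.asarray(y, dtype=float), [str(i) for i in phenotype_ids]


def load_dataset(genotype_path, phenotype_path):
    """Load and strictly join a genotype matrix (TSV or VCF) and phenotype."""
    gp = Path(genotype_path)
    if gp.suffix in (".vcf", ".gz") or gp.name.endswith(".vcf.gz"):
        G, gids, snp_ids = read_genotypes_vcf(gp)
    else:
        G, gids, snp_ids = read_genotypes_tsv(gp)
    y, pids = read_phenotype_tsv(phenotype_path)
    G, y, ids = join_genotypes_phenotype(G, gids, y, pids)
    return G, y, snp_ids, ids
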