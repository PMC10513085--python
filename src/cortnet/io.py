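"""File formats: VCF genotypes, TSV matrices, GMT gene sets, JSON truth.

Genotypes are written as unphased VCF 4.2 (GT field only) and read back
through cyvcf2; expression matrices are genes x samples TSVs with the gene
id in the first column; gene sets use the GMT convention (name, description,
members).  Round-trips reproduce the in-memory objects exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import Cohort, SimulationConfig, TruthModel

log = logging.getLogger(__name__)

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}
FLOAT_FMT = "%.10g"


def write_vcf(genotypes: pd.DataFrame, snp_info: pd.DataFrame, path) -> Path:
    """Write a dosage matrix (SNPs x samples) as an unphased VCF."""
    path = Path(path)
    samples = list(genotypes.columns)
    order = snp_info.sort_values(["chrom", "pos"]).index
    contigs = sorted(snp_info["chrom"].unique())
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=cortnet\n")
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for sid in order:
                row = genotypes.loc[sid]
                gts = "\t".join(_GT[int(v)] for v in row)
                info = snp_info.loc[sid]
                fh.write(f"{info['chrom']}\t{int(info['pos'])}\t{sid}\tA\tG\t"
                         f".\tPASS\t.\tGT\t{gts}\n")
    except OSError as exc:
        raise OSError(f"failed to write VCF at {path}: {exc}") from exc
    return path


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (dosage matrix, snp info) via cyvcf2."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, chroms, poss = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0, 1, -1, 2], dtype=np.int8)
    for var in vcf:
        ids.append(var.ID)
        rows.append(code[var.gt_types])
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    geno = pd.DataFrame(np.stack(rows), index=pd.Index(ids, name="snp"),
                        columns=samples)
    info = pd.DataFrame({"chrom": chroms, "pos": poss},
                        index=pd.Index(ids, name="snp"))
    return geno.sort_index(), info.sort_index()


def write_expression(expr: pd.DataFrame, path) -> Path:
    path = Path(path)
    expr.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)
    return path


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_gmt(sets: dict[str, set[str]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tcortnet\t{members}\n")
    return path


def read_gmt(path) -> dict[str, set[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Serialize a simulated cohort; round-trip read reproduces it exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    files["vcf"] = write_vcf(cohort.genotypes, cohort.snp_info,
                             out_dir / "genotypes.vcf")
    for tissue, mat in cohort.expression.items():
        files[f"expr_{tissue}"] = write_expression(
            mat, out_dir / f"expression_{tissue}.tsv")
    for tissue, mat in cohort.replication.items():
        files[f"repl_{tissue}"] = write_expression(
            mat, out_dir / f"replication_{tissue}.tsv")
    cohort.summary.to_csv(out_dir / "summary_stats.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT)
    files["summary"] = out_dir / "summary_stats.tsv"
    cohort.gene_info.to_csv(out_dir / "genes.tsv", sep="\t",
                            index_label="gene")
    files["genes"] = out_dir / "genes.tsv"
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1, sort_keys=True)
    files["truth"] = out_dir / "truth.json"
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    files["config"] = out_dir / "config.yaml"
    return files


def read_cohort(out_dir) -> Cohort:
    """Reconstruct a cohort from :func:`write_cohort` output.

    Expression values survive the round trip to the printed precision
    (10 significant digits); genotypes and the truth ledger exactly.
    """
    out_dir = Path(out_dir)
    config = SimulationConfig.from_yaml(out_dir / "config.yaml")
    geno, vcf_info = read_vcf(out_dir / "genotypes.vcf")
    summary = pd.read_csv(out_dir / "summary_stats.tsv", sep="\t",
                          dtype={"chrom": str})
    snp_info = summary.set_index("snp")[["chrom", "pos", "block"]].sort_index()
    gene_info = pd.read_csv(out_dir / "genes.tsv", sep="\t", index_col="gene",
                            dtype={"chrom": str})
    with open(out_dir / "truth.json") as fh:
        truth = TruthModel.from_dict(json.load(fh))
    expression, replication = {}, {}
    for tissue in config.tissues():
        expression[tissue] = read_expression(
            out_dir / f"expression_{tissue}.tsv")
        repl_path = out_dir / f"replication_{tissue}.tsv"
        if repl_path.exists():
            replication[tissue] = read_expression(repl_path)
    return Cohort(geno, snp_info, expression, gene_info, summary, truth,
                  config, replication)
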