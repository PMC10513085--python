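"""Stage 1: multi-tissue trans-eQTL scan with global-FDR selection.

Genome-wide-significant trait SNPs are tested against every gene of every
tissue with the secondary linkage test; LLRs are converted to posteriors
per SNP across the tissue's gene ensemble, and associations are selected so
that the Bayesian global FDR of the selection, 1 - mean(posterior), stays
below the nominal threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causal import (NullModel, _anova_llr, _encode_genotype,
                     estimate_posteriors, llr_null_pvalue, supernormalize_rows)

log = logging.getLogger(__name__)

RECORD_COLUMNS = ("snp", "gene", "tissue", "block", "llr", "pvalue",
                  "posterior", "cis", "selected", "status")

#: cis/trans labeling window around a SNP (bp)
CIS_WINDOW = 1_000_000


def filter_gwas_snps(summary: pd.DataFrame, threshold: float = 5e-8) -> list[str]:
    """SNPs with trait p-value strictly below ``threshold``, in input order."""
    missing = {"snp", "pval"} - set(summary.columns)
    if missing:
        raise ValueError(f"summary statistics lack columns: {sorted(missing)}")
    kept = summary.loc[summary["pval"] < threshold, "snp"]
    return list(kept)


def scan_tissue(
    snps,
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    tissue: str,
    snp_info: pd.DataFrame | None = None,
    gene_info: pd.DataFrame | None = None,
    cis_window: int = CIS_WINDOW,
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Test every (SNP, gene) pair of one tissue with the secondary linkage test.

    Returns one record per pair with llr, analytic p-value and posterior;
    posteriors are estimated per SNP across the tissue's gene ensemble.
    SNPs monomorphic in the overlapping samples yield records flagged
    ``status='monomorphic'`` with NaN statistics rather than being dropped.
    """
    snps = list(snps)
    samples = genotypes.columns.intersection(expression.columns)
    if len(samples) < min_overlap:
        raise ValueError(
            f"insufficient sample overlap between genotypes and expression: "
            f"{len(samples)} < {min_overlap}"
        )
    genes = list(expression.index)
    Y = supernormalize_rows(expression.loc[:, samples].to_numpy()).T  # n x G

    frames = []
    for sid in snps:
        if sid not in genotypes.index:
            raise KeyError(f"SNP {sid!r} absent from genotype matrix")
        E = genotypes.loc[sid, samples].to_numpy()
        inv, k = _encode_genotype(E)
        block = (int(snp_info.loc[sid, "block"])
                 if snp_info is not None and sid in snp_info.index else -1)
        if k < 2:
            log.warning("SNP %s monomorphic in %s; flagging %d records",
                        sid, tissue, len(genes))
            frames.append(pd.DataFrame({
                "snp": sid, "gene": genes, "tissue": tissue, "block": block,
                "llr": np.nan, "pvalue": np.nan, "posterior": np.nan,
                "cis": _cis_flags(sid, genes, snp_info, gene_info, cis_window),
                "selected": False, "status": "monomorphic",
            }))
            continue
        null = NullModel(n=len(samples), k=k)
        llr = _anova_llr(inv, k, Y)
        pval = llr_null_pvalue(llr, null.n, null.k)
        post = estimate_posteriors(llr, null)
        frames.append(pd.DataFrame({
            "snp": sid, "gene": genes, "tissue": tissue, "block": block,
            "llr": llr, "pvalue": pval, "posterior": post,
            "cis": _cis_flags(sid, genes, snp_info, gene_info, cis_window),
            "selected": False, "status": "ok",
        }))
    if not frames:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def _cis_flags(sid, genes, snp_info, gene_info, window) -> bool | list[bool]:
    if snp_info is None or gene_info is None or sid not in snp_info.index:
        return False
    chrom = snp_info.loc[sid, "chrom"]
    pos = int(snp_info.loc[sid, "pos"])
    gi = gene_info.reindex(genes)
    return list((gi["chrom"].astype(str) == str(chrom))
                & ((gi["pos"] - pos).abs() <= window))


@dataclass
class SelectionResult:
    """Posterior-descending prefix whose global FDR meets the threshold."""

    records: pd.DataFrame
    achieved_fdr: float
    threshold: float

    def __post_init__(self) -> None:
        if self.achieved_fdr > self.threshold + 1e-9:
            raise ValueError("achieved FDR exceeds the nominal threshold")


def select_by_global_fdr(
    records: pd.DataFrame,
    threshold: float,
    tie_cols: tuple[str, ...] = ("snp", "gene"),
) -> SelectionResult:
    """Largest posterior-descending prefix with 1 - mean(posterior) <= threshold.

    Ties in the posterior are broken lexicographically on ``tie_cols`` for
    determinism.  Records with missing posteriors (e.g. monomorphic flags)
    are never selectable.  An empty selection has achieved FDR 0.
    """
    usable = records.dropna(subset=["posterior"])
    if usable.empty:
        return SelectionResult(usable.copy(), 0.0, threshold)
    order = usable.sort_values(
        by=["posterior", *tie_cols],
        ascending=[False] + [True] * len(tie_cols),
        kind="mergesort",
    )
    post = order["posterior"].to_numpy()
    fdr = 1.0 - np.cumsum(post) / np.arange(1, post.size + 1)
    ok = np.nonzero(fdr <= threshold + 1e-12)[0]
    n_sel = int(ok[-1] + 1) if ok.size else 0
    selected = order.iloc[:n_sel].copy()
    if "selected" in selected.columns:
        selected["selected"] = True
    achieved = float(fdr[n_sel - 1]) if n_sel else 0.0
    return SelectionResult(selected, max(achieved, 0.0), threshold)


def tabulate_sharing(selections: dict[str, pd.DataFrame]) -> dict:
    """Tissue sharing and LD-block composition of the selected associations.

    Returns unique-gene counts per tissue, gene counts per tissue
    combination (upset-style, keyed by '+'-joined sorted tissue names), and
    association counts per LD block per tissue.
    """
    gene_tissues: dict[str, set[str]] = {}
    per_tissue: dict[str, int] = {}
    per_block: dict[str, dict[str, int]] = {}
    for tissue, df in selections.items():
        genes = set(df["gene"]) if len(df) else set()
        per_tissue[tissue] = len(genes)
        for g in genes:
            gene_tissues.setdefault(g, set()).add(tissue)
        counts = df.groupby("block").size() if len(df) else {}
        per_block[tissue] = {str(b): int(c) for b, c in dict(counts).items()}
    per_combination: dict[str, int] = {}
    for g, tissues in gene_tissues.items():
        key = "+".join(sorted(tissues))
        per_combination[key] = per_combination.get(key, 0) + 1
    return {
        "per_tissue": per_tissue,
        "per_combination": dict(sorted(per_combination.items())),
        "per_block": per_block,
    }
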