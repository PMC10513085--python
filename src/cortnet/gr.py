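"""Stage 2: glucocorticoid-receptor evidence scoring and instrument selection.

Trans-genes are scored 0-4 against four evidence criteria for regulation by
the glucocorticoid receptor (GR, encoded by NR3C1):

1. presence in a transcription-factor database (ENCODE, TRANSFAC, CHEA) —
   counted once however many databases contain the gene, all tissues;
2. GR ChIP-seq target in adipocytes — adipose tissues only;
3. differentially expressed under dexamethasone in adipocytes — adipose
   tissues only;
4. murine homolog dexamethasone-responsive (fold change > 1, p < 0.05) —
   subcutaneous adipose only.

Genes scoring at least 1 are carried forward; each is paired with the cis
SNP whose primary-linkage posterior is highest, provided it clears the
instrument-validity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scan import scan_tissue

log = logging.getLogger(__name__)

CRITERIA = (1, 2, 3, 4)

#: fold-change and p-value cutoffs for the murine dexamethasone criterion
MURINE_FC_MIN = 1.0
MURINE_P_MAX = 0.05

#: default validity threshold on the instrument's primary-linkage posterior
INSTRUMENT_POSTERIOR = 0.75


def default_applicability(tissues: Sequence[str]) -> dict[int, set[str]]:
    """Criterion -> tissues where it may be counted.

    Database evidence applies everywhere; adipocyte perturbation evidence
    only in adipose tissues; the murine subcutaneous experiment only in
    subcutaneous fat.
    """
    tissues = set(tissues)
    adipose = {t for t in tissues if "fat" in t or "adipose" in t}
    return {
        1: set(tissues),
        2: set(adipose),
        3: set(adipose),
        4: {t for t in adipose if "subcutaneous" in t},
    }


@dataclass
class EvidenceCatalog:
    """Named GR-evidence gene sets plus their tissue applicability."""

    tf_db_sets: dict[str, set[str]]
    chipseq_set: set[str]
    dex_de_set: set[str]
    murine_dex: pd.DataFrame  # columns gene, fc, pval
    applicability: dict[int, set[str]]

    def __post_init__(self) -> None:
        if set(self.applicability) != set(CRITERIA):
            raise ValueError("applicability must map criteria 1-4 exactly")
        missing = {"gene", "fc", "pval"} - set(self.murine_dex.columns)
        if missing:
            raise ValueError(f"murine table lacks columns: {sorted(missing)}")

    def known_tissues(self) -> set[str]:
        out: set[str] = set()
        for tissues in self.applicability.values():
            out |= tissues
        return out


@dataclass(frozen=True)
class GrScore:
    gene: str
    tissue: str
    score: int
    criteria_met: frozenset[int]

    def __post_init__(self) -> None:
        if self.score != len(self.criteria_met):
            raise ValueError("score must equal the number of criteria met")
        if not self.criteria_met <= set(CRITERIA):
            raise ValueError("criteria must be a subset of {1,2,3,4}")


def score_gr_evidence(gene: str, tissue: str,
                      catalog: EvidenceCatalog) -> GrScore:
    """Score one gene in one tissue against the four GR-evidence criteria."""
    if tissue not in catalog.known_tissues():
        raise ValueError(f"unknown tissue {tissue!r}")
    app = catalog.applicability
    met: set[int] = set()
    if tissue in app[1] and any(gene in s for s in catalog.tf_db_sets.values()):
        met.add(1)
    if tissue in app[2] and gene in catalog.chipseq_set:
        met.add(2)
    if tissue in app[3] and gene in catalog.dex_de_set:
        met.add(3)
    if tissue in app[4]:
        rows = catalog.murine_dex[catalog.murine_dex["gene"] == gene]
        if len(rows) and bool(((rows["fc"] > MURINE_FC_MIN)
                               & (rows["pval"] < MURINE_P_MAX)).any()):
            met.add(4)
    return GrScore(gene, tissue, len(met), frozenset(met))


def filter_gr_trans_genes(
    trans_genes: Mapping[str, Iterable[str]],
    scores: Iterable[GrScore],
) -> dict[str, list[str]]:
    """Per tissue, genes with score >= 1 sorted by (score desc, gene id)."""
    by_key = {(s.gene, s.tissue): s for s in scores}
    out: dict[str, list[str]] = {}
    for tissue, genes in trans_genes.items():
        scored = []
        for g in genes:
            s = by_key.get((g, tissue))
            if s is not None and s.score >= 1:
                scored.append((-s.score, g))
        out[tissue] = [g for _, g in sorted(scored)]
    return out


def select_instrumented_regulators(
    gr_genes: Mapping[str, Sequence[str]],
    genotypes: pd.DataFrame,
    snp_info: pd.DataFrame,
    expression: Mapping[str, pd.DataFrame],
    gene_info: pd.DataFrame,
    posterior_threshold: float = INSTRUMENT_POSTERIOR,
    cis_window: int = 1_000_000,
) -> pd.DataFrame:
    """Attach to each GR gene its best valid cis-eQTL instrument.

    For every candidate gene, SNPs within ``cis_window`` of the gene are
    tested; the posterior of the primary linkage test is estimated per SNP
    across the tissue's full gene ensemble (the same calibration as the
    scan).  The SNP with the highest posterior becomes the instrument if it
    reaches ``posterior_threshold``; ties break lexicographically on SNP id.
    Genes with no qualifying SNP are dropped with a logged reason.

    Returns a DataFrame (tissue, gene, instrument_snp, instrument_posterior).
    """
    rows = []
    for tissue, genes in gr_genes.items():
        expr = expression[tissue]
        candidates: dict[str, list[str]] = {}
        snp_pool: set[str] = set()
        for g in genes:
            if g not in gene_info.index:
                log.info("gene %s lacks annotation; dropped", g)
                continue
            chrom = str(gene_info.loc[g, "chrom"])
            pos = int(gene_info.loc[g, "pos"])
            near = snp_info[(snp_info["chrom"].astype(str) == chrom)
                            & ((snp_info["pos"] - pos).abs() <= cis_window)]
            cis = sorted(set(near.index) & set(genotypes.index))
            if not cis:
                log.info("gene %s in %s has no cis SNP in the data; dropped",
                         g, tissue)
                continue
            candidates[g] = cis
            snp_pool |= set(cis)
        if not candidates:
            continue
        records = scan_tissue(sorted(snp_pool), genotypes, expr, tissue,
                              snp_info=snp_info, gene_info=gene_info,
                              cis_window=cis_window)
        posts = records.set_index(["snp", "gene"])["posterior"]
        for g in sorted(candidates):
            best_snp, best_post = None, -1.0
            for sid in candidates[g]:  # candidates sorted: lexicographic ties
                p = posts.get((sid, g))
                if p is not None and pd.notna(p) and p > best_post:
                    best_snp, best_post = sid, float(p)
            if best_snp is None or best_post < posterior_threshold:
                log.info("gene %s in %s: no cis SNP reaches posterior %.2f "
                         "(best %.3f); dropped", g, tissue,
                         posterior_threshold, max(best_post, 0.0))
                continue
            rows.append({"tissue": tissue, "gene": g,
                         "instrument_snp": best_snp,
                         "instrument_posterior": best_post})
    return pd.DataFrame(rows, columns=["tissue", "gene", "instrument_snp",
                                       "instrument_posterior"])
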