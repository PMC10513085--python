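"""Synthetic multi-tissue cohort generator with a ground-truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without access-restricted data:

* SNPs come in LD blocks at a single "cortisol" locus (chromosome 14).
  Within a block, a latent haplotype is drawn per sample and each SNP copy
  is flipped with probability (1 - r)/2, inducing pairwise genotype
  correlation of roughly ``r``.
* Expression is generated on a standardized continuous scale (a surrogate
  for post-normalization data).  Per tissue, a subset of genes receives a
  trans effect (``trans_effect_size`` per allele) from an assigned block
  SNP; regulator genes additionally receive a cis effect from a dedicated
  instrument SNP placed within 1 Mb of the gene.
* Regulator -> target edges form a depth-1 linear structural equation
  model: each target equals a signed ``edge_effect_size`` multiple of its
  regulator's expression plus independent noise.
* A replication cohort re-uses the same edge list with effects scaled by
  ``replication_attenuation`` and contains no genotypes.

Every planted relation is recorded in a :class:`TruthModel` so recovery can
be scored against the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TISSUES = (
    "liver",
    "subcutaneous_fat",
    "visceral_fat",
    "aortic_root",
    "mammary_artery",
    "skeletal_muscle",
    "blood",
)

#: tissues in which perturbation-based GR evidence may be counted
ADIPOSE_TISSUES = ("subcutaneous_fat", "visceral_fat")

_LOCUS_CHROM = "14"
_LOCUS_BASE = 94_300_000
_GENE_CHROM = "1"
_GENE_BASE = 1_000_000
_GENE_SPACING = 2_500_000


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic discovery/replication cohorts.

    Counts describing cohort structure (samples, SNPs, blocks, tissues,
    genes) must be >= 1; counts describing planted signal (trans genes,
    regulators, targets) may be 0 to express pure-null cohorts.
    ``targets_per_regulator`` accepts either a single count or one count per
    regulator.
    """

    n_samples: int = 500
    n_snps_per_block: int = 5
    n_blocks: int = 4
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_tissues: int = 3
    n_genes_per_tissue: int = 1000
    n_trans_genes: int = 20
    trans_effect_size: float = 0.6
    cis_effect_size: float = 1.0
    n_regulators: int = 3
    targets_per_regulator: int | Sequence[int] = 20
    edge_effect_size: float = 0.6
    noise_sd: float = 1.0
    replication_attenuation: float = 0.7
    ld_r: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps_per_block", "n_blocks", "n_tissues",
                     "n_genes_per_tissue"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_trans_genes", "n_regulators"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.replication_attenuation <= 1.0:
            raise ValueError("replication_attenuation must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.cis_effect_size < 0:
            raise ValueError("cis_effect_size must be nonnegative")
        if not 0.0 <= self.ld_r <= 1.0:
            raise ValueError("ld_r must lie in [0, 1]")
        if self.n_tissues > len(TISSUES):
            raise ValueError(f"at most {len(TISSUES)} tissues supported")
        if self.n_regulators > self.n_trans_genes:
            raise ValueError("regulators are drawn from the trans genes")
        counts = self.target_counts()
        if any(c < 0 for c in counts):
            raise ValueError("target counts must be >= 0")
        if self.n_trans_genes + sum(counts) > self.n_genes_per_tissue:
            raise ValueError(
                "targets_per_regulator exceeds the available gene pool"
            )

    def target_counts(self) -> list[int]:
        if isinstance(self.targets_per_regulator, int):
            return [self.targets_per_regulator] * self.n_regulators
        counts = list(self.targets_per_regulator)
        if len(counts) != self.n_regulators:
            raise ValueError(
                "targets_per_regulator sequence must have one entry per regulator"
            )
        return counts

    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        if not isinstance(self.targets_per_regulator, int):
            d["targets_per_regulator"] = list(self.targets_per_regulator)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TruthModel:
    """Ledger of every planted relation in a simulated cohort."""

    snp_block_map: dict[str, int]
    true_trans_pairs: set[tuple[str, str, str]]
    true_edges: set[tuple[str, str, str, int]]
    instrument_map: dict[str, str]
    gwama_pvalues: dict[str, float]

    def __post_init__(self) -> None:
        regs = {r for (r, _, _, _) in self.true_edges}
        missing = regs - set(self.instrument_map)
        if missing:
            raise ValueError(f"regulators without instruments: {sorted(missing)}")

    def trans_genes(self, tissue: str) -> set[str]:
        return {g for (_, g, t) in self.true_trans_pairs if t == tissue}

    def regulators(self, tissue: str | None = None) -> set[str]:
        return {r for (r, _, t, _) in self.true_edges
                if tissue is None or t == tissue}

    def targets_of(self, regulator: str, tissue: str) -> set[str]:
        return {g for (r, g, t, _) in self.true_edges
                if r == regulator and t == tissue}

    def to_dict(self) -> dict:
        return {
            "snp_block_map": dict(sorted(self.snp_block_map.items())),
            "true_trans_pairs": sorted(list(p) for p in self.true_trans_pairs),
            "true_edges": sorted(list(e) for e in self.true_edges),
            "instrument_map": dict(sorted(self.instrument_map.items())),
            "gwama_pvalues": dict(sorted(self.gwama_pvalues.items())),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthModel":
        return cls(
            snp_block_map={k: int(v) for k, v in d["snp_block_map"].items()},
            true_trans_pairs={tuple(p) for p in d["true_trans_pairs"]},
            true_edges={(r, g, t, int(s)) for r, g, t, s in d["true_edges"]},
            instrument_map=dict(d["instrument_map"]),
            gwama_pvalues={k: float(v) for k, v in d["gwama_pvalues"].items()},
        )


@dataclass
class Cohort:
    """In-memory bundle of a simulated cohort."""

    genotypes: pd.DataFrame          # SNPs x samples, dosage 0/1/2
    snp_info: pd.DataFrame           # index snp: chrom, pos, block
    expression: dict[str, pd.DataFrame]   # tissue -> genes x samples
    gene_info: pd.DataFrame          # index gene: chrom, pos
    summary: pd.DataFrame            # snp, chrom, pos, pval, block
    truth: TruthModel
    config: SimulationConfig
    replication: dict[str, pd.DataFrame] = field(default_factory=dict)


def _draw_dosage(rng: np.random.Generator, latent: np.ndarray,
                 flip_p: float, label: str) -> np.ndarray:
    """Allele flip of a latent haplotype pair, with one monomorphic resample."""
    for _ in range(2):
        flip = rng.random(latent.shape) < flip_p
        dosage = (latent ^ flip).sum(axis=1).astype(np.int8)
        if dosage.min() != dosage.max():
            return dosage
    raise ValueError(f"monomorphic SNP after resampling: {label}; "
                     "increase n_samples or the minor allele frequency")


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate genotypes, per-tissue expression and the truth ledger.

    Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{j:04d}" for j in range(config.n_genes_per_tissue)]
    gene_pos = {g: _GENE_BASE + j * _GENE_SPACING for j, g in enumerate(genes)}

    # --- LD-block genotypes at the trait locus -----------------------------
    snp_rows, snp_meta = {}, {}
    block_snps: list[str] = []
    flip_p = (1.0 - config.ld_r) / 2.0
    for b in range(config.n_blocks):
        maf = rng.uniform(*config.maf_range)
        latent = rng.random((n, 2)) < maf
        for s in range(config.n_snps_per_block):
            sid = f"rs14b{b + 1}s{s + 1:02d}"
            snp_rows[sid] = _draw_dosage(rng, latent, flip_p, sid)
            snp_meta[sid] = (_LOCUS_CHROM,
                             _LOCUS_BASE + b * 250_000 + s * 7_000, b + 1)
            block_snps.append(sid)

    # --- per-tissue expression with planted trans effects and SEM edges ----
    expression: dict[str, pd.DataFrame] = {}
    true_trans: set[tuple[str, str, str]] = set()
    true_edges: set[tuple[str, str, str, int]] = set()
    instrument_map: dict[str, str] = {}
    cis_maf: dict[str, float] = {}

    target_counts = config.target_counts()
    for tissue in config.tissues():
        expr = config.noise_sd * rng.standard_normal((len(genes), n))
        trans_idx = rng.choice(len(genes), size=config.n_trans_genes,
                               replace=False)
        trans_genes = [genes[j] for j in trans_idx]
        assigned = rng.choice(len(block_snps), size=config.n_trans_genes)
        for j, gi in enumerate(trans_idx):
            sid = block_snps[assigned[j]]
            expr[gi] += config.trans_effect_size * snp_rows[sid].astype(float)
            true_trans.add((sid, genes[gi], tissue))

        regulators = trans_genes[: config.n_regulators]
        for reg in regulators:
            cid = f"cis_{reg}"
            if cid not in snp_rows:
                maf = rng.uniform(*config.maf_range)
                latent = rng.random((n, 2)) < maf
                snp_rows[cid] = _draw_dosage(rng, latent, 0.0, cid)
                snp_meta[cid] = (_GENE_CHROM, gene_pos[reg] + 1_000, -1)
                cis_maf[cid] = maf
            instrument_map[reg] = cid
            gi = genes.index(reg)
            expr[gi] += config.cis_effect_size * snp_rows[cid].astype(float)

        pool = [j for j in range(len(genes)) if j not in set(trans_idx)]
        total_targets = sum(target_counts)
        chosen = rng.choice(len(pool), size=total_targets, replace=False)
        signs = rng.choice([-1, 1], size=total_targets)
        pos = 0
        for reg, cnt in zip(regulators, target_counts):
            gi_reg = genes.index(reg)
            for c in range(cnt):
                tj = pool[chosen[pos]]
                sign = int(signs[pos])
                expr[tj] += sign * config.edge_effect_size * expr[gi_reg]
                true_edges.add((reg, genes[tj], tissue, sign))
                pos += 1
        expression[tissue] = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                                          columns=samples)

    # --- summary statistics -----------------------------------------------
    gwama = {}
    for sid in block_snps:
        gwama[sid] = float(10.0 ** (-rng.uniform(8.0, 30.0)))
    for sid in sorted(s for s in snp_rows if s.startswith("cis_")):
        gwama[sid] = float(rng.uniform(0.0, 1.0))

    snp_ids = sorted(snp_rows)
    genotypes = pd.DataFrame(
        np.stack([snp_rows[s] for s in snp_ids]),
        index=pd.Index(snp_ids, name="snp"), columns=samples,
    )
    snp_info = pd.DataFrame(
        {"chrom": [snp_meta[s][0] for s in snp_ids],
         "pos": [snp_meta[s][1] for s in snp_ids],
         "block": [snp_meta[s][2] for s in snp_ids]},
        index=pd.Index(snp_ids, name="snp"),
    )
    gene_info = pd.DataFrame(
        {"chrom": _GENE_CHROM, "pos": [gene_pos[g] for g in genes]},
        index=pd.Index(genes, name="gene"),
    )
    summary = pd.DataFrame(
        {"snp": snp_ids,
         "chrom": snp_info["chrom"].to_numpy(),
         "pos": snp_info["pos"].to_numpy(),
         "pval": [gwama[s] for s in snp_ids],
         "block": snp_info["block"].to_numpy()},
    )
    truth = TruthModel(
        snp_block_map={s: snp_meta[s][2] for s in snp_ids},
        true_trans_pairs=true_trans,
        true_edges=true_edges,
        instrument_map=instrument_map,
        gwama_pvalues=gwama,
    )
    cohort = Cohort(genotypes, snp_info, expression, gene_info, summary,
                    truth, config)
    cohort.replication = simulate_replication(truth, config)
    return cohort


def simulate_replication(truth: TruthModel,
                         config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Independent cohort re-using the planted edges at attenuated strength.

    New samples over the same gene universe; no genotypes.  With attenuation
    0 all edge effects vanish; with attenuation 1 they match discovery.
    """
    att = config.replication_attenuation
    if not 0.0 <= att <= 1.0:
        raise ValueError("replication_attenuation must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 7919])
    n = config.n_samples
    samples = [f"R{i:04d}" for i in range(n)]
    genes = [f"G{j:04d}" for j in range(config.n_genes_per_tissue)]
    gidx = {g: j for j, g in enumerate(genes)}
    out: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues():
        expr = config.noise_sd * rng.standard_normal((len(genes), n))
        for reg, target, t, sign in sorted(truth.true_edges):
            if t != tissue:
                continue
            expr[gidx[target]] += (att * sign * config.edge_effect_size
                                   * expr[gidx[reg]])
        out[tissue] = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                                   columns=samples)
    return out


# ---------------------------------------------------------------------------
# synthetic evidence catalogs
# ---------------------------------------------------------------------------

def synthetic_evidence_catalog(truth: TruthModel, config: SimulationConfig,
                               n_decoys: int = 20, seed: int | None = None):
    """Synthetic GR-evidence catalog and TF-target sets for pipeline runs.

    Planted regulators appear in the transcription-factor databases, the
    adipocyte ChIP-seq and dexamethasone sets, and the murine table (with
    qualifying fold change and p-value).  Decoy null genes are sprinkled into
    each source so the evidence filter is exercised against negatives.  Each
    regulator also gets a predicted-target set ("TF_<regulator>") mixing a
    majority of its true targets with random genes, for enrichment testing.

    Returns ``(EvidenceCatalog, tf_target_sets)``.
    """
    from .gr import EvidenceCatalog, default_applicability

    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 104729])
    genes = [f"G{j:04d}" for j in range(config.n_genes_per_tissue)]
    regulators = sorted(truth.regulators())
    signal = set(regulators) | {g for (_, g, _) in truth.true_trans_pairs} \
        | {g for (_, g, _, _) in truth.true_edges}
    null_pool = sorted(set(genes) - signal)
    n_decoys = min(n_decoys, len(null_pool))
    decoys = list(rng.choice(null_pool, size=n_decoys, replace=False))

    def mix(extra_frac: float) -> set[str]:
        k = max(1, int(extra_frac * n_decoys)) if n_decoys else 0
        return set(regulators) | set(decoys[:k])

    tf_db_sets = {
        "ENCODE": mix(0.5),
        "TRANSFAC": mix(0.3),
        "CHEA": mix(0.2),
    }
    chipseq = mix(0.4)
    dex_de = mix(0.3)

    murine_genes = regulators + decoys
    murine = pd.DataFrame({
        "gene": murine_genes,
        "fc": np.concatenate([rng.uniform(1.5, 3.0, len(regulators)),
                              rng.uniform(0.2, 0.9, len(decoys))]),
        "pval": np.concatenate([rng.uniform(0.0, 0.04, len(regulators)),
                                rng.uniform(0.06, 1.0, len(decoys))]),
    })

    tf_targets: dict[str, set[str]] = {}
    for reg in regulators:
        targets = sorted({g for (r, g, _, _) in truth.true_edges if r == reg})
        if not targets:
            continue
        n_true = max(1, int(0.7 * len(targets)))
        picked = list(rng.choice(targets, size=n_true, replace=False))
        n_rand = min(len(null_pool), len(picked))
        picked += list(rng.choice(null_pool, size=n_rand, replace=False))
        tf_targets[f"TF_{reg}"] = set(picked)

    catalog = EvidenceCatalog(
        tf_db_sets=tf_db_sets,
        chipseq_set=chipseq,
        dex_de_set=dex_de,
        murine_dex=murine,
        applicability=default_applicability(config.tissues()),
    )
    return catalog, tf_targets
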