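"""Pipeline orchestration: simulate -> scan -> gr-filter -> network -> enrich
-> replicate, with a JSON manifest of parameters and content hashes.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be run individually (`run_stage`) or end to end
(`run_pipeline`).  Reruns with identical config and seed are bit-identical;
`resume=True` skips stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .enrich import enrichment_scan
from .gr import (EvidenceCatalog, default_applicability, filter_gr_trans_genes,
                 score_gr_evidence, select_instrumented_regulators)
from .network import build_network, network_stats, score_all_pairs
from .replicate import replicate_network, transfer_cluster_order, abs_corr_matrix
from .scan import filter_gwas_snps, scan_tissue, select_by_global_fdr, \
    tabulate_sharing
from .simulate import SimulationConfig, simulate_cohort, \
    synthetic_evidence_catalog

log = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "gr-filter", "network", "enrich", "replicate")


class StageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Thresholds, paths and seed for a full pipeline run."""

    out_dir: str | Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gwas_p_threshold: float = 5e-8
    trans_fdr: float = 0.15
    network_fdr: float = 0.10
    enrichment_fdrs: tuple[float, ...] = (0.10, 0.15)
    min_targets: int = 4
    instrument_posterior: float = 0.75
    cis_window: int = 1_000_000
    n_background_draws: int = 1
    combine: str = "default"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("gwas_p_threshold", "trans_fdr", "network_fdr",
                     "instrument_posterior"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation,
                                                  seed=int(self.seed))

    @property
    def run_dir(self) -> Path:
        return Path(self.out_dir)

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "simulation": self.simulation.to_dict(),
            "gwas_p_threshold": self.gwas_p_threshold,
            "trans_fdr": self.trans_fdr,
            "network_fdr": self.network_fdr,
            "enrichment_fdrs": list(self.enrichment_fdrs),
            "min_targets": self.min_targets,
            "instrument_posterior": self.instrument_posterior,
            "cis_window": self.cis_window,
            "n_background_draws": self.n_background_draws,
            "combine": self.combine,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulation", {})
        if "enrichment_fdrs" in raw:
            raw["enrichment_fdrs"] = tuple(raw["enrichment_fdrs"])
        return cls(simulation=SimulationConfig.from_dict(sim), **raw)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise StageError(stage, "missing_upstream",
                         f"missing artifact {path}; run '{producer}' first")
    return path


def _stage_simulate(cfg: PipelineConfig) -> None:
    cohort_dir = cfg.run_dir / "cohort"
    cohort = simulate_cohort(cfg.simulation)
    cio.write_cohort(cohort, cohort_dir)
    catalog, tf_targets = synthetic_evidence_catalog(cohort.truth,
                                                     cfg.simulation)
    ev = cohort_dir / "evidence"
    ev.mkdir(exist_ok=True)
    cio.write_gmt(catalog.tf_db_sets, ev / "tf_db.gmt")
    cio.write_gmt({"chipseq": catalog.chipseq_set}, ev / "chipseq.gmt")
    cio.write_gmt({"dex_de": catalog.dex_de_set}, ev / "dex_de.gmt")
    catalog.murine_dex.to_csv(ev / "murine_dex.tsv", sep="\t", index=False,
                              float_format=cio.FLOAT_FMT)
    cio.write_gmt(tf_targets, ev / "tf_targets.gmt")


def _load_cohort(cfg: PipelineConfig, stage: str):
    _require(cfg.run_dir / "cohort" / "genotypes.vcf", stage, "simulate")
    return cio.read_cohort(cfg.run_dir / "cohort")


def _load_catalog(cfg: PipelineConfig, stage: str) -> EvidenceCatalog:
    ev = cfg.run_dir / "cohort" / "evidence"
    _require(ev / "tf_db.gmt", stage, "simulate")
    tissues = SimulationConfig.from_yaml(
        cfg.run_dir / "cohort" / "config.yaml").tissues()
    return EvidenceCatalog(
        tf_db_sets=cio.read_gmt(ev / "tf_db.gmt"),
        chipseq_set=cio.read_gmt(ev / "chipseq.gmt").get("chipseq", set()),
        dex_de_set=cio.read_gmt(ev / "dex_de.gmt").get("dex_de", set()),
        murine_dex=pd.read_csv(ev / "murine_dex.tsv", sep="\t"),
        applicability=default_applicability(tissues),
    )


def _stage_scan(cfg: PipelineConfig) -> None:
    cohort = _load_cohort(cfg, "scan")
    snps = filter_gwas_snps(cohort.summary, cfg.gwas_p_threshold)
    out = cfg.run_dir / "scan"
    out.mkdir(parents=True, exist_ok=True)
    all_records, selections = [], {}
    for tissue in cohort.config.tissues():
        rec = scan_tissue(snps, cohort.genotypes, cohort.expression[tissue],
                          tissue, snp_info=cohort.snp_info,
                          gene_info=cohort.gene_info,
                          cis_window=cfg.cis_window)
        sel = select_by_global_fdr(rec, cfg.trans_fdr)
        rec.loc[sel.records.index, "selected"] = True
        all_records.append(rec)
        selections[tissue] = sel.records
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(out / "associations.tsv", sep="\t", index=False,
                   float_format=cio.FLOAT_FMT)
    with open(out / "sharing.json", "w") as fh:
        json.dump(tabulate_sharing(selections), fh, indent=1, sort_keys=True)


def _stage_gr(cfg: PipelineConfig) -> None:
    cohort = _load_cohort(cfg, "gr-filter")
    catalog = _load_catalog(cfg, "gr-filter")
    assoc_path = _require(cfg.run_dir / "scan" / "associations.tsv",
                          "gr-filter", "scan")
    records = pd.read_csv(assoc_path, sep="\t")
    out = cfg.run_dir / "gr"
    out.mkdir(parents=True, exist_ok=True)

    trans_genes = {
        t: sorted(set(records.loc[records["selected"].fillna(False)
                                  & (records["tissue"] == t)
                                  & ~records["cis"].fillna(False), "gene"]))
        for t in cohort.config.tissues()
    }
    scores = [score_gr_evidence(g, t, catalog)
              for t, genes in trans_genes.items() for g in genes]
    pd.DataFrame(
        [{"gene": s.gene, "tissue": s.tissue, "score": s.score,
          "criteria": ",".join(map(str, sorted(s.criteria_met)))}
         for s in scores]
    ).to_csv(out / "gr_scores.tsv", sep="\t", index=False)

    gr_genes = filter_gr_trans_genes(trans_genes, scores)
    instruments = select_instrumented_regulators(
        gr_genes, cohort.genotypes, cohort.snp_info, cohort.expression,
        cohort.gene_info, posterior_threshold=cfg.instrument_posterior,
        cis_window=cfg.cis_window)
    instruments.to_csv(out / "instruments.tsv", sep="\t", index=False,
                       float_format=cio.FLOAT_FMT)


def _stage_network(cfg: PipelineConfig) -> None:
    cohort = _load_cohort(cfg, "network")
    inst_path = _require(cfg.run_dir / "gr" / "instruments.tsv",
                         "network", "gr-filter")
    instruments = pd.read_csv(inst_path, sep="\t")
    out = cfg.run_dir / "network"
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for tissue in cohort.config.tissues():
        expr = cohort.expression[tissue]
        sub = instruments[instruments["tissue"] == tissue]
        edge_sets = []
        for row in sub.sort_values("gene").itertuples():
            E = cohort.genotypes.loc[row.instrument_snp, expr.columns]
            if np.unique(E).size < 2:
                log.warning("instrument %s monomorphic; regulator %s skipped",
                            row.instrument_snp, row.gene)
                continue
            edge_sets.append(score_all_pairs(row.gene, E.to_numpy(), expr,
                                             tissue, combine=cfg.combine))
        candidates = (pd.concat(edge_sets, ignore_index=True) if edge_sets
                      else pd.DataFrame(columns=["regulator", "target",
                                                 "tissue", "posterior", "p1",
                                                 "p2", "p3", "p4", "p5"]))
        candidates.to_csv(out / f"candidates_{tissue}.tsv", sep="\t",
                          index=False, float_format=cio.FLOAT_FMT)
        net = build_network(candidates, cfg.network_fdr, cfg.min_targets,
                            tissue=tissue)
        net.edges.to_csv(out / f"edges_{tissue}.tsv", sep="\t", index=False,
                         float_format=cio.FLOAT_FMT)
        net.to_graphml(out / f"network_{tissue}.graphml")
        tables.append(network_stats(net))
    table1 = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame())
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)


def _stage_enrich(cfg: PipelineConfig) -> None:
    cohort = _load_cohort(cfg, "enrich")
    tf_path = _require(cfg.run_dir / "cohort" / "evidence" / "tf_targets.gmt",
                       "enrich", "simulate")
    tf_sets = cio.read_gmt(tf_path)
    out = cfg.run_dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for tissue in cohort.config.tissues():
        cand_path = _require(
            cfg.run_dir / "network" / f"candidates_{tissue}.tsv",
            "enrich", "network")
        candidates = pd.read_csv(cand_path, sep="\t")
        networks = {fdr: build_network(candidates, fdr, cfg.min_targets,
                                       tissue=tissue)
                    for fdr in cfg.enrichment_fdrs}
        res = enrichment_scan(networks, tf_sets,
                              cohort.expression[tissue].index)
        res.insert(0, "tissue", tissue)
        frames.append(res)
    result = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame())
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                  float_format=cio.FLOAT_FMT)


def _stage_replicate(cfg: PipelineConfig) -> None:
    cohort = _load_cohort(cfg, "replicate")
    out = cfg.run_dir / "replication"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.simulation.seed
    rows = []
    for tissue in cohort.config.tissues():
        edges_path = _require(cfg.run_dir / "network" / f"edges_{tissue}.tsv",
                              "replicate", "network")
        edges = pd.read_csv(edges_path, sep="\t")
        if tissue not in cohort.replication:
            raise StageError("replicate", "missing_upstream",
                             f"missing replication matrix for {tissue}")
        repl_expr = cohort.replication[tissue]
        disc_expr = cohort.expression[tissue]
        for i, reg in enumerate(sorted(set(edges["regulator"]))
                                if len(edges) else []):
            targets = sorted(edges.loc[edges["regulator"] == reg, "target"])
            if len(targets) < 2:
                log.info("regulator %s has <2 targets; replication skipped",
                         reg)
                continue
            res = replicate_network(
                reg, targets, disc_expr, repl_expr, dataset="replication",
                n_draws=cfg.n_background_draws,
                seed=np.random.default_rng([seed, 31337, i]))
            rows.append({"dataset": res.dataset, "tissue": tissue,
                         "regulator": reg, "pvalue": res.pvalue,
                         "kw_statistic": res.kw_statistic,
                         "n_targets": res.n_targets})
            disc_corr = abs_corr_matrix(disc_expr, targets)
            repl_corr = abs_corr_matrix(repl_expr, targets)
            _, disc_re, repl_re = transfer_cluster_order(disc_corr, repl_corr)
            disc_re.to_csv(out / f"corr_{tissue}_{reg}_discovery.tsv",
                           sep="\t", float_format=cio.FLOAT_FMT)
            repl_re.to_csv(out / f"corr_{tissue}_{reg}_replication.tsv",
                           sep="\t", float_format=cio.FLOAT_FMT)
    pd.DataFrame(rows, columns=["dataset", "tissue", "regulator", "pvalue",
                                "kw_statistic", "n_targets"]).to_csv(
        out / "table2.tsv", sep="\t", index=False, float_format=cio.FLOAT_FMT)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "gr-filter": _stage_gr,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "replicate": _stage_replicate,
}

_STAGE_MARKERS = {
    "simulate": "cohort/truth.json",
    "scan": "scan/associations.tsv",
    "gr-filter": "gr/instruments.tsv",
    "network": "network/table1.tsv",
    "enrich": "enrich/enrichment.tsv",
    "replicate": "replication/table2.tsv",
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    """Execute exactly one pipeline stage, failing fast on missing inputs."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg.run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        _STAGE_FUNCS[name](cfg)
    except StageError:
        raise
    except FileNotFoundError as exc:
        raise StageError(name, "missing_upstream", str(exc)) from exc
    log.info(json.dumps({"stage": name, "seconds": round(time.time() - t0, 2)}))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig) -> dict:
    """Hash every run artifact into manifest.json (timestamps kept apart)."""
    run_dir = cfg.run_dir
    outputs = {}
    for path in sorted(run_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            outputs[str(path.relative_to(run_dir))] = _hash_file(path)
    manifest = {"config": cfg.to_dict(), "outputs": outputs,
                "timing": {"written_at": time.time()}}
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Run all stages in order and return the manifest.

    With ``resume=True`` a stage whose marker output already exists is
    skipped, so deleting an intermediate regenerates only downstream stages.
    """
    dirty = False
    for name in STAGES:
        marker = cfg.run_dir / _STAGE_MARKERS[name]
        if resume and not dirty and marker.exists():
            log.info("stage %s: outputs present, skipped", name)
            continue
        run_stage(name, cfg)
        dirty = True
    return write_manifest(cfg)
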