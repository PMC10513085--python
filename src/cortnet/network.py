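"""Stage 3: directed causal network reconstruction under global FDR.

Each instrumented regulator is tested against every other gene of its
tissue with the five-test suite; candidate edges pooled across the tissue's
regulators are selected at a Bayesian global FDR threshold, and regulators
with fewer than ``min_targets`` surviving edges are pruned together with
their edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .causal import causal_posterior_table
from .scan import select_by_global_fdr

log = logging.getLogger(__name__)

MIN_TARGETS = 4

EDGE_COLUMNS = ("regulator", "target", "tissue", "posterior",
                "p1", "p2", "p3", "p4", "p5")


def score_all_pairs(
    regulator: str,
    instrument,
    expression: pd.DataFrame,
    tissue: str,
    combine: str = "default",
) -> pd.DataFrame:
    """Candidate edges from one regulator to every other gene of the tissue.

    ``instrument`` is the dosage vector of the regulator's cis SNP aligned
    to the expression samples.  The self-edge is excluded; posteriors come
    from the five-test suite calibrated on the tissue's gene ensemble.
    """
    if regulator not in expression.index:
        raise KeyError(f"regulator {regulator!r} absent from expression matrix")
    others = expression.drop(index=regulator)
    if others.empty:
        raise ValueError("expression matrix holds no candidate targets")
    A = expression.loc[regulator].to_numpy()
    B = others.to_numpy().T  # samples x genes
    table = causal_posterior_table(instrument, A, B, gene_ids=others.index,
                                   combine=combine)
    out = table.reset_index().rename(columns={"gene": "target"})
    out.insert(0, "regulator", regulator)
    out.insert(2, "tissue", tissue)
    return out[list(EDGE_COLUMNS)]


@dataclass
class Network:
    """Directed regulator->target network retained at a global FDR level."""

    tissue: str
    edges: pd.DataFrame
    fdr_threshold: float
    regulators: list[str]
    achieved_fdr: float

    def __post_init__(self) -> None:
        if len(self.edges):
            extra = set(self.edges["regulator"]) - set(self.regulators)
            if extra:
                raise ValueError(f"edges from unlisted regulators: {sorted(extra)}")
        if self.achieved_fdr > self.fdr_threshold + 1e-9:
            raise ValueError("achieved global FDR exceeds the threshold")

    def targets_of(self, regulator: str) -> list[str]:
        sub = self.edges[self.edges["regulator"] == regulator]
        return sorted(sub["target"])

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph(tissue=self.tissue, fdr_threshold=self.fdr_threshold)
        for row in self.edges.sort_values(["regulator", "target"]).itertuples():
            g.add_edge(row.regulator, row.target, posterior=float(row.posterior))
        return g

    def to_graphml(self, path) -> Path:
        path = Path(path)
        nx.write_graphml(self.to_graph(), path)
        return path


def build_network(
    edge_sets: pd.DataFrame | list[pd.DataFrame],
    fdr_threshold: float,
    min_targets: int = MIN_TARGETS,
    tissue: str | None = None,
    pool_scope: str = "regulator",
) -> Network:
    """Select candidate edges at global FDR, then prune small regulators.

    With ``pool_scope="regulator"`` (default) the global-FDR selection is
    applied separately to each regulator's candidate-edge set, so every
    retained subnetwork stands on its own evidence; ``"tissue"`` pools all
    candidates of the tissue into one selection.  Pruning then removes whole
    regulators whose surviving edge count falls below ``min_targets``.  The
    achieved FDR of the pruned set is recomputed; should it exceed the
    threshold (impossible when removing whole selection groups, still
    guarded), the lowest-posterior edges are dropped until it complies.
    """
    if pool_scope not in ("regulator", "tissue"):
        raise ValueError("pool_scope must be 'regulator' or 'tissue'")
    if isinstance(edge_sets, list):
        pool = (pd.concat(edge_sets, ignore_index=True) if edge_sets
                else pd.DataFrame(columns=list(EDGE_COLUMNS)))
    else:
        pool = edge_sets
    if tissue is None:
        tissues = sorted(set(pool["tissue"])) if len(pool) else []
        tissue = tissues[0] if len(tissues) == 1 else "+".join(tissues)
    if pool.empty:
        return Network(tissue, pool.copy(), fdr_threshold, [], 0.0)

    if pool_scope == "regulator":
        parts = [select_by_global_fdr(g, fdr_threshold,
                                      tie_cols=("regulator", "target")).records
                 for _, g in pool.groupby("regulator", sort=True)]
        sel = pd.concat(parts) if parts else pool.iloc[:0]
    else:
        sel = select_by_global_fdr(pool, fdr_threshold,
                                   tie_cols=("regulator", "target")).records
    while True:
        counts = sel["regulator"].value_counts()
        keep = counts[counts >= min_targets].index
        pruned = sel[sel["regulator"].isin(keep)]
        achieved = (1.0 - float(pruned["posterior"].mean())
                    if len(pruned) else 0.0)
        if not len(pruned) or achieved <= fdr_threshold + 1e-12:
            break
        log.warning("pruned network exceeds FDR %.3f (%.4f); tightening",
                    fdr_threshold, achieved)
        sel = pruned.sort_values(
            ["posterior", "regulator", "target"],
            ascending=[False, True, True], kind="mergesort").iloc[:-1]
    edges = pruned.sort_values(["regulator", "target"],
                               kind="mergesort").reset_index(drop=True)
    return Network(tissue, edges, fdr_threshold, sorted(keep), max(achieved, 0.0))


def network_stats(network: Network) -> pd.DataFrame:
    """Per-regulator target counts plus the tissue total, table-style.

    One row per regulator with columns (tissue, fdr_threshold,
    total_targets, regulator, regulator_targets); the total counts all
    retained pairwise interactions of the tissue at the threshold.
    """
    if not len(network.edges):
        return pd.DataFrame(columns=["tissue", "fdr_threshold", "total_targets",
                                     "regulator", "regulator_targets"])
    counts = network.edges.groupby("regulator").size()
    total = int(counts.sum())
    rows = [{"tissue": network.tissue,
             "fdr_threshold": network.fdr_threshold,
             "total_targets": total,
             "regulator": reg,
             "regulator_targets": int(counts[reg])}
            for reg in sorted(counts.index)]
    return pd.DataFrame(rows)
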