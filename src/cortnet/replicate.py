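"""Stage 5: co-expression replication of network targets in independent data.

If a reconstructed network is real, its targets should be more strongly
co-expressed than random same-size gene sets in a cohort that played no
part in discovery.  The test compares the distribution of absolute pairwise
Pearson correlations among targets with that of a random background set via
the Kruskal-Wallis rank test; discovery-side hierarchical clustering leaf
order is transferred to the replication correlation matrix for paired
heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def abs_corr_matrix(expression: pd.DataFrame, genes) -> pd.DataFrame:
    """Absolute Pearson correlation matrix of the given genes.

    Genes absent from the expression matrix are dropped with a logged
    count; at least 2 present genes and 3 samples are required.
    """
    genes = list(genes)
    present = [g for g in genes if g in expression.index]
    dropped = len(genes) - len(present)
    if dropped:
        log.info("dropped %d genes absent from the expression matrix", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 genes present in the matrix")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mat = expression.loc[present].to_numpy()
    corr = np.abs(np.corrcoef(mat))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=present, columns=present)


def offdiag_values(corr: pd.DataFrame) -> np.ndarray:
    """Upper-triangle off-diagonal entries of a correlation matrix."""
    arr = corr.to_numpy()
    iu = np.triu_indices_from(arr, k=1)
    return arr[iu]


def background_corr_sample(
    expression: pd.DataFrame,
    set_size: int,
    n_draws: int = 1,
    seed: int | np.random.Generator = 0,
    universe=None,
) -> np.ndarray:
    """Pooled off-diagonal |r| values of random same-size gene sets.

    Each draw samples ``set_size`` genes uniformly without replacement from
    ``universe`` (default: all genes of the matrix, i.e. the discovery /
    replication overlap prepared by the caller).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = list(universe) if universe is not None else list(expression.index)
    pool = [g for g in pool if g in expression.index]
    if len(pool) < set_size:
        raise ValueError(
            f"background ({len(pool)} genes) smaller than set size {set_size}")
    values = []
    for _ in range(n_draws):
        picked = rng.choice(pool, size=set_size, replace=False)
        values.append(offdiag_values(abs_corr_matrix(expression, picked)))
    return np.concatenate(values)


def compare_distributions(target_corr, background_corr) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction, chi-square df=1 p-value)."""
    target_corr = np.asarray(target_corr, dtype=float)
    background_corr = np.asarray(background_corr, dtype=float)
    if target_corr.size == 0 or background_corr.size == 0:
        raise ValueError("both correlation samples must be nonempty")
    if (np.array_equal(target_corr, background_corr)
            or (np.ptp(np.concatenate([target_corr, background_corr])) == 0)):
        return 0.0, 1.0  # identical pooled values: no separation
    h, p = stats.kruskal(target_corr, background_corr)
    return float(h), float(p)


def transfer_cluster_order(
    discovery_corr: pd.DataFrame,
    replication_corr: pd.DataFrame,
    method: str = "average",
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Cluster the discovery matrix; apply its leaf order to both matrices.

    Hierarchical clustering uses the dissimilarity 1 - |r| on the gene set
    shared by both matrices.  Returns (leaf_order, reordered discovery,
    reordered replication).
    """
    shared = [g for g in discovery_corr.index if g in replication_corr.index]
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared by both matrices")
    disc = discovery_corr.loc[shared, shared]
    repl = replication_corr.loc[shared, shared]
    dis = 1.0 - np.abs(disc.to_numpy())
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    np.fill_diagonal(dis, 0.0)
    z = linkage(squareform(dis, checks=False), method=method)
    order = leaves_list(z)
    genes = [shared[i] for i in order]
    return order, disc.loc[genes, genes], repl.loc[genes, genes]


@dataclass
class ReplicationResult:
    """Replication outcome of one regulator's target set in one dataset."""

    regulator: str
    dataset: str
    n_targets: int
    kw_statistic: float
    pvalue: float
    target_corr: np.ndarray
    background_corr: np.ndarray
    leaf_order: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.target_corr < 0) | (self.target_corr > 1)):
            raise ValueError("absolute correlations must lie in [0, 1]")


def replicate_network(
    regulator: str,
    targets,
    discovery_expr: pd.DataFrame,
    replication_expr: pd.DataFrame,
    dataset: str = "replication",
    n_draws: int = 1,
    seed: int | np.random.Generator = 0,
) -> ReplicationResult:
    """Full replication test of one network's targets.

    Targets are intersected with the replication matrix; the background
    universe is the overlap of the two expression gene sets.  Correlations
    among targets in the replication data are compared against ``n_draws``
    random same-size sets via Kruskal-Wallis, and the discovery clustering
    leaf order is computed for heatmap transfer.
    """
    targets = [g for g in targets if g in replication_expr.index
               and g in discovery_expr.index]
    if len(targets) < 2:
        raise ValueError("fewer than 2 targets present in both datasets")
    universe = [g for g in discovery_expr.index
                if g in set(replication_expr.index)]
    repl_corr = abs_corr_matrix(replication_expr, targets)
    disc_corr = abs_corr_matrix(discovery_expr, targets)
    bg = background_corr_sample(replication_expr, len(targets), n_draws,
                                seed, universe=universe)
    tv = offdiag_values(repl_corr)
    h, p = compare_distributions(tv, bg)
    order, _, _ = transfer_cluster_order(disc_corr, repl_corr)
    return ReplicationResult(regulator, dataset, len(targets), h, p, tv, bg,
                             order)
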