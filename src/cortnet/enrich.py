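"""Stage 4: transcription-factor target enrichment of network gene sets.

Network target sets are tested for over-representation of known TF targets
with Fisher's exact test on a 2x2 table built against a tissue-specific
background (all genes of the tissue's expression matrix).  P-values are
reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .network import Network


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    regulator: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.table
        if min(a, b, c, d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def fisher_enrichment(
    network_targets: Iterable[str],
    tf_targets: Iterable[str],
    background: Iterable[str],
    tf: str = "TF",
    regulator: str = "",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher's exact test of TF-target overlap against the background.

    The 2x2 table is (in-network & in-TF-set, in-network & not,
    out-of-network & in-TF-set, out-of-network & not); the TF set is
    intersected with the background first.  The odds ratio is the
    conditional maximum-likelihood estimate (``inf`` when a zero cell makes
    it unbounded).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    net = set(network_targets)
    if not net <= background:
        raise ValueError("network targets must be a subset of the background")
    tf_set = set(tf_targets) & background
    a = len(net & tf_set)
    b = len(net - tf_set)
    c = len(tf_set - net)
    d = len(background) - a - b - c
    table = [[a, b], [c, d]]
    _, pvalue = stats.fisher_exact(table, alternative=alternative)
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        orat, pvalue = np.nan, 1.0  # degenerate margin carries no information
    else:
        orat = float(_cond_odds_ratio(table, kind="conditional").statistic)
        if (a and d) and (not b or not c):
            orat = float("inf")
    return EnrichmentResult(tf, regulator, ((a, b), (c, d)), orat,
                            float(pvalue))


def enrichment_scan(
    networks: Mapping[float, Network],
    tf_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """One Fisher test per (TF set, FDR level, network regulator).

    ``networks`` maps each requested FDR level to the network built at that
    level.  Returns a tidy DataFrame with the 2x2 counts, odds ratio and
    raw p-value per combination.
    """
    background = set(background)
    rows = []
    for fdr in sorted(networks):
        net = networks[fdr]
        for reg in net.regulators:
            targets = net.targets_of(reg)
            for tf in sorted(tf_sets):
                res = fisher_enrichment(targets, tf_sets[tf], background,
                                        tf=tf, regulator=reg,
                                        alternative=alternative)
                (a, b), (c, d) = res.table
                rows.append({"tf": tf, "regulator": reg, "fdr_level": fdr,
                             "a": a, "b": b, "c": c, "d": d,
                             "odds_ratio": res.odds_ratio,
                             "pvalue": res.pvalue})
    return pd.DataFrame(rows, columns=["tf", "regulator", "fdr_level",
                                       "a", "b", "c", "d", "odds_ratio",
                                       "pvalue"])
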