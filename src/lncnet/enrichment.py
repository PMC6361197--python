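"""Gene-set over-representation analysis (ORA).

One-sided hypergeometric upper tail: given a universe of N genes of which K
belong to a set, and a query list of n genes with k falling in the set, the
enrichment P value is P(X >= k) for X ~ Hypergeometric(N, K, n) — identical
to one-sided Fisher's exact on the 2x2 overlap table.  Sets are ranked by
raw ascending P (the convention behind -log10 P bar charts); BH-adjusted
values are carried as a column but do not drive the ranking or the top-k
cut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "hypergeom_tail", "enrich", "records_to_frame"]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int                # overlap count
    n_selected: int       # effective query size
    K: int                # set size within the universe
    N: int                # universe size
    p_value: float
    p_adj_bh: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def hypergeom_tail(k: int, n_selected: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n_selected).

    scipy evaluates the tail in log-space internally, so the result is
    stable for the extreme overlaps ORA produces.
    """
    if not (0 <= k <= n_selected <= N):
        raise ValidationError(f"need 0 <= k <= n_selected <= N, got {(k, n_selected, N)}")
    if not (k <= K <= N):
        raise ValidationError(f"need k <= K <= N, got {(k, K, N)}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n_selected))
    return min(max(p, 0.0), 1.0)


def enrich(
    query: list[str],
    sets: GeneSetCollection,
    top_k: int = 20,
) -> list[EnrichmentRecord]:
    """Rank gene sets by over-representation of the query list.

    Query genes outside the universe are dropped with a warning; sets with
    zero overlap are not reported.  Ranking: ascending P, ties broken by
    descending overlap then set name.  ``top_k`` records are returned
    (top_k=None for all).
    """
    if not query:
        raise ValidationError("empty query list")
    uniq = list(dict.fromkeys(query))
    if len(uniq) < len(query):
        logger.warning("query contained %d duplicate id(s)", len(query) - len(uniq))
    effective = [g for g in uniq if g in sets.universe]
    n_dropped = len(uniq) - len(effective)
    if n_dropped:
        logger.warning("%d query gene(s) outside the universe dropped", n_dropped)
    if not effective:
        raise ValidationError("no query genes inside the universe")

    N = len(sets.universe)
    n_sel = len(effective)
    query_set = set(effective)

    rows = []
    for name, members in sets.sets.items():
        members_in_universe = members & sets.universe
        k = len(query_set & members_in_universe)
        if k == 0:
            continue
        K = len(members_in_universe)
        rows.append((name, k, K, hypergeom_tail(k, n_sel, K, N)))
    if not rows:
        return []

    p_adj = multipletests([p for *_, p in rows], method="fdr_bh")[1]
    records = [
        EnrichmentRecord(name, k, n_sel, K, N, p, float(q))
        for (name, k, K, p), q in zip(rows, p_adj)
    ]
    records.sort(key=lambda r: (r.p_value, -r.k, r.set_name))
    return records if top_k is None else records[:top_k]


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set_name": r.set_name, "k": r.k, "n_selected": r.n_selected,
             "K": r.K, "N": r.N, "p_value": r.p_value, "p_adj_bh": r.p_adj_bh,
             "neg_log10_p": r.neg_log10_p}
            for r in records
        ],
        columns=["set_name", "k", "n_selected", "K", "N", "p_value",
                 "p_adj_bh", "neg_log10_p"],
    )
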