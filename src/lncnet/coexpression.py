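"""Thresholded lncRNA-mRNA Pearson co-expression network and its topology.

Every candidate lncRNA x mRNA pair is scored by the sample Pearson
correlation of its normalized intensities across all samples pooled (both
groups together — co-expression is a property of the joint profile, not of
either group alone).  A pair becomes an edge when |r| exceeds ``pcc_min``
and its two-sided P value is below ``p_max``, both strictly; the defaults
(0.9 and 0.0005) are deliberately stringent and, at n = 10 samples, bind
almost together: r = 0.9 gives P ~ 3.9e-4.

P values use the exact t-transform of the correlation coefficient under the
null of zero correlation for a bivariate normal sample::

    t = r * sqrt((n - 2) / (1 - r^2)),   t ~ Student-t with n - 2 df

which is the standard exact test behind ``scipy.stats.pearsonr``; it is
authored here (scipy serves as an independent cross-check in the test
suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    CoexpressionEdge,
    EdgeSign,
    ExpressionMatrix,
    ValidationError,
    edges_to_graph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "pearson",
    "pearson_pvalue",
    "build_network",
    "degree_summary",
    "negative_edges",
    "connected_components",
    "edges_to_frame",
]

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class CoexpressionNetwork:
    """Edges surviving the joint |PCC| / P-value screen, plus bookkeeping."""

    edges: list[CoexpressionEdge]
    lncrna_nodes: frozenset[str]
    mrna_nodes: frozenset[str]
    pcc_min: float
    p_max: float
    n_pairs_tested: int
    n_pairs_skipped: int = 0

    def graph(self) -> nx.Graph:
        return edges_to_graph(self.edges)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Raises on unequal lengths, n < 3 or a zero-variance vector (correlation
    undefined; the caller drops the pair with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 observations, got {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.dot(xd, xd)))
    sy = float(np.sqrt(np.dot(yd, yd)))
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("undefined correlation: zero variance")
    r = float(np.dot(xd, yd) / (sx * sy))
    return max(-1.0, min(1.0, r))


def pearson_pvalue(pcc: float, n: int) -> float:
    """Two-sided P value for a sample correlation under the zero-correlation
    null, via the t-transform with n - 2 degrees of freedom.

    |r| = 1 underflows the transform; the smallest positive float is
    reported with a warning.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    if not -1.0 <= pcc <= 1.0:
        raise ValidationError(f"correlation {pcc} outside [-1, 1]")
    if abs(pcc) == 1.0:
        logger.warning("|r| = 1: reporting smallest positive P value")
        return _TINY_P
    df = n - 2
    t = abs(pcc) * np.sqrt(df / (1.0 - pcc * pcc))
    p = 2.0 * float(stats.t.sf(t, df))
    if p == 0.0:
        logger.warning("P-value underflow at r=%g, n=%d", pcc, n)
        return _TINY_P
    return min(p, 1.0)


def build_network(
    matrix: ExpressionMatrix,
    lncrna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    pcc_min: float = 0.9,
    p_max: float = 0.0005,
    on_log_scale: bool = False,
) -> CoexpressionNetwork:
    """Screen every lncRNA x mRNA pair and keep those passing both thresholds.

    Correlations run on linear normalized intensities across all samples
    pooled; ``on_log_scale`` switches to log2 intensities.  Pairs involving
    a zero-variance transcript are skipped with a warning and counted in
    ``n_pairs_skipped`` rather than failing the run.
    """
    for name, ids in (("lncRNA", lncrna_ids), ("mRNA", mrna_ids)):
        missing = [t for t in ids if t not in matrix.values.index]
        if missing:
            raise ValidationError(f"{name} id(s) absent from matrix: {missing}")
    if len(set(lncrna_ids)) != len(lncrna_ids) or len(set(mrna_ids)) != len(mrna_ids):
        raise ValidationError("duplicate candidate ids")

    data = matrix.values
    if on_log_scale:
        data = np.log2(data)
    n = data.shape[1]
    profiles = {t: data.loc[t].to_numpy() for t in [*lncrna_ids, *mrna_ids]}
    zero_var = {t for t, v in profiles.items() if np.std(v) == 0.0}
    for t in zero_var:
        logger.warning("transcript %r has zero variance; its pairs are skipped", t)

    edges: list[CoexpressionEdge] = []
    n_skipped = 0
    for li in lncrna_ids:
        for mi in mrna_ids:
            if li in zero_var or mi in zero_var:
                n_skipped += 1
                continue
            r = pearson(profiles[li], profiles[mi])
            if abs(r) <= pcc_min:
                continue
            p = pearson_pvalue(r, n)
            if p >= p_max:
                continue
            sign = EdgeSign.POSITIVE if r > 0 else EdgeSign.NEGATIVE
            edges.append(CoexpressionEdge(li, mi, r, p, sign))

    return CoexpressionNetwork(
        edges=edges,
        lncrna_nodes=frozenset(e.lncrna_id for e in edges),
        mrna_nodes=frozenset(e.mrna_id for e in edges),
        pcc_min=pcc_min,
        p_max=p_max,
        n_pairs_tested=len(lncrna_ids) * len(mrna_ids),
        n_pairs_skipped=n_skipped,
    )


def degree_summary(
    net: CoexpressionNetwork,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-node degree table plus the max-degree lncRNA(s) and mRNA(s).

    Ties at the maximum are all reported.  An empty network yields an empty
    table and empty argmax lists.
    """
    rows = []
    degree: dict[str, int] = {}
    for e in net.edges:
        degree[e.lncrna_id] = degree.get(e.lncrna_id, 0) + 1
        degree[e.mrna_id] = degree.get(e.mrna_id, 0) + 1
    for node in sorted(degree):
        cls = "lncRNA" if node in net.lncrna_nodes else "mRNA"
        rows.append({"node": node, "type": cls, "degree": degree[node]})
    table = pd.DataFrame(rows, columns=["node", "type", "degree"])

    def argmax(nodes: frozenset[str]) -> list[str]:
        if not nodes:
            return []
        top = max(degree[n] for n in nodes)
        return sorted(n for n in nodes if degree[n] == top)

    return table, argmax(net.lncrna_nodes), argmax(net.mrna_nodes)


def negative_edges(net: CoexpressionNetwork) -> list[CoexpressionEdge]:
    """All anti-correlated edges."""
    return [e for e in net.edges if e.sign is EdgeSign.NEGATIVE]


def connected_components(net: CoexpressionNetwork) -> list[set[str]]:
    """Components of the undirected bipartite graph, largest first; ties by
    lexicographic minimum member id.  Isolated 'satellite' components are
    the ones after the first."""
    comps = [set(c) for c in nx.connected_components(net.graph())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def edges_to_frame(net: CoexpressionNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lncrna": e.lncrna_id, "mrna": e.mrna_id, "pcc": e.pcc,
             "p_value": e.p_value, "sign": e.sign.value}
            for e in net.edges
        ],
        columns=["lncrna", "mrna", "pcc", "p_value", "sign"],
    )
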