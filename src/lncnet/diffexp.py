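"""Volcano-style two-group differential expression and sample clustering.

The screen calls a transcript differentially expressed when its linear fold
change between group means is at least ``fc_min`` (inclusive, default 2.0)
AND its two-sided Student's t-test P value is below ``alpha`` (strict,
default 0.05).  Fold change is the ratio of arithmetic means of linear
intensities, reported as max(ratio, 1/ratio) alongside the signed log2
ratio (tumor over normal).  The t-test runs on log2 intensities by default
(variance stabilization, the convention for volcano P values on microarray
data); equal variances are assumed unless Welch is requested.  Raw P drives
the call; Benjamini-Hochberg adjusted values are carried as an extra column
only.

Hierarchical clustering of samples and transcripts uses correlation distance
(1 - Pearson r) with average linkage, the common default for expression
heatmaps, and is made deterministic by ordering ties lexicographically.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import (
    DiffExprRecord,
    ExpressionMatrix,
    Group,
    Regulation,
    TranscriptClass,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DiffExprResult",
    "group_fold_change",
    "two_sample_t",
    "volcano_filter",
    "hierarchical_cluster",
    "result_to_frame",
]

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class DiffExprResult:
    """Outcome of the volcano screen with the thresholds that produced it."""

    records: list[DiffExprRecord]
    fc_min: float
    alpha: float
    counts: dict[TranscriptClass, tuple[int, int]]  # class -> (n_up, n_down)

    def by_id(self) -> dict[str, DiffExprRecord]:
        return {r.transcript_id: r for r in self.records}

    def regulated_ids(
        self,
        regulation: Regulation | None = None,
        transcript_class: TranscriptClass | None = None,
        classes: dict[str, TranscriptClass] | None = None,
    ) -> list[str]:
        """Ids of flagged transcripts, optionally filtered by direction/class."""
        out = []
        for r in self.records:
            if r.regulation is Regulation.UNCHANGED:
                continue
            if regulation is not None and r.regulation is not regulation:
                continue
            if transcript_class is not None:
                if classes is None:
                    raise ValueError("classes map required for class filtering")
                if classes[r.transcript_id] is not transcript_class:
                    continue
            out.append(r.transcript_id)
        return out


def group_fold_change(
    x_tumor: Sequence[float], x_normal: Sequence[float]
) -> tuple[float, float]:
    """Linear fold change and signed log2 fold change (tumor over normal).

    fold_change = max(m_t/m_n, m_n/m_t) with m_* the arithmetic means of the
    linear intensities; log2_fold_change = log2(m_t/m_n).
    """
    xt = np.asarray(x_tumor, dtype=float)
    xn = np.asarray(x_normal, dtype=float)
    if xt.size == 0 or xn.size == 0:
        raise ValidationError("empty intensity vector")
    m_t, m_n = float(xt.mean()), float(xn.mean())
    if m_t <= 0 or m_n <= 0:
        raise ValidationError(f"non-positive group mean: tumor={m_t}, normal={m_n}")
    ratio = m_t / m_n
    return max(ratio, 1.0 / ratio), math.log2(ratio)


def two_sample_t(
    x_tumor: Sequence[float],
    x_normal: Sequence[float],
    on_log_scale: bool = True,
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample Student's t-test P value.

    With ``on_log_scale`` (the default) intensities are log2-transformed
    before testing.  Zero pooled variance is resolved by the group means:
    equal means give P = 1, unequal means give the smallest positive float
    with a warning (perfect separation).
    """
    xt = np.asarray(x_tumor, dtype=float)
    xn = np.asarray(x_normal, dtype=float)
    if xt.size < 2 or xn.size < 2:
        raise ValidationError("need >= 2 observations per group")
    if on_log_scale:
        if (xt <= 0).any() or (xn <= 0).any():
            raise ValidationError("log-scale test requires positive intensities")
        xt, xn = np.log2(xt), np.log2(xn)
    if xt.var(ddof=1) == 0.0 and xn.var(ddof=1) == 0.0:
        if xt.mean() == xn.mean():
            return 1.0
        logger.warning("zero variance with unequal means; reporting smallest "
                       "positive P value")
        return _TINY_P
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(xt, xn, equal_var=equal_var).pvalue)
    if p == 0.0:
        logger.warning("t-test underflow; reporting smallest positive P value")
        return _TINY_P
    return p


def volcano_filter(
    matrix: ExpressionMatrix,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    on_log_scale: bool = True,
    equal_var: bool = True,
) -> DiffExprResult:
    """Joint fold-change / P-value screen over every transcript.

    Boundary semantics: fold change inclusive (>= fc_min), P strict
    (< alpha).  UP requires the tumor mean above the normal mean, DOWN the
    reverse.  Per-class UP/DOWN counts are tallied.
    """
    tumor = matrix.samples_in_group(Group.TUMOR)
    normal = matrix.samples_in_group(Group.NORMAL)
    xt_all = matrix.values[tumor].to_numpy()
    xn_all = matrix.values[normal].to_numpy()

    records: list[DiffExprRecord] = []
    p_values = np.empty(len(matrix.transcript_ids))
    for i, t in enumerate(matrix.transcript_ids):
        fc, log2fc = group_fold_change(xt_all[i], xn_all[i])
        p = two_sample_t(xt_all[i], xn_all[i], on_log_scale=on_log_scale,
                         equal_var=equal_var)
        p_values[i] = p
        if fc >= fc_min and p < alpha and log2fc != 0.0:
            reg = Regulation.UP if log2fc > 0 else Regulation.DOWN
        else:
            reg = Regulation.UNCHANGED
        records.append(DiffExprRecord(t, fc, log2fc, p, reg))

    p_adj = multipletests(p_values, method="fdr_bh")[1]
    records = [
        DiffExprRecord(r.transcript_id, r.fold_change, r.log2_fold_change,
                       r.p_value, r.regulation, float(q))
        for r, q in zip(records, p_adj)
    ]

    counts: dict[TranscriptClass, tuple[int, int]] = {}
    for cls in TranscriptClass:
        ids = set(matrix.transcripts_of_class(cls))
        n_up = sum(1 for r in records
                   if r.transcript_id in ids and r.regulation is Regulation.UP)
        n_down = sum(1 for r in records
                     if r.transcript_id in ids and r.regulation is Regulation.DOWN)
        counts[cls] = (n_up, n_down)
    return DiffExprResult(records, fc_min, alpha, counts)


def result_to_frame(result: DiffExprResult, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Flat table of the screen: one row per transcript."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "class": matrix.transcript_class[r.transcript_id].value,
                "fold_change": r.fold_change,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "p_adj_bh": r.p_adj_bh,
                "regulation": r.regulation.value,
            }
            for r in result.records
        ]
    )


def _corr_linkage(data: np.ndarray, labels: list[str]) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering on 1 - Pearson r; rows are observations.

    Rows are pre-sorted lexicographically by label so equal-distance merges
    resolve the same way regardless of input order.
    """
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    data = data[order]
    if len(labels_sorted) == 1:
        return labels_sorted, np.empty((0, 4))
    sd = data.std(axis=1)
    if (sd == 0).any():
        flat = [labels_sorted[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance row(s) break correlation distance: {flat}")
    dist = pdist(data, metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return [labels_sorted[i] for i in leaves], linkage


def hierarchical_cluster(
    matrix: ExpressionMatrix, subset: Sequence[str]
) -> tuple[list[str], list[str], dict[str, np.ndarray]]:
    """Cluster samples and transcripts on a transcript subset.

    Returns (sample leaf order, transcript leaf order, linkage records
    keyed 'samples'/'transcripts').  Intensities are log2-transformed first;
    the Pearson-correlation distance is scale-free, so this only tempers the
    influence of very bright transcripts.
    """
    subset = list(subset)
    if not subset:
        raise ValidationError("empty transcript subset")
    missing = [t for t in subset if t not in matrix.values.index]
    if missing:
        raise ValidationError(f"subset id(s) absent from matrix: {missing}")
    data = np.log2(matrix.values.loc[subset].to_numpy())

    transcript_order, t_linkage = _corr_linkage(data, subset)
    if len(subset) == 1:
        # one transcript cannot order samples: degenerate, no merges
        return list(matrix.sample_ids), transcript_order, {
            "samples": np.empty((0, 4)), "transcripts": t_linkage}
    sample_order, s_linkage = _corr_linkage(data.T, list(matrix.sample_ids))
    return sample_order, transcript_order, {
        "samples": s_linkage, "transcripts": t_linkage}
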