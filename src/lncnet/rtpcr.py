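"""2^-ddCt relative quantification and microarray concordance.

The Livak method: for each sample, dCt = Ct(gene) - Ct(reference); ddCt is
the difference of the group-mean dCt (tumor minus normal); the relative
expression ratio is 2^-ddCt, assuming perfect doubling per cycle.  Because
the reference Ct is subtracted per sample, any per-sample technical offset
(loading, cDNA input) cancels exactly.

Concordance against the microarray screen is directional: a gene counts as
concordant when its qPCR call (ratio above or below 1) matches the array's
UP/DOWN regulation call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .diffexp import DiffExprResult
from .io import CtTable, Group, Regulation, ValidationError

__all__ = ["RelativeExpression", "ddct", "concordance"]


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    ddct: float
    ratio: float          # 2^-ddct
    log2_ratio: float     # -ddct
    direction: Regulation

    def __post_init__(self) -> None:
        if not math.isclose(self.ratio, 2.0 ** (-self.ddct), rel_tol=1e-12):
            raise ValidationError(f"{self.gene_id}: ratio inconsistent with ddct")


def _group_mean_dct(table: CtTable, gene: str, group: Group) -> float:
    ct = table.ct
    ref = ct[ct["gene_id"] == table.reference_gene].set_index("sample_id")["ct"]
    sub = ct[ct["gene_id"] == gene]
    samples = [s for s in sub["sample_id"] if table.sample_group[s] is group]
    if not samples:
        raise ValidationError(
            f"gene {gene!r} not measured in any {group.value} sample")
    gene_ct = sub.set_index("sample_id")["ct"]
    dct = [float(gene_ct[s] - ref[s]) for s in samples]
    return sum(dct) / len(dct)


def ddct(table: CtTable, gene: str) -> RelativeExpression:
    """Relative tumor/normal expression of ``gene`` by 2^-ddCt."""
    if gene not in set(table.ct["gene_id"]):
        raise ValidationError(f"gene {gene!r} absent from Ct table")
    mean_t = _group_mean_dct(table, gene, Group.TUMOR)
    mean_n = _group_mean_dct(table, gene, Group.NORMAL)
    dd = mean_t - mean_n
    ratio = 2.0 ** (-dd)
    if ratio > 1.0:
        direction = Regulation.UP
    elif ratio < 1.0:
        direction = Regulation.DOWN
    else:
        direction = Regulation.UNCHANGED
    return RelativeExpression(gene, dd, ratio, -dd, direction)


def per_sample_ratios(table: CtTable, gene: str) -> pd.DataFrame:
    """Per-tumor-sample 2^-ddCt ratios against the normal-group mean dCt,
    for inspection alongside the group-level estimate."""
    if gene not in set(table.ct["gene_id"]):
        raise ValidationError(f"gene {gene!r} absent from Ct table")
    ct = table.ct
    ref = ct[ct["gene_id"] == table.reference_gene].set_index("sample_id")["ct"]
    gene_ct = ct[ct["gene_id"] == gene].set_index("sample_id")["ct"]
    mean_n = _group_mean_dct(table, gene, Group.NORMAL)
    rows = []
    for s in gene_ct.index:
        if table.sample_group[s] is not Group.TUMOR:
            continue
        dd = float(gene_ct[s] - ref[s]) - mean_n
        rows.append({"sample_id": s, "gene_id": gene, "ddct": dd,
                     "ratio": 2.0 ** (-dd)})
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "ddct", "ratio"])


def concordance(
    pcr: list[RelativeExpression], array: DiffExprResult
) -> tuple[float, pd.DataFrame]:
    """Fraction of genes whose qPCR direction matches the array call,
    plus a per-gene table."""
    if not pcr:
        raise ValidationError("nothing to compare: empty qPCR result list")
    by_id = array.by_id()
    missing = [r.gene_id for r in pcr if r.gene_id not in by_id]
    if missing:
        raise ValidationError(f"gene(s) absent from array results: {missing}")
    rows = []
    n_conc = 0
    for r in pcr:
        array_dir = by_id[r.gene_id].regulation
        ok = r.direction is array_dir and r.direction is not Regulation.UNCHANGED
        n_conc += ok
        rows.append({"gene_id": r.gene_id, "pcr_ratio": r.ratio,
                     "pcr_direction": r.direction.value,
                     "array_direction": array_dir.value,
                     "concordant": bool(ok)})
    table = pd.DataFrame(rows, columns=["gene_id", "pcr_ratio", "pcr_direction",
                                        "array_direction", "concordant"])
    return n_conc / len(pcr), table
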