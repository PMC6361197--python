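"""Domain types and readers/writers.

The pipeline's on-disk dialect is deliberately plain: tab-separated tables
with a mandatory header row, decimal points only.  Expression matrices are
transcripts x samples of strictly positive normalized intensities (linear
scale unless the caller declares otherwise); sample groups (tumor vs normal)
and transcript classes (lncRNA vs mRNA) live in two-column sidecar TSVs
rather than being encoded in identifiers.  Gene sets use the standard GMT
dialect.  Networks are exported in Cytoscape-loadable SIF / edge-attribute
TSV / GraphML form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "TranscriptClass",
    "Regulation",
    "EdgeSign",
    "ValidationError",
    "ExpressionMatrix",
    "DiffExprRecord",
    "CoexpressionEdge",
    "GeneSetCollection",
    "CtTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_ct_table",
    "write_ct_table",
    "write_network",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


class Group(str, Enum):
    TUMOR = "TUMOR"
    NORMAL = "NORMAL"


class TranscriptClass(str, Enum):
    LNCRNA = "LNCRNA"
    MRNA = "MRNA"


class Regulation(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"


class EdgeSign(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized intensities, transcripts x samples, linear scale, > 0.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id with one column per sample id.
    sample_group
        Map sample id -> :class:`Group`; every sample must be mapped and each
        group must contain at least two samples.
    transcript_class
        Map transcript id -> :class:`TranscriptClass`; every transcript must
        be mapped.
    """

    values: pd.DataFrame
    sample_group: dict[str, Group]
    transcript_class: dict[str, TranscriptClass]

    def __post_init__(self) -> None:
        self.sample_group = {s: Group(g) for s, g in self.sample_group.items()}
        self.transcript_class = {
            t: TranscriptClass(c) for t, c in self.transcript_class.items()
        }
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        missing = [s for s in cols if s not in self.sample_group]
        if missing:
            raise ValidationError(f"sample(s) without group annotation: {missing}")
        missing = [t for t in idx if t not in self.transcript_class]
        if missing:
            raise ValidationError(f"transcript(s) without class annotation: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric intensity values present")
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "non-positive or non-finite intensity at "
                f"transcript {idx[r]!r}, sample {cols[c]!r}: {arr[r, c]!r}"
            )
        for grp in Group:
            n = sum(1 for s in cols if self.sample_group[s] is grp)
            if n < 2:
                raise ValidationError(f"group {grp.value} has {n} sample(s); need >= 2")

    # -- convenience accessors ---------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: Group) -> list[str]:
        return [s for s in self.values.columns if self.sample_group[s] is group]

    def transcripts_of_class(self, cls: TranscriptClass) -> list[str]:
        return [t for t in self.values.index if self.transcript_class[t] is cls]

    def row(self, transcript_id: str) -> pd.Series:
        if transcript_id not in self.values.index:
            raise KeyError(f"transcript {transcript_id!r} not in matrix")
        return self.values.loc[transcript_id]


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-transcript two-group screen outcome."""

    transcript_id: str
    fold_change: float
    log2_fold_change: float
    p_value: float
    regulation: Regulation
    p_adj_bh: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"{self.transcript_id}: p_value {self.p_value} outside [0, 1]"
            )
        if self.fold_change < 0:
            raise ValidationError(
                f"{self.transcript_id}: fold_change {self.fold_change} < 0"
            )
        if not math.isclose(
            self.fold_change, 2.0 ** abs(self.log2_fold_change), rel_tol=1e-9
        ):
            raise ValidationError(
                f"{self.transcript_id}: fold_change {self.fold_change} inconsistent "
                f"with log2_fold_change {self.log2_fold_change}"
            )


@dataclass(frozen=True)
class CoexpressionEdge:
    """An lncRNA-mRNA pair surviving the |PCC| and P-value thresholds."""

    lncrna_id: str
    mrna_id: str
    pcc: float
    p_value: float
    sign: EdgeSign

    def __post_init__(self) -> None:
        if not -1.0 <= self.pcc <= 1.0:
            raise ValidationError(f"pcc {self.pcc} outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        expected = EdgeSign.POSITIVE if self.pcc > 0 else EdgeSign.NEGATIVE
        if self.sign is not expected:
            raise ValidationError(
                f"sign {self.sign.value} inconsistent with pcc {self.pcc}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def restricted_to_universe(self) -> "GeneSetCollection":
        """Drop members outside the universe; sets emptied by this are removed."""
        kept = {}
        for name, members in self.sets.items():
            inter = members & self.universe
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r empty after universe restriction", name)
        return GeneSetCollection(kept, self.universe, dict(self.descriptions))


@dataclass
class CtTable:
    """qRT-PCR cycle thresholds keyed by (sample, gene), with a reference gene."""

    ct: pd.DataFrame  # columns: sample_id, gene_id, ct
    reference_gene: str
    sample_group: dict[str, Group]

    def __post_init__(self) -> None:
        self.sample_group = {s: Group(g) for s, g in self.sample_group.items()}
        required = {"sample_id", "gene_id", "ct"}
        if not required <= set(self.ct.columns):
            raise ValidationError(f"Ct table needs columns {sorted(required)}")
        dup = self.ct.duplicated(subset=["sample_id", "gene_id"])
        if dup.any():
            pair = self.ct.loc[dup, ["sample_id", "gene_id"]].iloc[0].tolist()
            raise ValidationError(f"duplicate (sample, gene) measurement: {pair}")
        if not np.isfinite(self.ct["ct"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite Ct value present")
        samples = set(self.ct["sample_id"])
        with_ref = set(self.ct.loc[self.ct["gene_id"] == self.reference_gene, "sample_id"])
        missing = samples - with_ref
        if missing:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} not measured in "
                f"sample(s): {sorted(missing)}"
            )
        unmapped = samples - set(self.sample_group)
        if unmapped:
            raise ValidationError(f"sample(s) without group annotation: {sorted(unmapped)}")

    def genes(self) -> list[str]:
        return sorted(set(self.ct["gene_id"]))


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def _read_two_column_map(path: str | Path, what: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{what} file {path} must have exactly 2 columns")
    key, val = df.columns
    if df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].tolist()
        raise ValidationError(f"duplicate id(s) in {what} file {path}: {dups}")
    return dict(zip(df[key], df[val]))


def read_expression_matrix(
    path: str | Path,
    groups_path: str | Path,
    classes_path: str | Path,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Load a transcripts x samples TSV plus group/class sidecar maps.

    ``scale`` declares how intensities are stored on disk: ``"linear"``
    (default) or ``"log2"``, in which case they are exponentiated to the
    linear scale the in-memory contract requires.  The scale is declared,
    never guessed.
    """
    if scale not in ("linear", "log2"):
        raise ValidationError(f"scale must be 'linear' or 'log2', got {scale!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate transcript id(s) in {path}: {dups}")
    non_num = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_num:
        col = non_num[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValidationError(
            f"non-numeric intensity in {path}, sample column {col!r}, "
            f"transcript {where!r}"
        )
    if scale == "log2":
        df = 2.0 ** df
    groups = _read_two_column_map(groups_path, "sample-group")
    classes = _read_two_column_map(classes_path, "transcript-class")
    try:
        sample_group = {s: Group(groups[s]) for s in df.columns if s in groups}
        transcript_class = {
            t: TranscriptClass(classes[t]) for t in df.index if t in classes
        }
    except ValueError as exc:  # unknown label token
        raise ValidationError(str(exc)) from exc
    return ExpressionMatrix(df, sample_group, transcript_class)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    groups_path: str | Path,
    classes_path: str | Path,
    float_format: str = "%.10g",
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id",
                         float_format=float_format)
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": [matrix.sample_group[s].value for s in matrix.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": matrix.transcript_ids,
         "class": [matrix.transcript_class[t].value for t in matrix.transcript_ids]}
    ).to_csv(classes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    The universe defaults to the union of all members unless overridden.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and >= 1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members in set %r deduplicated",
                               path, lineno, name)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    if universe is None:
        universe = frozenset().union(*sets.values())
    return GeneSetCollection(sets, frozenset(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "na")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def read_ct_table(
    path: str | Path,
    groups_path: str | Path,
    reference_gene: str = "ACTB",
) -> CtTable:
    """Read a long-form Ct TSV (sample_id, gene_id, ct) with a group sidecar."""
    df = pd.read_csv(path, sep="\t", header=0,
                     dtype={"sample_id": str, "gene_id": str})
    groups = _read_two_column_map(groups_path, "sample-group")
    samples = set(df["sample_id"])
    try:
        group_map = {s: Group(groups[s]) for s in samples if s in groups}
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    return CtTable(df, reference_gene, group_map)


def write_ct_table(table: CtTable, path: str | Path, groups_path: str | Path) -> None:
    table.ct.to_csv(path, sep="\t", index=False, float_format="%.10g")
    samples = list(dict.fromkeys(table.ct["sample_id"]))
    pd.DataFrame(
        {"sample_id": samples,
         "group": [table.sample_group[s].value for s in samples]}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def edges_to_graph(edges: Sequence[CoexpressionEdge]) -> nx.Graph:
    """Undirected bipartite graph with node attribute ``type`` and edge
    attributes ``pcc``, ``p_value``, ``sign``."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.lncrna_id, type="lncRNA")
        g.add_node(e.mrna_id, type="mRNA")
        g.add_edge(e.lncrna_id, e.mrna_id,
                   pcc=float(e.pcc), p_value=float(e.p_value), sign=e.sign.value)
    return g


def write_network(
    edges: Sequence[CoexpressionEdge],
    sif_path: str | Path,
    attrs_path: str | Path,
    graphml_path: str | Path,
) -> None:
    """Emit Cytoscape-loadable SIF, edge-attribute TSV and GraphML files."""
    with open(sif_path, "w") as fh:
        for e in edges:
            fh.write(f"{e.lncrna_id}\tcoexp\t{e.mrna_id}\n")
    pd.DataFrame(
        [
            {"lncrna": e.lncrna_id, "mrna": e.mrna_id, "pcc": e.pcc,
             "p_value": e.p_value, "sign": e.sign.value}
            for e in edges
        ],
        columns=["lncrna", "mrna", "pcc", "p_value", "sign"],
    ).to_csv(attrs_path, sep="\t", index=False, float_format="%.10g")
    nx.write_graphml(edges_to_graph(edges), graphml_path)
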