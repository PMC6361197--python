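"""Synthetic two-group expression data with planted structure.

The generator emulates the study design every downstream stage assumes: two
groups of samples (default 5 tumor + 5 normal), log2-scale Gaussian noise
around per-transcript baselines, a planted tumor/normal shift for a chosen
fraction of transcripts (linear fold change >= 2 by default), and planted
co-expression blocks in which every member tracks a single shared latent
factor drawn per sample.  A member with a negative loading is anti-correlated
with the rest of its block.  The matrix is emitted on the linear scale
(2**log2), matching microarray "normalized intensity" convention, together
with machine-readable ground truth (true fold changes and expected network
edges) so that recovery can be scored without any external download.

Model for transcript t in sample s, on the log2 scale::

    log2 x[t, s] = baseline[t] + de_shift[t] * 1{s in tumor}
                   + loading[t] * factor[block(t), s] + eps[t, s]

with ``eps ~ Normal(0, noise_sd)`` i.i.d. and ``factor[b, .] ~
Normal(0, factor_sd)`` i.i.d. across samples.  All randomness flows from a
single ``numpy.random.Generator`` seeded from the design, so a design is
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CtTable,
    ExpressionMatrix,
    Group,
    TranscriptClass,
    ValidationError,
)

__all__ = [
    "CoexpressionBlock",
    "SyntheticDesign",
    "GroundTruth",
    "generate_matrix",
    "generate_ct_table",
    "default_blocks",
    "write_ground_truth",
]


@dataclass(frozen=True)
class CoexpressionBlock:
    """A set of transcripts driven by one shared latent factor.

    ``loadings`` are signed, with magnitude in (0, 1]; a negative loading
    plants an anti-correlated member.  Each block must contain at least one
    lncRNA and one mRNA (ids prefixed ``lnc``/``m`` by the default naming,
    checked against the design at generation time).
    """

    member_ids: tuple[str, ...]
    loadings: tuple[float, ...]
    factor_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.member_ids) != len(self.loadings):
            raise ValidationError("one loading per member required")
        if len(self.member_ids) < 2:
            raise ValidationError("a block needs >= 2 members")
        for lo in self.loadings:
            if not 0.0 < abs(lo) <= 1.0:
                raise ValidationError(f"|loading| must be in (0, 1], got {lo}")
        if self.factor_sd <= 0:
            raise ValidationError("factor_sd must be > 0")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated design: 5 tumor + 5 normal samples, 10
    lncRNAs, 80 mRNAs, 20% of transcripts differentially expressed with
    linear fold change drawn uniformly in [2, 8] (log2-uniform direction
    split), and log2-scale noise with standard deviation 0.1.
    """

    n_tumor: int = 5
    n_normal: int = 5
    n_lncrna: int = 10
    n_mrna: int = 80
    de_fraction: float = 0.2
    fc_range: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.1
    blocks: tuple[CoexpressionBlock, ...] = ()
    seed: int = 0
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValidationError("need >= 2 samples per group")
        if self.n_lncrna < 1 or self.n_mrna < 1:
            raise ValidationError("need >= 1 transcript of each class")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        if self.fc_range[0] < 1.0 or self.fc_range[1] < self.fc_range[0]:
            raise ValidationError("fc_range must satisfy 1 <= min <= max")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")

    @property
    def lncrna_ids(self) -> list[str]:
        return [f"lnc{i:04d}" for i in range(self.n_lncrna)]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"m{i:04d}" for i in range(self.n_mrna)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_tumor)] + [
            f"N{i + 1}" for i in range(self.n_normal)
        ]


@dataclass
class GroundTruth:
    """Machine-readable record of what was planted."""

    de_table: dict[str, tuple[float, str]] = field(default_factory=dict)
    # (lncrna_id, mrna_id) -> expected sign, "POSITIVE" | "NEGATIVE"
    edge_table: dict[tuple[str, str], str] = field(default_factory=dict)


def default_blocks(design_seed: int = 0) -> tuple[CoexpressionBlock, ...]:
    """Three blocks over the default 10 lncRNA + 80 mRNA naming, one of which
    carries a negative-loading member — a small planted network with both
    edge signs and more than one connected component."""
    return (
        CoexpressionBlock(
            member_ids=("lnc0000", "lnc0001", "m0000", "m0001", "m0002", "m0003"),
            loadings=(1.0, 1.0, 1.0, 1.0, 1.0, -1.0),
        ),
        CoexpressionBlock(
            member_ids=("lnc0002", "m0004", "m0005", "m0006"),
            loadings=(1.0, 1.0, 1.0, 1.0),
        ),
        CoexpressionBlock(
            member_ids=("lnc0003", "m0007", "m0008"),
            loadings=(-1.0, 1.0, 1.0),
        ),
    )


def _planted_edges(
    blocks: Sequence[CoexpressionBlock],
    lncrna_ids: Sequence[str],
    mrna_ids: Sequence[str],
) -> dict[tuple[str, str], str]:
    lnc = set(lncrna_ids)
    mrna = set(mrna_ids)
    edges: dict[tuple[str, str], str] = {}
    for block in blocks:
        loading = dict(zip(block.member_ids, block.loadings))
        block_lnc = [t for t in block.member_ids if t in lnc]
        block_mrna = [t for t in block.member_ids if t in mrna]
        for li in block_lnc:
            for mi in block_mrna:
                sign = "POSITIVE" if loading[li] * loading[mi] > 0 else "NEGATIVE"
                edges[(li, mi)] = sign
    return edges


def generate_matrix(design: SyntheticDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate an expression matrix and its ground truth from a design.

    Raises :class:`ValidationError` if a block references a transcript id the
    design does not generate, or if a block lacks an lncRNA or an mRNA.
    """
    rng = np.random.default_rng(design.seed)
    transcript_ids = design.lncrna_ids + design.mrna_ids
    id_to_row = {t: i for i, t in enumerate(transcript_ids)}
    lnc_set = set(design.lncrna_ids)
    mrna_set = set(design.mrna_ids)

    for block in design.blocks:
        unknown = [t for t in block.member_ids if t not in id_to_row]
        if unknown:
            raise ValidationError(f"block member(s) not generated: {unknown}")
        if not any(t in lnc_set for t in block.member_ids):
            raise ValidationError("block has no lncRNA member")
        if not any(t in mrna_set for t in block.member_ids):
            raise ValidationError("block has no mRNA member")

    n_t = len(transcript_ids)
    n_s = design.n_tumor + design.n_normal
    is_tumor = np.array([1.0] * design.n_tumor + [0.0] * design.n_normal)

    lo, hi = design.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n_t)

    # Planted differential expression: a random de_fraction of transcripts,
    # stratified by class so both lncRNAs and mRNAs are represented at the
    # same rate; fold change uniform in fc_range on the linear scale.
    n_lnc = len(design.lncrna_ids)
    n_de_lnc = int(round(design.de_fraction * n_lnc))
    n_de_mrna = int(round(design.de_fraction * len(design.mrna_ids)))
    de_rows = np.concatenate([
        rng.choice(n_lnc, size=n_de_lnc, replace=False),
        n_lnc + rng.choice(len(design.mrna_ids), size=n_de_mrna, replace=False),
    ]).astype(int)
    de_shift = np.zeros(n_t)
    truth = GroundTruth()
    for r in de_rows:
        fc = rng.uniform(*design.fc_range)
        direction = rng.choice(["UP", "DOWN"])
        shift = np.log2(fc) if direction == "UP" else -np.log2(fc)
        de_shift[r] = shift
        truth.de_table[transcript_ids[r]] = (float(fc), str(direction))

    log2x = baseline[:, None] + np.outer(de_shift, is_tumor)
    for block in design.blocks:
        factor = rng.normal(0.0, block.factor_sd, size=n_s)
        for t, loading in zip(block.member_ids, block.loadings):
            log2x[id_to_row[t]] += loading * factor
    log2x += rng.normal(0.0, design.noise_sd, size=(n_t, n_s))

    values = pd.DataFrame(2.0 ** log2x, index=transcript_ids,
                          columns=design.sample_ids)
    sample_group = {
        s: (Group.TUMOR if i < design.n_tumor else Group.NORMAL)
        for i, s in enumerate(design.sample_ids)
    }
    transcript_class = {t: TranscriptClass.LNCRNA for t in design.lncrna_ids}
    transcript_class.update({t: TranscriptClass.MRNA for t in design.mrna_ids})

    truth.edge_table = _planted_edges(design.blocks, design.lncrna_ids,
                                      design.mrna_ids)
    matrix = ExpressionMatrix(values, sample_group, transcript_class)
    return matrix, truth


def generate_ct_table(
    truth: GroundTruth,
    design: SyntheticDesign,
    reference_gene: str = "ACTB",
    ct_noise_sd: float = 0.0,
    base_ct: float = 22.0,
) -> CtTable:
    """Simulate Ct values whose 2^-ddCt recovers each planted fold change.

    A gene with true linear fold change ``fc`` (tumor over normal, signed by
    direction) gets tumor Ct lowered by ``log2(fc)`` cycles relative to the
    reference; the reference gene carries no group shift.  ``ct_noise_sd``
    adds Gaussian cycle noise (0 gives exact recovery).  Per-sample technical
    offsets are added to every gene of a sample and cancel in ddCt.
    """
    rng = np.random.default_rng(design.seed + 1)
    samples = design.sample_ids
    is_tumor = {s: (i < design.n_tumor) for i, s in enumerate(samples)}
    sample_offset = {s: rng.normal(0.0, 0.5) for s in samples}

    genes = [reference_gene] + sorted(truth.de_table)
    rows = []
    for gene in genes:
        if gene == reference_gene:
            shift = 0.0
        else:
            fc, direction = truth.de_table[gene]
            log2fc = np.log2(fc) if direction == "UP" else -np.log2(fc)
            shift = -log2fc  # lower Ct = higher expression
        for s in samples:
            ct = base_ct + sample_offset[s] + (shift if is_tumor[s] else 0.0)
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append({"sample_id": s, "gene_id": gene, "ct": float(ct)})
    table = pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct"])
    sample_group = {
        s: (Group.TUMOR if is_tumor[s] else Group.NORMAL) for s in samples
    }
    return CtTable(table, reference_gene, sample_group)


def write_ground_truth(truth: GroundTruth, de_path: str | Path,
                       edge_path: str | Path) -> None:
    """Ground truth as two TSVs: planted fold changes and planted edges."""
    pd.DataFrame(
        [
            {"transcript_id": t, "true_fold_change": fc, "direction": d}
            for t, (fc, d) in sorted(truth.de_table.items())
        ],
        columns=["transcript_id", "true_fold_change", "direction"],
    ).to_csv(de_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        [
            {"lncrna_id": l, "mrna_id": m, "expected_sign": s}
            for (l, m), s in sorted(truth.edge_table.items())
        ],
        columns=["lncrna_id", "mrna_id", "expected_sign"],
    ).to_csv(edge_path, sep="\t", index=False)
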