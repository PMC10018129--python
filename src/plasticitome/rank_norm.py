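"""Percentile-rank normalization and sample quality control.

Two platform-specific rank rules bring microarray signals and RNA-Seq TPM
onto a common 0-100 scale within each sample:

* RNA-Seq: zero-count genes are fixed at rank 0; the remaining N genes are
  ranked ascending by TPM and scored P = n/N x 100, so the top untied gene
  scores exactly 100.
* Microarray: signals are sorted ascending and divided into 100 equal
  parts; the gene at ordinal i scores ceil(i x 100 / N), in [1, 100].

Ties share the mean of their positional ranks in both rules, which makes
the output invariant under permutation of the input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from plasticitome.io_formats import ExpressionMatrix, ValidationError

#: Built-in marker genes used for marker-based sample QC.
CELL_TYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "B": ("CD79A", "CD79B"),
    "CD4T": ("CD3D", "CD3G", "CD4"),
    "CD8T": ("CD3D", "CD3G", "CD8A", "CD8B"),
    "NK": ("GNLY", "NKG7"),
    "monocyte": ("CD14",),
}


@dataclass(frozen=True)
class QcThresholds:
    """Sample-level QC cutoffs.

    ``min_total_pc_reads`` and ``min_detected_pc_genes`` are inclusive
    bounds; ``min_pc_fraction`` is strict (a sample with exactly half its
    reads in protein-coding genes fails).  ``marker_rank_min`` is the
    minimum percentile rank every cell-type marker must reach.
    """

    min_total_pc_reads: int = 500_000
    min_pc_fraction: float = 0.5
    min_detected_pc_genes: int = 10_000
    marker_rank_min: float = 70.0

    def __post_init__(self) -> None:
        if self.min_total_pc_reads <= 0 or self.min_detected_pc_genes <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.min_pc_fraction <= 1:
            raise ValueError("min_pc_fraction must be in (0, 1]")
        if not 0 <= self.marker_rank_min <= 100:
            raise ValueError("marker_rank_min must be in [0, 100]")


@dataclass
class RankMatrix:
    """Genes x samples matrix of percentile rank scores in [0, 100]."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    platform: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("rank matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValidationError("rank scores must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in rank matrix") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]


def tpm_from_counts(
    counts: np.ndarray, lengths: np.ndarray | Mapping[str, int], gene_ids=None
) -> np.ndarray:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    TPM_g = (counts_g / lengths_g) / sum_j(counts_j / lengths_j) x 1e6,
    so the output always sums to one million.
    """
    counts = np.asarray(counts, dtype=float)
    if isinstance(lengths, Mapping):
        if gene_ids is None:
            raise ValueError("gene_ids required when lengths is a mapping")
        missing = [g for g in gene_ids if g not in lengths]
        if missing:
            raise ValidationError(f"genes without length: {missing}")
        lengths = np.array([lengths[g] for g in gene_ids], dtype=float)
    else:
        lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValidationError("counts and lengths are not aligned")
    if np.any(counts < 0):
        raise ValidationError("negative counts")
    if np.any(lengths < 1):
        raise ValidationError("gene lengths must be >= 1")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValidationError("all-zero count vector: TPM undefined")
    return rate / total * 1e6


def qc_sample(
    counts: np.ndarray,
    is_protein_coding: np.ndarray,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[bool, list[str]]:
    """Read-count QC for one RNA-Seq sample.

    A sample passes when the protein-coding read total meets
    ``min_total_pc_reads`` (inclusive), protein-coding reads make up
    strictly more than ``min_pc_fraction`` of all reads, and at least
    ``min_detected_pc_genes`` protein-coding genes have a nonzero count.
    Returns (passed, list of failing criteria).
    """
    counts = np.asarray(counts, dtype=float)
    pc = np.asarray(is_protein_coding, dtype=bool)
    if counts.size == 0:
        raise ValidationError("empty count vector")
    if counts.shape != pc.shape:
        raise ValidationError("counts and protein-coding mask are not aligned")
    reasons: list[str] = []
    pc_total = counts[pc].sum()
    all_total = counts.sum()
    if pc_total < thresholds.min_total_pc_reads:
        reasons.append("total_pc_reads")
    if all_total == 0 or pc_total / all_total <= thresholds.min_pc_fraction:
        reasons.append("pc_fraction")
    if int((counts[pc] > 0).sum()) < thresholds.min_detected_pc_genes:
        reasons.append("detected_pc_genes")
    return (not reasons, reasons)


def rank_rnaseq(tpm: np.ndarray) -> np.ndarray:
    """Percentile rank scores for one RNA-Seq sample.

    Zero entries score 0.  Nonzero entries are ranked ascending among the
    N nonzero values and scored n/N x 100; tied values share the mean of
    their ordinal ranks before scaling.
    """
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm < 0):
        raise ValidationError("negative expression values")
    out = np.zeros(tpm.shape, dtype=float)
    nz = tpm > 0
    n_nz = int(nz.sum())
    if n_nz:
        out[nz] = rankdata(tpm[nz], method="average") / n_nz * 100.0
    return out


def rank_array(signal: np.ndarray) -> np.ndarray:
    """Percentile rank scores for one microarray sample.

    The N signals are sorted ascending and split into 100 equal parts:
    the gene at sorted position i (1-based) scores ceil(i x 100 / N).
    Ties share the mean score of their tied positions, so the result does
    not depend on input order.  Scores lie in [1, 100].
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n == 0:
        raise ValidationError("empty signal vector")
    order = np.argsort(signal, kind="stable")
    bucket = np.ceil(np.arange(1, n + 1) * 100.0 / n)
    scores = np.empty(n, dtype=float)
    scores[order] = bucket
    # average over ties
    sorted_vals = signal[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for a, b in zip(starts, ends):
        if b - a > 1:
            scores[order[a:b]] = bucket[a:b].mean()
    return scores


def rank_matrix(m: ExpressionMatrix) -> RankMatrix:
    """Apply the platform-appropriate rank rule to every sample."""
    if m.platform == "array-signal":
        ranker = rank_array
    elif m.platform in ("rnaseq-tpm", "rnaseq-count", "sc-umi"):
        ranker = rank_rnaseq
    else:  # pragma: no cover - platform enum is closed upstream
        raise ValidationError(f"cannot rank platform {m.platform}")
    ranks = np.column_stack([ranker(m.values[:, j]) for j in range(m.shape[1])])
    return RankMatrix(
        values=ranks,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        platform=m.platform,
    )


def marker_qc(
    r: RankMatrix,
    cell_type: str,
    thresholds: QcThresholds = QcThresholds(),
) -> dict[str, bool]:
    """Marker-based QC: a sample passes when every marker gene of the
    declared cell type reaches ``marker_rank_min`` in that sample."""
    if cell_type not in CELL_TYPE_MARKERS:
        raise ValueError(
            f"unknown cell type {cell_type!r}; expected one of "
            f"{sorted(CELL_TYPE_MARKERS)}"
        )
    markers = CELL_TYPE_MARKERS[cell_type]
    missing = [g for g in markers if g not in r.gene_ids]
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing}")
    rows = np.array([r.gene_index(g) for g in markers])
    ok = (r.values[rows] >= thresholds.marker_rank_min).all(axis=0)
    return dict(zip(r.sample_ids, map(bool, ok)))
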