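"""Per-gene plasticity statistics and cross-platform screens.

A gene's plasticity is measured on its percentile rank scores across
samples of one cell type:

* ARS (average rank score): mean rank, a rank-scale average expression.
* GPL (IQR): Q3 - Q1 of the ranks, robust spread.
* GPL (absolute): max - min of the ranks, bounded by 100; this is the
  score used for the polarized-gene screen and enrichment ranking.

Because the absolute score is a range, it is monotone under adding
samples: new conditions can only keep or increase a gene's plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasticitome.io_formats import ValidationError
from plasticitome.rank_norm import RankMatrix


@dataclass(frozen=True)
class GeneStats:
    """Plasticity statistics for one gene on one platform."""

    gene_id: str
    ars: float
    q1: float
    q3: float
    gpl_iqr: float
    gpl_abs: float
    rank_min: float
    rank_max: float
    n_samples: int
    platform: str

    def __post_init__(self) -> None:
        if not self.rank_min - 1e-9 <= self.ars <= self.rank_max + 1e-9:
            raise ValidationError(f"{self.gene_id}: ARS outside [min, max] rank")
        if self.gpl_iqr > self.gpl_abs + 1e-9:
            raise ValidationError(f"{self.gene_id}: IQR GPL exceeds absolute GPL")


@dataclass(frozen=True)
class MergedStats:
    """Statistics for a gene measured on both the array and RNA-Seq platforms."""

    gene_id: str
    array: GeneStats
    rnaseq: GeneStats

    @property
    def polarized(self) -> bool:
        return is_polarized(self)

    @property
    def high_plastic(self) -> bool:
        return self.array.gpl_abs >= 50 and self.rnaseq.gpl_abs >= 50


def ars(ranks: np.ndarray) -> float:
    """Average rank score: the mean percentile rank across samples."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValidationError("ARS undefined for empty rank vector")
    return float(ranks.mean())


def gpl_iqr(ranks: np.ndarray) -> float:
    """Interquartile-range plasticity score, Q3 - Q1 of the rank scores.

    Quartiles use linear interpolation between order statistics (the
    numpy default convention).
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size < 2:
        raise ValidationError("IQR GPL requires at least two samples")
    q1, q3 = np.percentile(ranks, [25, 75])
    return float(q3 - q1)


def gpl_abs(ranks: np.ndarray) -> float:
    """Absolute plasticity score, max - min of the rank scores (<= 100)."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValidationError("absolute GPL undefined for empty rank vector")
    return float(ranks.max() - ranks.min())


def gene_stats_table(r: RankMatrix) -> list[GeneStats]:
    """Compute :class:`GeneStats` for every gene of a rank matrix."""
    n = len(r.sample_ids)
    out: list[GeneStats] = []
    for i, gene in enumerate(r.gene_ids):
        row = r.values[i]
        if n >= 2:
            q1, q3 = (float(q) for q in np.percentile(row, [25, 75]))
        else:
            q1 = q3 = float(row[0])
        out.append(
            GeneStats(
                gene_id=gene,
                ars=float(row.mean()),
                q1=q1,
                q3=q3,
                gpl_iqr=q3 - q1,
                gpl_abs=float(row.max() - row.min()),
                rank_min=float(row.min()),
                rank_max=float(row.max()),
                n_samples=n,
                platform=r.platform,
            )
        )
    return out


def merge_platforms(
    array_stats: list[GeneStats], rnaseq_stats: list[GeneStats]
) -> tuple[list[MergedStats], float]:
    """Inner-join per-gene statistics from the two platforms.

    Returns the merged records (genes measured on both platforms, in
    array order) and the Pearson correlation of their paired ARS values —
    the cross-platform comparability check.
    """
    if not array_stats or not rnaseq_stats:
        raise ValidationError("both platforms must contribute statistics")
    by_gene = {s.gene_id: s for s in rnaseq_stats}
    merged = [
        MergedStats(gene_id=s.gene_id, array=s, rnaseq=by_gene[s.gene_id])
        for s in array_stats
        if s.gene_id in by_gene
    ]
    if not merged:
        raise ValidationError("no genes shared between platforms")
    a = np.array([m.array.ars for m in merged])
    b = np.array([m.rnaseq.ars for m in merged])
    if len(merged) < 2 or a.std() == 0 or b.std() == 0:
        pearson = 1.0 if len(merged) >= 1 and np.allclose(a, b) else float("nan")
    else:
        pearson = float(np.corrcoef(a, b)[0, 1])
    return merged, pearson


def is_polarized(
    m: MergedStats, gpl_min: float = 50.0, rankmax_min: float = 90.0
) -> bool:
    return (
        m.array.gpl_abs >= gpl_min
        and m.rnaseq.gpl_abs >= gpl_min
        and m.array.rank_max >= rankmax_min
        and m.rnaseq.rank_max >= rankmax_min
    )


def screen_polarized(
    merged: list[MergedStats], gpl_min: float = 50.0, rankmax_min: float = 90.0
) -> list[str]:
    """Genes capable of polarized (extreme high) expression on both platforms.

    Selects genes whose absolute GPL meets ``gpl_min`` on *both* platforms
    and whose maximum rank meets ``rankmax_min`` on *both* platforms, i.e.
    highly plastic genes that reach the top decile of expression.
    """
    return [m.gene_id for m in merged if is_polarized(m, gpl_min, rankmax_min)]


def marker_plastic_fraction(
    markers,
    merged: list[MergedStats],
    cutoff: float = 50.0,
    mode: str = "either",
) -> dict:
    """Fraction of marker genes whose absolute GPL meets *cutoff*.

    ``mode="either"`` counts a marker when it meets the cutoff on at least
    one platform; ``mode="both"`` requires both.  Markers absent from the
    merged table are excluded from numerator and denominator and listed
    under ``missing``.
    """
    markers = list(dict.fromkeys(markers))
    if not markers:
        raise ValidationError("empty marker set")
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    by_gene = {m.gene_id: m for m in merged}
    missing = [g for g in markers if g not in by_gene]
    measured = [g for g in markers if g in by_gene]
    hits = []
    for g in measured:
        m = by_gene[g]
        ok_a = m.array.gpl_abs >= cutoff
        ok_r = m.rnaseq.gpl_abs >= cutoff
        if (ok_a or ok_r) if mode == "either" else (ok_a and ok_r):
            hits.append(g)
    n, total = len(hits), len(measured)
    return {
        "n_plastic": n,
        "n_measured": total,
        "fraction": n / total if total else float("nan"),
        "percent": 100.0 * n / total if total else float("nan"),
        "plastic_markers": hits,
        "missing": missing,
    }
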