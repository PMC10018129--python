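"""Self-contained preranked gene-set enrichment.

Genes are ranked by descending absolute plasticity score and a marker set
is tested for concentration toward either end of the list with the
classic weighted Kolmogorov-Smirnov running statistic: walking down the
list, set members add their |score|^weight (normalized over the set) and
non-members subtract 1/(N - k); the enrichment score (ES) is the signed
maximum deviation of this walk from zero.  Significance comes from a
gene-set permutation null (random sets of the same size drawn from the
list), the only null available for preranked input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasticitome.io_formats import ValidationError
from plasticitome.plasticity import GeneStats


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending score with a deterministic tie-break.

    Equal scores are ordered by gene id ascending so the list is fully
    reproducible; duplicate genes are rejected.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        order = sorted(range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i]))
        object.__setattr__(self, "genes", tuple(self.genes[i] for i in order))
        object.__setattr__(self, "scores", tuple(float(self.scores[i]) for i in order))

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_gene_stats(cls, stats: list[GeneStats]) -> "RankedList":
        """Rank genes by descending absolute GPL score."""
        return cls(
            genes=tuple(s.gene_id for s in stats),
            scores=tuple(s.gpl_abs for s in stats),
        )


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: tuple[str, ...]

    def __post_init__(self) -> None:
        if not -1 <= self.es <= 1:
            raise ValidationError("ES outside [-1, 1]")
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


def _hit_positions(l: RankedList, s) -> np.ndarray:
    members = set(s)
    pos = np.array([i for i, g in enumerate(l.genes) if g in members], dtype=int)
    if pos.size == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if pos.size == len(l):
        raise ValidationError("gene set covers the entire list (degenerate)")
    return pos


def _es_batch(pos: np.ndarray, abs_w: np.ndarray, n: int) -> np.ndarray:
    """ES for each row of hit positions (B, k); positions sorted ascending.

    The running sum's extremes occur immediately after a hit or just
    before one, so only 2k candidate deviations per set are examined.
    """
    b, k = pos.shape
    hitw = abs_w[pos]
    cum = np.cumsum(hitw, axis=1)
    nr = cum[:, -1:].copy()
    nr[nr == 0] = 1.0  # all-zero weights: hits contribute nothing
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    up = cum / nr - (pos + 1 - j) * miss
    dn = (cum - hitw) / nr - (pos - (j - 1)) * miss
    dev = np.concatenate([up, dn], axis=1)
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(b), idx]


def running_es(
    l: RankedList, s, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and the full running-sum profile.

    Returns (es, profile) where ``profile[i]`` is the running statistic
    after list position i; ``es`` is the signed maximum deviation.
    """
    pos = _hit_positions(l, s)
    n = len(l)
    scores = np.asarray(l.scores, dtype=float)
    abs_w = np.abs(scores) ** weight
    hit = np.zeros(n, dtype=bool)
    hit[pos] = True
    nr = abs_w[hit].sum()
    steps = np.where(
        hit,
        abs_w / nr if nr > 0 else 0.0,
        -1.0 / (n - pos.size),
    )
    profile = np.cumsum(steps)
    es = float(_es_batch(pos[None, :], abs_w, n)[0])
    return es, profile


def nes_pvalue(
    l: RankedList,
    s,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Permutation-based significance of a gene set's enrichment.

    The null resamples ``n_perm`` random gene sets of the same size from
    the list.  NES is ES divided by the mean |null ES| of the same sign;
    the p-value is the add-one-corrected fraction of null sets with
    |ES_null| >= |ES|.  Fully reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValidationError("need at least 100 permutations")
    pos = _hit_positions(l, s)
    n, k = len(l), pos.size
    scores = np.asarray(l.scores, dtype=float)
    abs_w = np.abs(scores) ** weight
    es = float(_es_batch(pos[None, :], abs_w, n)[0])

    rng = np.random.default_rng(seed)
    null_pos = np.sort(
        np.argsort(rng.random((n_perm, n)), axis=1)[:, :k], axis=1
    )
    null_es = _es_batch(null_pos, abs_w, n)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else float("nan")
    p = (1 + int(np.sum(np.abs(null_es) >= abs(es)))) / (n_perm + 1)

    # leading edge: set members at or before (after, for negative ES) the extreme
    es_row, profile = running_es(l, s, weight)
    extreme = int(np.argmax(np.abs(profile)))
    if es_row >= 0:
        lead = [l.genes[i] for i in pos if i <= extreme]
    else:
        lead = [l.genes[i] for i in pos if i >= extreme]
    return EnrichmentResult(
        es=es,
        nes=float(nes),
        p_value=float(p),
        n_permutations=n_perm,
        leading_edge=tuple(lead),
    )
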