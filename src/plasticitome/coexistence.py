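"""Coexistence and mutual-exclusion statistics for gene pairs.

For a gene pair observed across N samples, the coexistence rate is
(C_PP + C_AA) / N — the fraction of samples where the genes are both
present or both absent — and the APA rate (absent-present +
present-absent) is its exact complement, measuring mutually exclusive
expression.  Presence comes from microarray detection calls, from a TPM
cutoff (present iff TPM >= cutoff), or, in single-cell data, from a
nonzero UMI count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from plasticitome.io_formats import ExpressionMatrix, ValidationError
from plasticitome.virtual_sorting import VirtualSortResult

#: TPM cutoffs conventionally screened side by side for bulk RNA-Seq.
DEFAULT_TPM_CUTOFFS = (1, 2, 3, 4, 5, 10, 20)


@dataclass(frozen=True)
class PairCounts:
    """Present/absent contingency counts for one gene pair."""

    c_pp: int
    c_aa: int
    c_pa: int
    c_ap: int

    @property
    def n(self) -> int:
        return self.c_pp + self.c_aa + self.c_pa + self.c_ap


@dataclass(frozen=True)
class CoexistenceResult:
    pair: tuple[str, str]
    counts: PairCounts
    coexistence_rate: float
    apa_rate: float
    method: str  # calls | tpm-cutoff | sc-umi
    cutoff: float | None = None


def _coexist_from_presence(
    presA: np.ndarray,
    presB: np.ndarray,
    pair: tuple[str, str],
    method: str,
    cutoff: float | None,
) -> CoexistenceResult:
    if presA.shape != presB.shape:
        raise ValidationError("pair vectors differ in length")
    n = presA.size
    if n == 0:
        raise ValidationError("empty pair vectors")
    c_pp = int(np.sum(presA & presB))
    c_aa = int(np.sum(~presA & ~presB))
    c_pa = int(np.sum(presA & ~presB))
    c_ap = int(np.sum(~presA & presB))
    rate = (c_pp + c_aa) / n
    return CoexistenceResult(
        pair=pair,
        counts=PairCounts(c_pp, c_aa, c_pa, c_ap),
        coexistence_rate=rate,
        apa_rate=1.0 - rate,
        method=method,
        cutoff=cutoff,
    )


def coexist_calls(
    callsA: np.ndarray, callsB: np.ndarray, pair: tuple[str, str] = ("A", "B")
) -> CoexistenceResult:
    """Coexistence rate from microarray present/absent detection calls."""
    a = np.asarray(callsA, dtype=object).astype(str)
    b = np.asarray(callsB, dtype=object).astype(str)
    for vec in (a, b):
        bad = set(vec.tolist()) - {"P", "A"}
        if bad:
            raise ValidationError(f"detection calls must be 'P'/'A'; found {sorted(bad)}")
    return _coexist_from_presence(a == "P", b == "P", pair, "calls", None)


def coexist_tpm(
    tpmA: np.ndarray,
    tpmB: np.ndarray,
    cutoff: float,
    pair: tuple[str, str] = ("A", "B"),
) -> CoexistenceResult:
    """Coexistence rate from TPM vectors: present iff TPM >= cutoff."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    a = np.asarray(tpmA, dtype=float)
    b = np.asarray(tpmB, dtype=float)
    return _coexist_from_presence(a >= cutoff, b >= cutoff, pair, "tpm-cutoff", cutoff)


def sc_pp_rate(umiA: np.ndarray, umiB: np.ndarray) -> float:
    """Fraction of cells where both genes have UMI count > 0."""
    a = np.asarray(umiA)
    b = np.asarray(umiB)
    if a.shape != b.shape:
        raise ValidationError("UMI vectors differ in length")
    if a.size == 0:
        raise ValidationError("empty UMI vectors")
    return float(np.mean((a > 0) & (b > 0)))


def expressed_fraction(m: ExpressionMatrix, gene: str) -> float:
    """Proportion of cells with detectable (UMI > 0) expression of *gene*."""
    if m.platform != "sc-umi":
        raise ValidationError("expressed_fraction expects an sc-umi matrix")
    return float(np.mean(m.row(gene) > 0))


@dataclass
class ScEvaluation:
    """Single-cell check of a virtual-sorting result.

    ``pearson`` / ``pp_rate`` map each evaluated gene to its per-cell
    Pearson correlation / present-present rate with the target.  The
    summary reports whether the correlated set dominates the
    anticorrelated set in the medians (the expected direction when bulk
    co-expression structure persists at single-cell level); the rank-sum
    p-values are descriptive.
    """

    target_gene: str
    pearson: dict[str, dict[str, float]]  # class -> gene -> r
    pp_rate: dict[str, dict[str, float]]  # class -> gene -> rate
    dropped: list[str]
    median_pearson: dict[str, float]
    median_pp_rate: dict[str, float]
    pearson_direction_ok: bool
    pp_direction_ok: bool
    pearson_pvalue: float
    pp_pvalue: float


def _sc_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x.astype(float), y.astype(float))[0, 1])


def evaluate_vsort_sc(
    v: VirtualSortResult,
    m: ExpressionMatrix,
    min_expressed_fraction: float = 0.0,
) -> ScEvaluation:
    """Evaluate bulk virtual-sorting gene sets in a single-cell UMI matrix.

    For every correlated and anticorrelated gene present in the matrix,
    compute the per-cell Pearson correlation and PP rate with the target.
    Genes absent from the matrix (or below ``min_expressed_fraction``
    detectable cells) are dropped and reported.  Errors if either class
    is empty after intersection.
    """
    if m.platform != "sc-umi":
        raise ValidationError("single-cell evaluation expects an sc-umi matrix")
    if v.target_gene not in m.gene_ids:
        raise ValidationError(f"target {v.target_gene!r} absent from single-cell matrix")
    target = m.row(v.target_gene)
    dropped: list[str] = []
    pearson: dict[str, dict[str, float]] = {}
    pp: dict[str, dict[str, float]] = {}
    for cls, genes in (("correlated", v.correlated), ("anticorrelated", v.anticorrelated)):
        pearson[cls] = {}
        pp[cls] = {}
        for g in genes:
            if g == v.target_gene or g not in m.gene_ids:
                dropped.append(g)
                continue
            row = m.row(g)
            if np.mean(row > 0) < min_expressed_fraction:
                dropped.append(g)
                continue
            pearson[cls][g] = _sc_pearson(target, row)
            pp[cls][g] = sc_pp_rate(target, row)
        if not pearson[cls]:
            raise ValidationError(f"no {cls} genes measurable in the single-cell matrix")
    med_r = {cls: float(np.nanmedian(list(d.values()))) for cls, d in pearson.items()}
    med_pp = {cls: float(np.median(list(d.values()))) for cls, d in pp.items()}

    def _ranksum(d: dict[str, dict[str, float]]) -> float:
        a = np.array([x for x in d["correlated"].values() if np.isfinite(x)])
        b = np.array([x for x in d["anticorrelated"].values() if np.isfinite(x)])
        if a.size == 0 or b.size == 0:
            return float("nan")
        return float(sps.mannwhitneyu(a, b, alternative="greater").pvalue)

    return ScEvaluation(
        target_gene=v.target_gene,
        pearson=pearson,
        pp_rate=pp,
        dropped=dropped,
        median_pearson=med_r,
        median_pp_rate=med_pp,
        pearson_direction_ok=med_r["correlated"] > med_r["anticorrelated"],
        pp_direction_ok=med_pp["correlated"] > med_pp["anticorrelated"],
        pearson_pvalue=_ranksum(pearson),
        pp_pvalue=_ranksum(pp),
    )
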