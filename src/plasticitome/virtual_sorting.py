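"""Virtual (in-silico) sorting of bulk samples on a highly plastic gene.

Mimicking a FACS gate, the samples are split into a target-high group g1
and a target-low group g2 by exact one-dimensional 2-means clustering of
the target gene's values.  For every other gene the difference of average
rank scores between the groups, delta_i = ARS_i(g1) - ARS_i(g2), measures
how strongly it follows (delta > 0) or opposes (delta < 0) the target.
Candidates are then filtered:

* correlated (cophenotype): delta >= 20 and Pearson r >= 0.5
* anticorrelated (mutually exclusive): delta <= -10, Pearson r < 0 and
  cosine similarity <= 0.1

Pearson captures linear co-expression; the cosine filter captures the
non-linear "never high together" signature that defines mutual exclusion
(two genes that are each expressed only when the other is off have
near-orthogonal expression vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from plasticitome.io_formats import ValidationError
from plasticitome.rank_norm import RankMatrix

#: Minimum absolute GPL score for a gene to be an eligible sorting target.
TARGET_GPL_MIN = 50.0


@dataclass(frozen=True)
class VirtualSortParams:
    """Filter thresholds for virtual sorting.

    ``delta_pos_min``/``delta_neg_max`` bound the group ARS difference for
    correlated / anticorrelated candidates; ``pearson_min_corr`` is the
    minimum linear correlation for correlated genes; anticorrelated genes
    need Pearson strictly below ``pearson_max_anti`` and cosine similarity
    at most ``cosine_max_anti``.
    """

    delta_pos_min: float = 20.0
    delta_neg_max: float = -10.0
    pearson_min_corr: float = 0.5
    pearson_max_anti: float = 0.0
    cosine_max_anti: float = 0.1

    def __post_init__(self) -> None:
        if not self.delta_pos_min > 0 > self.delta_neg_max:
            raise ValueError("need delta_pos_min > 0 > delta_neg_max")
        if not -1 <= self.pearson_min_corr <= 1 or not -1 <= self.pearson_max_anti <= 1:
            raise ValueError("Pearson thresholds must lie in [-1, 1]")
        if not 0 <= self.cosine_max_anti <= 1:
            raise ValueError("cosine threshold must lie in [0, 1]")


@dataclass
class VirtualSortResult:
    """Outcome of virtual sorting for one target gene."""

    target_gene: str
    group_labels: np.ndarray  # per-sample "g1" / "g2"
    delta: dict[str, float]
    pearson: dict[str, float]
    cosine: dict[str, float]
    correlated: list[str]
    anticorrelated: list[str]
    warnings: list[str] = field(default_factory=list)


def kmeans2_split(values: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means partition of the samples on one gene's values.

    The optimal 2-means partition in one dimension is a cut in sorted
    order, so the within-cluster sum of squares is minimized exactly by
    scanning all n-1 cut points — no random initialization is involved.
    Returns per-sample labels; ``g1`` is the higher-mean cluster.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValidationError("need at least two samples to split")
    if np.all(values == values[0]):
        raise ValidationError("gene not plastic in these samples (constant values)")
    if n < 4:
        warnings.warn("fewer than 4 samples: 2-means split is fragile", stacklevel=2)
    order = np.argsort(values, kind="stable")
    s = values[order]
    csum = np.cumsum(s)
    total = csum[-1]
    ks = np.arange(1, n)  # size of the low cluster
    mean_lo = csum[:-1] / ks
    mean_hi = (total - csum[:-1]) / (n - ks)
    csq = np.cumsum(s * s)
    wss = (
        (csq[:-1] - ks * mean_lo**2)
        + ((csq[-1] - csq[:-1]) - (n - ks) * mean_hi**2)
    )
    k_best = int(np.argmin(wss)) + 1  # ties: lowest cut, stable across runs
    labels = np.empty(n, dtype=object)
    labels[order[:k_best]] = "g2"
    labels[order[k_best:]] = "g1"
    return labels.astype(str)


def delta_scores(r: RankMatrix, labels: np.ndarray) -> dict[str, float]:
    """Per-gene delta = ARS(g1) - ARS(g2) for a given sample split."""
    labels = np.asarray(labels)
    if labels.shape != (len(r.sample_ids),):
        raise ValidationError("labels are not aligned to samples")
    g1 = labels == "g1"
    g2 = labels == "g2"
    if not g1.any() or not g2.any():
        raise ValidationError("both groups must be non-empty")
    d = r.values[:, g1].mean(axis=1) - r.values[:, g2].mean(axis=1)
    return dict(zip(r.gene_ids, map(float, d)))


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two non-negative expression vectors.

    1 for parallel vectors, 0 for orthogonal ones.  A zero vector is
    treated as vacuously exclusive (similarity 0, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 and ny == 0:
        raise ValidationError("cosine undefined for two zero vectors")
    if nx == 0 or ny == 0:
        warnings.warn("zero vector in cosine similarity; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), 0.0, 1.0))


def _pearson_rows(target_row: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Pearson r of one row against every row of a matrix (NaN for constants)."""
    t = target_row - target_row.mean()
    v = values - values.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(t)
    vn = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v @ t) / (vn * tn)
    r[vn == 0] = np.nan
    if tn == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def virtual_sort(
    target: str,
    r: RankMatrix,
    params: VirtualSortParams = VirtualSortParams(),
    require_plastic: bool = True,
) -> VirtualSortResult:
    """Virtual sorting of all genes against one highly plastic target.

    Splits the samples on the target's rank values (exact 1-D 2-means),
    computes per-gene delta, Pearson and cosine against the target's rank
    vector, and applies the correlated / anticorrelated filters.  Both
    output lists are sorted by \\|delta\\| descending and exclude the
    target itself.

    With ``require_plastic`` (default), targets whose absolute GPL across
    these samples is below 50 are rejected — only highly plastic genes
    define meaningful high/low gates.
    """
    idx = r.gene_index(target)
    target_row = r.values[idx]
    if require_plastic and (target_row.max() - target_row.min()) < TARGET_GPL_MIN:
        raise ValidationError(
            f"target {target!r} has absolute GPL "
            f"{target_row.max() - target_row.min():.1f} < {TARGET_GPL_MIN}; "
            "not a highly plastic gene in these samples "
            "(pass require_plastic=False to override)"
        )
    notes: list[str] = []
    labels = kmeans2_split(target_row)
    n1 = int((labels == "g1").sum())
    n2 = int((labels == "g2").sum())
    if min(n1, n2) < 2:
        notes.append(f"group sizes ({n1}, {n2}): fewer than 2 samples in a group")

    delta = delta_scores(r, labels)
    pear = _pearson_rows(target_row, r.values)
    tn = np.linalg.norm(target_row)
    vn = np.linalg.norm(r.values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (r.values @ target_row) / (vn * tn)
    cos = np.clip(np.where(vn == 0, 0.0, cos), 0.0, 1.0)

    pearson = dict(zip(r.gene_ids, map(float, pear)))
    cosine = dict(zip(r.gene_ids, map(float, cos)))

    correlated, anticorrelated = [], []
    for gene in r.gene_ids:
        if gene == target:
            continue
        d, p, c = delta[gene], pearson[gene], cosine[gene]
        if d >= params.delta_pos_min and p >= params.pearson_min_corr:
            correlated.append(gene)
        elif (
            d <= params.delta_neg_max
            and p < params.pearson_max_anti  # NaN (constant gene) never passes
            and c <= params.cosine_max_anti
        ):
            anticorrelated.append(gene)
    key = lambda g: -abs(delta[g])
    return VirtualSortResult(
        target_gene=target,
        group_labels=labels,
        delta=delta,
        pearson=pearson,
        cosine=cosine,
        correlated=sorted(correlated, key=key),
        anticorrelated=sorted(anticorrelated, key=key),
        warnings=notes,
    )
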