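"""Synthetic bulk, single-cell and phenotype-corpus data with planted truth.

The generator emulates the structure the plasticity pipeline is designed
to detect in real immune transcriptomes:

* housekeeping genes expressed highly in every sample (lowly plastic),
* silent genes essentially never expressed,
* driver genes that switch on/off across samples (highly plastic), each
  carrying a block of correlated genes (high exactly when the driver is
  on) and a block of anticorrelated genes (high exactly when the driver
  is off — the mutually exclusive partners),
* independent noise genes with stable intermediate expression.

One latent on/off state per driver per sample drives both the
array-signal matrix (log-normal noise, present/absent calls from a noise
floor) and the RNA-Seq count matrix (negative-binomial counts with
length-weighted means), so cross-platform operations can be tested
against a single truth.  Single-cell UMI matrices reuse the same gene
blocks with per-cell latent states, shallower counts and Bernoulli
dropout — reproducing the heavy zero-inflation of real droplet data.

Everything is driven by one seed: identical configuration and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from plasticitome.io_formats import AliasMap, ExpressionMatrix, ValidationError
from plasticitome.plasticity import GeneStats, MergedStats


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``effect_size`` is the fold separation between a block gene's on and
    off states; it is large by default because the driver/marker genes
    being emulated (cytokines, activation antigens) swing from silence to
    strong expression.  ``noise_sd`` is the standard deviation of
    log-normal expression noise on the natural-log scale.
    ``nb_dispersion`` is the negative-binomial dispersion alpha in
    var = m + alpha * m^2.  ``dropout_rate`` is the per-molecule Bernoulli
    thinning probability applied to single-cell counts.
    """

    seed: int
    n_samples: int = 60
    n_cells: int = 400
    housekeeping_high: int = 30
    silent: int = 30
    drivers: int = 5
    correlated_per_driver: int = 20
    anticorrelated_per_driver: int = 20
    noise: int = 50
    driver_on_fraction: float = 0.5
    effect_size: float = 1000.0
    noise_sd: float = 0.25
    nb_dispersion: float = 0.1
    dropout_rate: float = 0.3
    # expression scale (arbitrary TPM-like units)
    high_mean: float = 200.0
    housekeeping_mean: float = 100.0
    silent_mean: float = 0.05
    # corpus parameters
    n_markers: int = 171
    n_plastic_markers: int = 159
    n_phenotypes: int = 300
    unit_count_probs: tuple[float, ...] = (0.35, 0.28, 0.20, 0.10, 0.05, 0.02)
    alias_fraction: float = 0.3

    def __post_init__(self) -> None:
        sizes = (
            self.n_samples,
            self.n_cells,
            self.housekeeping_high,
            self.silent,
            self.drivers,
            self.correlated_per_driver,
            self.anticorrelated_per_driver,
            self.noise,
        )
        if any(s < 0 for s in sizes):
            raise ValidationError("gene-class sizes and counts must be non-negative")
        if self.n_samples < 2:
            raise ValidationError("need at least two samples")
        if not 0 < self.driver_on_fraction < 1:
            raise ValidationError("driver_on_fraction must lie in (0, 1)")
        if self.effect_size <= 1:
            raise ValidationError("effect_size must exceed 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.noise_sd < 0:
            raise ValidationError("dispersion and noise_sd must be non-negative")
        if self.n_plastic_markers > self.n_markers:
            raise ValidationError("n_plastic_markers cannot exceed n_markers")
        if abs(sum(self.unit_count_probs) - 1) > 1e-9:
            raise ValidationError("unit_count_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted structure behind a synthetic dataset."""

    gene_class: dict[str, str]  # gene -> housekeeping|silent|driver|correlated|anticorrelated|noise
    driver_members: dict[str, dict[str, list[str]]]
    sample_states: pd.DataFrame  # drivers x samples, bool (driver on?)
    gene_table: pd.DataFrame  # gene, klass, driver, mean_on, mean_off
    cell_states: pd.DataFrame | None = None

    def members(self, driver: str, which: str) -> list[str]:
        return list(self.driver_members[driver][which])


def _gene_universe(c: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    low_mean = c.high_mean / c.effect_size
    for i in range(c.housekeeping_high):
        rows.append((f"HK{i + 1:03d}", "housekeeping", "", c.housekeeping_mean, c.housekeeping_mean))
    for i in range(c.silent):
        rows.append((f"SIL{i + 1:03d}", "silent", "", c.silent_mean, c.silent_mean))
    for d in range(1, c.drivers + 1):
        drv = f"DRV{d}"
        rows.append((drv, "driver", drv, c.high_mean, low_mean))
        for i in range(c.correlated_per_driver):
            rows.append((f"{drv}C{i + 1:02d}", "correlated", drv, c.high_mean, low_mean))
        for i in range(c.anticorrelated_per_driver):
            # anticorrelated: high when the driver is OFF
            rows.append((f"{drv}A{i + 1:02d}", "anticorrelated", drv, low_mean, c.high_mean))
    baselines = np.exp(rng.uniform(np.log(1.0), np.log(60.0), size=c.noise))
    for i in range(c.noise):
        rows.append((f"NOI{i + 1:03d}", "noise", "", baselines[i], baselines[i]))
    return pd.DataFrame(rows, columns=["gene", "klass", "driver", "mean_on", "mean_off"])


def _state_means(table: pd.DataFrame, states: pd.DataFrame) -> np.ndarray:
    """Expected expression (genes x samples) given per-sample driver states."""
    n_genes = len(table)
    n_samples = states.shape[1]
    means = np.empty((n_genes, n_samples))
    for i, row in enumerate(table.itertuples()):
        if row.driver:
            on = states.loc[row.driver].to_numpy()
            means[i] = np.where(on, row.mean_on, row.mean_off)
        else:
            means[i] = row.mean_on
    return means


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_bulk(
    c: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, int], SyntheticTruth]:
    """Generate matched array-signal and RNA-Seq count matrices.

    Returns (array matrix with detection calls, count matrix, gene
    lengths, truth).  Each driver's per-sample latent state is
    Bernoulli(``driver_on_fraction``).  A driver whose drawn states are
    all identical (possible when the on-fraction is extreme) is simply
    not plastic in that dataset — by design, no variation is injected.
    """
    rng = np.random.default_rng(c.seed)
    table = _gene_universe(c, rng)
    genes = table["gene"].tolist()
    samples = [f"S{j + 1:03d}" for j in range(c.n_samples)]
    drivers = [f"DRV{d}" for d in range(1, c.drivers + 1)]

    states = pd.DataFrame(
        rng.random((len(drivers), c.n_samples)) < c.driver_on_fraction,
        index=drivers,
        columns=samples,
    )

    means = _state_means(table, states)

    # microarray: log-normal multiplicative noise; calls from a noise floor
    noise_floor = 1.0
    signals = means * np.exp(rng.normal(0.0, c.noise_sd, size=means.shape))
    calls = np.where(signals > noise_floor, "P", "A")
    array_m = ExpressionMatrix(
        values=signals,
        gene_ids=genes,
        sample_ids=samples,
        platform="array-signal",
        calls=calls,
    )

    # RNA-Seq: counts NB-distributed around length-weighted means
    lengths = {
        g: int(length)
        for g, length in zip(genes, rng.integers(1000, 3001, len(genes)))
    }
    len_arr = np.array([lengths[g] for g in genes], dtype=float)
    count_means = means * np.exp(rng.normal(0.0, c.noise_sd, size=means.shape))
    count_means = count_means * (len_arr[:, None] / len_arr.mean())
    counts = _nb_counts(rng, count_means, c.nb_dispersion)
    rnaseq_m = ExpressionMatrix(
        values=counts, gene_ids=genes, sample_ids=samples, platform="rnaseq-count"
    )

    members = {
        drv: {
            "correlated": table.loc[
                (table["driver"] == drv) & (table["klass"] == "correlated"), "gene"
            ].tolist(),
            "anticorrelated": table.loc[
                (table["driver"] == drv) & (table["klass"] == "anticorrelated"), "gene"
            ].tolist(),
        }
        for drv in drivers
    }
    truth = SyntheticTruth(
        gene_class=dict(zip(table["gene"], table["klass"])),
        driver_members=members,
        sample_states=states,
        gene_table=table,
    )
    return array_m, rnaseq_m, lengths, truth


def generate_singlecell(
    c: SyntheticConfig,
    truth: SyntheticTruth,
    total_counts_per_cell: float = 4000.0,
) -> ExpressionMatrix:
    """Generate a single-cell UMI matrix sharing the bulk gene blocks.

    Each cell draws its own on/off state per driver, expected expression
    follows the bulk profile of that state scaled to ``total_counts_per_cell``,
    UMI counts are negative-binomial and then thinned by independent
    Bernoulli dropout.  The per-cell states are recorded on the truth
    object.
    """
    # independent stream so single-cell data do not perturb bulk draws
    rng = np.random.default_rng((c.seed, 17))
    table = truth.gene_table
    genes = table["gene"].tolist()
    cells = [f"C{j + 1:04d}" for j in range(c.n_cells)]
    drivers = list(truth.sample_states.index)
    cell_states = pd.DataFrame(
        rng.random((len(drivers), c.n_cells)) < c.driver_on_fraction,
        index=drivers,
        columns=cells,
    )
    means = _state_means(table, cell_states)
    scale = total_counts_per_cell / means.sum(axis=0, keepdims=True)
    umis = _nb_counts(rng, means * scale, c.nb_dispersion)
    if c.dropout_rate > 0:
        umis = rng.binomial(umis, 1.0 - c.dropout_rate)
    truth.cell_states = cell_states
    return ExpressionMatrix(
        values=umis, gene_ids=genes, sample_ids=cells, platform="sc-umi"
    )


@dataclass
class MarkerCorpus:
    """Synthetic immunophenotype corpus with planted plasticity truth."""

    phenotypes: list[str]
    markers: list[str]
    plastic_markers: list[str]
    merged_stats: list[MergedStats]
    aliases: AliasMap
    expected_fraction: float


def _marker_stats(
    gene: str, gpl_array: float, gpl_rnaseq: float, n_samples: int = 100
) -> MergedStats:
    def one(gpl: float, platform: str) -> GeneStats:
        lo = (100.0 - gpl) / 2.0
        hi = lo + gpl
        mid = (lo + hi) / 2.0
        return GeneStats(
            gene_id=gene,
            ars=mid,
            q1=mid,
            q3=mid,
            gpl_iqr=0.0,
            gpl_abs=gpl,
            rank_min=lo,
            rank_max=hi,
            n_samples=n_samples,
            platform=platform,
        )

    return MergedStats(gene_id=gene, array=one(gpl_array, "array-signal"), rnaseq=one(gpl_rnaseq, "rnaseq-count"))


def generate_marker_corpus(c: SyntheticConfig) -> MarkerCorpus:
    """Generate phenotype strings over a planted marker universe.

    ``n_plastic_markers`` of the ``n_markers`` markers get an absolute
    GPL score >= 50 on at least one platform; the rest stay below 50 on
    both.  Unit counts per phenotype follow ``unit_count_probs`` and a
    fraction of marker mentions are written using aliases (``xMK..``
    forms) to exercise normalization.
    """
    rng = np.random.default_rng((c.seed, 29))
    markers = [f"MK{i + 1:03d}" for i in range(c.n_markers)]
    plastic = list(rng.choice(markers, size=c.n_plastic_markers, replace=False))
    plastic_set = set(plastic)

    stats: list[MergedStats] = []
    for g in markers:
        if g in plastic_set:
            high = float(rng.uniform(55, 100))
            other = float(rng.uniform(0, 100))
            gpls = (high, other) if rng.random() < 0.5 else (other, high)
        else:
            gpls = (float(rng.uniform(0, 45)), float(rng.uniform(0, 45)))
        stats.append(_marker_stats(g, *gpls))

    aliases = AliasMap({f"x{g}": g for g in markers})

    tags_graded = ("hi", "lo", "int", "bright", "dim")
    phenotypes: list[str] = []
    sizes = rng.choice(
        np.arange(1, len(c.unit_count_probs) + 1),
        size=c.n_phenotypes,
        p=np.asarray(c.unit_count_probs),
    )
    for size in sizes:
        chosen = rng.choice(markers, size=min(int(size), len(markers)), replace=False)
        units = []
        for g in chosen:
            name = f"x{g}" if rng.random() < c.alias_fraction else g
            roll = rng.random()
            tag = "+" if roll < 0.6 else ("-" if roll < 0.85 else str(rng.choice(tags_graded)))
            units.append(f"{name}{tag}")
        phenotypes.append("".join(units))

    return MarkerCorpus(
        phenotypes=phenotypes,
        markers=markers,
        plastic_markers=sorted(plastic),
        merged_stats=stats,
        aliases=aliases,
        expected_fraction=c.n_plastic_markers / c.n_markers,
    )


def with_seed(c: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of the configuration with a different seed."""
    return replace(c, seed=seed)
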