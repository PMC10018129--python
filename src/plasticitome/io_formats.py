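"""Readers and writers for expression tables, sparse single-cell matrices,
alias tables and gene statistics, plus probe-set collapse to gene level.

All delimited files are TSV by default; ``.csv`` extensions switch the
delimiter.  Every reader/writer pair is a lossless round trip on valid
input (values to the written precision, identifiers exactly).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

PLATFORMS = ("array-signal", "rnaseq-count", "rnaseq-tpm", "sc-umi")
_INTEGER_PLATFORMS = ("rnaseq-count", "sc-umi")


class ValidationError(ValueError):
    """Input violates a structural invariant (shape, sign, uniqueness)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a platform tag.

    Parameters
    ----------
    values
        Non-negative matrix of shape ``(n_genes, n_samples)``.  Count
        platforms (``rnaseq-count``, ``sc-umi``) must hold integers.
    gene_ids, sample_ids
        Unique row / column identifiers.
    platform
        One of ``array-signal``, ``rnaseq-count``, ``rnaseq-tpm``, ``sc-umi``.
    calls
        Optional present/absent detection-call matrix over ``{"P", "A"}``
        with the same shape and axes as ``values``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    platform: str
    calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.platform in _INTEGER_PLATFORMS and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValidationError(f"platform {self.platform} requires integer values")
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=object).astype(str)
            if self.calls.shape != self.values.shape:
                raise ValidationError("calls matrix shape differs from values")
            bad = set(np.unique(self.calls)) - {"P", "A"}
            if bad:
                raise ValidationError(f"calls must be 'P' or 'A'; found {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


class AliasMap(Mapping):
    """Case-insensitive alias -> standard gene symbol lookup.

    Standard symbols always resolve to themselves, so ``resolve`` is
    idempotent: ``resolve(resolve(x)) == resolve(x)``.
    """

    def __init__(self, pairs: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, symbol in (pairs or {}).items():
            self.add(alias, symbol)

    def add(self, alias: str, symbol: str) -> None:
        key = alias.strip().lower()
        symbol = symbol.strip()
        if not key or not symbol:
            raise ValidationError("empty alias or symbol")
        existing = self._map.get(key)
        if existing is not None and existing != symbol:
            raise ValidationError(
                f"alias {alias!r} maps to both {existing!r} and {symbol!r}"
            )
        self._map[key] = symbol
        # standard symbols are their own aliases
        self._map.setdefault(symbol.lower(), symbol)

    def resolve(self, marker: str) -> str | None:
        """Standard symbol for *marker*, or None if unknown."""
        return self._map.get(marker.strip().lower())

    def __getitem__(self, alias: str) -> str:
        symbol = self.resolve(alias)
        if symbol is None:
            raise KeyError(alias)
        return symbol

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_table(
    path: str | Path,
    platform: str,
    orientation: str = "genes-in-rows",
    calls_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The first column (or row, for ``samples-in-rows``) holds identifiers.
    Non-numeric cells, negative values and duplicate identifiers raise
    :class:`ValidationError` naming the offending entry.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if orientation == "samples-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # pandas mangles duplicate header columns to 'S1.1'; detect via raw header
    _check_unique_header(path, orientation)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        bad = _first_non_numeric(df)
        raise ValidationError(
            f"non-numeric value {bad[2]!r} at gene {bad[0]!r}, sample {bad[1]!r}"
        ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    calls = None
    if calls_path is not None:
        cdf = pd.read_csv(calls_path, sep=_sep_for(calls_path), index_col=0, comment="#")
        cdf.index = cdf.index.astype(str)
        if list(cdf.index) != list(df.index) or list(map(str, cdf.columns)) != list(
            df.columns
        ):
            raise ValidationError("calls table axes do not match expression table")
        calls = cdf.to_numpy()
    return ExpressionMatrix(
        values=values,
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        platform=platform,
        calls=calls,
    )


def _check_unique_header(path: str | Path, orientation: str) -> None:
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
        if orientation == "samples-in-rows":
            header = [line.split(sep)[0] for line in fh if line.strip()]
    if len(set(header)) != len(header):
        raise ValidationError(f"duplicate identifiers in header: {_duplicates(header)}")


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str, str]:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return str(df.index[i]), str(col), str(df.iloc[i, j])
    return "?", "?", "?"


def write_table(path: str | Path, m: ExpressionMatrix, float_format: str = "%.6g") -> None:
    """Write the expression values as a delimited table (genes in rows)."""
    m.to_frame().to_csv(path, sep=_sep_for(path), float_format=float_format)


def write_calls(path: str | Path, m: ExpressionMatrix) -> None:
    if m.calls is None:
        raise ValueError("matrix carries no detection calls")
    pd.DataFrame(m.calls, index=m.gene_ids, columns=m.sample_ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MarketMatrix triple (matrix + gene list + cell barcodes).

    Genes are rows, cells columns, platform ``sc-umi``; zero entries are
    implicit in the sparse file.
    """
    mat = spio.mmread(str(matrix_path))
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes "
            f"and {len(barcodes)} barcodes"
        )
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    return ExpressionMatrix(
        values=dense, gene_ids=genes, sample_ids=barcodes, platform="sc-umi"
    )


def write_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    m: ExpressionMatrix,
) -> None:
    if m.platform != "sc-umi":
        raise ValueError("write_mtx expects an sc-umi matrix")
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(m.values.astype(int)))
    _write_lines(genes_path, m.gene_ids)
    _write_lines(barcodes_path, m.sample_ids)


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_lines(path: str | Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


def collapse_probesets(
    m: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-set rows to one row per gene.

    When a gene has multiple probe sets, the probe with the largest mean
    value across samples represents the gene in every sample; ties are
    broken by the lexicographically smallest probe id.  Detection calls,
    when present, follow the retained probe.
    """
    missing = [p for p in m.gene_ids if p not in probe_to_gene]
    if missing:
        raise ValidationError(f"probes absent from probe->gene map: {missing}")
    means = m.values.mean(axis=1)
    best: dict[str, int] = {}  # gene -> row index of winning probe
    for i, probe in enumerate(m.gene_ids):
        gene = probe_to_gene[probe]
        j = best.get(gene)
        if (
            j is None
            or means[i] > means[j]
            or (means[i] == means[j] and probe < m.gene_ids[j])
        ):
            best[gene] = i
    genes = sorted(best)
    rows = [best[g] for g in genes]
    return ExpressionMatrix(
        values=m.values[rows],
        gene_ids=genes,
        sample_ids=list(m.sample_ids),
        platform=m.platform,
        calls=m.calls[rows] if m.calls is not None else None,
    )


def read_alias_table(path: str | Path) -> AliasMap:
    """Read a two-column (alias, symbol) TSV into an :class:`AliasMap`.

    Alias keys are lower-cased on load; an alias mapped to two different
    symbols raises :class:`ValidationError`.
    """
    amap = AliasMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t" if "\t" in line else ",")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns")
            amap.add(parts[0], parts[1])
    return amap


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read a gene -> length (bp) TSV; lengths must be >= 1."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene, raw = line.split("\t" if "\t" in line else ",")[:2]
            length = int(float(raw))
            if length < 1:
                raise ValidationError(f"{path}:{lineno}: length must be >= 1")
            lengths[gene] = length
    return lengths


def write_gene_lengths(path: str | Path, lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlength\n")
        for gene, length in lengths.items():
            fh.write(f"{gene}\t{int(length)}\n")


GENE_STATS_COLUMNS = (
    "gene",
    "ars",
    "q1",
    "q3",
    "gpl_iqr",
    "gpl_abs",
    "rank_min",
    "rank_max",
    "n_samples",
    "platform",
)


def write_gene_stats(path: str | Path, stats) -> None:
    """Write per-gene plasticity statistics as TSV (6-decimal fidelity)."""
    rows = [
        (
            s.gene_id,
            s.ars,
            s.q1,
            s.q3,
            s.gpl_iqr,
            s.gpl_abs,
            s.rank_min,
            s.rank_max,
            s.n_samples,
            s.platform,
        )
        for s in stats
    ]
    pd.DataFrame(rows, columns=GENE_STATS_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.6f"
    )


def read_gene_stats(path: str | Path):
    from plasticitome.plasticity import GeneStats

    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return [
        GeneStats(
            gene_id=str(r.gene),
            ars=float(r.ars),
            q1=float(r.q1),
            q3=float(r.q3),
            gpl_iqr=float(r.gpl_iqr),
            gpl_abs=float(r.gpl_abs),
            rank_min=float(r.rank_min),
            rank_max=float(r.rank_max),
            n_samples=int(r.n_samples),
            platform=str(r.platform),
        )
        for r in df.itertuples()
    ]
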