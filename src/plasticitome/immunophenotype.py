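"""Grammar and combinatorics of immunophenotype strings.

An immunophenotype such as ``CD4+FOXP3+CD25hi`` is an ordered list of
phenotypic units, each a marker (gene symbol or alias, e.g. ``CD25``)
followed by an expression tag (``+``, ``-``, ``hi``, ``lo``, ``int``,
``bright``, ``dim``, ``mid``, ``medium``, ``high``).  The module parses
such strings, mines candidates from free text, standardizes marker
aliases to gene symbols, deduplicates phenotypes irrespective of unit
order, splits a parent phenotype into its layer-k children (all k-unit
combinations), enumerates the 2^n on/off states of a gene combination and
scores plasticity support of a phenotype's member genes.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from plasticitome.io_formats import AliasMap, ValidationError
from plasticitome.plasticity import MergedStats

#: Closed tag vocabulary, matched longest-first during parsing.
TAGS: tuple[str, ...] = (
    "bright",
    "medium",
    "high",
    "dim",
    "int",
    "mid",
    "hi",
    "lo",
    "+",
    "-",
)

_MARKER_CHARS = re.compile(r"[A-Za-z0-9\-]")

#: Default text-mining patterns: the classic sign-near-cell pattern plus a
#: variant that recognizes graded expression labels (lo/hi/bright/...).
DEFAULT_EXTRACTION_PATTERNS: tuple[str, ...] = (
    r".{0,20}[+\-−].{0,12}[TB].{0,12}cell",
    r".{0,20}(?:bright|medium|high|dim|int|mid|hi|lo).{0,12}[TB].{0,12}cell",
)


class PhenotypeParseError(ValueError):
    """The string is not a valid concatenation of marker+tag units."""


@dataclass(frozen=True)
class PhenotypicUnit:
    """One marker with its expression tag."""

    marker: str
    tag: str

    def __post_init__(self) -> None:
        if not self.marker:
            raise ValidationError("empty marker in phenotypic unit")
        tag = _canonical_tag(self.tag)
        object.__setattr__(self, "tag", tag)
        if tag not in TAGS:
            raise ValidationError(f"unknown expression tag {self.tag!r}")

    def __str__(self) -> str:
        return f"{self.marker}{self.tag}"


def _canonical_tag(tag: str) -> str:
    tag = tag.replace("−", "-").strip().lower()
    return tag


@dataclass(frozen=True)
class Immunophenotype:
    """An ordered combination of phenotypic units.

    Exact duplicate units are merged at construction; two units naming the
    same marker with different tags are contradictory and rejected.  The
    ``canonical_key`` is the unit set sorted by (marker, tag), so two
    phenotypes that list the same units in different order compare equal
    by key.
    """

    units: tuple[PhenotypicUnit, ...]
    unmapped: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.units:
            raise ValidationError("immunophenotype needs at least one unit")
        seen: dict[str, str] = {}
        deduped: list[PhenotypicUnit] = []
        for u in self.units:
            prior = seen.get(u.marker)
            if prior is None:
                seen[u.marker] = u.tag
                deduped.append(u)
            elif prior != u.tag:
                raise ValidationError(
                    f"marker {u.marker!r} carries conflicting tags "
                    f"{prior!r} and {u.tag!r}"
                )
        object.__setattr__(self, "units", tuple(deduped))

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(u.marker for u in self.units)

    @property
    def n_layers(self) -> int:
        return len(self.units)

    @property
    def canonical_key(self) -> str:
        return "".join(str(u) for u in sorted(self.units, key=lambda u: (u.marker, u.tag)))

    def serialize(self) -> str:
        return "".join(str(u) for u in self.units)

    def __str__(self) -> str:
        return self.serialize()


def _preprocess(s: str) -> str:
    # normalize Unicode minus and superscript markup before parsing
    s = s.replace("−", "-").replace("^", "")
    return "".join(s.split())


def parse_phenotype(s: str, known_markers=None) -> Immunophenotype:
    """Parse a phenotype string into its ordered phenotypic units.

    Parsing is total-or-fail: every character must belong to a
    marker+tag unit.  Tags bind at the earliest position where the
    remainder still parses, and longer tags beat their prefixes, so
    ``CD25hi`` splits as ``CD25``+``hi`` (``5hi`` is no tag) and
    ``CD4highCD8A+`` takes ``high`` rather than ``hi``.

    Some tokens are ambiguous — the hyphen is the negative tag but also
    occurs inside marker names (``HLA-DRA``).  By default a hyphen ends
    the marker (``CD4-CD8A+`` reads as CD4- then CD8A+); pass a
    ``known_markers`` collection (for example the alias-table keys) to
    let recognized compounds win: with ``{"HLA-DRA"}`` the string
    ``HLA-DRA+`` parses as a single unit.
    """
    text = _preprocess(s)
    if not text:
        raise PhenotypeParseError("empty phenotype string")
    known = {m.lower() for m in known_markers} if known_markers is not None else set()

    n = len(text)
    lower = text.lower()

    def candidate_ends(pos: int, run: int):
        # known markers win (longest first); otherwise the shortest marker
        # followed by a tag, so tags bind at the earliest opportunity and
        # cannot be swallowed into a longer marker token
        ends = list(range(run, pos, -1))
        if known:
            yield from (e for e in ends if lower[pos:e] in known)
        yield from (e for e in reversed(ends) if lower[pos:e] not in known)

    @lru_cache(maxsize=None)
    def parse_from(pos: int) -> tuple[PhenotypicUnit, ...] | None:
        if pos == n:
            return ()
        run = pos
        while run < n and _MARKER_CHARS.match(text[run]):
            run += 1
        for end in candidate_ends(pos, run):
            marker = text[pos:end]
            for tag in TAGS:
                if lower.startswith(tag, end):
                    rest = parse_from(end + len(tag))
                    if rest is not None:
                        return (PhenotypicUnit(marker, tag),) + rest
        return None

    units = parse_from(0)
    if units is None:
        # deepest suffix that still parses locates the failure point
        fail_at = 0
        for pos in range(n, -1, -1):
            if parse_from(pos) is not None:
                fail_at = pos
                break
        raise PhenotypeParseError(
            f"cannot parse {s!r}: no marker+tag decomposition covering "
            f"offset {fail_at} (is a tag missing after the last marker?)"
        )
    return Immunophenotype(units=units)


def extract_candidates(
    text: str, patterns: tuple[str, ...] = DEFAULT_EXTRACTION_PATTERNS
) -> list[tuple[str, int]]:
    """Mine candidate immunophenotype mentions from plain text.

    Returns (matched substring, character offset) for every pattern hit;
    no deduplication is applied at this stage.  Both the ASCII hyphen and
    the Unicode minus count as negative signs.
    """
    out: list[tuple[str, int]] = []
    for pat in patterns:
        for m in re.finditer(pat, text, flags=re.IGNORECASE):
            out.append((m.group(0), m.start()))
    return out


def normalize(p: Immunophenotype, aliases: AliasMap) -> Immunophenotype:
    """Replace marker aliases by standard gene symbols.

    Unresolvable markers are kept verbatim and listed in the result's
    ``unmapped`` field (the phenotype is flagged, not rejected).  Two
    units that map to the same symbol merge when their tags agree and
    raise :class:`ValidationError` when they conflict.  The operation is
    idempotent because standard symbols resolve to themselves.
    """
    units: list[PhenotypicUnit] = []
    unmapped: list[str] = []
    for u in p.units:
        symbol = aliases.resolve(u.marker)
        if symbol is None:
            unmapped.append(u.marker)
            symbol = u.marker
        units.append(PhenotypicUnit(symbol, u.tag))
    return Immunophenotype(units=tuple(units), unmapped=tuple(dict.fromkeys(unmapped)))


def split_layers(p: Immunophenotype, k: int) -> list[Immunophenotype]:
    """All nonredundant k-unit child phenotypes of a parent.

    Children are the C(n, k) unit subsets, deduplicated by canonical key
    irrespective of unit order; k = n returns the phenotype itself and
    k = 1 the individual phenotypic units.
    """
    if not 1 <= k <= p.n_layers:
        raise ValidationError(f"k={k} outside [1, {p.n_layers}]")
    seen: set[str] = set()
    out: list[Immunophenotype] = []
    for combo in itertools.combinations(p.units, k):
        child = Immunophenotype(units=combo)
        if child.canonical_key not in seen:
            seen.add(child.canonical_key)
            out.append(child)
    return out


def enumerate_states(genes: list[str]) -> list[Immunophenotype]:
    """All 2^n on/off immunophenotypes of an n-gene combination.

    Each highly plastic gene contributes two functional states (high ``+``
    and low/no ``-``), so n genes span 2^n candidate immunophenotypes.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("need at least one gene")
    if len(set(genes)) != len(genes):
        raise ValidationError("gene symbols must be distinct")
    out = []
    for signs in itertools.product("+-", repeat=len(genes)):
        out.append(
            Immunophenotype(
                units=tuple(PhenotypicUnit(g, s) for g, s in zip(genes, signs))
            )
        )
    return out


def layer_support(
    p: Immunophenotype,
    stats: list[MergedStats],
    cutoff: float = 50.0,
    mode: str = "either",
) -> tuple[bool, dict[str, tuple[float, float] | None]]:
    """Is a phenotype supported by gene plasticity?

    True iff every member gene's absolute GPL meets *cutoff* on either
    (or, with ``mode="both"``, on both) platform(s).  Genes missing from
    the merged statistics map to ``None`` and make the phenotype
    unsupported.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    by_gene = {m.gene_id: m for m in stats}
    gpls: dict[str, tuple[float, float] | None] = {}
    supported = True
    for marker in p.markers:
        m = by_gene.get(marker)
        if m is None:
            gpls[marker] = None
            supported = False
            continue
        gpls[marker] = (m.array.gpl_abs, m.rnaseq.gpl_abs)
        ok_a = m.array.gpl_abs >= cutoff
        ok_r = m.rnaseq.gpl_abs >= cutoff
        if not ((ok_a or ok_r) if mode == "either" else (ok_a and ok_r)):
            supported = False
    return supported, gpls


def corpus_stats(phenotypes: list[Immunophenotype]) -> dict:
    """Corpus-level summaries of a normalized phenotype collection.

    Returns the unit-count histogram, the nonredundant marker set, the
    number of nonredundant phenotypes (by canonical key) and the global
    counts of unique 2- and 3-layer child combinations.
    """
    unique: dict[str, Immunophenotype] = {}
    for p in phenotypes:
        unique.setdefault(p.canonical_key, p)
    hist = Counter(p.n_layers for p in unique.values())
    markers = sorted({m for p in unique.values() for m in p.markers})
    combos: dict[int, int] = {}
    for k in (2, 3):
        keys: set[str] = set()
        for p in unique.values():
            if p.n_layers >= k:
                keys.update(c.canonical_key for c in split_layers(p, k))
        combos[k] = len(keys)
    return {
        "n_phenotypes": len(phenotypes),
        "n_nonredundant": len(unique),
        "unit_count_hist": dict(sorted(hist.items())),
        "markers": markers,
        "n_markers": len(markers),
        "layer_combinations": combos,
    }
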