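import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasticitome.io_formats import AliasMap, ValidationError
from plasticitome.immunophenotype import (
    Immunophenotype,
    PhenotypeParseError,
    PhenotypicUnit,
    corpus_stats,
    enumerate_states,
    extract_candidates,
    layer_support,
    normalize,
    parse_phenotype,
    split_layers,
)
from plasticitome.synthetic_data import _marker_stats

markers = st.sampled_from(
    ["CD4", "CD8A", "FOXP3", "CCR7", "ITGA6", "IL2RA", "PTPRC", "NKG7"]
)
tags = st.sampled_from(["+", "-", "hi", "lo", "int", "bright", "dim"])


@st.composite
def phenotypes(draw):
    chosen = draw(st.lists(markers, min_size=1, max_size=5, unique=True))
    return Immunophenotype(
        units=tuple(PhenotypicUnit(m, draw(tags)) for m in chosen)
    )


class TestParse:
    def test_treg_phenotype_three_units(self):
        p = parse_phenotype("CD4+FOXP3+CD25hi")
        assert [(u.marker, u.tag) for u in p.units] == [
            ("CD4", "+"),
            ("FOXP3", "+"),
            ("CD25", "hi"),
        ]

    def test_memory_subset_with_negative_sign(self):
        p = parse_phenotype("CD45RA+CCR7-")
        assert [(u.marker, u.tag) for u in p.units] == [
            ("CD45RA", "+"),
            ("CCR7", "-"),
        ]

    def test_unicode_minus_and_superscript_markup(self):
        assert parse_phenotype("CD45RA^+^CCR7^−^") == parse_phenotype("CD45RA+CCR7-")

    def test_tag_binds_right_greedily(self):
        # CD25hi is CD25 + hi, never CD2 + "5hi"
        p = parse_phenotype("CD25hi")
        assert p.units == (PhenotypicUnit("CD25", "hi"),)

    def test_hyphen_defaults_to_negative_tag(self):
        p = parse_phenotype("CD4-CD8A+")
        assert [(u.marker, u.tag) for u in p.units] == [("CD4", "-"), ("CD8A", "+")]

    def test_known_hyphenated_marker_wins(self):
        p = parse_phenotype("HLA-DRA+", known_markers={"HLA-DRA"})
        assert p.units == (PhenotypicUnit("HLA-DRA", "+"),)
        # without the lexicon the hyphen reads as a negative tag
        p2 = parse_phenotype("HLA-DRA+")
        assert [(u.marker, u.tag) for u in p2.units] == [("HLA", "-"), ("DRA", "+")]

    @pytest.mark.parametrize(
        "tag", ["hi", "lo", "int", "bright", "dim", "mid", "medium", "high"]
    )
    def test_graded_tag_vocabulary(self, tag):
        p = parse_phenotype(f"CD27{tag}")
        assert p.units == (PhenotypicUnit("CD27", tag),)

    def test_missing_tag_is_an_error(self):
        with pytest.raises(PhenotypeParseError):
            parse_phenotype("CD4")

    def test_empty_string_is_an_error(self):
        with pytest.raises(PhenotypeParseError):
            parse_phenotype("  ")

    @given(phenotypes())
    def test_parse_of_serialize_is_identity(self, p):
        assert parse_phenotype(p.serialize()).units == p.units


class TestCanonicalForm:
    def test_order_independent_key(self):
        a = parse_phenotype("CD4+CD25hi")
        b = parse_phenotype("CD25hiCD4+")
        assert a.canonical_key == b.canonical_key

    def test_conflicting_tags_rejected(self):
        with pytest.raises(ValidationError, match="conflicting"):
            parse_phenotype("CD4+CD4-")

    def test_exact_duplicate_units_merge(self):
        p = Immunophenotype(
            units=(PhenotypicUnit("CD4", "+"), PhenotypicUnit("CD4", "+"))
        )
        assert p.n_layers == 1


class TestNormalize:
    @pytest.fixture()
    def aliases(self):
        return AliasMap({"CD26": "DPP4", "CD49f": "ITGA6", "CD25": "IL2RA"})

    def test_alias_conversion(self, aliases):
        p = normalize(parse_phenotype("CD26+CD49f-"), aliases)
        assert p.serialize() == "DPP4+ITGA6-"
        assert p.unmapped == ()

    def test_idempotence(self, aliases):
        p1 = normalize(parse_phenotype("CD26+CD49f-"), aliases)
        p2 = normalize(p1, aliases)
        assert p1.units == p2.units

    def test_alias_collision_with_conflicting_tags(self, aliases):
        with pytest.raises(ValidationError, match="conflicting"):
            normalize(parse_phenotype("CD26+DPP4-"), aliases)

    def test_alias_collision_with_identical_tags_merges(self, aliases):
        p = normalize(parse_phenotype("CD26+DPP4+"), aliases)
        assert p.serialize() == "DPP4+"

    def test_unresolvable_marker_flagged_not_fatal(self, aliases):
        p = normalize(parse_phenotype("XYZW+CD26+"), aliases)
        assert p.unmapped == ("XYZW",)
        assert p.serialize() == "XYZW+DPP4+"


class TestSplitLayers:
    def test_treg_two_layer_children(self):
        p = parse_phenotype("CD4+FOXP3+CD25hi")
        children = {c.serialize() for c in split_layers(p, 2)}
        assert children == {"CD4+FOXP3+", "FOXP3+CD25hi", "CD4+CD25hi"}

    def test_k_equals_n_is_identity(self):
        p = parse_phenotype("CD4+CD8A-")
        assert split_layers(p, 2) == [p]

    def test_k_equals_one_gives_units(self):
        p = parse_phenotype("CD4+FOXP3+CD25hi")
        assert [c.serialize() for c in split_layers(p, 1)] == [
            "CD4+",
            "FOXP3+",
            "CD25hi",
        ]

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            split_layers(parse_phenotype("CD4+"), 2)

    @given(phenotypes(), st.integers(1, 5))
    def test_child_count_is_binomial(self, p, k):
        if k > p.n_layers:
            return
        assert len(split_layers(p, k)) == math.comb(p.n_layers, k)


class TestEnumerateStates:
    @pytest.mark.parametrize("n,expected", [(1, 2), (2, 4), (3, 8)])
    def test_counts_are_powers_of_two(self, n, expected):
        genes = [f"G{i}" for i in range(n)]
        states = enumerate_states(genes)
        assert len(states) == expected
        assert len({s.canonical_key for s in states}) == expected

    def test_single_gene_high_and_low(self):
        states = {s.serialize() for s in enumerate_states(["ITGA6"])}
        assert states == {"ITGA6+", "ITGA6-"}

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_states(["CD4", "CD4"])


class TestLayerSupport:
    def _stats(self):
        return [
            _marker_stats("CD4", 80, 90),
            _marker_stats("FOXP3", 95, 60),
            _marker_stats("IL2RA", 30, 20),
        ]

    def test_all_plastic_supported(self):
        ok, gpls = layer_support(parse_phenotype("CD4+FOXP3+"), self._stats())
        assert ok and gpls["CD4"] == (80, 90)

    def test_one_low_gene_unsupported(self):
        ok, _ = layer_support(parse_phenotype("CD4+IL2RAhi"), self._stats())
        assert not ok

    def test_missing_gene_unsupported_with_none(self):
        ok, gpls = layer_support(parse_phenotype("CD4+TCF7+"), self._stats())
        assert not ok and gpls["TCF7"] is None

    def test_zero_cutoff_always_supported(self):
        ok, _ = layer_support(parse_phenotype("CD4+IL2RA-"), self._stats(), cutoff=0)
        assert ok


class TestExtraction:
    def test_signed_phenotype_near_t_cell(self):
        text = "Sorted CD45RA+CCR7- T cells were analyzed by flow cytometry."
        hits = extract_candidates(text)
        assert any("CD45RA+CCR7-" in h for h, _ in hits)

    def test_graded_label_near_b_cell(self):
        hits = extract_candidates("We gated on CD25hi B cells for sorting.")
        assert any("CD25hi" in h for h, _ in hits)

    def test_no_match_gives_empty_list(self):
        assert extract_candidates("No immunology here at all.") == []

    def test_offsets_point_at_matches(self):
        text = "xx CD4+ T cell yy"
        for match, offset in extract_candidates(text):
            assert text[offset : offset + len(match)] == match


class TestCorpusStats:
    def test_order_variants_deduplicate(self):
        corpus = [parse_phenotype("CD4+CD8A+"), parse_phenotype("CD8A+CD4+")]
        stats = corpus_stats(corpus)
        assert stats["n_nonredundant"] == 1
        assert stats["n_markers"] == 2

    def test_three_unit_phenotype_combinations(self):
        stats = corpus_stats([parse_phenotype("CD4+FOXP3+CD25hi")])
        assert stats["layer_combinations"] == {2: 3, 3: 1}

    def test_empty_corpus(self):
        stats = corpus_stats([])
        assert stats["n_nonredundant"] == 0
        assert stats["markers"] == []
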