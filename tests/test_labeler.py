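"""The rule cascade: chain overrides, name keywords, owner labels."""

import pytest

from takeaway_cuisine.labeler import (
    EXCLUDED,
    IGNORED,
    CuisineScheme,
    assign_cuisine,
    collapse_scheme,
    default_scheme,
    detect_name_keywords,
    load_scheme,
    map_owner_label,
    six_point_collapse_map,
)
from takeaway_cuisine.records import UNCLASSIFIED, LabeledOutlet, OutletRecord
from takeaway_cuisine.synth import generate_corpus, separable_config


def rec(name, *labels):
    return OutletRecord(name=name, labels=tuple(labels))


@pytest.fixture(scope="module")
def scheme():
    return default_scheme()


class TestOwnerLabelMap:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("chinese", "southeast_east_asian"),
            ("thai", "southeast_east_asian"),
            ("indian", "south_asian"),
            ("halal", IGNORED),
            ("russian", EXCLUDED),
            ("tapas", EXCLUDED),
            ("Chinese ", "southeast_east_asian"),  # normalised before lookup
        ],
    )
    def test_named_labels(self, scheme, label, expected):
        assert map_owner_label(label, scheme) == expected

    def test_unknown_label_excluded_with_warning(self, scheme, caplog):
        with caplog.at_level("WARNING"):
            assert map_owner_label("martian", scheme) == EXCLUDED
        assert "martian" in caplog.text


class TestNameKeywords:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("tom's pizza and chicken shack", {"pizza", "chicken"}),
            ("tom's house", set()),
            ("kebabish", set()),          # whole-word rule
            ("best kebab house", {"kebab"}),
            ("burger-zone", {"burger"}),  # hyphen is a word boundary
        ],
    )
    def test_whole_word_matching(self, scheme, name, expected):
        assert detect_name_keywords(name, scheme) == expected

    def test_substring_mode_is_a_config_switch(self):
        scheme = CuisineScheme(keyword_whole_word=False)
        assert detect_name_keywords("kebabish", scheme) == {"kebab"}


class TestAssignCuisine:
    """The five published worked examples of the rule cascade."""

    @pytest.mark.parametrize(
        "record, expected, provenance",
        [
            (rec("Tom's House", "Burger", "Healthy"), "burger", "owner_label"),
            (rec("Tom's Grill", "Chicken", "Burger"), "chicken", "owner_label"),
            (rec("Tom's Kebab House", "South Asian", "Pizza"), "kebab", "single_keyword"),
            (rec("Tom's Pizza and Chicken Shack", "Burger", "Kebab"),
             "multi_fast_food", "multi_keyword"),
            (rec("McDonald's"), "burger", "chain"),
        ],
    )
    def test_worked_examples(self, scheme, record, expected, provenance):
        result = assign_cuisine(record, scheme)
        assert result.cuisine == expected
        assert result.provenance == provenance

    @pytest.mark.parametrize(
        "chain, expected",
        [("kfc", "chicken"), ("pizza hut", "pizza"), ("domino's", "pizza"),
         ("subway", "sandwich_cafe_bakery"), ("greggs", "sandwich_cafe_bakery"),
         ("burger king", "burger"), ("papa john's", "pizza")],
    )
    def test_chain_overrides(self, scheme, chain, expected):
        assert assign_cuisine(rec(chain), scheme).cuisine == expected

    def test_chain_takes_priority_over_keywords(self, scheme):
        # "burger king" contains the burger keyword, but the chain rule fires
        result = assign_cuisine(rec("burger king"), scheme)
        assert result.provenance == "chain"

    def test_ignored_label_falls_through_to_next(self, scheme):
        assert assign_cuisine(rec("tom's house", "halal", "thai"), scheme).cuisine == \
            "southeast_east_asian"

    def test_no_mappable_information_is_unclassified(self, scheme):
        result = assign_cuisine(rec("tom's house", "martian"), scheme)
        assert result.cuisine == UNCLASSIFIED
        assert result.provenance is None

    def test_deterministic_and_record_independent(self, scheme):
        records = [rec("tom's kebab house"), rec("golden wok", "chinese")]
        individually = [assign_cuisine(r, scheme).cuisine for r in records]
        reversed_order = [assign_cuisine(r, scheme).cuisine for r in reversed(records)]
        assert individually == list(reversed(reversed_order))

    def test_owner_label_path_recovers_truth_without_noise(self):
        corpus = generate_corpus(separable_config(seed=13, n_per_class=40))
        scheme = default_scheme()
        for record, truth in zip(corpus.records, corpus.truth):
            result = assign_cuisine(record, scheme)
            assert result.cuisine == truth
            assert result.provenance == "owner_label"


class TestCollapse:
    def test_six_point_merges_fast_food(self):
        scheme = default_scheme(six_point=True)
        for cls in ("chicken", "pizza", "kebab", "burger", "multi_fast_food"):
            labeled = LabeledOutlet(rec("x"), cls, "owner_label")
            assert collapse_scheme(labeled, scheme).cuisine == "multi_fast_food"

    def test_non_fast_food_classes_fixed(self):
        scheme = default_scheme(six_point=True)
        labeled = LabeledOutlet(rec("x"), "desserts", "owner_label")
        assert collapse_scheme(labeled, scheme).cuisine == "desserts"

    def test_unclassified_unchanged(self):
        scheme = default_scheme(six_point=True)
        labeled = LabeledOutlet(rec("x"))
        assert collapse_scheme(labeled, scheme).cuisine == UNCLASSIFIED

    def test_missing_collapse_map_is_an_error(self, scheme):
        labeled = LabeledOutlet(rec("x"), "desserts", "owner_label")
        with pytest.raises(ValueError):
            collapse_scheme(labeled, scheme)

    def test_collapse_map_is_total(self):
        cmap = six_point_collapse_map()
        assert set(cmap) == set(default_scheme().classes)
        assert len(set(cmap.values())) == 6


class TestSchemeConfig:
    def test_invalid_keyword_target_rejected(self):
        with pytest.raises(ValueError):
            CuisineScheme(name_keywords={"sushi": "not_a_class"})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scheme.yaml"
        path.write_text(
            "owner_label_map:\n"
            "  noodles: southeast_east_asian\n"
            "  pop-up: excluded\n"
            "  organic: ignored\n"
            "chain_map:\n"
            "  wimpy: burger\n"
        )
        scheme = load_scheme(path)
        assert map_owner_label("noodles", scheme) == "southeast_east_asian"
        assert map_owner_label("pop-up", scheme) == EXCLUDED
        assert map_owner_label("organic", scheme) == IGNORED
        assert assign_cuisine(rec("wimpy"), scheme).cuisine == "burger"
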