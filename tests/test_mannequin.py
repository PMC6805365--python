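"""Mannequin classification against an independent attribute oracle."""

import itertools

import numpy as np
import pytest

from lbptriage.mannequin import (
    BodyRegion,
    BodyRegionMap,
    PainStatus,
    classify_mannequin,
    default_region_map,
    has_lbp_region,
    is_widespread,
    load_region_map,
)


def oracle_widespread(regions, region_map):
    """Brute-force re-derivation: check the five attribute requirements
    one by one from the raw region attributes."""
    attrs = {r.id: (r.axial, r.side, r.body_half) for r in region_map.regions}
    marked = [attrs[r] for r in regions]
    checks = [
        any(a for a, _, _ in marked),
        any(s == "left" for _, s, _ in marked),
        any(s == "right" for _, s, _ in marked),
        any(h == "upper" for _, _, h in marked),
        any(h == "lower" for _, _, h in marked),
    ]
    return all(checks)


class TestIsWidespread:
    @pytest.mark.parametrize(
        "regions, expected",
        [
            (frozenset(), False),
            (frozenset({"lower_back"}), False),
            (frozenset({"lower_back", "shoulder_l", "knee_r"}), True),
        ],
    )
    def test_examples(self, region_map, regions, expected):
        assert is_widespread(regions, region_map) is expected

    def test_all_regions_widespread(self, region_map):
        assert is_widespread(frozenset(region_map.ids), region_map)

    def test_unknown_region_is_configuration_error(self, region_map):
        with pytest.raises(ValueError, match="unknown region"):
            is_widespread({"chest"}, region_map)

    def test_exhaustive_agreement_with_oracle_on_reduced_map(self, reduced_map):
        for k in range(len(reduced_map) + 1):
            for subset in itertools.combinations(reduced_map.ids, k):
                subset = frozenset(subset)
                assert is_widespread(subset, reduced_map) == oracle_widespread(
                    subset, reduced_map
                )

    def test_random_subset_agreement_with_oracle_on_full_map(self, region_map):
        rng = np.random.default_rng(42)
        ids = list(region_map.ids)
        for _ in range(10_000):
            k = int(rng.integers(0, 19))
            subset = frozenset(rng.choice(ids, size=k, replace=False))
            assert is_widespread(subset, region_map) == oracle_widespread(
                subset, region_map
            )

    def test_adding_a_region_never_revokes_widespreadness(self, region_map):
        rng = np.random.default_rng(7)
        ids = list(region_map.ids)
        for _ in range(500):
            k = int(rng.integers(0, 18))
            subset = frozenset(rng.choice(ids, size=k, replace=False))
            if is_widespread(subset, region_map):
                extra = rng.choice([i for i in ids if i not in subset])
                assert is_widespread(subset | {extra}, region_map)


class TestClassify:
    def test_no_chronic_pain_is_ncp(self, region_map):
        result = classify_mannequin(False, {"lower_back"}, region_map)
        assert result.status is PainStatus.NCP
        assert not result.ms_cwp and result.region_count == 1

    def test_chronic_regional(self, region_map):
        result = classify_mannequin(True, {"lower_back"}, region_map)
        assert result.status is PainStatus.CRP
        assert (result.region_count, result.multisite, result.ms_cwp) == (1, False, False)

    def test_cwp_with_seven_regions_is_ms_cwp(self, region_map):
        regions = {
            "lower_back", "upper_back", "shoulder_l", "shoulder_r",
            "knee_l", "knee_r", "hip_l",
        }
        result = classify_mannequin(True, regions, region_map)
        assert result.status is PainStatus.CWP
        assert (result.region_count, result.multisite, result.ms_cwp) == (7, True, True)

    def test_cwp_without_multisite(self, region_map):
        result = classify_mannequin(True, {"lower_back", "shoulder_l", "knee_r"}, region_map)
        assert result.status is PainStatus.CWP
        assert (result.multisite, result.ms_cwp) == (False, False)

    def test_missing_chronicity_is_instrument_missing(self, region_map):
        assert classify_mannequin(None, {"lower_back"}, region_map) is None

    def test_chronic_with_empty_regions_warns_and_classifies_crp(self, region_map):
        with pytest.warns(UserWarning, match="no regions"):
            result = classify_mannequin(True, frozenset(), region_map)
        assert result.status is PainStatus.CRP

    def test_classification_exhaustive_and_exclusive(self, reduced_map):
        for chronic in (True, False):
            for k in range(len(reduced_map) + 1):
                for subset in itertools.combinations(reduced_map.ids, k):
                    result = classify_mannequin(bool(chronic), frozenset(subset), reduced_map)
                    assert result.status in (PainStatus.NCP, PainStatus.CRP, PainStatus.CWP)
                    if not chronic:
                        assert result.status is PainStatus.NCP and not result.ms_cwp
                    assert result.ms_cwp == (
                        result.status is PainStatus.CWP and result.region_count >= 7
                    )

    def test_adding_region_never_downgrades_status(self, region_map):
        rng = np.random.default_rng(3)
        ids = list(region_map.ids)
        for _ in range(300):
            k = int(rng.integers(0, 18))
            subset = frozenset(rng.choice(ids, size=k, replace=False))
            base = classify_mannequin(True, subset, region_map)
            extra = rng.choice([i for i in ids if i not in subset])
            grown = classify_mannequin(True, subset | {extra}, region_map)
            assert grown.region_count == base.region_count + 1
            assert not (
                base.status is PainStatus.CWP and grown.status is PainStatus.CRP
            )


class TestRegionMap:
    def test_default_map_shape(self, region_map):
        assert len(region_map) == 18
        axial = [r for r in region_map.regions if r.axial]
        assert len(axial) == 4
        assert all(r.side == "midline" for r in axial)
        assert sum(r.side == "left" for r in region_map.regions) == 7
        assert sum(r.side == "right" for r in region_map.regions) == 7

    def test_map_requires_all_attributes_present(self):
        with pytest.raises(ValueError, match="axial"):
            BodyRegionMap(
                (
                    BodyRegion("a", False, "left", "upper"),
                    BodyRegion("b", False, "right", "lower"),
                )
            )

    def test_load_custom_map_from_yaml(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text(
            "regions:\n"
            "  - {id: spine, axial: true, side: midline, body_half: lower}\n"
            "  - {id: arm_l, axial: false, side: left, body_half: upper}\n"
            "  - {id: arm_r, axial: false, side: right, body_half: upper}\n"
        )
        custom = load_region_map(path)
        assert is_widespread({"spine", "arm_l", "arm_r"}, custom)

    def test_has_lbp_region(self, region_map):
        assert has_lbp_region({"lower_back"}, region_map)
        assert not has_lbp_region(frozenset(), region_map)
        assert has_lbp_region(frozenset(region_map.ids), region_map)

    def test_default_map_loads_identically_from_package_data(self, region_map):
        assert default_region_map() == region_map
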