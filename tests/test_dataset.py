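"""Unit conversions, harmonization, inclusion filters, specimen aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleobrain import dataset as ds
from paleobrain.dataset import (
    apply_filters,
    brain_mass_to_volume,
    brain_volume_to_endocast,
    harmonize,
    match_to_tree,
    specimen_to_species,
)


def make_records(**overrides) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "species": ["a", "b", "c"],
            "order": ["O1"] * 3,
            "body_mass_kg": [10.0, 20.0, 30.0],
            "endocast_volume_cm3": [100.0, np.nan, np.nan],
            "brain_mass_g": [90.0, 51.8, np.nan],
            "status": ["extant", "extant", "extinct"],
            "same_specimen": [True, True, True],
            "landmass_km2": [np.nan] * 3,
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base


class TestConversions:
    def test_density_unit_case(self):
        assert brain_mass_to_volume(1.036) == pytest.approx(1.0)

    def test_density_division(self):
        assert brain_mass_to_volume(518.0) == pytest.approx(500.0)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_mass_rejected(self, bad):
        with pytest.raises(ValueError):
            brain_mass_to_volume(bad)
        with pytest.raises(ValueError):
            brain_volume_to_endocast(bad)

    def test_endocast_calibration_values(self):
        assert brain_volume_to_endocast(1.0) == pytest.approx(
            10 ** (-0.0015), rel=1e-12
        )
        assert brain_volume_to_endocast(1000.0) == pytest.approx(
            10 ** (-0.0015 + 1.0222 * 3), rel=1e-12
        )

    @given(
        v1=st.floats(1e-3, 1e5),
        factor=st.floats(1.0001, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_composition_strictly_increasing_and_invertible(self, v1, factor):
        v2 = v1 * factor
        e1 = brain_volume_to_endocast(brain_mass_to_volume(v1))
        e2 = brain_volume_to_endocast(brain_mass_to_volume(v2))
        assert e2 > e1
        # invert analytically
        back = 10 ** ((np.log10(e1) - ds.ENDOCAST_INTERCEPT) / ds.ENDOCAST_SLOPE)
        assert back * ds.BRAIN_DENSITY == pytest.approx(v1, rel=1e-9)


class TestHarmonize:
    def test_endocast_preferred_over_brain_mass(self):
        out = harmonize(make_records())
        assert out.loc[out["species"] == "a", "endocast_volume_cm3"].item() == 100.0

    def test_brain_mass_composed_conversion(self):
        out = harmonize(make_records())
        expect = brain_volume_to_endocast(brain_mass_to_volume(51.8))
        assert out.loc[out["species"] == "b", "endocast_volume_cm3"].item() == (
            pytest.approx(expect)
        )

    def test_record_without_measurement_reported_and_dropped(self):
        out = harmonize(make_records())
        assert "c" not in set(out["species"])
        assert out.attrs["rejected"] == ["c"]

    def test_log_columns_populated(self):
        out = harmonize(make_records())
        np.testing.assert_allclose(
            out["log10_body"], np.log10(out["body_mass_kg"])
        )

    def test_empty_input(self):
        out = harmonize(make_records().iloc[:0])
        assert len(out) == 0

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(make_records(species=["a", "a", "b"]))

    def test_never_alters_existing_endocast(self):
        df = make_records(
            endocast_volume_cm3=[5.0, 6.0, 7.0], brain_mass_g=[1.0, 2.0, 3.0]
        )
        out = harmonize(df)
        np.testing.assert_allclose(out["endocast_volume_cm3"], [5.0, 6.0, 7.0])


class TestFilters:
    def test_body_mass_boundary_inclusive(self):
        df = harmonize(
            make_records(body_mass_kg=[1.3, 1.4, 10.0], brain_mass_g=[9.0] * 3)
        )
        out = apply_filters(df)
        assert set(out["species"]) == {"b", "c"}
        assert out.attrs["exclusions"]["body_mass"] == 1

    def test_landmass_strictly_greater(self):
        df = harmonize(
            make_records(
                landmass_km2=[40_000.0, 50_000.0, 60_000.0],
                brain_mass_g=[9.0, 9.0, 9.0],
            )
        )
        out = apply_filters(df)
        # 40,000 and exactly 50,000 are excluded ('larger than' is strict)
        assert set(out["species"]) == {"c"}
        assert out.attrs["exclusions"]["landmass"] == 2

    def test_idempotent_and_identity_when_all_pass(self):
        df = harmonize(make_records())
        once = apply_filters(df)
        twice = apply_filters(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestSpecimenAggregation:
    def test_geometric_mean_on_log_scale(self):
        rows = pd.DataFrame(
            {
                "species": ["x"] * 3,
                "endocast_volume_cm3": [10.0, 100.0, 1000.0],
                "body_mass_kg": [1.0, 1.0, 1.0],
                "status": ["extant"] * 3,
                "order": ["O"] * 3,
            }
        )
        out = specimen_to_species(rows)
        assert out["endocast_volume_cm3"].item() == pytest.approx(100.0)

    def test_arithmetic_option(self):
        rows = pd.DataFrame(
            {
                "species": ["x"] * 2,
                "endocast_volume_cm3": [10.0, 1000.0],
                "status": ["extant"] * 2,
            }
        )
        out = specimen_to_species(rows, agg="arithmetic")
        assert out["endocast_volume_cm3"].item() == pytest.approx(505.0)

    def test_single_specimen_passthrough_and_median_count(self):
        rows = pd.DataFrame(
            {
                "species": ["x", "y", "y", "y"],
                "endocast_volume_cm3": [7.0, 1.0, 10.0, 100.0],
                "status": ["extant"] * 4,
            }
        )
        out = specimen_to_species(rows)
        assert out.loc[out["species"] == "x", "endocast_volume_cm3"].item() == 7.0
        assert out.attrs["median_specimens"] == 2.0
        assert out.attrs["specimen_counts"] == {"x": 1, "y": 3}


class TestTreeMatching:
    def test_normalization(self):
        df = make_records(species=["Equus ferus", "BOS_taurus", "weird sp"])
        matched, unmatched = match_to_tree(
            df, ["Equus_ferus", "bos_taurus", "Other_sp"]
        )
        assert list(matched["species"]) == ["Equus_ferus", "bos_taurus"]
        assert unmatched == ["weird sp"]

    def test_hard_fail_option(self):
        df = make_records()
        with pytest.raises(KeyError):
            match_to_tree(df, ["a"], on_unmatched="error")
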