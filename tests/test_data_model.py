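"""Record validation, CSV round-trips, and the deterministic derived
quantities (GSI, length-weight biomass, transect summaries)."""

import textwrap

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefdemo.data_model import (
    ConfigurationError,
    FishRecord,
    LengthWeightCoefficients,
    RowValidationError,
    SchemaError,
    Stage,
    TransectRecord,
    Treatment,
    compute_gsi,
    length_to_weight,
    read_fish_table,
    read_island_table,
    read_transect_table,
    transect_summaries,
    write_fish_table,
    write_island_table,
    write_transect_table,
)
from reefdemo.synthetic_data import SyntheticConfig, simulate_fish, simulate_islands, simulate_transects

FISH_HEADER = (
    "fish_id,island_id,atoll_id,treatment,total_length_cm,wet_weight_kg,"
    "age_yr,stage,gonad_weight_g,percent_N,d15N,collection_day"
)


def _write(tmp_path, body, name="fish.csv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(body).strip() + "\n")
    return p


class TestFishReader:
    def test_well_formed_rows_read_back_as_records(self, tmp_path):
        path = _write(
            tmp_path,
            f"""\
            {FISH_HEADER}
            f1,I1,A1,rat_free,20.0,0.2,3,spawning_capable_female,1.5,13.2,10.4,3
            f2,I1,A1,rat_free,22.5,0.25,4,Spawning_Capable_Female,2.0,13.5,10.6,3
            f3,I2,A1,rat_infested,18.0,0.15,2,regenerating_female,,,,
            """,
        )
        records = read_fish_table(path)
        assert len(records) == 3
        assert records[0].treatment is Treatment.RAT_FREE
        assert records[1].stage is Stage.SPAWNING_CAPABLE_FEMALE  # case-insensitive
        assert records[2].gonad_weight is None and records[2].gsi is None

    def test_age_zero_rejected_with_row_number(self, tmp_path):
        path = _write(
            tmp_path,
            f"""\
            {FISH_HEADER}
            f1,I1,A1,rat_free,20.0,0.2,0,spawning_capable_female,1.5,,,
            """,
        )
        with pytest.raises(RowValidationError, match=r"row 1.*>= 1"):
            read_fish_table(path)

    def test_missing_required_column_names_it(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            fish_id,island_id,atoll_id,treatment,total_length_cm,age_yr,stage
            f1,I1,A1,rat_free,20.0,3,immature
            """,
        )
        with pytest.raises(SchemaError, match="wet_weight_kg"):
            read_fish_table(path)

    def test_non_numeric_length_is_row_error(self, tmp_path):
        path = _write(
            tmp_path,
            f"""\
            {FISH_HEADER}
            f1,I1,A1,rat_free,big,0.2,3,immature,,,,
            """,
        )
        with pytest.raises(RowValidationError, match="row 1"):
            read_fish_table(path)

    def test_treatment_must_be_constant_within_island(self, tmp_path):
        path = _write(
            tmp_path,
            f"""\
            {FISH_HEADER}
            f1,I1,A1,rat_free,20.0,0.2,3,immature,,,,
            f2,I1,A1,rat_infested,21.0,0.2,3,immature,,,,
            """,
        )
        with pytest.raises(RowValidationError, match="island I1"):
            read_fish_table(path)


class TestRoundTrips:
    def test_fish_round_trip(self, tmp_path):
        records = simulate_fish(SyntheticConfig(seed=5))
        path = tmp_path / "fish.csv"
        write_fish_table(records, path)
        assert read_fish_table(path) == records

    def test_transect_round_trip_keeps_empty_transects(self, tmp_path):
        records = simulate_transects(SyntheticConfig(seed=5))
        assert any(not r.observations for r in records)  # true zeros present
        path = tmp_path / "tr.csv"
        write_transect_table(records, path)
        assert read_transect_table(path) == records

    def test_island_round_trip(self, tmp_path):
        records = simulate_islands(SyntheticConfig(seed=5))
        path = tmp_path / "isl.csv"
        write_island_table(records, path)
        back = read_island_table(path)
        assert [r.island_id for r in back] == [r.island_id for r in records]
        for a, b in zip(back, records):
            assert a.covariates == pytest.approx(dict(b.covariates))


class TestGSI:
    @pytest.mark.parametrize(
        "gonad_g, body_kg, expected",
        [(1.2, 0.120, 1.0), (0.0, 0.2, 0.0), (1.5, 0.39, 0.3846)],
    )
    def test_known_values(self, gonad_g, body_kg, expected):
        assert compute_gsi(gonad_g, body_kg) == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_body_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_gsi(1.0, 0.0)

    @given(
        gonad=st.floats(0.0, 50.0),
        body=st.floats(0.05, 5.0),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, gonad, body, c):
        base = compute_gsi(gonad, body)
        scaled = compute_gsi(gonad * c, body * c)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestLengthWeight:
    @pytest.mark.parametrize(
        "a, b, L, expected",
        [(0.01, 3.0, 20.0, 80.0), (0.01, 3.0, 0.0, 0.0), (1.0, 1.0, 5.0, 5.0)],
    )
    def test_power_law(self, a, b, L, expected):
        assert length_to_weight(L, LengthWeightCoefficients(a, b)) == pytest.approx(expected)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            length_to_weight(-1.0, LengthWeightCoefficients(0.01, 3.0))

    def test_nonpositive_coefficients_rejected(self):
        with pytest.raises(ValueError):
            LengthWeightCoefficients(0.0, 3.0)


def _transect(tid, obs, treatment=Treatment.RAT_FREE):
    return TransectRecord(
        island_id="I1", atoll_id="A1", treatment=treatment,
        transect_id=tid, area=150.0, observations=tuple(obs),
    )


class TestTransectSummaries:
    COEFFS = {"parrot": LengthWeightCoefficients(0.01, 3.0)}

    def test_empty_transect_yields_zero_row(self):
        out = transect_summaries([_transect("t1", [])], self.COEFFS)
        row = out.iloc[0]
        assert (row["count"], row["density_per_m2"], row["biomass_g"]) == (0, 0.0, 0.0)

    def test_single_fish_composition(self):
        out = transect_summaries([_transect("t1", [("parrot", 20.0)])], self.COEFFS)
        row = out.iloc[0]
        assert row["count"] == 1
        assert row["density_per_m2"] == pytest.approx(1 / 150)
        assert row["biomass_g"] == pytest.approx(80.0)

    def test_identical_transects_identical_rows(self):
        obs = [("parrot", 12.0), ("parrot", 19.5)]
        out = transect_summaries([_transect("t1", obs), _transect("t2", obs)], self.COEFFS)
        a, b = out.iloc[0], out.iloc[1]
        assert a["biomass_g"] == b["biomass_g"] and a["count"] == b["count"]

    def test_missing_coefficients_named(self):
        with pytest.raises(ConfigurationError, match="grouper"):
            transect_summaries([_transect("t1", [("grouper", 30.0)])], self.COEFFS)

    @given(
        lengths=st.lists(st.floats(8.0, 60.0), max_size=12),
        split=st.integers(0, 12),
    )
    def test_biomass_additive_over_observations(self, lengths, split):
        split = min(split, len(lengths))
        obs = [("parrot", L) for L in lengths]
        total = transect_summaries([_transect("t", obs)], self.COEFFS)["biomass_g"][0]
        part1 = transect_summaries([_transect("t", obs[:split])], self.COEFFS)["biomass_g"][0]
        part2 = transect_summaries([_transect("t", obs[split:])], self.COEFFS)["biomass_g"][0]
        assert total == pytest.approx(part1 + part2, rel=1e-9, abs=1e-9)


def test_fish_record_validation_boundaries():
    base = dict(
        fish_id="f", island_id="i", atoll_id="a",
        treatment=Treatment.RAT_FREE, total_length=20.0, wet_weight=0.2,
        age=3, stage=Stage.IMMATURE,
    )
    FishRecord(**base).validate()
    with pytest.raises(RowValidationError):
        FishRecord(**{**base, "total_length": 80.0}).validate()
    with pytest.raises(RowValidationError):
        FishRecord(**{**base, "age": 0}).validate()
    with pytest.raises(RowValidationError):
        FishRecord(**{**base, "gonad_weight": -1.0}).validate()


def test_survey_cutoff_enforced():
    t = _transect("t1", [("parrot", 6.0)])
    with pytest.raises(RowValidationError, match="8.0 cm"):
        t.validate()
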