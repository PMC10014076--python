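"""Reading, transforming, assembling and summarizing event data."""

import numpy as np
import pandas as pd
import pytest

from glycocap import flow_data as fd
from glycocap.exceptions import (
    DomainError,
    DuplicationError,
    FormatError,
    LinkageError,
    SchemaError,
    UnsupportedVersionError,
)
from conftest import write_fcs


class TestReadFCS:
    def test_round_trip_events_and_channels(self, tmp_path):
        events = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        path = tmp_path / "t.fcs"
        write_fcs(path, ["BL1-A", "SSC-A"], events)
        table = fd.read_fcs(path)
        assert table.n_events == 3
        assert table.channels == ["BL1-A", "SSC-A"]
        np.testing.assert_allclose(table.events, events, rtol=1e-6)
        assert table.metadata["$MODE"] == "L"

    def test_declared_event_count_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "bad.fcs"
        write_fcs(path, ["GFP"], np.ones((3, 1)), tot_override=5)
        with pytest.raises(FormatError, match="byte offset"):
            fd.read_fcs(path)

    def test_truncated_data_segment_is_format_error(self, tmp_path):
        path = tmp_path / "trunc.fcs"
        write_fcs(path, ["GFP"], np.ones((4, 1)), truncate_data=4)
        with pytest.raises(FormatError):
            fd.read_fcs(path)

    def test_unsupported_version_rejected(self, tmp_path):
        path = tmp_path / "v2.fcs"
        write_fcs(path, ["GFP"], np.ones((2, 1)), version=b"FCS2.0")
        with pytest.raises(UnsupportedVersionError):
            fd.read_fcs(path)

    def test_fcs31_accepted(self, tmp_path):
        path = tmp_path / "v31.fcs"
        write_fcs(path, ["GFP"], np.arange(4.0).reshape(4, 1), version=b"FCS3.1")
        assert fd.read_fcs(path).n_events == 4

    def test_log_amplified_parameter_delogged(self, tmp_path):
        # $PnE = "4,1" over range 1024: stored x maps to 10^(4x/1024)
        path = tmp_path / "log.fcs"
        write_fcs(path, ["FL1"], np.array([[256.0], [512.0]]),
                  extra_keywords={"$P1E": "4,1", "$P1R": "1024"})
        table = fd.read_fcs(path)
        np.testing.assert_allclose(table.events[:, 0], [10.0, 100.0], rtol=1e-5)


class TestReadEventsCSV:
    def test_reads_rows(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("GFP\n10\n20\n30\n")
        t = fd.read_events_csv(p, ["GFP"])
        assert t.n_events == 3
        np.testing.assert_allclose(t.channel("GFP"), [10, 20, 30])

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("FSC\n1\n")
        with pytest.raises(SchemaError, match="GFP"):
            fd.read_events_csv(p, ["GFP"])

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("GFP\n10\nNA\n30\n")
        with pytest.raises(SchemaError, match="row 1"):
            fd.read_events_csv(p, ["GFP"])

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.lognormal(5, 1, size=200)
        p = tmp_path / "rt.csv"
        pd.DataFrame({"GFP-A": values}).to_csv(p, index=False)
        back = fd.read_events_csv(p, ["GFP-A"]).channel("GFP-A")
        np.testing.assert_allclose(back, values, rtol=1e-12)


class TestTransformIntensity:
    def test_log10_floor_on_positive_values(self):
        out = fd.transform_intensity([10, 100, 1000], "log10_floor")
        np.testing.assert_allclose(out, [1, 2, 3])

    def test_floor_rule_uses_half_smallest_positive(self):
        out = fd.transform_intensity([0, 10], "log10_floor")
        np.testing.assert_allclose(out, [np.log10(5), 1.0])

    def test_all_nonpositive_is_degenerate(self):
        with pytest.raises(DomainError):
            fd.transform_intensity([0, -1], "log10_floor")

    def test_arcsinh_zero_maps_to_zero(self):
        np.testing.assert_allclose(
            fd.transform_intensity([0.0], "arcsinh", cofactor=150), [0.0]
        )

    def test_identity_is_identity(self):
        v = np.array([-3.0, 0.0, 7.5])
        np.testing.assert_array_equal(fd.transform_intensity(v, "identity"), v)


def _sheet(rows):
    return fd.SampleSheet(pd.DataFrame(rows, columns=fd.SAMPLE_SHEET_COLUMNS))


def _row(sid, dose, receptor="dectin-2", ligand="FurFurMan", rep=1):
    return [sid, receptor, ligand, dose, "ug/mL", rep, 16.0, "GFP"]


class TestAssembleDataset:
    def test_one_condition_two_doses(self):
        sheet = _sheet([_row("s0", 0.0), _row("s1", 1.0)])
        tables = {
            "s0": fd.EventTable("s0", ["GFP"], np.array([[10.0], [20.0]])),
            "s1": fd.EventTable("s1", ["GFP"], np.array([[100.0], [200.0], [400.0]])),
        }
        (ds,) = fd.assemble_dataset(sheet, tables)
        np.testing.assert_array_equal(ds.doses, [0.0, 1.0])
        assert ds.transform_tag == "log10_floor"
        assert [len(y) for y in ds.outputs_per_dose] == [2, 3]

    def test_cell_counts_match_inputs(self):
        rng = np.random.default_rng(1)
        sheet = _sheet([_row(f"s{i}", float(i)) for i in range(4)])
        tables = {
            f"s{i}": fd.EventTable(
                f"s{i}", ["GFP"], rng.lognormal(3, 1, size=(50 + i, 1))
            )
            for i in range(4)
        }
        (ds,) = fd.assemble_dataset(sheet, tables)
        assert ds.cells_per_dose.tolist() == [50, 51, 52, 53]

    def test_two_conditions_three_doses(self):
        rows = [_row(f"a{d}", d, receptor="dectin-1") for d in (0.0, 1.0, 2.0)]
        rows += [_row(f"b{d}", d, receptor="dectin-2") for d in (0.0, 1.0, 2.0)]
        sheet = _sheet(rows)
        tables = {
            r[0]: fd.EventTable(r[0], ["GFP"], np.full((5, 1), 100.0)) for r in rows
        }
        datasets = fd.assemble_dataset(sheet, tables)
        assert len(datasets) == 2
        assert all(ds.n_doses == 3 for ds in datasets)

    def test_unresolved_sample_is_linkage_error(self):
        sheet = _sheet([_row("missing", 0.0), _row("s1", 1.0)])
        tables = {"s1": fd.EventTable("s1", ["GFP"], np.ones((2, 1)))}
        with pytest.raises(LinkageError, match="missing"):
            fd.assemble_dataset(sheet, tables)

    def test_duplicate_condition_dose_rejected(self):
        with pytest.raises(DuplicationError):
            _sheet([_row("s0", 1.0), _row("s1", 1.0)])


class TestSummarizePopulation:
    def test_geometric_mean(self):
        gm, _ = fd.summarize_population([10, 1000])
        assert gm == pytest.approx(100.0)

    def test_constant_population_has_unit_robust_sd(self):
        gm, rsd = fd.summarize_population([7.0, 7.0, 7.0])
        assert gm == pytest.approx(7.0)
        assert rsd == pytest.approx(1.0)

    def test_powers_of_two_against_direct_arithmetic(self):
        v = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        gm, rsd = fd.summarize_population(v)
        lv = np.log(v)
        mad = np.median(np.abs(lv - np.median(lv)))
        assert gm == pytest.approx(4.0)
        assert rsd == pytest.approx(np.exp(1.4826 * mad))

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            fd.summarize_population([1.0, 0.0])


class TestBeadCalibration:
    def test_prediction_at_a_standard(self):
        cal = fd.fit_bead_calibration([(100, 1000), (1000, 10000)])
        np.testing.assert_allclose(
            fd.calibrate_fi_to_molecules(cal, [100.0]), [1000.0], rtol=1e-9
        )

    def test_log_linear_interpolation(self):
        cal = fd.fit_bead_calibration([(100, 1000), (1000, 10000)])
        # oracle: slope 1 in log-log, so 316.23 FI -> 3162.3 molecules
        np.testing.assert_allclose(
            fd.calibrate_fi_to_molecules(cal, [316.23]), [3162.3], rtol=1e-4
        )

    def test_single_standard_rejected(self):
        with pytest.raises(DomainError):
            fd.fit_bead_calibration([(100, 1000)])

    def test_strictly_increasing_for_positive_slope(self):
        cal = fd.fit_bead_calibration([(50, 800), (500, 9000), (5000, 80000)])
        x = np.linspace(10, 10000, 200)
        y = fd.calibrate_fi_to_molecules(cal, x)
        assert np.all(np.diff(y) > 0)
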