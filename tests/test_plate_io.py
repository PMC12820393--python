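"""Interchange-format round trips, validation, and the packaged panel."""

import numpy as np
import pandas as pd
import pytest

from protprof import FormatError, LayoutError
from protprof.panel import SubstrateEntry, SubstratePanel, load_substrate_panel
from protprof.plate_io import (
    read_kinetic_table,
    read_sample_sheet,
    validate_layout,
    write_kinetic_table,
    write_sample_sheet,
)
from protprof.plates import PlateRun, WellRole
from protprof.simulate import SimulationConfig, simulate_study

from conftest import make_trace


def _write_csv(path, rows, header="plate_id,well_id,sample_id,substrate_id,ph,replicate,role,time_min,rfu"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def _two_well_rows():
    rows = []
    for t in range(0, 80, 5):
        rows.append(f"P1,A1,,,7.5,1,empty,{t},{50.0 + 0.01 * t}")
        rows.append(f"P1,B1,S1,Ac-RSVL-AMC,7.5,1,digestion,{t},{10 + 3 * t}")
    return rows


class TestReadKineticTable:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "k.csv"
        _write_csv(path, _two_well_rows())
        runs = read_kinetic_table(path)
        assert len(runs) == 1
        assert len(runs[0].traces) == 2
        assert all(t.n_reads == 16 for t in runs[0].traces)
        digestion = [t for t in runs[0].traces if t.role is WellRole.DIGESTION][0]
        assert digestion.sample_id == "S1"
        assert digestion.substrate_id == "Ac-RSVL-AMC"

    def test_row_order_invariance(self, tmp_path):
        rows = _two_well_rows()
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        _write_csv(a, rows)
        rng = np.random.default_rng(0)
        _write_csv(b, list(np.array(rows)[rng.permutation(len(rows))]))
        ra, rb = read_kinetic_table(a), read_kinetic_table(b)
        for ta, tb in zip(ra[0].traces, rb[0].traces):
            assert ta.well_id == tb.well_id
            np.testing.assert_array_equal(ta.timepoints, tb.timepoints)
            np.testing.assert_array_equal(ta.rfu, tb.rfu)

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("plate_id,well_id,sample_id,substrate_id,ph,replicate,role,time_min\n")
        with pytest.raises(FormatError, match="rfu"):
            read_kinetic_table(path)

    def test_unknown_role(self, tmp_path):
        path = tmp_path / "k.csv"
        rows = [f"P1,A1,,,7.5,1,blanko,{t},{50}" for t in range(0, 80, 5)]
        _write_csv(path, rows)
        with pytest.raises(FormatError, match="blanko"):
            read_kinetic_table(path)

    def test_ragged_grid_rejected(self, tmp_path):
        path = tmp_path / "k.csv"
        rows = _two_well_rows()
        rows.append("P1,C1,,,7.5,1,empty,2.5,50")
        rows.extend(f"P1,C1,,,7.5,1,empty,{t},50" for t in (10, 20, 30))
        _write_csv(path, rows)
        with pytest.raises(LayoutError, match="ragged"):
            read_kinetic_table(path)

    def test_missing_reads_flag_incomplete(self, tmp_path):
        path = tmp_path / "k.csv"
        rows = _two_well_rows()
        rows = [r if not r.startswith("P1,B1,S1,Ac-RSVL-AMC,7.5,1,digestion,10,")
                else "P1,B1,S1,Ac-RSVL-AMC,7.5,1,digestion,10," for r in rows]
        _write_csv(path, rows)
        runs = read_kinetic_table(path)
        digestion = [t for t in runs[0].traces if t.role is WellRole.DIGESTION][0]
        assert digestion.incomplete
        assert digestion.n_reads == 15


class TestRoundTrip:
    def test_write_read_write_fixpoint(self, tmp_path):
        cfg = SimulationConfig(
            cohorts=(("HC", 2), ("CD", 2)),
            substrates=("Ac-RSVL-AMC", "Pyr-RTKR-AMC"),
            ph_levels=(5.5, 7.5),
            seed=7,
        )
        runs, _, _ = simulate_study(cfg)
        p1, p2 = tmp_path / "one.csv", tmp_path / "two.csv"
        write_kinetic_table(runs, p1)
        runs2 = read_kinetic_table(p1)
        write_kinetic_table(runs2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_run_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_kinetic_table([], path)
        assert path.read_text().strip() == (
            "plate_id,well_id,sample_id,substrate_id,ph,replicate,role,time_min,rfu"
        )

    def test_unwritable_destination(self, tmp_path):
        with pytest.raises(OSError):
            write_kinetic_table([], tmp_path / "nope" / "missing" / "x.csv")


class TestSubstratePanel:
    def test_builtin_has_14_substrates(self, panel):
        assert len(panel) == 14

    def test_rtkr_entry(self, panel):
        e = panel.entry("Pyr-RTKR-AMC")
        assert e.custom is False  # commercially available
        assert e.subclass == "furin-like"
        assert e.protease_class == "serine"

    def test_class_subclass_split(self, panel):
        assert len(panel.ids_of_class("cysteine")) == 4
        assert len(panel.ids_of_class("serine")) == 10
        for entry in panel:
            assert (entry.subclass == "cathepsin-like") == (
                entry.protease_class == "cysteine"
            )

    def test_cathepsin_labeled_serine_rejected(self):
        good = SubstrateEntry("X-AMC", "X", "cysteine", "cathepsin-like", 5.0, 7.0, True)
        SubstratePanel([good])
        with pytest.raises(FormatError, match="inconsistent"):
            SubstratePanel(
                [SubstrateEntry("X-AMC", "X", "serine", "cathepsin-like", 5.0, 7.0, True)]
            )

    def test_duplicate_id_rejected(self, panel):
        e = panel.entry("Ac-RSVL-AMC")
        with pytest.raises(FormatError, match="duplicate"):
            SubstratePanel([e, e])

    def test_file_roundtrip(self, tmp_path, panel):
        path = tmp_path / "panel.tsv"
        panel.to_frame().to_csv(path, sep="\t", index=False)
        again = load_substrate_panel(path)
        assert again.ids == panel.ids
        assert again.entry("R-AMC").ph_opt_low is None


class TestSampleSheet:
    def test_roundtrip(self, tmp_path):
        sheet = pd.DataFrame(
            {"sample_id": ["S1", "S2"], "cohort": ["UC", "CD"],
             "phase": ["acute", "none"], "notes": ["", "x"]}
        )
        path = tmp_path / "s.csv"
        write_sample_sheet(sheet, path)
        again = read_sample_sheet(path)
        pd.testing.assert_frame_equal(sheet, again)

    def test_duplicate_sample_phase_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,cohort,phase,notes\nS1,UC,acute,\nS1,UC,acute,\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_sample_sheet(path)

    def test_same_sample_across_phases_allowed(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,cohort,phase,notes\nS1,UC,acute,\nS1,UC,remission,\n")
        assert len(read_sample_sheet(path)) == 2


class TestValidateLayout:
    @pytest.fixture
    def consistent(self, panel):
        cfg = SimulationConfig(
            cohorts=(("HC", 2),), substrates=("Ac-RSVL-AMC",), ph_levels=(7.5,), seed=3
        )
        runs, sheet, _ = simulate_study(cfg)
        return runs, sheet

    def test_consistent_dataset_has_no_issues(self, consistent, panel):
        runs, sheet = consistent
        assert validate_layout(runs, sheet, panel) == []

    def test_missing_intrinsic_detected(self, consistent, panel):
        runs, sheet = consistent
        pruned = [
            PlateRun(
                plate_id=r.plate_id,
                traces=[
                    t for t in r.traces
                    if not (t.role is WellRole.INTRINSIC and t.sample_id == "HC001")
                ],
            )
            for r in runs
        ]
        issues = validate_layout(pruned, sheet, panel)
        assert [i.kind for i in issues] == ["missing_intrinsic"]
        assert issues[0].sample_id == "HC001"

    def test_unknown_substrate_detected(self, consistent, panel):
        runs, sheet = consistent
        t = np.arange(0, 80, 5, dtype=float)
        extra = make_trace(10 + t, t, substrate_id="Ac-NOTREAL-AMC",
                           sample_id="HC001", plate_id=runs[0].plate_id,
                           well_id="Z9")
        runs2 = [PlateRun(runs[0].plate_id, runs[0].traces + [extra])] + runs[1:]
        kinds = [i.kind for i in validate_layout(runs2, sheet, panel)]
        assert kinds.count("unknown_substrate") == 1

    def test_orphan_sample_and_missing_empties(self, panel):
        t = np.arange(0, 80, 5, dtype=float)
        digestion = make_trace(10 + t, t, sample_id="GHOST")
        intrinsic = make_trace(np.full_like(t, 5.0), t, role=WellRole.INTRINSIC,
                               sample_id="GHOST", well_id="A2")
        run = PlateRun("P1", [digestion, intrinsic])
        sheet = pd.DataFrame({"sample_id": ["S1"], "cohort": ["HC"],
                              "phase": ["none"], "notes": [""]})
        kinds = {i.kind for i in validate_layout([run], sheet, panel)}
        assert kinds == {"orphan_sample", "no_empty_wells"}
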