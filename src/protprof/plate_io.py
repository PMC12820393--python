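"""Reading and writing the tidy plate-kinetics interchange formats.

The canonical on-disk form of a kinetic run is a long (tidy) CSV with one
row per well and timepoint::

    plate_id,well_id,sample_id,substrate_id,ph,replicate,role,time_min,rfu

Vendor plate-reader exports (wide Tecan-style grids) are expected to be
pre-converted to this layout.  Empty ``sample_id``/``substrate_id`` cells
encode nulls; an empty ``rfu`` cell encodes a missing read, which marks the
trace as incomplete rather than being interpolated.

The sample sheet is a CSV mapping samples to cohorts::

    sample_id,cohort,phase,notes

with ``phase`` one of ``acute``, ``remission`` or ``none`` (follow-up pairs
reuse a sample_id across phases).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import FormatError, LayoutError
from .panel import SubstratePanel
from .plates import KineticTrace, PlateRun, WellRole

__all__ = [
    "KINETIC_COLUMNS",
    "read_kinetic_table",
    "write_kinetic_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "LayoutIssue",
    "validate_layout",
]

KINETIC_COLUMNS = [
    "plate_id",
    "well_id",
    "sample_id",
    "substrate_id",
    "ph",
    "replicate",
    "role",
    "time_min",
    "rfu",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "cohort", "phase", "notes"]
PHASES = ("acute", "remission", "none")


def _none_if_blank(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_kinetic_table(source: str | Path) -> list[PlateRun]:
    """Parse a long-format kinetics CSV into per-plate runs.

    Row order in the file is irrelevant: rows are grouped by (plate, well)
    and sorted by time.  Plates are returned in order of first appearance.
    """
    df = pd.read_csv(
        source,
        dtype={"plate_id": str, "well_id": str, "sample_id": str,
               "substrate_id": str, "role": str},
        float_precision="round_trip",
    )
    for col in KINETIC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"kinetic table is missing column {col!r}")
    bad_roles = set(df["role"].dropna().unique()) - {r.value for r in WellRole}
    if bad_roles:
        raise FormatError(f"unknown well role(s): {sorted(bad_roles)}")

    runs: list[PlateRun] = []
    for plate_id in df["plate_id"].drop_duplicates():
        sub = df[df["plate_id"] == plate_id]
        grid = np.sort(sub["time_min"].unique().astype(float))
        traces = []
        for well_id in sub["well_id"].drop_duplicates().sort_values():
            w = sub[sub["well_id"] == well_id].sort_values("time_min")
            t = w["time_min"].to_numpy(dtype=float)
            if len(np.unique(t)) != len(t):
                raise FormatError(
                    f"plate {plate_id} well {well_id}: duplicate timepoints"
                )
            rfu = w["rfu"].to_numpy(dtype=float)
            keep = np.isfinite(rfu)
            incomplete = not keep.all()
            t, rfu = t[keep], rfu[keep]
            if len(t) < 4:
                raise FormatError(
                    f"plate {plate_id} well {well_id}: fewer than 4 usable reads"
                )
            if not incomplete and (len(t) != len(grid) or not np.allclose(t, grid)):
                raise LayoutError(
                    f"plate {plate_id}: ragged time grids (well {well_id})"
                )
            first = w.iloc[0]
            meta = {"incomplete": True} if incomplete else {}
            traces.append(
                KineticTrace(
                    plate_id=str(plate_id),
                    well_id=str(well_id),
                    sample_id=_none_if_blank(first["sample_id"]),
                    substrate_id=_none_if_blank(first["substrate_id"]),
                    ph=float(first["ph"]),
                    replicate_index=int(first["replicate"]),
                    role=WellRole(first["role"]),
                    timepoints=t,
                    rfu=rfu,
                    meta=meta,
                )
            )
        runs.append(PlateRun(plate_id=str(plate_id), traces=traces))
    if runs:
        runs[0].is_reference_plate = True
    return runs


def write_kinetic_table(runs: list[PlateRun], destination: str | Path) -> None:
    """Write runs as the long-format CSV, one row per (well, timepoint).

    Row order is deterministic — (plate input order, well id, time) — and
    quoting follows RFC 4180, so identical runs always serialize to
    byte-identical files.
    """
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(KINETIC_COLUMNS)
        for run in runs:
            for trace in sorted(run.traces, key=lambda t: t.well_id):
                for t, y in zip(trace.timepoints, trace.rfu):
                    writer.writerow(
                        [
                            run.plate_id,
                            trace.well_id,
                            trace.sample_id or "",
                            trace.substrate_id or "",
                            repr(trace.ph),
                            trace.replicate_index,
                            trace.role.value,
                            repr(float(t)),
                            repr(float(y)),
                        ]
                    )


def read_sample_sheet(source: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise FormatError(f"sample sheet is missing column {col!r}")
    if "phase" not in df.columns:
        df["phase"] = "none"
    df.loc[df["phase"] == "", "phase"] = "none"
    if "notes" not in df.columns:
        df["notes"] = ""
    bad_phase = set(df["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise FormatError(f"unknown phase value(s): {sorted(bad_phase)}")
    dup = df.duplicated(subset=["sample_id", "phase"])
    if dup.any():
        raise FormatError(
            "duplicate (sample_id, phase) rows: "
            f"{df.loc[dup, 'sample_id'].tolist()}"
        )
    return df[SAMPLE_SHEET_COLUMNS].reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, destination: str | Path) -> None:
    sheet = sheet.copy()
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in sheet.columns:
            sheet[col] = "none" if col == "phase" else ""
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(destination, index=False, lineterminator="\n")


@dataclass(frozen=True)
class LayoutIssue:
    """One structured inconsistency between runs, sheet and panel."""

    kind: str  # orphan_sample | missing_intrinsic | no_empty_wells | unknown_substrate
    message: str
    plate_id: str | None = None
    sample_id: str | None = None
    substrate_id: str | None = None


def validate_layout(
    runs: list[PlateRun],
    sheet: pd.DataFrame,
    panel: SubstratePanel,
) -> list[LayoutIssue]:
    """Cross-check plates against the sample sheet and substrate panel.

    Issues are data, not exceptions: a (possibly empty) list is returned so
    callers can decide whether any of them is fatal for their analysis.
    """
    issues: list[LayoutIssue] = []
    known_samples = set(sheet["sample_id"])
    for run in runs:
        if not run.empty_wells():
            issues.append(
                LayoutIssue(
                    kind="no_empty_wells",
                    message=f"plate {run.plate_id} has no empty wells",
                    plate_id=run.plate_id,
                )
            )
        intrinsic_samples = {t.sample_id for t in run.wells(WellRole.INTRINSIC)}
        seen_orphans: set[str] = set()
        seen_missing: set[str] = set()
        seen_unknown: set[str] = set()
        for t in run.traces:
            if t.sample_id is not None and t.sample_id not in known_samples:
                if t.sample_id not in seen_orphans:
                    seen_orphans.add(t.sample_id)
                    issues.append(
                        LayoutIssue(
                            kind="orphan_sample",
                            message=(
                                f"plate {run.plate_id}: sample {t.sample_id} "
                                "is not in the sample sheet"
                            ),
                            plate_id=run.plate_id,
                            sample_id=t.sample_id,
                        )
                    )
            if t.role is WellRole.DIGESTION:
                if t.sample_id not in intrinsic_samples and t.sample_id not in seen_missing:
                    seen_missing.add(t.sample_id)
                    issues.append(
                        LayoutIssue(
                            kind="missing_intrinsic",
                            message=(
                                f"plate {run.plate_id}: sample {t.sample_id} "
                                "has digestion wells but no intrinsic control"
                            ),
                            plate_id=run.plate_id,
                            sample_id=t.sample_id,
                        )
                    )
                if t.substrate_id not in panel and t.substrate_id not in seen_unknown:
                    seen_unknown.add(t.substrate_id)
                    issues.append(
                        LayoutIssue(
                            kind="unknown_substrate",
                            message=(
                                f"plate {run.plate_id}: substrate "
                                f"{t.substrate_id} is not in the panel"
                            ),
                            plate_id=run.plate_id,
                            substrate_id=t.substrate_id,
                        )
                    )
    return issues
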