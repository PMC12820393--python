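"""In-memory containers for kinetic plate-reader measurements.

A :class:`KineticTrace` is the atomic measurement: one well's fluorescence
progress curve (RFU against minutes) together with the metadata needed to
interpret it (which plate/well, which sample and substrate, assay pH, well
role).  A :class:`PlateRun` collects all traces of one physical plate, which
is the unit of normalization: every plate carries empty wells whose mean
fluorescence calibrates plate-to-plate gain differences.

Well roles
----------
``digestion``
    stool extract + fluorogenic substrate; the signal-carrying wells.
``intrinsic``
    extract + buffer only, no substrate; measures the extract's own
    (substrate-independent) fluorescence, subtracted from digestion curves.
``substrate_only``
    substrate + buffer, no extract; controls for spontaneous hydrolysis.
``empty``
    buffer only; plate background, used for the normalization factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from ._errors import InputError, LayoutError

__all__ = ["WellRole", "KineticTrace", "PlateRun"]


class WellRole(str, Enum):
    DIGESTION = "digestion"
    INTRINSIC = "intrinsic"
    SUBSTRATE_ONLY = "substrate_only"
    EMPTY = "empty"


@dataclass
class KineticTrace:
    """One well's fluorescence time series plus identity metadata.

    Parameters
    ----------
    plate_id, well_id
        Physical location of the measurement.
    ph
        Assay buffer pH for this well.
    role
        Well role; see module docstring.
    timepoints
        Read times in minutes, strictly increasing.
    rfu
        Fluorescence readings (relative fluorescence units), one per
        timepoint.
    sample_id, substrate_id
        Null for roles that lack them (e.g. empty wells carry neither).
    replicate_index
        1-based replicate number among a sample's digestion wells.
    meta
        Free-form provenance (simulation parameters, normalization factor,
        subtraction notes).  Never interpreted by core algorithms.
    """

    plate_id: str
    well_id: str
    ph: float
    role: WellRole
    timepoints: np.ndarray
    rfu: np.ndarray
    sample_id: str | None = None
    substrate_id: str | None = None
    replicate_index: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.role = WellRole(self.role)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.timepoints.ndim != 1 or self.rfu.ndim != 1:
            raise InputError("timepoints and rfu must be one-dimensional")
        if len(self.timepoints) != len(self.rfu):
            raise InputError(
                f"trace {self.plate_id}/{self.well_id}: {len(self.timepoints)} "
                f"timepoints but {len(self.rfu)} readings"
            )
        if len(self.timepoints) < 2:
            raise InputError("a trace needs at least two reads")
        if np.any(np.diff(self.timepoints) <= 0):
            raise InputError(
                f"trace {self.plate_id}/{self.well_id}: timepoints must be "
                "strictly increasing"
            )
        if self.role is WellRole.DIGESTION and (
            self.sample_id is None or self.substrate_id is None
        ):
            raise InputError("digestion wells need both sample_id and substrate_id")
        if self.role is WellRole.INTRINSIC and (
            self.sample_id is None or self.substrate_id is not None
        ):
            raise InputError("intrinsic wells need a sample_id and no substrate_id")
        if self.role is WellRole.EMPTY and (
            self.sample_id is not None or self.substrate_id is not None
        ):
            raise InputError("empty wells carry neither sample_id nor substrate_id")

    @property
    def n_reads(self) -> int:
        return len(self.timepoints)

    @property
    def incomplete(self) -> bool:
        """True when reads were missing in the source file."""
        return bool(self.meta.get("incomplete", False))

    def with_rfu(self, rfu: np.ndarray, **meta) -> "KineticTrace":
        """Copy of this trace with new readings and extra provenance."""
        new = replace(self, rfu=np.asarray(rfu, dtype=float))
        new.meta = {**self.meta, **meta}
        return new


@dataclass
class PlateRun:
    """All traces of one physical plate."""

    plate_id: str
    traces: list[KineticTrace]
    is_reference_plate: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.traces:
            if t.plate_id != self.plate_id:
                raise LayoutError(
                    f"trace from plate {t.plate_id!r} placed in run "
                    f"{self.plate_id!r}"
                )
            if t.well_id in seen:
                raise LayoutError(
                    f"plate {self.plate_id}: duplicate well {t.well_id!r}"
                )
            seen.add(t.well_id)
        grids = [t.timepoints for t in self.traces if not t.incomplete]
        if grids:
            ref = grids[0]
            for g in grids[1:]:
                if len(g) != len(ref) or not np.allclose(g, ref):
                    raise LayoutError(
                        f"plate {self.plate_id}: wells do not share one "
                        "timepoint grid"
                    )

    def wells(self, role: WellRole | None = None) -> list[KineticTrace]:
        if role is None:
            return list(self.traces)
        role = WellRole(role)
        return [t for t in self.traces if t.role is role]

    def empty_wells(self) -> list[KineticTrace]:
        return self.wells(WellRole.EMPTY)

    def intrinsic_well(self, sample_id: str) -> KineticTrace | None:
        for t in self.wells(WellRole.INTRINSIC):
            if t.sample_id == sample_id:
                return t
        return None

    def map_rfu(self, fn, **meta) -> "PlateRun":
        """New run with ``fn`` applied to every trace's readings."""
        return PlateRun(
            plate_id=self.plate_id,
            traces=[t.with_rfu(fn(t.rfu), **meta) for t in self.traces],
            is_reference_plate=self.is_reference_plate,
        )

    def scaled(self, k: float) -> "PlateRun":
        """All wells multiplied by ``k`` (simulates a global gain change)."""
        if k <= 0:
            raise InputError("scale factor must be positive")
        return self.map_rfu(lambda r: r * k)
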