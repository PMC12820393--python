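import numpy as np
import pytest

from protprof.panel import load_substrate_panel
from protprof.plates import KineticTrace, PlateRun, WellRole


@pytest.fixture(scope="session")
def panel():
    return load_substrate_panel()


def make_trace(
    rfu,
    timepoints=None,
    role=WellRole.DIGESTION,
    sample_id="S1",
    substrate_id="Ac-RSVL-AMC",
    plate_id="P1",
    well_id="A1",
    ph=7.5,
    replicate_index=1,
):
    rfu = np.asarray(rfu, dtype=float)
    if timepoints is None:
        timepoints = np.arange(len(rfu), dtype=float) * 5.0
    role = WellRole(role)
    if role is WellRole.INTRINSIC:
        substrate_id = None
    if role is WellRole.EMPTY:
        sample_id = substrate_id = None
    if role is WellRole.SUBSTRATE_ONLY:
        sample_id = None
    return KineticTrace(
        plate_id=plate_id,
        well_id=well_id,
        sample_id=sample_id,
        substrate_id=substrate_id,
        ph=ph,
        role=role,
        replicate_index=replicate_index,
        timepoints=np.asarray(timepoints, dtype=float),
        rfu=rfu,
    )


@pytest.fixture
def tiny_plate():
    """One plate: a digestion well + its intrinsic control + an empty well."""
    t = np.arange(0, 80, 5, dtype=float)
    digestion = make_trace(10 + 3 * t + 20.0, t, well_id="B1")
    intrinsic = make_trace(
        np.full_like(t, 20.0), t, role=WellRole.INTRINSIC, well_id="B2"
    )
    empty = make_trace(np.full_like(t, 50.0), t, role=WellRole.EMPTY, well_id="A1")
    return PlateRun(plate_id="P1", traces=[empty, digestion, intrinsic])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
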