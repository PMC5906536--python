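"""Shared fixtures: steady-state simulation runs for the protocol corner
cells, the full study grid, and a factory for synthetic single-beat series."""

from __future__ import annotations

import numpy as np
import pytest

from counterpulse import (IABPConfig, ModelParams, SimulationConfig, run)
from counterpulse.engine import BeatSeries
from counterpulse.experiments import ProtocolGrid, run_grid

#: corner cells of the protocol used throughout the suite
CELLS = {"baseline": ("none", 0.0), "AR10": ("AR", 10.0),
         "MR10": ("MR", 10.0)}


@pytest.fixture(scope="session")
def steady_runs():
    """SimulationResult for each corner cell with the pump off and on,
    keyed (cell_name, iabp_on)."""
    out = {}
    for name, (cond, sev) in CELLS.items():
        for on in (False, True):
            cfg = SimulationConfig(condition=cond, severity=sev,
                                   iabp=IABPConfig(enabled=on))
            out[(name, on)] = run(cfg)
    return out


@pytest.fixture(scope="session")
def grid_table():
    """Beat metrics for the full 22-cell study grid."""
    return run_grid(ProtocolGrid())


@pytest.fixture
def make_beat():
    """Factory for synthetic BeatSeries with prescribed traces; unspecified
    traces default to zeros."""

    def _make(t, *, v_lv=None, p_lv=None, aortic=None, mitral=None,
              atp_rate_lv=None, p_sa=None, params=None):
        t = np.asarray(t, dtype=float)
        n = len(t)
        z = np.zeros(n)

        def arr(x):
            return z if x is None else np.asarray(x, dtype=float)

        vols = {k: z.copy() for k in
                ("LA", "LV", "SA", "SV", "RA", "RV", "PA", "PV")}
        pres = {k: z.copy() for k in vols}
        vols["LV"] = arr(v_lv)
        pres["LV"] = arr(p_lv)
        pres["SA"] = arr(p_sa)
        flows = {k: z.copy() for k in
                 ("mitral", "aortic", "systemic", "venous_return",
                  "tricuspid", "pulmonary_valve", "pulmonary",
                  "pulmonary_venous")}
        flows["aortic"] = arr(aortic)
        flows["mitral"] = arr(mitral)
        return BeatSeries(
            t=t, volumes=vols, pressures=pres, flows=flows,
            tension_lv=z, tension_rv=z, atp_rate_lv=arr(atp_rate_lv),
            atp_rate_rv=z, ca=z, params=params or ModelParams(),
            config=SimulationConfig())

    return _make
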