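"""Reference desk-scale experiments and their headline read-outs.

The two canonical regimes drive a single quadrilateral domain (208 ECs +
80 SMCs) with a spatially uniform luminal ATP level for 500 physiological
seconds:

* the *apex* regime at the surrogate peak concentration (1 uM), where the
  SMC layer sustains coherent Ca2+ oscillations, and
* the *seam* regime at the surrogate floor concentration (0.2 uM), where
  SMCs sit near rest most of the time and spike sporadically while the
  endothelium holds an elevated Ca2+ level.

The read-outs mirror the quantities a study of these regimes reports:
dominant oscillation period and maximal Ca2+ in the apex regime; baseline
(modal) Ca2+, spike ceiling, endothelial mean Ca2+ and the peak
phosphorylated-protein fraction W* in the seam regime.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .agonist import uniform_atp_map
from .analysis import simulate_phospho, time_average_W
from .fixtures import patch_lattice
from .geometry import CellLattice, SMC_GRID
from .params import ModelParams
from .simulator import (SimulationConfig, TimeSeriesRecord, assemble_network,
                        run_simulation)

APEX_ATP = 1.0   # uM, surrogate peak
SEAM_ATP = 0.2   # uM, surrogate floor


def run_regime_patch(params: ModelParams, atp_level: float,
                     duration: float = 500.0, seed: int = 1,
                     record_interval: float = 1.0
                     ) -> tuple[CellLattice, TimeSeriesRecord]:
    """Simulate one 288-cell domain under uniform ATP."""
    lat = patch_lattice(1, 1)
    system = assemble_network(lat, uniform_atp_map(lat.n_ec, atp_level), params)
    cfg = SimulationConfig(duration=duration, record_interval=record_interval,
                           seed=seed)
    return lat, run_simulation(system, cfg)


def central_smcs(lat: CellLattice) -> np.ndarray:
    """SMCs on the interior axial rows of a single-domain patch."""
    rows = lat.smc_grid_pos[:, 1]
    interior = (rows > 0) & (rows < SMC_GRID[0] - 1)
    return np.flatnonzero(interior)


def monitored_smc(lat: CellLattice) -> int:
    """The centre SMC of a single-domain patch."""
    return int(lat.n_smc // 2)


def linked_ec(lat: CellLattice, smc: int) -> int:
    """The EC most strongly heterocellularly linked to an SMC."""
    col = lat.hetero_wt.getrow(smc)
    return int(col.indices[np.argmax(col.data)])


def dominant_period(record: TimeSeriesRecord, cells: np.ndarray,
                    t_min: float = 300.0, t_max: float = 500.0,
                    prominence: float = 0.05) -> float:
    """Median inter-peak interval of SMC Ca2+ pooled over ``cells`` (s)."""
    t = record.times
    sel = (t >= t_min) & (t <= t_max)
    tt = t[sel]
    intervals = []
    for c in cells:
        x = record.smc[sel, 0, c]
        peaks, _ = find_peaks(x, prominence=prominence)
        if len(peaks) >= 2:
            intervals.extend(np.diff(tt[peaks]))
    if not intervals:
        return float("nan")
    return float(np.median(intervals))


def modal_value(trace: np.ndarray, bins: int = 50) -> float:
    """Histogram mode: the concentration the cell spends most time at."""
    hist, edges = np.histogram(trace, bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def apex_regime_metrics(lat: CellLattice, record: TimeSeriesRecord) -> dict:
    """Oscillation period and Ca2+ ceiling of the apex-driven regime."""
    t = record.times
    late = (t >= 300.0) & (t <= 500.0)
    return {
        "period_s": dominant_period(record, central_smcs(lat)),
        "max_smc_ca_uM": float(record.smc[late, 0, :].max()),
    }


def seam_regime_metrics(lat: CellLattice, record: TimeSeriesRecord,
                        params: ModelParams) -> dict:
    """Baseline, spike ceiling, EC mean and peak W* of the seam regime."""
    t = record.times
    smc = monitored_smc(lat)
    ec = linked_ec(lat, smc)
    trace = record.smc[:, 0, smc]
    late = (t >= 300.0) & (t <= 500.0)
    W = simulate_phospho(trace, t, params.phospho)
    return {
        "baseline_smc_ca_uM": modal_value(trace),
        "max_smc_ca_uM": float(trace.max()),
        "mean_ec_ca_uM": float(record.ec[late, 0, ec].mean()),
        "max_W_star": float(W.max()),
        "mean_W_star": time_average_W(W, t),
    }
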