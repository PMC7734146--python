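"""Experiment drivers: conductance-plane sweeps, line scans, raster export.

The reference studies explore how autapses reshape synchronization and
firing rates in three network types: excitatory-only (g_e x g_e_aut
plane), inhibitory-only (g_i x g_i_aut) and mixed 80/20 networks
(g_ei x g_ie).  These drivers regenerate those studies at desk scale:
by default N = 200 neurons, 8 s runs analysed over [4, 8] s, coarse
grids and a handful of seeds.  The qualitative structure - the
synchronization transitions and the firing-rate orderings between
autaptic and non-autaptic neurons - survives the reduction; the
full-scale settings (N = 1000, 20 s) remain available through the
configuration.

By default one graph per seed is reused across a whole sweep, so grid
points differ only in conductances, not topology; set
``reuse_graph=False`` to resample wiring at every point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import SpikeData, compute_metrics
from .network import CONDUCTANCE_RANGES, NetworkConfig, assemble_network
from .simulate import SimResult, run_simulation

__all__ = [
    "SweepSpec",
    "sweep_2d",
    "line_scan",
    "raster_export",
    "desk_config",
    "full_scale_config",
    "EXC_ONLY_PRESETS",
    "MIXED_PRESETS",
]

logger = logging.getLogger(__name__)

DEFAULT_METRICS = (
    "R_mean", "R_mean_non", "R_mean_aut", "CV_mean",
    "F_mean", "F_mean_aut", "F_mean_non", "F_mean_exc", "F_mean_inh",
    "I_s_mean",
)


def desk_config(**overrides) -> NetworkConfig:
    """Desk-scale base configuration: N = 200, 8 s run, analysis window
    [4, 8] s.  Keyword overrides are applied on top."""
    base = dict(N=200, T_total=8000.0, t_ini=4000.0, t_fin=8000.0)
    base.update(overrides)
    return NetworkConfig(**base)


def full_scale_config(**overrides) -> NetworkConfig:
    """Full-scale configuration: N = 1000, 20 s run, window [10, 20] s."""
    return NetworkConfig(**overrides)


#: Marked parameter points of the excitatory-only study (g_e, g_e_aut) in nS.
EXC_ONLY_PRESETS = {
    "circle": {"g_e": 0.05, "g_e_aut": 10.0},
    "triangle": {"g_e": 0.05, "g_e_aut": 31.0},
    "square": {"g_e": 0.1, "g_e_aut": 15.0},
    "hexagon": {"g_e": 0.1, "g_e_aut": 22.0},
}

#: Marked points of the mixed-network study (g_ei, g_ie) in nS, on top of
#: g_e = 0.5 and g_i = 2 nS.
MIXED_PRESETS = {
    "circle": {"g_ei": 0.5, "g_ie": 1.5},
    "square": {"g_ei": 1.8, "g_ie": 1.5},
    "triangle": {"g_ei": 4.5, "g_ie": 0.5},
}


@dataclass
class SweepSpec:
    """A 1-D or 2-D conductance sweep over a base configuration.

    ``axis_x`` / ``axis_y`` are ``(conductance_field, values)`` pairs;
    the fields must be conductance parameters of
    :class:`~aeifnet.network.NetworkConfig`.  Values outside the
    reference exploration ranges are rejected unless
    ``allow_out_of_range``.
    """

    base: NetworkConfig
    axis_x: tuple[str, Sequence[float]]
    axis_y: tuple[str, Sequence[float]] | None = None
    metrics: tuple[str, ...] = DEFAULT_METRICS
    seeds: tuple[int, ...] = (0, 1, 2)
    reuse_graph: bool = True
    allow_out_of_range: bool = False

    def validate(self) -> None:
        self.base.validate()
        axes = [self.axis_x] + ([self.axis_y] if self.axis_y is not None else [])
        for name, values in axes:
            if name not in CONDUCTANCE_RANGES:
                raise ValueError(
                    f"{name!r} is not a conductance field "
                    f"(expected one of {sorted(CONDUCTANCE_RANGES)})"
                )
            lo, hi = CONDUCTANCE_RANGES[name]
            vals = np.asarray(values, dtype=float)
            if vals.size == 0:
                raise ValueError(f"axis {name} has no values")
            if not self.allow_out_of_range and ((vals < lo) | (vals > hi)).any():
                raise ValueError(
                    f"axis {name} values outside the reference range [{lo}, {hi}] nS; "
                    "set allow_out_of_range=True to override"
                )
        if len(self.seeds) == 0:
            raise ValueError("at least one seed is required")
        unknown = set(self.metrics) - set(DEFAULT_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")


def _point_rows(spec: SweepSpec, x_name, x, y_name, y, seed, graph) -> list[dict]:
    overrides = {x_name: float(x)}
    if y_name is not None:
        overrides[y_name] = float(y)
    cfg = spec.base.replace(seed=int(seed), **overrides)
    common = {"x_name": x_name, "x": float(x), "y_name": y_name,
              "y": float(y) if y is not None else np.nan, "seed": int(seed)}
    try:
        result = run_simulation(cfg, graph=graph)
        table = compute_metrics(
            result.spikes, cfg.t_ini, cfg.t_fin,
            current=(result.current_t, result.current_I),
        ).to_dict()
        return [dict(common, metric=m, value=table[m], error="") for m in spec.metrics]
    except Exception as exc:  # failed point -> missing rows, not an abort
        logger.warning("sweep point %s failed: %s", common, exc)
        return [dict(common, metric=m, value=np.nan, error=str(exc)) for m in spec.metrics]


def sweep_2d(spec: SweepSpec, n_jobs: int = 1) -> pd.DataFrame:
    """Run the sweep and return a long-format metric table.

    One row per (grid point, seed, metric) with columns
    ``x_name, x, y_name, y, seed, metric, value, error``.  With
    ``reuse_graph`` one topology per seed is shared across the grid
    (conductances are resolved from each point's configuration).  Runs
    are independent given distinct seeds; ``n_jobs > 1`` distributes
    grid points over processes with joblib.
    """
    spec.validate()
    x_name, x_values = spec.axis_x
    if spec.axis_y is not None:
        y_name, y_values = spec.axis_y
    else:
        y_name, y_values = None, [None]

    tasks = []
    for seed in spec.seeds:
        graph = (
            assemble_network(spec.base.replace(seed=int(seed)))
            if spec.reuse_graph else None
        )
        for y in y_values:
            for x in x_values:
                tasks.append((x, y, seed, graph))

    if n_jobs > 1:
        from joblib import Parallel, delayed

        rows_nested = Parallel(n_jobs=n_jobs)(
            delayed(_point_rows)(spec, x_name, x, y_name, y, seed, graph)
            for x, y, seed, graph in tasks
        )
    else:
        rows_nested = [
            _point_rows(spec, x_name, x, y_name, y, seed, graph)
            for x, y, seed, graph in tasks
        ]
    rows = [r for sub in rows_nested for r in sub]
    return pd.DataFrame(rows)


def line_scan(spec: SweepSpec, n_jobs: int = 1) -> pd.DataFrame:
    """1-D scan along ``axis_x`` (axis_y must be unset), reporting at
    least the firing-rate family F_mean / F_mean_aut / F_mean_non."""
    if spec.axis_y is not None:
        raise ValueError("line_scan takes a single axis; use sweep_2d for planes")
    needed = ("F_mean", "F_mean_aut", "F_mean_non")
    metrics = tuple(dict.fromkeys(tuple(spec.metrics) + needed))
    spec = SweepSpec(
        base=spec.base, axis_x=spec.axis_x, axis_y=None, metrics=metrics,
        seeds=spec.seeds, reuse_graph=spec.reuse_graph,
        allow_out_of_range=spec.allow_out_of_range,
    )
    return sweep_2d(spec, n_jobs=n_jobs)


def raster_export(
    result: SimResult | SpikeData,
    window: tuple[float, float],
    ordering: str = "index",
) -> pd.DataFrame:
    """Spike raster table: one row per spike inside ``window``.

    Columns ``row`` (1-based display row), ``neuron_id`` (1-based) and
    ``time_ms``.  With ``ordering='autaptic-last'`` the autaptic neurons
    occupy the top (highest-numbered) contiguous rows, matching the
    grouped presentation of the reference rasters; ``'index'`` keeps
    display row = neuron id.
    """
    spikes = result.spikes if isinstance(result, SimResult) else result
    t0, t1 = window
    if t1 < t0:
        raise ValueError("window must satisfy t0 <= t1")
    if ordering == "index":
        display = np.arange(spikes.n)
    elif ordering == "autaptic-last":
        order = np.concatenate([
            np.nonzero(~spikes.autaptic)[0],
            np.nonzero(spikes.autaptic)[0],
        ])
        display = np.empty(spikes.n, dtype=np.int64)
        display[order] = np.arange(spikes.n)
    else:
        raise ValueError("ordering must be 'index' or 'autaptic-last'")

    rows = []
    for j in range(spikes.n):
        tj = spikes.trains[j]
        tj = tj[(tj >= t0) & (tj <= t1)]
        for t in tj:
            rows.append((int(display[j]) + 1, j + 1, float(t)))
    df = pd.DataFrame(rows, columns=["row", "neuron_id", "time_ms"])
    return df.sort_values(["time_ms", "row"], kind="stable").reset_index(drop=True)
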