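"""Spike-train diagnostics: phase synchronization, ISI variability, rates.

Synchronization is measured with the Kuramoto order parameter computed
from linearly interpolated spike phases: between consecutive spikes of a
neuron the phase grows by 2*pi, so

    psi_j(t) = 2 pi m + 2 pi (t - t_{j,m}) / (t_{j,m+1} - t_{j,m})

for t in [t_{j,m}, t_{j,m+1}), and

    R(t) = | (1/N') sum_j exp(i psi_j(t)) |

over the neurons whose phase is defined at t (a neuron needs at least
two spikes spanning t inside the analysis window).  R = 1 means full
phase synchronization, R ~ 0 incoherence.  Time averages (R-bar, I-bar)
use the trapezoidal rule on the sampling grid.

Firing variability is quantified per neuron by the coefficient of
variation of interspike intervals, CV_j = sigma_ISI / mean(ISI); the
network mean CV-bar classifies the collective pattern as burst firing
when CV-bar >= 0.5 and (regular) spike firing below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpikeData",
    "MetricsTable",
    "UndefinedMetricError",
    "interpolate_phase",
    "phase_on_grid",
    "order_parameter_series",
    "time_average",
    "cv_stats",
    "classify_pattern",
    "firing_rate",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

SUBSETS = ("all", "aut", "non", "exc", "inh")


class UndefinedMetricError(ValueError):
    """A metric has no defined value (empty subset, no eligible neuron,
    or a time outside the phase-defined span)."""


@dataclass
class SpikeData:
    """Per-neuron sorted spike times with population and autapse labels.

    ``trains[j]`` is a strictly increasing float array of spike times in
    ms for neuron j (0-based internally; files use 1-based ids).
    """

    trains: list
    is_exc: np.ndarray
    autaptic: np.ndarray

    def __post_init__(self) -> None:
        self.is_exc = np.asarray(self.is_exc, dtype=bool)
        self.autaptic = np.asarray(self.autaptic, dtype=bool)
        if not (len(self.trains) == self.is_exc.size == self.autaptic.size):
            raise ValueError("trains, is_exc and autaptic must have equal length")
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for j, t in enumerate(self.trains):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"spike times of neuron {j + 1} are not strictly increasing")

    @property
    def n(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    @classmethod
    def from_flat(cls, neuron_ids, times, n, is_exc=None, autaptic=None) -> "SpikeData":
        """Build from flat (neuron id, time) arrays in any order."""
        ids = np.asarray(neuron_ids, dtype=np.int64)
        tt = np.asarray(times, dtype=float)
        order = np.lexsort((tt, ids))
        ids, tt = ids[order], tt[order]
        counts = np.bincount(ids, minlength=n)
        trains = np.split(tt, np.cumsum(counts)[:-1])
        if is_exc is None:
            is_exc = np.ones(n, dtype=bool)
        if autaptic is None:
            autaptic = np.zeros(n, dtype=bool)
        return cls(trains=list(trains), is_exc=is_exc, autaptic=autaptic)

    def subset_indices(self, subset: str = "all") -> np.ndarray:
        """Neuron indices of a named subset: all | aut | non | exc | inh."""
        if subset in ("all", None):
            return np.arange(self.n)
        if subset in ("aut", "autaptic"):
            return np.nonzero(self.autaptic)[0]
        if subset in ("non", "non-autaptic"):
            return np.nonzero(~self.autaptic)[0]
        if subset in ("exc", "excitatory"):
            return np.nonzero(self.is_exc)[0]
        if subset in ("inh", "inhibitory"):
            return np.nonzero(~self.is_exc)[0]
        raise ValueError(f"unknown subset {subset!r}")


def interpolate_phase(spike_times, t: float) -> float:
    """Linearly interpolated spike phase of one neuron at time ``t``.

    Defined for t in [first spike, last spike); the spike index m counts
    from zero at the first spike of the supplied train (an integer shift
    of m changes the phase by a multiple of 2*pi and leaves the order
    parameter untouched).
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size < 2:
        raise UndefinedMetricError("phase needs at least two spikes")
    if not (times[0] <= t < times[-1]):
        raise UndefinedMetricError(
            f"t = {t} outside the phase-defined span [{times[0]}, {times[-1]})"
        )
    m = int(np.searchsorted(times, t, side="right")) - 1
    frac = (t - times[m]) / (times[m + 1] - times[m])
    return 2.0 * np.pi * (m + frac)


def phase_on_grid(spike_times, grid) -> np.ndarray:
    """Vectorized :func:`interpolate_phase`; NaN where undefined."""
    times = np.asarray(spike_times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    psi = np.full(grid.shape, np.nan)
    if times.size < 2:
        return psi
    m = np.searchsorted(times, grid, side="right") - 1
    valid = (m >= 0) & (grid < times[-1])
    mv = m[valid]
    frac = (grid[valid] - times[mv]) / (times[mv + 1] - times[mv])
    psi[valid] = 2.0 * np.pi * (mv + frac)
    return psi


def order_parameter_series(
    spikes: SpikeData, grid, subset: str = "all"
) -> np.ndarray:
    """Kuramoto order parameter R(t) on a time grid for a neuron subset.

    At each grid point only neurons with a defined phase contribute: a
    neuron is excluded wherever its spike span does not cover the grid
    point (no extrapolation).  The phase origin is the neuron's first
    recorded spike; since an integer shift of the spike index changes
    the phase by a multiple of 2*pi, the origin convention does not
    affect R.  Points where no neuron has a defined phase are NaN and
    logged.
    """
    grid = np.asarray(grid, dtype=float)
    idx = spikes.subset_indices(subset)
    Z = np.zeros(grid.size, dtype=complex)
    cnt = np.zeros(grid.size)
    for j in idx:
        psi = phase_on_grid(spikes.trains[j], grid)
        ok = np.isfinite(psi)
        Z[ok] += np.exp(1j * psi[ok])
        cnt[ok] += 1
    R = np.full(grid.size, np.nan)
    has = cnt > 0
    R[has] = np.abs(Z[has]) / cnt[has]
    n_missing = int((~has).sum())
    if n_missing:
        logger.info("order parameter undefined at %d of %d grid points", n_missing, grid.size)
    return R


def time_average(t, y, t_ini: float, t_fin: float) -> float:
    """Trapezoidal time average of a sampled series over [t_ini, t_fin].

    Window endpoints are obtained by linear interpolation when they fall
    between samples; NaN samples are dropped (and logged).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_fin <= t_ini:
        raise ValueError("require t_ini < t_fin")
    tol = 1e-9 * max(1.0, abs(t_fin))
    if t[0] > t_ini + tol or t[-1] < t_fin - tol:
        raise ValueError(
            f"series [{t[0]}, {t[-1]}] does not cover the window [{t_ini}, {t_fin}]"
        )
    finite = np.isfinite(y)
    if not finite.all():
        logger.info("time_average: dropping %d non-finite samples", int((~finite).sum()))
        t, y = t[finite], y[finite]
    if t.size < 2:
        raise UndefinedMetricError("too few finite samples to average")
    inner = (t > t_ini) & (t < t_fin)
    ts = np.concatenate(([t_ini], t[inner], [t_fin]))
    ys = np.concatenate(([np.interp(t_ini, t, y)], y[inner], [np.interp(t_fin, t, y)]))
    return float(np.trapezoid(ys, ts) / (t_fin - t_ini))


def cv_stats(
    spikes: SpikeData,
    subset: str = "all",
    t_ini: float | None = None,
    t_fin: float | None = None,
    ddof: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-neuron ISI coefficient of variation and its subset mean.

    ``ddof = 0`` (population standard deviation) by default; neurons
    with fewer than two interspike intervals inside the window are NaN
    in the per-neuron array and excluded from the mean (their number is
    logged).

    Returns ``(cv_j, cv_mean)`` with ``cv_j`` aligned to the subset's
    neuron order.
    """
    idx = spikes.subset_indices(subset)
    cv = np.full(idx.size, np.nan)
    for pos, j in enumerate(idx):
        tj = spikes.trains[j]
        if t_ini is not None or t_fin is not None:
            lo = -np.inf if t_ini is None else t_ini
            hi = np.inf if t_fin is None else t_fin
            tj = tj[(tj >= lo) & (tj <= hi)]
        isi = np.diff(tj)
        if isi.size < 2:
            continue
        cv[pos] = isi.std(ddof=ddof) / isi.mean()
    eligible = np.isfinite(cv)
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info("cv_stats: %d of %d neurons had < 2 ISIs and were excluded",
                    n_excluded, idx.size)
    if not eligible.any():
        raise UndefinedMetricError("no neuron with at least two interspike intervals")
    return cv, float(np.nanmean(cv))


def classify_pattern(cv_mean: float) -> str:
    """Collective firing pattern from the mean CV: ``'burst'`` when
    CV-bar >= 0.5 (inclusive), else ``'spike'``."""
    if not np.isfinite(cv_mean) or cv_mean < 0:
        raise ValueError(f"cv_mean must be finite and non-negative, got {cv_mean}")
    return "burst" if cv_mean >= 0.5 else "spike"


def firing_rate(
    spikes: SpikeData, t_ini: float, t_fin: float, subset: str = "all"
) -> float:
    """Mean firing rate of a subset in Hz over the half-open window
    (t_ini, t_fin]: total subset spike count / (subset size * window)."""
    if t_fin <= t_ini:
        raise ValueError("require t_ini < t_fin")
    idx = spikes.subset_indices(subset)
    if idx.size == 0:
        raise UndefinedMetricError(f"subset {subset!r} is empty")
    count = 0
    for j in idx:
        tj = spikes.trains[j]
        count += int(np.searchsorted(tj, t_fin, side="right")
                     - np.searchsorted(tj, t_ini, side="right"))
    return count / (idx.size * (t_fin - t_ini) / 1000.0)


@dataclass
class MetricsTable:
    """Summary metrics of one run: order parameters (dimensionless, in
    [0, 1]), mean ISI CV, firing rates (Hz), mean synaptic current (pA)
    and the burst/spike classification.  Subgroup values are NaN when
    the subgroup is empty (e.g. no autapses or no inhibitory neurons)."""

    R_mean: float
    R_mean_non: float
    R_mean_aut: float
    CV_mean: float
    F_mean: float
    F_mean_aut: float
    F_mean_non: float
    F_mean_exc: float
    F_mean_inh: float
    I_s_mean: float
    pattern: str

    def to_dict(self) -> dict:
        return {
            "R_mean": self.R_mean,
            "R_mean_non": self.R_mean_non,
            "R_mean_aut": self.R_mean_aut,
            "CV_mean": self.CV_mean,
            "F_mean": self.F_mean,
            "F_mean_aut": self.F_mean_aut,
            "F_mean_non": self.F_mean_non,
            "F_mean_exc": self.F_mean_exc,
            "F_mean_inh": self.F_mean_inh,
            "I_s_mean": self.I_s_mean,
            "pattern": self.pattern,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def _safe(fn, *args, **kw) -> float:
    try:
        return float(fn(*args, **kw))
    except UndefinedMetricError:
        return float("nan")


def compute_metrics(
    spikes: SpikeData,
    t_ini: float,
    t_fin: float,
    current: tuple[np.ndarray, np.ndarray] | None = None,
    r_grid_dt: float = 1.0,
    ddof: int = 0,
) -> MetricsTable:
    """All summary metrics of a run over the analysis window [t_ini, t_fin].

    ``current`` is an optional ``(t, I_chem)`` pair for the mean synaptic
    current; ``r_grid_dt`` sets the order-parameter sampling grid (ms).
    """
    grid = np.arange(t_ini, t_fin + 0.5 * r_grid_dt, r_grid_dt)

    def r_bar(subset: str) -> float:
        if spikes.subset_indices(subset).size == 0:
            return float("nan")
        series = order_parameter_series(spikes, grid, subset)
        if not np.isfinite(series).any():
            return float("nan")
        return time_average(grid, series, t_ini, t_fin)

    def f_bar(subset: str) -> float:
        return _safe(firing_rate, spikes, t_ini, t_fin, subset)

    try:
        _, cv_mean = cv_stats(spikes, "all", t_ini, t_fin, ddof=ddof)
    except UndefinedMetricError:
        cv_mean = float("nan")

    if current is not None:
        i_s = time_average(current[0], current[1], t_ini, t_fin)
    else:
        i_s = float("nan")

    return MetricsTable(
        R_mean=r_bar("all"),
        R_mean_non=r_bar("non"),
        R_mean_aut=r_bar("aut"),
        CV_mean=cv_mean,
        F_mean=f_bar("all"),
        F_mean_aut=f_bar("aut"),
        F_mean_non=f_bar("non"),
        F_mean_exc=f_bar("exc"),
        F_mean_inh=f_bar("inh"),
        I_s_mean=i_s,
        pattern=classify_pattern(cv_mean) if np.isfinite(cv_mean) else "undefined",
    )
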