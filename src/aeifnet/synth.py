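"""Synthetic spike trains with known phase structure, for diagnostics.

Four generators cover the regimes the synchronization and variability
measures are designed to distinguish:

- ``periodic``: identical, perfectly aligned periodic trains
  (R-bar = 1, CV = 0);
- ``antiphase-pairs``: alternating half-period offsets, so a pair's
  phases sit on opposite sides of the circle (R = 0 mid-interval);
- ``jittered``: periodic trains plus independent per-spike Gaussian
  jitter (truncated so ISIs stay positive) - partial coherence without
  cumulative drift;
- ``poisson``: homogeneous Poisson trains (incoherent, CV ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnostics import SpikeData

__all__ = ["FixtureSpec", "make_synthetic_trains", "KINDS"]

KINDS = ("periodic", "jittered", "antiphase-pairs", "poisson")


@dataclass
class FixtureSpec:
    """Specification of a synthetic spike-train ensemble.

    Exactly one of ``period`` (ms) or ``rate`` (Hz) must be given.  The
    first ``round(frac_exc * n)`` neurons are labelled excitatory and
    the first ``round(frac_autaptic * n)`` flagged autaptic (fixed
    leading-block patterns, sufficient for subset diagnostics).
    """

    kind: str
    n_neurons: int
    period: float | None = None
    rate: float | None = None
    jitter_sd: float = 0.0
    duration: float = 1000.0
    frac_exc: float = 1.0
    frac_autaptic: float = 0.0
    seed: int = 0

    def resolved_period(self) -> float:
        if (self.period is None) == (self.rate is None):
            raise ValueError("give exactly one of period (ms) or rate (Hz)")
        p = self.period if self.period is not None else 1000.0 / self.rate
        if p <= 0:
            raise ValueError("period/rate must be positive")
        return p

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        p = self.resolved_period()
        if self.kind == "jittered" and self.jitter_sd >= p / 2:
            raise ValueError(
                f"jitter_sd = {self.jitter_sd} ms >= period/2 = {p / 2} ms "
                "cannot guarantee positive ISIs"
            )
        for name in ("frac_exc", "frac_autaptic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_synthetic_trains(spec: FixtureSpec) -> SpikeData:
    """Generate the spike ensemble described by ``spec``.

    Jitter is applied independently per spike (no cumulative drift) and
    truncated at +/- 0.49 period, so consecutive spikes cannot swap and
    all ISIs stay positive.  The jitter_sd -> 0 limit recovers the
    periodic ensemble exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    period = spec.resolved_period()
    base = np.arange(0.0, spec.duration + 1e-9, period)

    trains: list[np.ndarray] = []
    if spec.kind == "periodic":
        trains = [base.copy() for _ in range(n)]
    elif spec.kind == "antiphase-pairs":
        shifted = base + period / 2.0
        shifted = shifted[shifted <= spec.duration + 1e-9]
        for j in range(n):
            trains.append(base.copy() if j % 2 == 0 else shifted.copy())
    elif spec.kind == "jittered":
        bound = 0.49 * period
        for _ in range(n):
            jit = np.clip(rng.normal(0.0, spec.jitter_sd, size=base.size), -bound, bound)
            trains.append(base + jit)
    elif spec.kind == "poisson":
        mean_isi = period  # ms
        for _ in range(n):
            # enough exponential ISIs to cover the duration with margin
            m = max(16, int(spec.duration / mean_isi * 1.5) + 10)
            t = np.cumsum(rng.exponential(mean_isi, size=m))
            while t[-1] <= spec.duration:
                t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(mean_isi, size=m))])
            trains.append(t[t <= spec.duration])

    is_exc = np.zeros(n, dtype=bool)
    is_exc[: int(round(spec.frac_exc * n))] = True
    autaptic = np.zeros(n, dtype=bool)
    autaptic[: int(round(spec.frac_autaptic * n))] = True
    return SpikeData(trains=trains, is_exc=is_exc, autaptic=autaptic)
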