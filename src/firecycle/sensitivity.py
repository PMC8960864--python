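"""Monte-Carlo sensitivity sweep over uniform parameter ranges.

Each run draws an independent uniform sample per swept parameter, integrates
the model, and the sweep reports per-time-step percentile envelopes
(2.5/25/50/75/97.5) of the tracked outputs plus per-run scalar summaries.
The default design perturbs the perception and behaviour closures up to
twice their base value and the initial vegetation stocks between zero and
their base values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ensemble import integrate_ensemble, make_ensemble_params
from .errors import ConfigError
from .experiments import PEAK_PROMINENCE_FRACTION
from .params import ModelParams

__all__ = ["SweepSpec", "Envelope", "default_sweep", "monte_carlo"]

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass
class SweepSpec:
    """Design of a Monte-Carlo sweep.

    ``intervals`` maps parameter names to (low, high) uniform sampling
    bounds. ``outputs`` are the series to envelope.
    """

    intervals: dict[str, tuple[float, float]]
    runs: int = 2000
    seed: int = 0
    outputs: tuple[str, ...] = ("B", "S", "F", "V")
    horizon: float = 20.0
    dt: float = 1.0 / 64.0

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ConfigError("runs must be >= 1")
        for name, (low, high) in self.intervals.items():
            if not (low <= high):
                raise ConfigError(f"interval for {name!r} has low > high")


def default_sweep(params: ModelParams | None = None, runs: int = 2000, seed: int = 0) -> SweepSpec:
    """The standard robustness design.

    Perception delay, ignition-behaviour sensitivity, per-ignition burning
    rate, the human-ignition multiplier and initial vulnerable property vary
    over [base, 2*base]; the initial vegetation stocks vary over [0, base].
    """
    p = params or ModelParams()
    intervals = {
        "delta1": (p.delta1, 2.0 * p.delta1),
        "ignition_sensitivity": (p.ignition_sensitivity, 2.0 * p.ignition_sensitivity),
        "burn_per_ignition": (p.burn_per_ignition, 2.0 * p.burn_per_ignition),
        "ignition_baseline": (p.h0, 2.0 * p.h0),
        "v0": (p.v0, 2.0 * p.v0),
        "s0": (0.0, p.s0),
        "f0": (0.0, p.f0),
    }
    return SweepSpec(intervals=intervals, runs=runs, seed=seed)


@dataclass
class Envelope:
    """Sweep output: nested percentile bands plus per-run summaries."""

    t: np.ndarray
    bands: dict[str, np.ndarray]  # output name -> (n_percentiles, n_times)
    percentiles: tuple[float, ...]
    summaries: pd.DataFrame  # per retained run: total_burn, n_peaks
    n_excluded: int  # diverging runs recorded and excluded
    samples: pd.DataFrame  # the parameter draws, one row per run

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, variable, percentile, value."""
        records = []
        for name, band in self.bands.items():
            for q, row in zip(self.percentiles, band):
                records.append(
                    pd.DataFrame(
                        {"time": self.t, "variable": name, "percentile": q, "value": row}
                    )
                )
        return pd.concat(records, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _sample(spec: SweepSpec, params: ModelParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Independent uniform draws; resample rows violating s0 + f0 <= 1."""
    draws = {
        name: rng.uniform(low, high, size=spec.runs)
        for name, (low, high) in spec.intervals.items()
    }
    s0 = draws.get("s0", np.full(spec.runs, params.s0))
    f0 = draws.get("f0", np.full(spec.runs, params.f0))
    bad = s0 + f0 > 1.0
    while np.any(bad):
        idx = np.flatnonzero(bad)
        for name in ("s0", "f0"):
            if name in draws:
                low, high = spec.intervals[name]
                draws[name][idx] = rng.uniform(low, high, size=idx.size)
        s0 = draws.get("s0", s0)
        f0 = draws.get("f0", f0)
        bad = s0 + f0 > 1.0
    return draws


def monte_carlo(spec: SweepSpec, params: ModelParams | None = None) -> Envelope:
    """Run the sweep and aggregate percentile envelopes.

    Deterministic given ``spec.seed``. Diverging runs are excluded from the
    aggregates and counted in ``n_excluded`` rather than aborting.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(spec.seed)
    draws = _sample(spec, params, rng)
    ns = make_ensemble_params(params, draws)
    record = tuple(dict.fromkeys(spec.outputs + ("B",)))
    ens = integrate_ensemble(ns, horizon=spec.horizon, dt=spec.dt, record=record)

    keep = ~ens.diverged
    bands = {
        name: np.nanpercentile(ens.series[name][:, keep], PERCENTILES, axis=1)
        if np.any(keep)
        else np.full((len(PERCENTILES), ens.t.size), np.nan)
        for name in spec.outputs
    }

    B = ens.series["B"][:, keep]
    total_burn = np.trapezoid(B, ens.t, axis=0)
    prominences = PEAK_PROMINENCE_FRACTION * (np.max(B, axis=0) - np.min(B, axis=0))
    n_peaks = np.array(
        [
            len(find_peaks(B[:, j], prominence=prominences[j] or None)[0])
            for j in range(B.shape[1])
        ]
    )
    summaries = pd.DataFrame(
        {
            "run": np.flatnonzero(keep),
            "total_burn": total_burn,
            "n_peaks": n_peaks,
        }
    )
    return Envelope(
        t=ens.t,
        bands=bands,
        percentiles=PERCENTILES,
        summaries=summaries,
        n_excluded=int(np.count_nonzero(ens.diverged)),
        samples=pd.DataFrame(draws),
    )
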