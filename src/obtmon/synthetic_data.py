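"""Synthetic study generator with known ground truth.

Produces per-well oscillation-amplitude traces with the morphology of a
monitored stem-cell culture experiment: logistic confluence growth, a medium change
when the fill factor crosses 70%, a stochastic growth-arrest plateau
(truncated normal, mean 0.8 d, SD 0.1 d) and, for differentiating wells, a
linear rise of effective electrode coverage — plus a developing series
tissue resistance — toward a final amplitude above the undifferentiated
plateau.  Fill-factor trajectories are pushed through the oscillation
solver at 60-minute sampling and multiplicative/additive noise is applied.

The default well layout mirrors an 8-well plate in which wells 1 and 5
hold media only, wells 2/3 (undifferentiated) and 6 (differentiated) are
monitored, and wells 4/7 are unmonitored controls that produce no trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from obtmon.circuit_models import CellElectrodeModel, DomainError, InterfaceParams
from obtmon.obt_engine import (
    BandPassSpec,
    BioimpedanceBlockSpec,
    ComparatorSpec,
    solve_oscillation,
)

__all__ = [
    "GrowthScenario",
    "DifferentiationScenario",
    "NoiseSpec",
    "FfTrajectory",
    "SyntheticStudy",
    "DEFAULT_LAYOUT",
    "simulate_ff_trajectory",
    "simulate_study",
    "write_fixture",
    "load_fixture",
]

#: Well layout of the monitored 8-well plate: condition per well id.
DEFAULT_LAYOUT = {
    "W1": "medium_only",
    "W2": "undifferentiated",
    "W3": "undifferentiated",
    "W4": "unmonitored",
    "W5": "medium_only",
    "W6": "differentiated",
    "W7": "unmonitored",
}

CONDITIONS = {"medium_only", "undifferentiated", "differentiated", "unmonitored"}


@dataclass(frozen=True)
class GrowthScenario:
    """Logistic confluence growth ``ff(t) = ff_max / (1 + exp(-r (t-t0)))``.

    If ``t0_days`` is omitted it is derived from the seeding fill factor
    so that ``ff(0) = seed_ff``.  Defaults reach >90% of the well by day 5.
    """

    ff_max: float = 0.95
    rate_per_day: float = 1.8
    t0_days: float | None = None
    seed_ff: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.ff_max <= 1.0):
            raise DomainError("ff_max must lie in (0, 1]")
        if self.rate_per_day <= 0:
            raise DomainError("rate_per_day must be positive")
        if not (0.0 < self.seed_ff < self.ff_max):
            raise DomainError("seed_ff must lie in (0, ff_max)")

    @property
    def midpoint_days(self) -> float:
        if self.t0_days is not None:
            return self.t0_days
        return math.log(self.ff_max / self.seed_ff - 1.0) / self.rate_per_day

    def ff_at(self, t_days):
        t = np.asarray(t_days, dtype=float)
        val = self.ff_max / (1.0 + np.exp(-self.rate_per_day * (t - self.midpoint_days)))
        return float(val) if np.isscalar(t_days) else val

    def crossing_time_days(self, level: float) -> float | None:
        """Continuous time at which ff reaches ``level``; None if never."""
        if not (0.0 < level < self.ff_max):
            return None
        return self.midpoint_days + math.log(level / (self.ff_max - level)) / self.rate_per_day


@dataclass(frozen=True)
class DifferentiationScenario:
    """Growth arrest followed by a linear differentiation rise.

    The plateau duration is drawn from a normal distribution truncated at
    zero.  After the plateau, effective coverage rises linearly at
    ``rise_per_day`` from the medium-change level to ``final_coverage``
    while a series tissue resistance develops in proportion, so the final
    amplitude exceeds the undifferentiated plateau level.
    """

    plateau_mean_days: float = 0.8
    plateau_sd_days: float = 0.1
    rise_per_day: float = 0.1
    final_coverage: float = 1.0
    tissue_resistance_ohm: float = 150.0
    medium_change_ff: float = 0.70

    def __post_init__(self) -> None:
        if self.plateau_mean_days < 0 or self.plateau_sd_days < 0:
            raise DomainError("plateau moments must be non-negative")
        if self.rise_per_day <= 0:
            raise DomainError("rise_per_day must be positive")
        if not (0.0 < self.medium_change_ff < self.final_coverage <= 1.0):
            raise DomainError("need 0 < medium_change_ff < final_coverage <= 1")
        if self.tissue_resistance_ohm < 0:
            raise DomainError("tissue_resistance_ohm must be non-negative")

    def draw_plateau_days(self, rng: np.random.Generator) -> float:
        if self.plateau_sd_days == 0.0:
            return self.plateau_mean_days
        while True:  # truncation at zero; acceptance probability ~1
            d = rng.normal(self.plateau_mean_days, self.plateau_sd_days)
            if d >= 0.0:
                return d


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: multiplicative gain jitter plus additive volts."""

    multiplicative_sd: float = 0.01
    additive_sd_volt: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0 or self.additive_sd_volt < 0:
            raise DomainError("noise SDs must be non-negative")

    def apply(self, amplitudes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        a = np.asarray(amplitudes, dtype=float)
        out = a * (1.0 + self.multiplicative_sd * rng.standard_normal(a.shape))
        if self.additive_sd_volt > 0:
            out = out + self.additive_sd_volt * rng.standard_normal(a.shape)
        return out


@dataclass
class FfTrajectory:
    """Ground-truth fill-factor path with event annotations.

    ``extra_series_ohm`` holds the developing tissue resistance (zero for
    non-differentiating wells); ``events`` records continuous-time ground
    truth (medium change, plateau bounds, drawn plateau duration).
    """

    times_h: np.ndarray
    ff: np.ndarray
    extra_series_ohm: np.ndarray
    events: dict


def simulate_ff_trajectory(
    times_h,
    growth: GrowthScenario,
    differentiation: DifferentiationScenario | None = None,
    rng: np.random.Generator | None = None,
) -> FfTrajectory:
    """Fill-factor trajectory for one cell-seeded well.

    Without a differentiation scenario the trajectory is plain logistic
    growth.  With one, growth is frozen when ff crosses the medium-change
    level (70% by default), held for a drawn plateau duration, then risen
    linearly to ``final_coverage`` with the tissue resistance ramping in
    proportion to the coverage progress.
    """
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise DomainError("times_h must be a non-empty strictly increasing vector")
    t_days = t / 24.0
    if differentiation is None:
        ff = growth.ff_at(t_days)
        conf = growth.crossing_time_days(0.90 * growth.ff_max)
        return FfTrajectory(
            times_h=t, ff=ff, extra_series_ohm=np.zeros_like(ff),
            events={
                "condition": "undifferentiated",
                "confluence_time_h": None if conf is None else conf * 24.0,
            },
        )

    d = differentiation
    change_days = growth.crossing_time_days(d.medium_change_ff)
    if change_days is None:
        raise DomainError(
            f"growth scenario never reaches the medium-change level {d.medium_change_ff}"
        )
    rng = rng or np.random.default_rng()
    plateau_days = d.draw_plateau_days(rng)
    rise_start = change_days + plateau_days
    rise_span = (d.final_coverage - d.medium_change_ff) / d.rise_per_day
    rise_end = rise_start + rise_span

    ff = np.where(
        t_days <= change_days,
        growth.ff_at(t_days),
        np.where(
            t_days <= rise_start,
            d.medium_change_ff,
            np.minimum(
                d.medium_change_ff + d.rise_per_day * (t_days - rise_start),
                d.final_coverage,
            ),
        ),
    )
    progress = np.clip((ff - d.medium_change_ff) / (d.final_coverage - d.medium_change_ff), 0.0, 1.0)
    progress[t_days <= rise_start] = 0.0
    extra = d.tissue_resistance_ohm * progress
    return FfTrajectory(
        times_h=t, ff=ff, extra_series_ohm=extra,
        events={
            "condition": "differentiated",
            "medium_change_time_h": change_days * 24.0,
            "plateau_duration_days": plateau_days,
            "plateau_start_h": change_days * 24.0,
            "plateau_end_h": rise_start * 24.0,
            "rise_end_h": rise_end * 24.0,
        },
    )


@dataclass
class SyntheticStudy:
    """Generated traces plus full ground truth for one simulated study."""

    traces: pd.DataFrame  # columns: well, time_h, amplitude_v, freq_hz
    truth: dict
    layout: dict


class _AmplitudeForward:
    """Forward map (ff, extra series Ω) -> (a_osc, f_osc), memoised."""

    def __init__(self, params, bp, bio, cmp):
        self.params, self.bp, self.bio, self.cmp = params, bp, bio, cmp
        self._cache: dict[tuple[float, float], tuple[float, float]] = {}

    def __call__(self, ff: float, extra_ohm: float = 0.0) -> tuple[float, float]:
        key = (round(float(ff), 12), round(float(extra_ohm), 9))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = CellElectrodeModel(params=self.params, ff=float(ff))
        if extra_ohm > 0.0:
            Z = lambda w: model.impedance(w) + extra_ohm
        else:
            Z = model.impedance
        sol = solve_oscillation(self.bp, self.bio, self.cmp, Z)
        if not sol.converged:
            raise DomainError(f"oscillation solver failed at ff={ff:g}, extra={extra_ohm:g} Ω")
        self._cache[key] = (sol.a_osc, sol.f_osc)
        return self._cache[key]


def simulate_study(
    layout: dict | None = None,
    growth: GrowthScenario | None = None,
    differentiation: DifferentiationScenario | None = None,
    noise: NoiseSpec | None = None,
    params: InterfaceParams | None = None,
    bp: BandPassSpec | None = None,
    bio: BioimpedanceBlockSpec | None = None,
    cmp: ComparatorSpec | None = None,
    duration_days: float = 8.0,
    sample_minutes: float = 60.0,
    seed: int | None = None,
    forward: "_AmplitudeForward | None" = None,
) -> SyntheticStudy:
    """Simulate a full multi-well study.

    Every monitored well's fill-factor trajectory is mapped through the
    oscillation solver at the sampling cadence (60 min by default);
    medium-only wells sit at ff = 0 and unmonitored wells yield no trace.
    All randomness (plateau draws, noise) comes from one generator seeded
    by ``seed`` (or ``noise.seed`` when ``seed`` is None), so identical
    inputs give identical outputs.
    """
    layout = dict(DEFAULT_LAYOUT if layout is None else layout)
    if not layout:
        raise DomainError("layout must assign at least one well")
    bad = {c for c in layout.values() if c not in CONDITIONS}
    if bad:
        raise DomainError(f"unknown conditions in layout: {sorted(bad)}")
    growth = growth or GrowthScenario()
    differentiation = differentiation or DifferentiationScenario()
    noise = noise or NoiseSpec()
    params = params or InterfaceParams()
    bp = bp or BandPassSpec()
    bio = bio or BioimpedanceBlockSpec()
    cmp = cmp or ComparatorSpec()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    fwd = forward or _AmplitudeForward(params, bp, bio, cmp)

    n = int(math.floor(duration_days * 24.0 * 60.0 / sample_minutes)) + 1
    times_h = np.arange(n) * sample_minutes / 60.0

    rows = []
    truth_wells = {}
    for well in sorted(layout):
        condition = layout[well]
        if condition == "unmonitored":
            truth_wells[well] = {"condition": condition}
            continue
        if condition == "medium_only":
            traj = FfTrajectory(
                times_h=times_h,
                ff=np.zeros(n),
                extra_series_ohm=np.zeros(n),
                events={"condition": condition},
            )
        elif condition == "undifferentiated":
            traj = simulate_ff_trajectory(times_h, growth, None, rng)
        else:
            traj = simulate_ff_trajectory(times_h, growth, differentiation, rng)
        pairs = [fwd(f, x) for f, x in zip(traj.ff, traj.extra_series_ohm)]
        clean = np.array([p[0] for p in pairs])
        freqs = np.array([p[1] for p in pairs])
        noisy = noise.apply(clean, rng)
        rows.append(
            pd.DataFrame(
                {"well": well, "time_h": times_h, "amplitude_v": noisy, "freq_hz": freqs}
            )
        )
        truth_wells[well] = {
            **traj.events,
            "condition": condition,
            "ff_final": float(traj.ff[-1]),
            "amplitude_clean_final_v": float(clean[-1]),
        }

    traces = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["well", "time_h", "amplitude_v", "freq_hz"])
    )
    truth = {
        "seed": int(noise.seed if seed is None else seed),
        "duration_days": duration_days,
        "sample_minutes": sample_minutes,
        "growth": asdict(growth),
        "differentiation": asdict(differentiation),
        "noise": asdict(noise),
        "interface": asdict(params),
        "wells": truth_wells,
    }
    return SyntheticStudy(traces=traces, truth=truth, layout=layout)


def write_fixture(study: SyntheticStudy, out_dir) -> dict:
    """Write a study to ``traces.csv`` + ``truth.json`` + ``layout.json``.

    Returns the paths written.  Together the three files reproduce the
    study exactly (see :func:`load_fixture`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "traces.csv",
        "truth": out / "truth.json",
        "layout": out / "layout.json",
    }
    study.traces.to_csv(paths["traces"], index=False, float_format="%.17g")
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    paths["layout"].write_text(json.dumps(study.layout, indent=2, sort_keys=True))
    return paths


def load_fixture(out_dir) -> SyntheticStudy:
    """Reload a study written by :func:`write_fixture`."""
    out = Path(out_dir)
    traces = pd.read_csv(out / "traces.csv", float_precision="round_trip")
    for col in ("time_h", "amplitude_v", "freq_hz"):
        if col in traces:
            traces[col] = traces[col].astype(float)
    truth = json.loads((out / "truth.json").read_text())
    layout = json.loads((out / "layout.json").read_text())
    return SyntheticStudy(traces=traces, truth=truth, layout=layout)
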