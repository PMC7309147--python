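"""Per-well amplitude-trace analysis: segmentation, statistics, reporting.

A trace is the hourly oscillation amplitude of one well.  The pipeline

1. estimates the measurement-noise scale from medium-only wells,
2. locates the medium change (configured, or first 70%-confluence
   crossing via an amplitude calibration),
3. segments each cell well into growth / growth-arrest plateau /
   differentiation-rise phases with a slope-threshold window detector,
4. compares the amplitude gains of differentiated vs undifferentiated
   wells with an exact rank-sum permutation test, and
5. derives the interface-resistance table: per-well gap resistances for
   undifferentiated wells, their mean as the bulk resistance, and a
   tissue-resistance fit for each differentiated well.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import brentq as sp_brentq

from obtmon.circuit_models import DomainError, InterfaceParams
from obtmon.estimation import (
    CalibrationCurve,
    amplitude_to_ff,
    derive_rbulk,
    derive_rtissue,
    fit_interface_params,
)

__all__ = [
    "AmplitudeTrace",
    "PhaseSegmentation",
    "GroupComparison",
    "StudyReport",
    "TraceFormatError",
    "load_traces",
    "save_traces",
    "detect_confluence_threshold",
    "segment_phases",
    "estimate_noise_sd",
    "estimate_noise_rel",
    "exact_rank_sum",
    "group_compare",
    "build_table2",
    "plot_traces",
    "run_study_pipeline",
]

CONDITIONS = {"medium_only", "undifferentiated", "differentiated", "unmonitored"}


class TraceFormatError(ValueError):
    """Malformed trace file (missing columns, bad time axis...)."""


@dataclass
class AmplitudeTrace:
    """One well's oscillation-amplitude time series (hours / volts)."""

    well_id: str
    times_h: np.ndarray
    amplitudes_v: np.ndarray
    condition: str = "unmonitored"
    freq_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.amplitudes_v = np.asarray(self.amplitudes_v, dtype=float)
        if self.times_h.shape != self.amplitudes_v.shape or self.times_h.ndim != 1:
            raise TraceFormatError(f"{self.well_id}: time/amplitude vectors must match")
        if len(self.times_h) and np.any(np.diff(self.times_h) <= 0):
            bad = int(np.nonzero(np.diff(self.times_h) <= 0)[0][0]) + 1
            raise TraceFormatError(
                f"{self.well_id}: non-increasing time at row {bad} (t = {self.times_h[bad]:g} h)"
            )
        if self.condition not in CONDITIONS:
            raise TraceFormatError(f"{self.well_id}: unknown condition {self.condition!r}")

    @property
    def n(self) -> int:
        return len(self.times_h)

    def smoothed(self, window: int = 5) -> np.ndarray:
        """Centred median filter of the amplitudes (edge-nearest padding)."""
        if window <= 1 or self.n < window:
            return self.amplitudes_v.copy()
        return median_filter(self.amplitudes_v, size=window, mode="nearest")


def load_traces(path, condition_map: dict | None = None,
                expected_spacing_h: float = 1.0) -> list[AmplitudeTrace]:
    """Read per-well traces from CSV (``well,time_h,amplitude_v[,freq_hz]``).

    ``condition_map`` assigns each well its culture condition (defaults to
    ``unmonitored`` when absent).  Irregular sampling is tolerated with a
    warning when the median spacing deviates more than 10% from the
    expected cadence; duplicate or non-monotone timestamps are format
    errors naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"well", "time_h", "amplitude_v"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing columns {sorted(missing)}")
    condition_map = condition_map or {}
    traces = []
    for well, group in df.groupby("well", sort=True):
        t = group["time_h"].to_numpy(dtype=float)
        a = group["amplitude_v"].to_numpy(dtype=float)
        f = group["freq_hz"].to_numpy(dtype=float) if "freq_hz" in group else None
        trace = AmplitudeTrace(
            well_id=str(well), times_h=t, amplitudes_v=a,
            condition=condition_map.get(str(well), "unmonitored"), freq_hz=f,
        )
        if trace.n >= 2:
            spacing = float(np.median(np.diff(t)))
            if abs(spacing - expected_spacing_h) > 0.1 * expected_spacing_h:
                warnings.warn(
                    f"{well}: median sampling interval {spacing:.3g} h deviates "
                    f">10% from the expected {expected_spacing_h:g} h",
                    stacklevel=2,
                )
        traces.append(trace)
    return traces


def save_traces(traces, path) -> None:
    """Write traces back to the CSV schema accepted by :func:`load_traces`."""
    frames = []
    for tr in traces:
        d = {"well": tr.well_id, "time_h": tr.times_h, "amplitude_v": tr.amplitudes_v}
        if tr.freq_hz is not None:
            d["freq_hz"] = tr.freq_hz
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def detect_confluence_threshold(
    trace: AmplitudeTrace,
    calibration: CalibrationCurve,
    threshold_ff: float = 0.70,
    smooth_window: int = 5,
) -> float | None:
    """First time (hours) the fill-factor estimate crosses ``threshold_ff``.

    Amplitudes are median-smoothed, converted to fill factor through the
    calibration curve, and the crossing is linearly interpolated between
    samples.  Returns None if the threshold is never reached; if the trace
    starts at/above threshold the first timestamp is returned.
    """
    a = trace.smoothed(smooth_window)
    ffs = np.empty(trace.n)
    for i, amp in enumerate(a):
        try:
            ffs[i] = amplitude_to_ff(amp, calibration)
        except ValueError:
            ffs[i] = np.nan
    above = ffs >= threshold_ff
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(trace.times_h[0])
    f0, f1 = ffs[i - 1], ffs[i]
    if not np.isfinite(f0) or f1 == f0:
        return float(trace.times_h[i])
    frac = (threshold_ff - f0) / (f1 - f0)
    return float(trace.times_h[i - 1] + frac * (trace.times_h[i] - trace.times_h[i - 1]))


def estimate_noise_sd(traces) -> float:
    """Robust per-sample noise SD from flat (medium-only) traces.

    Uses the median absolute deviation of raw first differences, scaled
    to a Gaussian SD (×1.4826, ÷√2 per difference).
    """
    diffs = []
    for tr in traces:
        if tr.n >= 2:
            diffs.append(np.diff(tr.amplitudes_v))
    if not diffs:
        raise DomainError("need at least one trace with two samples to estimate noise")
    d = np.concatenate(diffs)
    mad = float(np.median(np.abs(d - np.median(d))))
    return mad * 1.4826 / math.sqrt(2.0)


def estimate_noise_rel(traces) -> float:
    """Relative (gain) noise: per-sample SD over mean amplitude of flat traces."""
    sd = estimate_noise_sd(traces)
    mean = float(np.mean(np.concatenate([tr.amplitudes_v for tr in traces if tr.n])))
    if mean <= 0:
        raise DomainError("flat traces must have positive mean amplitude")
    return sd / mean


@dataclass
class PhaseSegmentation:
    """Segmentation of one differentiating-well trace.

    Durations in days; slopes in volts/day; deltas in volts.  ``delta_growth``
    is the amplitude gained between the start of the trace and the medium
    change; ``delta_max`` between the start and the maximum (both on raw,
    unsmoothed data).
    """

    well_id: str
    medium_change_time_h: float
    plateau_start_h: float
    plateau_end_h: float
    plateau_duration_days: float
    diff_slope_v_per_day: float
    delta_growth_v: float
    delta_max_v: float


def _local_slopes(t_h: np.ndarray, a: np.ndarray, half_window_h: float) -> np.ndarray:
    """Centred least-squares slope (V/h) at each sample over ±half_window_h."""
    slopes = np.empty_like(a)
    for i in range(len(t_h)):
        m = np.abs(t_h - t_h[i]) <= half_window_h + 1e-9
        tt, aa = t_h[m], a[m]
        if len(tt) < 2:
            slopes[i] = 0.0
            continue
        tt = tt - tt.mean()
        denom = float(np.sum(tt * tt))
        slopes[i] = float(np.sum(tt * (aa - aa.mean())) / denom) if denom > 0 else 0.0
    return slopes


def segment_phases(
    trace: AmplitudeTrace,
    medium_change_time_h: float,
    noise_sd: float | None = None,
    noise_rel: float | None = None,
    slope_window_h: float = 6.0,
    smooth_window: int = 5,
    bound_factor: float = 3.0,
    max_gap: int = 3,
) -> PhaseSegmentation:
    """Slope-threshold segmentation of a differentiating-well trace.

    A sample after the medium change is 'flat' when the centred local
    least-squares slope of the raw trace stays within ``bound_factor``
    times the analytic SD of the windowed slope estimator at the local
    noise level.  The plateau is the first flat run starting near the
    medium change; isolated noisy excursions shorter than ``max_gap``
    samples do not end it.  The run is extended by half a slope window on
    each side to undo the estimator's edge bias.
    ``diff_slope`` is the least-squares slope from plateau end to the
    amplitude maximum.

    The noise scale can be given as an absolute per-sample SD
    (``noise_sd``, volts) or — better matched to instrument gain noise —
    as a fraction of the local amplitude (``noise_rel``); the pipeline
    passes the relative estimate from the medium-only wells.  If neither
    is given a robust first-difference estimate from the trace itself is
    used, adequate when drift per sample is below the noise.
    """
    if trace.n < 24:
        raise DomainError(f"{trace.well_id}: need >= 24 samples to segment")
    t, raw = trace.times_h, trace.amplitudes_v
    if not (t[0] <= medium_change_time_h <= t[-1]):
        raise DomainError(
            f"{trace.well_id}: medium change at {medium_change_time_h:g} h outside trace span"
        )
    if not np.any(t > medium_change_time_h):
        raise DomainError(f"{trace.well_id}: no samples after the medium change")
    smooth = trace.smoothed(smooth_window)
    if noise_rel is None and noise_sd is None:
        d = np.diff(raw)
        noise_sd = float(np.median(np.abs(d - np.median(d)))) * 1.4826 / math.sqrt(2.0)

    dt = float(np.median(np.diff(t)))
    w = max(int(round(slope_window_h / dt)) + 1, 3)  # points per slope window
    # SD of an OLS slope over w equispaced points: sigma * sqrt(12/(w(w^2-1)))/dt
    slope_factor = math.sqrt(12.0 / (w * (w * w - 1.0))) / dt
    if noise_rel is not None:
        sigma = noise_rel * np.abs(smooth)
    else:
        sigma = np.full(trace.n, float(noise_sd))
    eps = 1e-15 * max(1.0, float(np.max(np.abs(smooth))))
    bound = bound_factor * slope_factor * sigma + eps

    slopes = _local_slopes(t, raw, slope_window_h / 2.0)
    after = t >= medium_change_time_h - 1e-9
    flat = (np.abs(slopes) <= bound) & after

    idx = np.nonzero(flat)[0]
    if len(idx) == 0 or t[idx[0]] - medium_change_time_h > slope_window_h + 2.0 * dt:
        # no arrest near the medium change (a late flat region, e.g.
        # saturation at full coverage, is not the arrest plateau)
        plateau_start = plateau_end = medium_change_time_h
    else:
        first = last = idx[0]
        gap = 0
        for i in range(first + 1, trace.n):
            if flat[i]:
                last = i
                gap = 0
            else:
                gap += 1
                if gap >= max_gap:
                    break
        # edge-bias correction: the first/last flat samples sit up to half a
        # slope window inside the true plateau (their windows must clear the
        # neighbouring ramps).  The start extension is half a window plus
        # half a sample, clamped at the medium change.
        plateau_start = max(t[first] - slope_window_h / 2.0 - dt / 2.0, medium_change_time_h)
        # At the end, a non-zero noise bound lets windows that already dip
        # into the rise pass as flat.  For a window whose centre sits u*w
        # before a ramp of slope m, the expected OLS slope is m*phi(u) with
        # phi(u) = 1/2 - 3u/2 + 2u^3 (phi(1/2) = 0: window clear of the
        # ramp; phi(-1/2) = 1: fully inside).  Place the end where
        # m*phi(u) = bound, which reduces to the +w/2 correction as the
        # bound -> 0.
        ext = slope_window_h / 2.0
        rise_sel = (t > t[last]) & (t <= t[int(np.argmax(raw))])
        if np.sum(rise_sel) >= 2:
            m_rise = float(np.polyfit(t[rise_sel], smooth[rise_sel], 1)[0])
            frac = bound[last] / m_rise if m_rise > 0 else np.inf
            if 0.0 < frac < 0.5:
                u = float(sp_brentq(lambda u_: 0.5 - 1.5 * u_ + 2.0 * u_**3 - frac, 0.0, 0.5))
                ext = u * slope_window_h
        plateau_end = min(t[last] + ext, t[-1])
    duration_days = max(plateau_end - plateau_start, 0.0) / 24.0

    i0 = int(np.argmin(np.abs(t - t[0])))
    a_initial = raw[i0]
    a_change = float(np.interp(medium_change_time_h, t, raw))
    i_max = int(np.argmax(raw))
    delta_growth = a_change - a_initial
    delta_max = float(raw[i_max] - a_initial)

    rise = (t >= plateau_end) & (t <= t[i_max])
    if np.sum(rise) >= 2:
        coef = np.polyfit(t[rise] / 24.0, smooth[rise], 1)
        diff_slope = float(coef[0])
    else:
        diff_slope = 0.0

    return PhaseSegmentation(
        well_id=trace.well_id,
        medium_change_time_h=float(medium_change_time_h),
        plateau_start_h=float(plateau_start),
        plateau_end_h=float(plateau_end),
        plateau_duration_days=float(duration_days),
        diff_slope_v_per_day=diff_slope,
        delta_growth_v=float(delta_growth),
        delta_max_v=delta_max,
    )


# ---------------------------------------------------------------------------
# group statistics


def _rank_sum_stat(pooled_ranks: np.ndarray, idx) -> float:
    return float(np.sum(pooled_ranks[list(idx)]))


def exact_rank_sum(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum permutation test with midranks for ties.

    The statistic is the rank sum of the first sample; the p-value is the
    exact proportion of the ``C(n1+n2, n1)`` equally likely group
    assignments whose statistic deviates from the null mean at least as
    much as observed.  Enumerates all assignments, so intended for the
    small per-study group sizes (a normal approximation with tie
    correction takes over above 200k arrangements).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n1 + n2)
    sorted_vals = pooled[order]
    i = 0
    pos = 1.0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        midrank = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        pos += j - i + 1
        i = j + 1

    t_obs = float(np.sum(ranks[:n1]))
    mean = n1 * (n1 + n2 + 1) / 2.0
    dev_obs = abs(t_obs - mean)

    total = math.comb(n1 + n2, n1)
    if total > 200_000:  # pragma: no cover - large-sample fallback
        ties = pd.Series(pooled).value_counts().to_numpy()
        n = n1 + n2
        var = n1 * n2 / 12.0 * (n + 1 - np.sum(ties**3 - ties) / (n * (n - 1)))
        from scipy.stats import norm

        z = dev_obs / math.sqrt(var) if var > 0 else 0.0
        return t_obs, float(min(1.0, 2.0 * norm.sf(z)))

    count = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        if abs(_rank_sum_stat(ranks, idx) - mean) >= dev_obs - 1e-12:
            count += 1
    return t_obs, count / total


@dataclass
class GroupComparison:
    """Two-group comparison of amplitude gains."""

    method: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    group1_mean: float
    group1_sd: float
    group2_mean: float
    group2_sd: float
    n1: int
    n2: int


def group_compare(diff_deltas, undiff_deltas, alpha: float = 0.05,
                  method: str = "exact") -> GroupComparison:
    """Compare differentiated vs undifferentiated amplitude gains.

    ``method='exact'`` (default) runs the exact rank-sum permutation test;
    ``method='welch'`` runs Welch's unequal-variance t-test.
    """
    x = np.asarray(diff_deltas, dtype=float)
    y = np.asarray(undiff_deltas, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each group needs at least 2 observations")
    if method == "exact":
        stat, p = exact_rank_sum(x, y)
    elif method == "welch":
        from scipy.stats import ttest_ind

        res = ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise DomainError(f"unknown method {method!r}")
    return GroupComparison(
        method=method, statistic=stat, p_value=float(p),
        significant=bool(p < alpha), alpha=alpha,
        group1_mean=float(np.mean(x)), group1_sd=float(np.std(x, ddof=1)),
        group2_mean=float(np.mean(y)), group2_sd=float(np.std(y, ddof=1)),
        n1=len(x), n2=len(y),
    )


# ---------------------------------------------------------------------------
# resistance table


def build_table2(
    rgap_by_well: dict,
    diff_amplitudes_by_well: dict,
    interface: InterfaceParams | None = None,
    bp=None, bio=None, cmp=None,
    experiment: str | int = 1,
) -> dict:
    """Assemble the per-experiment resistance table.

    ``rgap_by_well`` maps each undifferentiated well to its fitted gap
    resistance; ``diff_amplitudes_by_well`` maps each differentiated well
    to its plateau amplitude observations (volts).  The bulk resistance is
    the mean of the gap resistances; a tissue resistance is fitted per
    differentiated well with the bulk value pinned.  Missing inputs yield
    a partial table with ``flags`` rather than an error.
    """
    interface = interface or InterfaceParams()
    flags = []
    table: dict = {"experiment": experiment, "R_gap_ohm": {}, "R_bulk_ohm": None,
                   "R_tissue_ohm": {}, "flags": flags}
    for well, rgap in sorted(rgap_by_well.items()):
        table["R_gap_ohm"][well] = float(rgap)
    if rgap_by_well:
        table["R_bulk_ohm"] = derive_rbulk(list(rgap_by_well.values()))
        if len(rgap_by_well) == 1:
            flags.append("R_bulk from a single undifferentiated well (n=1)")
    else:
        flags.append("no undifferentiated wells: R_bulk unavailable")
    for well, amps in sorted(diff_amplitudes_by_well.items()):
        if table["R_bulk_ohm"] is None:
            flags.append(f"{well}: R_tissue skipped (no R_bulk)")
            continue
        fit = derive_rtissue(amps, table["R_bulk_ohm"], interface, bp, bio, cmp)
        table["R_tissue_ohm"][well] = fit.params["R_tissue"]
        if not fit.converged:
            flags.append(f"{well}: R_tissue fit did not converge")
    return table


@dataclass
class StudyReport:
    """Full pipeline output for one study."""

    segmentations: dict
    comparison: GroupComparison | None
    table: dict
    noise_sd_v: float
    medium_change_times_h: dict
    deltas: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "noise_sd_v": self.noise_sd_v,
            "medium_change_times_h": self.medium_change_times_h,
            "segmentations": {k: asdict(v) for k, v in self.segmentations.items()},
            "comparison": None if self.comparison is None else asdict(self.comparison),
            "deltas": self.deltas,
            "table": self.table,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def table_frame(self) -> pd.DataFrame:
        rows = []
        exp = self.table.get("experiment", 1)
        for well, v in self.table.get("R_gap_ohm", {}).items():
            rows.append({"experiment": exp, "well": well, "quantity": "R_gap_ohm", "value": v})
        if self.table.get("R_bulk_ohm") is not None:
            rows.append({"experiment": exp, "well": "-", "quantity": "R_bulk_ohm",
                         "value": self.table["R_bulk_ohm"]})
        for well, v in self.table.get("R_tissue_ohm", {}).items():
            rows.append({"experiment": exp, "well": well, "quantity": "R_tissue_ohm", "value": v})
        return pd.DataFrame(rows)


def plot_traces(traces, segmentations: dict | None = None, path=None):
    """Plot amplitude traces with optional phase shading (matplotlib).

    Returns the figure; saves to ``path`` when given.  matplotlib is
    imported lazily so the pipeline has no hard plotting dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for tr in traces:
        ax.plot(tr.times_h / 24.0, tr.amplitudes_v * 1e3, label=f"{tr.well_id} ({tr.condition})")
        seg = (segmentations or {}).get(tr.well_id)
        if seg is not None:
            ax.axvspan(seg.plateau_start_h / 24.0, seg.plateau_end_h / 24.0,
                       alpha=0.15, color="grey")
    ax.set_xlabel("time [days]")
    ax.set_ylabel("oscillation amplitude [mV]")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def run_study_pipeline(
    traces,
    calibration: CalibrationCurve,
    interface: InterfaceParams | None = None,
    bp=None, bio=None, cmp=None,
    medium_change_times_h: dict | None = None,
    confluent_ff: float = 0.95,
    threshold_ff: float = 0.70,
    final_window_h: float = 24.0,
    alpha: float = 0.05,
    experiment: str | int = 1,
) -> StudyReport:
    """End-to-end analysis of a loaded study.

    Medium-change times default to the 70%-confluence crossing detected on
    each differentiated trace.  Gap resistances are fitted per
    undifferentiated well from its mean final-window amplitude assuming
    the confluent fill factor ``confluent_ff``; tissue resistances are
    fitted from the differentiated wells' final-window amplitudes.
    """
    interface = interface or InterfaceParams()
    traces = list(traces)
    medium = traces and [t for t in traces if t.condition == "medium_only"]
    cells = [t for t in traces if t.condition in ("undifferentiated", "differentiated")]
    if not cells:
        raise DomainError("no cell-seeded traces in study")
    noise_sd = estimate_noise_sd(medium) if medium else estimate_noise_sd(cells)
    noise_rel = estimate_noise_rel(medium) if medium else None

    change_times: dict = dict(medium_change_times_h or {})
    segmentations: dict = {}
    delta_max: dict = {}
    delta_growth: dict = {}
    for tr in cells:
        if tr.well_id not in change_times:
            detected = detect_confluence_threshold(tr, calibration, threshold_ff)
            change_times[tr.well_id] = detected if detected is not None else float(tr.times_h[-1])
        seg = segment_phases(tr, change_times[tr.well_id], noise_sd=noise_sd, noise_rel=noise_rel)
        segmentations[tr.well_id] = seg
        delta_max[tr.well_id] = seg.delta_max_v
        delta_growth[tr.well_id] = seg.delta_growth_v

    diff_wells = [t.well_id for t in cells if t.condition == "differentiated"]
    undiff_wells = [t.well_id for t in cells if t.condition == "undifferentiated"]
    comparison = None
    if len(diff_wells) >= 2 and len(undiff_wells) >= 2:
        comparison = group_compare(
            [delta_max[w] for w in diff_wells],
            [delta_max[w] for w in undiff_wells],
            alpha=alpha,
        )

    def final_amplitudes(tr):
        m = tr.times_h >= tr.times_h[-1] - final_window_h
        return tr.amplitudes_v[m]

    rgap_by_well = {}
    for tr in cells:
        if tr.condition != "undifferentiated":
            continue
        a_mean = float(np.mean(final_amplitudes(tr)))
        fit = fit_interface_params(
            [(confluent_ff, a_mean)], free=("R_gap",), start=interface,
            bp=bp, bio=bio, cmp=cmp,
        )
        rgap_by_well[tr.well_id] = fit.params["R_gap"]

    diff_amps = {
        tr.well_id: list(final_amplitudes(tr))
        for tr in cells
        if tr.condition == "differentiated"
    }
    table = build_table2(rgap_by_well, diff_amps, interface, bp, bio, cmp, experiment)

    return StudyReport(
        segmentations=segmentations,
        comparison=comparison,
        table=table,
        noise_sd_v=noise_sd,
        medium_change_times_h=change_times,
        deltas={"delta_max_v": delta_max, "delta_growth_v": delta_growth},
    )
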