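"""Fill-factor computation, amplitude inversion and parameter extraction.

The fill factor of a well follows from cell counts,
``ff = A_cell * N_cell / A_p`` (areas converted to µm² internally).
For on-line monitoring, :func:`build_calibration` tabulates the forward
oscillator prediction ``ff -> (f_osc, a_osc)`` and :func:`amplitude_to_ff`
inverts the amplitude channel by monotone interpolation plus root
refinement against the forward solver.

Circuit parameters are recovered from oscillation observations with
relative (log-residual) least squares: :func:`fit_interface_params` for the
proliferating-culture model and :func:`derive_rtissue` for the one-
dimensional tissue-resistance fit with ``R_bulk`` pinned to the mean gap
resistance of the undifferentiated wells (:func:`derive_rbulk`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

from obtmon.circuit_models import (
    CellElectrodeModel,
    DomainError,
    InterfaceParams,
    TissueModel,
)
from obtmon.obt_engine import (
    BandPassSpec,
    BioimpedanceBlockSpec,
    ComparatorSpec,
    solve_oscillation,
)

__all__ = [
    "UM2_PER_CM2",
    "FillFactorObservation",
    "CalibrationCurve",
    "CalibrationError",
    "RangeError",
    "FitResult",
    "fill_factor_from_counts",
    "build_calibration",
    "amplitude_to_ff",
    "fit_interface_params",
    "derive_rbulk",
    "derive_rtissue",
]

#: Unit conversion between well-scale (cm²) and cell-scale (µm²) areas.
UM2_PER_CM2 = 1e8


class RangeError(ValueError):
    """Measured amplitude falls outside the calibration range."""


class CalibrationError(ValueError):
    """Calibration curve unusable (non-monotone or failed grid point)."""


@dataclass(frozen=True)
class FillFactorObservation:
    """Cell-count based fill factor; ``overflow`` marks supra-confluent input."""

    N_cell: float
    A_cell_um2: float
    A_p_cm2: float
    ff: float
    overflow: bool


def fill_factor_from_counts(n_cell: float, a_cell_um2: float, a_p_cm2: float) -> FillFactorObservation:
    """Fill factor from a cell count and the mean single-cell area.

    ``ff = A_cell * N_cell / A_p`` with ``A_cell`` in µm² and ``A_p`` in
    cm² (converted internally).  Values above 1 are returned as-is with
    the ``overflow`` flag set — never silently clipped.
    """
    if a_p_cm2 <= 0 or not math.isfinite(a_p_cm2):
        raise DomainError("A_p must be strictly positive")
    if n_cell < 0 or a_cell_um2 < 0:
        raise DomainError("N_cell and A_cell must be non-negative")
    ff = a_cell_um2 * n_cell / (a_p_cm2 * UM2_PER_CM2)
    return FillFactorObservation(
        N_cell=n_cell, A_cell_um2=a_cell_um2, A_p_cm2=a_p_cm2,
        ff=ff, overflow=ff > 1.0,
    )


@dataclass
class CalibrationCurve:
    """Tabulated forward map ``ff -> (a_osc, f_osc)`` for one configuration."""

    ff: np.ndarray
    a_osc: np.ndarray
    f_osc: np.ndarray
    monotone: bool
    forward: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, dtype=float)
        self.a_osc = np.asarray(self.a_osc, dtype=float)
        self.f_osc = np.asarray(self.f_osc, dtype=float)
        if not (len(self.ff) == len(self.a_osc) == len(self.f_osc)):
            raise CalibrationError("calibration grids must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"ff": self.ff, "a_osc_volt": self.a_osc, "f_osc_hz": self.f_osc}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        a = df["a_osc_volt"].to_numpy()
        return cls(
            ff=df["ff"].to_numpy(),
            a_osc=a,
            f_osc=df["f_osc_hz"].to_numpy(),
            monotone=_strictly_monotone(a),
        )


def _strictly_monotone(a: np.ndarray) -> bool:
    if len(a) < 2:
        return True
    d = np.diff(a)
    return bool(np.all(d > 0) or np.all(d < 0))


def build_calibration(
    params: InterfaceParams,
    bp: BandPassSpec | None = None,
    bio: BioimpedanceBlockSpec | None = None,
    cmp: ComparatorSpec | None = None,
    ff_grid: np.ndarray | None = None,
    rs_slope: float = 0.0,
) -> CalibrationCurve:
    """Tabulate the oscillation solver over a fill-factor grid.

    Raises :class:`CalibrationError` naming the offending ``ff`` if the
    solver fails to converge at any grid point.  The returned curve keeps a
    reference to the forward amplitude function so that inversion can be
    refined beyond interpolation accuracy.
    """
    bp = bp or BandPassSpec()
    bio = bio or BioimpedanceBlockSpec()
    cmp = cmp or ComparatorSpec()
    if ff_grid is None:
        ff_grid = np.linspace(0.0, 1.0, 201)
    ff_grid = np.asarray(ff_grid, dtype=float)

    def forward(ff: float):
        model = CellElectrodeModel(params=params, ff=float(ff), rs_slope=rs_slope)
        return solve_oscillation(bp, bio, cmp, model.impedance)

    a = np.empty_like(ff_grid)
    f = np.empty_like(ff_grid)
    for i, ff in enumerate(ff_grid):
        sol = forward(ff)
        if not sol.converged:
            raise CalibrationError(f"oscillation solver did not converge at ff = {ff:g}")
        a[i], f[i] = sol.a_osc, sol.f_osc
    return CalibrationCurve(
        ff=ff_grid, a_osc=a, f_osc=f,
        monotone=_strictly_monotone(a),
        forward=lambda ff: forward(ff).a_osc,
    )


def amplitude_to_ff(
    a_measured: float,
    curve: CalibrationCurve,
    end_tolerance: float = 0.02,
    refine_tol: float = 1e-9,
) -> float:
    """Invert a measured oscillation amplitude to a fill-factor estimate.

    Monotone (PCHIP) interpolation of the calibration table provides the
    estimate; when the curve carries its forward solver the estimate is
    refined by root finding so the noiseless round trip is exact to
    ``refine_tol``.  Amplitudes outside the table are accepted within a
    tolerance band of ``end_tolerance`` times the amplitude span at either
    end (clamped to the endpoint); beyond that a :class:`RangeError` is
    raised.
    """
    if not curve.monotone:
        raise CalibrationError("calibration curve is not strictly monotone")
    if len(curve.ff) == 1:
        return float(curve.ff[0])
    a = np.asarray(curve.a_osc, dtype=float)
    ff = np.asarray(curve.ff, dtype=float)
    if a[-1] < a[0]:  # store increasing in amplitude
        a, ff = a[::-1], ff[::-1]
    lo, hi = a[0], a[-1]
    band = end_tolerance * (hi - lo)
    if a_measured < lo - band or a_measured > hi + band:
        raise RangeError(
            f"amplitude {a_measured:.6g} V outside calibration range "
            f"[{lo:.6g}, {hi:.6g}] V (±{band:.2g} V tolerance)"
        )
    if a_measured <= lo:
        return float(ff[0])
    if a_measured >= hi:
        return float(ff[-1])
    est = float(PchipInterpolator(a, ff)(a_measured))
    if curve.forward is None:
        return est
    # refine against the true forward map on a bracketing interval
    i = int(np.searchsorted(a, a_measured))
    lo_ff, hi_ff = sorted((float(ff[i - 1]), float(ff[i])))
    g = lambda x: curve.forward(x) - a_measured
    g_lo, g_hi = g(lo_ff), g(hi_ff)
    if g_lo == 0.0:
        return lo_ff
    if g_hi == 0.0:
        return hi_ff
    if g_lo * g_hi > 0:  # interpolation grid slightly off; fall back
        return est
    return float(brentq(g, lo_ff, hi_ff, xtol=refine_tol))


@dataclass
class FitResult:
    """Least-squares fit output with per-parameter standard errors."""

    params: dict
    stderr: dict
    cost: float
    converged: bool
    n_obs: int
    message: str = ""


def _osc_amplitude(params: InterfaceParams, ff: float, bp, bio, cmp, rs_slope=0.0) -> float:
    model = CellElectrodeModel(params=params, ff=ff, rs_slope=rs_slope)
    sol = solve_oscillation(bp, bio, cmp, model.impedance)
    if not sol.converged:
        raise CalibrationError(f"forward model did not oscillate at ff = {ff:g}")
    return sol.a_osc


def fit_interface_params(
    observations,
    free: tuple[str, ...] = ("R_gap",),
    start: InterfaceParams | None = None,
    bp: BandPassSpec | None = None,
    bio: BioimpedanceBlockSpec | None = None,
    cmp: ComparatorSpec | None = None,
    bounds_scale: tuple[float, float] = (1e-3, 1e3),
) -> FitResult:
    """Fit interface parameters to oscillation-amplitude observations.

    Parameters
    ----------
    observations : sequence of (ff, a_osc) pairs
        Known fill factors with measured oscillation amplitudes in volts.
    free : names of :class:`InterfaceParams` fields to fit
        Remaining fields are fixed at their ``start`` values.
    start : initial/fixed parameter values (package defaults if omitted).

    The loss is the log-residual ``log(a_model) - log(a_obs)`` so
    observations on different scales weigh equally.  Standard errors come
    from the Gauss-Newton covariance ``(J^T J)^{-1} * s²``.
    """
    bp = bp or BandPassSpec()
    bio = bio or BioimpedanceBlockSpec()
    cmp = cmp or ComparatorSpec()
    start = start or InterfaceParams()
    obs = [(float(ff), float(a)) for ff, a in observations]
    if len(obs) < len(free):
        raise DomainError(
            f"need at least {len(free)} observations to fit {len(free)} parameters, got {len(obs)}"
        )
    valid = {"R_s", "R_ct", "C_dl", "R_gap"}
    if not set(free) <= valid:
        raise DomainError(f"unknown free parameters: {set(free) - valid}")

    x0 = np.array([getattr(start, name) for name in free])
    lo = x0 * bounds_scale[0]
    hi = x0 * bounds_scale[1]

    def residuals(theta):
        p = replace(start, **{name: val for name, val in zip(free, theta)})
        return np.array(
            [math.log(_osc_amplitude(p, ff, bp, bio, cmp)) - math.log(a) for ff, a in obs]
        )

    res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    dof = max(len(obs) - len(free), 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        stderr = {name: float(math.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate(free)}
    except np.linalg.LinAlgError:  # pragma: no cover - singular Jacobian
        stderr = {name: math.nan for name in free}
    return FitResult(
        params={name: float(v) for name, v in zip(free, res.x)},
        stderr=stderr,
        cost=float(res.cost),
        converged=bool(res.success),
        n_obs=len(obs),
        message=res.message,
    )


def derive_rbulk(undiff_rgap_values) -> float:
    """Bulk resistance of the differentiated-tissue model.

    Defined as the arithmetic mean of the gap resistances fitted to the
    undifferentiated wells of the same experiment.
    """
    values = [float(v) for v in undiff_rgap_values]
    if not values:
        raise DomainError("derive_rbulk requires at least one R_gap value")
    if any(v <= 0 or not math.isfinite(v) for v in values):
        raise DomainError("R_gap values must be strictly positive and finite")
    return float(np.mean(values))


def derive_rtissue(
    amplitudes,
    r_bulk: float,
    interface: InterfaceParams | None = None,
    bp: BandPassSpec | None = None,
    bio: BioimpedanceBlockSpec | None = None,
    cmp: ComparatorSpec | None = None,
    include_R_s: bool = True,
    r_tissue_bounds: tuple[float, float] = (1e-3, 1e6),
) -> FitResult:
    """One-dimensional tissue-resistance fit in the full-coverage regime.

    ``R_bulk`` is held fixed (normally the :func:`derive_rbulk` value) and
    ``R_tissue`` is adjusted so the tissue-model oscillation amplitude
    matches the observed plateau amplitudes of the differentiated wells.
    """
    bp = bp or BandPassSpec()
    bio = bio or BioimpedanceBlockSpec()
    cmp = cmp or ComparatorSpec()
    interface = interface or InterfaceParams()
    amps = np.asarray([float(a) for a in amplitudes], dtype=float)
    if len(amps) == 0:
        raise DomainError("derive_rtissue requires at least one amplitude observation")
    if np.any(amps <= 0):
        raise DomainError("amplitudes must be strictly positive")

    def amplitude_of(r_tissue: float) -> float:
        model = TissueModel(
            R_bulk=r_bulk, R_tissue=r_tissue,
            R_ct=interface.R_ct, C_dl=interface.C_dl,
            include_R_s=include_R_s, R_s=interface.R_s,
        )
        sol = solve_oscillation(bp, bio, cmp, model.impedance)
        if not sol.converged:
            raise CalibrationError(f"tissue model did not oscillate at R_tissue = {r_tissue:g}")
        return sol.a_osc

    def residuals(theta):
        a = amplitude_of(theta[0])
        return np.log(a) - np.log(amps)

    x0 = np.array([max(r_tissue_bounds[0] * 10.0, 0.1 * r_bulk)])
    res = least_squares(
        residuals, x0, bounds=([r_tissue_bounds[0]], [r_tissue_bounds[1]]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    dof = max(len(amps) - 1, 1)
    s2 = 2.0 * res.cost / dof
    jtj = float(np.sum(res.jac * res.jac))
    stderr = math.sqrt(s2 / jtj) if jtj > 0 else math.nan
    return FitResult(
        params={"R_tissue": float(res.x[0])},
        stderr={"R_tissue": float(stderr)},
        cost=float(res.cost),
        converged=bool(res.success),
        n_obs=len(amps),
        message=res.message,
    )
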