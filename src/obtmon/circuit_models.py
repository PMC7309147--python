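"""Equivalent-circuit impedance models of cell-covered microelectrodes.

Two lumped models are provided:

* :class:`CellElectrodeModel` — a proliferating (undifferentiated) culture.
  The sensing electrode is split into an uncovered branch (``R_1 || C_1``)
  and a covered branch (``R_gap`` in series with ``R_2 || C_2``), both fed
  through the spreading/reference resistance ``R_s``.  The split is
  parameterised by the fill factor ``ff`` (fraction of electrode area
  covered by cells): ``R_1 = R_ct/(1-ff)``, ``C_1 = C_dl*(1-ff)``,
  ``R_2 = R_ct/ff``, ``C_2 = C_dl*ff``.

* :class:`TissueModel` — a differentiated tissue layer covering the whole
  electrode.  The gap resistance is replaced by two series resistances,
  ``R_bulk`` (electrode-to-tissue) and ``R_tissue`` (the tissue itself),
  in series with the interfacial ``R_ct || C_dl``.

All impedances are returned in ohms as complex numbers; angular frequency
``omega`` is in rad/s and may be a scalar or a numpy array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "ElectrodeGeometry",
    "InterfaceParams",
    "CellElectrodeModel",
    "TissueModel",
    "bare_electrode_impedance",
    "cell_electrode_impedance",
    "tissue_impedance",
    "consistency_check",
]


class DomainError(ValueError):
    """Raised when a physical parameter or frequency is out of domain."""


def _check_omega(omega) -> np.ndarray:
    w = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(w)):
        raise DomainError("omega must be finite")
    if np.any(w < 0):
        raise DomainError("omega must be non-negative")
    return w


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Geometry of the multi-electrode well.

    Defaults describe a well with ten circular 250 µm gold sensing
    electrodes in parallel and a total culture area of 0.8 cm².
    """

    n_electrodes: int = 10
    electrode_diameter_um: float = 250.0
    well_area_cm2: float = 0.8

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise DomainError("n_electrodes must be >= 1")
        if self.electrode_diameter_um <= 0:
            raise DomainError("electrode_diameter_um must be > 0")
        if self.well_area_cm2 <= 0:
            raise DomainError("well_area_cm2 must be > 0")
        if self.sensing_area_cm2 >= self.well_area_cm2:
            raise DomainError("sensing area must be smaller than the well area")

    @property
    def sensing_area_cm2(self) -> float:
        """Total sensing area: ``n`` circular electrodes, in cm²."""
        radius_cm = self.electrode_diameter_um * 1e-4 / 2.0
        return self.n_electrodes * math.pi * radius_cm**2


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class InterfaceParams:
    """Electrode–electrolyte interface primitives plus the cell-layer gap.

    Attributes
    ----------
    R_s : float
        Resistance between the cell layer and the reference electrode, Ω.
    R_ct : float
        Charge-transfer resistance of the fully bare sensing electrode, Ω.
    C_dl : float
        Double-layer capacitance of the fully bare sensing electrode, F.
    R_gap : float
        Resistance of the cleft between cell layer and electrode, Ω.
    """

    R_s: float = 200.0
    R_ct: float = 1e6
    C_dl: float = 120e-9
    R_gap: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("R_s", "R_ct", "C_dl", "R_gap"):
            _positive(name, getattr(self, name))

    @property
    def tau(self) -> float:
        """Interfacial time constant ``R_ct * C_dl`` in seconds."""
        return self.R_ct * self.C_dl


@dataclass(frozen=True)
class CellElectrodeModel:
    """Fill-factor-parameterised two-branch electrode model.

    ``rs_slope`` is an optional hook making ``R_s`` grow linearly with the
    fill factor (``R_s_eff = R_s + rs_slope * ff``); the default slope of
    zero keeps ``R_s`` coverage-independent.
    """

    params: InterfaceParams = field(default_factory=InterfaceParams)
    ff: float = 0.0
    rs_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ff <= 1.0) or not math.isfinite(self.ff):
            raise DomainError(f"ff must lie in [0, 1], got {self.ff!r}")

    # -- derived branch components -------------------------------------
    @property
    def R_1(self) -> float:
        """Uncovered-branch resistance, Ω (infinite at ff = 1)."""
        return self.params.R_ct / (1.0 - self.ff) if self.ff < 1.0 else math.inf

    @property
    def C_1(self) -> float:
        """Uncovered-branch capacitance, F."""
        return self.params.C_dl * (1.0 - self.ff)

    @property
    def R_2(self) -> float:
        """Covered-branch resistance, Ω (infinite at ff = 0)."""
        return self.params.R_ct / self.ff if self.ff > 0.0 else math.inf

    @property
    def C_2(self) -> float:
        """Covered-branch capacitance, F."""
        return self.params.C_dl * self.ff

    @property
    def R_s_eff(self) -> float:
        return self.params.R_s + self.rs_slope * self.ff

    def impedance(self, omega):
        """Complex impedance Z(jω) of the full cell–electrode network."""
        return cell_electrode_impedance(self, omega)

    def as_rational(self) -> tuple[np.ndarray, np.ndarray]:
        """Z(s) as a rational function ``(num, den)``, highest power first.

        The two branch time constants are both equal to ``tau = R_ct*C_dl``,
        which keeps the network second order:

        ``Z = R_s + R_1 (R_2 + R_gap (1+s tau)) /
             [(1+s tau)(R_1 + R_2 + R_gap (1+s tau))]``
        """
        p = self.params
        tau = p.tau
        rs = self.R_s_eff
        if self.ff <= 0.0 or self.ff >= 1.0:
            series = rs + (p.R_gap if self.ff >= 1.0 else 0.0)
            num = np.array([series * tau, series + p.R_ct])
            den = np.array([tau, 1.0])
            return num, den
        r1, r2, rg = self.R_1, self.R_2, p.R_gap
        # branch parallel combination over the common (1 + s*tau) pole
        n1 = np.array([r1 * rg * tau, r1 * (rg + r2)])
        d1 = np.convolve([tau, 1.0], [rg * tau, r1 + r2 + rg])
        num = np.polyadd(rs * d1, n1)
        return num, d1


@dataclass(frozen=True)
class TissueModel:
    """Differentiated-tissue model: series R_bulk + R_tissue + R_ct || C_dl."""

    R_bulk: float
    R_tissue: float
    R_ct: float = 1e6
    C_dl: float = 120e-9
    include_R_s: bool = False
    R_s: float = 200.0

    def __post_init__(self) -> None:
        for name in ("R_bulk", "R_tissue", "R_ct", "C_dl", "R_s"):
            _positive(name, getattr(self, name))

    @property
    def series_resistance(self) -> float:
        r = self.R_bulk + self.R_tissue
        return r + self.R_s if self.include_R_s else r

    def impedance(self, omega):
        return tissue_impedance(self, omega)

    def as_rational(self) -> tuple[np.ndarray, np.ndarray]:
        tau = self.R_ct * self.C_dl
        rser = self.series_resistance
        return np.array([rser * tau, rser + self.R_ct]), np.array([tau, 1.0])


def bare_electrode_impedance(params: InterfaceParams, omega):
    """Impedance of the bare electrode interface, ``R_ct || C_dl``.

    Returns ``R_ct / (1 + j*omega*R_ct*C_dl)``; exactly ``R_ct`` at DC.
    """
    w = _check_omega(omega)
    z = params.R_ct / (1.0 + 1j * w * params.tau)
    return complex(z) if np.isscalar(omega) else z


def cell_electrode_impedance(model: CellElectrodeModel, omega):
    """Impedance of the two-branch cell-covered electrode network.

    ``Z = R_s + Z_1 || (R_gap + Z_2)`` with ``Z_i = R_i || C_i``.  The
    covered branch is open at ``ff = 0`` and the uncovered branch is open
    at ``ff = 1``; both limits are handled exactly.
    """
    w = _check_omega(omega)
    p = model.params
    zb = p.R_ct / (1.0 + 1j * w * p.tau)
    if model.ff <= 0.0:
        z = model.R_s_eff + zb
    elif model.ff >= 1.0:
        z = model.R_s_eff + p.R_gap + zb
    else:
        z1 = zb / (1.0 - model.ff)
        z2 = zb / model.ff
        branch = p.R_gap + z2
        z = model.R_s_eff + z1 * branch / (z1 + branch)
    return complex(z) if np.isscalar(omega) else z


def tissue_impedance(model: TissueModel, omega):
    """Impedance of the differentiated-tissue circuit."""
    w = _check_omega(omega)
    tau = model.R_ct * model.C_dl
    z = model.series_resistance + model.R_ct / (1.0 + 1j * w * tau)
    return complex(z) if np.isscalar(omega) else z


def consistency_check(
    cell_model: CellElectrodeModel,
    tissue_model: TissueModel,
    freqs_hz: np.ndarray | None = None,
) -> dict:
    """Compare the fully covered cell model against the tissue model.

    When ``R_bulk + R_tissue`` equals ``R_gap`` and the interfacial
    parameters are shared, the two models are algebraically identical at
    ``ff = 1``; any mismatch shows up as a non-zero residual spectrum
    rather than an exception.

    Returns a dict with keys ``freqs_hz``, ``residual_ohm`` (per-frequency
    ``|Z_cell - Z_tissue|``) and ``max_residual_ohm``.
    """
    if cell_model.ff < 1.0:
        raise DomainError("consistency_check requires the cell model at ff = 1")
    if freqs_hz is None:
        freqs_hz = np.geomspace(1.0, 1e6, 61)
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float)
    resid = np.abs(cell_electrode_impedance(cell_model, w) - tissue_impedance(tissue_model, w))
    return {
        "freqs_hz": np.asarray(freqs_hz, dtype=float),
        "residual_ohm": resid,
        "max_residual_ohm": float(np.max(resid)),
    }


def spectrum_to_frame(z_func, freqs_hz: np.ndarray):
    """Tabulate an impedance function on a frequency grid.

    Returns a pandas DataFrame with columns ``freq_hz``, ``z_real_ohm``,
    ``z_imag_ohm`` (the CSV export schema for spectra).
    """
    import pandas as pd

    f = np.asarray(freqs_hz, dtype=float)
    z = z_func(2.0 * np.pi * f)
    return pd.DataFrame(
        {"freq_hz": f, "z_real_ohm": np.real(z), "z_imag_ohm": np.imag(z)}
    )
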