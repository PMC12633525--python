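"""Assay mathematics for ThDP-enzyme characterization.

Implements the deterministic calculations behind the kinetic and
spectroscopic characterization of DXPS variants:

* extinction coefficients from Trp/Tyr composition
  (ε = 5690·n_Trp + 1280·n_Tyr, M⁻¹cm⁻¹);
* Michaelis–Menten fitting (v = Vmax·S/(Km+S)) with deterministic
  initialization and Jacobian-based standard errors, plus the
  initial-slope route to kcat/Km;
* initial-velocity extraction from linear timecourse windows;
* densitometry band percentages (band/lane × 100);
* iminopyrimidine (IP) CD-signal percent change, in the printed
  convention ((CD_t − (CD_0 + ΔCD))/ΔCD)·100 and the alternative
  ((CD_t − CD_0)/ΔCD)·100, which differ by exactly 100;
* aminopyrimidine (AP) baseline normalization of PLThDP CD signals;
* apparent melting temperature as the maximum of the first derivative
  of the CD222-vs-temperature curve;
* fold-change summaries for narrative comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ExtinctionInput",
    "KineticModel",
    "Timecourse",
    "DensitometryRecord",
    "extinction_coefficient",
    "mm_velocity",
    "fit_michaelis_menten",
    "efficiency_from_slope",
    "initial_velocity",
    "band_density_percent",
    "ip_percent_change",
    "normalize_plthdp",
    "melting_temperature",
    "fold_change",
    "time_to_fraction",
]

TRP_COEF = 5690  # M⁻¹cm⁻¹ per Trp
TYR_COEF = 1280  # M⁻¹cm⁻¹ per Tyr


@dataclass(frozen=True)
class ExtinctionInput:
    n_trp: int
    n_tyr: int

    def __post_init__(self):
        if self.n_trp < 0 or self.n_tyr < 0:
            raise ValueError("residue counts must be non-negative")
        if self.n_trp != int(self.n_trp) or self.n_tyr != int(self.n_tyr):
            raise ValueError("residue counts must be integers")


def extinction_coefficient(x: ExtinctionInput) -> int:
    """Predicted monomer extinction coefficient at 280 nm (M⁻¹cm⁻¹)."""
    return TRP_COEF * int(x.n_trp) + TYR_COEF * int(x.n_tyr)


@dataclass
class KineticModel:
    """Michaelis–Menten parameters with enzyme-normalized quantities."""

    vmax: float  # signal or μM·s⁻¹
    km: float  # μM
    enzyme_conc: float  # μM
    vmax_se: float = np.nan
    km_se: float = np.nan

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("Vmax and Km must be positive")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")

    @property
    def kcat(self) -> float:
        """Turnover number, Vmax/[E] (s⁻¹ if vmax is μM·s⁻¹)."""
        return self.vmax / self.enzyme_conc

    @property
    def kcat_se(self) -> float:
        return self.vmax_se / self.enzyme_conc

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km from the fitted parameters."""
        return self.kcat / self.km


def mm_velocity(model: KineticModel, S) -> np.ndarray | float:
    """Michaelis–Menten initial velocity v = Vmax·S/(Km+S)."""
    S = np.asarray(S, dtype=float)
    v = model.vmax * S / (model.km + S)
    return float(v) if v.ndim == 0 else v


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(
    S: np.ndarray, v: np.ndarray, enzyme_conc: float
) -> KineticModel:
    """Nonlinear least-squares fit of initial velocities to v = Vmax·S/(Km+S).

    Deterministic initialization: Vmax₀ = max(v); Km₀ = the substrate
    concentration at which v first reaches Vmax₀/2, linearly
    interpolated.  Standard errors come from the Jacobian (covariance
    diagonal).  Warns if fewer than 3 distinct S values or if the data
    do not span the fitted Km.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise ValueError("S and v must be equal-length 1D arrays")
    if len(np.unique(S)) < 3:
        warnings.warn("fewer than 3 distinct substrate concentrations")
    if np.all(v <= 0):
        raise RuntimeError("all velocities are non-positive; fit cannot converge")
    order = np.argsort(S)
    Ss, vs = S[order], v[order]
    vmax0 = float(vs.max())
    half = vmax0 / 2.0
    above = np.nonzero(vs >= half)[0]
    i = int(above[0])
    if i == 0:
        km0 = max(float(Ss[0]), 1e-6)
    else:
        f = (half - vs[i - 1]) / (vs[i] - vs[i - 1])
        km0 = float(Ss[i - 1] + f * (Ss[i] - Ss[i - 1]))
        km0 = max(km0, 1e-6)
    try:
        popt, pcov = curve_fit(
            _mm, S, v, p0=[vmax0, km0], maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax_fit, km_fit = popt
    if vmax_fit <= 0 or km_fit <= 0:
        raise RuntimeError(
            f"fit produced non-positive parameters (Vmax={vmax_fit:g}, "
            f"Km={km_fit:g})"
        )
    se = np.sqrt(np.diag(pcov))
    if not (S.min() < km_fit < S.max()):
        warnings.warn(
            f"substrate range {S.min():g}-{S.max():g} does not span the "
            f"fitted Km ({km_fit:g})"
        )
    return KineticModel(
        vmax=float(vmax_fit),
        km=float(km_fit),
        enzyme_conc=enzyme_conc,
        vmax_se=float(se[0]),
        km_se=float(se[1]),
    )


def efficiency_from_slope(
    S: np.ndarray,
    v_over_E: np.ndarray,
    s_max: float,
) -> tuple[float, float]:
    """kcat/Km from the slope of the initial linear region of v/[E] vs [S].

    At S ≪ Km, v/[E] ≈ (kcat/Km)·S, so the ordinary least-squares slope
    over points with S ≤ ``s_max`` estimates the efficiency.  Returns
    (slope, intercept); the intercept is free and reported.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(v_over_E, dtype=float)
    mask = S <= s_max
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 points with S <= {s_max:g}; cannot fit a slope"
        )
    slope, intercept = np.polyfit(S[mask], y[mask], 1)
    return float(slope), float(intercept)


@dataclass
class Timecourse:
    """A signal versus time (s) or versus temperature (°C) for melts."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def initial_velocity(
    tc: Timecourse,
    window: tuple[float, float],
    conversion: float = 1.0,
) -> float:
    """Least-squares slope over a time window, times a conversion factor.

    For an NADPH-consumption readout (A340 decreasing) the conversion
    factor maps the negative absorbance slope to a positive
    product-formation rate, e.g. ``-1/(6220*path_cm) * 1e6`` for μM/s
    with the NADPH ε₃₄₀ = 6220 M⁻¹cm⁻¹.
    """
    lo, hi = window
    mask = (tc.times >= lo) & (tc.times <= hi)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 points in window {window}")
    slope = np.polyfit(tc.times[mask], tc.values[mask], 1)[0]
    return float(slope * conversion)


@dataclass(frozen=True)
class DensitometryRecord:
    band_density: float
    lane_density: float

    def __post_init__(self):
        if self.lane_density <= 0:
            raise ValueError("lane density must be positive")
        if not 0 <= self.band_density <= self.lane_density:
            raise ValueError("band density must lie within [0, lane density]")


def band_density_percent(rec: DensitometryRecord) -> float:
    """Band density as a percentage of the full-lane density."""
    return rec.band_density / rec.lane_density * 100.0


def ip_percent_change(
    cd_t: float, cd_0: float, delta: float, convention: str = "printed"
) -> float:
    """Percent change of the IP (LThDP) CD signal at 313 nm.

    ``printed``: ((CD_t − (CD_0 + ΔCD))/ΔCD)·100, which reads 0% when
    the signal is fully formed and −100% at t = 0.  ``relative``:
    ((CD_t − CD_0)/ΔCD)·100.  The two differ by exactly 100 for every
    input.
    """
    if delta == 0:
        raise ValueError("delta (total IP signal change) must be nonzero")
    if convention == "printed":
        return (cd_t - (cd_0 + delta)) / delta * 100.0
    if convention == "relative":
        return (cd_t - cd_0) / delta * 100.0
    raise ValueError(f"unknown convention {convention!r}")


def normalize_plthdp(tc: Timecourse, ap_reference: float) -> Timecourse:
    """Subtract the AP-tautomer baseline (mean of back-to-back scans at
    313 nm) from a PLThDP CD timecourse."""
    return Timecourse(
        times=tc.times.copy(),
        values=tc.values - ap_reference,
        channel=tc.channel,
    )


def melting_temperature(tc: Timecourse) -> float:
    """Apparent Tm: temperature of the maximal first derivative of the
    CD222-vs-temperature melt curve.

    Central finite differences give dCD/dT; the discrete maximum must
    be interior, and a 3-point quadratic through the surrounding points
    refines it.  Flat or monotone-derivative data (no interior peak)
    raise "no transition detected".
    """
    T, y = tc.times, tc.values
    if len(T) < 5:
        raise ValueError("need at least 5 points to locate a melting transition")
    d = np.gradient(y, T)
    if np.ptp(d) < 1e-12 * max(np.ptp(np.abs(y)), 1.0):
        raise ValueError("no transition detected: derivative is flat")
    i = int(np.argmax(d))
    if i == 0 or i == len(T) - 1:
        raise ValueError("no transition detected: derivative maximal at boundary")
    # quadratic through (T[i-1..i+1], d[i-1..i+1]); vertex = refined Tm
    a, b, c = np.polyfit(T[i - 1 : i + 2], d[i - 1 : i + 2], 2)
    if a >= 0:
        return float(T[i])
    return float(-b / (2 * a))


def fold_change(
    reference: float,
    variant: float,
    mode: str = "decrease",
    rounding: str = "none",
) -> float:
    """Fold change of a variant quantity relative to a reference.

    ``decrease`` → reference/variant; ``increase`` → variant/reference;
    ``rounding='nearest-int'`` rounds for narrative comparison.
    """
    if reference <= 0 or variant <= 0:
        raise ValueError("fold change requires positive inputs")
    if mode == "decrease":
        fold = reference / variant
    elif mode == "increase":
        fold = variant / reference
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if rounding == "nearest-int":
        return float(round(fold))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return float(fold)


def time_to_fraction(k: float, fraction: float = 0.95) -> float:
    """Time for an exponential-approach signal A·(1−e^(−kt)) to reach a
    given fraction of its amplitude: t = −ln(1−fraction)/k."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return float(-np.log(1.0 - fraction) / k)
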