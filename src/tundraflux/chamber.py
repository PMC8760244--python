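"""Closed dynamic chamber CO2 flux derivation.

A non-steady-state closed chamber accumulates (or depletes) CO2 over ~3
minutes; the concentration tendency is linearly interpolated and converted to
a surface flux with the ideal-gas chamber equation

    flux [umol m-2 s-1] = slope [ppm s-1] * Pr * V / (R * T_K * A)

where V is the effective headspace volume, A the collar area, Pr ambient
pressure and T_K ambient temperature.  NEE is measured with the transparent
chamber, ER with the darkened one, and GPP = NEE - ER under the convention
GPP <= 0, ER >= 0.  The IRGA is assumed to report dry mole fraction, so no
water-vapour dilution correction is applied; this is a documented
assumption of the conversion, not a hidden toggle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

R_GAS = 8.314462618  # J mol-1 K-1


@dataclass(frozen=True)
class ChamberGeometry:
    """Collar/chamber geometry in cm units as recorded in the field notes."""

    collar_area_cm2: float = 661.0
    chamber_height_cm: float = 10.0
    extra_headspace_cm3: float = 0.0

    def __post_init__(self) -> None:
        if self.collar_area_cm2 <= 0 or self.chamber_height_cm <= 0:
            raise ValueError("collar area and chamber height must be positive")
        if self.extra_headspace_cm3 < 0:
            raise ValueError("extra headspace cannot be negative")

    @property
    def headspace_volume_cm3(self) -> float:
        return self.collar_area_cm2 * self.chamber_height_cm + self.extra_headspace_cm3


@dataclass(frozen=True)
class AmbientState:
    ta_c: float = 10.0   # degC
    pr_hpa: float = 1013.0

    def __post_init__(self) -> None:
        if self.ta_c <= -273.15:
            raise ValueError("temperature below absolute zero")
        if self.pr_hpa <= 0:
            raise ValueError("pressure must be positive")


@dataclass
class ChamberTrace:
    """One chamber deployment: CO2 mole fraction vs time.

    mode: 'transparent' (NEE) or 'darkened' (ER).
    """

    timestamps: np.ndarray
    co2: np.ndarray
    geometry: ChamberGeometry
    ambient: AmbientState
    mode: str = "transparent"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.timestamps.shape != self.co2.shape:
            raise ValueError("timestamps and co2 must have equal length")
        if len(self.timestamps) < 5:
            raise ValueError("a trace needs at least 5 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.mode not in ("transparent", "darkened"):
            raise ValueError(f"unknown chamber mode {self.mode!r}")


@dataclass
class FluxEstimate:
    flux: float          # umol m-2 s-1
    slope: float         # ppm s-1
    r2: float
    mode: str
    qc_pass: bool
    warnings: list = field(default_factory=list)


def fit_concentration_slope(trace: ChamberTrace) -> tuple[float, float]:
    """OLS slope of CO2 vs time and the squared correlation of the fit.

    A trace with zero concentration variance has, by convention, r2 = 0.
    """
    t, c = trace.timestamps, trace.co2
    if np.var(t) == 0:
        raise ValueError("zero time variance in trace")
    if np.var(c) == 0:
        return 0.0, 0.0
    res = stats.linregress(t, c)
    return float(res.slope), float(res.rvalue**2)


def flux_to_slope(flux: float, geometry: ChamberGeometry, ambient: AmbientState) -> float:
    """ppm/s concentration tendency implied by a surface flux (inverse of
    :func:`slope_to_flux`)."""
    n_air = _moles_of_air(geometry, ambient)
    area_m2 = geometry.collar_area_cm2 * 1e-4
    return flux * area_m2 / n_air  # umol/s per mol air = umol/mol /s = ppm/s


def slope_to_flux(slope: float, geometry: ChamberGeometry, ambient: AmbientState) -> float:
    """Ideal-gas conversion of a ppm/s tendency to a flux in umol m-2 s-1."""
    n_air = _moles_of_air(geometry, ambient)
    area_m2 = geometry.collar_area_cm2 * 1e-4
    return slope * n_air / area_m2


def _moles_of_air(geometry: ChamberGeometry, ambient: AmbientState) -> float:
    vol_m3 = geometry.headspace_volume_cm3 * 1e-6
    pr_pa = ambient.pr_hpa * 100.0
    t_k = ambient.ta_c + 273.15
    return pr_pa * vol_m3 / (R_GAS * t_k)


def trace_to_flux(trace: ChamberTrace, r2_threshold: float = 0.70) -> FluxEstimate:
    """Full trace -> flux with quality control.

    Traces whose linear fit has r2 below the threshold are flagged
    (qc_pass=False), never dropped.
    """
    slope, r2 = fit_concentration_slope(trace)
    flux = slope_to_flux(slope, trace.geometry, trace.ambient)
    warnings = []
    qc = r2 >= r2_threshold
    if not qc:
        warnings.append(f"r2 {r2:.3f} below QC threshold {r2_threshold}")
    return FluxEstimate(flux=flux, slope=slope, r2=r2, mode=trace.mode, qc_pass=qc, warnings=warnings)


def partition_gpp(nee: FluxEstimate, er: FluxEstimate) -> FluxEstimate:
    """GPP = NEE - ER from a transparent/darkened pair at one point.

    Sign-convention violations (GPP > 0 or ER < 0) raise a warning flag on
    the result, not an error: field pairs occasionally cross zero by noise.
    """
    if nee.mode != "transparent":
        raise ValueError(f"NEE estimate must come from transparent mode, got {nee.mode!r}")
    if er.mode != "darkened":
        raise ValueError(f"ER estimate must come from darkened mode, got {er.mode!r}")
    gpp = nee.flux - er.flux
    warnings = []
    if gpp > 0:
        warnings.append("sign violation: GPP > 0")
    if er.flux < 0:
        warnings.append("sign violation: ER < 0")
    return FluxEstimate(
        flux=gpp,
        slope=nee.slope - er.slope,
        r2=min(nee.r2, er.r2),
        mode="partitioned",
        qc_pass=nee.qc_pass and er.qc_pass,
        warnings=warnings,
    )


def rosner_outliers(values, max_outliers: int = 3, alpha: float = 0.05) -> list[int]:
    """Generalized extreme studentized deviate (Rosner) outlier test.

    Iteratively removes the most extreme point, computing at step i the
    statistic R_i = max|x - mean|/sd and the critical value lambda_i from the
    Student-t distribution; the declared outliers are the first j points with
    j the largest step index at which R_j exceeds lambda_j.  Returns indices
    into ``values``.  Degenerate samples (sd = 0) yield no outliers.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Rosner test needs at least 3 values")
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    max_outliers = min(max_outliers, n - 2)

    remaining = np.arange(n)
    removed: list[int] = []
    r_stats: list[float] = []
    for i in range(1, max_outliers + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r_stats.append(dev[j] / sd)
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)

    n_outliers = 0
    for i, r in enumerate(r_stats, start=1):
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        t = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))
        if r > lam:
            n_outliers = i
    return removed[:n_outliers]
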