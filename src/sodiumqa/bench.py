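"""RF-coil bench-test and protocol arithmetic.

Implements the perturbing-sphere sensitivity measurement, quality factor,
Larmor frequency, Ernst angle, and scan-time bookkeeping used for periodic
coil quality control of a sodium birdcage coil.

Perturbing-sphere method: a small metallic sphere placed at the (zero
electric field) center of the coil shifts the resonance from f0 to f1 >= f0;
the coil sensitivity (B1 per sqrt(supplied power)) follows from

    eta = c_pol * sqrt( mu0 * (f1^2 - f0^2) / (pi^2 * Bw_eff * r_s^3 * f0^2) )

with c_pol = 1/2 for a linearly polarized coil and 1/sqrt(2) for quadrature
drive (the power splits between the two channels), Bw_eff the -3 dB
bandwidth -- doubled when the measurement is taken with the coil ports open.
The exact placement of the pi^2 and bandwidth factors is fixed here by
dimensional analysis (eta^2 must carry T^2 s / J); source renderings of the
formula are frequently garbled, so this module's closed form is the
documented contract, validated by its invariants (quadrature/linear ratio
sqrt(2), eta proportional to r_s^(-3/2), eta = 0 for f1 = f0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import pandas as pd

MU0 = 4.0e-7 * math.pi  # T m / A

__all__ = [
    "SphereMeasurement",
    "CoilSensitivityResult",
    "perturbing_sphere_sensitivity",
    "quality_factor",
    "larmor_frequency",
    "ernst_angle",
    "scan_time",
    "format_scan_time",
    "sensitivity_from_log",
]


@dataclass(frozen=True)
class SphereMeasurement:
    """One perturbing-sphere bench measurement (SI units: Hz, m)."""

    f0: float
    f1: float
    bandwidth_measured: float
    sphere_radius: float
    polarization: str = "quadrature"   # or "linear"
    ports_open: bool = True

    def __post_init__(self) -> None:
        if self.f1 < self.f0:
            raise ValueError(
                "f1 < f0: a metallic sphere raises the resonance frequency; "
                "check the measurement order")
        if self.bandwidth_measured <= 0:
            raise ValueError("bandwidth must be positive")
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.polarization not in ("linear", "quadrature"):
            raise ValueError("polarization must be 'linear' or 'quadrature'")


@dataclass
class CoilSensitivityResult:
    """Coil sensitivity eta = B1/sqrt(P) in T W^(-1/2)."""

    eta: float
    polarization_factor: float
    effective_bandwidth: float
    measurement: SphereMeasurement


def perturbing_sphere_sensitivity(m: SphereMeasurement) -> CoilSensitivityResult:
    """Coil sensitivity from a perturbing-sphere frequency-shift measurement."""
    c_pol = 0.5 if m.polarization == "linear" else 1.0 / math.sqrt(2.0)
    bw_eff = 2.0 * m.bandwidth_measured if m.ports_open else m.bandwidth_measured
    eta_sq = MU0 * (m.f1 ** 2 - m.f0 ** 2) / (
        math.pi ** 2 * bw_eff * m.sphere_radius ** 3 * m.f0 ** 2)
    eta = c_pol * math.sqrt(eta_sq)
    return CoilSensitivityResult(eta=eta, polarization_factor=c_pol,
                                 effective_bandwidth=bw_eff, measurement=m)


def quality_factor(f0: float, bandwidth: float) -> float:
    """Unloaded quality factor Q = f0 / (-3 dB bandwidth)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return f0 / bandwidth


def larmor_frequency(gamma_mhz_per_t: float, b0: float) -> float:
    """Larmor frequency in MHz (gamma in MHz/T, B0 in T)."""
    if b0 <= 0:
        raise ValueError("B0 must be positive")
    return gamma_mhz_per_t * b0


def ernst_angle(t1: float, tr: float) -> float:
    """Ernst angle arccos(exp(-TR/T1)) in degrees.

    The flip angle maximizing the spoiled gradient-echo steady-state signal;
    agrees with a numerical argmax of the steady-state amplitude to < 0.1
    degree.
    """
    if t1 <= 0 or tr <= 0:
        raise ValueError("T1 and TR must be positive")
    return math.degrees(math.acos(math.exp(-tr / t1)))


def scan_time(n_spokes: int, tr: float, n_averages: int = 1) -> float:
    """Total acquisition time in seconds: n_spokes * TR * n_averages."""
    if n_spokes <= 0 or tr <= 0 or n_averages <= 0:
        raise ValueError("all inputs must be positive")
    return n_spokes * tr * n_averages


def format_scan_time(seconds: float, style: str = "mm:ss") -> str:
    """'mm:ss' (seconds floored) or nearest-integer 'minutes'."""
    if style == "mm:ss":
        total = int(seconds)  # floor
        return f"{total // 60}:{total % 60:02d}"
    if style == "minutes":
        return f"{round(seconds / 60.0):d} min"
    raise ValueError(f"unknown style {style!r}")


def sensitivity_from_log(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD sensitivity over repeated bench measurements.

    Expects columns f0, f1, bw, radius, mode (and optionally ports_open);
    returns one row per (radius, mode) group with eta_mean, eta_sd, n.
    """
    required = {"f0", "f1", "bw", "radius", "mode"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement log missing columns: {sorted(missing)}")
    etas = []
    for _, row in table.iterrows():
        m = SphereMeasurement(
            f0=float(row["f0"]), f1=float(row["f1"]),
            bandwidth_measured=float(row["bw"]),
            sphere_radius=float(row["radius"]),
            polarization=str(row["mode"]),
            ports_open=bool(row.get("ports_open", True)))
        etas.append(perturbing_sphere_sensitivity(m).eta)
    out = table.copy()
    out["eta"] = etas
    grouped = out.groupby(["radius", "mode"])["eta"].agg(
        eta_mean="mean", eta_sd="std", n="count").reset_index()
    return grouped
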