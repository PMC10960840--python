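"""CCS calibration for travelling-wave (TWIMS) and trapped (TIMS) ion mobility.

TWIMS drift times are first corrected for the post-mobility flight time,

    t_D' = t_D - C * sqrt(m/z) / 1000,

with C the EDC delay coefficient (instrument constant, 1.41 here), and
reference CCS values are reduced by charge and reduced mass,

    CCS' = CCS * sqrt(mu) / z,      mu = m * M / (m + M),

where m is the ion mass and M the drift-gas molecule mass (N2).  The TWIMS
calibration is then a log-log straight line ln(CCS') = lnA + B * ln(t_D'),
fitted to a dextran calibrant ladder by unweighted least squares.  TIMS
reports reversed reduced mobility 1/K0 directly; per the Mason-Schamp
relation CCS' is proportional to 1/K0, so the TIMS calibration is a straight
line through the origin (an affine variant is available).

Conventions: the ion mass entering mu is the deprotonated ion's mass
m = mz * z (switchable to the neutral-equivalent m = mz*z + z*1.007276); the
gas mass defaults to the average N2 molecular mass 28.0134 Da (switchable to
monoisotopic 28.00615).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N2_AVERAGE",
    "N2_MONOISOTOPIC",
    "CalibrantPoint",
    "TWIMSCalibration",
    "TIMSCalibration",
    "correct_drift_time",
    "reduced_ccs",
    "inverse_reduced_ccs",
    "fit_twims",
    "twims_ccs",
    "fit_tims",
    "tims_ccs",
    "cross_instrument_std",
    "read_calibrants_csv",
]

N2_AVERAGE = 28.0134
N2_MONOISOTOPIC = 28.00615
PROTON = 1.007276
DEFAULT_EDC = 1.41


@dataclass(frozen=True)
class CalibrantPoint:
    """One calibrant species: measured drift time (TWIMS) or 1/K0 (TIMS)."""

    species: str
    mz: float
    z: int
    measured: float  # t_D in ms, or 1/K0 in V*s/cm^2
    reference_ccs: float  # Å²

    def __post_init__(self) -> None:
        if self.reference_ccs <= 0:
            raise ValueError("reference CCS must be positive")
        if self.measured <= 0:
            raise ValueError("measured value must be positive")


def correct_drift_time(t_d: float, mz: float, C: float = DEFAULT_EDC) -> float:
    """EDC-corrected drift time t_D' = t_D - C*sqrt(m/z)/1000 (ms)."""
    t = t_d - C * math.sqrt(mz) / 1000.0
    if t <= 0:
        raise ValueError(
            f"corrected drift time non-positive ({t:.4g} ms): t_D below EDC delay"
        )
    return t


def _ion_mass(mz: float, z: int, use_neutral: bool) -> float:
    m = mz * z
    if use_neutral:
        m += z * PROTON  # neutral-equivalent mass of a deprotonated ion
    return m


def reduced_ccs(
    ccs: float, mz: float, z: int, gas_mass: float = N2_AVERAGE,
    use_neutral_mass: bool = False,
) -> float:
    """Charge/reduced-mass-corrected CCS' = CCS * sqrt(mu) / z."""
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    m = _ion_mass(mz, z, use_neutral_mass)
    mu = m * gas_mass / (m + gas_mass)
    return ccs * math.sqrt(mu) / z


def inverse_reduced_ccs(
    ccs_prime: float, mz: float, z: int, gas_mass: float = N2_AVERAGE,
    use_neutral_mass: bool = False,
) -> float:
    """Invert :func:`reduced_ccs`: CCS = CCS' * z / sqrt(mu)."""
    m = _ion_mass(mz, z, use_neutral_mass)
    mu = m * gas_mass / (m + gas_mass)
    return ccs_prime * z / math.sqrt(mu)


@dataclass
class TWIMSCalibration:
    lnA: float
    B_exp: float
    edc_C: float = DEFAULT_EDC
    gas_mass: float = N2_AVERAGE
    use_neutral_mass: bool = False
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.B_exp <= 0:
            raise ValueError("TWIMS exponent must be positive")


@dataclass
class TIMSCalibration:
    slope: float  # Å² * cm² / (V*s)
    intercept: float = 0.0
    gas_mass: float = N2_AVERAGE
    use_neutral_mass: bool = False
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("TIMS slope must be positive")


def fit_twims(
    points: list[CalibrantPoint],
    edc_C: float = DEFAULT_EDC,
    gas_mass: float = N2_AVERAGE,
    use_neutral_mass: bool = False,
) -> TWIMSCalibration:
    """Unweighted least-squares fit of ln(CCS') vs ln(t_D')."""
    if len(points) < 3:
        raise ValueError(f"TWIMS calibration needs >=3 points, got {len(points)}")
    x = np.array([
        math.log(correct_drift_time(p.measured, p.mz, edc_C)) for p in points
    ])
    y = np.array([
        math.log(reduced_ccs(p.reference_ccs, p.mz, p.z, gas_mass,
                             use_neutral_mass))
        for p in points
    ])
    if np.ptp(x) == 0:
        raise ValueError("calibrant drift times do not span distinct values")
    B, lnA = np.polyfit(x, y, 1)
    resid = y - (lnA + B * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return TWIMSCalibration(
        lnA=float(lnA), B_exp=float(B), edc_C=edc_C, gas_mass=gas_mass,
        use_neutral_mass=use_neutral_mass, r_squared=r2, residuals=resid,
    )


def twims_ccs(t_d: float, mz: float, z: int, cal: TWIMSCalibration) -> float:
    """CCS (Å²) of an analyte from its TWIMS drift time."""
    td_prime = correct_drift_time(t_d, mz, cal.edc_C)
    ccs_prime = math.exp(cal.lnA + cal.B_exp * math.log(td_prime))
    return inverse_reduced_ccs(ccs_prime, mz, z, cal.gas_mass,
                               cal.use_neutral_mass)


def fit_tims(
    points: list[CalibrantPoint],
    fit_intercept: bool = False,
    gas_mass: float = N2_AVERAGE,
    use_neutral_mass: bool = False,
) -> TIMSCalibration:
    """Least-squares fit CCS' = slope * (1/K0) [+ intercept].

    The default constrains the intercept to 0 (Mason-Schamp
    proportionality); set ``fit_intercept=True`` for the affine variant.
    """
    if len(points) < 2:
        raise ValueError(f"TIMS calibration needs >=2 points, got {len(points)}")
    x = np.array([p.measured for p in points])
    y = np.array([
        reduced_ccs(p.reference_ccs, p.mz, p.z, gas_mass, use_neutral_mass)
        for p in points
    ])
    if fit_intercept:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return TIMSCalibration(
        slope=float(slope), intercept=float(intercept), gas_mass=gas_mass,
        use_neutral_mass=use_neutral_mass, r_squared=r2, residuals=resid,
    )


def tims_ccs(inv_k0: float, mz: float, z: int, cal: TIMSCalibration) -> float:
    """CCS (Å²) of an analyte from its reversed mobility 1/K0."""
    ccs_prime = cal.slope * inv_k0 + cal.intercept
    return inverse_reduced_ccs(ccs_prime, mz, z, cal.gas_mass,
                               cal.use_neutral_mass)


def tims_inv_k0(ccs: float, mz: float, z: int, cal: TIMSCalibration) -> float:
    """Forward model: 1/K0 at which an ion of the given CCS elutes."""
    ccs_prime = reduced_ccs(ccs, mz, z, cal.gas_mass, cal.use_neutral_mass)
    return (ccs_prime - cal.intercept) / cal.slope


def cross_instrument_std(
    pairs: list[tuple[float, float]]
) -> tuple[list[float], float]:
    """Per-pair %STD between two instruments' CCS values, and the maximum.

    For a pair (a, b) the sample standard deviation (n-1 denominator) is
    |a - b| / sqrt(2); the %STD divides by the pair mean and multiplies by
    100.  Symmetric in a and b.
    """
    out = []
    for a, b in pairs:
        if a <= 0 or b <= 0:
            raise ValueError("CCS values must be positive")
        out.append(abs(a - b) / math.sqrt(2.0) / ((a + b) / 2.0) * 100.0)
    return out, max(out) if out else float("nan")


def read_calibrants_csv(path: str) -> list[CalibrantPoint]:
    """Read a calibrant table (columns species, mz, z, measured, reference_ccs)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"species", "mz", "z", "measured", "reference_ccs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibrant table missing columns: {sorted(missing)}")
    return [
        CalibrantPoint(
            species=str(r.species), mz=float(r.mz), z=int(r.z),
            measured=float(r.measured), reference_ccs=float(r.reference_ccs),
        )
        for r in df.itertuples()
    ]
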