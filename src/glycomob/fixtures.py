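"""Deterministic synthetic data generators.

Every generator takes an explicit seed (no global RNG state) and returns its
ground truth next to the data, so tests compare against the truth rather
than re-deriving it.  Intensity noise is multiplicative log-normal, the
usual heteroscedastic behaviour of electrospray ion counts; detector
baseline, isotope envelopes and chimeric spectra are deliberately not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem
from .calibration import TIMSCalibration, TWIMSCalibration, CalibrantPoint, \
    correct_drift_time, reduced_ccs, tims_inv_k0
from .fragments import generate_fragments, DEFAULT_KINDS
from .mobilogram import MobilityFrame
from .structures import parse_structure

__all__ = [
    "TruthRecord",
    "synth_frame",
    "synth_spectrum",
    "synth_calibrants",
    "DEXTRAN_LIKE_MZ",
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic mobility species."""

    composition: str  # canonical composition string
    structure: str | None
    z: int
    centroid: float  # mobility coordinate (1/K0 or t_D)
    sigma: float
    abundance: float  # total area of the Gaussian profile
    sample: str = "synthetic"

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def synth_frame(
    truth: list[TruthRecord],
    noise_rel: float,
    seed: int,
    scan_range: tuple[float, float] = (0.6, 1.6),
    grid_step: float = 0.0005,
    coordinate: str = "inv_k0",
) -> MobilityFrame:
    """Simulate an accumulated IMS-MS frame from truth records.

    Each record contributes a Gaussian mobility profile (area = abundance)
    at the theoretical m/z of its composition and charge, sampled on a fixed
    mobility grid; intensities get multiplicative log-normal noise of
    relative level *noise_rel*.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = scan_range
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    mzs, mobs, intens = [], [], []
    for rec in truth:
        comp = chem.Composition.parse(rec.composition)
        target_mz = chem.mz(comp, rec.z)
        if not (lo <= rec.centroid <= hi):
            raise ValueError(
                f"truth centroid {rec.centroid} outside scan range {scan_range}"
            )
        amp = rec.abundance / (rec.sigma * np.sqrt(2 * np.pi))
        profile = amp * np.exp(-0.5 * ((grid - rec.centroid) / rec.sigma) ** 2)
        if noise_rel > 0:
            sigma_ln = np.sqrt(np.log1p(noise_rel**2))
            profile = profile * rng.lognormal(
                -0.5 * sigma_ln**2, sigma_ln, size=profile.shape
            )
        keep = profile > 0
        mzs.append(np.full(keep.sum(), target_mz))
        mobs.append(grid[keep])
        intens.append(profile[keep])
    return MobilityFrame(
        np.concatenate(mzs) if mzs else np.empty(0),
        np.concatenate(mobs) if mobs else np.empty(0),
        np.concatenate(intens) if intens else np.empty(0),
        coordinate,
        scan_range,
    )


def synth_spectrum(
    structure_text: str,
    kinds: frozenset[str] = DEFAULT_KINDS,
    noise_rel: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], list]:
    """Simulate a negative-mode CID peak list for a structure.

    Fragment m/z come from :func:`glycomob.fragments.generate_fragments`;
    intensities are unit with multiplicative log-normal noise; each peak is
    dropped independently with probability *dropout*.  Returns the peak list
    and the underlying fragment truth.
    """
    rng = np.random.default_rng(seed)
    s = parse_structure(structure_text)
    frags = generate_fragments(s, kinds=kinds)
    peaks: list[tuple[float, float]] = []
    for f in frags:
        if dropout > 0 and rng.random() < dropout:
            continue
        inten = 1.0
        if noise_rel > 0:
            sigma_ln = np.sqrt(np.log1p(noise_rel**2))
            inten *= rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
        peaks.append((f.mz_1minus, inten))
    return peaks, frags


#: Singly charged dextran-ladder-like m/z values (Glc_n alditol-free ladder
#: spacing of one Hex, spanning the O-glycan m/z range).
DEXTRAN_LIKE_MZ = [
    341.11, 503.16, 665.21, 827.27, 989.32, 1151.37, 1313.42, 1475.48,
]


def synth_calibrants(
    mode: str,
    true_params: dict,
    n_points: int = 8,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> list[CalibrantPoint]:
    """Generate calibrant points from a forward calibration model.

    ``mode="twims"``: *true_params* holds ``lnA``, ``B_exp`` (and optionally
    ``edc_C``, ``gas_mass``); measured drift times are computed so that the
    log-log model reproduces reference CCS values spaced over 150-400 Å².
    ``mode="tims"``: *true_params* holds ``slope`` (and optionally
    ``intercept``, ``gas_mass``); measured values are 1/K0.
    Multiplicative noise of level *noise_rel* on the measured coordinate.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    mzs = np.array(DEXTRAN_LIKE_MZ)
    if n_points > len(mzs):
        mzs = np.linspace(300.0, 1500.0, n_points)
    mzs = mzs[:n_points]
    ccs = np.linspace(150.0, 400.0, n_points)
    gas = true_params.get("gas_mass", 28.0134)
    points = []
    for i, (mz_i, ccs_i) in enumerate(zip(mzs, ccs)):
        ccs_prime = reduced_ccs(float(ccs_i), float(mz_i), 1, gas)
        if mode == "twims":
            lnA, b = true_params["lnA"], true_params["B_exp"]
            edc = true_params.get("edc_C", 1.41)
            td_prime = np.exp((np.log(ccs_prime) - lnA) / b)
            measured = td_prime + edc * np.sqrt(mz_i) / 1000.0
        elif mode == "tims":
            cal = TIMSCalibration(
                slope=true_params["slope"],
                intercept=true_params.get("intercept", 0.0),
                gas_mass=gas,
            )
            measured = tims_inv_k0(float(ccs_i), float(mz_i), 1, cal)
        else:
            raise ValueError(f"unknown calibration mode {mode!r}")
        if noise_rel > 0:
            measured *= rng.lognormal(
                -0.5 * np.log1p(noise_rel**2), np.sqrt(np.log1p(noise_rel**2))
            )
        points.append(
            CalibrantPoint(
                species=f"dextran_{i + 2}", mz=float(mz_i), z=1,
                measured=float(measured), reference_ccs=float(ccs_i),
            )
        )
    return points
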