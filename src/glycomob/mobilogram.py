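"""Extracted ion mobilograms and Gaussian peak deconvolution.

An ion-mobility frame is a set of (m/z, mobility, intensity) triples; an
extracted ion mobilogram (EIM) sums the intensity of all triples within an
m/z window onto a mobility grid.  Arrival-time / mobility distributions are
modelled as sums of Gaussians; the number of components is chosen by the
Bayesian information criterion and components below a noise-derived
amplitude threshold (median absolute deviation of the fit residuals) are
discarded.  Peak areas (A * sigma * sqrt(2*pi)) quantify isomer abundance;
relative areas are reported as percent of the summed isomer area at one m/z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "MobilityFrame",
    "EIM",
    "MobilityPeak",
    "extract_eim",
    "detect_peaks",
    "relative_areas",
    "charge_gate",
    "resolving_power",
    "read_frame_csv",
    "read_frame_mzml",
    "DeconvolutionError",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class MobilityFrame:
    """Accumulated IMS-MS frame as parallel arrays of triples."""

    mz: np.ndarray
    mobility: np.ndarray
    intensity: np.ndarray
    coordinate: str = "inv_k0"  # or "drift_time"
    scan_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.mobility = np.asarray(self.mobility, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.mz) == len(self.mobility) == len(self.intensity)):
            raise ValueError("triple arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.scan_range is None and len(self.mobility):
            self.scan_range = (float(self.mobility.min()),
                               float(self.mobility.max()))


@dataclass
class EIM:
    """Extracted ion mobilogram on a strictly increasing mobility grid."""

    target_mz: float
    tol: float
    grid: np.ndarray
    intensity: np.ndarray
    coordinate: str = "inv_k0"
    empty: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.grid) > 1 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("mobility grid must be strictly increasing")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class MobilityPeak:
    """One fitted Gaussian component of an EIM."""

    centroid: float  # mobility units (or Å² once calibrated)
    sigma: float
    amplitude: float
    ccs: float | None = None
    sigma_ccs: float | None = None
    relative_area: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * _SQRT2PI


class DeconvolutionError(RuntimeError):
    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


def extract_eim(
    frame: MobilityFrame,
    mz: float,
    tol: float = 0.05,
    tol_is_ppm: bool = False,
    n_bins: int | None = None,
) -> EIM:
    """Sum frame intensity within an m/z window onto the mobility grid.

    The grid uses the frame's native mobility values when they are already
    discretized (the common case for accumulated frames); otherwise, or when
    *n_bins* is given, fixed-width bins over the scan range (default 1000).
    An empty window yields an EIM flagged ``empty``, not an error.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    half = mz * tol * 1e-6 if tol_is_ppm else tol
    sel = np.abs(frame.mz - mz) <= half
    lo, hi = frame.scan_range if frame.scan_range else (0.0, 1.0)
    if not np.any(sel):
        grid = np.linspace(lo, hi, n_bins or 1000)
        return EIM(mz, tol, grid, np.zeros_like(grid), frame.coordinate, empty=True)
    mob = frame.mobility[sel]
    inten = frame.intensity[sel]
    native = np.unique(frame.mobility)
    if n_bins is None and len(native) <= 200_000:
        grid = native
        idx = np.searchsorted(native, mob)
        acc = np.zeros_like(native, dtype=float)
        np.add.at(acc, idx, inten)
        return EIM(mz, tol, grid, acc, frame.coordinate)
    nb = n_bins or 1000
    edges = np.linspace(lo, hi, nb + 1)
    acc, _ = np.histogram(mob, bins=edges, weights=inten)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EIM(mz, tol, centers, acc, frame.coordinate)


def _gaussian_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sig = params[i : i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def _fit_k(x: np.ndarray, y: np.ndarray, k: int, init: np.ndarray,
           sigma: np.ndarray | None = None):
    lo = np.tile([0.0, x.min(), 1e-12], k)
    hi = np.tile([np.inf, x.max(), x.max() - x.min()], k)
    w = 1.0 if sigma is None else 1.0 / sigma
    res = least_squares(
        lambda p: (_gaussian_sum(x, p) - y) * w, init, bounds=(lo, hi),
        method="trf", max_nfev=4000 * k,
    )
    return res


def detect_peaks(
    eim: EIM,
    max_components: int = 6,
    min_snr: float = 5.0,
    smooth_window: int = 7,
    merge_factor: float = 1.0,
    min_width_bins: float = 2.0,
) -> list[MobilityPeak]:
    """Deconvolve an EIM into Gaussian components.

    Fits 1..max_components Gaussians by nonlinear least squares, picks the
    component count by BIC, merges components whose centroids are closer
    than ``merge_factor`` times their width (duplicate components describing
    one physical peak, an artefact of heteroscedastic noise) and refits, and
    finally discards components whose amplitude is below ``min_snr`` times
    the noise level (1.4826 * median absolute deviation of the residuals in
    the signal region).  Initial centroids come from peak-picking on a
    Savitzky-Golay-smoothed trace; extra components are seeded at the
    largest remaining residual, so the procedure is deterministic.
    Peaks are returned sorted by centroid.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    x = eim.grid
    y = eim.intensity.astype(float)
    if eim.empty or y.sum() <= 0 or len(x) < 5:
        return []
    win = min(smooth_window | 1, len(y) - (1 - len(y) % 2))
    ys = savgol_filter(y, win, 2) if len(y) > win >= 5 else y
    prominence = 0.01 * float(ys.max())
    cand_idx, _ = find_peaks(ys, prominence=prominence)
    cand_idx = cand_idx[np.argsort(ys[cand_idx])[::-1]]  # strongest first
    if len(cand_idx) == 0:
        cand_idx = np.array([int(np.argmax(y))])
    dx = float(np.median(np.diff(x)))
    sigma0 = max(3.0 * dx, (x.max() - x.min()) / 100.0)
    # heteroscedastic weights: ion-count noise scales with the signal level
    sig_w = np.maximum(np.clip(ys, 0.0, None), 0.03 * float(y.max()))

    best = None  # (bic, k, params)
    n = len(x)
    prev_params: np.ndarray | None = None
    for k in range(1, max_components + 1):
        if prev_params is None:
            i0 = cand_idx[0]
            init = np.array([max(y[i0], 1e-9), x[i0], sigma0])
        else:
            resid = y - _gaussian_sum(x, prev_params)
            if k - 1 < len(cand_idx):
                j = int(cand_idx[k - 1])
            else:
                j = int(np.argmax(resid / sig_w))
            init = np.concatenate(
                [prev_params, [max(resid[j], 0.05 * y.max()), x[j], sigma0]]
            )
        try:
            res = _fit_k(x, y, k, init, sig_w)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            raise DeconvolutionError(f"fit with {k} components failed: {exc}")
        chi2 = float(np.sum(res.fun**2))
        bic = n * math.log(max(chi2 / n, 1e-300)) + 3 * k * math.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, res.x)
        prev_params = res.x
    if best is None:
        raise DeconvolutionError("no Gaussian fit converged")
    _, k, params = best

    # merge components that describe the same physical peak, then refit
    while k > 1:
        comps = [tuple(params[i : i + 3]) for i in range(0, 3 * k, 3)]
        comps.sort(key=lambda c: c[1])
        merged = None
        for (a1, m1, s1), (a2, m2, s2) in zip(comps, comps[1:]):
            if abs(m2 - m1) < merge_factor * max(s1, s2):
                area = a1 * s1 + a2 * s2  # up to sqrt(2*pi)
                mu = (m1 * a1 * s1 + m2 * a2 * s2) / area
                sig = max(s1, s2)
                merged = (area / sig, mu, sig)
                rest = [c for c in comps if c not in ((a1, m1, s1), (a2, m2, s2))]
                break
        if merged is None:
            break
        k -= 1
        init = np.concatenate([np.array(merged)] + [np.array(c) for c in rest]) \
            if rest else np.array(merged)
        res = _fit_k(x, y, k, init, sig_w)
        params = res.x

    resid = _gaussian_sum(x, params) - y
    fitted = _gaussian_sum(x, params)
    signal = fitted > 0.02 * fitted.max() if fitted.max() > 0 else np.ones_like(
        fitted, dtype=bool
    )
    r = resid[signal]
    noise = 1.4826 * float(np.median(np.abs(r - np.median(r)))) if len(r) else 0.0
    peaks = []
    for i in range(0, 3 * k, 3):
        a, mu, sig = params[i : i + 3]
        if a <= 0 or sig <= 0:
            continue
        if sig < min_width_bins * dx:  # narrower than sampling: noise spike
            continue
        if noise > 0 and a < min_snr * noise:
            continue
        peaks.append(MobilityPeak(centroid=float(mu), sigma=float(sig),
                                  amplitude=float(a)))
    peaks.sort(key=lambda p: p.centroid)
    return peaks


def relative_areas(peaks: list[MobilityPeak]) -> list[MobilityPeak]:
    """Annotate peaks with their percent of the summed isomer area."""
    if not peaks:
        raise ValueError("no peaks to normalize")
    total = sum(p.area for p in peaks)
    if total <= 0:
        raise ValueError("zero total area")
    return [replace(p, relative_area=100.0 * p.area / total) for p in peaks]


@dataclass
class ChargeBand:
    """Mobility band for one charge state: mobility bounds as functions of m/z."""

    z: int
    lower: callable  # mz -> mobility lower bound
    upper: callable  # mz -> mobility upper bound


def charge_gate(
    frame: MobilityFrame, bands: list[ChargeBand]
) -> dict[int | str, MobilityFrame]:
    """Split a frame into per-charge subsets using m/z-dependent mobility bands.

    Each triple is assigned to the band containing it, or to "unassigned".
    Overlapping bands (at any observed m/z) are an error.
    """
    labels = np.full(len(frame.mz), -1, dtype=int)
    for i, band in enumerate(bands):
        lo = np.array([band.lower(m) for m in frame.mz])
        hi = np.array([band.upper(m) for m in frame.mz])
        inside = (frame.mobility >= lo) & (frame.mobility <= hi)
        clash = inside & (labels >= 0)
        if np.any(clash):
            raise ValueError(
                f"overlapping charge bands at m/z {frame.mz[clash][0]:.4f}"
            )
        labels[inside] = i
    out: dict[int | str, MobilityFrame] = {}
    for i, band in enumerate(bands):
        sel = labels == i
        out[band.z] = MobilityFrame(
            frame.mz[sel], frame.mobility[sel], frame.intensity[sel],
            frame.coordinate, frame.scan_range,
        )
    sel = labels < 0
    out["unassigned"] = MobilityFrame(
        frame.mz[sel], frame.mobility[sel], frame.intensity[sel],
        frame.coordinate, frame.scan_range,
    )
    return out


def resolving_power(peak: MobilityPeak) -> float:
    """CCS-space resolving power CCS / FWHM, with FWHM = 2*sqrt(2 ln 2)*sigma.

    Returns ``inf`` for a vanishing width (flagged by the caller as
    unphysical).  Invariant under uniform rescaling of CCS and sigma.
    """
    if peak.ccs is None or peak.sigma_ccs is None:
        raise ValueError("peak is not CCS-calibrated")
    if peak.sigma_ccs <= 0:
        return float("inf")
    return peak.ccs / (_FWHM * peak.sigma_ccs)


def read_frame_csv(path: str, coordinate: str = "inv_k0") -> MobilityFrame:
    """Read a frame from a CSV of columns mz, mobility, intensity."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"mz", "mobility", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"frame CSV missing columns: {sorted(missing)}")
    return MobilityFrame(
        df["mz"].to_numpy(), df["mobility"].to_numpy(),
        df["intensity"].to_numpy(), coordinate,
    )


_MOBILITY_ARRAY_KEYS = (
    "mean inverse reduced ion mobility array",
    "inverse reduced ion mobility array",
    "raw ion mobility array",
    "mean drift time array",
)


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    names = {cv.get("name") for cv in bda.iter() if cv.tag.endswith("cvParam")}
    dtype = np.float32 if "32-bit float" in names else np.float64
    binary = next(el for el in bda.iter() if el.tag.endswith("}binary"))
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_frame_mzml(path: str, coordinate: str = "inv_k0") -> MobilityFrame:
    """Read an mzML file whose spectra carry ion-mobility arrays.

    A contained decoder (stdlib XML + base64/zlib) for the mzML subset this
    workflow needs: per-spectrum m/z, intensity and one ion-mobility array
    (by cvParam name; 32/64-bit floats, optional zlib compression).  All
    spectra are pooled into one accumulated frame.
    """
    import xml.etree.ElementTree as ET

    mzs, mobs, intens = [], [], []
    tree = ET.parse(path)
    for spectrum in tree.iter():
        if not spectrum.tag.endswith("}spectrum"):
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter():
            if not bda.tag.endswith("}binaryDataArray"):
                continue
            names = {cv.get("name") for cv in bda.iter()
                     if cv.tag.endswith("cvParam")}
            data = _decode_binary_array(bda)
            if "m/z array" in names:
                arrays["mz"] = data
            elif "intensity array" in names:
                arrays["intensity"] = data
            elif names & set(_MOBILITY_ARRAY_KEYS):
                arrays["mobility"] = data
        if {"mz", "intensity", "mobility"} <= set(arrays):
            mzs.append(arrays["mz"])
            intens.append(arrays["intensity"])
            mobs.append(arrays["mobility"])
    if not mzs:
        raise ValueError(f"no ion-mobility spectra found in {path}")
    return MobilityFrame(
        np.concatenate(mzs), np.concatenate(mobs), np.concatenate(intens),
        coordinate,
    )
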