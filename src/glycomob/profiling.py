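"""Sample-level glycosylation summaries.

A profile is the set of assigned mobility peaks of one sample.  Grouping the
mobility peak areas by core structure gives the core distribution (percent
of total area, summing to 100); grouping by glycosylation feature
(sialylation, fucosylation, sulfation) counts each peak once per feature it
carries, so those percentages are independent and need not sum to 100.
Isomer-ratio tables compare the relative areas of the isomers at one m/z
between two samples and flag rank-order inversions, the most direct sign of
a shifted isomer equilibrium between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import Composition
from .mobilogram import MobilityPeak
from .structures import MotifSet

__all__ = [
    "AssignedPeak",
    "Profile",
    "group_by_core",
    "group_by_feature",
    "isomer_ratio_table",
    "read_profile_csv",
    "write_profile_csv",
    "MAIN_CORES",
]

#: Cores reported individually; everything else is folded into "other".
MAIN_CORES = ("core1", "core2", "core3", "core4")

FEATURES = ("sialylated", "fucosylated", "sulfated")


@dataclass
class AssignedPeak:
    """A mobility peak with its composition/structure assignment."""

    sample: str
    composition: Composition
    peak: MobilityPeak
    mz: float
    z: int = 1
    structure: str | None = None
    core: str = "unassigned"
    motifs: MotifSet = field(default_factory=MotifSet)

    @property
    def area(self) -> float:
        return self.peak.area


@dataclass
class Profile:
    """All assigned peaks of one sample."""

    sample: str
    peaks: list[AssignedPeak]

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.peaks)


def group_by_core(
    profile: Profile, fold_minor: bool = True
) -> dict[str, float]:
    """Percent of total mobility area per core label (sums to 100).

    Cores 5-8 and unassigned peaks are folded into "other" by default.
    """
    if not profile.peaks:
        raise ValueError(f"profile {profile.sample!r} is empty")
    total = profile.total_area
    if total <= 0:
        raise ValueError("profile has zero total area")
    out: dict[str, float] = {}
    for p in profile.peaks:
        label = p.core
        if fold_minor and label not in MAIN_CORES:
            label = "other"
        out[label] = out.get(label, 0.0) + p.area
    return {k: 100.0 * v / total for k, v in out.items()}


def group_by_feature(profile: Profile) -> dict[str, float]:
    """Percent of total area carrying each feature (multi-membership).

    A peak that is both fucosylated and sulfated counts toward both
    features, so the three percentages are each in [0, 100] but their sum is
    unconstrained.
    """
    total = profile.total_area
    if total <= 0:
        return {f: 0.0 for f in FEATURES}
    out = {}
    for feature in FEATURES:
        area = sum(p.area for p in profile.peaks if getattr(p.motifs, feature))
        out[feature] = 100.0 * area / total
    return out


def isomer_ratio_table(
    a: Profile,
    b: Profile,
    mz_list: list[float],
    mz_tol: float = 0.05,
) -> pd.DataFrame:
    """Side-by-side relative isomer areas at each m/z, with inversion flags.

    For each requested m/z the peaks of both samples are ordered by mobility
    centroid and their relative areas (percent of the per-sample isomer sum)
    are tabulated.  A row's ``inversion`` flag is set when the abundance
    rank order of the shared isomers differs between the samples; an m/z
    missing in one sample sets ``missing`` instead of raising.
    """
    rows = []
    for target in mz_list:
        pa = sorted(
            (p for p in a.peaks if abs(p.mz - target) <= mz_tol),
            key=lambda p: p.peak.centroid,
        )
        pb = sorted(
            (p for p in b.peaks if abs(p.mz - target) <= mz_tol),
            key=lambda p: p.peak.centroid,
        )
        if not pa or not pb:
            rows.append(
                {"mz": target, "rel_areas_a": [], "rel_areas_b": [],
                 "inversion": False, "missing": True}
            )
            continue
        ta = sum(p.area for p in pa)
        tb = sum(p.area for p in pb)
        ra = [100.0 * p.area / ta for p in pa]
        rb = [100.0 * p.area / tb for p in pb]
        n = min(len(ra), len(rb))
        rank_a = _rank(ra[:n])
        rank_b = _rank(rb[:n])
        rows.append(
            {"mz": target, "rel_areas_a": ra, "rel_areas_b": rb,
             "inversion": rank_a != rank_b, "missing": False}
        )
    return pd.DataFrame(rows)


def _rank(values: list[float]) -> list[int]:
    order = sorted(range(len(values)), key=lambda i: -values[i])
    rank = [0] * len(values)
    for r, i in enumerate(order):
        rank[i] = r
    return rank


_PROFILE_COLUMNS = [
    "sample", "mz", "z", "centroid", "sigma", "amplitude", "ccs",
    "composition", "structure", "core", "flags",
]


def write_profile_csv(profile: Profile, path: str) -> None:
    rows = []
    for p in profile.peaks:
        rows.append(
            {
                "sample": p.sample, "mz": p.mz, "z": p.z,
                "centroid": p.peak.centroid, "sigma": p.peak.sigma,
                "amplitude": p.peak.amplitude,
                "ccs": p.peak.ccs if p.peak.ccs is not None else "",
                "composition": str(p.composition),
                "structure": p.structure or "",
                "core": p.core,
                "flags": ";".join(sorted(p.motifs.flags)),
            }
        )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def read_profile_csv(path: str) -> Profile:
    """Load a profile written by :func:`write_profile_csv`."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    peaks = []
    sample = ""
    for r in df.itertuples():
        sample = str(r.sample)
        comp = Composition.parse(str(r.composition))
        flags = set(str(r.flags).split(";")) if r.flags else set()
        motifs = MotifSet(
            core=str(r.core),
            blood_group_H="blood_group_H" in flags,
            type_I_chain="type_I_chain" in flags,
            type_II_chain="type_II_chain" in flags,
            LacNAc_extension="LacNAc_extension" in flags,
            sialylated="sialylated" in flags,
            fucosylated="fucosylated" in flags,
            sulfated="sulfated" in flags,
        )
        peak = MobilityPeak(
            centroid=float(r.centroid), sigma=float(r.sigma),
            amplitude=float(r.amplitude),
            ccs=float(r.ccs) if r.ccs != "" else None,
        )
        peaks.append(
            AssignedPeak(
                sample=sample, composition=comp, peak=peak,
                mz=float(r.mz), z=int(r.z),
                structure=str(r.structure) or None, core=str(r.core),
                motifs=motifs,
            )
        )
    if not peaks:
        raise ValueError(f"empty profile file {path}")
    return Profile(sample=sample, peaks=peaks)
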