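"""CCS reference-library I/O and (m/z, CCS) matching.

A library record pairs a glycan composition (and optionally a structure)
with its theoretical m/z and the CCS measured on one or both instrument
types (TIMS, TWIMS).  Because CCS is an instrument-independent molecular
property, a library built on one instrument can drive assignment on
another; matching uses an m/z tolerance in ppm and a CCS tolerance in
percent, combined into a normalized Euclidean distance for ranking.

CSV columns are fixed: composition, structure, z, mz, ccs_tims, ccs_twims,
source, accession (unknown extra columns are tolerated).  A small synthetic
demonstration library emulating a porcine-gastric-mucin O-glycome is
shipped with the package (``demo_library_path()``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources

import pandas as pd

from .chem import Composition, mz as theoretical_mz

__all__ = [
    "LibraryRecord",
    "LibraryValidationError",
    "read_library",
    "write_library",
    "match",
    "demo_library_path",
]

_COLUMNS = [
    "composition", "structure", "z", "mz", "ccs_tims", "ccs_twims",
    "source", "accession",
]

_MZ_CONSISTENCY_PPM = 5.0


@dataclass(frozen=True)
class LibraryRecord:
    composition: str
    z: int
    mz: float
    structure: str | None = None
    ccs_tims: float | None = None
    ccs_twims: float | None = None
    source: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        if self.ccs_tims is None and self.ccs_twims is None:
            raise ValueError("record needs at least one CCS value")

    @property
    def ccs(self) -> float:
        """Preferred CCS: TIMS when present, else TWIMS."""
        return self.ccs_tims if self.ccs_tims is not None else self.ccs_twims


class LibraryValidationError(ValueError):
    def __init__(self, problems: list[str]):
        super().__init__(
            "library validation failed:\n  " + "\n  ".join(problems)
        )
        self.problems = problems


def _validate_row(rec: LibraryRecord) -> str | None:
    comp = Composition.parse(rec.composition)
    theo = theoretical_mz(comp, rec.z)
    ppm = (rec.mz - theo) / theo * 1e6
    if abs(ppm) > _MZ_CONSISTENCY_PPM:
        return (
            f"{rec.composition} z={rec.z}: m/z {rec.mz:.4f} is {ppm:+.1f} ppm "
            f"from theoretical {theo:.4f}"
        )
    return None


def read_library(
    path: str, dialect: str | None = None, strict: bool = False
) -> tuple[list[LibraryRecord], list[str]]:
    """Read and validate a CCS library (CSV or JSON).

    Returns ``(records, problems)``: rows whose m/z disagrees with their
    composition by more than 5 ppm (or that cannot be parsed) are rejected
    and reported in *problems*.  ``strict=True`` raises instead.
    """
    if dialect is None:
        dialect = "json" if path.endswith(".json") else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, comment="#", keep_default_na=False)
        missing = {"composition", "z", "mz"} - set(df.columns)
        if missing:
            raise ValueError(f"library missing required columns: {sorted(missing)}")
        raw = df.to_dict("records")
    elif dialect == "json":
        with open(path) as fh:
            raw = json.load(fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not raw:
        raise ValueError(f"library {path} contains no records")

    records: list[LibraryRecord] = []
    problems: list[str] = []
    for i, row in enumerate(raw):
        try:
            rec = LibraryRecord(
                composition=str(row["composition"]),
                structure=str(row.get("structure") or "") or None,
                z=int(row["z"]),
                mz=float(row["mz"]),
                ccs_tims=_opt_float(row.get("ccs_tims")),
                ccs_twims=_opt_float(row.get("ccs_twims")),
                source=str(row.get("source") or ""),
                accession=str(row.get("accession") or ""),
            )
            problem = _validate_row(rec)
        except (KeyError, ValueError) as exc:
            problem = f"row {i}: {exc}"
            rec = None
        if problem is not None:
            problems.append(problem)
        else:
            records.append(rec)
    if strict and problems:
        raise LibraryValidationError(problems)
    return records, problems


def _opt_float(v) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def write_library(records: list[LibraryRecord], path: str,
                  dialect: str | None = None) -> None:
    """Write records as CSV (fixed column order) or JSON."""
    if dialect is None:
        dialect = "json" if path.endswith(".json") else "csv"
    rows = []
    for rec in records:
        d = asdict(rec)
        rows.append({
            k: ("" if d.get(k) is None else d.get(k)) for k in _COLUMNS
        })
    if dialect == "csv":
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump(
                [{k: v for k, v in r.items() if v != ""} for r in rows],
                fh, indent=1,
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def match(
    query_mz: float,
    query_ccs: float,
    z: int,
    records: list[LibraryRecord],
    mz_tol_ppm: float = 10.0,
    ccs_tol_pct: float = 0.5,
    instrument: str | None = None,
) -> list[tuple[LibraryRecord, float]]:
    """Rank library records compatible with an (m/z, CCS) query.

    Candidates must match the charge, lie within *mz_tol_ppm* of the query
    m/z and within *ccs_tol_pct* percent of the query CCS; they are ranked
    by the combined normalized distance
    ``d = sqrt((dppm/mz_tol)^2 + (dccs_pct/ccs_tol)^2)``.  The default CCS
    tolerance of 0.5% reflects sub-1% inter-instrument reproducibility.
    """
    if mz_tol_ppm <= 0 or ccs_tol_pct <= 0:
        raise ValueError("tolerances must be positive")
    hits = []
    for rec in records:
        if rec.z != z:
            continue
        ref_ccs = rec.ccs if instrument is None else getattr(
            rec, f"ccs_{instrument}"
        )
        if ref_ccs is None:
            continue
        dppm = (query_mz - rec.mz) / rec.mz * 1e6
        dccs = (query_ccs - ref_ccs) / ref_ccs * 100.0
        if abs(dppm) > mz_tol_ppm or abs(dccs) > ccs_tol_pct:
            continue
        d = math.hypot(dppm / mz_tol_ppm, dccs / ccs_tol_pct)
        hits.append((rec, d))
    hits.sort(key=lambda h: h[1])
    return hits


def demo_library_path() -> str:
    """Path of the packaged synthetic PGM-like demonstration library."""
    return str(
        resources.files("glycomob").joinpath("data/pgm_demo_synthetic.csv")
    )
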