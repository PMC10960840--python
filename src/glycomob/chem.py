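"""Monoisotopic mass arithmetic for O-glycan alditols.

Mucin-type O-glycans released by reductive beta-elimination are open-chain
alditols: the neutral monoisotopic mass of a glycan is the sum of dehydrated
residue masses plus one water, plus 2H for the reduction of the former
reducing end.  In negative-mode ESI the species observed are deprotonated,
``[M - zH]^{z-}``; singly deprotonated ions dominate and doubly deprotonated
ions only appear above ~1200 Da neutral mass.

Residue masses are derived from elemental formulas (Hex C6H10O5,
HexNAc C8H13NO5, dHex C6H10O4, NeuAc C11H17NO8); sulfation is carried as a
+SO3 count on the composition, not as a residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

__all__ = [
    "MONOSACCHARIDE_CLASSES",
    "RESIDUE_FORMULAS",
    "Composition",
    "MassConstants",
    "MASS",
    "residue_mass",
    "neutral_mass",
    "mz",
    "allowed_charges",
    "search_compositions",
    "DEFAULT_BOUNDS",
]

#: Canonical ordering of monosaccharide classes (fixed for string forms).
MONOSACCHARIDE_CLASSES = ("Hex", "HexNAc", "dHex", "NeuAc")

RESIDUE_FORMULAS = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "dHex": "C6H10O4",
    "NeuAc": "C11H17NO8",
}

_RESIDUE_MASSES = {
    name: _pmass.calculate_mass(formula=f) for name, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic mass constants (Da).

    ``proton`` follows the 1.007276 Da convention, i.e. the electron mass is
    already folded in; ``reduction_2H`` is the 2H added by NaBH4 reduction.
    """

    water: float = _pmass.calculate_mass(formula="H2O")
    reduction_2H: float = _pmass.calculate_mass(formula="H2")
    sulfate: float = _pmass.calculate_mass(formula="SO3")
    proton: float = 1.007276


MASS = MassConstants()


def residue_mass(cls: str) -> float:
    """Monoisotopic mass (Da) of the dehydrated residue of class *cls*."""
    try:
        return _RESIDUE_MASSES[cls]
    except KeyError:
        raise ValueError(
            f"unknown monosaccharide class {cls!r}; known: {MONOSACCHARIDE_CLASSES}"
        ) from None


@dataclass(frozen=True)
class Composition:
    """Multiset of monosaccharide classes with a sulfate count and reduced-end flag.

    The canonical string form lists classes in the fixed order
    Hex, HexNAc, dHex, NeuAc, S, omitting zero counts:
    ``"Hex2HexNAc2dHex1"``.
    """

    counts: dict[str, int] = field(default_factory=dict)
    sulfate: int = 0
    reduced: bool = True

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if cls not in _RESIDUE_MASSES:
                raise ValueError(f"unknown monosaccharide class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for {cls}")
        if self.sulfate < 0:
            raise ValueError("negative sulfate count")
        # freeze the dict so the dataclass is safely hashable by string form
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def n_residues(self) -> int:
        return sum(self.counts.values())

    def count(self, cls: str) -> int:
        return self.counts.get(cls, 0)

    def __str__(self) -> str:
        parts = [
            f"{cls}{self.counts[cls]}"
            for cls in MONOSACCHARIDE_CLASSES
            if self.counts.get(cls, 0)
        ]
        if self.sulfate:
            parts.append(f"S{self.sulfate}")
        return "".join(parts) if parts else "(empty)"

    def __hash__(self) -> int:
        return hash((str(self), self.reduced))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Composition):
            return NotImplemented
        return str(self) == str(other) and self.reduced == other.reduced

    @classmethod
    def parse(cls, text: str, reduced: bool = True) -> "Composition":
        """Parse a canonical composition string like ``"Hex2HexNAc3S1"``."""
        import re

        counts: dict[str, int] = {}
        sulfate = 0
        pos = 0
        pat = re.compile(r"(Hex(?:NAc)?|dHex|NeuAc|S)(\d+)")
        while pos < len(text):
            m = pat.match(text, pos)
            if m is None:
                raise ValueError(f"malformed composition string {text!r} at offset {pos}")
            name, n = m.group(1), int(m.group(2))
            if name == "S":
                sulfate += n
            else:
                counts[name] = counts.get(name, 0) + n
            pos = m.end()
        return cls(counts=counts, sulfate=sulfate, reduced=reduced)

    def with_reduced(self, reduced: bool) -> "Composition":
        return replace(self, reduced=reduced)


def neutral_mass(comp: Composition) -> float:
    """Neutral monoisotopic mass (Da) of a composition.

    Sum of residue masses + sulfate*SO3 + water, + 2H if the glycan is a
    reduced alditol.  Raises for an empty composition.
    """
    if comp.n_residues < 1:
        raise ValueError("composition has no residues; mass is undefined")
    m = sum(n * _RESIDUE_MASSES[cls] for cls, n in comp.counts.items())
    m += comp.sulfate * MASS.sulfate + MASS.water
    if comp.reduced:
        m += MASS.reduction_2H
    return m


def mz(comp: Composition, z: int) -> float:
    """m/z of the ``[M - zH]^{z-}`` ion of *comp* (negative mode)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass(comp) - z * MASS.proton) / z


def allowed_charges(neutral: float, threshold: float = 1200.0) -> set[int]:
    """Charge states expected for a glycan of the given neutral mass.

    Deprotonated O-glycan alditols are predominantly singly charged; doubly
    deprotonated species appear only above *threshold* Da (default 1200).
    The boundary itself is treated as singly charged.
    """
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    return {1} if neutral <= threshold else {1, 2}


#: Default per-class maxima for composition search (covers the <=2500 Da range
#: of the PGM O-glycome).
DEFAULT_BOUNDS = {"Hex": 8, "HexNAc": 8, "dHex": 4, "NeuAc": 4, "S": 2}

#: Default biological constraints for mucin-type alditols.
DEFAULT_CONSTRAINTS = {"min_hexnac": 1, "max_sulfate": 2, "max_neuac": 4}


def search_compositions(
    observed_mz: float,
    z: int,
    tol_ppm: float = 10.0,
    bounds: dict[str, int] | None = None,
    constraints: dict[str, int] | None = None,
    reduced: bool = True,
) -> list[tuple[Composition, float]]:
    """Enumerate compositions whose theoretical m/z matches an observed peak.

    Exhaustively searches the count lattice within *bounds* (keys Hex,
    HexNAc, dHex, NeuAc, S) for reduced compositions with
    ``|mz(comp, z) - observed_mz| / observed_mz <= tol_ppm * 1e-6``, filtered
    by mucin-type constraints (default: HexNAc >= 1, sulfate <= 2,
    NeuAc <= 4).  Returns ``(composition, ppm_error)`` pairs sorted by
    absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds is not None:
        b.update(bounds)
    if not b or all(v == 0 for v in b.values()):
        raise ValueError("empty composition bounds")
    c = dict(DEFAULT_CONSTRAINTS)
    if constraints is not None:
        c.update(constraints)

    out: list[tuple[Composition, float]] = []
    ranges = [range(b.get(k, 0) + 1) for k in MONOSACCHARIDE_CLASSES]
    s_range = range(min(b.get("S", 0), c["max_sulfate"]) + 1)
    for hex_, hexnac, dhex, neuac in itertools.product(*ranges):
        if hex_ + hexnac + dhex + neuac == 0:
            continue
        if hexnac < c["min_hexnac"] or neuac > c["max_neuac"]:
            continue
        base = (
            hex_ * _RESIDUE_MASSES["Hex"]
            + hexnac * _RESIDUE_MASSES["HexNAc"]
            + dhex * _RESIDUE_MASSES["dHex"]
            + neuac * _RESIDUE_MASSES["NeuAc"]
            + MASS.water
            + (MASS.reduction_2H if reduced else 0.0)
        )
        for s in s_range:
            theo = (base + s * MASS.sulfate - z * MASS.proton) / z
            ppm = (theo - observed_mz) / observed_mz * 1e6
            if abs(ppm) <= tol_ppm:
                comp = Composition(
                    counts={
                        k: v
                        for k, v in zip(
                            MONOSACCHARIDE_CLASSES, (hex_, hexnac, dhex, neuac)
                        )
                        if v
                    },
                    sulfate=s,
                    reduced=reduced,
                )
                out.append((comp, ppm))
    out.sort(key=lambda t: abs(t[1]))
    return out
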