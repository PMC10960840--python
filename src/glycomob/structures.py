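"""Tree model of mucin-type O-glycan alditol structures.

Structures are written in a compact IUPAC-like condensed notation read
right-to-left, with the reduced GalNAc alditol at the right end and square
brackets for branches::

    Fuc(a1-2)Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol

Each residue token carries its anomeric configuration (a/b/?) and the carbon
of the parent it is linked to (1-8 or ?).  Unknown anomer or position is a
wildcard in motif matching, because MS/MS cannot always fix them.

Eight core types are defined by the residues directly attached to the
GalNAc-ol: core 1 Galb1-3, core 2 Galb1-3 + GlcNAcb1-6, core 3 GlcNAcb1-3,
core 4 GlcNAcb1-3 + GlcNAcb1-6, core 5 GalNAca1-3, core 6 GlcNAcb1-6 alone,
core 7 GalNAca1-6, core 8 Gala1-3.  Extensions beyond the core (LacNAc
repeats, fucosylation, sialylation) do not change the core label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .chem import Composition

__all__ = [
    "Residue",
    "GlycanStructure",
    "MotifSet",
    "StructureParseError",
    "parse_structure",
    "serialize_structure",
    "classify_core",
    "detect_motifs",
    "composition_of",
    "RESIDUE_CLASSES",
    "CORE_TEMPLATES",
]

#: Named monosaccharides and the mass class each maps to.
RESIDUE_CLASSES = {
    "Gal": "Hex",
    "Glc": "Hex",
    "Man": "Hex",
    "Hex": "Hex",
    "GalNAc": "HexNAc",
    "GlcNAc": "HexNAc",
    "HexNAc": "HexNAc",
    "Fuc": "dHex",
    "dHex": "dHex",
    "Neu5Ac": "NeuAc",
    "NeuAc": "NeuAc",
}

#: Anomeric carbon per identity (sialic acids link through C2).
_ANOMERIC_CARBON = {"Neu5Ac": 2, "NeuAc": 2}


@dataclass
class Residue:
    """A monosaccharide node: identity, anomer, linkage to parent, children."""

    identity: str
    anomer: str = "?"  # 'a', 'b' or '?'
    linkage_position: int | None = None  # carbon on the parent, None = unknown
    children: list["Residue"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.identity not in RESIDUE_CLASSES:
            raise ValueError(f"unknown residue identity {self.identity!r}")
        if self.anomer not in ("a", "b", "?"):
            raise ValueError(f"anomer must be 'a', 'b' or '?', got {self.anomer!r}")

    @property
    def mass_class(self) -> str:
        return RESIDUE_CLASSES[self.identity]

    def sort_children(self) -> None:
        """Canonical branch order: lowest linkage position first, unknown last."""
        self.children.sort(
            key=lambda c: (c.linkage_position is None, c.linkage_position or 0,
                           c.identity, c.anomer)
        )
        for c in self.children:
            c.sort_children()

    def child_at(self, position: int) -> "Residue | None":
        for c in self.children:
            if c.linkage_position == position:
                return c
        return None

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Residue):
            return NotImplemented
        return (
            self.identity == other.identity
            and self.anomer == other.anomer
            and self.linkage_position == other.linkage_position
            and self.children == other.children
        )


@dataclass
class GlycanStructure:
    """Rooted O-glycan tree; ``reduced`` marks the GalNAc-ol alditol root."""

    root: Residue
    reduced: bool = True

    @property
    def text(self) -> str:
        return serialize_structure(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.reduced == other.reduced and self.root == other.root

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class MotifSet:
    """Structural flags: one core label plus independent feature flags."""

    core: str = "unassigned"
    blood_group_H: bool = False
    type_I_chain: bool = False
    type_II_chain: bool = False
    LacNAc_extension: bool = False
    sialylated: bool = False
    fucosylated: bool = False
    sulfated: bool = False

    @property
    def flags(self) -> frozenset[str]:
        out = set()
        if self.core != "unassigned":
            out.add(self.core)
        for name in (
            "blood_group_H",
            "type_I_chain",
            "type_II_chain",
            "LacNAc_extension",
            "sialylated",
            "fucosylated",
            "sulfated",
        ):
            if getattr(self, name):
                out.add(name)
        return frozenset(out)


class StructureParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at offset {position})")
        self.position = position


_UNIT = re.compile(r"([A-Za-z][A-Za-z0-9]*?)\(([ab?])([12?])-([1-8?])\)")
_ROOT = re.compile(r"([A-Za-z][A-Za-z0-9]*)-ol$")


def parse_structure(text: str) -> GlycanStructure:
    """Parse condensed notation into a tree with branches in canonical order.

    Raises :class:`StructureParseError` with the failing offset on malformed
    input.
    """
    text = text.strip()
    if not text:
        raise StructureParseError("empty structure string", 0)

    def parse_chain(s: str, offset: int) -> Residue:
        """Parse one bracket-free-at-top-level chain; returns its final residue."""
        pending: list[Residue] = []
        pos = 0
        while pos < len(s):
            if s[pos] == "[":
                depth, j = 1, pos + 1
                while j < len(s) and depth:
                    if s[j] == "[":
                        depth += 1
                    elif s[j] == "]":
                        depth -= 1
                    j += 1
                if depth:
                    raise StructureParseError("unbalanced '['", offset + pos)
                pending.append(parse_chain(s[pos + 1 : j - 1], offset + pos + 1))
                pos = j
                continue
            m = _UNIT.match(s, pos)
            if m is not None:
                identity, anomer, _c1, ppos = m.groups()
                if identity not in RESIDUE_CLASSES:
                    raise StructureParseError(
                        f"unknown residue {identity!r}", offset + pos
                    )
                r = Residue(
                    identity=identity,
                    anomer=anomer,
                    linkage_position=None if ppos == "?" else int(ppos),
                    children=pending,
                )
                pending = [r]
                pos = m.end()
                continue
            m = _ROOT.match(s[pos:])
            if m is not None and pos + m.end() == len(s):
                identity = m.group(1)
                if identity not in RESIDUE_CLASSES:
                    raise StructureParseError(
                        f"unknown residue {identity!r}", offset + pos
                    )
                return Residue(identity=identity, children=pending)
            raise StructureParseError("cannot parse residue token", offset + pos)
        if len(pending) != 1:
            raise StructureParseError("chain does not end in a single residue", offset)
        return pending[0]

    reduced = text.endswith("-ol")
    root = parse_chain(text, 0)
    # distinct linkage positions per parent
    for node in root.walk():
        seen: set[int] = set()
        for c in node.children:
            if c.linkage_position is not None:
                if c.linkage_position in seen:
                    raise StructureParseError(
                        f"duplicate linkage position {c.linkage_position} on "
                        f"{node.identity}",
                        0,
                    )
                seen.add(c.linkage_position)
    root.sort_children()
    return GlycanStructure(root=root, reduced=reduced)


def _serialize_residue(r: Residue, is_root: bool, reduced: bool) -> str:
    if is_root:
        token = f"{r.identity}-ol" if reduced else f"{r.identity}(?1-?)"
    else:
        c1 = _ANOMERIC_CARBON.get(r.identity, 1)
        ppos = "?" if r.linkage_position is None else str(r.linkage_position)
        token = f"{r.identity}({r.anomer}{c1}-{ppos})"
    if not r.children:
        return token
    main, *others = r.children
    branches = "".join(
        f"[{_serialize_residue(c, False, reduced)}]" for c in others
    )
    return _serialize_residue(main, False, reduced) + branches + token


def serialize_structure(s: GlycanStructure) -> str:
    """Canonical condensed text (branches ordered by linkage position)."""
    s.root.sort_children()
    return _serialize_residue(s.root, True, s.reduced)


def _matches(child: Residue | None, spec: tuple[str, str] | None) -> bool:
    """Does the child slot match a core-template entry (identity, anomer)?

    ``None`` spec means the slot must be empty; '?' anomer on the observed
    residue is a wildcard.
    """
    if spec is None:
        return child is None
    if child is None:
        return False
    identity, anomer = spec
    if child.identity != identity:
        return False
    return child.anomer in (anomer, "?")


#: Core templates as (slot at C3, slot at C6) of the GalNAc-ol.
CORE_TEMPLATES: dict[str, tuple[tuple[str, str] | None, tuple[str, str] | None]] = {
    "core1": (("Gal", "b"), None),
    "core2": (("Gal", "b"), ("GlcNAc", "b")),
    "core3": (("GlcNAc", "b"), None),
    "core4": (("GlcNAc", "b"), ("GlcNAc", "b")),
    "core5": (("GalNAc", "a"), None),
    "core6": (None, ("GlcNAc", "b")),
    "core7": (None, ("GalNAc", "a")),
    "core8": (("Gal", "a"), None),
}


def classify_core(s: GlycanStructure) -> str:
    """Core 1-8 label from the residues attached to GalNAc-ol, or "unassigned".

    Only the identity/anomer of the immediate C3 and C6 substituents matter;
    extensions beyond the core leave the label unchanged.
    """
    if not s.reduced:
        raise ValueError("core classification requires a reduced (alditol) structure")
    c3 = s.root.child_at(3)
    c6 = s.root.child_at(6)
    for label, (spec3, spec6) in CORE_TEMPLATES.items():
        if _matches(c3, spec3) and _matches(c6, spec6):
            return label
    return "unassigned"


def _edge_matches(parent: Residue, child: Residue, child_id: str, anomer: str,
                  position: int, parent_id: str) -> bool:
    if child.identity != child_id or parent.identity != parent_id:
        return False
    if child.anomer not in (anomer, "?"):
        return False
    return child.linkage_position in (position, None)


def detect_motifs(s: GlycanStructure, composition: Composition | None = None) -> MotifSet:
    """Detect feature motifs on a parsed structure.

    blood group H = Fuc(a1-2) on a Gal; type I / type II chain =
    Gal(b1-3) / Gal(b1-4) on a GlcNAc; LacNAc extension = either chain type.
    Sulfation is not encoded in the tree, so the sulfated flag is taken from
    *composition* when one is supplied.
    """
    h = t1 = t2 = False
    for parent in s.root.walk():
        for child in parent.children:
            if _edge_matches(parent, child, "Fuc", "a", 2, "Gal"):
                h = True
            if _edge_matches(parent, child, "Gal", "b", 3, "GlcNAc"):
                t1 = True
            if _edge_matches(parent, child, "Gal", "b", 4, "GlcNAc"):
                t2 = True
    comp = composition if composition is not None else composition_of(s)
    return MotifSet(
        core=classify_core(s) if s.reduced else "unassigned",
        blood_group_H=h,
        type_I_chain=t1,
        type_II_chain=t2,
        LacNAc_extension=t1 or t2,
        sialylated=comp.count("NeuAc") > 0,
        fucosylated=comp.count("dHex") > 0,
        sulfated=comp.sulfate > 0,
    )


def composition_of(s: GlycanStructure) -> Composition:
    """Monosaccharide-class counts of a structure (sulfate always 0 here)."""
    counts: dict[str, int] = {}
    for node in s.root.walk():
        cls = node.mass_class
        counts[cls] = counts.get(cls, 0) + 1
    return Composition(counts=counts, sulfate=0, reduced=s.reduced)
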