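"""Negative-mode fragment generation and diagnostic core scoring.

Collision-induced dissociation of deprotonated glycan alditols yields
glycosidic B/C ions (non-reducing side) and Y/Z ions (alditol side), plus
cross-ring/chain cleavages (A-type) that are diagnostic for linkage
position.  Because the reduced GalNAc-ol is open-chain, its "cross-ring"
cleavages are chain cleavages: splitting the C2-C3 bond leaves a C4H8O4
backbone carrying the C3- and C6-substituents, and splitting C4-C5 leaves a
C2H6O2 backbone carrying the C6-substituent only.  The latter is the classic
evidence for a 6-arm (cores 2/4/6/7) versus a 3-substituted-only core.

Masses obey, for every single glycosidic cleavage of a parent of neutral
mass M:  B + Y = M  and  C + Z = M  (exactly), with C = B + water and
Y = Z + water.  Only singly deprotonated fragments are modelled, matching
the predominant charge state of the precursors.

Core assignment is rule-based: rules test structural *descriptors* of the
matched fragments (which child of the alditol a root-retaining ion proves;
whether a chain cleavage proves a 6-arm and what its first residue is)
rather than absolute masses, so the same rule set works for extended
structures.  Rules are replaceable via YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from pyteomics import mass as _pmass

from .chem import MASS, Composition, residue_mass
from .structures import CORE_TEMPLATES, GlycanStructure, Residue

__all__ = [
    "FragmentIon",
    "SpectrumMatch",
    "DiagnosticRule",
    "CoreAssignment",
    "generate_fragments",
    "annotate_spectrum",
    "score_core_diagnostics",
    "default_rules",
    "load_rules",
    "CROSS_RING_TABLE",
]

_KIND_ORDER = {"B": 0, "C": 1, "Y": 2, "Z": 3, "A": 4, "M": 5}


@dataclass
class FragmentSite:
    """Where a fragment comes from: retained tree (root-side ions) or subtree."""

    retained_root: Residue | None = None  # pruned copy, for Y/Z/M/A ions
    retained_positions: tuple[int, ...] = ()  # root chain positions kept (A ions)
    first_residues: tuple[tuple[str, str, int], ...] = ()  # (identity, anomer, pos)
    at_root: bool = False


@dataclass
class FragmentIon:
    """A neutral fragment and its singly deprotonated m/z."""

    kind: str  # B, C, Y, Z, A or M (intact precursor)
    label: str  # e.g. "Y", "0,2A"
    neutral: float
    retains_alditol: bool
    composition: Composition
    sites: list[FragmentSite] = field(default_factory=list)

    @property
    def mz_1minus(self) -> float:
        return self.neutral - MASS.proton


@dataclass
class SpectrumMatch:
    """A peak matched to its nearest candidate fragment within tolerance."""

    peak_mz: float
    intensity: float
    fragment: FragmentIon
    ppm_error: float


#: Chain-cleavage table for the open-chain alditol, keyed by
#: (residue class key, A-label): (backbone mass in Da, retained positions).
#: Backbones from elemental formulas: C2-C3 split keeps C4H8O4, C4-C5 split
#: keeps C2H6O2.
CROSS_RING_TABLE: dict[tuple[str, str], tuple[float, tuple[int, ...]]] = {
    ("HexNAc-ol", "0,2A"): (_pmass.calculate_mass(formula="C4H8O4"), (3, 4, 5, 6)),
    ("HexNAc-ol", "2,4A"): (_pmass.calculate_mass(formula="C2H6O2"), (5, 6)),
}

DEFAULT_KINDS = frozenset({"B", "C", "Y", "Z", "A", "M"})


def _subtree_residue_mass(r: Residue) -> float:
    return sum(residue_mass(n.mass_class) for n in r.walk())


def _subtree_composition(r: Residue, reduced: bool = False) -> Composition:
    counts: dict[str, int] = {}
    for n in r.walk():
        counts[n.mass_class] = counts.get(n.mass_class, 0) + 1
    return Composition(counts=counts, reduced=reduced)


def _pruned_copy(r: Residue, removed: set[int]) -> Residue | None:
    """Copy of the subtree at *r* with nodes whose id is in *removed* cut off."""
    if id(r) in removed:
        return None
    kept = [c2 for c in r.children if (c2 := _pruned_copy(c, removed)) is not None]
    return Residue(
        identity=r.identity, anomer=r.anomer,
        linkage_position=r.linkage_position, children=kept,
    )


def _edges(root: Residue) -> list[tuple[Residue, Residue]]:
    out = []
    for parent in root.walk():
        for child in parent.children:
            out.append((parent, child))
    return out


def _is_descendant(node: Residue, maybe_ancestor: Residue) -> bool:
    return any(n is node for n in maybe_ancestor.walk())


def generate_fragments(
    s: GlycanStructure,
    kinds: frozenset[str] | set[str] = DEFAULT_KINDS,
    max_cleavages: int = 2,
    cross_ring_table: dict | None = None,
) -> list[FragmentIon]:
    """Enumerate fragments of a structure, deduplicated by (kind, neutral).

    Single glycosidic cleavages give B/C (non-reducing subtree) and Y/Z
    (root-retaining) ions; with ``max_cleavages=2`` double root-retaining
    Y/Y and Z/Z losses are added.  A-type entries come from the chain
    cleavage table (default: the two alditol backbone splits).  The intact
    precursor is emitted as kind "M" when requested.  A structure with no
    glycosidic bond yields no B/C/Y/Z ions (empty list is not an error).
    """
    if max_cleavages not in (1, 2):
        raise ValueError("max_cleavages must be 1 or 2")
    kinds = frozenset(kinds)
    table = CROSS_RING_TABLE if cross_ring_table is None else cross_ring_table
    root = s.root
    reduction = MASS.reduction_2H if s.reduced else 0.0
    frags: dict[tuple[str, str, float], FragmentIon] = {}

    def emit(kind: str, label: str, neutral: float, retains: bool,
             comp: Composition, site: FragmentSite) -> None:
        key = (kind, label, round(neutral, 6))
        if key in frags:
            frags[key].sites.append(site)
        else:
            frags[key] = FragmentIon(
                kind=kind, label=label, neutral=neutral,
                retains_alditol=retains, composition=comp, sites=[site],
            )

    if "M" in kinds:
        m = _subtree_residue_mass(root) + MASS.water + reduction
        emit("M", "M", m, s.reduced, _subtree_composition(root, s.reduced),
             FragmentSite(retained_root=_pruned_copy(root, set()), at_root=True))

    edges = _edges(root)

    for parent, child in edges:
        sub_mass = _subtree_residue_mass(child)
        sub_comp = _subtree_composition(child)
        nr_site = FragmentSite(retained_root=_pruned_copy(child, set()))
        if "B" in kinds:
            emit("B", "B", sub_mass, False, sub_comp, nr_site)
        if "C" in kinds:
            emit("C", "C", sub_mass + MASS.water, False, sub_comp, nr_site)
        y_neutral = (
            _subtree_residue_mass(root) - sub_mass + MASS.water + reduction
        )
        removed = {id(n) for n in child.walk()}
        kept = _pruned_copy(root, removed)
        site = FragmentSite(retained_root=kept, at_root=True)
        y_comp = _subtree_composition(kept, s.reduced)
        if "Y" in kinds:
            emit("Y", "Y", y_neutral, s.reduced, y_comp, site)
        if "Z" in kinds:
            emit("Z", "Z", y_neutral - MASS.water, s.reduced, y_comp, site)

    if max_cleavages == 2:
        for i, (p1, c1) in enumerate(edges):
            for p2, c2 in edges[i + 1 :]:
                if _is_descendant(c2, c1) or _is_descendant(c1, c2):
                    continue  # nested cuts do not give a root-retaining pair
                lost = _subtree_residue_mass(c1) + _subtree_residue_mass(c2)
                removed = {id(n) for n in c1.walk()} | {id(n) for n in c2.walk()}
                kept = _pruned_copy(root, removed)
                site = FragmentSite(retained_root=kept, at_root=True)
                comp = _subtree_composition(kept, s.reduced)
                y_neutral = (
                    _subtree_residue_mass(root) - lost + MASS.water + reduction
                )
                if "Y" in kinds:
                    emit("Y", "Y/Y", y_neutral, s.reduced, comp, site)
                if "Z" in kinds:
                    emit("Z", "Z/Z", y_neutral - 2 * MASS.water, s.reduced,
                         comp, site)

    if "A" in kinds and s.reduced:
        class_key = f"{root.mass_class}-ol"
        for (key_cls, label), (backbone, positions) in table.items():
            if key_cls != class_key:
                continue
            retained = [
                c for c in root.children
                if c.linkage_position is not None and c.linkage_position in positions
            ]
            if not retained:
                continue  # bare backbone: below any useful mass range
            neutral = backbone + sum(_subtree_residue_mass(c) for c in retained)
            counts: dict[str, int] = {}
            for c in retained:
                for n in c.walk():
                    counts[n.mass_class] = counts.get(n.mass_class, 0) + 1
            site = FragmentSite(
                retained_positions=positions,
                first_residues=tuple(
                    (c.identity, c.anomer, c.linkage_position) for c in retained
                ),
                at_root=True,
            )
            emit("A", label, neutral, False, Composition(counts=counts), site)

    out = list(frags.values())
    out.sort(key=lambda f: (f.neutral, _KIND_ORDER.get(f.kind, 9)))
    return out


def annotate_spectrum(
    peaks: list[tuple[float, float]],
    candidates: list[FragmentIon],
    tol_ppm: float = 20.0,
) -> list[SpectrumMatch]:
    """Match each peak to its nearest candidate fragment within *tol_ppm*.

    One match per peak; unmatched peaks are dropped.  Equidistant candidates
    are broken deterministically by fragment kind order B < C < Y < Z < A.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches: list[SpectrumMatch] = []
    for peak_mz, intensity in peaks:
        best: tuple[float, int, FragmentIon] | None = None
        for f in candidates:
            ppm = (peak_mz - f.mz_1minus) / f.mz_1minus * 1e6
            if abs(ppm) > tol_ppm:
                continue
            key = (abs(ppm), _KIND_ORDER.get(f.kind, 9))
            if best is None or key < (best[0], best[1]):
                best = (abs(ppm), _KIND_ORDER.get(f.kind, 9), f)
        if best is not None:
            f = best[2]
            ppm = (peak_mz - f.mz_1minus) / f.mz_1minus * 1e6
            matches.append(SpectrumMatch(peak_mz, intensity, f, ppm))
    return matches


# ---------------------------------------------------------------------------
# diagnostic rules

@dataclass
class DiagnosticRule:
    """A weighted rule: all *required* descriptors present, none *forbidden*."""

    name: str
    implies: str
    weight: float = 1.0
    required: list[dict] = field(default_factory=list)
    forbidden: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("rule weight must be positive")


@dataclass
class CoreAssignment:
    ranking: list[tuple[str, float]]
    top: str
    tie: bool

    @property
    def unassigned(self) -> bool:
        return self.top == "unassigned"


def _anomer_ok(observed: str, wanted: str) -> bool:
    return wanted == "?" or observed in (wanted, "?")


def _descriptor_satisfied(desc: dict, matches: list[SpectrumMatch]) -> bool:
    dtype = desc["type"]
    for m in matches:
        f = m.fragment
        if dtype == "root_child":
            # a root-retaining ion proving a specific child on the alditol
            if f.kind not in ("Y", "Z", "M"):
                continue
            for site in f.sites:
                r = site.retained_root
                if r is None or not site.at_root:
                    continue
                for c in r.children:
                    if (
                        c.identity == desc["identity"]
                        and _anomer_ok(c.anomer, desc.get("anomer", "?"))
                        and c.linkage_position in (desc.get("position"), None)
                    ):
                        return True
        elif dtype == "root_child_any":
            if f.kind not in ("Y", "Z", "M"):
                continue
            for site in f.sites:
                r = site.retained_root
                if r is None or not site.at_root:
                    continue
                for c in r.children:
                    if c.linkage_position in (desc.get("position"), None):
                        return True
        elif dtype == "chain_A":
            # alditol chain cleavage retaining >=1 residue (6-arm evidence)
            if f.kind != "A":
                continue
            if desc.get("label") and f.label != desc["label"]:
                continue
            for site in f.sites:
                firsts = site.first_residues
                if not firsts:
                    continue
                ident = desc.get("identity")
                if ident is None:
                    return True
                for fi, fa, _fp in firsts:
                    if fi == ident and _anomer_ok(fa, desc.get("anomer", "?")):
                        return True
        elif dtype == "neutral":
            if abs(f.neutral - desc["mass"]) <= desc.get("tol", 0.01):
                return True
        else:
            raise ValueError(f"unknown descriptor type {dtype!r}")
    return False


def default_rules() -> list[DiagnosticRule]:
    """Rules for cores 1-8, derived from the core templates.

    A core with only a C3 substituent is evidenced by a root-retaining ion
    proving that child and contradicted by any 6-arm chain cleavage; a core
    with a 6-arm needs both the C3 evidence (if the template has one) and a
    chain cleavage whose first retained residue matches the template.
    Double-slot cores carry weight 2 (two pieces of evidence).
    """
    rules: list[DiagnosticRule] = []
    for label, (spec3, spec6) in CORE_TEMPLATES.items():
        required: list[dict] = []
        forbidden: list[dict] = []
        if spec3 is not None:
            required.append(
                {"type": "root_child", "identity": spec3[0],
                 "anomer": spec3[1], "position": 3}
            )
        else:
            forbidden.append({"type": "root_child_any", "position": 3})
        if spec6 is not None:
            required.append(
                {"type": "chain_A", "label": "2,4A",
                 "identity": spec6[0], "anomer": spec6[1]}
            )
        else:
            forbidden.append({"type": "chain_A", "label": "2,4A"})
        rules.append(
            DiagnosticRule(
                name=f"{label}-diagnostics",
                implies=label,
                weight=float(len(required)),
                required=required,
                forbidden=forbidden,
            )
        )
    return rules


def load_rules(path: str) -> list[DiagnosticRule]:
    """Load diagnostic rules from a YAML or JSON file."""
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return [DiagnosticRule(**entry) for entry in data]


def score_core_diagnostics(
    matches: list[SpectrumMatch],
    rules: list[DiagnosticRule] | None = None,
) -> CoreAssignment:
    """Score core labels against matched fragments and rank them.

    score(label) = sum of weights of rules implying the label whose required
    descriptors are all matched and no forbidden one is, minus the weight of
    rules whose forbidden set is violated.  All-zero scores (e.g. empty
    match list) are flagged "unassigned"; equal top scores are flagged ties.
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rule set is empty")
    scores: dict[str, float] = {}
    for rule in rules:
        scores.setdefault(rule.implies, 0.0)
        violated = any(_descriptor_satisfied(d, matches) for d in rule.forbidden)
        satisfied = all(_descriptor_satisfied(d, matches) for d in rule.required)
        if violated:
            scores[rule.implies] -= rule.weight
        elif satisfied and rule.required:
            scores[rule.implies] += rule.weight
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    tie = len(ranking) > 1 and ranking[0][1] == ranking[1][1]
    top = ranking[0][0] if ranking[0][1] > 0 and not tie else "unassigned"
    return CoreAssignment(ranking=ranking, top=top, tie=tie)
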