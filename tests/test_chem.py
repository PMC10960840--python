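"""Mass arithmetic and composition search."""

import itertools

import numpy as np
import pytest

from glycomob.chem import (
    MASS,
    Composition,
    allowed_charges,
    mz,
    neutral_mass,
    residue_mass,
    search_compositions,
)

# frozen monoisotopic residue masses computed independently from the CODATA
# atomic masses (C 12, H 1.0078250319, O 15.9949146221, N 14.0030740052,
# S 31.97207069)
_C, _H, _O, _N, _S = 12.0, 1.0078250319, 15.9949146221, 14.0030740052, 31.97207069
ORACLE_RESIDUES = {
    "Hex": 6 * _C + 10 * _H + 5 * _O,
    "HexNAc": 8 * _C + 13 * _H + _N + 5 * _O,
    "dHex": 6 * _C + 10 * _H + 4 * _O,
    "NeuAc": 11 * _C + 17 * _H + _N + 8 * _O,
}
ORACLE_WATER = 2 * _H + _O
ORACLE_2H = 2 * _H
ORACLE_SO3 = _S + 3 * _O


@pytest.mark.parametrize(
    "cls,expected",
    [("Hex", 162.052824), ("dHex", 146.057909), ("HexNAc", 203.079373),
     ("NeuAc", 291.095417)],
)
def test_residue_masses(cls, expected):
    assert residue_mass(cls) == pytest.approx(expected, abs=1e-6)
    assert residue_mass(cls) == pytest.approx(ORACLE_RESIDUES[cls], abs=1e-5)


def test_unknown_residue_class_named_in_error():
    with pytest.raises(ValueError, match="Pent"):
        residue_mass("Pent")


@pytest.mark.parametrize(
    "comp,expected",
    [
        (Composition({"Hex": 1}, reduced=True), 182.079039),
        (Composition({"dHex": 1, "Hex": 2, "HexNAc": 2}, reduced=True),
         896.348524),
        (Composition({"Hex": 1}, reduced=False), 180.063389),
    ],
)
def test_neutral_mass_examples(comp, expected):
    assert neutral_mass(comp) == pytest.approx(expected, abs=1e-5)


def test_neutral_mass_empty_composition_raises():
    with pytest.raises(ValueError):
        neutral_mass(Composition({}))


@pytest.mark.parametrize(
    "text,z,nominal",
    [
        ("Hex2HexNAc2dHex1", 1, 895),
        ("Hex1HexNAc1NeuAc1", 1, 675),
        ("Hex2HexNAc2", 1, 749),
        ("Hex1HexNAc2", 1, 587),
        ("Hex2HexNAc3", 1, 952),
    ],
)
def test_deprotonated_mz_rounds_to_reported_nominal(text, z, nominal):
    assert round(mz(Composition.parse(text), z)) == nominal


def test_mz_double_charge():
    comp = Composition.parse("Hex2HexNAc2")
    assert mz(comp, 2) == pytest.approx((750.290609 - 2 * 1.007276) / 2, abs=1e-4)


def test_mz_strictly_decreasing_in_charge():
    comp = Composition.parse("Hex3HexNAc3NeuAc2")
    values = [mz(comp, z) for z in (1, 2, 3, 4)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_mz_invalid_charge():
    with pytest.raises(ValueError):
        mz(Composition.parse("Hex1HexNAc1"), 0)


@pytest.mark.parametrize(
    "neutral,expected",
    [(896.35, {1}), (1500.0, {1, 2}), (1200.0, {1})],
)
def test_allowed_charges(neutral, expected):
    assert allowed_charges(neutral) == expected


def test_mass_additivity_of_reduced_union():
    rng = np.random.default_rng(11)
    classes = ["Hex", "HexNAc", "dHex", "NeuAc"]
    for _ in range(50):
        a = {c: int(rng.integers(0, 4)) for c in classes}
        b = {c: int(rng.integers(0, 4)) for c in classes}
        if sum(a.values()) == 0 or sum(b.values()) == 0:
            continue
        union = {c: a[c] + b[c] for c in classes}
        lhs = neutral_mass(Composition(union))
        rhs = (
            neutral_mass(Composition(a))
            + neutral_mass(Composition(b))
            - MASS.water
            - MASS.reduction_2H
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)


def test_composition_string_round_trip():
    comp = Composition({"Hex": 2, "HexNAc": 2, "dHex": 1}, sulfate=1)
    assert str(comp) == "Hex2HexNAc2dHex1S1"
    assert Composition.parse(str(comp)) == comp


def _oracle_search(observed, z, tol_ppm, bounds, min_hexnac=1):
    """Independent brute force with independently computed masses."""
    hits = []
    keys = ["Hex", "HexNAc", "dHex", "NeuAc"]
    for counts in itertools.product(*(range(bounds[k] + 1) for k in keys)):
        cdict = dict(zip(keys, counts))
        if sum(counts) == 0 or cdict["HexNAc"] < min_hexnac:
            continue
        for s in range(bounds["S"] + 1):
            m = (
                sum(ORACLE_RESIDUES[k] * cdict[k] for k in keys)
                + s * ORACLE_SO3 + ORACLE_WATER + ORACLE_2H
            )
            theo = (m - z * 1.007276) / z
            if abs(theo - observed) / observed * 1e6 <= tol_ppm:
                hits.append((tuple(counts), s))
    return sorted(hits)


def test_search_unique_assignments():
    hits675 = search_compositions(675.246, 1, 10)
    assert [str(c) for c, _ in hits675] == ["Hex1HexNAc1NeuAc1"]
    hits952 = search_compositions(952.362, 1, 10)
    assert [str(c) for c, _ in hits952] == ["Hex2HexNAc3"]
    assert search_compositions(100.0, 1, 5) == []


def test_search_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    bounds = {"Hex": 4, "HexNAc": 4, "dHex": 2, "NeuAc": 2, "S": 1}
    for _ in range(100):
        observed = float(rng.uniform(300, 1800))
        z = int(rng.integers(1, 3))
        got = search_compositions(observed, z, 10, bounds=bounds)
        got_set = sorted(
            (tuple(c.count(k) for k in ("Hex", "HexNAc", "dHex", "NeuAc")),
             c.sulfate)
            for c, _ in got
        )
        assert got_set == _oracle_search(observed, z, 10, bounds)


def test_search_sorted_by_abs_ppm():
    hits = search_compositions(895.35, 1, 200)
    errs = [abs(p) for _, p in hits]
    assert errs == sorted(errs)


def test_search_empty_bounds_raises():
    with pytest.raises(ValueError):
        search_compositions(675.0, 1, 10,
                            bounds={k: 0 for k in
                                    ("Hex", "HexNAc", "dHex", "NeuAc", "S")})
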