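"""Shared fixtures: core template strings, random tree generation, mzML writer."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from glycomob.structures import GlycanStructure, Residue, parse_structure

#: Condensed text of the eight bare core templates.
CORE_TEMPLATE_TEXT = {
    "core1": "Gal(b1-3)GalNAc-ol",
    "core2": "Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol",
    "core3": "GlcNAc(b1-3)GalNAc-ol",
    "core4": "GlcNAc(b1-3)[GlcNAc(b1-6)]GalNAc-ol",
    "core5": "GalNAc(a1-3)GalNAc-ol",
    "core6": "GlcNAc(b1-6)GalNAc-ol",
    "core7": "GalNAc(a1-6)GalNAc-ol",
    "core8": "Gal(a1-3)GalNAc-ol",
}

#: The four isomeric dHex1Hex2HexNAc2 alditols separated at m/z 895:
#: two core 2 (CCS 273 and 275 Å²) and two core 1 (290 and 297 Å²),
#: all carrying a blood-group H epitope; 275/290 have a type II and 297 a
#: type I chain.
ISOMERS_895 = {
    273.0: "Fuc(a1-2)Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol",
    275.0: "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)[Gal(b1-3)]GalNAc-ol",
    290.0: "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-3)GalNAc-ol",
    297.0: "Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)Gal(b1-3)GalNAc-ol",
}


@pytest.fixture
def core_templates() -> dict[str, str]:
    return dict(CORE_TEMPLATE_TEXT)


@pytest.fixture
def isomers_895() -> dict[float, str]:
    return dict(ISOMERS_895)


_IDENTITIES = ["Gal", "GlcNAc", "GalNAc", "Fuc", "NeuAc"]


def random_tree(rng: np.random.Generator, max_nodes: int = 7) -> GlycanStructure:
    """Random reduced glycan tree rooted at GalNAc-ol (for property tests)."""
    root = Residue(identity="GalNAc")
    nodes = [root]
    n_extra = int(rng.integers(1, max_nodes))
    for _ in range(n_extra):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        taken = {c.linkage_position for c in parent.children}
        free = [p for p in range(2, 7) if p not in taken]
        if not free:
            continue
        child = Residue(
            identity=_IDENTITIES[int(rng.integers(0, len(_IDENTITIES)))],
            anomer="ab?"[int(rng.integers(0, 3))],
            linkage_position=int(free[int(rng.integers(0, len(free)))]),
        )
        parent.children.append(child)
        nodes.append(child)
    root.sort_children()
    return GlycanStructure(root=root, reduced=True)


def write_minimal_mzml(path, mz, mobility, intensity) -> None:
    """Emit a minimal mzML file with m/z, intensity and 1/K0 arrays."""

    def enc(arr):
        return base64.b64encode(
            np.asarray(arr, dtype=np.float64).tobytes()
        ).decode()

    def bda(name, accession, arr):
        return f"""<binaryDataArray encodedLength="0">
  <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
  <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
  <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
  <binary>{enc(arr)}</binary>
 </binaryDataArray>"""

    content = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
   <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
   <binaryDataArrayList count="3">
    {bda("m/z array", "MS:1000514", mz)}
    {bda("intensity array", "MS:1000515", intensity)}
    {bda("mean inverse reduced ion mobility array", "MS:1003006", mobility)}
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run>
</mzML>
"""
    path.write_text(content)


@pytest.fixture
def parsed_isomers_895():
    return {ccs: parse_structure(t) for ccs, t in ISOMERS_895.items()}
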