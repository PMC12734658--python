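"""Independent reference routes used by the test suite.

These deliberately avoid the code paths they check: the cis/trans oracle
works on an embedded 3D conformer (the package classifier is 2D parity
bookkeeping), and the stereoisomer enumeration oracle brute-forces all
descriptor combinations through canonicalization only.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


def same_face_config_3d(smiles: str, seed: int = 7) -> str:
    """cis/trans call from the sign of the two substituent displacements off
    the best-fit ring plane of an embedded conformer."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    centers = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetChiralTag()
        in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    ]
    assert len(centers) == 2
    a, b = centers
    ring = next(r for r in mol.GetRingInfo().AtomRings() if a in r and b in r)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    conf = mol.GetConformer()
    pos = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    ring_xyz = pos[list(ring)]
    centroid = ring_xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_xyz - centroid)
    normal = vt[2]
    signs = []
    for center in (a, b):
        atom = mol.GetAtomWithIdx(center)
        sub = next(
            n.GetIdx()
            for n in atom.GetNeighbors()
            if n.GetIdx() not in ring and n.GetAtomicNum() > 1
        )
        signs.append(np.sign(np.dot(pos[sub] - pos[center], normal)))
    return "cis" if signs[0] * signs[1] > 0 else "trans"


def all_stereoisomer_smiles(template: str) -> dict[tuple[str, str], str]:
    """Brute-force canonical SMILES of the four stereoisomers of a two-slot
    template (slots ``{a}`` and ``{b}`` take tetrahedral descriptors)."""
    out = {}
    for a, b in itertools.product(["[C@H]", "[C@@H]"], repeat=2):
        out[(a, b)] = Chem.CanonSmiles(template.format(a=a, b=b))
    return out
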