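"""Molecular representation and stereochemistry primitives.

Everything downstream (enumeration, profiling, novelty analysis) works on
:class:`Molecule`, a thin identity-carrying wrapper around an RDKit mol with
its canonical isomeric SMILES cached.  The stereochemistry operations model
how racemic, relative-configuration-defined fragments are handled:

* :func:`invert_stereocenters` produces the mirror-image enantiomer by
  flipping every defined tetrahedral descriptor,
* :func:`racemate_key` gives an identity shared by the two enantiomers of a
  racemate (used for deduplication),
* :func:`classify_relative_config` labels a vicinal disubstituted saturated
  ring as *cis* (both exocyclic substituents on the same ring face) or
  *trans*.

Relative configuration is computed by parity bookkeeping on the two chiral
tags, with no 3D embedding; the test suite checks it against an independent
conformer-based same-face oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, rdBase
from rdkit.Chem import Descriptors

__all__ = [
    "Molecule",
    "StereoSummary",
    "ChemCoreError",
    "SmilesParseError",
    "DegenerateInputError",
    "parse_structure",
    "invert_stereocenters",
    "classify_relative_config",
    "racemate_key",
]

_TETRAHEDRAL = (
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)


class ChemCoreError(ValueError):
    """Base class for structure-handling errors."""


class SmilesParseError(ChemCoreError):
    """Raised when a SMILES string cannot be parsed."""


class DegenerateInputError(ChemCoreError):
    """Raised when an input is structurally empty (e.g. only counterions)."""


@dataclass(frozen=True)
class Molecule:
    """A parsed structure with a stable identifier.

    Attributes
    ----------
    id:
        Caller-supplied identifier (e.g. a FRAG label or library row id).
    smiles:
        Canonical isomeric SMILES.  Canonicalization is idempotent, so this
        string is the molecule's identity within one RDKit version.
    mol:
        The parsed RDKit mol (opaque handle; treat as read-only).
    """

    id: str
    smiles: str
    mol: Chem.Mol

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def formula(self) -> str:
        return Chem.rdMolDescriptors.CalcMolFormula(self.mol)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule(id={self.id!r}, smiles={self.smiles!r})"


@dataclass(frozen=True)
class StereoSummary:
    """Counts of defined/undefined tetrahedral centers plus the cis/trans call.

    ``relative_config`` is ``"cis"`` or ``"trans"`` only when the molecule has
    exactly two defined stereocenters sitting on adjacent atoms of one
    saturated ring, each bearing exactly one exocyclic heavy substituent;
    otherwise ``"not_applicable"`` with the counts still reported.
    """

    n_defined_centers: int
    n_undefined_centers: int
    relative_config: str  # "cis" | "trans" | "not_applicable"


def _capture_rdkit_error(smiles_text: str) -> str:
    """Re-parse a bad SMILES with the RDKit log routed to Python to recover
    the token-position diagnostic."""
    records: list[str] = []
    handler = logging.Handler()
    handler.emit = lambda rec: records.append(rec.getMessage())  # type: ignore[method-assign]
    logger = logging.getLogger("rdkit")
    rdBase.LogToPythonLogger()
    logger.addHandler(handler)
    old_level = logger.level
    logger.setLevel(logging.DEBUG)
    try:
        Chem.MolFromSmiles(smiles_text)
    finally:
        logger.removeHandler(handler)
        logger.setLevel(old_level)
        rdBase.LogToCppStreams()
    return "; ".join(records) if records else "unspecified parse failure"


def parse_structure(smiles_text: str, strip_salts: bool = False, id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    With ``strip_salts=True`` the largest covalently connected organic
    component is kept (fragments are typically registered as HCl/HI salts but
    profiled as the neutral parent).  Components are compared by heavy-atom
    count; carbon-containing components always beat carbon-free ones, so an
    inorganic counterion never wins.

    Raises
    ------
    SmilesParseError
        If the SMILES does not parse; the message carries RDKit's diagnostic
        naming the offending token position.
    DegenerateInputError
        If the input is empty, or nothing organic remains after stripping.
    """
    if not smiles_text or not smiles_text.strip():
        raise DegenerateInputError("empty SMILES input")
    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(smiles_text)
    if mol is None:
        raise SmilesParseError(
            f"cannot parse SMILES {smiles_text!r}: {_capture_rdkit_error(smiles_text)}"
        )
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        if not strip_salts:
            raise ChemCoreError(
                f"{smiles_text!r} has {len(frags)} components; "
                "pass strip_salts=True to keep the largest organic one"
            )
        organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
        if not organic:
            raise DegenerateInputError(
                f"{smiles_text!r}: no organic component remains after salt stripping"
            )
        mol = max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    canonical = Chem.MolToSmiles(mol)
    return Molecule(id=id, smiles=canonical, mol=mol)


def invert_stereocenters(mol: Molecule) -> Molecule:
    """Return the enantiomer: every defined tetrahedral descriptor flipped.

    Double-bond geometry and the molecular graph are untouched; undefined
    centers stay undefined.  Applying the operation twice is the identity on
    canonical SMILES.  Molecules with any number of defined centers
    (including zero) are accepted; all of them are inverted.
    """
    inverted = Chem.Mol(mol.mol)
    for atom in inverted.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    # refresh stereo perception so downstream consumers (e.g. chirality-aware
    # fingerprints) see the flipped descriptors, not stale CIP labels
    Chem.AssignStereochemistry(inverted, cleanIt=True, force=True)
    return Molecule(id=mol.id, smiles=Chem.MolToSmiles(inverted), mol=inverted)


def count_stereocenters(mol: Molecule) -> tuple[int, int]:
    """(defined, undefined) tetrahedral stereocenter counts."""
    centers = Chem.FindMolChiralCenters(
        mol.mol, includeUnassigned=True, useLegacyImplementation=False
    )
    defined = sum(1 for _, code in centers if code != "?")
    return defined, len(centers) - defined


def _permutation_parity(seq: list[int], ref: list[int]) -> int:
    """Parity (0 even / 1 odd) of the permutation taking ``seq`` onto ``ref``."""
    seq = list(seq)
    swaps = 0
    for i, want in enumerate(ref):
        j = seq.index(want)
        if j != i:
            seq[i], seq[j] = seq[j], seq[i]
            swaps += 1
    return swaps % 2


def _vicinal_ring_pair(molH: Chem.Mol) -> tuple[int, int, tuple[int, ...]] | None:
    """Locate two defined stereocenters on adjacent atoms of one saturated
    ring, each carrying exactly one exocyclic heavy substituent.

    Returns (idx_a, idx_b, ring_atom_tuple) or None if the pattern does not
    hold.  ``molH`` must have explicit hydrogens.
    """
    centers = [
        a.GetIdx() for a in molH.GetAtoms() if a.GetChiralTag() in _TETRAHEDRAL
    ]
    if len(centers) != 2:
        return None
    a, b = centers
    if molH.GetBondBetweenAtoms(a, b) is None:
        return None
    shared = [r for r in molH.GetRingInfo().AtomRings() if a in r and b in r]
    if len(shared) != 1:
        return None
    ring = shared[0]
    for idx in ring:
        if molH.GetAtomWithIdx(idx).GetIsAromatic():
            return None
    for idx in (a, b):
        atom = molH.GetAtomWithIdx(idx)
        exo_heavy = [
            n for n in atom.GetNeighbors()
            if n.GetIdx() not in ring and n.GetAtomicNum() > 1
        ]
        exo_h = [
            n for n in atom.GetNeighbors()
            if n.GetIdx() not in ring and n.GetAtomicNum() == 1
        ]
        if len(exo_heavy) != 1 or len(exo_h) != 1:
            return None
    return a, b, ring


def classify_relative_config(mol: Molecule) -> StereoSummary:
    """Label a vicinal disubstituted saturated ring as cis or trans.

    The call is made by parity bookkeeping: for each stereocenter the chiral
    tag is re-expressed relative to the neighbor order (other stereocenter,
    other ring neighbor, exocyclic substituent, H).  With both tags in that
    frame, opposite tags mean the two substituents sit on the same ring face
    (cis), equal tags mean opposite faces (trans).  The convention is fixed by
    the ring geometry and is independent of atom numbering; enantiomers flip
    both tags and therefore share the label.

    If the molecule does not present exactly two defined stereocenters on
    adjacent saturated-ring atoms with one exocyclic heavy substituent each,
    ``relative_config`` is ``"not_applicable"``.
    """
    n_def, n_undef = count_stereocenters(mol)
    molH = Chem.AddHs(mol.mol)
    located = _vicinal_ring_pair(molH)
    if located is None:
        return StereoSummary(n_def, n_undef, "not_applicable")
    a, b, ring = located
    frame_tags: list[bool] = []
    for center, other in ((a, b), (b, a)):
        atom = molH.GetAtomWithIdx(center)
        nbrs = [bond.GetOtherAtomIdx(center) for bond in atom.GetBonds()]
        ring_nbr = next(n for n in nbrs if n in ring and n != other)
        h = next(n for n in nbrs if molH.GetAtomWithIdx(n).GetAtomicNum() == 1)
        sub = next(n for n in nbrs if n not in (other, ring_nbr, h))
        ccw = atom.GetChiralTag() == Chem.ChiralType.CHI_TETRAHEDRAL_CCW
        if _permutation_parity(nbrs, [other, ring_nbr, sub, h]):
            ccw = not ccw
        frame_tags.append(ccw)
    config = "cis" if frame_tags[0] != frame_tags[1] else "trans"
    return StereoSummary(n_def, n_undef, config)


def racemate_key(mol: Molecule) -> str:
    """Racemate-level identity: the lexicographically smaller of the canonical
    SMILES of the molecule and of its enantiomer.

    The two enantiomers of any pair map to the same key; diastereomers map to
    different keys.  For achiral molecules the key equals the canonical
    SMILES.
    """
    partner = invert_stereocenters(mol).smiles
    return min(mol.smiles, partner)
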