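"""File I/O, run configuration and the seeded decoy-library generator.

The decoy generator stands in for commercial comparator catalogues in tests
and examples: it assembles drug-like decorated small ring systems by grafting
common substituents onto scaffold templates, with a configurable fraction of
decoys built on each of the collection's four central motifs.  Template-based
assembly guarantees valence-valid, canonicalizable structures without a
validity-filter loop, and a fixed seed makes the output reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

import rdkit

from .chem_core import ChemCoreError, Molecule, parse_structure
from .enumerator import DesignLibrary

__all__ = [
    "RunConfig",
    "DecoySpec",
    "read_smiles_table",
    "write_smiles_table",
    "write_design_table",
    "generate_decoys",
]


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run; fully YAML-serializable.

    Emitted alongside results so any run can be reproduced from its config
    and seed alone.  ``toolkit_version`` records the RDKit release because
    canonical SMILES strings are dialect-dependent.
    """

    seed: int = 42
    ro3_limits: dict = field(
        default_factory=lambda: {
            "mw": 300.0, "clogp": 3.0, "hbd": 3.0, "hba": 3.0, "tpsa": 60.0, "rotb": 3.0,
        }
    )
    fingerprint: dict = field(
        default_factory=lambda: {"radius": 2, "n_bits": 2048, "chirality": False}
    )
    embedding: dict = field(
        default_factory=lambda: {"method": "umap", "n_neighbors": 15, "min_dist": 0.1}
    )
    descriptor_convention: str = (
        "MW standard atomic weights; Crippen cLogP; Lipinski HBD/HBA; "
        "Ertl TPSA; strict rotatable bonds (amide C-N and terminal excluded)"
    )
    toolkit_version: str = field(default_factory=lambda: rdkit.__version__)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**data)


def write_run_log(path: str | Path, command: str, params: dict) -> Path:
    """Plain-text log of a run: tool versions, timestamp, resolved params."""
    path = Path(path)
    lines = [
        f"command: {command}",
        f"timestamp: {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"rdkit: {rdkit.__version__}",
    ]
    lines += [f"{k}: {v}" for k, v in params.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_smiles_table(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: str = "id",
    strip_salts: bool = True,
) -> tuple[list[Molecule], list[tuple[str, str]]]:
    """Read a .smi file or a CSV with SMILES + id columns.

    ``.smi`` rows are whitespace-separated ``SMILES [id]``; CSV needs the
    declared SMILES column (missing id column falls back to the row number).
    Returns (molecules, rejects) where rejects are (raw_row, reason) pairs —
    unparseable rows are reported, never silently dropped.  A file yielding
    no parseable molecule at all is an error.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path, dtype=str)
        if smiles_col not in table.columns:
            raise ValueError(
                f"{path}: CSV lacks required column {smiles_col!r} "
                f"(columns: {list(table.columns)})"
            )
        for i, rec in table.iterrows():
            ident = str(rec[id_col]) if id_col in table.columns else f"row{i}"
            rows.append((str(rec[smiles_col]), ident))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((parts[0], parts[1] if len(parts) > 1 else f"row{i}"))
    mols: list[Molecule] = []
    rejects: list[tuple[str, str]] = []
    for smi, ident in rows:
        try:
            mols.append(parse_structure(smi, strip_salts=strip_salts, id=ident))
        except ChemCoreError as exc:
            rejects.append((f"{smi} {ident}", str(exc)))
    if not mols:
        raise ValueError(f"{path}: no parseable SMILES rows (of {len(rows)})")
    return mols, rejects


def write_smiles_table(mols: Sequence[Molecule], path: str | Path) -> Path:
    """Write molecules as a .smi file (SMILES, id)."""
    path = Path(path)
    path.write_text("".join(f"{m.smiles} {m.id}\n" for m in mols))
    return path


def write_design_table(library: DesignLibrary, path: str | Path) -> Path:
    """Write the design matrix as CSV (one row per design, SMILES included)."""
    path = Path(path)
    rows = []
    for d in library.designs:
        rows.append(
            {
                "frag_id": d.frag_id,
                "scaffold": d.scaffold,
                "head_position": d.head_position,
                "aryl_position": d.aryl_position,
                "relative_config": d.relative_config,
                "aryl": d.aryl,
                "polar_head": d.polar_head,
                "status": d.status,
                "status_reason": d.status_reason,
                "smiles": library.molecules[d.frag_id].smiles,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# --- decoy generation -------------------------------------------------------

#: Motif scaffolds (grafting sites: ring carbons with a free H).
_MOTIF_SCAFFOLDS = {
    "pyrrolidine": "C1CCNC1",
    "piperidine": "C1CCNCC1",
    "cyclic_sulfone_6": "O=S1(=O)CCCCC1",
    "gem_difluorocyclohexane": "FC1(F)CCCCC1",
}

#: Motif-free filler scaffolds emulating generic commercial fragment cores.
_FILLER_SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "C1CCCCC1",        # cyclohexane
    "C1CCCC1",         # cyclopentane
    "C1CCOCC1",        # tetrahydropyran
    "C1CCOC1",         # tetrahydrofuran
    "C1COCCN1",        # morpholine
    "c1ccc2ccccc2c1",  # naphthalene
]

#: Small common substituents (attachment at the first atom of each fragment).
DEFAULT_SUBSTITUENTS = {
    "fluoro": "F",
    "chloro": "Cl",
    "methyl": "C",
    "methoxy": "OC",
    "hydroxyl": "O",
    "amide": "C(N)=O",
    "nitrile": "C#N",
    "phenyl": "c1ccccc1",
}


@dataclass
class DecoySpec:
    """Parameters of one decoy library.

    ``motif_fractions`` gives, per central motif, the fraction of decoys
    built on that scaffold (exclusive draw; the fractions must sum to <= 1,
    the remainder is built on motif-free filler rings).  One to
    ``max_substituents`` substituents from the pool are grafted onto random
    ring carbons, no two on the same atom.
    """

    n_molecules: int
    motif_fractions: dict[str, float] = field(default_factory=dict)
    substituents: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUENTS)
    )
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.motif_fractions) - set(_MOTIF_SCAFFOLDS)
        if unknown:
            raise ValueError(f"unknown motifs in DecoySpec: {sorted(unknown)}")
        bad = {k: v for k, v in self.motif_fractions.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"motif fractions outside [0,1]: {bad}")
        if sum(self.motif_fractions.values()) > 1 + 1e-9:
            raise ValueError(
                f"motif fractions sum to {sum(self.motif_fractions.values()):.3f} > 1"
            )
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")


def _graft(scaffold: Chem.Mol, sub_smiles: Sequence[str], rng: np.random.Generator) -> Chem.Mol:
    """Attach each substituent to a distinct ring carbon bearing a hydrogen.

    Sites are drawn without replacement from the pristine scaffold, so no
    atom is substituted twice (this also keeps a filler cyclohexane from
    accidentally acquiring a gem-difluoro motif)."""
    sites = [
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetAtomicNum() == 6 and a.IsInRing() and a.GetTotalNumHs() >= 1
    ]
    chosen_sites = rng.choice(sites, size=min(len(sub_smiles), len(sites)), replace=False)
    mol = Chem.RWMol(scaffold)
    for site, smi in zip(chosen_sites, sub_smiles):
        frag = Chem.MolFromSmiles(smi)
        offset = mol.GetNumAtoms()
        mol.InsertMol(frag)
        mol.AddBond(int(site), offset, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def generate_decoys(spec: DecoySpec) -> list[Molecule]:
    """Generate a seeded decoy library emulating a commercial fragment set.

    Each decoy's scaffold category is drawn from the motif fractions (with
    the leftover probability on motif-free fillers), then decorated with
    1..max_substituents random substituents.  Output is deterministic for a
    given spec + seed and every structure is valence-valid by construction.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = sorted(spec.motif_fractions)
    probs = [spec.motif_fractions[m] for m in motifs]
    p_filler = 1.0 - sum(probs)
    categories = motifs + ["__filler__"]
    probs = np.array(probs + [p_filler])
    probs = probs / probs.sum()
    subs = sorted(spec.substituents)
    decoys: list[Molecule] = []
    for i in range(spec.n_molecules):
        cat = categories[int(rng.choice(len(categories), p=probs))]
        if cat == "__filler__":
            scaffold_smiles = _FILLER_SCAFFOLDS[int(rng.choice(len(_FILLER_SCAFFOLDS)))]
        else:
            scaffold_smiles = _MOTIF_SCAFFOLDS[cat]
        scaffold = Chem.MolFromSmiles(scaffold_smiles)
        n_subs = int(rng.integers(1, spec.max_substituents + 1))
        chosen = [spec.substituents[subs[int(j)]] for j in rng.choice(len(subs), size=n_subs)]
        mol = _graft(scaffold, chosen, rng)
        decoys.append(
            Molecule(id=f"DECOY{i + 1}", smiles=Chem.MolToSmiles(mol), mol=mol)
        )
    return decoys
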