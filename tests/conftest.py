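import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from heterofrag.chem_core import Molecule, parse_structure
from heterofrag.enumerator import (
    enumerate_designs,
    load_design_config,
    packaged_design_path,
)
from heterofrag.workbench import DecoySpec, generate_decoys


@pytest.fixture(scope="session")
def design_library():
    """The packaged design matrix, enumerated once per session."""
    return enumerate_designs(load_design_config(packaged_design_path()))


@pytest.fixture(scope="session")
def synthesized_molecules(design_library):
    synth = design_library.subset(status="synthesized")
    return [synth.molecules[d.frag_id] for d in synth.designs]


@pytest.fixture(scope="session")
def decoy_benchmark():
    """The packaged decoy comparator: 1000 decoys, motif fractions 0.4
    piperidine / 0.3 pyrrolidine / 0.05 sulfone / 0.05 difluorocyclohexane."""
    spec = DecoySpec(
        n_molecules=1000,
        motif_fractions={
            "piperidine": 0.4,
            "pyrrolidine": 0.3,
            "cyclic_sulfone_6": 0.05,
            "gem_difluorocyclohexane": 0.05,
        },
        seed=1,
    )
    return spec, generate_decoys(spec)


def random_chiral_molecules(n: int, seed: int) -> list[Molecule]:
    """A reproducible pool of molecules with defined stereocenters, built by
    assigning stereochemistry to generated ring systems."""
    spec = DecoySpec(
        n_molecules=4 * n,
        motif_fractions={"piperidine": 0.35, "pyrrolidine": 0.35},
        seed=seed,
    )
    opts = StereoEnumerationOptions(maxIsomers=1, rand=seed)
    out: list[Molecule] = []
    for decoy in generate_decoys(spec):
        isomers = list(EnumerateStereoisomers(decoy.mol, options=opts))
        if not isomers:
            continue
        iso = isomers[0]
        if not any(
            a.GetChiralTag()
            in (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            )
            for a in iso.GetAtoms()
        ):
            continue
        out.append(parse_structure(Chem.MolToSmiles(iso), id=decoy.id))
        if len(out) == n:
            break
    assert len(out) == n, f"only {len(out)} chiral molecules generated"
    return out


@pytest.fixture(scope="session")
def chiral_pool():
    return random_chiral_molecules(100, seed=11)
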