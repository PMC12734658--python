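"""Physicochemical profiling of a fragment library against Rule-of-3 limits.

Six descriptors per molecule — molecular weight, Crippen cLogP, Lipinski
H-bond donors/acceptors, Ertl topological polar surface area, and strict
rotatable-bond count — averaged over the library and normalized to
fragment-likeness (Rule-of-3) limits for radar-plot comparison.

Descriptors are computed on the neutral parent structure.  Because all six
are constitutional/2D, an enantiomer pair has identical values; the racemate
average therefore equals the single-enantiomer value, and
:func:`racemate_properties` asserts that equality at run time rather than
assuming it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chem_core import ChemCoreError, Molecule, invert_stereocenters

__all__ = [
    "PROPERTY_NAMES",
    "PropertyVector",
    "Ro3Limits",
    "LibraryStats",
    "RadarProfile",
    "compute_properties",
    "racemate_properties",
    "property_table",
    "library_statistics",
    "ro3_profile",
    "radar_render",
]

PROPERTY_NAMES = ("mw", "clogp", "hbd", "hba", "tpsa", "rotb")


@dataclass(frozen=True)
class PropertyVector:
    """The six fragment-relevant descriptors.

    mw in g/mol (standard atomic weights, implicit H included); clogp is the
    Crippen atom-contribution logP (unitless); hbd/hba are Lipinski counts
    (O-H/N-H donors, N/O acceptors); tpsa is the Ertl fragment-contribution
    topological polar surface area in A^2; rotb counts non-ring single bonds
    between heavy atoms excluding amide C-N and terminal bonds.
    """

    mw: float
    clogp: float
    hbd: int
    hba: int
    tpsa: float
    rotb: int

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mw, self.clogp, self.hbd, self.hba, self.tpsa, self.rotb)


@dataclass(frozen=True)
class Ro3Limits:
    """Rule-of-3 fragment-likeness limits.

    MW < 300 g/mol, logP < 3 and HBD/HBA < 3 follow the printed Rule-of-3;
    the TPSA (<= 60 A^2) and rotatable-bond (<= 3) axes follow the common
    extended convention so that all six radar axes have a normalization
    target.  Compliance is evaluated with strict "<"; a value exactly at the
    limit is reported as non-compliant.
    """

    mw: float = 300.0
    clogp: float = 3.0
    hbd: float = 3.0
    hba: float = 3.0
    tpsa: float = 60.0
    rotb: float = 3.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"Ro3 limit {f.name} must be positive")


@dataclass(frozen=True)
class LibraryStats:
    """Per-property mean/SD/min/max over a library (racemate properties).

    ``sd`` uses the sample convention (n - 1); for a single molecule it is
    reported as 0.0 with ``sd_defined`` False.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    n_molecules: int
    sd_defined: bool


@dataclass(frozen=True)
class RadarProfile:
    """Library means normalized to Ro3 limits, plus compliance bookkeeping."""

    normalized_means: dict[str, float]
    reference: dict[str, float]
    limits: Ro3Limits
    compliance_fraction: dict[str, float]
    fully_compliant_fraction: float


def compute_properties(mol: Molecule) -> PropertyVector:
    """Compute the six descriptors for a neutral single-component parent.

    Charged or multi-component input raises :class:`ChemCoreError`: profiling
    is defined on salt-stripped neutral parents (see
    :func:`heterofrag.chem_core.parse_structure`).
    """
    m = mol.mol
    if len(Chem.GetMolFrags(m)) > 1:
        raise ChemCoreError(f"{mol.id or mol.smiles}: multi-component input; strip salts first")
    if Chem.GetFormalCharge(m) != 0:
        raise ChemCoreError(f"{mol.id or mol.smiles}: charged input; profiler expects neutral parents")
    return PropertyVector(
        mw=Descriptors.MolWt(m),
        clogp=Crippen.MolLogP(m),
        hbd=Lipinski.NumHDonors(m),
        hba=Lipinski.NumHAcceptors(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(m),
    )


def racemate_properties(mol: Molecule) -> PropertyVector:
    """Racemate-representative descriptors: the mean over both enantiomers.

    All six descriptors are constitutional, so the mean must equal the
    single-enantiomer value exactly; that equality is asserted here as a
    run-time self-check of descriptor chirality-blindness rather than taken
    on faith.
    """
    own = compute_properties(mol)
    partner = compute_properties(invert_stereocenters(mol))
    averaged = PropertyVector(
        mw=(own.mw + partner.mw) / 2.0,
        clogp=(own.clogp + partner.clogp) / 2.0,
        hbd=(own.hbd + partner.hbd) // 2,
        hba=(own.hba + partner.hba) // 2,
        tpsa=(own.tpsa + partner.tpsa) / 2.0,
        rotb=(own.rotb + partner.rotb) // 2,
    )
    if averaged != own:  # descriptors must be blind to chirality
        raise AssertionError(
            f"{mol.id or mol.smiles}: enantiomer descriptor mismatch {own} vs {partner}"
        )
    return averaged


def property_table(mols: Sequence[Molecule]) -> pd.DataFrame:
    """Per-molecule racemate property table (one row per molecule)."""
    rows = []
    for m in mols:
        pv = racemate_properties(m)
        rows.append({"id": m.id, "smiles": m.smiles, **asdict(pv)})
    return pd.DataFrame(rows)


def library_statistics(mols: Sequence[Molecule]) -> LibraryStats:
    """Mean/SD/min/max of racemate properties over a non-empty library."""
    if len(mols) == 0:
        raise ValueError("library_statistics requires at least one molecule")
    table = property_table(mols)[list(PROPERTY_NAMES)].astype(float)
    sd_defined = len(mols) > 1
    sd = table.std(ddof=1) if sd_defined else pd.Series(0.0, index=table.columns)
    return LibraryStats(
        mean=table.mean().to_dict(),
        sd=sd.to_dict(),
        min=table.min().to_dict(),
        max=table.max().to_dict(),
        n_molecules=len(mols),
        sd_defined=sd_defined,
    )


def ro3_profile(
    stats: LibraryStats,
    limits: Ro3Limits = Ro3Limits(),
    mols: Sequence[Molecule] | None = None,
) -> RadarProfile:
    """Normalize library means to Ro3 limits.

    ``normalized_means[p] = mean[p] / limit[p]``; the unit reference vector is
    the Ro3 boundary itself.  When the molecules are supplied, per-property
    compliance fractions (strict ``value < limit``) and the fraction of
    molecules compliant on all six axes are evaluated; otherwise those fields
    are NaN.
    """
    lim = {f.name: getattr(limits, f.name) for f in fields(limits)}
    normalized = {p: stats.mean[p] / lim[p] for p in PROPERTY_NAMES}
    reference = {p: 1.0 for p in PROPERTY_NAMES}
    if mols is not None:
        table = property_table(mols)[list(PROPERTY_NAMES)].astype(float)
        flags = pd.DataFrame({p: table[p] < lim[p] for p in PROPERTY_NAMES})
        compliance = flags.mean().to_dict()
        fully = float(flags.all(axis=1).mean())
    else:
        compliance = {p: math.nan for p in PROPERTY_NAMES}
        fully = math.nan
    return RadarProfile(normalized, reference, limits, compliance, fully)


def radar_render(profile: RadarProfile, path: str | Path) -> Path:
    """Write the six-axis radar plot and a companion CSV of its numbers.

    The library polygon (normalized means) is drawn against the unit Ro3
    reference polygon.  A CSV with the same stem carries the plotted values
    so the figure is reproducible without re-running the profiler.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    labels = list(PROPERTY_NAMES)
    values = [profile.normalized_means[p] for p in labels]
    ref = [profile.reference[p] for p in labels]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False).tolist()
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(5, 5))
    for series, style, label in (
        (ref, "r--", "Ro3 limit"),
        (values, "-", "library mean"),
    ):
        closed = series + series[:1]
        ax.plot(angles + angles[:1], closed, style, label=label)
    ax.fill(angles + angles[:1], values + values[:1], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels([lbl.upper() for lbl in labels])
    ax.set_title("Library profile normalized to Rule-of-3 limits")
    ax.legend(loc="lower right", bbox_to_anchor=(1.15, -0.1))
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["property", "normalized_mean", "ro3_reference"])
        for lbl, v, r in zip(labels, values, ref):
            writer.writerow([lbl, f"{v:.6f}", f"{r:.1f}"])
    return path
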