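"""Enumeration of the stereochemically explicit fragment design matrix.

A design configuration (YAML) declares series of (scaffold, substitution
pattern) with blocks of allowed polar heads, aryl groups and relative
configurations, plus an editorial fragment numbering and per-fragment
synthesis status.  :func:`enumerate_designs` expands the configuration into a
:class:`DesignLibrary`: one :class:`FragmentDesign` row per fragment and one
materialized enantiomer SMILES per racemate, deduplicated by racemate key.

Ring positions count from the anchor group — the ring nitrogen, the sulfonyl
sulfur, or the CF2 carbon — as position 1.  The aryl group always sits
vicinal to the polar head (|head_position - aryl_position| = 1), reflecting
arylation directed to the position beta to the head-group attachment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

import yaml

from .chem_core import (
    Molecule,
    classify_relative_config,
    invert_stereocenters,
    parse_structure,
    racemate_key,
)

__all__ = [
    "ScaffoldTemplate",
    "FragmentDesign",
    "DesignLibrary",
    "SeriesSpec",
    "ConfigError",
    "SCAFFOLDS",
    "ARYL_SMILES",
    "HEAD_SMILES",
    "packaged_design_path",
    "load_design_config",
    "build_structure",
    "enumerate_designs",
    "tally",
]

STATUSES = ("synthesized", "commercial", "not_prepared")
STEREO = ("cis", "trans")

#: Aryl substituents as SMILES fragments (attachment at the first atom).
ARYL_SMILES = {
    "4-methoxyphenyl": "c1ccc(OC)cc1",
    "4-fluorophenyl": "c1ccc(F)cc1",
}

#: Polar head groups as SMILES fragments (attachment at the first atom).
HEAD_SMILES = {
    "carboxylic_acid": "C(=O)O",
    "primary_amide": "C(N)=O",
    "primary_alcohol": "CO",
    "nitrile": "C#N",
}


@dataclass(frozen=True)
class ScaffoldTemplate:
    """A ring skeleton with two adjacent substitution sites.

    ``smiles_core`` is a format template whose ``{A}``/``{B}`` slots take the
    stereocenter atoms (head site and aryl site respectively) and whose
    ``{head}``/``{aryl}`` slots take the substituent SMILES.  The ring is
    written starting from the head site, so the two sites close the ring bond
    and are guaranteed adjacent.
    """

    name: str
    ring_size: int
    anchor: str  # ring atom defining position 1: "N", "SO2" or "CF2"
    head_position: int
    aryl_position: int
    smiles_core: str


#: Supported (scaffold, head_position, aryl_position) combinations.
SCAFFOLDS: dict[tuple[str, int, int], ScaffoldTemplate] = {}


def _register(name, ring_size, anchor, head_pos, aryl_pos, core):
    tpl = ScaffoldTemplate(name, ring_size, anchor, head_pos, aryl_pos, core)
    SCAFFOLDS[(name, head_pos, aryl_pos)] = tpl


_register("pyrrolidine", 5, "N", 2, 3, "{A}1({head})NCC{B}1{aryl}")
_register("pyrrolidine", 5, "N", 3, 4, "{A}1({head})CNC{B}1{aryl}")
_register("piperidine", 6, "N", 2, 3, "{A}1({head})NCCC{B}1{aryl}")
_register("piperidine", 6, "N", 3, 4, "{A}1({head})CNCC{B}1{aryl}")
_register("piperidine", 6, "N", 4, 3, "{A}1({head})CCNC{B}1{aryl}")
_register("cyclic_sulfone_6", 6, "SO2", 4, 3, "{A}1({head})CCS(=O)(=O)C{B}1{aryl}")
_register("gem_difluorocyclohexane", 6, "CF2", 4, 3, "{A}1({head})CCC(F)(F)C{B}1{aryl}")

#: Scaffold families counted together as N-heterocycles in library tallies.
N_HETEROCYCLES = ("pyrrolidine", "piperidine")


class ConfigError(ValueError):
    """Design configuration fails schema or chemical-invariant validation."""


@dataclass(frozen=True)
class FragmentDesign:
    """One row of the design matrix."""

    frag_id: str
    scaffold: str
    head_position: int
    aryl_position: int
    relative_config: str  # cis | trans
    aryl: str
    polar_head: str
    status: str = "synthesized"
    status_reason: str = ""


@dataclass
class SeriesSpec:
    """One series of the configuration: a scaffold/pattern with its blocks."""

    name: str
    scaffold: str
    head_position: int
    aryl_position: int
    blocks: list[dict] = field(default_factory=list)
    #: frag_id -> {status, reason} annotations shared across the config
    status_map: dict = field(default_factory=dict)


@dataclass
class DesignLibrary:
    """The enumerated matrix: ordered designs plus one molecule per racemate."""

    designs: list[FragmentDesign]
    molecules: dict[str, Molecule]

    def __len__(self) -> int:
        return len(self.designs)

    def subset(self, status: str | None = None, scaffolds=None) -> "DesignLibrary":
        """Filtered view (by status and/or scaffold family), order preserved."""
        keep = [
            d for d in self.designs
            if (status is None or d.status == status)
            and (scaffolds is None or d.scaffold in scaffolds)
        ]
        return DesignLibrary(keep, {d.frag_id: self.molecules[d.frag_id] for d in keep})


def packaged_design_path() -> Path:
    """Path to the design configuration shipped with the package."""
    return Path(resources.files("heterofrag.data") / "design_matrix.yaml")


def load_design_config(path: str | Path) -> list[SeriesSpec]:
    """Load and validate a design configuration file.

    Raises :class:`ConfigError` listing the failing keys on schema violation,
    including a violated vicinal rule (head and aryl positions must be
    adjacent) or an unknown scaffold/pattern combination.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "series" not in raw:
        raise ConfigError(f"{path}: expected a mapping with a 'series' list")
    problems: list[str] = []
    specs: list[SeriesSpec] = []
    for i, ser in enumerate(raw["series"] or []):
        label = ser.get("name", f"series[{i}]")
        missing = [k for k in ("scaffold", "head_position", "aryl_position", "blocks") if k not in ser]
        if missing:
            problems.append(f"{label}: missing keys {missing}")
            continue
        hp, ap = ser["head_position"], ser["aryl_position"]
        if abs(hp - ap) != 1:
            problems.append(
                f"{label}: vicinal rule violated (|head_position - aryl_position| "
                f"= {abs(hp - ap)}, must be 1)"
            )
        if (ser["scaffold"], hp, ap) not in SCAFFOLDS:
            problems.append(f"{label}: no scaffold template for ({ser['scaffold']}, {hp}, {ap})")
        blocks = []
        for j, blk in enumerate(ser["blocks"] or []):
            bad = [k for k in ("head", "stereo", "aryl", "frag_ids") if k not in blk]
            if bad:
                problems.append(f"{label} block[{j}]: missing keys {bad}")
                continue
            if blk["head"] not in HEAD_SMILES:
                problems.append(f"{label} block[{j}]: unknown head {blk['head']!r}")
            unknown_aryl = [a for a in blk["aryl"] if a not in ARYL_SMILES]
            if unknown_aryl:
                problems.append(f"{label} block[{j}]: unknown aryl {unknown_aryl}")
            bad_stereo = [s for s in blk["stereo"] if s not in STEREO]
            if bad_stereo:
                problems.append(f"{label} block[{j}]: unknown stereo {bad_stereo}")
            n_expect = len(blk["stereo"]) * len(blk["aryl"])
            if len(blk["frag_ids"]) != n_expect:
                problems.append(
                    f"{label} block[{j}]: {len(blk['frag_ids'])} frag_ids for "
                    f"{n_expect} stereo x aryl combinations"
                )
            blocks.append(blk)
        specs.append(SeriesSpec(label, ser["scaffold"], hp, ap, blocks))
    status = raw.get("status", {}) or {}
    for fid, entry in status.items():
        if not isinstance(entry, dict) or entry.get("status") not in STATUSES:
            problems.append(f"status.{fid}: status must be one of {STATUSES}")
    if problems:
        raise ConfigError("invalid design config:\n  " + "\n  ".join(problems))
    if not specs:
        raise ConfigError(f"{path}: no series defined")
    for s in specs:
        s.status_map = status
    return specs


def build_structure(design: FragmentDesign) -> Molecule:
    """Assemble the isomeric SMILES realizing a design.

    The two stereocenters are written with explicit descriptors chosen so that
    the parity-based relative-configuration classifier returns the requested
    cis/trans label; the classification is asserted on the result.  Of the two
    enantiomers of the racemate, the one whose canonical SMILES equals the
    racemate key (the lexicographically smaller) is materialized.  The ring
    N-H of N-heterocycles is free: protecting groups belong to the synthesis,
    not the fragment.
    """
    key = (design.scaffold, design.head_position, design.aryl_position)
    if key not in SCAFFOLDS:
        raise ConfigError(f"no scaffold template for {key}")
    tpl = SCAFFOLDS[key]
    head = HEAD_SMILES[design.polar_head]
    aryl = ARYL_SMILES[design.aryl]
    for b_tag in ("[C@H]", "[C@@H]"):
        smi = tpl.smiles_core.format(A="[C@H]", B=b_tag, head=head, aryl=aryl)
        mol = parse_structure(smi, id=design.frag_id)
        summary = classify_relative_config(mol)
        if summary.relative_config == design.relative_config:
            break
    else:  # pragma: no cover - both parities classified, one must match
        raise ConfigError(f"{design.frag_id}: cannot realize {design.relative_config}")
    key_smiles = racemate_key(mol)
    if mol.smiles != key_smiles:
        mol = invert_stereocenters(mol)
    assert classify_relative_config(mol).relative_config == design.relative_config
    return mol


def enumerate_designs(specs: list[SeriesSpec]) -> DesignLibrary:
    """Expand series specifications into the full design library.

    Blocks expand with relative configuration as the outer loop and aryl
    group as the inner loop, matching the editorial fragment numbering.
    Duplicate fragment ids or racemate-key collisions across distinct ids
    raise :class:`ConfigError` (the matrix must be a set of distinct
    racemates).
    """
    status_map = specs[0].status_map if specs else {}
    designs: list[FragmentDesign] = []
    molecules: dict[str, Molecule] = {}
    for spec in specs:
        for blk in spec.blocks:
            combos = [(s, a) for s in blk["stereo"] for a in blk["aryl"]]
            for (stereo, aryl), fid in zip(combos, blk["frag_ids"]):
                entry = status_map.get(fid, {})
                design = FragmentDesign(
                    frag_id=fid,
                    scaffold=spec.scaffold,
                    head_position=spec.head_position,
                    aryl_position=spec.aryl_position,
                    relative_config=stereo,
                    aryl=aryl,
                    polar_head=blk["head"],
                    status=entry.get("status", "synthesized"),
                    status_reason=entry.get("reason", ""),
                )
                if design.frag_id in molecules:
                    raise ConfigError(f"duplicate frag_id {design.frag_id}")
                designs.append(design)
                molecules[design.frag_id] = build_structure(design)
    keys: dict[str, str] = {}
    for d in designs:
        k = racemate_key(molecules[d.frag_id])
        if k in keys:
            raise ConfigError(
                f"racemate-key collision: {d.frag_id} duplicates {keys[k]} ({k})"
            )
        keys[k] = d.frag_id
    return DesignLibrary(designs, molecules)


def tally(library: DesignLibrary) -> dict:
    """Bookkeeping counts: totals, per status, per scaffold, and the
    synthesized-per-scaffold breakdown used for library summaries."""
    by_status = Counter(d.status for d in library.designs)
    by_scaffold = Counter(d.scaffold for d in library.designs)
    by_reason = Counter(d.status_reason for d in library.designs if d.status_reason)
    synth = [d for d in library.designs if d.status == "synthesized"]
    synth_by_scaffold = Counter(d.scaffold for d in synth)
    return {
        "total": len(library.designs),
        "by_status": dict(by_status),
        "by_scaffold": dict(by_scaffold),
        "by_status_reason": dict(by_reason),
        "synthesized_by_scaffold": dict(synth_by_scaffold),
        "synthesized_total": len(synth),
        "synthesized_n_heterocycle": sum(
            n for s, n in synth_by_scaffold.items() if s in N_HETEROCYCLES
        ),
        "synthesized_other_ring": sum(
            n for s, n in synth_by_scaffold.items() if s not in N_HETEROCYCLES
        ),
    }
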