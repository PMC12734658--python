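"""Chemical-space novelty analysis against comparator fragment libraries.

The workflow mirrors how a new fragment collection is benchmarked against
commercial catalogues: comparator molecules sharing one of the collection's
central ring motifs are extracted by SMARTS matching, everything is encoded
as folded Morgan (circular) fingerprints, novelty is scored as one minus the
maximum Tanimoto similarity to the comparator set, and the joint fingerprint
matrix is embedded in 2D (UMAP, or PCA as the deterministic fallback) with a
silhouette coefficient quantifying how well the collection separates.

Fingerprints default to radius 2 (ECFP4-like), 2048 bits, chirality excluded
so that the two enantiomers of a racemate coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_core import Molecule

__all__ = [
    "ScaffoldQuerySet",
    "BitFingerprint",
    "SimilarityReport",
    "Embedding2D",
    "DEFAULT_QUERIES",
    "scaffold_filter",
    "morgan_fingerprint",
    "fingerprint_matrix",
    "tanimoto",
    "nearest_neighbor_report",
    "embed_2d",
    "separation_score",
    "scatter_render",
]

#: Central ring motifs of the collection, as SMARTS.  Aliphatic-only ring
#: atoms keep aromatic look-alikes (pyrrole, pyridine) out; the sulfone and
#: gem-difluoro patterns pin both geminal substituents so plain thianes and
#: monofluorides do not match.
DEFAULT_QUERY_SMARTS = {
    "pyrrolidine": "[#7X3;!$([#7]~[!#6;!#1])]1[CX4][CX4][CX4][CX4]1",
    "piperidine": "[#7X3;!$([#7]~[!#6;!#1])]1[CX4][CX4][CX4][CX4][CX4]1",
    "cyclic_sulfone_6": "[SX4]1(=[OX1])(=[OX1])[CX4][CX4][CX4][CX4][CX4]1",
    "gem_difluorocyclohexane": "[CX4]1(F)(F)[CX4][CX4][CX4][CX4][CX4]1",
}

#: Parent scaffolds each motif must match (and the other motifs must not).
PARENT_SCAFFOLD_SMILES = {
    "pyrrolidine": "C1CCNC1",
    "piperidine": "C1CCNCC1",
    "cyclic_sulfone_6": "O=S1(=O)CCCCC1",
    "gem_difluorocyclohexane": "FC1(F)CCCCC1",
}


class QueryError(ValueError):
    """Invalid SMARTS or a query set failing its parent-scaffold check."""


@dataclass
class ScaffoldQuerySet:
    """Named SMARTS patterns for the central ring motifs.

    On construction every pattern is compiled (invalid SMARTS fail here, not
    per molecule) and validated against the parent scaffolds: each pattern
    must match its own parent ring and none of the other three.
    """

    smarts: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_QUERY_SMARTS)
    )
    validate_parents: bool = True

    def __post_init__(self):
        self.patterns: dict[str, Chem.Mol] = {}
        for name, sm in self.smarts.items():
            patt = Chem.MolFromSmarts(sm)
            if patt is None:
                raise QueryError(f"invalid SMARTS for motif {name!r}: {sm!r}")
            self.patterns[name] = patt
        if self.validate_parents:
            for name, patt in self.patterns.items():
                if name not in PARENT_SCAFFOLD_SMILES:
                    continue
                for parent, parent_smiles in PARENT_SCAFFOLD_SMILES.items():
                    parent_mol = Chem.MolFromSmiles(parent_smiles)
                    hit = parent_mol.HasSubstructMatch(patt)
                    if (parent == name) != hit:
                        raise QueryError(
                            f"motif {name!r} {'misses' if parent == name else 'matches'} "
                            f"parent scaffold {parent!r}"
                        )

    def match(self, mol: Molecule) -> frozenset[str]:
        return frozenset(
            name for name, patt in self.patterns.items()
            if mol.mol.HasSubstructMatch(patt)
        )


DEFAULT_QUERIES = ScaffoldQuerySet


@dataclass(frozen=True)
class BitFingerprint:
    """A folded binary substructure fingerprint."""

    bits: np.ndarray  # bool array, length n_bits
    radius: int
    mol_id: str = ""

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class SimilarityReport:
    """Nearest-neighbor novelty of one query molecule vs a reference set."""

    query_id: str
    max_tanimoto: float
    nearest_id: str

    @property
    def novelty(self) -> float:
        return 1.0 - self.max_tanimoto


@dataclass(frozen=True)
class Embedding2D:
    """Planar coordinates of a fingerprint collection plus run metadata."""

    coords: np.ndarray  # (n, 2)
    method: str  # "umap" | "pca"
    metric: str
    seed: int
    params: dict


def scaffold_filter(
    library: Sequence[Molecule], queries: ScaffoldQuerySet | None = None
) -> list[tuple[Molecule, frozenset[str]]]:
    """Extract library members containing at least one central motif.

    Returns (molecule, matched-motif-set) pairs in input order; molecules
    matching no motif are dropped.
    """
    queries = queries or ScaffoldQuerySet()
    out = []
    for mol in library:
        hits = queries.match(mol)
        if hits:
            out.append((mol, hits))
    return out


def morgan_fingerprint(
    mol: Molecule, radius: int = 2, n_bits: int = 2048, chirality: bool = False
) -> BitFingerprint:
    """Folded Morgan fingerprint.

    Chirality is excluded from the atom environments by default so an
    enantiomer pair hashes identically, consistent with racemate-level
    comparison.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=chirality
    )
    arr = gen.GetFingerprintAsNumPy(mol.mol).astype(bool)
    arr.setflags(write=False)
    return BitFingerprint(bits=arr, radius=radius, mol_id=mol.id)


def fingerprint_matrix(fps: Sequence[BitFingerprint]) -> np.ndarray:
    """Stack fingerprints into an (n, n_bits) boolean matrix."""
    if not fps:
        raise ValueError("no fingerprints given")
    sizes = {fp.n_bits for fp in fps}
    if len(sizes) != 1:
        raise ValueError(f"mixed fingerprint lengths {sorted(sizes)}")
    return np.stack([fp.bits for fp in fps])


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |A and B| / |A or B|.

    Two all-zero fingerprints are defined as identical (similarity 1.0).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


def nearest_neighbor_report(
    queries: Sequence[BitFingerprint], references: Sequence[BitFingerprint]
) -> list[SimilarityReport]:
    """Exact maximum-Tanimoto search of every query against the references.

    Brute force by design: comparator libraries at this scale (tens of
    thousands) are a single dense matrix product.
    """
    if not queries:
        raise ValueError("empty query set")
    if not references:
        raise ValueError("empty reference set")
    q = fingerprint_matrix(queries).astype(np.int32)
    r = fingerprint_matrix(references).astype(np.int32)
    if q.shape[1] != r.shape[1]:
        raise ValueError(f"fingerprint length mismatch: {q.shape[1]} vs {r.shape[1]}")
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    best = sim.argmax(axis=1)
    return [
        SimilarityReport(
            query_id=fp.mol_id,
            max_tanimoto=float(sim[i, best[i]]),
            nearest_id=references[best[i]].mol_id,
        )
        for i, fp in enumerate(queries)
    ]


def report_table(reports: Sequence[SimilarityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.query_id for r in reports],
            "max_tanimoto": [r.max_tanimoto for r in reports],
            "nearest_id": [r.nearest_id for r in reports],
            "novelty": [r.novelty for r in reports],
        }
    )


def embed_2d(
    fps: Sequence[BitFingerprint],
    method: str = "umap",
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding2D:
    """Embed fingerprints in the plane.

    ``method="umap"`` uses the Jaccard metric on the raw bit vectors with a
    fixed random state; coordinates are reproducible for a given seed but
    carry the usual rotation/reflection freedom between library versions.
    ``method="pca"`` projects the centered bit matrix onto its top two
    principal components and is bit-for-bit deterministic; it is the fallback
    the test suite leans on.
    """
    X = fingerprint_matrix(fps)
    n = X.shape[0]
    if method == "pca":
        if n < 3:
            raise ValueError(f"pca embedding needs >= 3 fingerprints, got {n}")
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(
            X.astype(float)
        )
        params = {"svd_solver": "full"}
        metric = "euclidean"
    elif method == "umap":
        if n < n_neighbors + 1:
            raise ValueError(
                f"umap embedding needs >= n_neighbors+1 = {n_neighbors + 1} fingerprints, got {n}"
            )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from umap import UMAP

            coords = UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                metric="jaccard",
                random_state=seed,
            ).fit_transform(X)
        params = {"n_neighbors": n_neighbors, "min_dist": min_dist}
        metric = "jaccard"
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        method=method,
        metric=metric,
        seed=seed,
        params=params,
    )


def separation_score(embedding: Embedding2D, labels: Sequence) -> float:
    """Mean silhouette coefficient of a labeling in the 2D embedding.

    Euclidean distance on the planar coordinates; positive values mean the
    labeled groups occupy distinguishable regions.  Requires at least two
    labels with at least two members each.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != embedding.coords.shape[0]:
        raise ValueError("one label per embedded point required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError(
            "separation_score needs >= 2 labels with >= 2 members each; "
            f"got {dict(zip(uniq.tolist(), counts.tolist()))}"
        )
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(embedding.coords, labels, metric="euclidean"))


def scatter_render(
    embedding: Embedding2D,
    labels: Sequence[str],
    path,
    highlight: str | None = None,
):
    """Scatter plot of the embedding, one color per label; the ``highlight``
    label (typically the in-house collection) is overplotted as crosses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(labels):
        sel = labels == lab
        if lab == highlight:
            continue
        ax.scatter(*embedding.coords[sel].T, s=12, alpha=0.5, label=str(lab))
    if highlight is not None:
        sel = labels == highlight
        ax.scatter(*embedding.coords[sel].T, marker="x", c="green", s=40, label=str(highlight))
    ax.set_xlabel(f"{embedding.method} 1")
    ax.set_ylabel(f"{embedding.method} 2")
    ax.legend()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
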