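# heterofrag

Design, Rule-of-3 profiling and chemical-space novelty analysis of
stereodefined heterocyclic fragment libraries.

## The problem

Fragment-based drug discovery screens very small molecules (< 300 Da) and
elaborates the hits.  A well-curated fragment collection therefore needs
(i) controlled *exit vectors* — the directions in which a bound fragment can
be grown, set by the substitution pattern and the cis/trans relative
configuration of the ring substituents; (ii) fragment-like physicochemical
properties (the Rule-of-3: MW < 300 g/mol, logP < 3, H-bond donors and
acceptors < 3, with the common extensions TPSA ≤ 60 Å² and ≤ 3 rotatable
bonds); and (iii) structural novelty relative to what commercial catalogues
already cover.

`heterofrag` is the computational side of building such a collection on four
saturated ring cores — pyrrolidine, piperidine, a six-membered cyclic
sulfone, and gem-difluorocyclohexane — each carrying an aryl group
(4-methoxyphenyl or 4-fluorophenyl) vicinal to a polar head group
(carboxylic acid, primary amide, primary alcohol, or nitrile) in defined
*cis* or *trans* relative configuration, prepared as racemates.  The package
is for medicinal/computational chemists who want to enumerate such a design
matrix, audit its bookkeeping, profile it against Ro3 limits, and quantify
its novelty against any comparator SMILES collection.

## What it computes

- **Enumeration** (`enumerator`): expands a declarative YAML design matrix
  (series × aryl × head × stereochemistry) into stereochemically explicit
  SMILES, one enantiomer per racemate, deduplicated by *racemate key*
  (the lexicographically smaller of the canonical SMILES of a molecule and
  its mirror image — identical for the two enantiomers of a pair, distinct
  for diastereomers).
- **Stereochemistry** (`chem_core`): enantiomer generation by inverting all
  defined tetrahedral descriptors, and cis/trans classification of vicinal
  disubstituted saturated rings by parity bookkeeping on the two chiral
  tags (no 3D embedding; the test suite checks it against a conformer-based
  same-face oracle).
- **Profiling** (`profiler`): per-molecule MW, Crippen cLogP, Lipinski
  HBD/HBA, Ertl TPSA and strict rotatable-bond counts; racemate-aware
  library statistics; means normalized to Ro3 limits
  (`mean_p / limit_p`) for the six-axis radar plot.
- **Novelty** (`novelty`): SMARTS extraction of comparator molecules sharing
  one of the four ring motifs, 2048-bit Morgan fingerprints (radius 2,
  chirality-blind so racemates coincide), exact nearest-neighbor Tanimoto
  novelty (`1 − max T`), seeded 2D embedding (UMAP with Jaccard metric, or
  PCA as the deterministic fallback) and a silhouette separation score.
- **Workbench** (`workbench` + `heterofrag` CLI): .smi/CSV I/O with audited
  rejects, run logs, and a seeded template-based decoy generator that stands
  in for commercial catalogues in tests and benchmarks.

## Worked example

```bash
python examples/enumerate_library.py
python examples/profile_library.py
```

prints (abridged):

```
designs enumerated:            51
synthesized:                   44
  N-heterocycles:              38
  sulfone / CF2 rings:         6
commercially available (skip): 2
not prepared:                  5

property     mean      sd      max  limit  mean/limit
mw         224.47   20.84   284.33  300.0       0.748
clogp        1.39    0.68     3.30    3.0       0.465
hbd          1.82    0.39     2.00    3.0       0.606
hba          2.55    0.59     4.00    3.0       0.848
tpsa        49.71   11.81    80.67   60.0       0.828
rotb         2.55    0.55     3.00    3.0       0.848
```

Of the 51 designs in the packaged matrix, 44 carry status `synthesized`;
every `mean/limit` ratio is below 1.0, i.e. the library average sits inside
Ro3 fragment space on all six axes (the heaviest member is 284.3 g/mol,
still under the 300 g/mol fragment limit).  `examples/novelty_benchmark.py`
and `examples/stereochemistry.py` walk through the novelty pipeline and the
stereochemistry primitives the same way, and the `heterofrag` CLI exposes
each step (`enumerate`, `profile`, `radar`, `novelty`, `embed`, `decoys`)
for shell use.

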