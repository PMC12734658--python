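"""Stereochemistry primitives: enantiomer inversion, racemate identity, and
cis/trans classification of vicinal disubstituted rings."""

from heterofrag import (
    classify_relative_config,
    invert_stereocenters,
    parse_structure,
    racemate_key,
)

# a 2,3-disubstituted pyrrolidine: acid head at C2, 4-methoxyphenyl at C3
mol = parse_structure("COc1ccc([C@@H]2CCN[C@@H]2C(=O)O)cc1", id="example")
ent = invert_stereocenters(mol)

print(f"molecule:   {mol.smiles}")
print(f"enantiomer: {ent.smiles}")
print(f"same racemate key: {racemate_key(mol) == racemate_key(ent)}")

for label, m in (("original", mol), ("enantiomer", ent)):
    s = classify_relative_config(m)
    print(
        f"{label:10s} defined centers={s.n_defined_centers} "
        f"relative configuration={s.relative_config}"
    )

# flipping one of the two descriptors gives the diastereomer, not the mirror
dia = parse_structure("COc1ccc([C@H]2CCN[C@@H]2C(=O)O)cc1", id="dia")
print(f"diastereomer relative configuration: "
      f"{classify_relative_config(dia).relative_config}")
print(f"diastereomer shares racemate key: {racemate_key(dia) == racemate_key(mol)}")
# Enantiomers share cis/trans label and racemate key; diastereomers share
# neither — the basis for deduplicating a racemic design matrix.
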