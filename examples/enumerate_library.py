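"""Enumerate the packaged fragment design matrix and print its bookkeeping.

The design configuration declares seven series — (scaffold, substitution
pattern) combinations — each expanded over its allowed aryl groups, polar
head groups and cis/trans relative configurations.  One enantiomer SMILES is
materialized per racemate.
"""

from heterofrag import enumerate_designs, load_design_config, packaged_design_path, tally

library = enumerate_designs(load_design_config(packaged_design_path()))
counts = tally(library)

print(f"designs enumerated:            {counts['total']}")
print(f"synthesized:                   {counts['synthesized_total']}")
print(f"  N-heterocycles:              {counts['synthesized_n_heterocycle']}")
print(f"  sulfone / CF2 rings:         {counts['synthesized_other_ring']}")
print(f"commercially available (skip): {counts['by_status'].get('commercial', 0)}")
print(f"not prepared:                  {counts['by_status'].get('not_prepared', 0)}")
print()
print("first rows of the matrix:")
for design in library.designs[:5]:
    mol = library.molecules[design.frag_id]
    print(
        f"  {design.frag_id:7s} {design.scaffold:12s} "
        f"{design.head_position},{design.aryl_position}-{design.relative_config:5s} "
        f"{design.polar_head:15s} {design.aryl:15s} {mol.smiles}"
    )
# The counts are the library's ledger: 51 considered designs, of which 44
# were realized (38 on pyrrolidine/piperidine cores, 6 on sulfone/CF2 rings),
# 2 skipped as commercial paroxetine substructures and 5 blocked by chemistry.
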