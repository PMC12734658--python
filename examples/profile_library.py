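"""Profile the synthesized fragments against Rule-of-3 fragment space.

Computes the six fragment-relevant descriptors per molecule (racemate-aware),
averages them over the library, normalizes to Ro3 limits and renders the
radar plot.  A normalized mean below 1.0 means the library average sits
inside the fragment-likeness boundary on that axis.
"""

from pathlib import Path

from heterofrag import (
    Ro3Limits,
    enumerate_designs,
    library_statistics,
    load_design_config,
    packaged_design_path,
    radar_render,
    ro3_profile,
)

library = enumerate_designs(load_design_config(packaged_design_path()))
synthesized = library.subset(status="synthesized")
mols = [synthesized.molecules[d.frag_id] for d in synthesized.designs]

stats = library_statistics(mols)
profile = ro3_profile(stats, Ro3Limits(), mols=mols)

print(f"library size: {stats.n_molecules}")
print(f"{'property':8s} {'mean':>8s} {'sd':>7s} {'max':>8s} {'limit':>6s} {'mean/limit':>11s}")
for p in ("mw", "clogp", "hbd", "hba", "tpsa", "rotb"):
    print(
        f"{p:8s} {stats.mean[p]:8.2f} {stats.sd[p]:7.2f} {stats.max[p]:8.2f} "
        f"{getattr(profile.limits, p):6.1f} {profile.normalized_means[p]:11.3f}"
    )
print(f"\nfraction compliant on all six axes: {profile.fully_compliant_fraction:.2f}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = radar_render(profile, out / "radar.svg")
print(f"radar plot written to {path} (numbers in {path.with_suffix('.csv')})")
# Every mean/limit ratio below 1.0 puts the library average inside Ro3
# fragment space; individual molecules may still exceed single limits
# (see the per-axis compliance fractions in the profile object).
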