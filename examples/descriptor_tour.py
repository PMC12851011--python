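"""Compute the full descriptor vector for one scaffold and explain the 3D terms."""

from spirospace.descriptors import compute_descriptor_vector
from spirospace.geometry import embed_and_optimize
from spirospace.library import ScaffoldRecord

record = ScaffoldRecord("pip", "C1CCNCC1", "piperidine")
conf = embed_and_optimize(record, n_starts=10, seed=2025)
vec = compute_descriptor_vector(record, conf)

print(f"{record.name}: best-of-10 conformer, "
      f"{conf.meta['forcefield']} energy {conf.energy:.2f} kcal/mol\n")
for cat in ("1D", "2D", "3D"):
    print(f"{cat} descriptors:")
    for name, value in vec.values.items():
        if vec.categories[name] == cat:
            unit = f" {vec.units[name]}" if vec.units[name] else ""
            print(f"  {name:<16s} {value:10.3f}{unit}")
    print()

print("pbf is the mean heavy-atom distance from the least-squares plane (0 = flat);")
print("asphericity runs from 0 (sphere-like) to 1 (rod-like); volume is the grid")
print("union of Bondi vdW spheres; strain_energy is the force-field proxy relative")
print("to the hydrogen-capped ring-opened analogue.")
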