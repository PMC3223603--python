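"""Steric descriptors of a conformer population.

Prints monopole volume, shape quadrupole (length/width/height second
moments) and feature counts for a few synthetic compounds.
"""

from combotan import GeneratorConfig, describe, sample_population

population = sample_population(GeneratorConfig(seed=3, n_compounds=5))
print(f"{'cid':>4} {'atoms':>5} {'V (A^3)':>9} {'Qx':>8} {'Qy':>8} {'Qz':>8} {'features':>8}")
for conf in population:
    d = describe(conf)
    print(
        f"{d.cid:>4} {d.heavy_atom_count:>5} {d.volume:>9.1f} "
        f"{d.q[0]:>8.1f} {d.q[1]:>8.1f} {d.q[2]:>8.1f} {d.total_features:>8}"
    )

# The volume is the first-order inclusion-exclusion Gaussian volume; the
# quadrupole components (Qx >= Qy >= Qz) are the principal second moments of
# the steric density, i.e. a measure of conformer length, width and height.
# Both are invariant under rigid motion.
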