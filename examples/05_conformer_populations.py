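"""Conformer population bookkeeping: prune, group, normalize.

A conformer-sampling run (e.g. CREST) yields relative energies and raw
Boltzmann-weighted populations. Conformers that differ only in parts
invisible to the RDC analysis (a remote rotamer) are grouped; high-energy,
low-population conformers are pruned; retained group populations are
renormalized to 1.
"""

from rdctensor import PopulationTable, boltzmann, combine_and_normalize, prune_conformers

table = PopulationTable(
    conf_ids=("01", "02", "03", "04", "05", "06"),
    e_rel=(0.000, 0.108, 1.496, 1.935, 2.258, 2.449),   # kcal/mol
    p_raw=(0.4881, 0.4064, 0.0391, 0.0187, 0.0048, 0.0052),
    groups={"01": "g1", "02": "g1", "03": "g2", "04": "g2",
            "05": "g3", "06": "g3"},
)

pruned = prune_conformers(table, e_max=2.2, p_min=0.01)
print("retained conformers:", ", ".join(pruned.conf_ids))

final = combine_and_normalize(pruned)
print(f"\n{'group':<8}{'p_comb':>9}{'p_norm':>9}")
for g in sorted(final.p_comb):
    print(f"{g:<8}{final.p_comb[g]:>9.4f}{final.p_norm[g]:>9.4f}")

p = boltzmann([0.0, 0.108], temperature=298.15)
print(f"\npure Boltzmann ratio for the 0.108 kcal/mol gap: {p[1] / p[0]:.3f}")
# The ~94:6 normalized split between the two retained groups is what an
# ensemble RDC fit would take as its starting populations. The raw
# populations are consumed as given: sampling tools fold conformer
# degeneracies into them, so they are not pure Boltzmann factors.
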