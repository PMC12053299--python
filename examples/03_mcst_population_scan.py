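"""Multi-conformer-single-tensor (MCST) fit with a population scan.

A flexible molecule exchanging between two conformers is simulated at a
70:30 population ratio. Scanning the MCST quality factor Q over the
population p1 of conformer 1 recovers the mixing ratio at the minimum of
Q(p1), and beats both single-conformer fits.
"""

from rdctensor import (
    SimulationSpec,
    make_two_conformer_system,
    random_saupe,
    scan_populations,
    simulate_rdcs,
)

p_true = 0.70
spec = SimulationSpec(
    n_vectors=15, gdo_target=5e-4, noise_sigma=0.3, seed=11,
    geometry="two-conformer-dihedral", populations=(p_true, 1 - p_true),
)
conf_a, conf_b, _ = make_two_conformer_system(spec)
S = random_saupe(5e-4, seed=11)
dataset = simulate_rdcs([conf_a, conf_b], S, [p_true, 1 - p_true], spec)

result = scan_populations((conf_a, conf_b), dataset, step=0.01)

print(f"true population of conformer A : {p_true:.2f}")
print(f"Q(p1=1.00), conformer A only   : {result.fits_endpoints[0].q:.4f}")
print(f"Q(p1=0.00), conformer B only   : {result.fits_endpoints[1].q:.4f}")
print(f"scan minimum                   : Q({result.p_best:.2f}) = {result.fit_best.q:.4f}")
print("\np1      Q(p1)")
for p, q in zip(result.grid[::10], result.q_curve[::10]):
    print(f"{p:.2f}   {q:.4f}")

# The ensemble fit at the recovered population improves on the better
# single-conformer fit; a sharp, single minimum indicates the two
# conformers' RDC predictions differ enough to resolve the ratio.
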