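"""Extract residual dipolar couplings from scalar/total coupling pairs.

A one-bond coupling measured in an isotropic solvent gives the scalar
coupling J; the same splitting measured in a weakly aligning medium gives
the total coupling T = J + 2D. The difference yields the RDC D with its
propagated error.
"""

from rdctensor import extract_rdc

measurements = [
    # atom pair, J (Hz), sigJ, T (Hz), sigT
    ("C1-H1", 125.4, 0.20, 145.9, 0.30),
    ("C2-H2", 131.0, 0.15, 118.6, 0.25),
    ("C3-H3", 127.2, 0.20, 127.2, 0.20),
]

print(f"{'pair':<8}{'J/Hz':>8}{'T/Hz':>8}{'D/Hz':>8}{'sigD/Hz':>9}")
for pair, J, sigJ, T, sigT in measurements:
    D, sigD = extract_rdc(J, sigJ, T, sigT)
    print(f"{pair:<8}{J:>8.2f}{T:>8.2f}{D:>8.2f}{sigD:>9.3f}")

# D = (T - J)/2: positive when alignment widens the splitting, zero when the
# anisotropic and isotropic splittings coincide. sigD combines both
# measurement errors in quadrature (halved, like D itself).
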