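# rdctensor

Analysis of residual dipolar couplings (RDCs) for small-molecule structure
elucidation: alignment-tensor fitting by error-weighted SVD, multi-conformer
ensemble fits in a common Eckart frame, quality factors, tensor comparison for
enantiodifferentiation, and conformer-population bookkeeping.

## The problem

When a small molecule is dissolved in a weakly aligning medium (for example a
lyotropic liquid-crystalline phase of a helical polyglutamate in chloroform),
the dipolar coupling between bonded nuclei no longer averages to zero. The
measured one-bond splitting becomes *T* = *J* + 2*D*, where *J* is the scalar
coupling from an isotropic sample and *D* the residual dipolar coupling. Each
RDC is linear in the Saupe order matrix **S** — a symmetric, traceless 3×3
matrix with five independent elements describing the average orientation of
the molecule relative to the magnetic field:

> *D* = κ · **e**ᵀ **S** **e**,   κ = −μ₀γ₁γ₂h / (16π³ r³)

with **e** the internuclear unit vector in the molecular frame. Five or more
RDCs in general position therefore determine **S** by linear least squares,
and the agreement between measured and back-calculated RDCs — the Cornilescu
quality factor *Q* = √(Σ(D_exp − D_calc)² / ΣD_exp²) — scores how well a
structural model explains the data.

The package implements both analysis modes used in practice:

- **SCST** (single conformer, single tensor): one rigid structure, one
  error-weighted SVD fit.
- **MCST** (multiple conformers, single tensor): interconverting conformers
  are superposed into a common Eckart frame (mass-weighted RMSD-minimizing
  rotation), the design matrix is the population-weighted sum over
  conformers, and scanning *Q*(*p*₁) over the population of conformer 1
  locates the solution-state conformer ratio at the minimum.

It also computes the generalized 5D angle β between two alignment tensors
(β = 0° means two media orient the analyte identically — no
enantiodifferentiation), Boltzmann/combined/normalized conformer populations,
and ships seeded synthetic-data generators so the whole pipeline can be
exercised and tested without any experimental data.

## Worked example

Fit a tensor to a simulated rigid molecule (`examples/02_scst_fit.py`):

```python
from rdctensor import (SimulationSpec, make_rigid_molecule, random_saupe,
                       simulate_rdcs, fit_scst)

spec = SimulationSpec(n_vectors=10, gdo_target=5e-4, noise_sigma=0.3, seed=42)
conformer, _ = make_rigid_molecule(spec)
S_true = random_saupe(gdo_target=5e-4, seed=42)
dataset = simulate_rdcs([conformer], S_true, [1.0], spec)
fit = fit_scst(conformer, dataset)
print(fit.q, fit.tensor.gdo)
```

prints `Q = 0.0386` and `GDO = 4.69e-04`: with 0.3 Hz of noise on couplings
of a few Hz, the fit recovers the generating tensor (true GDO 5e-4) with a
quality factor in the range typical of good experimental data. The ensemble
workflow (`examples/03_mcst_population_scan.py`) simulates a 70:30
two-conformer mixture and recovers it from the *Q*(*p*₁) scan:

```
Q(p1=1.00), conformer A only   : 0.1476
Q(p1=0.00), conformer B only   : 0.3605
scan minimum                   : Q(0.69) = 0.0198
```

— the ensemble fit at the recovered population is a large improvement over
either single conformer, and the minimum sits one grid step from the true
mixing fraction. The other examples cover RDC extraction from (J, T) pairs,
the β-angle between two media's tensors, and population bookkeeping.

A thin command line mirrors the library:

```bash
rdctensor simulate --n-vectors 10 --seed 1 --out-prefix sim
rdctensor fit --structure sim_A.xyz --couplings sim_rdc.tsv --out fit.json
rdctensor scan --structure a.xyz --structure b.xyz --couplings rdc.tsv --out scan.json
rdctensor compare --fit1 fit1.json --fit2 fit2.json
rdctensor populations --table pops.tsv
```

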