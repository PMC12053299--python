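import numpy as np
import pytest

import rdctensor as rt

# Conformer population table for a six-conformer ensemble from a CREST/DFT
# run: relative energies (kcal/mol) and raw Boltzmann-weighted populations,
# with conformer pairs (01,02) and (03,04) indistinguishable to the RDC
# analysis (they differ only in a methoxy rotamer / remote ring pucker).
CREST_TABLE = {
    "conf_ids": ("01", "02", "03", "04", "05", "06"),
    "e_rel": (0.000, 0.108, 1.496, 1.935, 2.258, 2.449),
    "p_raw": (0.4881, 0.4064, 0.0391, 0.0187, 0.0048, 0.0052),
    "groups": {"01": "g1", "02": "g1", "03": "g2", "04": "g2",
               "05": "g3", "06": "g3"},
}


@pytest.fixture
def crest_table() -> rt.PopulationTable:
    return rt.PopulationTable(
        conf_ids=CREST_TABLE["conf_ids"],
        e_rel=CREST_TABLE["e_rel"],
        p_raw=CREST_TABLE["p_raw"],
        groups=dict(CREST_TABLE["groups"]),
    )


@pytest.fixture
def rigid_system():
    """Noiseless synthetic rigid molecule: (conformer, true tensor, dataset)."""
    spec = rt.SimulationSpec(n_vectors=10, gdo_target=5e-4, noise_sigma=0.0, seed=11)
    conf, _ = rt.make_rigid_molecule(spec)
    S = rt.random_saupe(5e-4, 11)
    ds = rt.simulate_rdcs([conf], S, [1.0], spec)
    return conf, S, ds


@pytest.fixture
def two_conformer_system():
    """Noiseless 70:30 two-conformer mixture: (A, B, true tensor, dataset)."""
    spec = rt.SimulationSpec(
        n_vectors=15, gdo_target=5e-4, noise_sigma=0.0, seed=7,
        geometry="two-conformer-dihedral", populations=(0.7, 0.3),
    )
    a, b, _ = rt.make_two_conformer_system(spec)
    S = rt.random_saupe(5e-4, 7)
    ds = rt.simulate_rdcs([a, b], S, [0.7, 0.3], spec)
    return a, b, S, ds


def random_traceless(rng: np.random.Generator, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric traceless 3x3 matrix (helper for tensor tests)."""
    sxx, syy, sxy, sxz, syz = rng.standard_normal(5) * scale
    return np.array(
        [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]]
    )
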