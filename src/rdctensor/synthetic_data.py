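"""Synthetic structures, alignment tensors and RDC datasets.

The generators emulate the data regime of small rigid organic molecules in a
weakly ordering lyotropic liquid-crystal medium: 8-20 one-bond C-H vectors
in general position, generalized degrees of order around 1e-4 to 1e-3
(giving RDCs in the tens of Hz), homoscedastic Gaussian coupling noise of
0.1-1 Hz, and two-conformer mixtures with a known mixing fraction.  A single
integer seed drives one named pseudo-random stream per generator, so every
output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .couplings import effective_vector
from .molio import Atom, Conformer, CouplingRecord, RDCDataset
from .saupe_fit import SIGMA_FLOOR, SaupeTensor, tensor_params

__all__ = [
    "SimulationSpec",
    "random_saupe",
    "make_rigid_molecule",
    "make_two_conformer_system",
    "simulate_rdcs",
]

_CH_BOND = 1.09  # Å
_STREAMS = {"saupe": 1, "geometry": 2, "noise": 3, "couplings": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``geometry`` is one of ``random-rigid`` (quasi-uniform C-H vectors),
    ``template`` (same construction, reserved for user-supplied templates)
    or ``two-conformer-dihedral`` (conformer B differs from A by rotating a
    subset of vectors by ``dihedral_deg`` about a common axis).
    """

    n_vectors: int = 10
    gdo_target: float = 5e-4
    noise_sigma: float = 0.0
    populations: tuple[float, ...] = (1.0,)
    seed: int = 0
    geometry: str = "random-rigid"
    dihedral_deg: float = 40.0

    def __post_init__(self) -> None:
        if self.n_vectors < 5:
            raise ValueError("need at least 5 vectors for a determinate tensor fit")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        p = np.asarray(self.populations, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be a valid simplex vector")
        if self.geometry not in ("random-rigid", "template", "two-conformer-dihedral"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def random_saupe(gdo_target: float, seed: int) -> SaupeTensor:
    """Random symmetric traceless tensor rescaled to an exact target GDO."""
    if gdo_target <= 0:
        raise ValueError("gdo_target must be positive")
    rng = _rng(seed, "saupe")
    sxx, syy, sxy, sxz, syz = rng.standard_normal(5)
    S = np.array(
        [
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]
    )
    gdo = np.sqrt((2.0 / 3.0) * np.sum(S * S))
    return tensor_params(S * (gdo_target / gdo))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def _build_molecule(spec: SimulationSpec) -> tuple[Conformer, RDCDataset]:
    rng = _rng(spec.seed, "geometry")
    R = _random_rotation(rng)
    bond_dirs = _fibonacci_sphere(spec.n_vectors) @ R.T
    # carbons sit on a larger quasi-uniform shell so atom positions are distinct
    c_pos = 3.0 * (_fibonacci_sphere(spec.n_vectors)[::-1] @ R.T)
    atoms: list[Atom] = []
    records: list[CouplingRecord] = []
    for i in range(spec.n_vectors):
        c_label, h_label = f"C{i + 1}", f"H{i + 1}"
        atoms.append(Atom(label=c_label, element="C", mass=12.011, xyz=c_pos[i]))
        atoms.append(
            Atom(
                label=h_label,
                element="H",
                mass=1.008,
                xyz=c_pos[i] + _CH_BOND * bond_dirs[i],
            )
        )
        records.append(
            CouplingRecord(atom1=c_label, atom2=h_label, ctype="CH", D=0.0, sigD=None)
        )
    conf = Conformer(id="synthetic-A", atoms=tuple(atoms), e_rel=0.0)
    return conf, RDCDataset(records=records, meta={"seed": spec.seed, "synthetic": True})


def make_rigid_molecule(spec: SimulationSpec) -> tuple[Conformer, RDCDataset]:
    """A rigid molecule of n C-H pairs at 1.09 Å in general position.

    Bond directions are quasi-uniform on the sphere (no two closer than 5
    degrees for n <= 50), which guarantees rank-5 design matrices.  The
    returned dataset is a skeleton: pairs and coupling types only, D = 0.
    """
    if spec.geometry not in ("random-rigid", "template"):
        raise ValueError("make_rigid_molecule expects random-rigid or template geometry")
    return _build_molecule(spec)


def make_two_conformer_system(
    spec: SimulationSpec,
) -> tuple[Conformer, Conformer, RDCDataset]:
    """Two conformers sharing labels, differing by a dihedral-like rotation.

    Conformer B equals A with the last half of the C-H units rotated by
    ``spec.dihedral_deg`` about the z axis of A's frame (a fixed common
    axis through the origin), emulating a ring-flip or side-chain rotation.
    """
    if spec.geometry != "two-conformer-dihedral":
        raise ValueError("make_two_conformer_system expects two-conformer-dihedral geometry")
    conf_a, ds = _build_molecule(spec)
    theta = np.radians(spec.dihedral_deg)
    c, s = np.cos(theta), np.sin(theta)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    coords = conf_a.coords.copy()
    # move whole C-H units (atom order is C1, H1, C2, H2, ...)
    moving = (np.arange(len(coords)) // 2) >= spec.n_vectors // 2
    coords[moving] = coords[moving] @ Rz.T
    conf_b = conf_a.with_coords(coords)
    conf_b = Conformer(id="synthetic-B", atoms=conf_b.atoms, e_rel=0.5)
    return conf_a, conf_b, ds


def simulate_rdcs(
    confs,
    S: SaupeTensor | np.ndarray,
    pops,
    spec: SimulationSpec,
) -> RDCDataset:
    """Forward-simulate an RDC dataset from a tensor and conformer mixture.

    D_i = sum_k pops_k * scale_i * kappa_i * (e_ik^T S e_ik), evaluated
    after superposing every conformer onto the first; Gaussian noise
    N(0, noise_sigma^2) is added per record.  J is drawn from N(145, 10^2)
    Hz and T = J + 2D, so scalar-to-RDC extraction can be exercised on the
    emitted table; sigD is the noise level (or the default error floor for
    noiseless data).
    """
    from .ensemble_fit import eckart_superpose

    if isinstance(S, SaupeTensor):
        S = S.S
    S = np.asarray(S, dtype=float)
    confs = list(confs)
    pops = np.asarray(pops, dtype=float)
    if pops.shape != (len(confs),) or np.any(pops < 0) or abs(pops.sum() - 1.0) > 1e-9:
        raise ValueError("invalid population vector")

    template = confs[0]
    ds_out: list[CouplingRecord] = []
    frames = [template] + [eckart_superpose(template, c) for c in confs[1:]]

    skeleton = [
        CouplingRecord(atom1=f"C{i + 1}", atom2=f"H{i + 1}", ctype="CH", D=0.0)
        for i in range(sum(a.element == "C" for a in template.atoms))
    ]
    noise_rng = _rng(spec.seed, "noise")
    j_rng = _rng(spec.seed, "couplings")
    sig = spec.noise_sigma if spec.noise_sigma > 0 else SIGMA_FLOOR
    for rec in skeleton:
        d = 0.0
        for frame, p in zip(frames, pops):
            eff = effective_vector(frame, rec)
            e = eff.unit_vec
            d += p * eff.scale * eff.kappa * float(e @ S @ e)
        if spec.noise_sigma > 0:
            d += noise_rng.normal(0.0, spec.noise_sigma)
        J = j_rng.normal(145.0, 10.0)
        ds_out.append(
            CouplingRecord(
                atom1=rec.atom1,
                atom2=rec.atom2,
                ctype="CH",
                J=J,
                sigJ=sig,
                T=J + 2.0 * d,
                sigT=sig,
                D=d,
                sigD=sig,
            )
        )
    return RDCDataset(
        records=ds_out,
        meta={"seed": spec.seed, "pops": pops.tolist(), "synthetic": True},
    )
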