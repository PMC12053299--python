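"""Coupling-to-RDC conversion and per-record geometric/physical factors.

The convention is fixed throughout the package: the total one-bond splitting
in the partially oriented phase is

    T = J + 2 D

so the dipolar contribution to the splitting is 2D.  With the dipolar
prefactor below, an internuclear vector fully ordered along the field
(e.g. a C-H bond with S_zz = 1 along z) gives D equal to half the static
dipolar splitting, which keeps the forward simulator and the fitter on one
consistent absolute scale.  The absolute scale cancels in the Cornilescu Q
for datasets of a single coupling type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .molio import Conformer, CouplingRecord

__all__ = [
    "GAMMA",
    "EffectiveCoupling",
    "ConversionError",
    "extract_rdc",
    "dipolar_prefactor",
    "effective_vector",
]

#: Gyromagnetic ratios, rad s^-1 T^-1 (CODATA proton; 13C literature value).
GAMMA: dict[str, float] = {
    "H": constants.value("proton gyromag. ratio"),  # 2.675e8
    "C": 6.728284e7,
}

_ANGSTROM = 1e-10


class ConversionError(ValueError):
    """A record cannot be converted or geometrically parameterized."""


@dataclass(frozen=True)
class EffectiveCoupling:
    """Geometric/physical parameterization of one coupling record.

    ``unit_vec`` is the (averaged) internuclear direction in the conformer
    frame, ``kappa`` the dipolar prefactor in Hz, and ``scale`` the motional
    averaging factor (1 for rigid pairs, ≈ -1/3 for an ideal methyl rotor).
    The predicted RDC is ``scale * kappa * (e^T S e)``.
    """

    record: CouplingRecord
    unit_vec: np.ndarray
    kappa: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.unit_vec, dtype=float).reshape(3)
        object.__setattr__(self, "unit_vec", v)
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError("unit_vec must have unit norm")
        if not math.isfinite(self.kappa) or self.kappa == 0:
            raise ValueError("kappa must be finite and nonzero")
        if not -1.0 <= self.scale <= 1.0:
            raise ValueError(f"scale must lie in [-1, 1], got {self.scale}")


def extract_rdc(
    J: float, sigJ: float | None, T: float, sigT: float | None
) -> tuple[float, float | None]:
    """Convert (J, T) to the RDC D with propagated error.

    D = (T - J)/2 under the T = J + 2D convention;
    sigD = sqrt(sigJ^2 + sigT^2)/2 when both errors are given.
    """
    if J is None or T is None:
        raise ConversionError("both J and T are required to extract D")
    D = (T - J) / 2.0
    sigD = None
    if sigJ is not None and sigT is not None:
        sigD = math.sqrt(sigJ**2 + sigT**2) / 2.0
    return D, sigD


def dipolar_prefactor(ctype: str, r: float) -> float:
    """Dipolar prefactor kappa (Hz) for a nucleus pair at distance r (Å).

    kappa = -(mu0 * gamma_i * gamma_j * h) / (16 pi^3 r^3), negative for two
    positive-gamma nuclei.  Supported pairs: C-H (types CH/CH2/CH3/generic)
    and C-C (type CC).
    """
    if r <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r}")
    if ctype in ("CH", "CH2", "CH3", "generic"):
        g1, g2 = GAMMA["C"], GAMMA["H"]
    elif ctype == "CC":
        g1, g2 = GAMMA["C"], GAMMA["C"]
    else:
        raise ConversionError(f"no gyromagnetic ratios for coupling type {ctype!r}")
    r_m = r * _ANGSTROM
    return -(constants.mu_0 * g1 * g2 * constants.h) / (16 * math.pi**3 * r_m**3)


def _p2(x: float) -> float:
    return 0.5 * (3.0 * x * x - 1.0)


def _bonded_hydrogens(conf: Conformer, carbon_label: str, cutoff: float = 1.3) -> list:
    c = conf.atom(carbon_label)
    return [
        a
        for a in conf.atoms
        if a.element == "H" and 0 < np.linalg.norm(a.xyz - c.xyz) < cutoff
    ]


def _heavy_neighbor(conf: Conformer, carbon_label: str, cutoff: float = 1.8):
    c = conf.atom(carbon_label)
    cands = [
        a
        for a in conf.atoms
        if a.element != "H"
        and a.label != carbon_label
        and 0 < np.linalg.norm(a.xyz - c.xyz) < cutoff
    ]
    if not cands:
        return None
    return min(cands, key=lambda a: np.linalg.norm(a.xyz - c.xyz))


def effective_vector(
    conf: Conformer, rec: CouplingRecord, fixed_r: float | None = None
) -> EffectiveCoupling:
    """Geometric parameterization of a record against a conformer.

    Rigid pairs (CH, CH2, CC, generic): unit vector along atom1 -> atom2, r
    from the coordinates (or ``fixed_r`` if given), scale = 1.

    Methyl (CH3) records: fast rotation about the local threefold axis
    projects each C-H vector onto the C(methyl)->C(neighbor) axis; the
    returned unit vector is that axis, scale = P2(cos theta) averaged over
    the three H positions (≈ -1/3 for ideal tetrahedral geometry), and kappa
    uses the mean of the actual C-H distances.
    """
    try:
        a1 = conf.atom(rec.atom1)
        a2 = conf.atom(rec.atom2)
    except KeyError as exc:
        raise ConversionError(str(exc)) from exc

    if rec.ctype != "CH3":
        vec = a2.xyz - a1.xyz
        r = float(np.linalg.norm(vec))
        if r == 0:
            raise ConversionError(f"coincident atoms {rec.atom1}/{rec.atom2}")
        kappa = dipolar_prefactor(rec.ctype, fixed_r if fixed_r is not None else r)
        return EffectiveCoupling(record=rec, unit_vec=vec / r, kappa=kappa, scale=1.0)

    # methyl: atom1 is the methyl carbon (or swap if atom2 is the carbon)
    cm = a1 if a1.element == "C" else a2
    hydrogens = _bonded_hydrogens(conf, cm.label)
    if len(hydrogens) < 3:
        raise ConversionError(
            f"methyl record {rec.atom1}-{rec.atom2}: need 3 bonded H on {cm.label}, "
            f"found {len(hydrogens)}"
        )
    neighbor = _heavy_neighbor(conf, cm.label)
    if neighbor is None:
        raise ConversionError(
            f"methyl record {rec.atom1}-{rec.atom2}: no heavy-atom neighbor defines the axis"
        )
    axis = neighbor.xyz - cm.xyz
    axis /= np.linalg.norm(axis)
    cosines = []
    r_ch = []
    for h in hydrogens[:3]:
        ch = h.xyz - cm.xyz
        d = np.linalg.norm(ch)
        r_ch.append(d)
        cosines.append(float(np.dot(ch / d, axis)))
    scale = float(np.mean([_p2(c) for c in cosines]))
    r_eff = fixed_r if fixed_r is not None else float(np.mean(r_ch))
    kappa = dipolar_prefactor("CH", r_eff)
    return EffectiveCoupling(record=rec, unit_vec=axis, kappa=kappa, scale=scale)
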