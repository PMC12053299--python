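"""Multi-conformer-single-tensor (MCST) fitting and population scanning.

Interconverting conformers that are structurally similar (or exchange faster
than molecular tumbling) share a single alignment tensor once they are
expressed in a common reference frame.  Here that frame is realized by
mass-weighted superposition onto a reference conformer: the proper rotation
minimizing the mass-weighted RMSD satisfies the rotational Eckart condition
for similar structures.  The ensemble design matrix is then the
population-weighted sum of the per-conformer design matrices, so one SVD fit
yields the common tensor; scanning the population of conformer 1 and
locating the minimum of Q(p1) estimates the solution-state conformer ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .molio import Conformer, RDCDataset
from .saupe_fit import SIGMA_FLOOR, FitError, FitResult, _solve_and_report, build_design_matrix

__all__ = [
    "EnsembleFitResult",
    "SuperpositionError",
    "eckart_superpose",
    "fit_mcst",
    "scan_populations",
]


class SuperpositionError(ValueError):
    """Conformers cannot be superposed (label mismatch, degenerate geometry)."""


@dataclass
class EnsembleFitResult:
    """Q(p1) scan output: the grid, the Q curve, and the best/endpoint fits."""

    grid: np.ndarray
    q_curve: np.ndarray
    p_best: float
    fit_best: FitResult
    fits_endpoints: tuple[FitResult, FitResult]  # (p1=1, p1=0)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "q_curve": self.q_curve.tolist(),
            "p_best": self.p_best,
            "q_best": float(self.q_curve[int(np.argmin(self.q_curve))]),
            "fit_best": self.fit_best.to_dict(),
            "fit_p1": self.fits_endpoints[0].to_dict(),
            "fit_p0": self.fits_endpoints[1].to_dict(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=kw.pop("indent", 2), **kw)

    def qp_table(self) -> str:
        """Two-column plain-text Q(p1) table for plotting."""
        lines = ["# p1\tQ"] + [f"{p:.4f}\t{q:.6f}" for p, q in zip(self.grid, self.q_curve)]
        return "\n".join(lines) + "\n"


def eckart_superpose(
    ref: Conformer, conf: Conformer, subset: list[str] | None = None
) -> Conformer:
    """Superpose ``conf`` onto ``ref`` in the common (Eckart) frame.

    Both conformers are matched through their atom labels (optionally
    restricted to ``subset``).  ``conf`` is translated so the mass-weighted
    centroid of the matched atoms coincides with that of ``ref`` and rotated
    by the proper rotation minimizing the mass-weighted RMSD (Kabsch /
    quaternion solution).  The internal geometry is untouched: all
    interatomic distances are preserved.
    """
    labels = list(subset) if subset is not None else list(ref.labels)
    missing_ref = [l for l in labels if l not in ref.labels]
    missing_conf = [l for l in labels if l not in conf.labels]
    if missing_ref or missing_conf:
        raise SuperpositionError(
            f"label mismatch: missing in reference {missing_ref}, in conformer {missing_conf}"
        )
    if len(labels) < 3:
        raise SuperpositionError("need at least 3 shared atoms to define a frame")

    ref_xyz = np.array([ref.atom(l).xyz for l in labels])
    conf_xyz = np.array([conf.atom(l).xyz for l in labels])
    masses = np.array([ref.atom(l).mass for l in labels])

    ref_c = np.average(ref_xyz, axis=0, weights=masses)
    conf_c = np.average(conf_xyz, axis=0, weights=masses)
    a = ref_xyz - ref_c
    b = conf_xyz - conf_c
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise SuperpositionError("matched atoms are collinear; rotation is underdetermined")

    rot, _ = Rotation.align_vectors(a, b, weights=masses)
    R = rot.as_matrix()

    all_xyz = conf.coords
    new_xyz = (all_xyz - conf_c) @ R.T + ref_c
    return conf.with_coords(new_xyz)


def fit_mcst(
    confs: list[Conformer],
    pops,
    ds: RDCDataset,
    ref_index: int | None = None,
    weighted: bool = True,
    sigma_floor: float = SIGMA_FLOOR,
    superpose_subset: list[str] | None = None,
) -> FitResult:
    """Fit one common tensor to a population-weighted conformer ensemble.

    All conformers are brought into the frame of ``confs[ref_index]``
    (default: the lowest-energy conformer, falling back to index 0) by
    :func:`eckart_superpose`; the design matrix is the population-weighted
    sum of per-conformer design matrices.  With a single conformer, or a
    population vector like (1, 0, ...), the result is identical to the
    single-conformer fit.
    """
    pops = np.asarray(pops, dtype=float)
    if len(confs) == 0 or pops.shape != (len(confs),):
        raise FitError("populations must match the number of conformers")
    if np.any(pops < 0) or abs(pops.sum() - 1.0) > 1e-9:
        raise FitError(f"invalid population vector {pops}: must be >= 0 and sum to 1")

    if ref_index is None:
        energies = [c.e_rel if c.e_rel is not None else np.inf for c in confs]
        ref_index = int(np.argmin(energies)) if np.isfinite(min(energies)) else 0
    ref = confs[ref_index]

    A = None
    d = w = None
    for k, (conf, p) in enumerate(zip(confs, pops)):
        frame_conf = conf if k == ref_index else eckart_superpose(ref, conf, superpose_subset)
        Ak, dk, wk = build_design_matrix(frame_conf, ds, sigma_floor=sigma_floor)
        if A is None:
            A = p * Ak
            d, w = dk, wk
        else:
            A = A + p * Ak
    if not weighted:
        w = np.ones_like(w)
    pairs = [r.pair for r in ds.included]
    return _solve_and_report(A, d, w, pairs, 1.0 / w)


def scan_populations(
    confs: tuple[Conformer, Conformer],
    ds: RDCDataset,
    step: float = 0.01,
    weighted: bool = True,
    sigma_floor: float = SIGMA_FLOOR,
    ref_index: int | None = None,
    superpose_subset: list[str] | None = None,
) -> EnsembleFitResult:
    """Exhaustive grid scan of Q over the population p1 of conformer 1.

    The grid is {0, step, ..., 1}; ``p_best`` is the argmin of Q (ties break
    toward the smaller p1).  The endpoint fits (p1 = 1 and p1 = 0) are the
    two single-conformer fits in the common frame.
    """
    if len(confs) != 2:
        raise FitError("the population scan is defined for exactly two conformers")
    if not 0 < step <= 0.1:
        raise FitError(f"step must lie in (0, 0.1], got {step}")

    n = int(round(1.0 / step))
    grid = np.round(np.linspace(0.0, 1.0, n + 1), 12)
    fits = [
        fit_mcst(
            list(confs),
            (p1, 1.0 - p1),
            ds,
            ref_index=ref_index,
            weighted=weighted,
            sigma_floor=sigma_floor,
            superpose_subset=superpose_subset,
        )
        for p1 in grid
    ]
    q_curve = np.array([f.q for f in fits])
    # ties (within numerical noise of the minimum) break toward the smaller p1
    best = int(np.flatnonzero(q_curve <= q_curve.min() + 1e-9)[0])
    return EnsembleFitResult(
        grid=grid,
        q_curve=q_curve,
        p_best=float(grid[best]),
        fit_best=fits[best],
        fits_endpoints=(fits[-1], fits[0]),
    )
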