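"""Error-weighted SVD fit of the Saupe order matrix to a rigid conformer (SCST).

A measured RDC for internuclear direction e is linear in the five independent
elements of the symmetric traceless order matrix S:

    D = scale * kappa * e^T S e
      = scale * kappa * [ex^2-ez^2, ey^2-ez^2, 2 ex ey, 2 ex ez, 2 ey ez]
        . (S_xx, S_yy, S_xy, S_xz, S_yz)

with S_zz = -S_xx - S_yy.  Stacking one row per included record gives an
overdetermined linear system solved by SVD pseudo-inverse; rows are scaled by
1/sigD so precise couplings dominate the fit.  Agreement between experiment
and back-calculation is summarized by the Cornilescu quality factor

    Q = sqrt( sum (D_exp - D_calc)^2 / sum D_exp^2 ).

Q is computed on unweighted residuals; a weighted variant is exposed
separately because weighting conventions differ between fitting programs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .couplings import effective_vector
from .molio import Conformer, RDCDataset

__all__ = [
    "SIGMA_FLOOR",
    "SVD_RCOND",
    "SaupeTensor",
    "FitResult",
    "FitError",
    "build_design_matrix",
    "fit_scst",
    "qfactor",
    "qfactor_weighted",
    "tensor_params",
    "s_to_matrix",
    "matrix_to_s",
]

#: Error floor (Hz) applied when a record carries no sigD: a realistic
#: precision for coupling extraction from well-resolved HSQC-type spectra.
SIGMA_FLOOR = 0.1

#: Relative singular-value cutoff of the pseudo-inverse.
SVD_RCOND = 1e-10


class FitError(ValueError):
    """Raised when a fit cannot be set up (too few records, bad input)."""


def s_to_matrix(s: np.ndarray) -> np.ndarray:
    """Expand the 5-vector (S_xx, S_yy, S_xy, S_xz, S_yz) to the 3x3 matrix."""
    sxx, syy, sxy, sxz, syz = np.asarray(s, dtype=float)
    return np.array(
        [
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]
    )


def matrix_to_s(S: np.ndarray) -> np.ndarray:
    """Collapse a symmetric traceless 3x3 matrix to the 5-vector parameterization."""
    S = np.asarray(S, dtype=float)
    return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])


@dataclass(frozen=True)
class SaupeTensor:
    """Saupe order matrix with its standard derived descriptors.

    ``eigvals`` are ordered by decreasing magnitude (|Szz'| >= |Syy'| >=
    |Sxx'|) and ``eigvecs`` maps molecule frame -> principal axis frame
    (columns are principal axes, det = +1).  ``gdo`` is the generalized
    degree of order sqrt((2/3) sum S_ab^2), ``da`` the axial component
    Szz'/2 and ``rhombicity`` the ratio Dr/Da = (2/3) |Sxx' - Syy'| / Szz',
    which lies in [0, 2/3] under this eigenvalue ordering.
    """

    S: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    gdo: float
    da: float
    rhombicity: float

    def to_dict(self) -> dict:
        return {
            "S": self.S.tolist(),
            "eigvals": self.eigvals.tolist(),
            "eigvecs": self.eigvecs.tolist(),
            "gdo": self.gdo,
            "da": self.da,
            "rhombicity": self.rhombicity,
        }


@dataclass
class FitResult:
    """Everything an SVD tensor fit produces.

    ``singvals`` are the five singular values of the weighted design matrix
    and ``condition`` their extreme ratio (+inf when rank-deficient below
    the cutoff, flagged by ``rank_deficient``).
    """

    tensor: SaupeTensor
    d_exp: np.ndarray
    d_calc: np.ndarray
    residuals: np.ndarray
    q: float
    rmsd: float
    singvals: np.ndarray
    condition: float
    rank_deficient: bool = False
    pairs: list = field(default_factory=list)
    sigmas: np.ndarray | None = None

    def to_dict(self) -> dict:
        table = []
        for i, (a1, a2) in enumerate(self.pairs):
            table.append(
                {
                    "atom1": a1,
                    "atom2": a2,
                    "d_exp": float(self.d_exp[i]),
                    "sigD": float(self.sigmas[i]) if self.sigmas is not None else None,
                    "d_calc": float(self.d_calc[i]),
                    "residual": float(self.residuals[i]),
                }
            )
        return {
            "tensor": self.tensor.to_dict(),
            "records": table,
            "q": self.q,
            "rmsd": self.rmsd,
            "singvals": self.singvals.tolist(),
            "condition": self.condition,
            "rank_deficient": self.rank_deficient,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=kw.pop("indent", 2), **kw)


def qfactor(d_exp: np.ndarray, d_calc: np.ndarray) -> float:
    """Cornilescu quality factor sqrt(sum(d_exp - d_calc)^2 / sum d_exp^2)."""
    d_exp = np.asarray(d_exp, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_exp.shape != d_calc.shape or d_exp.size == 0:
        raise ValueError("d_exp and d_calc must be equal-length, non-empty")
    denom = float(np.sum(d_exp**2))
    if denom == 0:
        raise ValueError("Q undefined: experimental RDCs are all zero")
    return math.sqrt(float(np.sum((d_exp - d_calc) ** 2)) / denom)


def qfactor_weighted(d_exp, d_calc, sig) -> float:
    """Q on error-weighted residuals: sqrt(sum(w r)^2 / sum(w d_exp)^2), w = 1/sig."""
    w = 1.0 / np.asarray(sig, dtype=float)
    return qfactor(w * np.asarray(d_exp, float), w * np.asarray(d_calc, float))


def tensor_params(S: np.ndarray) -> SaupeTensor:
    """Eigen-analysis and standard descriptors of a symmetric traceless matrix."""
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    scale = np.abs(S).max()
    tol = 1e-10 * max(scale, 1.0)
    if np.abs(S - S.T).max() > tol:
        raise ValueError("matrix is not symmetric")
    if abs(np.trace(S)) > tol:
        raise ValueError("matrix is not traceless")
    S = 0.5 * (S + S.T)

    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(np.abs(vals))  # |Sxx'| <= |Syy'| <= |Szz'|
    vals = vals[order]
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs = vecs * np.array([1.0, 1.0, -1.0])  # flip last axis -> proper rotation
    sxx, syy, szz = vals
    gdo = math.sqrt((2.0 / 3.0) * float(np.sum(S * S)))
    da = szz / 2.0
    # rhombicity R = Dr/Da with Dr = (Sxx' - Syy')/3, Da = Szz'/2; R in [0, 2/3]
    rhomb = abs((2.0 / 3.0) * (sxx - syy) / szz) if szz != 0 else 0.0
    # eigvals reported largest-magnitude first to match the |Szz'| >= ... ordering
    return SaupeTensor(
        S=S,
        eigvals=np.array([szz, syy, sxx]),
        eigvecs=vecs,
        gdo=gdo,
        da=da,
        rhombicity=rhomb,
    )


def build_design_matrix(
    conf: Conformer,
    ds: RDCDataset,
    sigma_floor: float = SIGMA_FLOOR,
    fixed_r: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (A, d, w) for the linear RDC system over included records.

    Row i is scale_i * kappa_i * [ex^2-ez^2, ey^2-ez^2, 2exey, 2exez, 2eyez];
    d_i is the experimental RDC (computed from (J, T) when D is absent);
    w_i = 1/sigD_i with the error floor applied to missing/zero sigmas.
    Rank deficiency of A is not an error here — it surfaces as the condition
    number of the fit.
    """
    from .couplings import extract_rdc

    recs = ds.included
    if len(recs) < 5:
        raise FitError(f"need >= 5 included records for a 5-parameter fit, got {len(recs)}")
    A = np.empty((len(recs), 5))
    d = np.empty(len(recs))
    w = np.empty(len(recs))
    for i, rec in enumerate(recs):
        eff = effective_vector(conf, rec, fixed_r=fixed_r)
        ex, ey, ez = eff.unit_vec
        A[i] = eff.scale * eff.kappa * np.array(
            [ex**2 - ez**2, ey**2 - ez**2, 2 * ex * ey, 2 * ex * ez, 2 * ey * ez]
        )
        if rec.D is not None:
            d[i] = rec.D
            sig = rec.sigD
        else:
            D, sigD = extract_rdc(rec.J, rec.sigJ, rec.T, rec.sigT)
            d[i] = D
            sig = sigD
        w[i] = 1.0 / (sig if sig is not None and sig > 0 else sigma_floor)
    return A, d, w


def _solve_and_report(
    A: np.ndarray,
    d: np.ndarray,
    w: np.ndarray,
    pairs: list,
    sigmas: np.ndarray,
) -> FitResult:
    Aw = w[:, None] * A
    dw = w * d
    U, sv, Vt = np.linalg.svd(Aw, full_matrices=False)
    cutoff = SVD_RCOND * sv[0] if sv[0] > 0 else 0.0
    keep = sv > cutoff
    rank_deficient = not bool(keep.all())
    if rank_deficient:
        warnings.warn(
            "design matrix is rank-deficient below the SVD cutoff; "
            "the minimum-norm solution is returned",
            stacklevel=3,
        )
    inv = np.where(keep, 1.0 / np.where(keep, sv, 1.0), 0.0)
    s = Vt.T @ (inv * (U.T @ dw))
    d_calc = A @ s
    residuals = d - d_calc
    q = qfactor(d, d_calc)
    rmsd = math.sqrt(float(np.mean(residuals**2)))
    condition = float(sv[0] / sv[-1]) if keep.all() and sv[-1] > 0 else math.inf
    return FitResult(
        tensor=tensor_params(s_to_matrix(s)),
        d_exp=d,
        d_calc=d_calc,
        residuals=residuals,
        q=q,
        rmsd=rmsd,
        singvals=sv,
        condition=condition,
        rank_deficient=rank_deficient,
        pairs=pairs,
        sigmas=sigmas,
    )


def fit_scst(
    conf: Conformer,
    ds: RDCDataset,
    weighted: bool = True,
    sigma_floor: float = SIGMA_FLOOR,
    fixed_r: float | None = None,
) -> FitResult:
    """Single-conformer-single-tensor fit: one rigid structure, one tensor.

    Solves diag(w) A s = diag(w) d by SVD pseudo-inverse (``weighted=False``
    sets all weights to 1) and back-calculates D_calc = A s.  Q is always the
    unweighted Cornilescu value.
    """
    A, d, w = build_design_matrix(conf, ds, sigma_floor=sigma_floor, fixed_r=fixed_r)
    if not np.any(d):
        raise FitError("all experimental RDCs are zero; the tensor is undetermined")
    if not weighted:
        w = np.ones_like(w)
    pairs = [r.pair for r in ds.included]
    return _solve_and_report(A, d, w, pairs, 1.0 / w)
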