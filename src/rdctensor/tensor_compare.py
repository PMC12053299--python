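"""Comparison of alignment tensors via the generalized 5D angle.

Two symmetric traceless order matrices live in a 5-dimensional irreducible
representation; the generalized angle beta between them,

    beta = arccos( <S1, S2>_F / (||S1||_F ||S2||_F) ),

measures how differently the two media orient the same analyte.  For fits of
one analyte in two enantiomeric alignment media, beta = 0 means no
observable enantiodifferentiation and beta = 90 deg the maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .saupe_fit import FitResult

__all__ = [
    "TensorComparison",
    "beta_angle",
    "compare_enantiomer_media",
    "mirror_tensor",
]


@dataclass(frozen=True)
class TensorComparison:
    """beta angle (deg), ratio of generalized degrees of order, frame note."""

    beta_deg: float
    gdo_ratio: float
    frame_note: str

    def to_dict(self) -> dict:
        return {
            "beta_deg": self.beta_deg,
            "gdo_ratio": self.gdo_ratio,
            "frame_note": self.frame_note,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=kw.pop("indent", 2), **kw)


def beta_angle(S1: np.ndarray, S2: np.ndarray) -> float:
    """Generalized angle (degrees) between two symmetric traceless tensors.

    Uses the full 3x3 Frobenius inner product, which equals the normalized
    scalar product of the 5-vector irreducible representations.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    n1 = np.linalg.norm(S1)
    n2 = np.linalg.norm(S2)
    if n1 == 0 or n2 == 0:
        raise ValueError("beta angle undefined for a zero tensor")
    # atan2 form of arccos(<u,v>) — accurate near 0 and 180 degrees
    u = S1.ravel() / n1
    v = S2.ravel() / n2
    return math.degrees(
        2.0 * math.atan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    )


def mirror_tensor(S: np.ndarray, axis: int = 1) -> np.ndarray:
    """Order matrix after mirroring the molecular coordinates across one axis.

    Negating coordinate ``axis`` (default y, i.e. the xz plane) conjugates S
    by diag with -1 in that slot, flipping the sign of the two off-diagonal
    elements involving that axis.
    """
    m = np.ones(3)
    m[axis] = -1.0
    M = np.diag(m)
    return M @ np.asarray(S, dtype=float) @ M


def compare_enantiomer_media(
    fitL: FitResult, fitD: FitResult, mirror: bool = False
) -> TensorComparison:
    """Compare the alignment tensors fitted in two (enantiomeric) media.

    Both fits must be on the same analyte structure in the same coordinate
    frame.  By default the two fitted tensors are compared directly; with
    ``mirror=True`` the second tensor is transformed as if its fit had used
    y-mirrored coordinates before the angle is taken.
    """
    S1 = fitL.tensor.S
    S2 = fitD.tensor.S
    note = "direct comparison, no mirror applied"
    if mirror:
        S2 = mirror_tensor(S2)
        note = "second tensor mirrored across the xz plane (y negated)"
    if fitL.pairs and fitD.pairs and fitL.pairs != fitD.pairs:
        note += "; WARNING: record lists differ between the two fits (frame mismatch?)"
    return TensorComparison(
        beta_deg=beta_angle(S1, S2),
        gdo_ratio=fitL.tensor.gdo / fitD.tensor.gdo,
        frame_note=note,
    )
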