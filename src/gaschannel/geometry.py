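"""Distance and superposition primitives shared by all analyses.

Distances are Euclidean in Å.  When a periodic box is given, the minimum-image
convention is applied componentwise (orthorhombic boxes only, which is all the
package supports).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AnalysisError

__all__ = ["pairwise_distances", "min_distance", "superpose"]


def _min_image(diff: np.ndarray, box) -> np.ndarray:
    b = np.asarray(box, dtype=float)
    return diff - b * np.round(diff / b)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box=None) -> np.ndarray:
    """All-pairs distances between coordinate sets ``a`` (n,3) and ``b`` (m,3)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    if box is not None:
        diff = _min_image(diff, box)
    return np.sqrt((diff ** 2).sum(axis=-1))


def min_distance(a: np.ndarray, b: np.ndarray, box=None) -> float:
    """Smallest atom-atom distance between two coordinate sets."""
    return float(pairwise_distances(a, b, box=box).min())


def superpose(mobile: np.ndarray, fixed: np.ndarray):
    """Rigid least-squares (Kabsch) superposition of ``mobile`` onto ``fixed``.

    Returns ``(transform, rmsd)`` where ``transform`` maps arbitrary
    coordinates from the mobile frame into the fixed frame and ``rmsd`` is the
    post-fit RMSD over the paired atoms.

    Raises
    ------
    AnalysisError
        If fewer than 3 atom pairs are given or the points are collinear
        (the rotation is then underdetermined).
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AnalysisError("superpose: coordinate sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise AnalysisError("superpose: need at least 3 reference atoms")
    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    centered = fixed - fc
    # collinear reference -> rank < 2 after centering
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise AnalysisError("superpose: reference atoms are collinear")
    rot, rssd = Rotation.align_vectors(centered, mobile - mc)
    rmsd = float(rssd / np.sqrt(n))

    def transform(x: np.ndarray) -> np.ndarray:
        return rot.apply(np.asarray(x, dtype=float) - mc) + fc

    return transform, rmsd
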