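"""Cubic B-spline bases, difference penalties and centering constraints.

P-spline construction (Eilers-Marx convention): a cubic B-spline basis of
dimension ``k`` on *equally spaced, unclamped* knots spanning the (tail
capped) data range, penalized by the second-order difference of adjacent
basis coefficients (``DᵀD``). With uniform knots the Greville abscissae are
equally spaced, so coefficient vectors linear in the index represent exactly
the linear functions of the covariate — the penalty null space is
{constant, linear}; after the sum-to-zero centering constraint the constant
is removed and the linear component remains. (Unequally spaced knots would
break this correspondence, which is why uniform spacing is used even for
skewed covariates; skew is handled by capping the knot range instead.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3  # cubic


def pspline_knots(x: np.ndarray, k: int, cap_quantile: float = 0.995) -> np.ndarray:
    """Uniform unclamped knot vector for a k-dimensional cubic basis.

    The basis' base interval is ``[min(x), Q(cap_quantile)]`` (distance
    covariates have long right tails; values past the cap are handled by
    polynomial extension of the basis). Knots are equally spaced and extend
    ``DEGREE`` intervals beyond each end, the standard P-spline layout.
    """
    if k < DEGREE + 1:
        raise ValueError(f"basis dimension k must be >= {DEGREE + 1}, got {k}")
    x = np.asarray(x, float)
    if len(np.unique(x)) < k:
        raise ValueError(
            f"need at least {k} distinct covariate values, got {len(np.unique(x))}"
        )
    xc = np.minimum(x, np.quantile(x, cap_quantile))
    lo, hi = float(xc.min()), float(xc.max())
    h = (hi - lo) / (k - DEGREE)
    return lo + h * np.arange(-DEGREE, k + 1)


def bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the cubic B-spline basis at ``x`` (dense n x k matrix).

    Points outside the knot range are evaluated by polynomial extension, so
    the basis (and the linear span of its penalty null space) is defined on
    the whole axis.
    """
    x = np.asarray(x, float)
    return BSpline.design_matrix(x, knots, DEGREE, extrapolate=True).toarray()


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """Penalty matrix DᵀD from the order-th difference of coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def center_transform(col_sums: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the sum-to-zero constraint's null space.

    For a basis B with training column sums ``c = B.sum(0)``, the constraint
    ``1ᵀBβ = cᵀβ = 0`` is absorbed by reparameterising ``β = Zγ`` with
    ``Z`` (k x k-1) spanning the null space of ``cᵀ``; every column of ``BZ``
    then sums to zero over the training sample.
    """
    c = np.asarray(col_sums, float)
    k = len(c)
    # Householder reflection mapping c to a multiple of e1; remaining columns span null(c)
    v = c.copy()
    v[0] += np.sign(c[0] if c[0] != 0 else 1.0) * np.linalg.norm(c)
    H = np.eye(k) - 2.0 * np.outer(v, v) / (v @ v)
    return H[:, 1:]


@dataclass
class BSplineBasis:
    """A fitted univariate cubic B-spline basis (knots frozen at training)."""

    knots: np.ndarray

    @classmethod
    def from_data(cls, x, k: int, cap_quantile: float = 0.995) -> "BSplineBasis":
        return cls(pspline_knots(np.asarray(x, float), k, cap_quantile))

    @property
    def k(self) -> int:
        return len(self.knots) - DEGREE - 1

    def design(self, x) -> np.ndarray:
        return bspline_design(x, self.knots)

    def penalty(self) -> np.ndarray:
        return difference_penalty(self.k)


def tensor_design(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product of two marginal design matrices.

    Column ``i*k_y + j`` of the result is ``bx[:, i] * by[:, j]``; each row is
    the outer product of the two marginal rows, flattened row-major.
    """
    n, kx = bx.shape
    ky = by.shape[1]
    return (bx[:, :, None] * by[:, None, :]).reshape(n, kx * ky)


def tensor_penalties(kx: int, ky: int, order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Kronecker-structured row-wise and column-wise difference penalties.

    The first penalizes roughness along the x margin (differences over the
    x-index at fixed y-index), the second along the y margin; each carries its
    own smoothing parameter. The joint null space is the bilinear surface
    ``a + bx + cy + dxy`` in covariate space.
    """
    Px = difference_penalty(kx, order)
    Py = difference_penalty(ky, order)
    return np.kron(Px, np.eye(ky)), np.kron(np.eye(kx), Py)
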