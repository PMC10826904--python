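"""Sum-to-zero identifiability constraints via orthogonal projection.

Probe-deviation vectors in both samplers are restricted to linear
subspaces of the form {u : sum(u) = 0} or {u : sum(u) = 0, sum(u * x) = 0}.
Working in an orthonormal basis of the subspace keeps constrained Gibbs
updates exact: an isotropic (or diagonal, after a change of basis) normal
full conditional restricted to the subspace is again normal in the basis
coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["constraint_basis", "constraint_project"]


def constraint_basis(n: int, x: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis (n x m columns) of the nullspace of the constraint
    rows {1} (and {x} if given).

    With ``x`` None the subspace is {u : sum u = 0} (m = n-1); otherwise
    {u : sum u = 0, sum u*x = 0} (m = n-2 for non-constant x).
    """
    rows = [np.ones(n)]
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.size != n:
            raise ValueError("x length must match n")
        if np.allclose(x, x[0]):
            raise ValueError("x must be non-constant")
        rows.append(x)
    A = np.vstack(rows)
    # nullspace via SVD: rows of Vt beyond rank(A) span ker(A)
    _, s, Vt = np.linalg.svd(A, full_matrices=True)
    rank = int(np.sum(s > s.max() * n * np.finfo(float).eps))
    return Vt[rank:].T


def constraint_project(v: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Orthogonal projection of ``v`` onto the constraint subspace.

    Idempotent and linear; preserves Gaussianity of isotropic draws within
    the subspace, which is why constrained generation can draw
    unconstrained vectors and project.
    """
    v = np.asarray(v, dtype=float)
    Q = constraint_basis(v.shape[-1], x)
    return v @ Q @ Q.T
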