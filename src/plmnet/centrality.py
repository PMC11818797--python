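"""Eigenvector centrality of connectivity matrices and lobe aggregation.

For a symmetric nonnegative connectivity matrix A, the centrality score of
node i satisfies

    x_i = (1 / lambda) * sum_j a_ij x_j,   i.e.   A x = lambda x,

with x the eigenvector of the largest eigenvalue lambda.  For a strictly
positive (irreducible) A, the Perron-Frobenius theorem guarantees lambda
is simple and x can be chosen entrywise positive.  Scores are normalized
to unit length, sum_i x_i**2 = 1, so they are comparable across networks.

Region scores are then averaged within each lobe group to give one value
per lobe per subject and band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .atlas import LOBE_GROUPS, LobePartition
from .plm import ConnectivityMatrix

__all__ = ["CentralityVector", "LobeCentrality", "eigenvector_centrality",
           "lobe_average"]

# Above this size a dense eigendecomposition is replaced by power iteration.
_DENSE_LIMIT = 256
_POWER_TOL = 1e-12
_POWER_MAXITER = 10_000


@dataclass
class CentralityVector:
    """Normalized eigenvector-centrality scores for one subject and band.

    ``scores`` are nonnegative with unit sum of squares; ``leading_eigenvalue``
    keeps lambda as metadata.
    """

    region_labels: list[str]
    band: str
    scores: np.ndarray
    leading_eigenvalue: float

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("centrality scores contain NaN/Inf")
        if s.min() < 0:
            raise ValueError("centrality scores must be nonnegative")
        if abs(np.sum(s ** 2) - 1.0) > 1e-10:
            raise ValueError("centrality scores must have unit sum of squares")
        self.scores = s


@dataclass
class LobeCentrality:
    """Mean centrality per lobe group for one subject and band."""

    band: str
    values: dict[str, float]

    def __getitem__(self, group: str) -> float:
        return self.values[group]


def _power_iteration(a: np.ndarray) -> tuple[np.ndarray, float]:
    # Shift by a positive multiple of the identity: for a nonnegative
    # symmetric matrix the Perron root equals the spectral radius, but a
    # -lambda twin (bipartite structure) would make the unshifted
    # iteration oscillate.  The shift breaks the tie without moving the
    # eigenvector.
    n = a.shape[0]
    mu = float(a.max())
    shifted = a + mu * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(_POWER_MAXITER):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0.0:
            raise ValueError("power iteration hit the zero vector")
        y /= norm
        lam_new = float(y @ (a @ y))
        if np.linalg.norm(y - x) < _POWER_TOL:
            return y, lam_new
        x, lam = y, lam_new
    return x, lam


def eigenvector_centrality(A: ConnectivityMatrix | np.ndarray,
                           band: str = "",
                           region_labels: list[str] | None = None,
                           method: str = "auto") -> CentralityVector:
    """Leading-eigenvector centrality, unit-length normalized.

    Parameters
    ----------
    A : ConnectivityMatrix or ndarray
        Symmetric nonnegative matrix; the diagonal is forced to zero
        (self-coupling is undefined for phase-based connectivity).
    method : {'auto', 'dense', 'power'}
        'auto' uses a dense symmetric eigendecomposition up to N = 256
        and power iteration beyond; the explicit choices are exposed so
        the two routes can be cross-checked.

    Raises
    ------
    ValueError
        For an all-zero matrix, or when the leading eigenspace is
        ambiguous (degenerate leading eigenvalue of a disconnected
        matrix — cannot occur for strictly positive PLM matrices).
    """
    if isinstance(A, ConnectivityMatrix):
        mat = A.values.copy()
        labels = list(A.region_labels)
        band = band or A.band
    else:
        mat = np.array(A, dtype=float)
        labels = list(region_labels) if region_labels is not None else [
            f"node_{i}" for i in range(mat.shape[0])
        ]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    if mat.min() < 0:
        raise ValueError("connectivity matrix must be nonnegative")
    np.fill_diagonal(mat, 0.0)
    if not mat.any():
        raise ValueError("all-zero connectivity matrix has no centrality")

    n = mat.shape[0]
    if method not in ("auto", "dense", "power"):
        raise ValueError(f"unknown method {method!r}")
    use_dense = method == "dense" or (method == "auto" and n <= _DENSE_LIMIT)
    if use_dense:
        w, v = eigh(mat)
        lam = float(w[-1])
        x = v[:, -1]
        # A degenerate leading eigenvalue means the Perron vector is not
        # unique (disconnected graph); refuse rather than pick a branch.
        if n > 1 and lam - w[-2] < 1e-10 * max(1.0, abs(lam)):
            raise ValueError(
                "leading eigenvalue is (near-)degenerate; eigenvector "
                "centrality is ambiguous for this disconnected matrix"
            )
    else:
        x, lam = _power_iteration(mat)

    # Perron-Frobenius sign fix: orient so the largest-magnitude entry is
    # positive, then clamp the tiny negative round-off.
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    if x.min() < -1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("leading eigenvector is not sign-consistent "
                         "(matrix is not irreducible)")
    x = np.clip(x, 0.0, None)
    x = x / np.sqrt(np.sum(x ** 2))
    return CentralityVector(labels, band, x, lam)


def lobe_average(x: CentralityVector, partition: LobePartition) -> LobeCentrality:
    """Arithmetic mean of the member regions' scores, per lobe group.

    Every region label of ``x`` must be covered by the partition; a
    missing label is rejected by name.  Groups with no member among the
    labels of ``x`` are omitted.
    """
    sums: dict[str, list[float]] = {}
    for lab, s in zip(x.region_labels, x.scores):
        g = partition.group_of(lab)
        sums.setdefault(g, []).append(float(s))
    values = {g: float(np.mean(v)) for g, v in sums.items()}
    return LobeCentrality(x.band, values)
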