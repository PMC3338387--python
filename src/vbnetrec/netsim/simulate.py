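"""Random weighted directed graphs, moralized precision matrices, and MVN data.

The generator draws a directed adjacency matrix ``A`` with independent
Bernoulli edges carrying standard-normal weights and unit diagonal, forms the
precision matrix ``Theta = A @ A.T`` (moralization: nodes sharing a child in
``A`` acquire an undirected edge in ``Theta``), and samples rows of ``Y`` from
``N(0, Theta^{-1})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, SeedSequence

__all__ = [
    "SimulatedNetwork",
    "sample_weighted_graph",
    "moralized_precision",
    "sample_mvn_data",
    "true_edges",
    "simulate_network",
    "simulate_replicates",
]


@dataclass(frozen=True)
class SimulatedNetwork:
    """One simulated network replicate with its ground truth.

    Attributes
    ----------
    p : int
        Number of nodes (variables).
    n : int
        Number of sampled observations.
    A : ndarray of shape (p, p)
        Weighted directed adjacency; diagonal is exactly 1.
    Theta : ndarray of shape (p, p)
        Moralized precision matrix ``A @ A.T``.
    Y : ndarray of shape (n, p)
        Data sampled from ``N(0, Theta^{-1})``.
    seed : int
        Seed used for this replicate.
    edge_prob : float
        Per-ordered-pair edge probability used for ``A``.
    """

    p: int
    n: int
    A: np.ndarray = field(repr=False)
    Theta: np.ndarray = field(repr=False)
    Y: np.ndarray = field(repr=False)
    seed: int
    edge_prob: float

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Ground-truth undirected edge set of the precision matrix."""
        return true_edges(self.Theta)


def _rng(seed) -> Generator:
    return np.random.default_rng(seed)


def sample_weighted_graph(p: int, edge_prob: float, seed) -> np.ndarray:
    """Sample a weighted directed adjacency matrix.

    Each of the ``p*(p-1)`` ordered off-diagonal entries is nonzero
    independently with probability ``edge_prob``; nonzero entries are
    standard-normal draws. The diagonal is set to 1. Self-loops are never
    sampled.

    Parameters
    ----------
    p : int
        Node count, must be positive.
    edge_prob : float
        Probability of each directed edge, in [0, 1].
    seed : int or numpy SeedSequence/Generator
        Randomness source.

    Returns
    -------
    ndarray of shape (p, p)
    """
    if not isinstance(p, (int, np.integer)) or p <= 0:
        raise ValueError(f"node count p must be a positive integer, got {p!r}")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must lie in [0, 1], got {edge_prob!r}")
    rng = _rng(seed)
    mask = rng.random((p, p)) < edge_prob
    np.fill_diagonal(mask, False)
    A = np.zeros((p, p))
    k = int(mask.sum())
    if k:
        A[mask] = rng.standard_normal(k)
    np.fill_diagonal(A, 1.0)
    return A


def moralized_precision(A: np.ndarray) -> np.ndarray:
    """Precision matrix ``A @ A.T`` of the moralized graph.

    Co-parents of a shared child in the directed graph obtain a nonzero
    off-diagonal entry, which inflates connectivity relative to the directed
    support.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    return A @ A.T


def sample_mvn_data(Theta: np.ndarray, n: int, seed) -> np.ndarray:
    """Draw ``n`` iid rows from ``N(0, Theta^{-1})``.

    Uses the Cholesky factor of ``Theta``: if ``Theta = L L^T`` then solving
    ``L^T y = z`` for standard-normal ``z`` gives ``y ~ N(0, Theta^{-1})``
    without forming the inverse.

    Raises
    ------
    ValueError
        If ``Theta`` is not symmetric or is numerically singular (the
        smallest eigenvalue is reported).
    """
    Theta = np.asarray(Theta, dtype=float)
    if Theta.ndim != 2 or Theta.shape[0] != Theta.shape[1]:
        raise ValueError(f"precision must be square, got shape {Theta.shape}")
    if not np.allclose(Theta, Theta.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    if not isinstance(n, (int, np.integer)) or n <= 0:
        raise ValueError(f"sample count n must be a positive integer, got {n!r}")
    try:
        L = np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(Theta)[0])
        raise ValueError(
            f"precision matrix is numerically singular or indefinite "
            f"(smallest eigenvalue {smallest:.3e})"
        ) from None
    rng = _rng(seed)
    Z = rng.standard_normal((n, Theta.shape[0]))
    # y = L^{-T} z  =>  cov(y) = (L L^T)^{-1} = Theta^{-1}
    from scipy.linalg import solve_triangular

    return solve_triangular(L, Z.T, lower=True, trans="T").T


def true_edges(Theta: np.ndarray, tol: float | None = None) -> set[tuple[int, int]]:
    """Undirected edge set {(i, j), i < j : |Theta_ij| > tol}.

    ``tol`` defaults to ``1e-12 * max|Theta|``; exact cancellation of
    continuous weights is measure-zero, so the choice is cosmetic.
    """
    Theta = np.asarray(Theta, dtype=float)
    if not np.allclose(Theta, Theta.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    if tol is None:
        tol = 1e-12 * float(np.max(np.abs(Theta))) if Theta.size else 0.0
    iu, ju = np.triu_indices_from(Theta, k=1)
    keep = np.abs(Theta[iu, ju]) > tol
    return {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}


def simulate_network(
    p: int = 1000,
    n: int = 300,
    edge_prob: float | None = None,
    seed: int = 0,
) -> SimulatedNetwork:
    """Generate one replicate: graph, precision, and sampled data.

    ``edge_prob`` defaults to ``1/p``. The single seed deterministically
    spawns independent child streams for the graph and the data.
    """
    if edge_prob is None:
        edge_prob = 1.0 / p
    ss = SeedSequence(seed)
    graph_ss, data_ss = ss.spawn(2)
    A = sample_weighted_graph(p, edge_prob, graph_ss)
    Theta = moralized_precision(A)
    Y = sample_mvn_data(Theta, n, data_ss)
    return SimulatedNetwork(p=p, n=n, A=A, Theta=Theta, Y=Y, seed=seed, edge_prob=edge_prob)


def simulate_replicates(
    replicates: int,
    p: int = 1000,
    n: int = 300,
    edge_prob: float | None = None,
    master_seed: int = 0,
) -> list[SimulatedNetwork]:
    """Generate independent replicates from per-replicate child seeds."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = SeedSequence(master_seed).spawn(replicates)
    out = []
    for r, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0])
        out.append(simulate_network(p=p, n=n, edge_prob=edge_prob, seed=rep_seed))
    return out
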