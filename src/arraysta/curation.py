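"""Geometric cleaning of aligned particle sets.

Duplicate collapse (connected components of the threshold-distance graph),
lattice-neighbour filtering (annulus census, single pass), and lattice
spacing statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .particles import ParticleSet

SQRT3 = np.sqrt(3.0)


class InsufficientDataError(ValueError):
    pass


@dataclass
class LatticeStats:
    nn_distances: np.ndarray     # Angstrom, one per particle
    modal_spacing: float         # Angstrom, mode of smoothed NN histogram
    lattice_constant: float      # sqrt(3) * modal_spacing (honeycomb mode)
    neighbor_counts: dict        # annulus neighbour count -> frequency


def collapse_duplicates(particles: ParticleSet, threshold: float = 10.0) -> ParticleSet:
    """Collapse clusters of particles closer than ``threshold`` Angstrom.

    Clusters are connected components of the graph linking pairs within the
    threshold. Each cluster becomes one particle at the unweighted centroid,
    carrying the orientation, score, id and tomogram of its best-scoring
    member. Idempotent: output minimum pairwise distance exceeds the
    threshold (components are re-collapsed until it does, which terminates
    because the particle count strictly decreases).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    current = particles
    while len(current) > 1:
        tree = cKDTree(current.positions)
        graph = tree.sparse_distance_matrix(tree, max_distance=threshold, output_type="coo_matrix")
        n_comp, labels = connected_components(graph, directed=False)
        if n_comp == len(current):
            break
        pos = np.zeros((n_comp, 3))
        keep = np.zeros(n_comp, dtype=int)
        for comp in range(n_comp):
            members = np.nonzero(labels == comp)[0]
            pos[comp] = current.positions[members].mean(axis=0)
            keep[comp] = members[np.argmax(current.scores[members])]
        current = ParticleSet(
            positions=pos,
            eulers=current.eulers[keep],
            tomo_ids=current.tomo_ids[keep],
            scores=current.scores[keep],
            ids=current.ids[keep],
        )
    return current


def annulus_counts(positions: np.ndarray, expected: float, tol: float) -> np.ndarray:
    """Number of OTHER particles within [expected-tol, expected+tol] of each."""
    positions = np.asarray(positions, float).reshape(-1, 3)
    n = len(positions)
    if n == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(positions)
    outer = tree.query_ball_point(positions, r=expected + tol)
    counts = np.zeros(n, dtype=int)
    lo = expected - tol
    for i, idx in enumerate(outer):
        idx = [j for j in idx if j != i]
        if idx:
            d = np.linalg.norm(positions[idx] - positions[i], axis=1)
            counts[i] = int(np.sum(d >= lo))
    return counts


def neighbor_filter(
    particles: ParticleSet,
    expected: float = 120.0,
    tol: float = 20.0,
    min_neighbors: int = 3,
) -> ParticleSet:
    """Keep particles with strictly more than ``min_neighbors`` others in the
    closed annulus [expected-tol, expected+tol]. Single pass on the input
    set (counts are taken against the unfiltered set, no recursion)."""
    if not expected > tol or tol < 0:
        raise ValueError("require expected > tol >= 0")
    counts = annulus_counts(particles.positions, expected, tol)
    return particles.subset(np.nonzero(counts > min_neighbors)[0])


def estimate_lattice_spacing(particles: ParticleSet, smoothing: float = 3.0,
                             expected: float | None = None,
                             tol: float | None = None) -> LatticeStats:
    """Nearest-neighbour statistics and kernel-smoothed modal spacing.

    The modal spacing is the argmax of a Gaussian-kernel density (bandwidth
    ``smoothing`` Angstrom) over all first-shell pair distances (pairs closer
    than 1.45x the median NN distance). Using the full first shell rather
    than per-particle minima keeps the estimate unbiased under jitter; the
    lattice constant assumes honeycomb placement (factor sqrt(3)).
    """
    if len(particles) < 10:
        raise InsufficientDataError(
            f"need >= 10 particles to estimate lattice spacing, got {len(particles)}")
    tree = cKDTree(particles.positions)
    dist, _ = tree.query(particles.positions, k=2)
    nn = dist[:, 1]
    shell_cut = 1.45 * float(np.median(nn))
    pairs = tree.query_pairs(r=shell_cut, output_type="ndarray")
    shell = np.linalg.norm(particles.positions[pairs[:, 0]]
                           - particles.positions[pairs[:, 1]], axis=1)
    if len(shell) == 0:
        shell = nn
    grid = np.arange(max(0.5, shell.min() - 3 * smoothing),
                     shell.max() + 3 * smoothing, 0.5)
    density = np.exp(-0.5 * ((grid[:, None] - shell[None, :]) / smoothing) ** 2).sum(axis=1)
    modal = float(grid[np.argmax(density)])
    if expected is None:
        expected, tol = modal, 0.25 * modal
    counts = annulus_counts(particles.positions, expected, tol)
    hist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    return LatticeStats(nn_distances=nn, modal_spacing=modal,
                        lattice_constant=tod_to_lattice_constant(modal),
                        neighbor_counts=hist)


def tod_to_lattice_constant(tod_spacing: float) -> float:
    """Hexagonal lattice constant from the honeycomb nearest-neighbour
    spacing of trimer-of-dimer axes: ``sqrt(3) * tod_spacing``.
    Unit-preserving (nm in -> nm out, Angstrom in -> Angstrom out)."""
    if tod_spacing <= 0:
        raise ValueError("tod_spacing must be > 0")
    return SQRT3 * float(tod_spacing)
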