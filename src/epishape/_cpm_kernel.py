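"""Numba kernels for the Cellular Potts Metropolis dynamics.

The lattice is a 2D array of cell ids with periodic boundaries; label 0 is
medium and carries no energy terms.  One attempted move picks a random
boundary site (uniform over sites with at least one differing neighbor, by
rejection), proposes copying the id of a uniformly chosen differing neighbor,
and accepts with the Metropolis probability min(1, exp(-dH/T)).  Moves that
would annihilate a cell or locally disconnect the source cell are rejected.

Area and perimeter caches are updated incrementally; the kernels return the
accumulated energy change so callers can verify the bookkeeping against a
full recomputation.  The RNG is numba's own numpy-compatible generator,
seeded through :func:`seed_rng` for bit-reproducible trajectories.
"""

import numpy as np
from numba import njit

# neighbor offsets: bond neighborhood used for perimeter and copy moves
SQUARE_NEIGHBORS = np.array([[0, 1], [1, 0], [0, -1], [-1, 0]], dtype=np.int64)
# axial coordinates, cyclic order
HEX_NEIGHBORS = np.array(
    [[0, 1], [1, 0], [1, -1], [0, -1], [-1, 0], [-1, 1]], dtype=np.int64
)
# connectivity ring in cyclic order (8-ring for the square lattice)
SQUARE_RING = np.array(
    [[0, 1], [1, 1], [1, 0], [1, -1], [0, -1], [-1, -1], [-1, 0], [-1, 1]],
    dtype=np.int64,
)
HEX_RING = HEX_NEIGHBORS


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def compute_areas(spins, n_labels):
    areas = np.zeros(n_labels + 1, dtype=np.int64)
    for i in range(spins.shape[0]):
        for j in range(spins.shape[1]):
            areas[spins[i, j]] += 1
    return areas


@njit(cache=True)
def compute_perimeters(spins, nbr, n_labels):
    """Mismatched-bond count per label; each bond counts for both sides."""
    rows, cols = spins.shape
    per = np.zeros(n_labels + 1, dtype=np.int64)
    for i in range(rows):
        for j in range(cols):
            s = spins[i, j]
            for k in range(nbr.shape[0]):
                ni = (i + nbr[k, 0]) % rows
                nj = (j + nbr[k, 1]) % cols
                if spins[ni, nj] != s:
                    per[s] += 1
    return per


@njit(cache=True)
def total_energy(areas, perims, lam_a, lam_p, a0, p0, n_labels):
    e = 0.0
    for lab in range(1, n_labels + 1):
        da = areas[lab] - a0
        dp = perims[lab] - p0
        e += lam_a * da * da + lam_p * dp * dp
    return e


@njit(cache=True)
def _locally_connected(spins, i, j, s, ring):
    """True if the source cell's pixels on the ring form <= 1 cyclic block.

    A single block means removing (i, j) cannot split the cell locally; this
    is the standard local-connectivity heuristic keeping cells compact.
    """
    rows, cols = spins.shape
    m = ring.shape[0]
    blocks = 0
    prev = spins[(i + ring[m - 1, 0]) % rows, (j + ring[m - 1, 1]) % cols] == s
    for k in range(m):
        cur = spins[(i + ring[k, 0]) % rows, (j + ring[k, 1]) % cols] == s
        if cur and not prev:
            blocks += 1
        prev = cur
    return blocks <= 1


@njit(cache=True)
def run_attempts(
    spins,
    areas,
    perims,
    nbr,
    ring,
    lam_a,
    lam_p,
    a0,
    p0,
    temperature,
    n_attempts,
    check_connectivity,
):
    """Run ``n_attempts`` boundary-site copy attempts in place.

    Returns ``(accepted, delta_h_total)``; the caches are kept consistent
    with the spin configuration at every step.
    """
    rows, cols = spins.shape
    n_nbr = nbr.shape[0]
    accepted = 0
    dh_total = 0.0
    inv_t = 1.0 / temperature
    for _ in range(n_attempts):
        # uniform boundary site by rejection
        while True:
            i = np.random.randint(0, rows)
            j = np.random.randint(0, cols)
            s = spins[i, j]
            n_diff = 0
            for k in range(n_nbr):
                ni = (i + nbr[k, 0]) % rows
                nj = (j + nbr[k, 1]) % cols
                if spins[ni, nj] != s:
                    n_diff += 1
            if n_diff > 0:
                break
        # uniformly chosen differing neighbor supplies the proposed id
        pick = np.random.randint(0, n_diff)
        t = -1
        seen = 0
        same_s = 0
        for k in range(n_nbr):
            ni = (i + nbr[k, 0]) % rows
            nj = (j + nbr[k, 1]) % cols
            lab = spins[ni, nj]
            if lab == s:
                same_s += 1
            else:
                if seen == pick:
                    t = lab
                seen += 1
        # annihilation guard
        if s != 0 and areas[s] <= 1:
            continue
        # local connectivity of the shrinking cell
        if s != 0 and check_connectivity:
            if not _locally_connected(spins, i, j, s, ring):
                continue
        same_t = 0
        for k in range(n_nbr):
            ni = (i + nbr[k, 0]) % rows
            nj = (j + nbr[k, 1]) % cols
            if spins[ni, nj] == t:
                same_t += 1
        d_per_s = same_s - (n_nbr - same_s)
        d_per_t = (n_nbr - same_t) - same_t
        dh = 0.0
        if s != 0:
            da = areas[s] - a0
            dp = perims[s] - p0
            dh += lam_a * ((da - 1.0) ** 2 - da * da)
            dh += lam_p * ((dp + d_per_s) ** 2 - dp * dp)
        if t != 0:
            da = areas[t] - a0
            dp = perims[t] - p0
            dh += lam_a * ((da + 1.0) ** 2 - da * da)
            dh += lam_p * ((dp + d_per_t) ** 2 - dp * dp)
        if dh <= 0.0 or np.random.random() < np.exp(-dh * inv_t):
            spins[i, j] = t
            areas[s] -= 1
            areas[t] += 1
            perims[s] += d_per_s
            perims[t] += d_per_t
            accepted += 1
            dh_total += dh
    return accepted, dh_total
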