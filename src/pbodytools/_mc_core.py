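"""Numba kernels for the lattice Monte Carlo engine.

State layout (flat arrays shared with :mod:`pbodytools.lattice_mc`):

* ``coords``      (N, 3) int64 — *unwrapped* bead coordinates; the occupancy
  grid is indexed by the wrapped site, so periodic boundaries act only through
  the grid.  Keeping coordinates unwrapped makes rigid rotations exact.
* ``btype``       (N,)   int8  — 0 = IDR, 1 = OD, 2 = RNA.
* ``chain_start`` (C+1,) int64 — beads of chain c are [chain_start[c], chain_start[c+1]).
* ``grid``        (L³,)  int64 — bead index occupying each wrapped site, −1 if empty.
* ``eps``         (3, 3) float64 — contact energies in kT, symmetric.

Contacts are face-adjacent (6-neighbourhood) non-bonded bead pairs; bonded
means consecutive beads of the same chain.  Moves are Metropolis-accepted at
kT = 1 with structural (excluded-volume) rejections treated as infinite energy.
"""

from __future__ import annotations

import itertools

import numpy as np
from numba import njit

# 6 face-neighbour offsets on the cubic lattice.
OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

# move kind codes
TRANSLATE, ROTATE, LOCAL_PIVOT, GLOBAL_PIVOT = 0, 1, 2, 3


def _proper_cubic_rotations() -> np.ndarray:
    """The 24 proper rotation matrices of the cube (det = +1, entries in {-1,0,1})."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    assert len(mats) == 24
    return np.stack(mats)


ROTATIONS = _proper_cubic_rotations()


@njit(cache=True, inline="always")
def _site(x, y, z, L):
    return ((x % L) * L + (y % L)) * L + (z % L)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def build_grid(coords, L):
    grid = np.full(L * L * L, -1, dtype=np.int64)
    for i in range(coords.shape[0]):
        s = _site(coords[i, 0], coords[i, 1], coords[i, 2], L)
        if grid[s] != -1:
            raise ValueError("excluded volume violated: two beads on one site")
        grid[s] = i
    return grid


@njit(cache=True)
def total_energy_kernel(coords, btype, bond_prev, bond_next, grid, L, eps):
    """Sum eps over unordered face-adjacent non-bonded bead pairs."""
    E = 0.0
    for i in range(coords.shape[0]):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        for d in range(6):
            j = grid[_site(x + OFFSETS[d, 0], y + OFFSETS[d, 1], z + OFFSETS[d, 2], L)]
            if j > i and j != bond_prev[i] and j != bond_next[i]:
                E += eps[btype[i], btype[j]]
    return E


@njit(cache=True, inline="always")
def _wrapped_adjacent(ax, ay, az, bx, by, bz, L):
    dx = (ax - bx) % L
    dy = (ay - by) % L
    dz = (az - bz) % L
    n = 0
    if dx != 0:
        if dx != 1 and dx != L - 1:
            return False
        n += 1
    if dy != 0:
        if dy != 1 and dy != L - 1:
            return False
        n += 1
    if dz != 0:
        if dz != 1 and dz != L - 1:
            return False
        n += 1
    return n == 1


@njit(cache=True)
def _segment_grid_energy(seg_xyz, s, e, btype, bond_prev, bond_next, grid, L, eps):
    """Energy of beads [s, e) (at positions seg_xyz) against grid occupants.

    Pairs where both members lie in [s, e) are counted once (higher index only),
    so the value is comparable before/after a move of that segment.
    """
    E = 0.0
    for k in range(e - s):
        i = s + k
        x, y, z = seg_xyz[k, 0], seg_xyz[k, 1], seg_xyz[k, 2]
        for d in range(6):
            j = grid[_site(x + OFFSETS[d, 0], y + OFFSETS[d, 1], z + OFFSETS[d, 2], L)]
            if j == -1 or j == bond_prev[i] or j == bond_next[i]:
                continue
            if s <= j < e and j <= i:
                continue
            E += eps[btype[i], btype[j]]
    return E


@njit(cache=True)
def _internal_energy(seg_xyz, s, e, btype, bond_prev, bond_next, L, eps):
    """Pairwise energy among beads [s, e) at positions seg_xyz (counted once)."""
    E = 0.0
    n = e - s
    for a in range(n):
        i = s + a
        for b in range(a + 1, n):
            j = s + b
            if j == bond_next[i] or j == bond_prev[i]:
                continue
            if _wrapped_adjacent(
                seg_xyz[a, 0], seg_xyz[a, 1], seg_xyz[a, 2],
                seg_xyz[b, 0], seg_xyz[b, 1], seg_xyz[b, 2], L,
            ):
                E += eps[btype[i], btype[j]]
    return E


@njit(cache=True)
def run_chunk(coords, btype, chain_start, bond_prev, bond_next, grid, L, eps,
              move_cum, rotations, n_moves, energy0):
    """Advance the chain system by ``n_moves`` Metropolis moves.

    Returns (energy, n_accepted).  ``energy`` is tracked incrementally from
    ``energy0`` via per-move ΔE; tests verify it against a from-scratch
    recomputation.
    """
    n_chains = chain_start.shape[0] - 1
    maxlen = 0
    for c in range(n_chains):
        ln = chain_start[c + 1] - chain_start[c]
        if ln > maxlen:
            maxlen = ln
    new_xyz = np.empty((maxlen, 3), dtype=np.int64)
    old_xyz = np.empty((maxlen, 3), dtype=np.int64)
    energy = energy0
    n_acc = 0

    for _ in range(n_moves):
        c = np.random.randint(n_chains)
        a = chain_start[c]
        b = chain_start[c + 1]
        ln = b - a
        u = np.random.random()
        if u < move_cum[0]:
            kind = TRANSLATE
        elif u < move_cum[1]:
            kind = ROTATE
        elif u < move_cum[2]:
            kind = LOCAL_PIVOT
        else:
            kind = GLOBAL_PIVOT
        if kind == LOCAL_PIVOT and ln < 3:
            kind = ROTATE  # no internal bead to pivot about

        # --- build proposal: segment [s, e) with candidate coords in new_xyz ---
        if kind == TRANSLATE:
            s, e = a, b
            d = np.random.randint(6)
            for k in range(ln):
                new_xyz[k, 0] = coords[a + k, 0] + OFFSETS[d, 0]
                new_xyz[k, 1] = coords[a + k, 1] + OFFSETS[d, 1]
                new_xyz[k, 2] = coords[a + k, 2] + OFFSETS[d, 2]
        else:
            if kind == ROTATE:
                pivot = a + np.random.randint(ln)
                s, e = a, b
            elif kind == LOCAL_PIVOT:
                pivot = a + 1 + np.random.randint(ln - 2)  # internal bead
                left = pivot - a
                right = b - pivot - 1
                if left <= right:
                    s, e = a, pivot
                else:
                    s, e = pivot + 1, b
            else:  # GLOBAL_PIVOT
                pivot = a + np.random.randint(ln)
                if np.random.random() < 0.5:
                    s, e = a, pivot
                else:
                    s, e = pivot + 1, b
            if e <= s:  # empty segment: no-op, counts as accepted
                n_acc += 1
                continue
            R = rotations[np.random.randint(rotations.shape[0])]
            px, py, pz = coords[pivot, 0], coords[pivot, 1], coords[pivot, 2]
            for k in range(e - s):
                dx = coords[s + k, 0] - px
                dy = coords[s + k, 1] - py
                dz = coords[s + k, 2] - pz
                new_xyz[k, 0] = px + R[0, 0] * dx + R[0, 1] * dy + R[0, 2] * dz
                new_xyz[k, 1] = py + R[1, 0] * dx + R[1, 1] * dy + R[1, 2] * dz
                new_xyz[k, 2] = pz + R[2, 0] * dx + R[2, 1] * dy + R[2, 2] * dz

        seg = e - s
        # --- excluded volume: candidate sites must be empty or vacated ---
        ok = True
        for k in range(seg):
            occ = grid[_site(new_xyz[k, 0], new_xyz[k, 1], new_xyz[k, 2], L)]
            if occ != -1 and not (s <= occ < e):
                ok = False
                break
        if not ok:
            continue  # structural rejection: state unchanged

        for k in range(seg):
            old_xyz[k, 0] = coords[s + k, 0]
            old_xyz[k, 1] = coords[s + k, 1]
            old_xyz[k, 2] = coords[s + k, 2]

        # --- ΔE with the segment removed from the grid ---
        for k in range(seg):
            grid[_site(old_xyz[k, 0], old_xyz[k, 1], old_xyz[k, 2], L)] = -1
        e_old = (
            _segment_grid_energy(old_xyz[:seg], s, e, btype, bond_prev, bond_next, grid, L, eps)
            + _internal_energy(old_xyz[:seg], s, e, btype, bond_prev, bond_next, L, eps)
        )
        e_new = (
            _segment_grid_energy(new_xyz[:seg], s, e, btype, bond_prev, bond_next, grid, L, eps)
            + _internal_energy(new_xyz[:seg], s, e, btype, bond_prev, bond_next, L, eps)
        )
        dE = e_new - e_old

        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            for k in range(seg):
                coords[s + k, 0] = new_xyz[k, 0]
                coords[s + k, 1] = new_xyz[k, 1]
                coords[s + k, 2] = new_xyz[k, 2]
                grid[_site(new_xyz[k, 0], new_xyz[k, 1], new_xyz[k, 2], L)] = s + k
            energy += dE
            n_acc += 1
        else:
            for k in range(seg):
                grid[_site(old_xyz[k, 0], old_xyz[k, 1], old_xyz[k, 2], L)] = s + k

    return energy, n_acc


@njit(cache=True)
def chain_adjacency_pairs(coords, chain_of, grid, L):
    """Unique (chain_i, chain_j) pairs (i < j) sharing ≥1 face-adjacent bead pair."""
    n = coords.shape[0]
    out = np.empty((n * 6, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        ci = chain_of[i]
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        for d in range(6):
            j = grid[_site(x + OFFSETS[d, 0], y + OFFSETS[d, 1], z + OFFSETS[d, 2], L)]
            if j > i:
                cj = chain_of[j]
                if ci != cj:
                    lo = min(ci, cj)
                    hi = max(ci, cj)
                    out[m, 0] = lo
                    out[m, 1] = hi
                    m += 1
    return out[:m]
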