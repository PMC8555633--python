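"""Coarse-grained lattice Monte Carlo simulation of protein-RNA condensation.

The model represents an RNA-helicase-like protein as a five-bead chain — a
single central ordered-domain (OD) bead flanked by two intrinsically
disordered (IDR) beads on each side — and RNA as a 20-bead homopolymer, on a
periodic cubic lattice with excluded volume.  Short-range contact energies
(face-adjacent, non-bonded bead pairs) drive condensation; the default
interaction ordering is OD:OD strongest, then OD:IDR, with IDR:IDR weakest
and RNA:RNA repulsive.  Moves (chain translate, rigid rotation, local and
global pivots) are accepted by the Metropolis criterion at kT = 1.

The dense/dilute-phase analysis identifies condensates as connected
components of chains (any inter-chain face-adjacent bead pair connects two
chains) and reports condensate integrity (fraction of protein chains in the
largest cluster) and the fraction of RNA chains outside the largest
protein-containing cluster, the model's readout for RNA release when
protein:protein interactions are weakened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from . import _mc_core as core


class BeadType(IntEnum):
    """The three bead species of the coarse-grained model."""

    IDR = 0
    OD = 1
    RNA = 2


@dataclass(frozen=True)
class PolymerSpec:
    """A chain species: an ordered list of bead types."""

    name: str
    bead_types: tuple[BeadType, ...]

    def __post_init__(self):
        if len(self.bead_types) < 1:
            raise ValueError("a polymer needs at least one bead")

    def __len__(self) -> int:
        return len(self.bead_types)

    @property
    def is_protein(self) -> bool:
        return BeadType.RNA not in self.bead_types


def default_protein_spec() -> PolymerSpec:
    """Five-bead protein: central OD bead flanked by two IDR beads per side."""
    return PolymerSpec(
        "protein",
        (BeadType.IDR, BeadType.IDR, BeadType.OD, BeadType.IDR, BeadType.IDR),
    )


def default_rna_spec() -> PolymerSpec:
    """20-bead RNA homopolymer."""
    return PolymerSpec("rna", (BeadType.RNA,) * 20)


class InteractionMatrix:
    """Symmetric pairwise contact energies over {IDR, OD, RNA}, in kT.

    Negative entries are attractive.  Defaults honour the qualitative
    ordering OD:OD < OD:IDR < IDR:IDR ≤ 0 with RNA:RNA repulsive; exact
    magnitudes are model parameters, not measurements.  Protein-RNA
    attraction is kept weak enough that protein-RNA bridging alone cannot
    sustain a condensate: in this model both protein-protein and protein-RNA
    interactions are necessary for condensation, which is what makes
    condensate integrity a proxy for RNA retention.
    """

    def __init__(self, eps: np.ndarray):
        eps = np.asarray(eps, dtype=float)
        if eps.shape != (3, 3):
            raise ValueError("interaction matrix must be 3x3 over (IDR, OD, RNA)")
        if not np.allclose(eps, eps.T):
            raise ValueError("interaction matrix must be symmetric")
        self.eps = eps

    @classmethod
    def default(cls) -> "InteractionMatrix":
        e = np.zeros((3, 3))
        pairs = {
            (BeadType.OD, BeadType.OD): -3.0,
            (BeadType.OD, BeadType.IDR): -1.0,
            (BeadType.IDR, BeadType.IDR): -0.2,
            (BeadType.OD, BeadType.RNA): -1.5,
            (BeadType.IDR, BeadType.RNA): -0.75,
            (BeadType.RNA, BeadType.RNA): +1.0,
        }
        for (a, b), v in pairs.items():
            e[a, b] = e[b, a] = v
        return cls(e)

    def __call__(self, a: BeadType, b: BeadType) -> float:
        return float(self.eps[a, b])

    def with_protein_scale(self, scale: float) -> "InteractionMatrix":
        """Scale only the three protein-protein entries (IDR/OD block).

        Protein:RNA and RNA:RNA strengths stay fixed, mirroring how the
        protein:protein interaction strength is swept in the condensate
        integrity analysis.
        """
        e = self.eps.copy()
        e[:2, :2] *= scale
        return InteractionMatrix(e)


DEFAULT_MOVE_MIX = (0.3, 0.2, 0.4, 0.1)  # translate, rotate, local pivot, global pivot


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one lattice MC run (desk-scale defaults).

    The desk defaults (24³ lattice, 60 protein and 10 RNA chains, 3×10⁷
    moves) are the smallest system we found that both condenses and
    equilibrates its cluster structure within minutes on one CPU; cluster
    coarsening proceeds only by single-chain exchange, so larger systems
    nucleate several condensates and need far longer runs to merge them.
    ``production()`` is the full-scale preset: 60³ lattice, 800 protein and
    50 RNA chains, with analysis on the terminal 20% of frames.
    """

    L: int = 24
    n_protein: int = 60
    n_rna: int = 10
    n_steps: int = 30_000_000
    burn_in_fraction: float = 0.8
    move_mix: tuple[float, float, float, float] = DEFAULT_MOVE_MIX
    protein_scale: float = 1.0
    seed: int = 0
    n_replicas: int = 3
    frame_interval: int = 500_000
    protein_spec: PolymerSpec = field(default_factory=default_protein_spec)
    rna_spec: PolymerSpec = field(default_factory=default_rna_spec)

    @classmethod
    def production(cls, **kw) -> "SimulationConfig":
        return cls(L=60, n_protein=800, n_rna=50, **kw)

    def chain_specs(self) -> list[PolymerSpec]:
        return [self.protein_spec] * self.n_protein + [self.rna_spec] * self.n_rna

    @property
    def total_beads(self) -> int:
        return self.n_protein * len(self.protein_spec) + self.n_rna * len(self.rna_spec)

    def validate(self) -> None:
        if self.L < 10:
            raise ValueError("lattice side must be at least 10")
        if self.total_beads > 0.5 * self.L**3:
            raise DensityError(
                f"{self.total_beads} beads exceed half of {self.L}^3 = {self.L ** 3} sites"
            )
        longest = max(len(self.protein_spec), len(self.rna_spec) if self.n_rna else 1)
        if longest >= self.L:
            raise ValueError("lattice side must exceed the longest chain length")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if abs(sum(self.move_mix) - 1.0) > 1e-9 or min(self.move_mix) < 0:
            raise ValueError("move_mix must be non-negative and sum to 1")
        if self.n_steps < 0 or self.frame_interval < 1 or self.n_replicas < 1:
            raise ValueError("n_steps >= 0, frame_interval >= 1, n_replicas >= 1 required")


class DensityError(ValueError):
    """Raised when chains cannot be placed at the requested density."""


@dataclass
class LatticeState:
    """All chains on the lattice, as flat bead arrays.

    ``coords`` are unwrapped integers; occupancy is defined on wrapped sites.
    ``chain_start`` gives bead ranges per chain; ``chain_is_protein`` marks
    protein (vs RNA) chains.
    """

    L: int
    coords: np.ndarray          # (N, 3) int64, unwrapped
    btype: np.ndarray           # (N,) int8
    chain_start: np.ndarray     # (C+1,) int64
    chain_is_protein: np.ndarray  # (C,) bool

    @property
    def n_chains(self) -> int:
        return len(self.chain_start) - 1

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def wrapped_coords(self) -> np.ndarray:
        return np.mod(self.coords, self.L)

    def chain_of_bead(self) -> np.ndarray:
        out = np.empty(self.n_beads, dtype=np.int64)
        for c in range(self.n_chains):
            out[self.chain_start[c]:self.chain_start[c + 1]] = c
        return out

    def bond_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(bond_prev, bond_next): neighbour bead index along the chain, −1 at ends."""
        prev = np.full(self.n_beads, -1, dtype=np.int64)
        nxt = np.full(self.n_beads, -1, dtype=np.int64)
        for c in range(self.n_chains):
            a, b = self.chain_start[c], self.chain_start[c + 1]
            prev[a + 1:b] = np.arange(a, b - 1)
            nxt[a:b - 1] = np.arange(a + 1, b)
        return prev, nxt

    def occupancy(self) -> np.ndarray:
        """Flat L³ array of bead indices (−1 empty); raises on overlap."""
        return core.build_grid(self.coords, self.L)

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.L, self.coords.copy(), self.btype.copy(),
            self.chain_start.copy(), self.chain_is_protein.copy(),
        )

    def validate(self) -> None:
        """Check excluded volume and chain connectivity."""
        self.occupancy()
        for c in range(self.n_chains):
            a, b = self.chain_start[c], self.chain_start[c + 1]
            d = np.abs(np.diff(self.coords[a:b], axis=0))
            if b - a > 1 and not np.all(d.sum(axis=1) == 1):
                raise ValueError(f"chain {c} is not face-connected")


@dataclass(frozen=True)
class FrameSummary:
    """Per-saved-frame observables of a run."""

    step: int
    energy: float
    largest_cluster_chains: int
    protein_fraction_largest: float
    rna_dilute_fraction: float  # NaN when the system has no RNA


# ---------------------------------------------------------------------------
# construction


def initialize_system(config: SimulationConfig, rng: np.random.Generator) -> LatticeState:
    """Place all chains as non-overlapping self-avoiding face-adjacent walks.

    Deterministic given the generator state.  Raises :class:`DensityError`
    if placement repeatedly fails (too dense a system).
    """
    config.validate()
    specs = config.chain_specs()
    n_beads = sum(len(s) for s in specs)
    L = config.L
    coords = np.empty((n_beads, 3), dtype=np.int64)
    btype = np.empty(n_beads, dtype=np.int8)
    chain_start = np.zeros(len(specs) + 1, dtype=np.int64)
    occupied: set[tuple[int, int, int]] = set()

    max_restarts = 50
    for _ in range(max_restarts):
        occupied.clear()
        pos = 0
        ok_all = True
        for ci, spec in enumerate(specs):
            chain_start[ci] = pos
            placed = _place_chain(len(spec), L, occupied, rng)
            if placed is None:
                ok_all = False
                break
            for k, site in enumerate(placed):
                coords[pos + k] = site
                occupied.add((site[0] % L, site[1] % L, site[2] % L))
            btype[pos:pos + len(spec)] = [int(t) for t in spec.bead_types]
            pos += len(spec)
        if ok_all:
            chain_start[len(specs)] = pos
            state = LatticeState(
                L, coords, btype, chain_start,
                np.array([s.is_protein for s in specs], dtype=bool),
            )
            state.validate()
            return state
    raise DensityError(
        f"could not place {config.n_protein} protein + {config.n_rna} RNA chains "
        f"({n_beads} beads) on a {L}^3 lattice after {max_restarts} attempts"
    )


def _place_chain(length, L, occupied, rng):
    """One self-avoiding walk; returns list of unwrapped sites or None."""
    for _ in range(200):
        x0 = rng.integers(0, L, size=3)
        if (x0[0] % L, x0[1] % L, x0[2] % L) in occupied:
            continue
        walk = [np.array(x0, dtype=np.int64)]
        taken = {tuple(np.mod(x0, L))}
        dead = False
        for _ in range(length - 1):
            dirs = rng.permutation(6)
            for d in dirs:
                cand = walk[-1] + core.OFFSETS[d]
                key = (cand[0] % L, cand[1] % L, cand[2] % L)
                if key not in occupied and key not in taken:
                    walk.append(cand)
                    taken.add(key)
                    break
            else:
                dead = True
                break
        if not dead:
            return walk
    return None


# ---------------------------------------------------------------------------
# energy and moves


def total_energy(state: LatticeState, matrix: InteractionMatrix) -> float:
    """Contact energy in kT: eps summed over face-adjacent non-bonded pairs."""
    prev, nxt = state.bond_arrays()
    return float(core.total_energy_kernel(
        state.coords, state.btype, prev, nxt, state.occupancy(), state.L, matrix.eps
    ))


def metropolis_accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion at kT = 1: accept with probability min(1, e^(−ΔE))."""
    return delta_e <= 0.0 or rng.random() < math.exp(-delta_e)


MOVE_KINDS = ("translate", "rotate", "local_pivot", "global_pivot")


def propose_move(
    state: LatticeState, chain_id: int, kind: str, rng: np.random.Generator
) -> np.ndarray | None:
    """Candidate coordinates for one move, or None on structural rejection.

    The returned array is a full (N, 3) coordinate set (only the moved
    segment differs).  Connectivity is preserved by construction; overlap of
    a moved bead with any unmoved bead rejects the proposal.
    """
    if kind not in MOVE_KINDS:
        raise ValueError(f"unknown move kind {kind!r}; expected one of {MOVE_KINDS}")
    a, b = int(state.chain_start[chain_id]), int(state.chain_start[chain_id + 1])
    ln = b - a
    new = state.coords.copy()
    if kind == "translate":
        s, e = a, b
        new[s:e] += core.OFFSETS[rng.integers(6)]
    else:
        if kind == "local_pivot" and ln < 3:
            kind = "rotate"
        if kind == "rotate":
            pivot = a + int(rng.integers(ln))
            s, e = a, b
        elif kind == "local_pivot":
            pivot = a + 1 + int(rng.integers(ln - 2))
            left, right = pivot - a, b - pivot - 1
            s, e = (a, pivot) if left <= right else (pivot + 1, b)
        else:  # global_pivot
            pivot = a + int(rng.integers(ln))
            s, e = (a, pivot) if rng.random() < 0.5 else (pivot + 1, b)
        if e <= s:
            return new  # empty segment: identity proposal
        R = core.ROTATIONS[rng.integers(24)]
        new[s:e] = state.coords[pivot] + (state.coords[s:e] - state.coords[pivot]) @ R.T
    # excluded volume against unmoved beads (wrapped sites)
    L = state.L
    moved_sites = {tuple(p) for p in np.mod(new[s:e], L)}
    if len(moved_sites) < e - s:
        return None
    unmoved = np.concatenate([np.mod(new[:s], L), np.mod(new[e:], L)])
    if moved_sites & {tuple(p) for p in unmoved}:
        return None
    return new


def metropolis_step(
    state: LatticeState,
    matrix: InteractionMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[LatticeState, bool]:
    """One reference Metropolis step (clear but slow; the run loop uses the
    jitted kernel with identical semantics)."""
    chain_id = int(rng.integers(state.n_chains))
    kind = MOVE_KINDS[int(rng.choice(4, p=np.asarray(config.move_mix)))]
    cand = propose_move(state, chain_id, kind, rng)
    if cand is None:
        return state, False
    e_old = total_energy(state, matrix)
    cand_state = LatticeState(
        state.L, cand, state.btype, state.chain_start, state.chain_is_protein
    )
    d_e = total_energy(cand_state, matrix) - e_old
    if metropolis_accept(d_e, rng):
        state.coords = cand
        return state, True
    return state, False


# ---------------------------------------------------------------------------
# clustering and phase analysis


def find_clusters(state: LatticeState) -> list[list[int]]:
    """Partition chains into connected components.

    Two chains are connected iff any inter-chain bead pair is face-adjacent.
    Returns clusters as sorted lists of chain ids, largest first.
    """
    parent = np.arange(state.n_chains)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = core.chain_adjacency_pairs(
        state.coords, state.chain_of_bead(), state.occupancy(), state.L
    )
    for ci, cj in pairs:
        ri, rj = find(ci), find(cj)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for c in range(state.n_chains):
        groups.setdefault(find(c), []).append(c)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g[0]))


def rna_dilute_fraction(state: LatticeState) -> float:
    """Fraction of RNA chains outside the largest protein-containing cluster.

    Returns 1.0 when no cluster contains a protein chain.  Raises if the
    system has no RNA chains (the quantity is undefined).
    """
    rna_ids = np.flatnonzero(~state.chain_is_protein)
    if len(rna_ids) == 0:
        raise ValueError("rna_dilute_fraction is undefined without RNA chains")
    clusters = find_clusters(state)
    protein_clusters = [g for g in clusters if any(state.chain_is_protein[c] for c in g)]
    if not protein_clusters:
        return 1.0
    largest = set(protein_clusters[0])  # clusters are sorted largest-first
    n_out = sum(1 for c in rna_ids if c not in largest)
    return n_out / len(rna_ids)


def summarize_frame(state: LatticeState, matrix: InteractionMatrix, step: int,
                    energy: float | None = None) -> FrameSummary:
    clusters = find_clusters(state)
    largest = clusters[0] if clusters else []
    n_prot = int(state.chain_is_protein.sum())
    frac_prot = (
        sum(1 for c in largest if state.chain_is_protein[c]) / n_prot if n_prot else 0.0
    )
    has_rna = bool((~state.chain_is_protein).any())
    dilute = rna_dilute_fraction(state) if has_rna else float("nan")
    if energy is None:
        energy = total_energy(state, matrix)
    return FrameSummary(step, float(energy), len(largest), frac_prot, dilute)


# ---------------------------------------------------------------------------
# running


def run_simulation(
    config: SimulationConfig,
    matrix: InteractionMatrix | None = None,
    return_all_frames: bool = True,
) -> tuple[list[FrameSummary], LatticeState]:
    """Run one replica; frames are saved every ``frame_interval`` moves.

    The initial state counts as frame 0.  Reproducible given ``config.seed``.
    """
    config.validate()
    if matrix is None:
        matrix = InteractionMatrix.default()
    matrix = matrix.with_protein_scale(config.protein_scale)
    rng = np.random.default_rng(config.seed)
    state = initialize_system(config, rng)
    prev, nxt = state.bond_arrays()
    grid = state.occupancy()
    move_cum = np.cumsum(np.asarray(config.move_mix, dtype=float))
    core.seed_rng(int(rng.integers(2**31 - 1)))

    energy = total_energy(state, matrix)
    frames = [summarize_frame(state, matrix, 0, energy)]
    done = 0
    while done < config.n_steps:
        chunk = min(config.frame_interval, config.n_steps - done)
        energy, _ = core.run_chunk(
            state.coords, state.btype, state.chain_start, prev, nxt, grid,
            state.L, matrix.eps, move_cum, core.ROTATIONS, chunk, energy,
        )
        done += chunk
        frames.append(summarize_frame(state, matrix, done, energy))
    return frames, state


def terminal_frames(frames: Sequence[FrameSummary], burn_in_fraction: float) -> list[FrameSummary]:
    """The analysis window: frames after discarding the first burn_in fraction."""
    n = len(frames)
    start = int(math.floor(burn_in_fraction * n))
    return list(frames[min(start, n - 1):])


def frames_to_dataframe(frames: Sequence[FrameSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": [f.step for f in frames],
            "energy_kT": [f.energy for f in frames],
            "largest_cluster_chains": [f.largest_cluster_chains for f in frames],
            "protein_fraction_largest": [f.protein_fraction_largest for f in frames],
            "rna_dilute_fraction": [f.rna_dilute_fraction for f in frames],
        }
    )


def sweep_protein_interaction(
    base_config: SimulationConfig,
    scales: Sequence[float],
    matrix: InteractionMatrix | None = None,
) -> pd.DataFrame:
    """Sweep the protein:protein interaction scale.

    For each scale, ``n_replicas`` independent runs (seeds seed + replica
    index) are analysed on the terminal window; the table reports replicate
    mean and SEM of condensate integrity (protein fraction in the largest
    cluster) and RNA dilute fraction.  SEM is NaN for a single replica.
    """
    if len(scales) < 1:
        raise ValueError("at least one scale required")
    rows = []
    for scale in scales:
        integ, dilute = [], []
        for rep in range(base_config.n_replicas):
            cfg = replace(base_config, protein_scale=scale, seed=base_config.seed + rep)
            frames, _ = run_simulation(cfg, matrix)
            window = terminal_frames(frames, cfg.burn_in_fraction)
            integ.append(float(np.mean([f.protein_fraction_largest for f in window])))
            if cfg.n_rna:
                dilute.append(float(np.mean([f.rna_dilute_fraction for f in window])))
        def _sem(x):
            return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")
        rows.append(
            {
                "protein_scale": scale,
                "integrity_mean": float(np.mean(integ)),
                "integrity_sem": _sem(integ),
                "rna_dilute_mean": float(np.mean(dilute)) if dilute else float("nan"),
                "rna_dilute_sem": _sem(dilute) if dilute else float("nan"),
                "n_replicas": base_config.n_replicas,
            }
        )
    return pd.DataFrame(rows)
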