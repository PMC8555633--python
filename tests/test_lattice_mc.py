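"""Lattice MC engine: construction, energy, moves, clustering, phase readouts."""

import numpy as np
import pytest
from scipy import stats

from pbodytools import _mc_core as core
from pbodytools import lattice_mc as lmc
from pbodytools.lattice_mc import (
    BeadType,
    DensityError,
    InteractionMatrix,
    LatticeState,
    PolymerSpec,
    SimulationConfig,
)

# a small, fast configuration used throughout (L must exceed the 20-bead RNA)
SMALL = SimulationConfig(
    L=21, n_protein=8, n_rna=2, n_steps=50_000, frame_interval=10_000,
    seed=3, n_replicas=1,
)


def brute_force_energy(state: LatticeState, matrix: InteractionMatrix) -> float:
    """Independent all-pairs oracle: wrapped minimal-image face adjacency."""
    L = state.L
    w = state.wrapped_coords
    prev, nxt = state.bond_arrays()
    E = 0.0
    for i in range(state.n_beads):
        for j in range(i + 1, state.n_beads):
            d = np.abs(w[i] - w[j]) % L
            d = np.minimum(d, L - d)
            if d.sum() == 1 and nxt[i] != j and prev[i] != j:
                E += matrix.eps[state.btype[i], state.btype[j]]
    return E


def brute_force_clusters(state: LatticeState) -> list[list[int]]:
    """Union-find over all bead pairs, independent of the grid-based path."""
    L = state.L
    w = state.wrapped_coords
    chain_of = state.chain_of_bead()
    parent = list(range(state.n_chains))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(state.n_beads):
        for j in range(i + 1, state.n_beads):
            d = np.abs(w[i] - w[j]) % L
            d = np.minimum(d, L - d)
            if d.sum() == 1 and chain_of[i] != chain_of[j]:
                ri, rj = find(chain_of[i]), find(chain_of[j])
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for c in range(state.n_chains):
        groups.setdefault(find(c), []).append(c)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g[0]))


def _single_bead_state(L, positions, types, is_protein):
    """A LatticeState of single-bead chains at the given wrapped positions."""
    n = len(positions)
    return LatticeState(
        L=L,
        coords=np.array(positions, dtype=np.int64),
        btype=np.array([int(t) for t in types], dtype=np.int8),
        chain_start=np.arange(n + 1, dtype=np.int64),
        chain_is_protein=np.array(is_protein, dtype=bool),
    )


class TestInitialization:
    def test_single_protein_occupies_five_sites(self, rng):
        cfg = SimulationConfig(L=30, n_protein=1, n_rna=0, n_steps=0)
        state = lmc.initialize_system(cfg, rng)
        assert state.n_beads == 5
        assert (state.occupancy() >= 0).sum() == 5
        state.validate()

    def test_overfull_lattice_raises_density_error(self, rng):
        cfg = SimulationConfig(L=10, n_protein=200, n_rna=0, n_steps=0)
        with pytest.raises(DensityError):
            cfg.validate()

    def test_same_seed_gives_identical_states(self):
        s1 = lmc.initialize_system(SMALL, np.random.default_rng(7))
        s2 = lmc.initialize_system(SMALL, np.random.default_rng(7))
        np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_chains_are_self_avoiding_and_connected(self, rng):
        state = lmc.initialize_system(SMALL, rng)
        state.validate()  # raises on overlap or broken connectivity


class TestEnergy:
    def test_empty_lattice_has_zero_energy(self, rng):
        cfg = SimulationConfig(L=12, n_protein=0, n_rna=0, n_steps=0)
        state = lmc.initialize_system(cfg, rng)
        assert lmc.total_energy(state, InteractionMatrix.default()) == 0.0

    def test_two_adjacent_od_beads_contribute_one_contact(self):
        state = _single_bead_state(
            10, [[0, 0, 0], [0, 0, 1]], [BeadType.OD, BeadType.OD], [True, True]
        )
        assert lmc.total_energy(state, InteractionMatrix.default()) == -3.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_energy_matches_brute_force_oracle(self, seed):
        cfg = SimulationConfig(
            L=21, n_protein=3, n_rna=1, n_steps=20_000, frame_interval=20_000,
            seed=seed, n_replicas=1,
        )
        m = InteractionMatrix.default()
        _, state = lmc.run_simulation(cfg, m)
        assert lmc.total_energy(state, m) == pytest.approx(
            brute_force_energy(state, m), abs=1e-9
        )

    def test_periodic_translation_invariance(self, rng):
        state = lmc.initialize_system(SMALL, rng)
        m = InteractionMatrix.default()
        e0 = lmc.total_energy(state, m)
        shifted = state.copy()
        shifted.coords += np.array([5, 17, 101])  # any lattice vector
        assert lmc.total_energy(shifted, m) == pytest.approx(e0, abs=1e-9)

    def test_incremental_energy_matches_recomputation(self):
        """Tracked energy after chunks of accepted moves equals from-scratch."""
        m = InteractionMatrix.default()
        state = lmc.initialize_system(SMALL, np.random.default_rng(SMALL.seed))
        prev, nxt = state.bond_arrays()
        grid = state.occupancy()
        move_cum = np.cumsum(SMALL.move_mix)
        core.seed_rng(99)
        energy = lmc.total_energy(state, m)
        for _ in range(100):
            energy, _ = core.run_chunk(
                state.coords, state.btype, state.chain_start, prev, nxt, grid,
                state.L, m.eps, move_cum, core.ROTATIONS, 500, energy,
            )
            assert energy == pytest.approx(lmc.total_energy(state, m), abs=1e-9)
        state.validate()  # excluded volume and connectivity survive the run


class TestMoves:
    def test_translate_on_empty_lattice_always_valid(self, rng):
        cfg = SimulationConfig(L=30, n_protein=1, n_rna=0, n_steps=0)
        state = lmc.initialize_system(cfg, rng)
        for _ in range(50):
            assert lmc.propose_move(state, 0, "translate", rng) is not None

    def test_unknown_move_kind_rejected(self, rng):
        state = lmc.initialize_system(SMALL, rng)
        with pytest.raises(ValueError, match="move kind"):
            lmc.propose_move(state, 0, "teleport", rng)

    @pytest.mark.parametrize("kind", lmc.MOVE_KINDS)
    def test_proposals_preserve_connectivity_and_volume(self, kind, rng):
        state = lmc.initialize_system(SMALL, rng)
        for _ in range(200):
            chain = int(rng.integers(state.n_chains))
            cand = lmc.propose_move(state, chain, kind, rng)
            if cand is None:
                continue
            cand_state = LatticeState(
                state.L, cand, state.btype, state.chain_start, state.chain_is_protein
            )
            cand_state.validate()

    def test_pivot_onto_occupied_site_is_rejected(self, rng):
        # a straight 3-bead chain: local pivots swing the first bead about the
        # middle bead; blocking all four lateral targets leaves only the
        # identity rotation (or the in-chain site, which is itself rejected)
        blockers = [[1, 0, 1], [-1, 0, 1], [0, 1, 1], [0, -1, 1]]
        coords = [[0, 0, 0], [0, 0, 1], [0, 0, 2]] + blockers
        state = LatticeState(
            L=15,
            coords=np.array(coords, dtype=np.int64),
            btype=np.array([1] * len(coords), dtype=np.int8),
            chain_start=np.array([0, 3] + list(range(4, 4 + len(blockers))), dtype=np.int64),
            chain_is_protein=np.ones(1 + len(blockers), dtype=bool),
        )
        state.validate()
        rejected = accepted_identity = 0
        for _ in range(200):
            cand = lmc.propose_move(state, 0, "local_pivot", rng)
            if cand is None:
                rejected += 1
            else:
                np.testing.assert_array_equal(cand, state.coords)  # only identity fits
                accepted_identity += 1
        assert rejected > 0


class TestMetropolis:
    def test_downhill_moves_always_accepted(self, rng):
        assert all(lmc.metropolis_accept(-0.5, rng) for _ in range(100))
        assert all(lmc.metropolis_accept(0.0, rng) for _ in range(100))

    def test_acceptance_rate_at_unit_penalty_estimates_exp_minus_one(self, rng):
        n = 100_000
        acc = sum(lmc.metropolis_accept(1.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_single_step_api_runs_and_reports_flag(self, rng):
        state = lmc.initialize_system(SMALL, rng)
        m = InteractionMatrix.default()
        flags = [lmc.metropolis_step(state, m, SMALL, rng)[1] for _ in range(20)]
        state.validate()
        assert any(flags)  # some moves accepted at this dilution


class TestClusters:
    def test_distant_chains_are_singletons(self):
        state = _single_bead_state(
            15, [[0, 0, 0], [5, 5, 5], [10, 2, 7]],
            [BeadType.OD] * 3, [True] * 3,
        )
        assert lmc.find_clusters(state) == [[0], [1], [2]]

    def test_one_contact_merges_two_chains(self):
        state = _single_bead_state(
            15, [[0, 0, 0], [0, 1, 0], [7, 7, 7]],
            [BeadType.OD] * 3, [True] * 3,
        )
        assert lmc.find_clusters(state) == [[0, 1], [2]]

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_matches_brute_force_union_find(self, seed):
        cfg = SimulationConfig(
            L=21, n_protein=6, n_rna=2, n_steps=30_000, frame_interval=30_000,
            seed=seed, n_replicas=1,
        )
        _, state = lmc.run_simulation(cfg)
        assert lmc.find_clusters(state) == brute_force_clusters(state)


class TestRnaDiluteFraction:
    def test_no_rna_is_an_error(self):
        state = _single_bead_state(10, [[0, 0, 0]], [BeadType.OD], [True])
        with pytest.raises(ValueError, match="RNA"):
            lmc.rna_dilute_fraction(state)

    def test_counting_three_of_ten_rna_in_protein_cluster(self):
        # protein at origin; 3 RNA beads chained off it; 7 RNA isolated
        positions = [[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]]
        positions += [[10, 10, 2 * k] for k in range(7)]
        types = [BeadType.OD] + [BeadType.RNA] * 10
        state = _single_bead_state(25, positions, types, [True] + [False] * 10)
        assert lmc.rna_dilute_fraction(state) == pytest.approx(0.7)

    def test_no_protein_rna_contact_gives_one(self):
        state = _single_bead_state(
            15, [[0, 0, 0], [7, 7, 7]], [BeadType.OD, BeadType.RNA], [True, False]
        )
        assert lmc.rna_dilute_fraction(state) == 1.0

    def test_all_rna_in_protein_cluster_gives_zero(self):
        state = _single_bead_state(
            15, [[0, 0, 0], [0, 0, 1]], [BeadType.OD, BeadType.RNA], [True, False]
        )
        assert lmc.rna_dilute_fraction(state) == 0.0


class TestRunSimulation:
    def test_zero_steps_yields_single_initial_frame(self):
        cfg = SimulationConfig(
            L=21, n_protein=4, n_rna=1, n_steps=0, frame_interval=1000, seed=5
        )
        frames, state = lmc.run_simulation(cfg)
        assert len(frames) == 1
        assert frames[0].step == 0
        state.validate()

    def test_reproducible_given_seed(self):
        f1, s1 = lmc.run_simulation(SMALL)
        f2, s2 = lmc.run_simulation(SMALL)
        assert f1 == f2
        np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_frame_fractions_are_valid(self):
        frames, _ = lmc.run_simulation(SMALL)
        for f in frames:
            assert 0.0 <= f.protein_fraction_largest <= 1.0
            assert 0.0 <= f.rna_dilute_fraction <= 1.0
            assert np.isfinite(f.energy)

    def test_strong_attraction_condenses_desk_system(self):
        """Strong protein:protein coupling collapses most chains into one cluster."""
        fracs = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, protein_scale=1.5)
            frames, _ = lmc.run_simulation(cfg)
            window = lmc.terminal_frames(frames, cfg.burn_in_fraction)
            fracs.append(np.mean([f.protein_fraction_largest for f in window]))
        assert np.mean(fracs) > 0.8

    def test_zero_interaction_occupancy_is_uniform(self):
        """With all eps = 0 the chains fill the box uniformly (octant chi-square)."""
        zero = InteractionMatrix(np.zeros((3, 3)))
        passes = 0
        for seed in range(3):
            cfg = SimulationConfig(
                L=16, n_protein=8, n_rna=0, n_steps=0, seed=seed
            )
            state = lmc.initialize_system(cfg, np.random.default_rng(seed))
            prev, nxt = state.bond_arrays()
            grid = state.occupancy()
            move_cum = np.cumsum(cfg.move_mix)
            core.seed_rng(seed + 100)
            counts = np.zeros(8)
            energy = 0.0
            for _ in range(60):  # 60 weakly-correlated snapshots
                energy, _ = core.run_chunk(
                    state.coords, state.btype, state.chain_start, prev, nxt,
                    grid, state.L, zero.eps, move_cum, core.ROTATIONS, 5_000, energy,
                )
                w = state.wrapped_coords
                octant = (w[:, 0] >= 8) * 4 + (w[:, 1] >= 8) * 2 + (w[:, 2] >= 8)
                counts += np.bincount(octant, minlength=8)
            if stats.chisquare(counts).pvalue >= 0.01:
                passes += 1
        assert passes >= 2


class TestSweep:
    def test_single_scale_single_replica_flags_sem(self):
        cfg = SimulationConfig(
            L=21, n_protein=4, n_rna=1, n_steps=20_000, frame_interval=10_000,
            seed=2, n_replicas=1,
        )
        tab = lmc.sweep_protein_interaction(cfg, [1.0])
        assert len(tab) == 1
        assert np.isnan(tab["integrity_sem"].iloc[0])

    def test_sweep_is_deterministic(self):
        cfg = SimulationConfig(
            L=21, n_protein=4, n_rna=1, n_steps=20_000, frame_interval=10_000,
            seed=2, n_replicas=2,
        )
        t1 = lmc.sweep_protein_interaction(cfg, [0.0, 1.0])
        t2 = lmc.sweep_protein_interaction(cfg, [0.0, 1.0])
        assert t1.equals(t2)


class TestConfigAndMatrix:
    def test_default_matrix_honours_qualitative_ordering(self):
        m = InteractionMatrix.default()
        od_od = m(BeadType.OD, BeadType.OD)
        od_idr = m(BeadType.OD, BeadType.IDR)
        idr_idr = m(BeadType.IDR, BeadType.IDR)
        assert od_od < od_idr < idr_idr <= 0
        assert m(BeadType.RNA, BeadType.RNA) >= 0

    def test_protein_scale_leaves_rna_entries_fixed(self):
        m = InteractionMatrix.default()
        m2 = m.with_protein_scale(0.25)
        assert m2(BeadType.OD, BeadType.OD) == pytest.approx(0.25 * m(BeadType.OD, BeadType.OD))
        assert m2(BeadType.OD, BeadType.RNA) == m(BeadType.OD, BeadType.RNA)
        assert m2(BeadType.RNA, BeadType.RNA) == m(BeadType.RNA, BeadType.RNA)

    def test_asymmetric_matrix_rejected(self):
        e = np.zeros((3, 3))
        e[0, 1] = -1.0
        with pytest.raises(ValueError, match="symmetric"):
            InteractionMatrix(e)

    def test_bad_move_mix_rejected(self):
        cfg = SimulationConfig(move_mix=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="move_mix"):
            cfg.validate()

    def test_default_specs_match_model(self):
        p = lmc.default_protein_spec()
        r = lmc.default_rna_spec()
        assert len(p) == 5 and p.bead_types[2] == BeadType.OD
        assert sum(t == BeadType.IDR for t in p.bead_types) == 4
        assert len(r) == 20 and all(t == BeadType.RNA for t in r.bead_types)
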