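"""Coarse-grained side-arm brush: geometry, energies, moves, observables."""

import math

import numpy as np
import pytest

from nfstoich import brush as br
from nfstoich.brush import (
    BrushConfig,
    BrushState,
    SideArmSpec,
    build_system,
    coarsen_sidearm_spec,
    gyration_contrasts,
    load_sidearm_specs,
    mc_sweeps,
    pair_energy,
    radius_of_gyration,
    run_simulation,
    total_energy,
)


def tiny_specs(n_beads=2, charge=0.0):
    spec = SideArmSpec("NfL", n_beads, np.full(n_beads, charge), np.zeros(n_beads))
    return {"NfL": spec, "NfM": spec, "NfH": spec}


def small_charged_config(**overrides):
    """Single backbone, length-scaled arms: a fast interacting system."""
    specs = {k: coarsen_sidearm_spec(v, 0.05) for k, v in load_sidearm_specs().items()}
    kwargs = dict(
        n_backbones=1, arm_specs=specs, seed=9,
        sweeps_equil=10, sweeps_prod=20, sample_every=10,
    )
    kwargs.update(overrides)
    return BrushConfig(**kwargs)


class TestSideArmSpecs:
    def test_packaged_tables(self):
        specs = load_sidearm_specs()
        assert {s: specs[s].n_beads for s in specs} == {
            "NfL": 143, "NfM": 510, "NfH": 606,
        }
        assert {s: specs[s].charge_seq.sum() for s in specs} == {
            "NfL": -25.0, "NfM": -43.0, "NfH": -44.0,
        }
        # KSP phospho charge: -2 per designated serine (0 / 13 / 44 sites)
        assert {s: specs[s].phospho_extra.sum() for s in specs} == {
            "NfL": 0.0, "NfM": -26.0, "NfH": -88.0,
        }

    def test_coarsening_preserves_net_charge(self):
        for spec in load_sidearm_specs().values():
            small = coarsen_sidearm_spec(spec, 0.25)
            assert small.n_beads == round(spec.n_beads * 0.25)
            assert small.charge_seq.sum() == spec.charge_seq.sum()
            assert small.phospho_extra.sum() == spec.phospho_extra.sum()

    def test_coarsening_identity_and_domain(self):
        spec = load_sidearm_specs()["NfL"]
        assert coarsen_sidearm_spec(spec, 1.0) is spec
        with pytest.raises(ValueError):
            coarsen_sidearm_spec(spec, 0.0)


class TestGeometry:
    def test_default_graft_sites(self):
        cfg = BrushConfig()
        assert cfg.n_graft_sites == 31

    def test_graft_sites_tile_period(self):
        cfg = BrushConfig(arm_specs=tiny_specs(), use_excluded_volume=False)
        state = build_system(cfg)
        per_backbone = np.bincount(state.arm_backbone)
        assert np.all(per_backbone == 31)
        z = np.sort(state.pos[state.arm_start[state.arm_backbone == 0], 2])
        assert np.allclose(np.diff(z), 50.0 / 31)

    def test_degenerate_mixture_all_nfl(self):
        cfg = BrushConfig(stoichiometry=(1, 0, 0), arm_specs=tiny_specs(),
                          use_excluded_volume=False)
        state = build_system(cfg)
        assert set(state.arm_species) == {"NfL"}

    def test_species_fractions_follow_stoichiometry(self):
        # law of large numbers on the categorical sampler: use many sites
        cfg = BrushConfig(graft_interval=0.05, arm_specs=tiny_specs(),
                          use_excluded_volume=False, use_electrostatics=False,
                          seed=4)
        state = build_system(cfg)
        frac = np.array([
            np.mean([s == sp for s in state.arm_species])
            for sp in ("NfL", "NfM", "NfH")
        ])
        assert frac == pytest.approx([7 / 12, 3 / 12, 2 / 12], abs=0.05)

    def test_first_beads_on_backbone_surface(self):
        cfg = small_charged_config()
        state = build_system(cfg)
        centers = cfg.backbone_centers()
        first = state.pos[state.arm_start]
        d = np.linalg.norm(first[:, :2] - centers[state.arm_backbone], axis=1)
        assert d == pytest.approx(cfg.backbone_radius, abs=1e-9)


class TestPairEnergy:
    def test_neutral_bead_zero(self):
        cfg = BrushConfig()
        assert pair_energy(1.0, 0, -1, cfg) == 0.0

    def test_hard_core(self):
        cfg = BrushConfig()
        assert pair_energy(0.59, -1, 1, cfg) == math.inf
        assert pair_energy(0.59, 0, 0, cfg) == math.inf

    def test_screened_coulomb_value(self):
        # hand evaluation at the Debye length: 0.714 e^-1 / 0.785
        cfg = BrushConfig()
        assert 1 / cfg.kappa == pytest.approx(0.785, abs=1e-3)
        assert pair_energy(0.785, -1, -1, cfg) == pytest.approx(0.3346, abs=2e-4)

    def test_like_charges_repel_opposite_attract(self):
        cfg = BrushConfig()
        assert pair_energy(1.0, -1, -1, cfg) > 0
        assert pair_energy(1.0, -1, 1, cfg) < 0

    def test_cutoff(self):
        cfg = BrushConfig(cutoff=2.0)
        assert pair_energy(2.5, -1, -1, cfg) == 0.0

    def test_invalid_separation(self):
        with pytest.raises(ValueError):
            pair_energy(0.0, 1, 1, BrushConfig())


class TestTotalEnergy:
    def two_bead_pair_state(self, separation):
        """Two 2-bead arms; only the terminal beads carry charge."""
        cfg = BrushConfig(n_backbones=1, use_excluded_volume=False,
                          arm_specs=tiny_specs())
        t0 = np.array([10.0, 10.0, 10.6])
        t1 = t0 + np.array([separation, 0.0, 0.0])
        pos = np.array([
            t0 - [0.0, 0.0, 0.6], t0,   # arm 0: neutral first bead, charged tip
            t1 - [0.0, 0.0, 0.6], t1,   # arm 1
        ])
        charge = np.array([0.0, -1.0, 0.0, -1.0])
        return cfg, BrushState(
            pos=pos, charge=charge,
            arm_start=np.array([0, 2]), arm_len=np.array([2, 2]),
            arm_species=["NfL", "NfL"], arm_backbone=np.array([0, 0]),
            arm_site=np.array([0, 1]), config=cfg,
        )

    def test_two_isolated_charges_reduce_to_pair_energy(self):
        for r in (0.785, 1.5, 3.0):
            cfg, state = self.two_bead_pair_state(r)
            assert total_energy(state) == pytest.approx(
                pair_energy(r, -1, -1, cfg), rel=1e-9
            )

    def test_neutral_system_zero_energy(self):
        cfg = BrushConfig(arm_specs=tiny_specs(), use_excluded_volume=False)
        state = build_system(cfg)
        assert total_energy(state) == 0.0

    def test_no_overlaps_in_built_system(self):
        cfg = small_charged_config()
        state = build_system(cfg)
        assert np.isfinite(total_energy(state))

    def test_incremental_energy_matches_recomputation(self):
        # bookkeeping identity over >= 1000 accepted moves
        cfg = small_charged_config()
        state = build_system(cfg)
        e0 = total_energy(state)
        accepted, de = mc_sweeps(state, 8, seed=cfg.seed)
        assert accepted >= 1000
        assert e0 + de == pytest.approx(total_energy(state), abs=1e-6)


class TestMoves:
    def test_bond_lengths_preserved(self):
        cfg = small_charged_config()
        state = build_system(cfg)
        mc_sweeps(state, 5, seed=1)
        for a in range(state.n_arms):
            p = state.arm_positions(a)
            bonds = np.linalg.norm(np.diff(p, axis=0), axis=1)
            assert bonds == pytest.approx(cfg.bond_length, abs=1e-9)

    def test_first_beads_fixed(self):
        cfg = small_charged_config()
        state = build_system(cfg)
        before = state.pos[state.arm_start].copy()
        mc_sweeps(state, 5, seed=2)
        assert np.array_equal(state.pos[state.arm_start], before)

    def test_zero_delta_always_accepted(self):
        # Metropolis identity: a non-interacting chain accepts every move
        spec = SideArmSpec("NfL", 30, np.zeros(30), np.zeros(30))
        cfg = BrushConfig(graft_interval=50.0, n_backbones=1,
                          stoichiometry=(1, 0, 0),
                          use_excluded_volume=False, use_electrostatics=False,
                          sweeps_equil=0, sweeps_prod=50, sample_every=10,
                          seed=3, arm_specs={"NfL": spec, "NfM": spec,
                                             "NfH": spec})
        summary = run_simulation(cfg)
        assert summary.acceptance_rate == 1.0

    def test_hard_core_never_violated(self):
        cfg = small_charged_config()
        state = build_system(cfg)
        mc_sweeps(state, 10, seed=4)
        arm_id = state.arm_id_per_bead()
        d = state.pos[None, :, :] - state.pos[:, None, :]
        box = np.array([cfg.box_xy, cfg.box_xy, cfg.box_z])
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=-1)
        bonded = (np.abs(np.subtract.outer(np.arange(state.n_beads),
                                           np.arange(state.n_beads))) == 1) & (
            arm_id[:, None] == arm_id[None, :]
        )
        np.fill_diagonal(r, np.inf)
        r[bonded] = np.inf
        assert r.min() >= cfg.bead_diameter - 1e-9


class TestObservables:
    def test_rg_collinear_beads(self):
        p = np.array([[0, 0, 0], [0.6, 0, 0], [1.2, 0, 0]])
        assert radius_of_gyration(p) == pytest.approx(0.6 * math.sqrt(2 / 3),
                                                      rel=1e-12)

    def test_rg_coincident_beads(self):
        assert radius_of_gyration(np.zeros((4, 3))) == 0.0

    def test_rg_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.normal(0, 1, (20, 3))
        rg = radius_of_gyration(p)
        # rotation about z by 40 degrees plus a translation
        th = math.radians(40)
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        assert radius_of_gyration(p @ rot.T + 17.0) == pytest.approx(rg, rel=1e-12)

    def test_rg_needs_two_beads(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((1, 3)))

    def test_run_is_seed_deterministic(self):
        cfg = small_charged_config(sweeps_equil=5, sweeps_prod=10, sample_every=5)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.samples.equals(b.samples)
        assert a.table.equals(b.table)

    def test_phosphorylation_extends_charged_arms(self):
        # more negative charge -> stronger intra-arm repulsion -> larger R_g
        specs = {k: coarsen_sidearm_spec(v, 0.1)
                 for k, v in load_sidearm_specs().items()}
        means = {}
        for phospho in (False, True):
            cfg = BrushConfig(
                graft_interval=50.0, n_backbones=1, stoichiometry=(0, 0, 1),
                phosphorylated=phospho, arm_specs=specs, seed=6,
                sweeps_equil=1500, sweeps_prod=1500, sample_every=25,
            )
            means[phospho] = run_simulation(cfg).species_mean("NfH")
        assert means[True] > means[False]


class TestGyrationContrasts:
    @staticmethod
    def cells(shift=0.0, rng=None):
        rng = rng or np.random.default_rng(7)
        cells = {}
        for mix in ("control", "adaptive"):
            for sp in ("NfL", "NfM", "NfH"):
                for ph in (False, True):
                    mu = {"NfL": 3.0, "NfM": 9.0, "NfH": 12.0}[sp]
                    if mix == "adaptive" and sp == "NfH" and not ph:
                        mu += shift
                    cells[(mix, sp, ph)] = rng.normal(mu, 0.5, 40)
        return cells

    def test_shifted_cell_detected(self):
        res = gyration_contrasts(self.cells(shift=-5.0))
        table = res["contrasts"].set_index(["species", "phospho"])
        assert res["omnibus"].p_value < 0.05
        assert bool(table.loc[("NfH", False), "significant"])
        assert table["alpha_corrected"].iloc[0] == pytest.approx(0.05 / 6)

    def test_twelve_cells_and_six_contrasts(self):
        res = gyration_contrasts(self.cells())
        assert len(res["omnibus"].groups) == 12
        assert len(res["contrasts"]) == 6

    def test_identical_cells_nothing_significant(self):
        cells = {
            (mix, sp, ph): np.tile([1.0, 2.0, 3.0], 5)
            for mix in ("control", "adaptive")
            for sp in ("NfL", "NfM", "NfH")
            for ph in (False, True)
        }
        res = gyration_contrasts(cells)
        assert res["omnibus"].statistic == pytest.approx(0.0, abs=1e-10)
        assert not res["contrasts"]["significant"].any()


def test_xyz_dump_round_trips_bead_count(tmp_path):
    cfg = BrushConfig(arm_specs=tiny_specs(), use_excluded_volume=False,
                      n_backbones=1)
    state = build_system(cfg)
    path = tmp_path / "frame.xyz"
    br.dump_xyz(state, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == state.n_beads
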