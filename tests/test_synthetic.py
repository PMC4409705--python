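"""Ground-truth world generation: planted structure, formats, determinism."""

import json

import numpy as np
import pytest

from coregulation import (
    CoregulationModel,
    WorldConfig,
    check_rate_consistency,
    expand_group_pairs,
    load_world,
    pair_values,
    restrict_to_analyzable,
    shuffle_interactome,
    simulate_world,
    spearman_with_ci,
    write_world,
)
from oracles import spearman_of_bivariate_normal


def dimer_config(n, rho, seed, planted=("x",)):
    """Complexes of size 2: every within-complex pair is independent."""
    return WorldConfig(
        seed=seed, n_complexes=n, complex_size_min=2, complex_size_max=2,
        rho_complex=rho, rho_binary=0.0, n_binary_edges=0, n_operons=0,
        n_party_hubs=0, n_date_hubs=0, n_free_proteins=0,
        planted_parameters=planted, missing_m_b_fraction=0.0,
    )


def complex_spearman(world, parameter, order_seed=0):
    table = world.analysis_table()
    pairs = expand_group_pairs(world.complexes, "co-complex")
    usable = restrict_to_analyzable(pairs, table, parameter)
    pv = pair_values(usable, table, parameter, seed=order_seed)
    return spearman_with_ci(pv)


class TestDeterminismAndFormats:
    def test_same_seed_same_world(self):
        cfg = WorldConfig(seed=5)
        w1, w2 = simulate_world(cfg), simulate_world(cfg)
        assert w1.binary.pairs == w2.binary.pairs
        assert w1.params.frame.equals(w2.params.frame)
        assert w1.hubs == w2.hubs

    def test_write_is_byte_identical(self, tmp_path):
        cfg = WorldConfig(seed=6, n_complexes=10, n_operons=5,
                          n_binary_edges=5, n_party_hubs=2, n_date_hubs=2,
                          n_free_proteins=20)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_world(simulate_world(cfg), d1)
        write_world(simulate_world(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_roundtrip_through_real_readers(self, tmp_path):
        cfg = WorldConfig(seed=7, n_complexes=8, n_operons=4, n_binary_edges=4,
                          n_party_hubs=2, n_date_hubs=2, n_free_proteins=10)
        world = simulate_world(cfg)
        write_world(world, tmp_path)
        back = load_world(tmp_path)
        assert back.binary.pairs == world.binary.pairs
        assert back.complexes.groups == {k: tuple(v) for k, v in world.complexes.groups.items()}
        assert back.hubs == world.hubs
        np.testing.assert_array_equal(
            back.params.frame.to_numpy(), world.params.frame.to_numpy())

    def test_manifest_records_seed_and_planted_rho(self, tmp_path):
        cfg = WorldConfig(seed=42, n_complexes=5, n_operons=0,
                          n_binary_edges=0, n_party_hubs=1, n_date_hubs=1)
        write_world(simulate_world(cfg), tmp_path)
        manifest = json.loads((tmp_path / "ground_truth.json").read_text())
        assert manifest["seed"] == 42
        assert manifest["rho_complex"] == cfg.rho_complex
        assert manifest["config"]["seed"] == 42


class TestPlantedStructure:
    def test_independence_limit(self):
        """rho_complex = 0: within-complex Spearman is zero up to noise."""
        world = simulate_world(dimer_config(5000, 0.0, seed=8))
        est = complex_spearman(world, "x")
        assert abs(est.rho) < 0.03

    def test_degenerate_limit_rho_one(self):
        """rho_complex = 1: complex members share identical parameter values."""
        world = simulate_world(dimer_config(500, 1.0, seed=9))
        est = complex_spearman(world, "x")
        assert est.rho == pytest.approx(1.0, abs=1e-12)
        # values are literally equal within each complex
        table = world.analysis_table()
        for cid in list(world.complexes.groups)[:10]:
            a, b = world.complexes.members(cid)
            assert table.frame.loc[a, "x"] == table.frame.loc[b, "x"]

    def test_planted_rho_recovered_via_closed_form(self):
        """Latent Pearson 0.6 on the log scale appears as Spearman
        (6/pi)*arcsin(0.3) across within-complex pairs."""
        world = simulate_world(dimer_config(6000, 0.6, seed=10))
        est = complex_spearman(world, "x")
        assert est.rho == pytest.approx(spearman_of_bivariate_normal(0.6), abs=0.02)

    def test_unplanted_parameter_uncorrelated(self):
        world = simulate_world(dimer_config(4000, 0.6, seed=11, planted=("x",)))
        est = complex_spearman(world, "g")
        assert abs(est.rho) < 0.05

    def test_derived_rate_inherits_planted_structure(self):
        """R = x/I inherits the planted log-scale correlation when both x
        and I are planted with independent complex factors."""
        world = simulate_world(dimer_config(6000, 0.6, seed=12, planted=("x", "I")))
        est = complex_spearman(world, "R")
        assert est.rho == pytest.approx(spearman_of_bivariate_normal(0.6), abs=0.03)

    def test_signal_ordering_recovered(self, default_world):
        """co-complex > binary > |random| for a planted parameter."""
        model = CoregulationModel.from_world(default_world)
        model.add_controls(n_random=500, seed=1)
        res = model.fit(seed=2)
        rows = res.frame.set_index(["set", "parameter"])
        assert (rows.loc[("co-complex", "x"), "rho"]
                > rows.loc[("binary", "x"), "rho"]
                > abs(rows.loc[("random", "x"), "rho"]))

    def test_label_shuffling_destroys_planted_signal(self):
        world = simulate_world(dimer_config(5000, 0.6, seed=13))
        table = world.analysis_table()
        pairs = expand_group_pairs(world.complexes, "co-complex")
        shuffled = shuffle_interactome(pairs, seed=99)
        usable = restrict_to_analyzable(shuffled, table, "x")
        est = spearman_with_ci(pair_values(usable, table, "x", seed=0))
        assert abs(est.rho) < 0.05


class TestOperonsAndIdentities:
    def test_operon_members_share_x_and_m_exactly(self, default_world):
        frame = default_world.params.frame
        for oid in default_world.operons.groups:
            members = default_world.operons.members(oid)
            if len(members) < 2:
                continue
            assert frame.loc[list(members), "x"].nunique() == 1
            ms = frame.loc[list(members), "m"].dropna()
            assert ms.nunique() <= 1

    def test_intra_operon_spearman_of_x_is_one(self, default_world):
        table = default_world.analysis_table()
        pairs = expand_group_pairs(default_world.operons, "operon")
        usable = restrict_to_analyzable(pairs, table, "x")
        est = spearman_with_ci(pair_values(usable, table, "x", seed=0))
        assert est.rho >= 0.99

    def test_b_equals_m_over_I_identity(self, default_world):
        table = default_world.analysis_table()
        report = check_rate_consistency(table, rel_tol=1e-9)
        assert len(report) > 0
        assert report.flagged == []

    def test_every_network_endpoint_has_parameters(self, default_world):
        genes = set(default_world.params.genes)
        assert default_world.binary.proteins <= genes
        assert default_world.complexes.proteins <= genes
        assert default_world.operons.proteins <= genes


class TestConfigValidation:
    def test_rho_ordering_enforced(self):
        with pytest.raises(ValueError, match="rho"):
            simulate_world(WorldConfig(rho_complex=0.3, rho_binary=0.5))

    def test_latent_blend_budget_enforced(self):
        with pytest.raises(ValueError, match="exceed 1"):
            simulate_world(WorldConfig(rho_complex=0.9, rho_binary=0.3))

    def test_infeasible_binary_edges(self):
        cfg = WorldConfig(n_complexes=2, complex_size_min=2, complex_size_max=2,
                          n_binary_edges=10, n_operons=0,
                          n_party_hubs=0, n_date_hubs=0)
        with pytest.raises(ValueError, match="binary"):
            simulate_world(cfg)

    def test_planted_must_be_base_parameter(self):
        with pytest.raises(ValueError, match="base parameters"):
            simulate_world(WorldConfig(planted_parameters=("R",)))
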