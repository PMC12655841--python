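"""Descriptor engineering: σ-potential binning, fusion thermodynamics,
mixture weighting, relative descriptors and feature-set assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dooit.descriptors import (BIN_NAMES, SET1_COLUMNS, SET2_COLUMNS,
                               DescriptorError, DescriptorTable,
                               EnergeticDescriptors, FusionData, MixtureSpec,
                               SigmaPotential, SolubilityRecord,
                               assemble_feature_sets, bin_sigma_potential,
                               gibbs_fusion, mixture_descriptor,
                               relative_descriptor)
from dooit.synthetic import generate_sigma_curves

GRID = np.linspace(-0.03, 0.03, 61)


def curve(mu, species="s"):
    return SigmaPotential(species_id=species, sigma_grid=GRID.copy(),
                          mu_values=np.asarray(mu, float))


def brute_force_bins(sigma_grid, mu_values, edge_tol=1e-9):
    """Independent per-bin averaging by explicit membership loop.

    Convention: bins are half-open [lo, lo+0.005) with the last closed at
    +0.03; a grid point within ``edge_tol`` of an edge belongs to the
    upper bin (float grids place edge points a few ulp off the edge).
    """
    means = []
    for b in range(12):
        lo = -0.03 + 0.005 * b
        hi = lo + 0.005
        members = [m for s, m in zip(sigma_grid, mu_values)
                   if (lo - edge_tol <= s < hi - edge_tol)
                   or (b == 11 and s >= lo - edge_tol)]
        means.append(float(np.mean(members)))
    return np.array(means)


class TestSigmaBinning:
    def test_constant_curve_gives_constant_bins(self):
        out = bin_sigma_potential(curve(np.full(61, 5.0)))
        assert out.values.shape == (12,)
        assert np.allclose(out.values, 5.0, atol=0)

    def test_any_valid_curve_gives_twelve_values(self):
        for c in generate_sigma_curves(5, seed=3):
            out = bin_sigma_potential(c)
            assert len(out.values) == 12
            assert list(out.as_dict()) == list(BIN_NAMES)

    def test_identity_curve_matches_brute_force(self):
        out = bin_sigma_potential(curve(GRID))
        expected = brute_force_bins(GRID, GRID)
        assert np.allclose(out.values, expected, atol=1e-12, rtol=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_curves_match_brute_force(self, seed):
        mu = np.random.default_rng(seed).normal(size=61)
        out = bin_sigma_potential(curve(mu))
        assert np.allclose(out.values, brute_force_bins(GRID, mu),
                           atol=1e-12, rtol=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_occupancy_weighted_bin_means_conserve_curve_mean(self, seed):
        mu = np.random.default_rng(seed).normal(size=61)
        out = bin_sigma_potential(curve(mu))
        occupancy = np.array([5] * 11 + [6])  # uniform grid, closed last bin
        weighted = float(np.dot(out.values, occupancy) / occupancy.sum())
        assert weighted == pytest.approx(float(mu.mean()), abs=1e-12)

    def test_wrong_grid_rejected_naming_species(self):
        with pytest.raises(DescriptorError, match="badspecies"):
            SigmaPotential("badspecies", GRID[:-1], np.zeros(60))
        with pytest.raises(DescriptorError, match="span"):
            SigmaPotential("offrange", GRID + 0.001, np.zeros(61))
        decreasing = GRID.copy()
        decreasing[5], decreasing[6] = decreasing[6], decreasing[5]
        with pytest.raises(DescriptorError, match="increasing"):
            SigmaPotential("disordered", decreasing, np.zeros(61))


class TestGibbsFusion:
    def test_zero_at_melting_point(self):
        fd = FusionData("mef", T_m=400.0, dH_fus=30.0)
        assert gibbs_fusion(fd, 400.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        fd = FusionData("mef", T_m=400.0, dH_fus=30.0)
        assert gibbs_fusion(fd, 298.15) == pytest.approx(7.63875, abs=1e-9)

    def test_equals_enthalpy_minus_t_times_entropy(self):
        fd = FusionData("nif", T_m=476.0, dH_fus=27.3)
        for T in (273.15, 298.15, 350.0):
            assert gibbs_fusion(fd, T) == pytest.approx(
                fd.dH_fus - T * fd.dS_fus, abs=1e-12)

    def test_domain_errors(self):
        fd = FusionData("x", T_m=400.0, dH_fus=30.0)
        with pytest.raises(DescriptorError):
            gibbs_fusion(fd, 0.0)
        with pytest.raises(DescriptorError):
            FusionData("x", T_m=-1.0, dH_fus=30.0)
        with pytest.raises(DescriptorError):
            FusionData("x", T_m=400.0, dH_fus=0.0)


class TestMixtureDescriptor:
    def test_single_component_identity(self):
        mix = MixtureSpec((("a", 1.0),))
        assert mixture_descriptor({"a": 7.5}, mix) == 7.5

    def test_hand_computed_weighted_mean(self):
        mix = MixtureSpec((("a", 1 / 3), ("b", 2 / 3)))
        assert mixture_descriptor({"a": 3.0, "b": 6.0}, mix) == \
            pytest.approx(5.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-10, 10, allow_nan=False), st.integers(0, 2**31 - 1))
    def test_linearity_under_scaling(self, a, seed):
        rng = np.random.default_rng(seed)
        fracs = rng.dirichlet(np.ones(3))
        fracs = fracs / fracs.sum()
        mix = MixtureSpec(tuple((f"c{i}", float(x))
                                for i, x in enumerate(fracs)))
        vals = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=3))}
        scaled = {k: a * v for k, v in vals.items()}
        assert mixture_descriptor(scaled, mix) == pytest.approx(
            a * mixture_descriptor(vals, mix), abs=1e-9)

    def test_missing_component_and_bad_fractions(self):
        mix = MixtureSpec((("a", 0.5), ("b", 0.5)))
        with pytest.raises(DescriptorError, match="b"):
            mixture_descriptor({"a": 1.0}, mix)
        with pytest.raises(DescriptorError, match="sum"):
            MixtureSpec((("a", 0.5), ("b", 0.6)))
        with pytest.raises(DescriptorError, match="positive"):
            MixtureSpec((("a", -0.2), ("b", 1.2)))


class TestRelativeDescriptor:
    def test_self_difference_is_zero(self):
        for v in (-3.2, 0.0, 11.0):
            assert relative_descriptor(v, v) == 0.0

    def test_signed_arithmetic(self):
        assert relative_descriptor(-10.0, -4.0) == -6.0

    def test_non_finite_rejected(self):
        with pytest.raises(DescriptorError):
            relative_descriptor(float("nan"), 1.0)


def _species_inputs(seed=0):
    rng = np.random.default_rng(seed)
    species = ["solute_a", "solute_b", "hba", "hbd", "water"]
    energetics = {
        s: EnergeticDescriptors(s, *[float(v) for v in rng.normal(size=5)])
        for s in species
    }
    curves = generate_sigma_curves(len(species), seed=seed)
    sigma = {s: SigmaPotential(s, c.sigma_grid, c.mu_values)
             for s, c in zip(species, curves)}
    return species, energetics, sigma


def _records():
    dry = MixtureSpec((("hba", 0.5), ("hbd", 0.5)))
    wet = MixtureSpec((("hba", 0.4), ("hbd", 0.4), ("water", 0.2)))
    return [
        SolubilityRecord("solute_a", dry, 298.15, -2.1, -1.9),
        SolubilityRecord("solute_a", wet, 298.15, -2.6, -2.2),
        SolubilityRecord("solute_b", dry, 310.15, -3.4, -3.0),
    ]


class TestAssembleFeatureSets:
    def test_set_sizes_sixteen_and_twentyeight(self):
        _, energetics, sigma = _species_inputs()
        table = assemble_feature_sets(_records(), energetics, sigma)
        assert len(table.set1_columns) == 16
        assert len(table.set2_columns) == 28
        assert set(table.set1_columns) <= set(table.set2_columns)
        assert len(table.frame) == 3

    def test_identical_solute_and_des_gives_zero_deltas(self):
        rng = np.random.default_rng(1)
        vals = [float(v) for v in rng.normal(size=5)]
        shared_curve = generate_sigma_curves(1, seed=9)[0]
        energetics = {s: EnergeticDescriptors(s, *vals)
                      for s in ("sol", "hba", "hbd")}
        sigma = {s: SigmaPotential(s, shared_curve.sigma_grid,
                                   shared_curve.mu_values)
                 for s in ("sol", "hba", "hbd")}
        rec = SolubilityRecord(
            "sol", MixtureSpec((("hba", 0.5), ("hbd", 0.5))),
            298.15, -1.0, -1.0)
        table = assemble_feature_sets([rec], energetics, sigma)
        delta_cols = [c for c in table.frame.columns if c.startswith("Δ")]
        assert len(delta_cols) == 17  # 5 energetic + 12 sigma
        assert np.allclose(table.frame[delta_cols].to_numpy(), 0.0, atol=1e-12)

    def test_deterministic_assembly(self):
        _, energetics, sigma = _species_inputs()
        t1 = assemble_feature_sets(_records(), energetics, sigma)
        t2 = assemble_feature_sets(_records(), energetics, sigma)
        assert list(t1.frame.columns) == list(t2.frame.columns)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_columns_match_brute_force_recomputation(self):
        _, energetics, sigma = _species_inputs()
        rec = _records()[1]  # water-diluted system
        table = assemble_feature_sets([rec], energetics, sigma)
        row = table.frame.iloc[0]
        comps = rec.mixture.components
        # independent recomputation of one energetic triple
        e_api = energetics[rec.solute_id].E_vdW
        e_des = sum(x * energetics[s].E_vdW for s, x in comps)
        assert row["E_vdW_API"] == pytest.approx(e_api, abs=1e-12)
        assert row["E_vdW_DES"] == pytest.approx(e_des, abs=1e-12)
        assert row["ΔE_vdW"] == pytest.approx(e_api - e_des, abs=1e-12)
        # and of one sigma bin
        def bins(s):
            return brute_force_bins(sigma[s].sigma_grid, sigma[s].mu_values)
        hba1_api = bins(rec.solute_id)[8]
        hba1_des = sum(x * bins(s)[8] for s, x in comps)
        assert row["ΔHBA1"] == pytest.approx(hba1_api - hba1_des, abs=1e-12)

    def test_missing_species_reported(self):
        _, energetics, sigma = _species_inputs()
        del energetics["solute_b"]
        with pytest.raises(DescriptorError, match="record 2"):
            assemble_feature_sets(_records(), energetics, sigma)

    def test_winning_model_descriptor_names_exist(self):
        # the published 8-descriptor model draws only on these columns
        _, energetics, sigma = _species_inputs()
        table = assemble_feature_sets(_records(), energetics, sigma)
        for name in ("E_vdW_API", "ΔHBA1", "log_x_cosmo", "mu_API",
                     "ΔHH1", "ΔHH4", "E_HB_API", "ΔHH2"):
            assert name in table.set2_columns

    def test_invalid_record_invariants(self):
        mix = MixtureSpec((("hba", 1.0),))
        with pytest.raises(DescriptorError, match="log_x"):
            SolubilityRecord("s", mix, 298.15, 0.5, -1.0)
        with pytest.raises(DescriptorError, match="temperature"):
            SolubilityRecord("s", mix, -5.0, -1.0, -1.0)

    def test_descriptor_table_rejects_missing_values(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "log_x": [-1.0, -2.0]})
        with pytest.raises(DescriptorError, match="missing"):
            DescriptorTable(frame=frame, set_tags={"a": "set1"})
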