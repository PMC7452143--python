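"""Molecular-mechanics terms, generalized Born, MMGBSA bookkeeping and
experimental affinity conversions."""

import numpy as np
import pandas as pd
import pytest

from tcrlens.datasets import affinity_record
from tcrlens.energetics import (
    AffinityRecord,
    EnergeticsConfig,
    EnergeticsError,
    ForceFieldParameters,
    PerResidueEnergyTable,
    classify_ddg,
    ddg_exp,
    decompose_per_residue,
    effective_born_radii,
    fold_change,
    gb_polar_energy,
    kd_to_dg,
    mm_interaction_energy,
    mmgbsa_binding,
    rank_correlation,
)
from tcrlens.synthetic import make_toy_binding_system


def two_atom_arrays(q1, q2, r, rmin_half=1.9, eps=0.1):
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return (coords, np.array([q1, q2]), np.full(2, rmin_half),
            np.full(2, eps))


class TestMMInteraction:
    def test_coulomb_closed_form(self):
        coords, q, rh, eps = two_atom_arrays(1.0, 1.0, 3.320637)
        _, e_elec = mm_interaction_energy(
            coords, q, rh, eps, np.array([0]), np.array([1]))
        assert e_elec == pytest.approx(100.0, abs=1e-4)

    def test_lj_minimum_is_minus_combined_epsilon(self):
        eps_i, eps_j = 0.12, 0.30
        coords = np.array([[0.0, 0.0, 0.0], [1.7 + 2.1, 0.0, 0.0]])
        e_vdw, _ = mm_interaction_energy(
            coords, np.zeros(2), np.array([1.7, 2.1]),
            np.array([eps_i, eps_j]), np.array([0]), np.array([1]))
        assert e_vdw == pytest.approx(-np.sqrt(eps_i * eps_j), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        n = 50
        coords = rng.uniform(0, 15, (n, 3))
        q = rng.uniform(-0.5, 0.5, n)
        rh = rng.uniform(1.5, 2.0, n)
        eps = rng.uniform(0.05, 0.2, n)
        ia, ib = np.arange(25), np.arange(25, 50)
        e_vdw, e_elec = mm_interaction_energy(coords, q, rh, eps, ia, ib)
        ref_v = ref_e = 0.0
        k = EnergeticsConfig().coulomb_constant
        for i in ia:
            for j in ib:
                r = np.linalg.norm(coords[i] - coords[j])
                ref_e += k * q[i] * q[j] / r
                rm, ep = rh[i] + rh[j], np.sqrt(eps[i] * eps[j])
                ref_v += ep * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert e_elec == pytest.approx(ref_e, abs=1e-8)
        assert e_vdw == pytest.approx(ref_v, abs=1e-8)

    def test_overlapping_atoms_rejected(self):
        coords, q, rh, eps = two_atom_arrays(0.0, 0.0, 0.05)
        with pytest.raises(EnergeticsError):
            mm_interaction_energy(coords, q, rh, eps,
                                  np.array([0]), np.array([1]))


def scalar_gb_oracle(coords, q, born, screen, cfg):
    """Straight scalar re-implementation of the OBC-II GB formulas."""
    n = len(coords)
    rho = born - cfg.born_offset
    sr = screen * rho
    reff = np.empty(n)
    for i in range(n):
        I = 0.0
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r + sr[j] <= rho[i]:
                continue
            U = r + sr[j]
            L = max(rho[i], abs(r - sr[j]))
            term = 0.5 * (1 / L - 1 / U
                          + 0.25 * (r - sr[j] ** 2 / r) * (1 / U**2 - 1 / L**2)
                          + 0.5 * np.log(L / U) / r)
            if sr[j] - r > rho[i]:
                term += 2 * (1 / rho[i] - 1 / L)
            I += term
        psi = rho[i] * I
        reff[i] = 1.0 / (1 / rho[i] - np.tanh(
            cfg.obc_alpha * psi - cfg.obc_beta * psi**2
            + cfg.obc_gamma * psi**3) / born[i])
    E = 0.0
    for i in range(n):
        for j in range(n):
            r2 = float(np.sum((coords[i] - coords[j]) ** 2))
            f = np.sqrt(r2 + reff[i] * reff[j]
                        * np.exp(-r2 / (4 * reff[i] * reff[j])))
            D = 1 / cfg.eps_in - np.exp(-cfg.kappa * f) / cfg.eps_out
            E += -0.5 * cfg.coulomb_constant * D * q[i] * q[j] / f
    return reff, E


class TestGeneralizedBorn:
    def test_born_ion_closed_form(self):
        cfg = EnergeticsConfig(salt_molar=0.0)
        coords = np.zeros((1, 3))
        # intrinsic radius chosen so the effective radius is exactly 2.0 A
        e = gb_polar_energy(coords, np.array([1.0]),
                            np.array([2.0 + cfg.born_offset]),
                            np.array([0.8]), cfg)
        closed = -0.5 * cfg.coulomb_constant * (1 - 1 / cfg.eps_out) / 2.0
        assert e == pytest.approx(closed, abs=1e-6)

    def test_zero_charge_means_zero_energy(self):
        s, ann, params = make_toy_binding_system(10, seed=1)
        e = gb_polar_energy(s.coords, np.zeros(s.n_atoms),
                            np.full(s.n_atoms, 1.7), np.full(s.n_atoms, 0.8))
        assert e == 0.0

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_scalar_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        coords = rng.uniform(0, 6, (n, 3))
        q = rng.uniform(-1, 1, n)
        born = rng.uniform(1.4, 2.2, n)
        screen = rng.uniform(0.7, 0.9, n)
        cfg = EnergeticsConfig()
        reff_ref, e_ref = scalar_gb_oracle(coords, q, born, screen, cfg)
        reff = effective_born_radii(coords, born, screen, cfg)
        e = gb_polar_energy(coords, q, born, screen, cfg)
        np.testing.assert_allclose(reff, reff_ref, atol=1e-10)
        assert e == pytest.approx(e_ref, abs=1e-8)

    def test_salt_deepens_polar_solvation_monotonically(self):
        coords, q, _, _ = two_atom_arrays(1.0, -0.5, 4.0)
        born = np.full(2, 1.8)
        screen = np.full(2, 0.8)
        energies = [
            gb_polar_energy(coords, q, born, screen,
                            EnergeticsConfig(salt_molar=m))
            for m in (0.0, 0.05, 0.15, 0.50)
        ]
        assert all(b < a for a, b in zip(energies, energies[1:]))

    def test_no_salt_limit_is_continuous(self):
        coords, q, _, _ = two_atom_arrays(1.0, -0.5, 4.0)
        born = np.full(2, 1.8)
        screen = np.full(2, 0.8)
        e0 = gb_polar_energy(coords, q, born, screen,
                             EnergeticsConfig(salt_molar=0.0))
        e_eps = gb_polar_energy(coords, q, born, screen,
                                EnergeticsConfig(salt_molar=1e-12))
        assert e_eps == pytest.approx(e0, abs=1e-6)


class TestMmgbsa:
    def test_identical_snapshots_have_zero_spread(self):
        s, ann, params = make_toy_binding_system(10, seed=2)
        cfg = EnergeticsConfig(sasa_points=120)
        est = mmgbsa_binding([s.coords, s.coords.copy()], params, ann, s, cfg)
        assert est.sd == 0.0
        single = mmgbsa_binding([s.coords], params, ann, s, cfg)
        assert est.dg_bind == pytest.approx(single.dg_bind, abs=1e-12)

    def test_rigid_translation_leaves_binding_energy_unchanged(self):
        s, ann, params = make_toy_binding_system(10, seed=3)
        cfg = EnergeticsConfig(sasa_points=120)
        a = mmgbsa_binding([s.coords], params, ann, s, cfg).dg_bind
        b = mmgbsa_binding([s.coords + np.array([30.0, -12.0, 5.0])],
                           params, ann, s, cfg).dg_bind
        assert b == pytest.approx(a, abs=1e-9)

    def test_two_atom_dimer_matches_hand_computation(self):
        """End-to-end single-snapshot check on a 1+1 atom host-guest pair."""
        from tcrlens.structure import ComplexAnnotation
        from tcrlens.synthetic import _Builder

        b = _Builder()
        b.add("CA", "C", "ALA", "C", 1, (0.0, 0.0, 0.0))
        b.add("CA", "C", "ALA", "D", 1, (4.0, 0.0, 0.0))
        s = b.build()
        ann = ComplexAnnotation(role_map={"C": "peptide", "D": "TCR_alpha"})
        table = pd.DataFrame({
            "chain": ["C", "D"], "resnum": [1, 1], "atom": ["CA", "CA"],
            "charge": [0.4, -0.6], "rmin_half": [1.9, 1.9],
            "epsilon": [0.1, 0.1], "born_radius": [1.7, 1.7],
            "screen": [0.8, 0.8],
        })
        params = ForceFieldParameters(table=table)
        cfg = EnergeticsConfig(gamma_np=0.0, sasa_points=240)
        est = mmgbsa_binding([s.coords], params, ann, s, cfg)

        r = 4.0
        e_elec = cfg.coulomb_constant * 0.4 * -0.6 / r
        rm = 3.8
        e_vdw = 0.1 * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        _, gb_complex = scalar_gb_oracle(
            s.coords, np.array([0.4, -0.6]), np.full(2, 1.7),
            np.full(2, 0.8), cfg)
        rho = 1.7 - cfg.born_offset
        gb_single = 0.0
        for q in (0.4, -0.6):
            f = rho
            D = 1 / cfg.eps_in - np.exp(-cfg.kappa * f) / cfg.eps_out
            gb_single += -0.5 * cfg.coulomb_constant * D * q * q / f
        expected = e_elec + e_vdw + (gb_complex - gb_single)
        assert est.dg_bind == pytest.approx(expected, abs=1e-8)


class TestDecomposition:
    @pytest.mark.parametrize("seed", range(4))
    def test_residue_contributions_sum_to_total(self, seed):
        s, ann, params = make_toy_binding_system(14, seed=seed)
        cfg = EnergeticsConfig(sasa_points=120)
        dec = decompose_per_residue([s.coords], params, ann, s, cfg)
        assert dec.table["total"].sum() == pytest.approx(dec.dg_bind, abs=1e-6)

    def test_only_charged_pair_carries_electrostatics(self):
        s, ann, params = make_toy_binding_system(10, seed=5)
        table = params.table.copy()
        table["charge"] = 0.0
        # one charged atom per side
        table.loc[0, "charge"] = 0.5    # chain C, residue 1
        table.loc[10, "charge"] = -0.5  # chain D, residue 1
        params = ForceFieldParameters(table=table)
        cfg = EnergeticsConfig(gamma_np=0.0, sasa_points=120)
        dec = decompose_per_residue([s.coords], params, ann, s, cfg)
        t = dec.table
        charged = t[(t["resnum"] == 1)]
        uncharged = t[(t["resnum"] != 1)]
        assert np.abs(uncharged["elec"]).max() == 0.0
        assert np.abs(charged["elec"]).sum() > 0.0

    def test_residue_order_does_not_change_content(self):
        s, ann, params = make_toy_binding_system(12, seed=6)
        cfg = EnergeticsConfig(sasa_points=120)
        dec1 = decompose_per_residue([s.coords], params, ann, s, cfg)
        perm = np.random.default_rng(0).permutation(s.n_atoms)
        s2 = s.subset(perm)
        dec2 = decompose_per_residue([s2.coords], params, ann, s2, cfg)
        key = ["chain", "resnum"]
        merged = dec1.table.set_index(key).join(
            dec2.table.set_index(key), lsuffix="_1", rsuffix="_2")
        np.testing.assert_allclose(
            merged["total_1"], merged["total_2"], atol=1e-9)


def _energy_table(values, chain="D"):
    rows = [{"chain": chain, "resnum": i + 1, "resname": "ALA",
             "role": "TCR_alpha", "vdw": 0.0, "elec": 0.0, "gb": 0.0,
             "np": 0.0, "total": v} for i, v in enumerate(values)]
    return PerResidueEnergyTable(table=pd.DataFrame(rows),
                                 dg_bind=float(np.sum(values)))


class TestClassification:
    def test_threshold_bands(self):
        wt = _energy_table([0.0, 0.0, 0.0])
        var = _energy_table([-1.0, 0.2, 0.7])
        cls = classify_ddg(wt, var, threshold=0.5)
        assert list(cls.table["label"]) == ["favorable", "neutral", "unfavorable"]

    def test_identical_tables_are_all_neutral(self):
        t = _energy_table([0.3, -0.2, 1.1])
        cls = classify_ddg(t, t)
        assert (cls.table["label"] == "neutral").all()
        assert (cls.table["ddg"] == 0).all()

    def test_zero_threshold_removes_neutral_band(self):
        wt = _energy_table([0.0, 0.0])
        var = _energy_table([0.01, -0.01])
        cls = classify_ddg(wt, var, threshold=0.0)
        assert "neutral" not in set(cls.table["label"])

    def test_mutation_sites_flagged(self):
        wt = _energy_table([0.0])
        var = _energy_table([0.0])
        var.table.loc[0, "resname"] = "TRP"
        cls = classify_ddg(wt, var)
        assert bool(cls.table.loc[0, "mutated"])


class TestExperimentalAffinities:
    def test_mel5_pair_fold_change_is_about_thirty_thousand(self):
        wt = affinity_record("MEL5_wt_ELA")
        var = affinity_record("MEL5_a24b17_ELA")
        fold = fold_change(wt, var)
        assert fold == pytest.approx(18000 / 0.61, rel=1e-12)
        assert 2.9e4 < fold < 3.1e4

    def test_mel5_pair_experimental_ddg(self):
        wt = affinity_record("MEL5_wt_ELA")
        var = affinity_record("MEL5_a24b17_ELA")
        assert ddg_exp(wt, var) == pytest.approx(-6.10, abs=0.01)

    def test_equal_affinities_give_zero_ddg_and_unit_fold(self):
        a = AffinityRecord(label="x", kd_nM=100.0)
        b = AffinityRecord(label="y", kd_nM=100.0)
        assert ddg_exp(a, b) == 0.0
        assert fold_change(a, b) == 1.0

    def test_dg_from_kd_sign_and_magnitude(self):
        # micromolar binder: dG = RT ln(1e-6) ~ -8.18 kcal/mol at 298.15 K
        rec = AffinityRecord(label="um", kd_nM=1000.0)
        assert kd_to_dg(rec) == pytest.approx(0.59247 * np.log(1e-6), abs=1e-3)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(EnergeticsError):
            AffinityRecord(label="bad", kd_nM=0.0)

    def test_kinetic_consistency_reported_not_enforced(self):
        rec = AffinityRecord(label="r", kd_nM=4.0, on_rate=45000.0,
                             off_rate=0.00018)
        assert rec.kinetic_consistency() is True
        rec2 = AffinityRecord(label="r2", kd_nM=4.0, on_rate=45000.0,
                              off_rate=0.9)
        assert rec2.kinetic_consistency() is False


class TestRankCorrelation:
    def test_identical_lists_agree_perfectly(self):
        res = rank_correlation([-3, -2, -1.5], [-3, -2, -1.5])
        assert res["sign_agreement"] == 1.0
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_one_sign_flip_in_four(self):
        res = rank_correlation([-3, -2, 1.0, -4], [-3, -2, -1.0, -4])
        assert res["n_sign_agree"] == 3 and res["n"] == 4

    def test_matches_closed_form_spearman_on_tie_free_lists(self):
        rng = np.random.default_rng(2)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        res = rank_correlation(x, y)
        dx = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        rho = 1 - 6 * np.sum(dx**2) / (10 * (100 - 1))
        assert res["spearman_rho"] == pytest.approx(rho, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EnergeticsError):
            rank_correlation([1.0], [1.0, 2.0])
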