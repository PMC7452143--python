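"""Replica-ensemble statistics: alignment, RMSF, occupancies, averages."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrlens.contacts import find_contacts, per_residue_contact_map
from tcrlens.ensemble import (
    EnsembleError,
    TrajectoryEnsemble,
    align_frames,
    average_bsasa,
    average_contacts,
    compare_rmsf,
    compute_rmsf,
    hb_occupancy,
)
from tcrlens.synthetic import (
    EnsembleSpec,
    HBondEvent,
    PlantedContact,
    ToyComplexSpec,
    make_ensemble,
    make_toy_complex,
)
from conftest import single_chain_trace

SQRT3 = np.sqrt(3.0)


class TestAlignment:
    def test_rigid_copies_collapse_to_one_conformation(self, chain120):
        rng = np.random.default_rng(1)
        frames = []
        for k in range(8):
            R = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
            frames.append(chain120.coords @ R.T + rng.uniform(-20, 20, 3))
        e = TrajectoryEnsemble(chain120, [np.array(frames)], burn_in_fraction=0.0)
        aligned = align_frames(e)
        spread = aligned.replicas[0].std(axis=0).max()
        assert spread < 1e-8

    def test_alignment_is_idempotent(self, chain120):
        e = make_ensemble(chain120, EnsembleSpec(replicas=2, frames=20,
                                                 sigma_profile=0.3, seed=3))
        once = align_frames(e)
        twice = align_frames(once)
        for r1, r2 in zip(once.replicas, twice.replicas):
            assert np.abs(r1 - r2).max() < 1e-6

    def test_empty_selection_rejected(self, chain120):
        e = make_ensemble(chain120, EnsembleSpec(replicas=2, frames=5, seed=0))
        with pytest.raises(EnsembleError):
            align_frames(e, selection=[("Z", 1)])


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, chain120):
        frames = np.repeat(chain120.coords[None], 5, axis=0)
        e = TrajectoryEnsemble(chain120, [frames], burn_in_fraction=0.0)
        r = compute_rmsf(e)
        assert r["rmsf"].max() < 1e-9

    def test_single_frame_replica_rejected(self, chain120):
        e = TrajectoryEnsemble(chain120, [chain120.coords[None]],
                               burn_in_fraction=0.0)
        with pytest.raises(EnsembleError):
            compute_rmsf(e)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self, chain120):
        sigma = 0.3
        e = make_ensemble(chain120, EnsembleSpec(
            replicas=4, frames=800, sigma_profile=sigma, seed=7))
        r = compute_rmsf(align_frames(e))
        assert r["rmsf"].mean() == pytest.approx(sigma * SQRT3, rel=0.05)

    def test_doubling_sigma_doubles_rmsf(self, chain120):
        r = {}
        for sigma in (0.25, 0.5):
            e = make_ensemble(chain120, EnsembleSpec(
                replicas=4, frames=600, sigma_profile=sigma, seed=11))
            r[sigma] = compute_rmsf(align_frames(e))["rmsf"].mean()
        assert r[0.5] / r[0.25] == pytest.approx(2.0, rel=0.05)

    def test_statistics_invariant_to_replica_order(self, chain120):
        e = make_ensemble(chain120, EnsembleSpec(replicas=4, frames=50,
                                                 sigma_profile=0.3, seed=2))
        e_rev = TrajectoryEnsemble(chain120, e.replicas[::-1],
                                   burn_in_fraction=e.burn_in_fraction)
        a = compute_rmsf(align_frames(e))
        b = compute_rmsf(align_frames(e_rev))
        import numpy as np
        np.testing.assert_allclose(
            sorted(a["rmsf"]), sorted(b["rmsf"]), atol=1e-9)


class TestCompareRmsf:
    def test_identical_ensembles_show_no_change(self, chain120):
        e = make_ensemble(chain120, EnsembleSpec(replicas=4, frames=100,
                                                 sigma_profile=0.3, seed=5))
        comp = compare_rmsf(e, e)
        assert (comp.table["delta_rmsf"] == 0).all()
        assert not comp.table["significant"].any()

    def test_planted_stiffness_change_is_detected(self, chain120):
        sig_wt = np.full(120, 0.3)
        sig_var = sig_wt.copy()
        sig_var[94:100] = 0.6        # residues 95-100
        e_wt = make_ensemble(chain120, EnsembleSpec(
            replicas=10, frames=300, sigma_profile=sig_wt, seed=21))
        e_var = make_ensemble(chain120, EnsembleSpec(
            replicas=10, frames=300, sigma_profile=sig_var, seed=22))
        comp = compare_rmsf(e_wt, e_var)
        flagged = set(comp.significant_residues)
        planted = {("D", r) for r in range(95, 101)}
        assert planted <= flagged
        # false positives occur at roughly the test level, far below power
        assert len(flagged - planted) <= 15

    def test_welch_and_pooled_agree_on_planted_effects(self, chain120):
        sig_wt = np.full(120, 0.3)
        sig_var = sig_wt.copy()
        sig_var[94:100] = 0.6
        e_wt = make_ensemble(chain120, EnsembleSpec(
            replicas=8, frames=200, sigma_profile=sig_wt, seed=31))
        e_var = make_ensemble(chain120, EnsembleSpec(
            replicas=8, frames=200, sigma_profile=sig_var, seed=32))
        planted = {("D", r) for r in range(95, 101)}
        for welch in (True, False):
            comp = compare_rmsf(e_wt, e_var, welch=welch)
            assert planted <= set(comp.significant_residues)

    def test_too_few_replicas_rejected(self, chain120):
        e1 = make_ensemble(chain120, EnsembleSpec(replicas=1, frames=10, seed=0))
        e4 = make_ensemble(chain120, EnsembleSpec(replicas=4, frames=10, seed=0))
        with pytest.raises(EnsembleError):
            compare_rmsf(e1, e4)


@pytest.fixture(scope="module")
def contact_toy():
    return make_toy_complex(ToyComplexSpec(
        seed=13,
        planted_contacts=[PlantedContact(kind="hb", distance=2.9,
                                         target="peptide", target_index=2)],
    ))


class TestAverageContacts:
    def test_static_ensemble_equals_static_map(self, contact_toy):
        s, a = contact_toy
        frames = np.repeat(s.coords[None], 3, axis=0)
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        avg = average_contacts(e, a)
        static = per_residue_contact_map(find_contacts(s, a))
        assert len(avg) == len(static) == 1
        assert avg.iloc[0]["mean_vdw"] == static.iloc[0]["n_vdw"]

    def test_intermittent_contact_averages_to_half(self, contact_toy):
        s, a = contact_toy
        broken = s.coords.copy()
        probe = (s.chain_id == "D") & (s.resnum == 150)
        broken[probe] += np.array([0.0, 0.0, 30.0])
        frames = np.stack([s.coords, broken])
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        avg = average_contacts(e, a)
        assert avg.iloc[0]["mean_vdw"] == pytest.approx(0.5)


class TestHbOccupancy:
    def test_constant_bond_has_unit_occupancy(self, contact_toy):
        s, a = contact_toy
        frames = np.repeat(s.coords[None], 4, axis=0)
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        occ = hb_occupancy(e, [(("D", 150, "N"), ("C", 3, "O"))])
        assert (occ.table["occupancy"] == 1.0).all()

    def test_alternating_bond_has_half_occupancy(self, contact_toy):
        s, a = contact_toy
        broken = s.coords.copy()
        probe = (s.chain_id == "D") & (s.resnum == 150)
        broken[probe] += np.array([0.0, 0.0, 2.0])
        frames = np.stack([s.coords, broken, s.coords, broken])
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        occ = hb_occupancy(e, [(("D", 150, "N"), ("C", 3, "O"))])
        assert occ.pooled()["occupancy"].iloc[0] == pytest.approx(0.5)

    def test_two_state_fixture_recovers_planted_occupancy(self, chain120):
        ev = HBondEvent(donor=("D", 60, "CA"), acceptor=("D", 61, "CA"),
                        p_bound=0.7)
        e = make_ensemble(chain120, EnsembleSpec(
            replicas=5, frames=400, sigma_profile=0.1, hb_events=[ev], seed=8))
        occ = hb_occupancy(e, [(ev.donor, ev.acceptor)])
        pooled = occ.pooled()["occupancy"].iloc[0]
        assert pooled == pytest.approx(0.7, abs=0.03)

    def test_unknown_atom_rejected(self, chain120):
        e = make_ensemble(chain120, EnsembleSpec(replicas=2, frames=5, seed=0))
        with pytest.raises(KeyError):
            hb_occupancy(e, [(("D", 1, "XX"), ("D", 2, "CA"))])


class TestAverageBsasa:
    def test_static_ensemble_has_zero_spread(self, contact_toy):
        s, a = contact_toy
        frames = np.repeat(s.coords[None], 3, axis=0)
        e = TrajectoryEnsemble(s, [frames, frames.copy()], burn_in_fraction=0.0)
        res = average_bsasa(e, a, n_points=120)
        assert res["sd"] == 0.0

    def test_separated_ensemble_buries_nothing(self, contact_toy):
        s, a = contact_toy
        apart = s.coords.copy()
        apart[s.chain_mask(a.tcr_chains())] += np.array([0.0, 0.0, 200.0])
        frames = np.repeat(apart[None], 2, axis=0)
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        res = average_bsasa(e, a, n_points=120)
        assert abs(res["mean"]) < 10.0

    def test_mixture_of_two_conformations_averages_linearly(self, contact_toy):
        s, a = contact_toy
        apart = s.coords.copy()
        apart[s.chain_mask(a.tcr_chains())] += np.array([0.0, 0.0, 200.0])
        from tcrlens.surface import compute_bsasa
        b_bound = compute_bsasa(s, a, n_points=120)
        b_free = compute_bsasa(s, a, n_points=120, coords=apart)
        frames = np.stack([s.coords, apart])
        e = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        res = average_bsasa(e, a, n_points=120)
        assert res["mean"] == pytest.approx((b_bound + b_free) / 2, abs=1e-9)
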