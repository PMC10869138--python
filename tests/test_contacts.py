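"""Contact detection, occupancy statistics, Hamming distance and BSA."""

import numpy as np
import pytest

from tcrmech import contacts as C
from tcrmech import synthetic
from tcrmech.contacts import (ContactCriteria, ConfigurationError,
                              OccupancyThresholds, build_timelines,
                              count_high_occupancy, detect_contacts,
                              hamming_distance, heatmap_table,
                              rolling_occupancy, shrake_rupley_sasa,
                              windowed_total_occupancy)
from tcrmech.trajio import AnalysisWindows

from conftest import toy_structure, toy_trajectory


def brute_force_contacts(coords, structure, idx_a, idx_b, criteria):
    """Independent O(N^2) all-pairs oracle for residue-level contacts."""
    keys = set()
    for i in idx_a:
        for j in idx_b:
            res_i = structure.residue_key(i)
            res_j = structure.residue_key(j)
            if res_i == res_j:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if (structure.is_donor[i] and structure.is_acceptor[j]
                    or structure.is_acceptor[i] and structure.is_donor[j]):
                if d <= criteria.hbond_cutoff:
                    keys.add((res_i, res_j, "hbond"))
            if (structure.elements[i] != "H" and structure.elements[j] != "H"
                    and abs(structure.charges[i]) < criteria.charge_cutoff
                    and abs(structure.charges[j]) < criteria.charge_cutoff
                    and d <= criteria.nonpolar_cutoff):
                keys.add((res_i, res_j, "nonpolar"))
    return keys


class TestDetectContacts:
    def test_hbond_below_cutoff_detected(self):
        s = toy_structure([[0, 0, 0], [2.3, 0, 0]], names=["O", "N"],
                          elements=["O", "N"], charges=[-0.5, 0.4],
                          donor=[False, True], acceptor=[True, False])
        events = detect_contacts(s.coords, s, ([0], [1]))
        assert len(events) == 1 and next(iter(events)).kind == "hbond"

    def test_nonpolar_charge_criterion(self):
        # 2.9 Å apart: contact iff both |q| < 0.3e
        for q, expected in ((-0.05, 1), (0.4, 0)):
            s = toy_structure([[0, 0, 0], [2.9, 0, 0]],
                              elements=["C", "C"], charges=[0.1, q],
                              donor=[False] * 2, acceptor=[False] * 2)
            events = detect_contacts(s.coords, s, ([0], [1]),
                                     kinds=("nonpolar",))
            assert len(events) == expected

    def test_missing_charges_is_a_configuration_error(self):
        s = toy_structure([[0, 0, 0], [2.0, 0, 0]])
        s.is_donor = np.zeros(2, bool)
        s.is_acceptor = np.zeros(2, bool)
        with pytest.raises(ConfigurationError):
            detect_contacts(s.coords, s, ([0], [1]), kinds=("nonpolar",))

    def test_atom_pairs_collapse_to_residue_pairs(self):
        # two acceptor atoms of one residue against one donor -> one contact
        s = toy_structure([[0, 0, 0], [0.5, 0, 0], [2.0, 0, 0]],
                          names=["OD1", "OD2", "N"],
                          elements=["O", "O", "N"], charges=[0, 0, 0],
                          donor=[False, False, True],
                          acceptor=[True, True, False])
        s.res_index = np.array([1, 1, 2])
        events = detect_contacts(s.coords, s, ([0, 1], [2]),
                                 kinds=("hbond",))
        assert len(events) == 1

    def test_matches_brute_force_on_random_placements(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = 60
            coords = rng.uniform(0, 12, size=(n, 3))
            elements = rng.choice(["C", "N", "O", "H"], size=n)
            charges = rng.uniform(-0.6, 0.6, size=n)
            s = toy_structure(coords, elements=elements, charges=charges,
                              donor=elements == "N",
                              acceptor=elements == "O")
            idx_a, idx_b = np.arange(0, 30), np.arange(30, 60)
            crit = ContactCriteria()
            got = {e.key for e in detect_contacts(
                coords, s, (idx_a, idx_b), crit)}
            assert got == brute_force_contacts(
                coords, s, idx_a, idx_b, crit)

    def test_placed_pairs_inside_and_outside_cutoffs(self, template):
        # 10 pseudo-pairs on the template; switch 6 off geometrically
        cfg = synthetic.SyntheticConfig(
            seed=1, n_frames=1, noise_sigma=0.0,
            contacts=[synthetic.ContactSchedule(
                p, template.contact_pairs[p]["kind"], occupancy=0.0)
                for p in range(6)])
        traj, _ = synthetic.generate_trajectory(cfg, template)
        events = detect_contacts(traj.coords[0], template.structure,
                                 template.interface)
        assert len(events) == 4


class TestTimelines:
    def make_timeline(self, presence, dt=0.02):
        return C.ContactTimeline((("A", 1), ("D", 1), "hbond"),
                                 np.asarray(presence, bool), dt)

    def test_always_present_contact(self):
        tl = self.make_timeline(np.ones(100))
        assert tl.avg_occupancy() == 1.0
        assert np.all(tl.inst_occupancy == 1.0)

    def test_partial_occupancy_definition(self):
        presence = np.zeros(100, bool)
        presence[:60] = True
        assert self.make_timeline(presence).avg_occupancy() == \
            pytest.approx(0.60)

    def test_alternating_presence_rolls_to_half(self):
        tl = self.make_timeline(np.arange(200) % 2 == 0)
        # full 40-frame trailing windows contain exactly 20 present frames
        assert np.allclose(tl.inst_occupancy[39:], 0.5)

    def test_rolling_window_is_trailing_and_truncated(self):
        presence = np.zeros(50, bool)
        presence[0] = True
        occ = rolling_occupancy(presence, 40)
        assert occ[0] == 1.0                      # window of size 1
        assert occ[1] == pytest.approx(0.5)       # window of size 2
        assert occ[39] == pytest.approx(1 / 40)
        assert occ[40] == 0.0                     # frame 0 left the window

    def test_occupancy_conservation(self):
        # avg over an interval == mean of rolling occupancy with window = n
        rng = np.random.default_rng(3)
        presence = rng.random(500) < 0.3
        tl = self.make_timeline(presence)
        whole = rolling_occupancy(presence, len(presence))
        assert whole[-1] == pytest.approx(tl.avg_occupancy())

    def test_build_timelines_empty_trajectory_rejected(self, template):
        s = template.structure
        traj = toy_trajectory(np.zeros((0, s.n_atoms, 3)), s)
        with pytest.raises(ValueError):
            build_timelines(traj, template.interface)

    def test_scheduled_occupancy_recovered_exactly(self, template):
        cfg = synthetic.SyntheticConfig(
            seed=0, n_frames=250, noise_sigma=0.0,
            contacts=[
                synthetic.ContactSchedule(0, "hbond", occupancy=0.6),
                synthetic.ContactSchedule(1, "nonpolar", occupancy=0.17),
                synthetic.ContactSchedule(2, "hbond", occupancy=1.0),
            ])
        traj, truth = synthetic.generate_trajectory(cfg, template)
        timelines = {tl.key: tl for tl in build_timelines(
            traj, template.interface)}
        for key, expected in truth.contact_occupancy.items():
            assert timelines[key].avg_occupancy() == pytest.approx(
                expected, abs=1.0 / cfg.n_frames)


class TestCountsAndHeatmap:
    def tl(self, presence, dt=1.0):
        return C.ContactTimeline((("A", 1), ("D", 1), "hbond"),
                                 np.asarray(presence, bool), dt)

    def test_count_criteria_avg_and_inst(self):
        w = AnalysisWindows(equilibration_cut=0.0)
        high = self.tl(np.ones(100))
        assert count_high_occupancy([high], windows=w) == 1
        # avg 0.55 but instantaneous never reaches 0.8: alternating blocks
        presence = (np.arange(100) // 2) % 2 == 1
        presence[40:50] = True
        weak = self.tl(presence)
        assert weak.max_inst() < 0.8
        assert count_high_occupancy([weak], windows=w) == 0

    def test_count_matches_brute_force_on_random_schedules(self):
        rng = np.random.default_rng(7)
        w = AnalysisWindows(equilibration_cut=100.0)
        thr = OccupancyThresholds()
        tls = []
        for _ in range(20):
            presence = rng.random(400) < rng.uniform(0.2, 1.0)
            tls.append(self.tl(presence))
        expected = 0
        for tl in tls:
            post = tl.presence[100:]
            inst = rolling_occupancy(tl.presence, 40)[100:]
            if post.mean() > thr.count_avg and inst.max() >= \
                    thr.count_inst_max:
                expected += 1
        assert count_high_occupancy(tls, thr, w) == expected

    def test_heatmap_inclusion_rules(self):
        rng = np.random.default_rng(0)
        # avg 0.35 with bursts -> max inst high
        bursty = np.zeros(1000, bool)
        bursty[:350] = True
        included = self.tl(bursty)
        spread = self.tl(rng.random(1000) < 0.35)   # avg .35, inst ~.35
        assert spread.max_inst() <= 0.8
        table = heatmap_table([included, spread], bin_ns=100.0)
        assert len(table) == 1
        assert table.shape[1] == 10

    def test_all_below_threshold_gives_empty_table(self):
        table = heatmap_table([self.tl(np.zeros(100))])
        assert table.empty

    def test_two_phase_contact_bins(self):
        presence = np.zeros(1000, bool)
        presence[:500] = True
        table = heatmap_table([self.tl(presence)], bin_ns=250.0)
        row = table.iloc[0].to_numpy()
        assert np.allclose(row, [1.0, 1.0, 0.0, 0.0])


class TestHamming:
    def tl(self, presence, key_id, dt=1.0):
        return C.ContactTimeline((("A", key_id), ("D", key_id), "hbond"),
                                 np.asarray(presence, bool), dt)

    def test_persistent_baseline_keeps_H_zero(self):
        tls = [self.tl(np.ones(200), i) for i in range(5)]
        h = hamming_distance(tls, baseline_interval=50.0)
        assert len(h.baseline) == 5
        assert np.all(h.H == 0)

    def test_programmed_losses_counted(self, template):
        # 10 always-on baseline pairs; 3 switch off permanently at 3 ns
        cfg = synthetic.SyntheticConfig(
            seed=0, n_frames=500, noise_sigma=0.0,
            contacts=[synthetic.ContactSchedule(
                p, template.contact_pairs[p]["kind"], off_at=3.0)
                for p in range(3)])
        traj, truth = synthetic.generate_trajectory(cfg, template)
        tls = build_timelines(traj, template.interface)
        h = hamming_distance(tls, baseline_interval=1.0)
        assert len(h.baseline) == 10
        assert h.H[0] == 0
        assert h.H[-1] == 3
        t_loss = np.flatnonzero(h.H == 3)[0] * traj.dt_save
        assert t_loss >= 3.0

    def test_H_nondecreasing_under_permanent_rule(self):
        rng = np.random.default_rng(11)
        tls = []
        for i in range(8):
            presence = np.ones(300, bool)
            presence[rng.integers(60, 300):] = rng.random() < 0.5
            tls.append(self.tl(presence, i))
        h = hamming_distance(tls, baseline_interval=50.0,
                             loss_rule="permanent")
        assert np.all(np.diff(h.H) >= 0)
        assert h.H.max() <= len(h.baseline)

    def test_empty_baseline_warns_and_returns_zero(self):
        tls = [self.tl(np.random.default_rng(0).random(200) < 0.3, 0)]
        with pytest.warns(UserWarning):
            h = hamming_distance(tls, baseline_interval=50.0)
        assert h.baseline == [] and np.all(h.H == 0)


class TestWindowedTotals:
    def tl(self, presence, key_id, dt=1.0):
        return C.ContactTimeline((("A", key_id), ("D", key_id), "hbond"),
                                 np.asarray(presence, bool), dt)

    def test_constant_contacts_give_constant_total(self):
        tls = [self.tl(np.ones(300), i) for i in range(5)]
        table = windowed_total_occupancy(tls)
        assert np.allclose(table["total_occupancy"], 5.0)

    def test_window_boundaries(self):
        tls = [self.tl(np.ones(280), 0)]
        table = windowed_total_occupancy(tls)
        assert list(zip(table["start_ns"], table["end_ns"])) == [
            (200.0, 240.0), (220.0, 260.0), (240.0, 280.0)]

    def test_decaying_contact_matches_per_window_means(self):
        rng = np.random.default_rng(5)
        n = 300
        p_on = np.clip(1.0 - np.arange(n) / n, 0, 1)
        presence = rng.random(n) < p_on
        presence[:150] = True     # keep it selected (avg > 0.5, inst > 0.8)
        tls = [self.tl(presence, 0)]
        table = windowed_total_occupancy(tls)
        for _, row in table.iterrows():
            i0, i1 = int(row["start_ns"]), int(row["end_ns"])
            assert row["total_occupancy"] == pytest.approx(
                presence[i0:i1].mean())

    def test_short_trajectory_rejected(self):
        tls = [self.tl(np.ones(100), 0)]
        with pytest.raises(ValueError):
            windowed_total_occupancy(tls)


def analytic_two_sphere_sasa(r1, r2, d, probe):
    """Closed-form accessible areas of two intersecting solvent spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2
    # spherical cap heights from the plane of intersection
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    return (4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1,
            4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2)


class TestSasaAndBsa:
    def test_isolated_sphere_matches_closed_form(self):
        for r in (1.52, 1.7, 2.0):
            sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]))
            assert sasa[0] == pytest.approx(4 * np.pi * (r + 1.4) ** 2,
                                            rel=0.01)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r1, r2, d = 1.7, 1.52, 2.5
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        sasa = shrake_rupley_sasa(coords, np.array([r1, r2]))
        a1, a2 = analytic_two_sphere_sasa(r1, r2, d, 1.4)
        assert sasa[0] == pytest.approx(a1, rel=0.02)
        assert sasa[1] == pytest.approx(a2, rel=0.02)

    def test_bsa_of_sphere_against_itself_is_zero(self):
        s = toy_structure([[0.0, 0, 0]], elements=["C"])
        traj = toy_trajectory(np.zeros((2, 1, 3)), s, dt_save=1.0)
        result = C.compute_bsa(
            traj, s, side=np.array([0]), partner=np.array([], dtype=int),
            windows=AnalysisWindows(equilibration_cut=0.0,
                                    window_start=0.0))
        assert result.total_mean == pytest.approx(0.0, abs=1e-9)

    def test_distant_partner_buries_nothing_and_close_partner_buries(self):
        w = AnalysisWindows(equilibration_cut=0.0, window_start=0.0)
        for dx, buried in ((50.0, False), (3.0, True)):
            s = toy_structure([[0.0, 0, 0], [dx, 0, 0]],
                              elements=["C", "C"])
            traj = toy_trajectory(s.coords[None], s, dt_save=1.0)
            result = C.compute_bsa(traj, s, side=np.array([0]),
                                   partner=np.array([1]), windows=w)
            if buried:
                assert result.total_mean > 1.0
            else:
                assert result.total_mean == pytest.approx(0.0, abs=1e-9)

    def test_residues_below_occupancy_threshold_excluded(self, template):
        # contact 0 stays on; pair 2's partner never approaches
        cfg = synthetic.SyntheticConfig(
            seed=0, n_frames=60, noise_sigma=0.0,
            contacts=[synthetic.ContactSchedule(2, "hbond", occupancy=0.0)])
        traj, _ = synthetic.generate_trajectory(cfg, template)
        tls = build_timelines(traj, template.interface)
        partner, side = template.interface
        result = C.compute_bsa(
            traj, template.structure, side=side, partner=partner,
            timelines=tls,
            windows=AnalysisWindows(equilibration_cut=0.0, window_start=0.0),
            frame_stride=30)
        selected = set(result.residues)
        assert ("E", 53) not in selected        # pair 2 switched off
        assert ("D", 52) in selected            # pair 0 always on
        assert result.total_mean > 0
        assert result.per_residue_mean == pytest.approx(
            result.total_mean / len(result.residues))
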