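"""Exchange-event detection, selection and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trajectory, random_walk_z
from glutx import Trajectory
from glutx.exchange import (
    DetectorConfig,
    classify_exchange,
    detect_exchanges,
    exchange_series,
    hbond_contacts,
)
from oracles import oracle_detect

SPAN = (-25.0, 20.0)


def detect_z(zs, **cfg_kwargs):
    cfg = DetectorConfig(span=SPAN, **cfg_kwargs)
    return detect_exchanges(make_trajectory(zs), cfg, classify=False), cfg


class TestDetection:
    def test_constant_ordering_yields_no_events(self):
        zs = np.column_stack([np.full(100, 5.0), np.full(100, -5.0)])
        events, _ = detect_z(zs)
        assert events == []

    def test_symmetric_linear_crossing_yields_one_central_event(self):
        """Two ligands crossing linearly swap ordering once; the smallest
        window whose normalised gap change exceeds the threshold is kept
        and its mean Z is the crossing point."""
        f = np.arange(11)
        za = 10.0 - 2.0 * f  # +10 -> -10
        zb = -10.0 + 2.0 * f
        events, _ = detect_z(np.column_stack([za, zb]))
        assert len(events) == 1
        ev = events[0]
        assert (ev.frame_start, ev.frame_end) == (1, 6)
        assert ev.z_mean == pytest.approx(0.0, abs=1e-12)
        assert ev.time_mid == pytest.approx((1 + 6) / 2)

    def test_reversal_below_threshold_is_ignored(self):
        # ordering reverses but the normalised gap change stays tiny
        za = np.array([1.0, -1.0] * 10)
        zb = np.zeros(20)
        events, _ = detect_z(np.column_stack([za, zb]))
        assert events == []

    def test_events_outside_region_are_rejected(self):
        f = np.arange(11)
        za, zb = 10.0 - 2.0 * f, -10.0 + 2.0 * f
        events, _ = detect_z(
            np.column_stack([za, zb]) + 30.0,  # crossing at Z = +30
            region=(-15.0, 12.0),
        )
        # shifted out of both the region and the span-normalised window
        assert events == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_lig = int(rng.integers(2, 6))
        n_frames = int(rng.integers(20, 120))
        zs = random_walk_z(n_lig, n_frames, seed=seed + 1000)
        events, cfg = detect_z(zs)
        got = {(e.ligand_a, e.ligand_b, e.frame_start, e.frame_end) for e in events}
        want = oracle_detect(zs, [f"L{i}" for i in range(n_lig)],
                             cfg.z_norm_threshold, cfg.span, cfg.region)
        assert got == want

    @pytest.mark.parametrize("seed", range(70, 140))
    def test_matches_brute_force_oracle_dense(self, seed):
        # denser, shorter instances with ligands crowded into the region
        rng = np.random.default_rng(seed)
        zs = random_walk_z(4, int(rng.integers(15, 60)), seed=seed,
                           lo=-14.0, hi=11.0, step=6.0)
        events, cfg = detect_z(zs)
        got = {(e.ligand_a, e.ligand_b, e.frame_start, e.frame_end) for e in events}
        want = oracle_detect(zs, [f"L{i}" for i in range(4)],
                             cfg.z_norm_threshold, cfg.span, cfg.region)
        assert got == want

    def test_fewer_than_two_ligands_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            events = detect_exchanges(make_trajectory(np.zeros((50, 1))))
        assert events == []


class TestEventProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_per_pair_windows_are_disjoint(self, seed):
        zs = random_walk_z(5, 150, seed=seed, lo=-20, hi=15, step=5.0)
        events, _ = detect_z(zs)
        by_pair = {}
        for e in events:
            by_pair.setdefault(e.pair, []).append((e.frame_start, e.frame_end))
        for windows in by_pair.values():
            windows.sort()
            for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
                assert b1 < a2  # closed intervals do not intersect

    @pytest.mark.parametrize("seed", range(6))
    def test_raising_threshold_never_increases_event_count(self, seed):
        zs = random_walk_z(4, 120, seed=seed, lo=-20, hi=15, step=5.0)
        counts = [
            len(detect_z(zs, z_norm_threshold=t)[0]) for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @given(st.integers(min_value=0, max_value=500),
           st.floats(min_value=-30, max_value=30),
           st.floats(min_value=-100, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_translation_and_time_shift_invariance(self, seed, dz, dt):
        zs = random_walk_z(3, 80, seed=seed, lo=-20, hi=15, step=5.0)
        base, cfg = detect_z(zs)
        shifted_cfg = DetectorConfig(
            span=(SPAN[0] + dz, SPAN[1] + dz),
            region=(cfg.region[0] + dz, cfg.region[1] + dz),
        )
        traj = make_trajectory(zs + dz, times=np.arange(80, dtype=float) + dt)
        shifted = detect_exchanges(traj, shifted_cfg, classify=False)
        assert [(e.pair, e.frame_start, e.frame_end) for e in base] == [
            (e.pair, e.frame_start, e.frame_end) for e in shifted
        ]
        for e0, e1 in zip(base, shifted):
            assert e1.z_mean == pytest.approx(e0.z_mean + dz, abs=1e-9)
            assert e1.time_mid == pytest.approx(e0.time_mid + dt, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mirror_invariance_negates_z_mean(self, seed):
        zs = random_walk_z(4, 100, seed=seed, lo=-20, hi=15, step=5.0)
        base, cfg = detect_z(zs)
        mirror_cfg = DetectorConfig(
            span=(-SPAN[1], -SPAN[0]),
            region=(-cfg.region[1], -cfg.region[0]),
        )
        mirrored = detect_exchanges(make_trajectory(-zs), mirror_cfg, classify=False)
        assert len(base) == len(mirrored)
        assert sorted(e.z_mean for e in base) == pytest.approx(
            sorted(-e.z_mean for e in mirrored), abs=1e-9
        )

    def test_relabeling_preserves_events(self):
        zs = random_walk_z(4, 100, seed=5, lo=-20, hi=15, step=5.0)
        base, cfg = detect_z(zs)
        perm = [2, 0, 3, 1]
        traj = make_trajectory(zs[:, perm], ids=[f"L{i}" for i in perm])
        relabeled = detect_exchanges(traj, cfg, classify=False)
        assert {(e.pair, e.frame_start, e.frame_end) for e in base} == {
            (e.pair, e.frame_start, e.frame_end) for e in relabeled
        }


class TestClassification:
    def _crossing_traj(self, lateral_offset):
        """Two ligands crossing in Z, kept apart in X by the offset."""
        f = np.arange(11, dtype=float)
        pos = np.zeros((11, 2, 3))
        pos[:, 0, 2] = 10.0 - 2.0 * f
        pos[:, 1, 2] = -10.0 + 2.0 * f
        pos[:, 1, 0] = lateral_offset
        return Trajectory(times=f, ligand_ids=["A", "B"], positions=pos)

    def test_close_apposition(self):
        traj = self._crossing_traj(2.0)
        cfg = DetectorConfig(span=SPAN)
        events = detect_exchanges(traj, cfg)
        assert len(events) == 1 and events[0].kind == "close"
        assert events[0].min_distance == pytest.approx(2.0)

    def test_wide_bypass(self):
        traj = self._crossing_traj(6.0)
        events = detect_exchanges(traj, DetectorConfig(span=SPAN))
        assert events[0].kind == "bypass"
        assert events[0].min_distance == pytest.approx(6.0)

    def test_cutoff_is_inclusive(self):
        traj = self._crossing_traj(3.5)
        events = detect_exchanges(traj, DetectorConfig(span=SPAN))
        assert events[0].kind == "close"

    def test_surface_exchange_overrides(self):
        """A long-resident well-bound ligand displaced by a partner
        arriving straight from solution is a surface exchange."""
        F = 20
        pos = np.zeros((F, 2, 3))
        pos[:, 0, 2] = 0.0  # A parked in the central binding well
        pos[:, 1, 0] = 6.0  # B passes wide
        pos[:, 1, 2] = 25.0
        pos[15:, 1, 2] = -5.0  # B drops from solution past A at frame 15
        traj = Trajectory(times=np.arange(F, dtype=float),
                          ligand_ids=["A", "B"], positions=pos)
        events = detect_exchanges(traj, DetectorConfig(span=SPAN))
        assert len(events) == 1
        ev = events[0]
        assert ev.frame_start == 14 and ev.frame_end == 15
        assert ev.kind == "surface"

    def test_window_outside_bounds_rejected(self):
        traj = self._crossing_traj(2.0)
        ev = detect_exchanges(traj, DetectorConfig(span=SPAN))[0]
        ev.frame_end = 99
        with pytest.raises(ValueError, match="outside trajectory bounds"):
            classify_exchange(ev, traj, DetectorConfig(span=SPAN))


class TestSeries:
    def test_empty_events(self):
        out = exchange_series([], time_bin=10.0)
        assert out["n_events"] == 0
        assert out["totals_by_kind"] == {}
        assert list(out["bin_counts"]) == [0]

    def test_binned_counts(self):
        f = np.arange(11, dtype=float)
        base = np.column_stack([10 - 2 * f, -10 + 2 * f])
        events, _ = detect_z(base)
        ev = events[0]
        import dataclasses

        evs = [dataclasses.replace(ev, time_mid=t) for t in (10.0, 20.0, 30.0)]
        out = exchange_series(evs, time_bin=25.0)
        assert list(out["bin_counts"]) == [2, 1]

    def test_totals_match_detector_output(self, small_fluid_run):
        events = detect_exchanges(small_fluid_run, DetectorConfig())
        out = exchange_series(events, time_bin=50.0)
        assert out["n_events"] == len(events)
        assert sum(out["totals_by_kind"].values()) == len(events)
        if len(events):
            assert out["bin_counts"].sum() == len(events)


class TestHbond:
    def _atomistic_pair(self, acceptor_x, acceptor_y=0.0):
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = acceptor_x
        atoms = {
            "A": np.array([[[0.0, 0.0, 0.0], [0.95, 0.0, 0.0]]]),  # O1, HO1
            "B": np.array([[[acceptor_x, acceptor_y, 0.0]]]),  # O2
        }
        names = {"A": ["O1", "HO1"], "B": ["O2"]}
        return Trajectory(times=[0.0], ligand_ids=["A", "B"], positions=pos,
                          atom_positions=atoms, atom_names=names)

    def test_linear_short_contact_is_flagged(self):
        traj = self._atomistic_pair(2.8)  # D-A 2.8 Å, angle 180°
        assert hbond_contacts(traj, ("A", "B"))[0]

    def test_long_distance_is_not_flagged(self):
        assert not hbond_contacts(self._atomistic_pair(4.2), ("A", "B"))[0]

    def test_bent_geometry_is_not_flagged(self):
        # acceptor beside the donor: D-A 2.0 Å but D-H-A angle ~ 64° < 120°
        traj = self._atomistic_pair(0.0, acceptor_y=2.0)
        assert not hbond_contacts(traj, ("A", "B"))[0]

    def test_com_only_trajectory_is_unsupported(self):
        traj = make_trajectory(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="atomic coordinates"):
            hbond_contacts(traj, ("L0", "L1"))


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(z_norm_threshold=1.5)
    with pytest.raises(ValueError):
        DetectorConfig(contact_cutoff=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(region=(-40.0, 0.0))  # outside the span
    with pytest.raises(ValueError):
        DetectorConfig(mode="sideways")
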