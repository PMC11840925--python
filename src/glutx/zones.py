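"""Zone occupancy, dwell, transit and exchange-vs-net-flux statistics.

The pore axis is partitioned into ordered, half-open Z-intervals
covering the whole line — by default the two bulk solutions, the two
vestibules and the central channel.  All statistics here are functions
of each ligand's zone sequence: dwell segments, complete
solution-to-solution transits (net flux), pore entry rates, co-occupancy
and the exchange-to-net flux ratio that summarises the accelerated
exchange phenomenology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "ZoneSet",
    "TransitRecord",
    "dwell_times",
    "net_transits",
    "pore_entry_rate",
    "co_occupancy",
    "exchange_to_net_ratio",
]

_DEFAULT_ZONES = [
    ("IC_solution", -math.inf, -25.0),
    ("IC_vestibule", -25.0, -15.0),
    ("central", -15.0, 5.0),
    ("EC_vestibule", 5.0, 20.0),
    ("EC_solution", 20.0, math.inf),
]


@dataclass
class ZoneSet:
    """Ordered, named, half-open Z-intervals [lo, hi) covering the line."""

    zones: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(_DEFAULT_ZONES)
    )

    def __post_init__(self) -> None:
        zs = self.zones
        if not zs:
            raise ValueError("at least one zone required")
        if zs[0][1] != -math.inf or zs[-1][2] != math.inf:
            raise ValueError("zones must cover the whole real line")
        for (n1, _, hi), (n2, lo, _) in zip(zs, zs[1:]):
            if hi != lo:
                raise ValueError(f"zones {n1} and {n2} are not contiguous")
        for name, lo, hi in zs:
            if not lo < hi:
                raise ValueError(f"zone {name} is empty")

    @property
    def names(self) -> list[str]:
        return [z[0] for z in self.zones]

    @property
    def solution_zones(self) -> tuple[str, str]:
        """The two unbounded end zones (IC side first)."""
        return self.zones[0][0], self.zones[-1][0]

    def pore_zones(self) -> list[str]:
        return self.names[1:-1]

    def assign(self, z: np.ndarray) -> np.ndarray:
        """Zone index per Z value (half-open [lo, hi) intervals)."""
        edges = np.array([zone[2] for zone in self.zones[:-1]])
        return np.searchsorted(edges, np.asarray(z, dtype=float), side="right")

    def sequence(self, trajectory: Trajectory, ligand_id: str) -> np.ndarray:
        return self.assign(trajectory.z(ligand_id))


@dataclass
class TransitRecord:
    """One complete solution-to-solution traversal."""

    ligand_id: str
    direction: str  # "influx" (EC -> IC) or "efflux" (IC -> EC)
    start_frame: int  # last frame in the source solution zone
    end_frame: int  # first frame in the destination solution zone

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("transit must span at least one frame step")


def dwell_times(
    trajectory: Trajectory, zones: ZoneSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ligand dwell segments and per-zone dwell totals.

    A segment is a maximal run of frames in one zone; its dwell time is
    (number of frames) x (frame interval), so per-ligand totals sum to
    the trajectory's frame count times the interval exactly.

    Returns ``(segments, totals)``: segments with columns
    ``ligand_id, zone, frame_start, frame_end, dwell_ns``; totals
    indexed by ligand with one column per zone (ns).
    """
    zones = zones or ZoneSet()
    dt = (
        float(np.median(np.diff(trajectory.times)))
        if trajectory.n_frames > 1
        else 0.0
    )
    seg_rows = []
    totals = np.zeros((trajectory.n_ligands, len(zones.zones)))
    for li, lid in enumerate(trajectory.ligand_ids):
        seq = zones.assign(trajectory.positions[:, li, 2])
        # boundaries of maximal constant runs
        change = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(seq)]])  # exclusive
        for s, e in zip(starts, ends):
            zi = seq[s]
            seg_rows.append(
                (lid, zones.names[zi], int(s), int(e - 1), (e - s) * dt)
            )
            totals[li, zi] += (e - s) * dt
    segments = pd.DataFrame(
        seg_rows,
        columns=["ligand_id", "zone", "frame_start", "frame_end", "dwell_ns"],
    )
    totals_df = pd.DataFrame(
        totals, index=trajectory.ligand_ids, columns=zones.names
    )
    return segments, totals_df


def net_transits(
    trajectory: Trajectory, zones: ZoneSet | None = None
) -> tuple[list[TransitRecord], dict[str, float]]:
    """Complete solution-to-solution traversals and per-direction rates.

    A transit is recorded when a ligand, last seen in one solution zone,
    first reaches the opposite solution zone; any intermediate return to
    the source solution zone resets the attempt.  Rates are counts per
    trajectory duration (transits/ns), reported per direction and total.
    """
    zones = zones or ZoneSet()
    ic, ec = 0, len(zones.zones) - 1
    records: list[TransitRecord] = []
    for li, lid in enumerate(trajectory.ligand_ids):
        seq = zones.assign(trajectory.positions[:, li, 2])
        source = None  # zone index of the solution last visited
        source_frame = -1
        for f, zi in enumerate(seq):
            if zi == ic or zi == ec:
                if source is not None and zi != source:
                    records.append(
                        TransitRecord(
                            ligand_id=lid,
                            direction="influx" if zi == ic else "efflux",
                            start_frame=source_frame,
                            end_frame=f,
                        )
                    )
                source = zi
                source_frame = f
    duration = trajectory.duration
    n_in = sum(1 for r in records if r.direction == "influx")
    n_out = len(records) - n_in
    rates = {
        "influx_per_ns": n_in / duration if duration > 0 else math.nan,
        "efflux_per_ns": n_out / duration if duration > 0 else math.nan,
        "total_per_ns": len(records) / duration if duration > 0 else math.nan,
    }
    return records, rates


def pore_entry_rate(
    trajectory: Trajectory, zones: ZoneSet | None = None
) -> dict[str, float]:
    """Entries into the pore region (vestibules + central) per μs.

    Counts every solution -> pore-zone transition, per source solution
    zone, normalised by total trajectory time (not ligand-time), so the
    result is "entries per μs of simulation" for the whole system.
    """
    zones = zones or ZoneSet()
    ic, ec = 0, len(zones.zones) - 1
    counts = {"from_IC": 0, "from_EC": 0}
    for li in range(trajectory.n_ligands):
        seq = zones.assign(trajectory.positions[:, li, 2])
        prev, cur = seq[:-1], seq[1:]
        counts["from_IC"] += int(np.sum((prev == ic) & (cur != ic) & (cur != ec)))
        counts["from_EC"] += int(np.sum((prev == ec) & (cur != ec) & (cur != ic)))
    duration_us = trajectory.duration / 1000.0
    out = {k: (v / duration_us if duration_us > 0 else math.nan) for k, v in counts.items()}
    out["total_per_us"] = (
        (counts["from_IC"] + counts["from_EC"]) / duration_us
        if duration_us > 0
        else math.nan
    )
    return out


def co_occupancy(
    trajectory: Trajectory,
    interval: tuple[float, float] | None = None,
    zones: ZoneSet | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame count of ligands in a Z-interval and the fraction of
    frames with two or more co-resident ligands.

    ``interval`` is half-open [lo, hi); by default the pore region of
    ``zones`` (everything between the two solution zones).
    """
    if interval is None:
        zones = zones or ZoneSet()
        interval = (zones.zones[0][2], zones.zones[-1][1])
    lo, hi = interval
    zs = trajectory.positions[:, :, 2]
    counts = np.sum((zs >= lo) & (zs < hi), axis=1)
    frac = float(np.mean(counts >= 2)) if len(counts) else 0.0
    return counts, frac


def exchange_to_net_ratio(
    n_events: int, n_transits: int, duration: float
) -> tuple[float, str]:
    """Ratio of exchange-event rate to net-transit rate.

    Both rates share the same duration, so the ratio reduces to
    events/transits.  Returns ``(ratio, flag)`` where flag is ``"ok"``,
    ``"no_transits"`` (ratio +inf) or ``"undefined"`` (both zero, NaN).
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if n_transits > 0:
        return n_events / n_transits, "ok"
    if n_events > 0:
        return math.inf, "no_transits"
    return math.nan, "undefined"
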