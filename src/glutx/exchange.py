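"""Positional exchange-event detection and classification.

An exchange is a pairwise swap of axial (Z) ordering between two ligands
A and B inside the pore: a pair of frames (i, j), i < j, between which
the pair's Z-ordering reverses and the *normalised ordering gap*
``n(z_A) - n(z_B)`` (pore span mapped linearly onto [0, 1]) changes by
more than a threshold (default 0.4), with the event's mean Z — the mean
of the four CoM Z-coordinates, both ligands at both bounding frames —
inside the central analysis region (default -15 ... +12 Å).  Every
ligand pair and every frame pair is examined; to avoid double counting,
only the smallest non-overlapping windows per pair are kept (greedy by
ascending window length).

Accepted events are classified by the partners' minimum approach
distance over the window: ``close`` when they come within the contact
cutoff (default 3.5 Å, inclusive), ``bypass`` when they stay wider
apart throughout; ``surface`` overrides either when a long-resident
well-bound ligand is displaced by a partner arriving from solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "DetectorConfig",
    "ExchangeEvent",
    "detect_exchanges",
    "classify_exchange",
    "exchange_series",
    "events_to_frame",
    "hbond_contacts",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the exchange definition.

    ``mode`` selects how the 0.4 normalised-Z criterion is read:
    ``"gap_change"`` (default) thresholds the change of the normalised
    ordering gap n(z_A) - n(z_B) between the two frames — unit-free and
    translation-invariant; ``"abs_position"`` is an alternate reading
    that thresholds the displaced ligand's absolute normalised Z at the
    later frame, kept for sensitivity analysis.
    """

    z_norm_threshold: float = 0.4
    region: tuple[float, float] = (-15.0, 12.0)
    contact_cutoff: float = 3.5
    span: tuple[float, float] = (-25.0, 20.0)
    mode: str = "gap_change"
    # surface-exchange residency rule
    well_bands: tuple[tuple[float, float], ...] = ((-3.0, 3.0), (12.0, 18.0))
    min_residency_frames: int = 10
    solution_z: tuple[float, float] = (-25.0, 20.0)  # outside = solution

    def __post_init__(self) -> None:
        if not (0.0 < self.z_norm_threshold < 1.0):
            raise ValueError("z_norm_threshold must lie in (0, 1)")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        lo, hi = self.span
        if not lo < hi:
            raise ValueError("normalization span must be a nonempty interval")
        if not (lo <= self.region[0] < self.region[1] <= hi):
            raise ValueError("region must lie within the normalization span")
        if self.mode not in ("gap_change", "abs_position"):
            raise ValueError("mode must be 'gap_change' or 'abs_position'")

    def normalize(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self.span
        return (np.asarray(z, dtype=float) - lo) / (hi - lo)


@dataclass
class ExchangeEvent:
    """One accepted pairwise positional exchange."""

    ligand_a: str
    ligand_b: str
    frame_start: int
    frame_end: int
    time_mid: float  # ns, midpoint of the two bounding frame times
    z_mean: float  # Å, mean of the four bounding Z coordinates
    min_distance: float = float("nan")  # Å, minimum approach over the window
    kind: str = ""  # close | bypass | surface

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.ligand_a, self.ligand_b)))

    @property
    def window_length(self) -> int:
        return self.frame_end - self.frame_start


def detect_exchanges(
    trajectory: Trajectory,
    config: DetectorConfig | None = None,
    classify: bool = True,
) -> list[ExchangeEvent]:
    """Detect all pairwise exchange events in a trajectory.

    Every unordered ligand pair is compared across every frame pair; a
    candidate window is accepted greedily by ascending window length
    (ties: earlier start frame, then lexicographic pair), rejecting
    candidates that overlap an already-accepted window *of the same
    pair*.  Windows of different pairs are independent.

    Returns events sorted by (time_mid, pair).
    """
    config = config or DetectorConfig()
    if trajectory.n_ligands < 2 or trajectory.n_frames < 2:
        warnings.warn("need >= 2 ligands and >= 2 frames; returning no events")
        return []
    zs = trajectory.positions[:, :, 2]  # (F, N)
    nz = config.normalize(zs)
    times = trajectory.times
    ids = trajectory.ligand_ids
    reg_lo, reg_hi = config.region
    thr = config.z_norm_threshold
    F, N = zs.shape

    events: list[ExchangeEvent] = []
    iu, ju = np.triu_indices(F, k=1)
    for ai in range(N):
        for bi in range(ai + 1, N):
            s = nz[:, ai] - nz[:, bi]  # normalised ordering gap per frame
            m = (zs[:, ai] + zs[:, bi]) / 2.0  # pairwise mean Z per frame
            # cheap prefilters: the pair must reorder at some point, and the
            # event z_mean (mean of two frame-means) must be able to reach
            # the analysis region
            if s.min() >= 0 or s.max() <= 0:
                continue
            if m.max() < reg_lo or m.min() > reg_hi:
                continue
            cand = _pair_candidates(s, m, nz[:, bi], iu, ju, config)
            if not len(cand):
                continue
            accepted = _greedy_accept(cand)
            for (i, j) in accepted:
                z_mean = (zs[i, ai] + zs[i, bi] + zs[j, ai] + zs[j, bi]) / 4.0
                events.append(
                    ExchangeEvent(
                        ligand_a=ids[ai],
                        ligand_b=ids[bi],
                        frame_start=int(i),
                        frame_end=int(j),
                        time_mid=float((times[i] + times[j]) / 2.0),
                        z_mean=float(z_mean),
                    )
                )
    events.sort(key=lambda e: (e.time_mid, e.pair))
    if classify:
        for ev in events:
            ev.min_distance, ev.kind = classify_exchange(ev, trajectory, config)
    return events


def _pair_candidates(
    s: np.ndarray,
    m: np.ndarray,
    nz_b: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    config: DetectorConfig,
) -> np.ndarray:
    """All candidate frame windows (i, j) for one ligand pair, as an
    (n, 2) int array."""
    si, sj = s[iu], s[ju]
    reversal = si * sj < 0
    if config.mode == "gap_change":
        strong = np.abs(sj - si) > config.z_norm_threshold
    else:  # abs_position: B must end up beyond the threshold position
        strong = nz_b[ju] > config.z_norm_threshold
    z_mean = (m[iu] + m[ju]) / 2.0
    reg_lo, reg_hi = config.region
    in_region = (z_mean >= reg_lo) & (z_mean <= reg_hi)
    mask = reversal & strong & in_region
    return np.column_stack([iu[mask], ju[mask]])


def _greedy_accept(cand: np.ndarray) -> list[tuple[int, int]]:
    """Greedy smallest-window-first selection of non-overlapping windows.

    Overlap means sharing any frame (closed intervals intersect)."""
    lengths = cand[:, 1] - cand[:, 0]
    order = np.lexsort((cand[:, 0], lengths))
    accepted: list[tuple[int, int]] = []
    for k in order:
        i, j = int(cand[k, 0]), int(cand[k, 1])
        if any(i <= bj and ai <= j for ai, bj in accepted):
            continue
        accepted.append((i, j))
    accepted.sort()
    return accepted


def classify_exchange(
    event: ExchangeEvent, trajectory: Trajectory, config: DetectorConfig | None = None
) -> tuple[float, str]:
    """Minimum approach distance over the event window and the kind.

    Distance is the minimum heavy-atom inter-ligand distance when atomic
    coordinates are available, else the CoM distance (both reported as
    ``min_distance``).  ``close`` if min_distance <= contact cutoff
    (inclusive), else ``bypass``; either is overridden to ``surface``
    when exactly one partner started the window well-bound (>= the
    residency minimum of frames inside a binding-well Z-band) while the
    other partner entered from solution.
    """
    config = config or DetectorConfig()
    i, j = event.frame_start, event.frame_end
    if not (0 <= i < j < trajectory.n_frames):
        raise ValueError(f"event window [{i}, {j}] outside trajectory bounds")
    ai = trajectory.ligand_ids.index(event.ligand_a)
    bi = trajectory.ligand_ids.index(event.ligand_b)
    sl = slice(i, j + 1)
    if trajectory.has_atoms():
        pa = trajectory.atom_positions[event.ligand_a][sl]  # (W, na, 3)
        pb = trajectory.atom_positions[event.ligand_b][sl]
        d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=-1)
        min_distance = float(d.min())
    else:
        diff = trajectory.positions[sl, ai] - trajectory.positions[sl, bi]
        if trajectory.box is not None:
            box = np.asarray(trajectory.box, dtype=float)
            if box.ndim == 1:  # minimum image in periodic X/Y
                diff[:, 0] -= box[0] * np.round(diff[:, 0] / box[0])
                diff[:, 1] -= box[1] * np.round(diff[:, 1] / box[1])
        min_distance = float(np.linalg.norm(diff, axis=1).min())

    kind = "close" if min_distance <= config.contact_cutoff else "bypass"
    if _is_surface(event, trajectory, config, ai, bi):
        kind = "surface"
    return min_distance, kind


def _in_any_band(z: np.ndarray, bands) -> np.ndarray:
    out = np.zeros(np.shape(z), dtype=bool)
    for lo, hi in bands:
        out |= (z >= lo) & (z <= hi)
    return out


def _is_surface(
    event: ExchangeEvent,
    trajectory: Trajectory,
    config: DetectorConfig,
    ai: int,
    bi: int,
) -> bool:
    i = event.frame_start
    za = trajectory.positions[:, ai, 2]
    zb = trajectory.positions[:, bi, 2]
    sol_lo, sol_hi = config.solution_z

    def bound_at_start(z: np.ndarray) -> bool:
        if not _in_any_band(z[i : i + 1], config.well_bands)[0]:
            return False
        lo = max(0, i - config.min_residency_frames + 1)
        recent = _in_any_band(z[lo : i + 1], config.well_bands)
        return bool(recent.all() and (i - lo + 1) >= config.min_residency_frames)

    def from_solution(z: np.ndarray) -> bool:
        return bool(z[i] < sol_lo or z[i] >= sol_hi)

    a_bound, b_bound = bound_at_start(za), bound_at_start(zb)
    a_sol, b_sol = from_solution(za), from_solution(zb)
    return (a_bound and b_sol and not b_bound) or (b_bound and a_sol and not a_bound)


# ---------------------------------------------------------------------------
# tabulation


def events_to_frame(events: list[ExchangeEvent]) -> pd.DataFrame:
    """Events as a DataFrame in the on-disk column layout."""
    cols = [
        "ligand_a",
        "ligand_b",
        "frame_start",
        "frame_end",
        "time_mid_ns",
        "z_mean_A",
        "min_distance_A",
        "kind",
    ]
    rows = [
        (e.ligand_a, e.ligand_b, e.frame_start, e.frame_end, e.time_mid, e.z_mean,
         e.min_distance, e.kind)
        for e in events
    ]
    return pd.DataFrame(rows, columns=cols)


def exchange_series(
    events: list[ExchangeEvent], time_bin: float | None = None
) -> dict:
    """Scatter table and binned counts of exchange events over time.

    Returns a dict with ``table`` (DataFrame sorted by time_mid),
    ``bin_edges``/``bin_counts`` (when ``time_bin`` is given, bins of
    that width in ns starting at t = 0), and ``totals_by_kind``.
    """
    table = events_to_frame(events).sort_values(
        "time_mid_ns", kind="stable", ignore_index=True
    )
    out: dict = {"table": table, "n_events": len(events)}
    if time_bin is not None and len(events):
        t = table["time_mid_ns"].to_numpy()
        n_bins = int(np.floor(t.max() / time_bin)) + 1
        edges = np.arange(n_bins + 1) * time_bin
        counts, _ = np.histogram(t, bins=edges)
        out["bin_edges"] = edges
        out["bin_counts"] = counts
    elif time_bin is not None:
        out["bin_edges"] = np.array([0.0, time_bin])
        out["bin_counts"] = np.array([0])
    out["totals_by_kind"] = (
        table["kind"].value_counts().to_dict() if len(table) else {}
    )
    return out


# ---------------------------------------------------------------------------
# hydrogen-bond descriptor (atomistic input only)


def hbond_contacts(
    trajectory: Trajectory,
    pair: tuple[str, str],
    distance_cutoff: float = 3.5,
    angle_cutoff_deg: float = 120.0,
    hydrogen_bond_length: float = 1.2,
) -> np.ndarray:
    """Per-frame geometric H-bond contact flags between two ligands.

    A frame is flagged when any donor-H...acceptor triple across the
    pair satisfies donor-acceptor distance <= ``distance_cutoff`` Å and
    donor-H-acceptor angle >= ``angle_cutoff_deg``.  Donors are O/N
    atoms with a hydrogen within ``hydrogen_bond_length`` Å; acceptors
    are O/N atoms.  Requires atomic coordinates (atomistic input); a
    CoM-only trajectory raises ``ValueError``.
    """
    if not trajectory.has_atoms():
        raise ValueError(
            "hbond_contacts requires atomic coordinates; this trajectory "
            "stores centres of mass only"
        )
    a, b = pair
    flags = np.zeros(trajectory.n_frames, dtype=bool)
    names = trajectory.atom_names
    for fi in range(trajectory.n_frames):
        pa = trajectory.atom_positions[a][fi]
        pb = trajectory.atom_positions[b][fi]
        flags[fi] = _frame_hbond(
            pa, names[a], pb, names[b], distance_cutoff, angle_cutoff_deg,
            hydrogen_bond_length,
        ) or _frame_hbond(
            pb, names[b], pa, names[a], distance_cutoff, angle_cutoff_deg,
            hydrogen_bond_length,
        )
    return flags


def _polar_mask(names: list[str]) -> np.ndarray:
    return np.array([n.strip()[:1].upper() in ("O", "N") for n in names])


def _hydrogen_mask(names: list[str]) -> np.ndarray:
    return np.array([n.strip()[:1].upper() == "H" for n in names])


def _frame_hbond(
    donor_pos, donor_names, acceptor_pos, acceptor_names,
    d_cut, ang_cut, hb_len,
) -> bool:
    dmask, hmask = _polar_mask(donor_names), _hydrogen_mask(donor_names)
    amask = _polar_mask(acceptor_names)
    if not dmask.any() or not hmask.any() or not amask.any():
        return False
    donors, hyds, accs = donor_pos[dmask], donor_pos[hmask], acceptor_pos[amask]
    dh = np.linalg.norm(donors[:, None, :] - hyds[None, :, :], axis=-1)
    for di, hi in zip(*np.nonzero(dh <= hb_len)):
        d_xyz, h_xyz = donors[di], hyds[hi]
        da = np.linalg.norm(accs - d_xyz, axis=1)
        for aidx in np.flatnonzero(da <= d_cut):
            v1 = d_xyz - h_xyz
            v2 = accs[aidx] - h_xyz
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= ang_cut:
                return True
    return False
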