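"""Brownian-dynamics generator for multi-ligand gated-channel trajectories.

The generator emulates the statistical structure of a saturated-flooded
glucose/GLUT1 system: a wide-vestibuled channel spanning the membrane,
narrow bottleneck apertures at both ends whose open/closed state
switches stochastically, attractive binding wells inside the pore, and
dozens of finite-size ligands (12 docked along the pore plus 44 free in
solution in a 116 x 116 x 120 Å box by default).  The lipid fluid and
gel phases are encoded purely as gating/diffusion presets: gelation
prolongs bottleneck closure and modestly slows in-pore diffusion, while
the channel interior is unchanged — which is exactly the regime in which
net transit collapses but positional exchanges between co-resident
ligands persist.

Dynamics are overdamped (position Langevin / Brownian) with kT = 1,
lengths in Å and times in ns: per substep each ligand receives a
Gaussian displacement of variance 2*D*dt per axis plus a drift
-D*dt*dU (kT=1) from the binding wells and a soft pairwise repulsion,
then hard constraints are enforced (channel walls, membrane slab,
closed gate planes, box Z faces; X/Y are periodic).  Two ligands can
therefore pass one another only where the local channel radius admits
two ligand radii side by side — single file through the bottlenecks,
two-lane in the vestibules and central cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "ChannelGeometry",
    "GateSpec",
    "PhasePreset",
    "GeneratorConfig",
    "default_config",
    "simulate",
    "equilibrium_z_histogram",
]

PHASES = ("fluid", "gel")


@dataclass
class ChannelGeometry:
    """Static pore geometry in the membrane frame (Z = 0 at bilayer centre).

    ``radius_profile`` is piecewise constant: a list of ``(z_lo, z_hi,
    radius)`` segments covering ``[z_pore_lo, z_pore_hi)``.  ``wells``
    are Gaussian attractive wells ``(z_center, depth_kT, width_A)``
    acting on the axial coordinate.
    """

    z_pore_lo: float = -25.0
    z_pore_hi: float = 20.0
    radius_profile: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (-25.0, -16.0, 12.0),
            (-16.0, -14.0, 4.5),
            (-14.0, 14.0, 9.0),
            (14.0, 16.0, 4.5),
            (16.0, 20.0, 12.0),
        ]
    )
    membrane_half_width: float = 18.0
    box: tuple[float, float, float] = (116.0, 116.0, 120.0)
    wells: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.0, 6.0, 3.0), (15.0, 6.0, 3.0)]
    )

    def __post_init__(self) -> None:
        if not self.z_pore_lo < self.z_pore_hi:
            raise ValueError("z_pore_lo must be < z_pore_hi")
        if any(r <= 0 for _, _, r in self.radius_profile):
            raise ValueError("all channel radii must be positive")
        if any(w <= 0 for _, _, w in self.wells):
            raise ValueError("well widths must be positive")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")

    def radius(self, z: np.ndarray) -> np.ndarray:
        """Local channel radius; +inf outside the pore region (no wall)."""
        z = np.asarray(z, dtype=float)
        r = np.full(z.shape, np.inf)
        for z_lo, z_hi, rad in self.radius_profile:
            r = np.where((z >= z_lo) & (z < z_hi), rad, r)
        return r

    def well_force_z(self, z: np.ndarray) -> np.ndarray:
        """Axial force -dU/dz (kT/Å) from the Gaussian wells."""
        f = np.zeros_like(np.asarray(z, dtype=float))
        for zc, depth, width in self.wells:
            dz = z - zc
            f += -depth * dz / width**2 * np.exp(-0.5 * (dz / width) ** 2)
        return f

    def well_potential(self, z: np.ndarray) -> np.ndarray:
        u = np.zeros_like(np.asarray(z, dtype=float))
        for zc, depth, width in self.wells:
            u += -depth * np.exp(-0.5 * ((z - zc) / width) ** 2)
        return u


@dataclass
class GateSpec:
    """Two-state Markov bottleneck at an axial plane.

    While closed, the plane reflects any ligand whose lateral position
    lies inside the channel aperture; switching is Poisson with rates
    ``k_open`` (closed -> open) and ``k_close`` (open -> closed), ns^-1.
    """

    z_gate: float
    k_open: float
    k_close: float
    initially_open: bool = True

    def __post_init__(self) -> None:
        if self.k_open < 0 or self.k_close < 0:
            raise ValueError("gate rates must be non-negative")

    @property
    def open_fraction(self) -> float:
        tot = self.k_open + self.k_close
        return 1.0 if tot == 0 else self.k_open / tot


@dataclass
class PhasePreset:
    """Lipid-phase parameter bundle: gating kinetics and diffusivity.

    The fluid preset has balanced gating (open fraction 0.5, ~10 ns mean
    dwell per state); the gel preset keeps the bottlenecks closed ~98%
    of the time with ~200 ns mean closed dwells, emulating the prolonged
    bottleneck closures of the gel bilayer.
    """

    name: str
    external_gate: GateSpec
    internal_gate: GateSpec
    D: float  # ligand diffusion coefficient, Å²/ns

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        for g in (self.external_gate, self.internal_gate):
            if not (0.0 < g.open_fraction <= 1.0):
                raise ValueError("gate open fraction must lie in (0, 1]")


def fluid_preset() -> PhasePreset:
    # open fraction 0.5, mean dwell 10 ns per state
    return PhasePreset(
        name="fluid",
        external_gate=GateSpec(z_gate=15.0, k_open=0.1, k_close=0.1),
        internal_gate=GateSpec(z_gate=-15.0, k_open=0.1, k_close=0.1),
        D=8.0,
    )


def gel_preset() -> PhasePreset:
    # open fraction 0.02, mean closed dwell 200 ns
    k_open = 1.0 / 200.0
    k_close = k_open * (1 - 0.02) / 0.02
    return PhasePreset(
        name="gel",
        external_gate=GateSpec(15.0, k_open, k_close, initially_open=False),
        internal_gate=GateSpec(-15.0, k_open, k_close, initially_open=False),
        D=4.0,
    )


@dataclass
class GeneratorConfig:
    geometry: ChannelGeometry
    phase: PhasePreset
    n_docked: int
    n_solution: int
    docked_z_positions: list[float]
    ligand_radius: float = 4.0
    repulsion_k: float = 2.0  # kT/Å², soft-sphere spring constant
    n_frames: int = 1000
    frame_interval: float = 1.0  # ns
    substeps_per_frame: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docked != len(self.docked_z_positions):
            raise ValueError("n_docked must equal len(docked_z_positions)")
        g = self.geometry
        for z in self.docked_z_positions:
            if not (g.z_pore_lo <= z <= g.z_pore_hi):
                raise ValueError(f"docked position {z} outside the pore region")
        if self.n_solution < 0 or self.n_frames < 1:
            raise ValueError("n_solution >= 0 and n_frames >= 1 required")

    @property
    def n_ligands(self) -> int:
        return self.n_docked + self.n_solution

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(phase_name: str, *, n_frames: int = 1000, seed: int = 0) -> GeneratorConfig:
    """Saturated-flooded default: 12 docked + 44 solution ligands.

    The 12 docked ligands are spread evenly over Z = -20 ... +15 Å along
    the pore (with small alternating lateral offsets where the channel
    is wide enough for two ligands abreast); 44 further ligands are
    placed uniformly at random in the solution compartments.  56 ligands
    in the 116 x 116 x 120 Å box correspond to ~57.5 mM, matching the
    50-60 mM equilibrated saturated-flooded concentration.
    """
    if phase_name not in PHASES:
        raise ValueError(
            f"unknown phase {phase_name!r}; valid phases are {', '.join(PHASES)}"
        )
    phase = fluid_preset() if phase_name == "fluid" else gel_preset()
    return GeneratorConfig(
        geometry=ChannelGeometry(),
        phase=phase,
        n_docked=12,
        n_solution=44,
        docked_z_positions=list(np.linspace(-20.0, 15.0, 12)),
        n_frames=n_frames,
        seed=seed,
    )


def ligand_concentration_mM(n_ligands: int, box: tuple[float, float, float]) -> float:
    """Concentration of n ligands in an orthorhombic box, in mM."""
    N_A = 6.02214076e23
    volume_L = float(np.prod(box)) * 1e-27  # Å³ -> L
    return n_ligands / (N_A * volume_L) * 1e3


# ---------------------------------------------------------------------------
# initial placement


def _initial_positions(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    g = config.geometry
    R = config.ligand_radius
    pos = np.zeros((config.n_ligands, 3))
    # docked ligands: on-axis, with alternating lateral offsets where the
    # channel admits them, so near-neighbours are not forced into deep overlap
    for i, z in enumerate(config.docked_z_positions):
        r_max = float(g.radius(np.array([z]))[0]) - R
        offset = min(4.0, max(0.0, r_max - 0.1))
        pos[i] = (offset * (1 if i % 2 == 0 else -1), 0.0, z)
    # solution ligands: uniform outside the membrane slab
    lx, ly, lz = g.box
    n = config.n_solution
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("could not place solution ligands without overlap")
        x = rng.uniform(-lx / 2, lx / 2)
        y = rng.uniform(-ly / 2, ly / 2)
        z = rng.uniform(-lz / 2, lz / 2)
        if abs(z) < g.membrane_half_width + R:
            continue
        cand = np.array([x, y, z])
        prev = pos[: config.n_docked + placed]
        if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < 2 * R:
            continue
        pos[config.n_docked + placed] = cand
        placed += 1
    # severe-overlap check on the docked layout (soft-sphere compression of
    # the evenly-spread default is tolerated; interpenetration is not)
    for i in range(config.n_docked):
        for j in range(i + 1, config.n_docked):
            if np.linalg.norm(pos[i] - pos[j]) < R:
                raise ValueError(
                    f"docked ligands {i} and {j} overlap beyond the soft-core limit"
                )
    # docked ligands must sit inside the channel wall
    r_lat = np.hypot(pos[: config.n_docked, 0], pos[: config.n_docked, 1])
    r_wall = g.radius(pos[: config.n_docked, 2]) - R
    inside_slab = np.abs(pos[: config.n_docked, 2]) < g.membrane_half_width
    if np.any(inside_slab & (r_lat > np.maximum(r_wall, 0.0) + 1e-9)):
        raise ValueError("docked ligand placed outside the channel wall")
    return pos


# ---------------------------------------------------------------------------
# dynamics


def _pair_forces(pos: np.ndarray, box_xy: np.ndarray, R: float, k: float) -> np.ndarray:
    """Soft-sphere repulsion, truncated at contact distance 2R; minimum
    image in the periodic X/Y directions."""
    n = len(pos)
    if n < 2 or k == 0 or R == 0:
        return np.zeros_like(pos)
    d = pos[None, :, :] - pos[:, None, :]  # r_i - r_j
    d[..., 0] -= box_xy[0] * np.round(d[..., 0] / box_xy[0])
    d[..., 1] -= box_xy[1] * np.round(d[..., 1] / box_xy[1])
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    overlap = np.clip(2 * R - dist, 0.0, None)
    with np.errstate(invalid="ignore"):
        coef = np.where(overlap > 0, k * overlap / dist, 0.0)
    # force on i points away from j: along -(r_i - r_j)? d[i,j] = r_j - r_i
    f = -(d * coef[..., None]).sum(axis=1)
    return f


def simulate(config: GeneratorConfig) -> Trajectory:
    """Run the Brownian gated-channel dynamics and sample every frame.

    Deterministic given ``config.seed``: gate chains and ligand noise are
    drawn from a single seeded generator in a fixed order, so replicas
    are produced with distinct seeds.
    """
    g = config.geometry
    rng = np.random.default_rng(config.seed)
    n = config.n_ligands
    dt = config.frame_interval / config.substeps_per_frame
    D = config.phase.D
    sigma = np.sqrt(2.0 * D * dt)
    R = config.ligand_radius
    lx, ly, lz = g.box
    box_xy = np.array([lx, ly])
    hw = g.membrane_half_width

    pos = _initial_positions(config, rng)
    gates = [config.phase.external_gate, config.phase.internal_gate]
    gate_open = np.array([gt.initially_open for gt in gates])
    p_open = np.array([1 - np.exp(-gt.k_open * dt) for gt in gates])
    p_close = np.array([1 - np.exp(-gt.k_close * dt) for gt in gates])
    gate_z = np.array([gt.z_gate for gt in gates])

    frames = np.empty((config.n_frames, n, 3))
    gate_open_frac = np.zeros(len(gates))
    frames[0] = pos
    for fi in range(1, config.n_frames):
        for _ in range(config.substeps_per_frame):
            # 1. gate switching (fixed draw order: gates, then ligand noise)
            u = rng.random(len(gates))
            flip = np.where(gate_open, u < p_close, u < p_open)
            gate_open = np.where(flip, ~gate_open, gate_open)
            gate_open_frac += gate_open
            if n == 0:
                continue
            # 2. drift + diffusion
            force = _pair_forces(pos, box_xy, R, config.repulsion_k)
            force[:, 2] += g.well_force_z(pos[:, 2])
            drift = D * dt * force
            # cap the deterministic displacement so deep soft-sphere
            # overlaps relax over a few substeps instead of teleporting
            # a ligand through a wall corner in one step
            norm = np.linalg.norm(drift, axis=1, keepdims=True)
            drift *= np.minimum(1.0, 2.0 / np.maximum(norm, 1e-12))
            new = pos + drift + sigma * rng.standard_normal((n, 3))
            # 3. box Z faces reflect
            new[:, 2] = _reflect_interval(new[:, 2], -lz / 2, lz / 2)
            # 4. membrane slab / channel walls
            new = _enforce_walls(pos, new, g, R, hw)
            # 5. closed gate planes reflect (ligands in the aperture)
            for gi in range(len(gates)):
                if gate_open[gi]:
                    continue
                zg = gate_z[gi]
                crossed = (pos[:, 2] - zg) * (new[:, 2] - zg) < 0
                if not crossed.any():
                    continue
                # a ligand crosses the plane near its pre-step lateral
                # position; block it if that lies within the aperture
                r_lat = np.hypot(pos[:, 0], pos[:, 1])
                blocked = crossed & (r_lat < g.radius(np.full(n, zg)) + R)
                new[blocked, 2] = 2 * zg - new[blocked, 2]
                # re-enforce walls in case the reflection crossed a segment
                new = _enforce_walls(pos, new, g, R, hw)
            # 6. periodic wrap in X, Y
            new[:, 0] = (new[:, 0] + lx / 2) % lx - lx / 2
            new[:, 1] = (new[:, 1] + ly / 2) % ly - ly / 2
            pos = new
        frames[fi] = pos

    times = np.arange(config.n_frames) * config.frame_interval
    substeps_total = max(1, (config.n_frames - 1) * config.substeps_per_frame)
    meta = {
        "generator": "glutx.channel.simulate",
        "phase": config.phase.name,
        "seed": config.seed,
        "D_A2_per_ns": D,
        "n_docked": config.n_docked,
        "n_solution": config.n_solution,
        "gate_open_fraction_observed": (gate_open_frac / substeps_total).tolist(),
    }
    return Trajectory(
        times=times,
        ligand_ids=[f"L{i:03d}" for i in range(n)],
        positions=frames,
        box=np.array(g.box),
        meta=meta,
    )


def _reflect_interval(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (single fold is enough for small steps)."""
    z = np.where(z > hi, 2 * hi - z, z)
    z = np.where(z < lo, 2 * lo - z, z)
    return np.clip(z, lo, hi)


def _enforce_walls(
    old: np.ndarray, new: np.ndarray, g: ChannelGeometry, R: float, hw: float
) -> np.ndarray:
    """Membrane slab and channel-wall constraints.

    A position with |z| < half-width must have lateral radius inside the
    (ligand-size-reduced) channel wall.  Violations are resolved by the
    cheapest reflection consistent with where the ligand came from:
    solution ligands bounce off the slab face; channel ligands bounce
    off the cylindrical wall, or have the axial move rejected when they
    stepped into a narrower segment.
    """
    new = new.copy()
    z = new[:, 2]
    in_slab = np.abs(z) < hw
    if not in_slab.any():
        return new
    r_lat = np.hypot(new[:, 0], new[:, 1])
    r_wall = g.radius(z) - R
    bad = in_slab & (r_lat > r_wall)
    if not bad.any():
        return new
    idx = np.flatnonzero(bad)
    for i in idx:
        was_outside = abs(old[i, 2]) >= hw
        if was_outside:
            # bounce off the slab face
            face = np.sign(old[i, 2]) * hw
            new[i, 2] = 2 * face - new[i, 2]
            if abs(new[i, 2]) < hw:  # pathological large step: reject z move
                new[i, 2] = old[i, 2]
            continue
        # came from inside the slab: first try rejecting the axial move
        # (stepped into a narrower segment), then reflect laterally
        rw_old = g.radius(np.array([old[i, 2]]))[0] - R
        rl = np.hypot(new[i, 0], new[i, 1])
        if rl <= rw_old:
            new[i, 2] = old[i, 2]
            continue
        new[i, 2] = old[i, 2] if rl > g.radius(np.array([new[i, 2]]))[0] - R else new[i, 2]
        rw = g.radius(np.array([new[i, 2]]))[0] - R
        rw = max(rw, 1e-6)
        rl_new = 2 * rw - rl
        if rl_new < 0:
            rl_new = rw  # clamp: reflection overshot the axis
        if rl > 0:
            new[i, 0] *= rl_new / rl
            new[i, 1] *= rl_new / rl
    return new


def equilibrium_z_histogram(
    trajectory: Trajectory, bins: int = 50, z_range: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised Z-occupancy histogram over all ligands and frames.

    Returns ``(edges, occupancy)`` with ``occupancy.sum() == 1``.
    """
    if trajectory.n_frames == 0 or trajectory.n_ligands == 0:
        raise ValueError("cannot histogram an empty trajectory")
    zs = trajectory.positions[:, :, 2].ravel()
    counts, edges = np.histogram(zs, bins=bins, range=z_range)
    return edges, counts / counts.sum()
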