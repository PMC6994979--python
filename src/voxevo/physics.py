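"""Soft-body voxel physics: mass-spring lattice, CPG actuation, contact, drag.

A design is simulated as point masses at voxel corners connected by
springs along voxel edges and face diagonals. Contractile voxels
modulate the rest lengths of their springs with a global sine-wave
central pattern generator (default 2 Hz), shifted per voxel by its phase
offset. The environment provides gravity, a penalty-force ground plane
at z = 0 with regularized Coulomb friction, and — in aquatic mode —
reduced effective gravity (buoyancy) plus a first-order drag force on
every exposed voxel face, proportional to the face-normal velocity.

Every evaluation starts with a settling period under gravity with the
actuation switched off; the locomotion trajectory and net displacement
are measured from the post-settling position. Integration is
semi-implicit (symplectic) Euler at a fixed timestep, which makes a
simulation a pure function of (design, configs, seed): identical inputs
give bit-identical trajectories.

None of the material constants are dimensionful beyond the declared
units (voxel edge = 1 length unit, voxel mass = 1 mass unit, seconds for
time); defaults are chosen for numerical stability at the default
working resolution and are recorded in every output file.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from numba import njit

from .errors import (ConfigurationError, ContractViolationError,
                     InvalidDesignError, SimulationUnstableError)
from .genome import CONTRACTILE, EMPTY, PHASE_BOUND, VoxelDesign

#: Reference gravitational acceleration, length-units / s^2.
GRAVITY_REFERENCE = 9.81


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ActuationConfig:
    """Central-pattern-generator settings: 2 Hz sine, fractional amplitude."""

    frequency: float = 2.0       # Hz
    amplitude: float = 0.1       # fractional rest-length excursion
    phase_bound: float = PHASE_BOUND  # radians; fixed +-pi/2

    def validate(self) -> None:
        if self.frequency <= 0:
            raise ConfigurationError("frequency must be positive")
        if not (0 < self.amplitude < 0.5):
            raise ConfigurationError("amplitude must lie in (0, 0.5)")


@dataclasses.dataclass
class EnvironmentConfig:
    """Physical environment: terrestrial (dry plane) or aquatic.

    Aquatic mode approximates submersion by scaling gravity down
    (buoyancy) and applying per-exposed-face normal drag.
    """

    mode: str = "terrestrial"
    gravity_scale: float = 1.0        # fraction of GRAVITY_REFERENCE
    drag_coefficient: float = 0.0     # force / (area * normal velocity)
    friction_coefficient: float = 0.8
    ground_stiffness: float = 1e4
    ground_damping: float = 10.0

    @classmethod
    def terrestrial(cls) -> "EnvironmentConfig":
        return cls(mode="terrestrial", gravity_scale=1.0, drag_coefficient=0.0)

    @classmethod
    def aquatic(cls) -> "EnvironmentConfig":
        # Submerged regime: tissue stays clearly negatively buoyant and a
        # millimeter-scale body in water is heavily damped, so effective
        # gravity is halved and linear face drag is strong. In this regime
        # hopping is ineffective and bodies keep ventral ground contact.
        return cls(mode="aquatic", gravity_scale=0.5, drag_coefficient=40.0)

    def validate(self, strict: bool = True) -> None:
        if not (0 < self.gravity_scale <= 1):
            raise ConfigurationError("gravity_scale must lie in (0, 1]")
        if self.drag_coefficient < 0:
            raise ConfigurationError("drag_coefficient must be >= 0")
        if self.mode not in ("terrestrial", "aquatic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if strict and self.mode == "aquatic":
            if not (self.drag_coefficient > 0 and self.gravity_scale < 1):
                raise ConfigurationError(
                    "aquatic mode requires drag_coefficient > 0 and "
                    "gravity_scale < 1")


@dataclasses.dataclass
class SimulationConfig:
    """Integration and material constants."""

    settle_time: float = 1.0     # s, gravity settling (no actuation)
    eval_time: float = 10.0      # s, evaluation window
    timestep: float = 1e-3       # s
    output_rate: float = 100.0   # Hz, trajectory sampling
    stiffness: float = 5e3       # spring constant, all tissues
    damping_ratio: float = 0.3   # per-spring critical-damping fraction
    voxel_mass: float = 1.0      # mass unit per voxel, split over corners
    contact_tolerance: float = 1e-3  # voxel lengths above z=0

    def validate(self) -> None:
        if self.timestep <= 0 or self.eval_time <= 0 or self.settle_time < 0:
            raise ConfigurationError("need timestep>0, eval_time>0, settle_time>=0")
        if self.output_rate <= 0 or self.stiffness <= 0 or self.voxel_mass <= 0:
            raise ConfigurationError("output_rate, stiffness, voxel_mass must be >0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(eq=False)
class SimResult:
    """Trajectory, contact record and net displacement of one simulation.

    The trajectory covers only the evaluation window; t = 0 is the end of
    settling. ``net_displacement`` is the horizontal-plane Euclidean
    distance between the first and last center-of-mass positions.
    """

    t: np.ndarray          # (n,), seconds since end of settling
    com: np.ndarray        # (n, 3) center-of-mass positions
    contact: np.ndarray    # (n,) bool, any voxel touching the ground
    net_displacement: float
    output_rate: float
    meta: dict = dataclasses.field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t,
            "x": self.com[:, 0],
            "y": self.com[:, 1],
            "z": self.com[:, 2],
            "contact": self.contact.astype(int),
        })


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def actuation_scale(t: float, phase: float,
                    cfg: Optional[ActuationConfig] = None) -> float:
    """Rest-length multiplier of the CPG at time ``t`` for a given phase.

    Returns ``1 + amplitude * sin(2*pi*frequency*t + phase)``; periodic
    with period ``1/frequency`` (0.5 s at the default 2 Hz).
    """
    cfg = cfg or ActuationConfig()
    cfg.validate()
    if abs(phase) > cfg.phase_bound + 1e-12:
        raise ContractViolationError(
            f"phase {phase} outside +-{cfg.phase_bound}")
    return 1.0 + cfg.amplitude * math.sin(
        2.0 * math.pi * cfg.frequency * t + phase)


_FACE_NORMALS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1))


def exposed_faces(design: VoxelDesign):
    """Enumerate exposed voxel faces: ((i, j, k), (nx, ny, nz)) per face.

    A face is exposed iff the neighboring cell across it is EMPTY or
    outside the grid. Each exposed face appears exactly once.
    """
    occ = design.grid != EMPTY
    faces = []
    for (i, j, k) in np.argwhere(occ):
        for n in _FACE_NORMALS:
            ii, jj, kk = i + n[0], j + n[1], k + n[2]
            inside = (0 <= ii < occ.shape[0] and 0 <= jj < occ.shape[1]
                      and 0 <= kk < occ.shape[2])
            if not inside or not occ[ii, jj, kk]:
                faces.append(((int(i), int(j), int(k)), n))
    return faces


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

_CORNERS = ((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
            (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1))

# Corner-index pairs: 12 edges, 12 face diagonals (2 per face).
_EDGES = tuple((p, q) for p in range(8) for q in range(p + 1, 8)
               if sum(a != b for a, b in zip(_CORNERS[p], _CORNERS[q])) == 1)
_FDIAGS = tuple((p, q) for p in range(8) for q in range(p + 1, 8)
                if sum(a != b for a, b in zip(_CORNERS[p], _CORNERS[q])) == 2)

# Corner indices of the 4 nodes of each face, keyed by (axis, side).
_FACE_CORNERS = {
    (ax, side): tuple(c for c in range(8) if _CORNERS[c][ax] == side)
    for ax in range(3) for side in (0, 1)
}


class _Lattice:
    """Precomputed kernel arrays for one (design, phases) pair."""

    __slots__ = ("pos0", "mass", "inv_mass", "si", "sj", "rest0", "ks", "cs",
                 "n_own", "cptr", "cph", "face_nodes", "face_axis")


def _build_lattice(design: VoxelDesign, phases: np.ndarray,
                   sim: SimulationConfig) -> _Lattice:
    grid = design.grid
    vs = design.voxel_size
    nx, ny, nz = grid.shape
    voxels = np.argwhere(grid != EMPTY)

    node_id = np.full((nx + 1, ny + 1, nz + 1), -1, dtype=np.int64)
    node_coords = []
    for (i, j, k) in voxels:
        for (di, dj, dk) in _CORNERS:
            key = (i + di, j + dj, k + dk)
            if node_id[key] < 0:
                node_id[key] = len(node_coords)
                node_coords.append(key)
    n_nodes = len(node_coords)
    pos0 = np.asarray(node_coords, dtype=np.float64) * vs
    mass = np.zeros(n_nodes)

    spring_index: dict = {}
    si, sj, rest0, owners = [], [], [], []
    m_corner = sim.voxel_mass / 8.0
    for v, (i, j, k) in enumerate(voxels):
        nodes8 = [node_id[i + di, j + dj, k + dk] for (di, dj, dk) in _CORNERS]
        for n in nodes8:
            mass[n] += m_corner
        for pairs, rest in ((_EDGES, vs), (_FDIAGS, vs * math.sqrt(2.0))):
            for (p, q) in pairs:
                a, b = nodes8[p], nodes8[q]
                key = (a, b) if a < b else (b, a)
                s = spring_index.get(key)
                if s is None:
                    s = len(si)
                    spring_index[key] = s
                    si.append(key[0])
                    sj.append(key[1])
                    rest0.append(rest)
                    owners.append([])
                owners[s].append(v)

    lat = _Lattice()
    lat.pos0 = pos0
    lat.mass = mass
    lat.inv_mass = 1.0 / mass
    lat.si = np.asarray(si, dtype=np.int64)
    lat.sj = np.asarray(sj, dtype=np.int64)
    lat.rest0 = np.asarray(rest0)
    lat.ks = np.full(len(si), sim.stiffness)
    # Per-spring damping from the reduced mass of its endpoints.
    mu = (mass[lat.si] * mass[lat.sj]) / (mass[lat.si] + mass[lat.sj])
    lat.cs = 2.0 * sim.damping_ratio * np.sqrt(lat.ks * mu)

    lat.n_own = np.asarray([len(o) for o in owners], dtype=np.int64)
    is_contr = grid[tuple(voxels.T)] == CONTRACTILE
    vox_phase = phases[tuple(voxels.T)]
    cptr = [0]
    cph = []
    for o in owners:
        for v in o:
            if is_contr[v]:
                cph.append(vox_phase[v])
        cptr.append(len(cph))
    lat.cptr = np.asarray(cptr, dtype=np.int64)
    lat.cph = np.asarray(cph, dtype=np.float64)

    face_nodes, face_axis = [], []
    for (i, j, k), n in exposed_faces(design):
        ax = 0 if n[0] else (1 if n[1] else 2)
        side = 1 if n[ax] > 0 else 0
        corners = _FACE_CORNERS[(ax, side)]
        face_nodes.append([node_id[i + _CORNERS[c][0], j + _CORNERS[c][1],
                                   k + _CORNERS[c][2]] for c in corners])
        face_axis.append(ax)
    lat.face_nodes = (np.asarray(face_nodes, dtype=np.int64)
                      if face_nodes else np.zeros((0, 4), dtype=np.int64))
    lat.face_axis = np.asarray(face_axis, dtype=np.int64)
    return lat


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _integrate(pos, vel, mass, inv_mass, si, sj, rest0, ks, cs, n_own,
               cptr, cph, face_nodes, face_axis, n_settle, n_eval, out_every,
               dt, amp, omega, g, k_ground, c_ground, mu_friction, v_eps,
               drag_face, contact_tol, t_out, com_out, contact_out):
    n_nodes = pos.shape[0]
    n_springs = si.shape[0]
    n_faces = face_nodes.shape[0]
    total_mass = 0.0
    for n in range(n_nodes):
        total_mass += mass[n]
    force = np.zeros((n_nodes, 3))
    total_steps = n_settle + n_eval
    iout = 0
    for step in range(total_steps + 1):
        if step >= n_settle and (step - n_settle) % out_every == 0:
            cx = cy = cz = 0.0
            contact = False
            for n in range(n_nodes):
                cx += mass[n] * pos[n, 0]
                cy += mass[n] * pos[n, 1]
                cz += mass[n] * pos[n, 2]
                if pos[n, 2] <= contact_tol:
                    contact = True
            cx /= total_mass
            cy /= total_mass
            cz /= total_mass
            if not (math.isfinite(cx) and math.isfinite(cy)
                    and math.isfinite(cz)):
                return 1
            t_out[iout] = (step - n_settle) * dt
            com_out[iout, 0] = cx
            com_out[iout, 1] = cy
            com_out[iout, 2] = cz
            contact_out[iout] = contact
            iout += 1
        if step == total_steps:
            break

        for n in range(n_nodes):
            force[n, 0] = 0.0
            force[n, 1] = 0.0
            force[n, 2] = -mass[n] * g

        actuating = step >= n_settle
        te = (step - n_settle) * dt if actuating else 0.0
        for s in range(n_springs):
            rest = rest0[s]
            if actuating:
                c0 = cptr[s]
                c1 = cptr[s + 1]
                if c1 > c0:
                    ssum = 0.0
                    for q in range(c0, c1):
                        ssum += math.sin(omega * te + cph[q])
                    rest = rest * (1.0 + amp * ssum / n_own[s])
            i = si[s]
            j = sj[s]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            length = math.sqrt(dx * dx + dy * dy + dz * dz)
            if length < 1e-12:
                continue
            inv = 1.0 / length
            ux = dx * inv
            uy = dy * inv
            uz = dz * inv
            vrel = ((vel[j, 0] - vel[i, 0]) * ux
                    + (vel[j, 1] - vel[i, 1]) * uy
                    + (vel[j, 2] - vel[i, 2]) * uz)
            fmag = ks[s] * (length - rest) + cs[s] * vrel
            fx = fmag * ux
            fy = fmag * uy
            fz = fmag * uz
            force[i, 0] += fx
            force[i, 1] += fy
            force[i, 2] += fz
            force[j, 0] -= fx
            force[j, 1] -= fy
            force[j, 2] -= fz

        for n in range(n_nodes):
            z = pos[n, 2]
            if z < 0.0:
                fn = -k_ground * z - c_ground * vel[n, 2]
                if fn > 0.0:
                    force[n, 2] += fn
                    vx = vel[n, 0]
                    vy = vel[n, 1]
                    vt = math.sqrt(vx * vx + vy * vy)
                    # Coulomb friction, capped at the force that would stop
                    # the node within one step (keeps sticking stable).
                    ffr = mu_friction * fn / (vt + v_eps)
                    cap = mass[n] / dt
                    if ffr > cap:
                        ffr = cap
                    force[n, 0] -= ffr * vx
                    force[n, 1] -= ffr * vy

        if drag_face > 0.0:
            for f in range(n_faces):
                ax = face_axis[f]
                vn = 0.25 * (vel[face_nodes[f, 0], ax]
                             + vel[face_nodes[f, 1], ax]
                             + vel[face_nodes[f, 2], ax]
                             + vel[face_nodes[f, 3], ax])
                fd = -0.25 * drag_face * vn
                for q in range(4):
                    force[face_nodes[f, q], ax] += fd

        for n in range(n_nodes):
            vel[n, 0] += dt * force[n, 0] * inv_mass[n]
            vel[n, 1] += dt * force[n, 1] * inv_mass[n]
            vel[n, 2] += dt * force[n, 2] * inv_mass[n]
            pos[n, 0] += dt * vel[n, 0]
            pos[n, 1] += dt * vel[n, 1]
            pos[n, 2] += dt * vel[n, 2]
    return 0


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------


#: Friction regularization velocity (length-units/s); below this sliding
#: speed the tangential force ramps linearly to zero instead of jumping.
FRICTION_V_EPS = 1e-3


def simulate(design: VoxelDesign,
             env: Optional[EnvironmentConfig] = None,
             sim: Optional[SimulationConfig] = None,
             act: Optional[ActuationConfig] = None,
             seed: int = 0,
             phase_noise_sd: float = 0.0,
             origin=(0.0, 0.0)) -> SimResult:
    """Simulate a design and return its trajectory and net displacement.

    If ``phase_noise_sd`` is positive, one random perturbation of the
    design's phase field (clipped Gaussian, drawn with ``seed``) is
    applied for the whole evaluation — the randomized phase modulation
    under which locomotion fitness is scored. With ``phase_noise_sd=0``
    the simulation is noise-free and ``seed`` has no effect.

    ``origin`` horizontally translates the reported trajectory; the
    dynamics are computed in the body frame, so translation is exact.
    """
    env = env or EnvironmentConfig.terrestrial()
    sim = sim or SimulationConfig()
    act = act or ActuationConfig()
    env.validate(strict=False)
    sim.validate()
    act.validate()
    if design.is_empty:
        raise InvalidDesignError("cannot simulate an empty design")

    phases = design.phases
    if phase_noise_sd > 0.0:
        from .filters import perturb_phases

        phases = perturb_phases(phases, np.random.default_rng(int(seed)),
                                phase_noise_sd)

    lat = _build_lattice(design, phases, sim)
    pos = lat.pos0.copy()
    pos[:, 2] -= pos[:, 2].min()  # rest the lowest nodes on the ground plane
    vel = np.zeros_like(pos)

    dt = sim.timestep
    n_settle = int(round(sim.settle_time / dt))
    n_eval = int(round(sim.eval_time / dt))
    out_every = max(1, int(round(1.0 / (sim.output_rate * dt))))
    n_out = n_eval // out_every + 1
    t_out = np.zeros(n_out)
    com_out = np.zeros((n_out, 3))
    contact_out = np.zeros(n_out, dtype=np.bool_)

    rc = _integrate(
        pos, vel, lat.mass, lat.inv_mass, lat.si, lat.sj, lat.rest0, lat.ks,
        lat.cs, lat.n_own, lat.cptr, lat.cph, lat.face_nodes, lat.face_axis,
        n_settle, n_eval, out_every, dt, act.amplitude,
        2.0 * math.pi * act.frequency, env.gravity_scale * GRAVITY_REFERENCE,
        env.ground_stiffness, env.ground_damping, env.friction_coefficient,
        FRICTION_V_EPS, env.drag_coefficient * design.voxel_size ** 2,
        sim.contact_tolerance * design.voxel_size, t_out, com_out,
        contact_out)
    if rc != 0:
        raise SimulationUnstableError(
            f"non-finite coordinates for design {design.name or design.resolution}"
            f" at timestep {dt}")

    # Displacement is computed in the body frame before the origin offset
    # is applied, so translating the placement cannot perturb it.
    net = math.hypot(com_out[-1, 0] - com_out[0, 0],
                     com_out[-1, 1] - com_out[0, 1])
    com_out[:, 0] += origin[0]
    com_out[:, 1] += origin[1]
    meta = {
        "seed": int(seed),
        "phase_noise_sd": float(phase_noise_sd),
        "environment": dataclasses.asdict(env),
        "simulation": dataclasses.asdict(sim),
        "actuation": dataclasses.asdict(act),
        "gravity_reference": GRAVITY_REFERENCE,
    }
    return SimResult(t=t_out, com=com_out, contact=contact_out,
                     net_displacement=net, output_rate=sim.output_rate,
                     meta=meta)


def contact_fraction(result: SimResult) -> float:
    """Fraction of evaluation-window output steps with ground contact."""
    if result.contact.size == 0:
        raise ContractViolationError("empty contact series")
    return float(result.contact.mean())
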