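"""Trajectory and design analysis: displacement, smoothing, inversion.

Includes the in-silico upright-vs-inverted comparison protocol: a design
is evaluated repeatedly under independent random phase modulation, then
flipped 180 degrees about its transverse (horizontal mid-) plane and
evaluated again; a one-sided permutation test on mean net displacement
decides whether inversion reduced locomotion. The permutation test is a
distribution-free stand-in for the original statistics, and is flagged
as such in reports.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import comb

from .errors import ContractViolationError
from .genome import VoxelDesign
from .physics import (ActuationConfig, EnvironmentConfig, SimResult,
                      SimulationConfig, simulate)


@dataclasses.dataclass(eq=False)
class Trajectory:
    """Horizontal (x, y) movement track sampled at strictly increasing t."""

    t: np.ndarray
    xy: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.size < 2:
            raise ContractViolationError("trajectory needs >= 2 samples")
        if not (np.diff(self.t) > 0).all():
            raise ContractViolationError("timestamps must strictly increase")

    @classmethod
    def from_sim_result(cls, result: SimResult) -> "Trajectory":
        return cls(t=result.t.copy(), xy=result.com[:, :2].copy())


@dataclasses.dataclass
class ComparisonResult:
    mean_a: float
    mean_b: float
    difference: float
    p_value: float
    exact: bool
    n_permutations: int
    method: str = "one-sided permutation test on difference of means"


def net_displacement(traj: Trajectory) -> float:
    """Euclidean distance between the first and last samples."""
    d = traj.xy[-1] - traj.xy[0]
    return float(math.hypot(d[0], d[1]))


def smooth_trajectory(traj: Trajectory, sigma: float = 5.0) -> Trajectory:
    """Gaussian-smooth each coordinate series (reflect boundary).

    ``sigma`` is in samples; 0 returns an identical copy. Timestamps are
    unchanged.
    """
    if sigma < 0:
        raise ContractViolationError("sigma must be >= 0")
    if sigma == 0:
        return Trajectory(traj.t.copy(), traj.xy.copy())
    sm = gaussian_filter1d(traj.xy, sigma=sigma, axis=0, mode="reflect")
    return Trajectory(traj.t.copy(), sm)


def invert_design(design: VoxelDesign) -> VoxelDesign:
    """Rotate a design 180 degrees about its transverse (horizontal) plane.

    Dorsal becomes ventral: the grid and phase field are flipped along z
    (the rotation's accompanying horizontal flip is a rigid-body yaw with
    no effect on locomotion and is omitted). Tissue counts, connectivity
    and exposed-face counts are conserved; ``invert`` is an involution.
    """
    out = VoxelDesign(grid=design.grid[:, :, ::-1].copy(),
                      phases=design.phases[:, :, ::-1].copy(),
                      voxel_size=design.voxel_size,
                      name=(design.name + "_inverted") if design.name else "")
    return out


def evaluate_protocol(design: VoxelDesign,
                      n_evals: int = 25,
                      eval_time: float = 60.0,
                      seed: int = 0,
                      env: Optional[EnvironmentConfig] = None,
                      sim: Optional[SimulationConfig] = None,
                      act: Optional[ActuationConfig] = None,
                      phase_noise_sd: float = 0.4 * math.pi) -> list:
    """Evaluate a design repeatedly under independent phase modulation.

    Returns one SimResult per evaluation; evaluations differ only in the
    per-evaluation phase-noise draw, so all trajectories share the same
    starting position.
    """
    if n_evals < 1:
        raise ContractViolationError("n_evals must be >= 1")
    sim = dataclasses.replace(sim or SimulationConfig(), eval_time=eval_time)
    env = env or EnvironmentConfig.aquatic()
    act = act or ActuationConfig()
    eval_seeds = np.random.default_rng(int(seed)).integers(
        0, 2**31 - 1, size=n_evals)
    return [simulate(design, env, sim, act, seed=int(s),
                     phase_noise_sd=phase_noise_sd) for s in eval_seeds]


def airborne_fraction(result: SimResult, act: Optional[ActuationConfig] = None
                      ) -> float:
    """Fraction of the gait with zero ground contact, over whole cycles.

    The contact series is truncated to an integer number of actuation
    cycles (0.5 s at the default 2 Hz) before averaging, so partial
    cycles do not bias the estimate.
    """
    act = act or ActuationConfig()
    per_cycle = int(round(result.output_rate / act.frequency))
    n = result.contact.size
    usable = (n // per_cycle) * per_cycle if n >= per_cycle else n
    if usable == 0:
        raise ContractViolationError("contact series shorter than one cycle")
    return float((~result.contact[:usable]).mean())


def compare_displacements(group_a: Sequence[float], group_b: Sequence[float],
                          n_permutations: int = 100_000,
                          seed: int = 0) -> ComparisonResult:
    """One-sided permutation test that group A out-displaces group B.

    Tests mean(A) > mean(B) by permuting group labels. When the number
    of distinct assignments C(nA+nB, nA) is at most 1e6, all are
    enumerated and the p-value is the exact fraction of assignments with
    a difference of means at least as large as observed. Otherwise a
    seeded Monte-Carlo estimate with add-one smoothing is returned:
    p = (1 + #extreme) / (1 + n_permutations).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractViolationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = a.mean() - b.mean()
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    total = comb(pooled.size, n_a, exact=True)
    if total <= 1_000_000:
        # Difference of means is monotone in sum(A) for fixed sizes.
        extreme = 0
        for idx in combinations(range(pooled.size), n_a):
            sel = pooled[list(idx)]
            mask = np.ones(pooled.size, dtype=bool)
            mask[list(idx)] = False
            diff = sel.mean() - pooled[mask].mean()
            if diff >= observed - tol:
                extreme += 1
        return ComparisonResult(float(a.mean()), float(b.mean()),
                                float(observed), extreme / total, True, total)
    rng = np.random.default_rng(int(seed))
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = perm[:n_a].mean() - perm[n_a:].mean()
        if diff >= observed - tol:
            extreme += 1
    p = (1 + extreme) / (1 + n_permutations)
    return ComparisonResult(float(a.mean()), float(b.mean()), float(observed),
                            p, False, n_permutations)
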