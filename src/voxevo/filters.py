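"""Robustness and manufacturability screening of evolved designs.

The robustness filter ranks candidate designs by how well they keep
locomoting when the phase offsets of their contractile voxels are
scrambled: each design is re-simulated under independent clipped-Gaussian
phase perturbations (SD 0.4*pi, i.e. 40% of the pi-wide valid phase
range) and ranked by mean net displacement.

The build filter screens for manufacturability with living tissue:
designs that are more than 50% muscle are rejected (to reserve design
space and limit metabolic cost), as are designs whose narrowest
concavity is finer than 12% of body length — aggregates of developing
cells close gaps below roughly 100 um, so such features would not
persist in a built organism.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import (ConfigurationError, ContractViolationError,
                     SimulationUnstableError)
from .genome import (CONTRACTILE, EMPTY, PHASE_BOUND, VoxelDesign,
                     face_connected_components)
from .physics import (ActuationConfig, EnvironmentConfig, SimulationConfig,
                      simulate)

#: Phase-noise SD of the robustness filter: 40% of the valid phase range.
DEFAULT_PHASE_NOISE_SD = 0.4 * math.pi


@dataclasses.dataclass
class RobustnessConfig:
    phase_noise_sd: float = DEFAULT_PHASE_NOISE_SD
    n_noise_samples: int = 25
    env: EnvironmentConfig = dataclasses.field(
        default_factory=EnvironmentConfig.aquatic)
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    act: ActuationConfig = dataclasses.field(default_factory=ActuationConfig)

    def validate(self) -> None:
        if self.phase_noise_sd <= 0:
            raise ConfigurationError("phase_noise_sd must be positive")
        if self.n_noise_samples < 2:
            raise ConfigurationError("need at least 2 noise samples")


@dataclasses.dataclass
class BuildFilterConfig:
    max_muscle_fraction: float = 0.5
    min_concavity_fraction: float = 0.12
    #: Physical anchor of the concavity rule: 100 um at build scale
    #: corresponds to 12% of total body length.
    reference_concavity_um: float = 100.0

    def validate(self) -> None:
        if not (0 < self.max_muscle_fraction < 1):
            raise ConfigurationError("max_muscle_fraction must be in (0,1)")
        if not (0 < self.min_concavity_fraction < 1):
            raise ConfigurationError("min_concavity_fraction must be in (0,1)")


@dataclasses.dataclass
class FilterEntry:
    """Per-design screening record."""

    design_id: str
    mean_displacement: float = float("nan")
    sd_displacement: float = float("nan")
    rank: int = 0
    muscle_fraction: float = float("nan")
    min_concavity_fraction: Optional[float] = None  # None = no concavity
    passed: bool = False
    reasons: tuple = ()
    displacements: tuple = ()


# ---------------------------------------------------------------------------
# Robustness filter
# ---------------------------------------------------------------------------


def perturb_phases(phases: np.ndarray, rng: np.random.Generator,
                   sd: float = DEFAULT_PHASE_NOISE_SD) -> np.ndarray:
    """Add Gaussian phase noise (mean 0, SD ``sd``), clipped to +-pi/2.

    The input array is left untouched; clipping (rather than resampling)
    means large SDs pile perturbed phases up against the bounds.
    """
    if sd <= 0:
        raise ConfigurationError("phase-noise SD must be positive")
    noise = rng.normal(0.0, sd, size=phases.shape)
    return np.clip(phases + noise, -PHASE_BOUND, PHASE_BOUND)


def robustness_rank(designs: Sequence[VoxelDesign],
                    cfg: Optional[RobustnessConfig] = None,
                    seed: int = 0,
                    log: Optional[list] = None) -> List[FilterEntry]:
    """Rank designs by mean net displacement under actuation noise.

    Each design is simulated ``n_noise_samples`` times; sample ``j`` uses
    the same noise seed for every design so the comparison is paired.
    Ranking is by mean displacement descending, ties broken by lower
    displacement SD, then by input order. An unstable sample scores zero
    displacement (and is logged) rather than aborting the ranking.
    """
    cfg = cfg or RobustnessConfig()
    cfg.validate()
    sample_seeds = np.random.default_rng(int(seed)).integers(
        0, 2**31 - 1, size=cfg.n_noise_samples)
    entries = []
    for idx, design in enumerate(designs):
        disps = []
        for j, s in enumerate(sample_seeds):
            try:
                res = simulate(design, cfg.env, cfg.sim, cfg.act, seed=int(s),
                               phase_noise_sd=cfg.phase_noise_sd)
                disps.append(res.net_displacement)
            except SimulationUnstableError:
                disps.append(0.0)
                if log is not None:
                    log.append(f"unstable: design={design.name or idx} "
                               f"sample={j} seed={int(s)}")
        disps = np.asarray(disps)
        sd = float(disps.std(ddof=1)) if len(disps) > 1 else 0.0
        entries.append(FilterEntry(
            design_id=design.name or str(idx),
            mean_displacement=float(disps.mean()),
            sd_displacement=sd,
            displacements=tuple(disps),
        ))
    order = sorted(range(len(entries)),
                   key=lambda i: (-entries[i].mean_displacement,
                                  entries[i].sd_displacement, i))
    ranked = [entries[i] for i in order]
    for r, e in enumerate(ranked, start=1):
        e.rank = r
    return ranked


# ---------------------------------------------------------------------------
# Build filter
# ---------------------------------------------------------------------------


def muscle_fraction(design: VoxelDesign) -> float:
    """Contractile voxels as a fraction of all non-empty voxels."""
    n_body = int((design.grid != EMPTY).sum())
    if n_body == 0:
        raise ContractViolationError("design has no tissue")
    return float((design.grid == CONTRACTILE).sum()) / n_body


_BOX = ndimage.generate_binary_structure(3, 3)  # 3x3x3 cube


def _box_closing(occ: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a cube of half-width ``radius``.

    On a voxel lattice the cube is the natural isotropic structuring
    element: unlike a discretized sphere it has no corner-rounding
    artifacts, so a rectangular gap of width w closes exactly when
    2*radius >= w — the behavior the concavity rule measures.
    """
    dilated = ndimage.binary_dilation(occ, _BOX, iterations=radius)
    return ndimage.binary_erosion(dilated, _BOX, iterations=radius)


def concave_regions(design_or_mask) -> np.ndarray:
    """Boolean mask of concave space: closing-to-convergence minus body.

    The occupancy volume is closed with cubes of growing half-width (up
    to half the largest grid extent, so arbitrarily wide gaps can be
    bridged); the union of all closings, minus the body itself, is the
    concave space that surrounding tissue could seal off.
    """
    if isinstance(design_or_mask, VoxelDesign):
        occ = design_or_mask.grid != EMPTY
    else:
        occ = np.asarray(design_or_mask, dtype=bool)
    r_max = max(occ.shape) // 2 + 1
    pad = r_max + 2
    padded = np.pad(occ, pad)
    closed = padded.copy()
    for r in range(1, r_max + 1):
        closed |= _box_closing(padded, r)
    core = tuple(slice(pad, pad + n) for n in occ.shape)
    return closed[core] & ~occ


def min_concavity_width(design_or_mask) -> Optional[float]:
    """Narrowest concavity as a fraction of body length, or None.

    Each face-connected concave region is measured by the smallest
    axis-aligned extent of its bounding box (the width of the gap); body
    length is the largest occupancy extent over the three axes. Returns
    the minimum width/body-length ratio, or None when the shape has no
    concavity (closing adds nothing).
    """
    if isinstance(design_or_mask, VoxelDesign):
        occ = design_or_mask.grid != EMPTY
    else:
        occ = np.asarray(design_or_mask, dtype=bool)
    concave = concave_regions(occ)
    if not concave.any():
        return None
    n, labels = face_connected_components(concave)
    body_idx = np.argwhere(occ)
    body_length = int((body_idx.max(axis=0) - body_idx.min(axis=0) + 1).max())
    widths = []
    for region in ndimage.find_objects(labels):
        extents = [sl.stop - sl.start for sl in region]
        widths.append(min(extents))
    return float(min(widths)) / float(body_length)


def build_filter(designs: Sequence[VoxelDesign],
                 cfg: Optional[BuildFilterConfig] = None,
                 entries: Optional[List[FilterEntry]] = None) -> List[FilterEntry]:
    """Apply the manufacturability screen, preserving input order.

    A design passes iff its muscle fraction does not exceed the maximum
    (exactly 50% still passes) and it either has no concavity or its
    narrowest concavity is at least the minimum fraction of body length.
    Every decision carries machine-readable reason codes.
    """
    cfg = cfg or BuildFilterConfig()
    cfg.validate()
    if entries is None:
        entries = [FilterEntry(design_id=d.name or str(i))
                   for i, d in enumerate(designs)]
    if len(entries) != len(designs):
        raise ContractViolationError("entries and designs length mismatch")
    for design, entry in zip(designs, entries):
        reasons = []
        entry.muscle_fraction = muscle_fraction(design)
        if entry.muscle_fraction > cfg.max_muscle_fraction:
            reasons.append("muscle_fraction")
        entry.min_concavity_fraction = min_concavity_width(design)
        if (entry.min_concavity_fraction is not None
                and entry.min_concavity_fraction < cfg.min_concavity_fraction):
            reasons.append("concavity")
        entry.reasons = tuple(reasons)
        entry.passed = not reasons
    return list(entries)


def report_to_dataframe(entries: Sequence[FilterEntry]):
    """Flatten filter entries into the report CSV schema."""
    import pandas as pd

    return pd.DataFrame([{
        "design_id": e.design_id,
        "mean_disp": e.mean_displacement,
        "sd_disp": e.sd_displacement,
        "rank": e.rank,
        "muscle_fraction": e.muscle_fraction,
        "min_concavity_fraction": (float("nan")
                                   if e.min_concavity_fraction is None
                                   else e.min_concavity_fraction),
        "pass": e.passed,
        "reasons": ";".join(e.reasons),
    } for e in entries])
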