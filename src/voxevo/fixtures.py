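"""Canonical toy designs, constructed deterministically in code.

These cover every stage of the pipeline without downloads or stored
data: a convex passive block, a parameterized notched block for the
build filter, a ventral-driven two-legged walker that locomotes, a
transverse-plane-symmetric brick, and a 60%-muscle block that trips the
muscle-fraction rule.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError
from .genome import CONTRACTILE, EMPTY, PASSIVE, VoxelDesign


def solid_block(nx: int = 4, ny: int = 4, nz: int = 3) -> VoxelDesign:
    """Convex all-passive rectangular block."""
    grid = np.full((nx, ny, nz), PASSIVE, dtype=np.int8)
    return VoxelDesign(grid, np.zeros(grid.shape), name="solid_block")


def notched_block(length: int = 10, width: int = 4, height: int = 5,
                  notch_width: int = 1, notch_depth: int = 2) -> VoxelDesign:
    """Passive block with a notch of given width cut into the top face.

    The notch runs the full transverse width; its along-body width (in
    voxels) divided by the body length is what the build filter's
    concavity rule measures.
    """
    if notch_width >= length or notch_depth >= height:
        raise ConfigurationError("notch must be smaller than the body")
    grid = np.full((length, width, height), PASSIVE, dtype=np.int8)
    x0 = (length - notch_width) // 2
    grid[x0:x0 + notch_width, :, height - notch_depth:] = EMPTY
    return VoxelDesign(grid, np.zeros(grid.shape),
                       name=f"notched_block_{notch_width}")


def walker(length: int = 6, width: int = 4, leg_height: int = 2,
           body_height: int = 2) -> VoxelDesign:
    """Ventral-driven walker: passive slab on two antiphase contractile legs.

    Two full-width contractile legs (front and rear) sit under a passive
    body slab; the legs actuate pi radians apart (+pi/2 and -pi/2), the
    largest separation the valid phase range allows, producing a rocking
    gait. The design is mirror-symmetric about its x-z midplane, so any
    net motion is along x.
    """
    nz = leg_height + body_height
    grid = np.full((length, width, nz), EMPTY, dtype=np.int8)
    grid[:, :, leg_height:] = PASSIVE                      # body slab
    grid[:2, :, :leg_height] = CONTRACTILE                 # front leg
    grid[-2:, :, :leg_height] = CONTRACTILE                # rear leg
    phases = np.zeros(grid.shape)
    phases[:2, :, :leg_height] = math.pi / 2
    phases[-2:, :, :leg_height] = -math.pi / 2
    return VoxelDesign(grid, phases, name="walker")


def symmetric_brick(nx: int = 4, ny: int = 3, nz: int = 3) -> VoxelDesign:
    """Transverse-plane-symmetric brick: inversion leaves it unchanged.

    Passive shell with a zero-phase contractile middle layer; the layout
    and phases are mirror-symmetric about the horizontal mid-plane.
    """
    grid = np.full((nx, ny, nz), PASSIVE, dtype=np.int8)
    grid[:, :, nz // 2] = CONTRACTILE
    phases = np.zeros(grid.shape)
    return VoxelDesign(grid, phases, name="symmetric_brick")


def muscle_heavy() -> VoxelDesign:
    """Convex block that is 60% contractile (fails the 50%-muscle rule)."""
    grid = np.full((5, 2, 1), PASSIVE, dtype=np.int8)
    flat = grid.reshape(-1)
    flat[:6] = CONTRACTILE
    return VoxelDesign(grid, np.zeros(grid.shape), name="muscle_heavy")


_FIXTURES = {
    "solid_block": solid_block,
    "notched_block": notched_block,
    "walker": walker,
    "symmetric_brick": symmetric_brick,
    "muscle_heavy": muscle_heavy,
}


def make_fixture(name: str, **params) -> VoxelDesign:
    """Construct a named fixture design; raises listing known names."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return builder(**params)


def fixture_names():
    return sorted(_FIXTURES)
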