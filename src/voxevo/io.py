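"""Text formats for designs, genomes, trajectories and reports.

Conventions (stated in every file header): 0-based voxel indices,
x-fastest serialization order, z axis up, ground plane at z = 0.

Design format v1: a header (resolution, voxel size, version), one
integer tissue label per voxel (0 empty, 1 passive, 2 contractile) in
x-fastest order, and a parallel phase block in radians to 6 decimal
places (0 at non-contractile sites). Round-tripping is exact for grids
and exact to 6 decimals for phases.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .errors import DesignParseError
from .genome import (CONTRACTILE, EMPTY, PASSIVE, PHASE_BOUND, FieldNode,
                     Genome, VoxelDesign)

FORMAT_VERSION = 1

_HEADER_COMMENT = ("# voxevo voxel design; 0-based indices, x-fastest order, "
                   "z up, ground plane z=0")


def _flatten_x_fastest(arr: np.ndarray) -> np.ndarray:
    # x-fastest = Fortran order for (x, y, z)-indexed arrays.
    return arr.reshape(-1, order="F")


def _unflatten_x_fastest(flat: np.ndarray, shape) -> np.ndarray:
    return np.asarray(flat).reshape(shape, order="F")


def write_design(design: VoxelDesign, path) -> None:
    """Write a design in the versioned text format."""
    path = Path(path)
    lines = [_HEADER_COMMENT,
             f"version {FORMAT_VERSION}",
             f"resolution {design.grid.shape[0]} {design.grid.shape[1]} "
             f"{design.grid.shape[2]}",
             f"voxel_size {design.voxel_size!r}",
             "tissues"]
    labels = _flatten_x_fastest(design.grid)
    for row in range(0, labels.size, design.grid.shape[0]):
        lines.append(" ".join(str(int(v))
                              for v in labels[row:row + design.grid.shape[0]]))
    lines.append("phases")
    phases = _flatten_x_fastest(design.phases)
    for row in range(0, phases.size, design.grid.shape[0]):
        lines.append(" ".join(f"{v:.6f}"
                              for v in phases[row:row + design.grid.shape[0]]))
    path.write_text("\n".join(lines) + "\n")


def read_design(path) -> VoxelDesign:
    """Read a design file, validating version, labels, phases and shape."""
    path = Path(path)
    raw = path.read_text().splitlines()
    tokens = []  # (line_number, list of fields), comments stripped
    for ln, line in enumerate(raw, start=1):
        line = line.strip()
        if line and not line.startswith("#"):
            tokens.append((ln, line.split()))

    def fail(ln, msg):
        raise DesignParseError(f"{path.name}:{ln}: {msg}")

    idx = 0

    def expect(keyword):
        nonlocal idx
        if idx >= len(tokens) or tokens[idx][1][0] != keyword:
            ln = tokens[idx][0] if idx < len(tokens) else len(raw)
            fail(ln, f"expected {keyword!r}")
        ln, fields = tokens[idx]
        idx += 1
        return ln, fields[1:]

    ln, fields = expect("version")
    if fields != [str(FORMAT_VERSION)]:
        fail(ln, f"unsupported version {' '.join(fields)}")
    ln, fields = expect("resolution")
    try:
        shape = tuple(int(v) for v in fields)
    except ValueError:
        fail(ln, "resolution must be three integers")
    if len(shape) != 3 or any(n < 1 for n in shape):
        fail(ln, f"bad resolution {shape}")
    ln, fields = expect("voxel_size")
    try:
        voxel_size = float(fields[0])
    except (IndexError, ValueError):
        fail(ln, "voxel_size must be a number")
    n_total = shape[0] * shape[1] * shape[2]

    def read_block(keyword, parse, n_expected):
        expect(keyword)
        nonlocal idx
        values, lns = [], []
        while idx < len(tokens) and len(values) < n_expected:
            ln, fields = tokens[idx]
            if fields[0] in ("tissues", "phases"):
                break
            for f in fields:
                try:
                    values.append(parse(f))
                except ValueError:
                    fail(ln, f"bad {keyword} value {f!r}")
                lns.append(ln)
            idx += 1
        if len(values) != n_expected:
            fail(tokens[idx - 1][0] if idx else len(raw),
                 f"{keyword}: expected {n_expected} values, got {len(values)}")
        return values, lns

    labels, label_lines = read_block("tissues", int, n_total)
    for v, ln in zip(labels, label_lines):
        if v not in (EMPTY, PASSIVE, CONTRACTILE):
            fail(ln, f"tissue label {v} outside {{0,1,2}}")
    phases, phase_lines = read_block("phases", float, n_total)
    for v, ln in zip(phases, phase_lines):
        if abs(v) > PHASE_BOUND + 1e-6:
            fail(ln, f"phase {v} outside +-pi/2")

    grid = _unflatten_x_fastest(np.asarray(labels, dtype=np.int8), shape)
    phase_arr = _unflatten_x_fastest(np.asarray(phases, dtype=float), shape)
    return VoxelDesign(grid=grid, phases=phase_arr, voxel_size=voxel_size,
                       name=path.stem)


# ---------------------------------------------------------------------------
# Genome serialization (full float precision: development must round-trip
# bit-identically)
# ---------------------------------------------------------------------------


def write_genome(genome: Genome, path) -> None:
    path = Path(path)
    ws = genome.phase_grid.shape
    lines = ["# voxevo genome",
             f"version {FORMAT_VERSION}",
             f"clade_id {genome.clade_id}",
             f"age {genome.age}",
             f"workspace {ws[0]} {ws[1]} {ws[2]}",
             f"presence_bias {genome.presence_bias!r}",
             f"tissue_bias {genome.tissue_bias!r}"]
    for kind, nodes in (("presence", genome.presence_nodes),
                        ("tissue", genome.tissue_nodes)):
        for n in nodes:
            lines.append(f"{kind}_node {n.func} {n.w!r} {n.a!r} {n.b!r} "
                         f"{n.c!r} {n.d!r}")
    for (i, j, k), label in sorted(genome.overrides.items()):
        lines.append(f"override {i} {j} {k} {label}")
    lines.append("phases")
    flat = _flatten_x_fastest(genome.phase_grid)
    lines.extend(repr(float(v)) for v in flat)
    path.write_text("\n".join(lines) + "\n")


def read_genome(path) -> Genome:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    fields = {"presence_node": [], "tissue_node": [], "override": []}
    scalars = {}
    phases = []
    in_phases = False
    for ln_no, line in enumerate(lines, start=1):
        parts = line.split()
        if in_phases:
            phases.extend(float(v) for v in parts)
        elif parts[0] == "phases":
            in_phases = True
        elif parts[0] in fields:
            fields[parts[0]].append(parts[1:])
        else:
            scalars[parts[0]] = parts[1:]
    try:
        ws = tuple(int(v) for v in scalars["workspace"])
        genome = Genome(
            presence_bias=float(scalars["presence_bias"][0]),
            presence_nodes=[FieldNode(p[0], *(float(v) for v in p[1:]))
                            for p in fields["presence_node"]],
            tissue_bias=float(scalars["tissue_bias"][0]),
            tissue_nodes=[FieldNode(p[0], *(float(v) for v in p[1:]))
                          for p in fields["tissue_node"]],
            phase_grid=_unflatten_x_fastest(np.asarray(phases), ws),
            clade_id=int(scalars["clade_id"][0]),
            age=int(scalars["age"][0]),
            overrides={(int(p[0]), int(p[1]), int(p[2])): int(p[3])
                       for p in fields["override"]},
        )
    except (KeyError, IndexError, ValueError) as exc:
        raise DesignParseError(f"{path.name}: malformed genome file ({exc})")
    return genome


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------


def write_trajectory(result, path) -> None:
    """Write a SimResult as CSV with all configuration in '#' header lines."""
    path = Path(path)
    header = [_HEADER_COMMENT]
    for key, val in sorted(result.meta.items()):
        header.append(f"# {key} = {val!r}")
    df = result.to_dataframe()
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trajectory(path):
    """Read a trajectory CSV back into a DataFrame (header comments skipped)."""
    import pandas as pd

    return pd.read_csv(path, comment="#")
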