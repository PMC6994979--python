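"""Scale-free generative genomes for voxel-based soft-bodied organisms.

A genome encodes two deterministic scalar fields over the normalized body
cube [0, 1]^3 — one deciding voxel *presence*, one deciding *tissue type*
(passive vs. contractile) — plus a per-workspace-location phase offset
that shifts each contractile voxel's timing relative to a global central
pattern generator. Because the fields are functions of continuous
coordinates, the same genome can be developed at any grid resolution
while preserving geometry (the encoding is scale-free).

Each field is a small composition graph: a bias plus a weighted sum of
primitive nodes (linear ramp, sine, absolute value, Gaussian bump of
radial distance). Development thresholds the presence field at zero,
prunes everything but the largest face-connected component, and labels
surviving voxels contractile where the tissue field is positive.

Phase offsets live on a fixed *workspace* grid, are sampled uniformly in
[-pi/2, pi/2] when a new genetic lineage (clade) is founded, and — in
second-pass mode — are inherited unchanged by every descendant: mutation
only rewires the body, never its clock.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidDesignError, MutationFailureError

# Tissue alphabet.
EMPTY = 0
PASSIVE = 1
CONTRACTILE = 2

#: Valid phase offsets span [-PHASE_BOUND, PHASE_BOUND] radians.
PHASE_BOUND = math.pi / 2.0

#: Default working resolution of the evolutionary workspace.
DEFAULT_WORKSPACE = (8, 8, 7)

_PRIMITIVES = ("linear", "sin", "abs", "gauss")

# 6-connectivity (shared faces only) for component analysis.
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenomeConfig:
    """Knobs of the generative encoding.

    Parameters
    ----------
    primitives
        Primitive function set available to field graphs.
    min_nodes, max_nodes
        Bounds on the number of primitive nodes per field graph.
    workspace
        Resolution of the phase-offset workspace grid (and the default
        working resolution of the evolutionary search).
    encoding
        ``"generative"`` mutates the field graphs; ``"direct"`` mutates
        individual workspace voxels via override entries.
    mutation_retries
        How many mutation attempts may be made before giving up on
        producing a phenotypic change.
    coef_sigma
        Standard deviation of Gaussian coefficient perturbations.
    phase_mutation_sd, phase_mutation_prob
        First-pass-only phase mutation: with probability
        ``phase_mutation_prob`` every workspace phase receives additive
        Gaussian noise of this SD, clipped to the valid bounds.
    """

    primitives: tuple = _PRIMITIVES
    min_nodes: int = 2
    max_nodes: int = 6
    workspace: tuple = DEFAULT_WORKSPACE
    encoding: str = "generative"
    mutation_retries: int = 50
    coef_sigma: float = 0.3
    phase_mutation_sd: float = 0.1 * math.pi
    phase_mutation_prob: float = 0.5
    presence_bias_mean: float = 0.2

    def validate(self) -> None:
        if not self.primitives:
            raise ConfigurationError("primitive set must not be empty")
        for p in self.primitives:
            if p not in _PRIMITIVES:
                raise ConfigurationError(f"unknown primitive {p!r}")
        if not (1 <= self.min_nodes <= self.max_nodes):
            raise ConfigurationError("need 1 <= min_nodes <= max_nodes")
        if self.encoding not in ("generative", "direct"):
            raise ConfigurationError(f"unknown encoding {self.encoding!r}")
        if any(n < 1 for n in self.workspace) or len(self.workspace) != 3:
            raise ConfigurationError("workspace must be three positive ints")


@dataclasses.dataclass
class FieldNode:
    """One primitive node of a scalar-field composition graph."""

    func: str
    w: float  # output weight
    a: float  # x coefficient / Gaussian center x
    b: float  # y coefficient / Gaussian center y
    c: float  # z coefficient / Gaussian center z
    d: float  # offset / Gaussian width


@dataclasses.dataclass(eq=False)
class Genome:
    """Generative genotype: two field graphs plus a clade phase grid."""

    presence_bias: float
    presence_nodes: list
    tissue_bias: float
    tissue_nodes: list
    phase_grid: np.ndarray  # radians, shape = workspace, in [-pi/2, pi/2]
    clade_id: int
    age: int = 0
    # Direct-encoding layer: workspace index -> tissue label override.
    overrides: dict = dataclasses.field(default_factory=dict)

    def copy(self) -> "Genome":
        return Genome(
            presence_bias=self.presence_bias,
            presence_nodes=[dataclasses.replace(n) for n in self.presence_nodes],
            tissue_bias=self.tissue_bias,
            tissue_nodes=[dataclasses.replace(n) for n in self.tissue_nodes],
            phase_grid=self.phase_grid.copy(),
            clade_id=self.clade_id,
            age=self.age,
            overrides=dict(self.overrides),
        )


@dataclasses.dataclass(eq=False)
class VoxelDesign:
    """The phenotype: a 3D grid of tissue labels plus a phase field.

    ``grid`` holds labels from {EMPTY, PASSIVE, CONTRACTILE}; ``phases``
    is a parallel array of CPG phase offsets in radians, zero wherever
    the voxel is not contractile.
    """

    grid: np.ndarray
    phases: np.ndarray
    voxel_size: float = 1.0
    name: str = ""

    @property
    def resolution(self) -> tuple:
        return tuple(self.grid.shape)

    @property
    def is_empty(self) -> bool:
        return not bool((self.grid != EMPTY).any())

    @property
    def n_voxels(self) -> int:
        return int((self.grid != EMPTY).sum())

    def copy(self) -> "VoxelDesign":
        return VoxelDesign(self.grid.copy(), self.phases.copy(),
                           self.voxel_size, self.name)

    def same_as(self, other: "VoxelDesign") -> bool:
        return (self.grid.shape == other.grid.shape
                and bool(np.array_equal(self.grid, other.grid))
                and bool(np.array_equal(self.phases, other.phases)))

    def validate(self) -> None:
        if self.grid.shape != self.phases.shape:
            raise InvalidDesignError("grid and phase field shapes differ")
        labels = np.unique(self.grid)
        if not np.isin(labels, (EMPTY, PASSIVE, CONTRACTILE)).all():
            raise InvalidDesignError(f"labels outside alphabet: {labels}")
        if self.is_empty:
            raise InvalidDesignError("design has no tissue")
        if np.abs(self.phases).max() > PHASE_BOUND + 1e-9:
            raise InvalidDesignError("phase offset outside +-pi/2")
        n, _ = face_connected_components(self.grid != EMPTY)
        if n != 1:
            raise InvalidDesignError(f"{n} face-connected components (need 1)")


def face_connected_components(mask: np.ndarray):
    """Label face-connected (6-neighborhood) components of a boolean mask."""
    labels, n = ndimage.label(mask, structure=_FACE_STRUCTURE)
    return n, labels


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------


def _eval_field(bias: float, nodes: list, x: np.ndarray, y: np.ndarray,
                z: np.ndarray) -> np.ndarray:
    out = np.full(x.shape, bias, dtype=np.float64)
    for n in nodes:
        if n.func == "gauss":
            r2 = (x - n.a) ** 2 + (y - n.b) ** 2 + (z - n.c) ** 2
            width = max(abs(n.d), 0.05)
            out += n.w * np.exp(-r2 / (2.0 * width * width))
        else:
            g = n.a * x + n.b * y + n.c * z + n.d
            if n.func == "linear":
                out += n.w * g
            elif n.func == "sin":
                out += n.w * np.sin(g)
            elif n.func == "abs":
                out += n.w * np.abs(g)
            else:  # pragma: no cover - guarded by config validation
                raise ConfigurationError(f"unknown primitive {n.func!r}")
    return out


def _voxel_centers(resolution):
    nx, ny, nz = resolution
    xs = (np.arange(nx) + 0.5) / nx
    ys = (np.arange(ny) + 0.5) / ny
    zs = (np.arange(nz) + 0.5) / nz
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _workspace_index(resolution, workspace):
    """Map each voxel center of `resolution` to its workspace cell."""
    idx = []
    for n, w in zip(resolution, workspace):
        u = (np.arange(n) + 0.5) / n
        idx.append(np.minimum((u * w).astype(np.int64), w - 1))
    return np.meshgrid(*idx, indexing="ij")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _random_node(rng: np.random.Generator, config: GenomeConfig) -> FieldNode:
    func = str(rng.choice(config.primitives))
    if func == "gauss":
        return FieldNode(func, w=float(rng.normal(0, 1)),
                         a=float(rng.uniform(0, 1)), b=float(rng.uniform(0, 1)),
                         c=float(rng.uniform(0, 1)),
                         d=float(rng.uniform(0.1, 0.5)))
    # Coefficient scale ~3 keeps spatial features coarse enough that the
    # phenotype boundary occupies only a few percent of the grid, so the
    # same genome developed at doubled resolution stays geometry-consistent.
    return FieldNode(func, w=float(rng.normal(0, 1)),
                     a=float(rng.normal(0, 3)), b=float(rng.normal(0, 3)),
                     c=float(rng.normal(0, 3)), d=float(rng.normal(0, 1)))


def random_genome(seed: int, config: Optional[GenomeConfig] = None,
                  clade_id: Optional[int] = None) -> Genome:
    """Sample a fresh random genome founding a new clade.

    Presence and tissue field graphs are drawn independently; the phase
    grid is sampled uniformly over the valid [-pi/2, pi/2] range at every
    workspace location and is thereafter immutable in second-pass mode.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_pres = int(rng.integers(config.min_nodes, config.max_nodes + 1))
    n_tis = int(rng.integers(config.min_nodes, config.max_nodes + 1))
    genome = Genome(
        presence_bias=float(rng.normal(config.presence_bias_mean, 0.6)),
        presence_nodes=[_random_node(rng, config) for _ in range(n_pres)],
        tissue_bias=float(rng.normal(0.0, 0.6)),
        tissue_nodes=[_random_node(rng, config) for _ in range(n_tis)],
        phase_grid=rng.uniform(-PHASE_BOUND, PHASE_BOUND, size=config.workspace),
        clade_id=int(seed if clade_id is None else clade_id),
        age=0,
    )
    return genome


def develop(genome: Genome, resolution=None,
            config: Optional[GenomeConfig] = None) -> VoxelDesign:
    """Develop a genome into a voxel phenotype at the given resolution.

    A voxel is present iff the presence field is strictly positive at its
    normalized center (ties break to EMPTY), contractile iff the tissue
    field is strictly positive there (ties break to PASSIVE). All but the
    largest face-connected component are pruned to EMPTY. Phases are read
    from the clade phase grid at the matching normalized coordinates.
    """
    config = config or GenomeConfig(workspace=genome.phase_grid.shape)
    resolution = tuple(resolution or config.workspace)
    if any(n < 1 for n in resolution):
        raise ConfigurationError(f"resolution must be >= 1 per axis: {resolution}")
    x, y, z = _voxel_centers(resolution)
    present = _eval_field(genome.presence_bias, genome.presence_nodes,
                          x, y, z) > 0.0
    contractile = _eval_field(genome.tissue_bias, genome.tissue_nodes,
                              x, y, z) > 0.0

    wi, wj, wk = _workspace_index(resolution, genome.phase_grid.shape)
    if genome.overrides:
        override = np.full(genome.phase_grid.shape, -1, dtype=np.int8)
        for key, label in genome.overrides.items():
            override[key] = label
        ov = override[wi, wj, wk]
        present = np.where(ov >= 0, ov != EMPTY, present)
        contractile = np.where(ov >= 0, ov == CONTRACTILE, contractile)

    # Keep only the largest face-connected component.
    n, labels = face_connected_components(present)
    if n > 1:
        sizes = ndimage.sum_labels(present, labels, index=np.arange(1, n + 1))
        present = labels == (1 + int(np.argmax(sizes)))
    grid = np.where(present,
                    np.where(contractile, CONTRACTILE, PASSIVE),
                    EMPTY).astype(np.int8)
    phases = np.where(grid == CONTRACTILE,
                      genome.phase_grid[wi, wj, wk], 0.0)
    return VoxelDesign(grid=grid, phases=phases)


def _mutate_graph(child: Genome, rng: np.random.Generator,
                  config: GenomeConfig) -> None:
    """Perturb one primitive node or coefficient of one field graph."""
    if rng.random() < 0.5:
        nodes, bias_attr = child.presence_nodes, "presence_bias"
    else:
        nodes, bias_attr = child.tissue_nodes, "tissue_bias"
    ops = ["perturb", "perturb", "add", "remove"]
    op = ops[int(rng.integers(len(ops)))]
    if op == "add" and len(nodes) < config.max_nodes:
        nodes.insert(int(rng.integers(len(nodes) + 1)), _random_node(rng, config))
    elif op == "remove" and len(nodes) > config.min_nodes:
        nodes.pop(int(rng.integers(len(nodes))))
    else:
        k = int(rng.integers(len(nodes) + 1))
        if k == len(nodes):
            setattr(child, bias_attr,
                    getattr(child, bias_attr) + float(rng.normal(0, config.coef_sigma)))
        else:
            node = nodes[k]
            coef = ("w", "a", "b", "c", "d")[int(rng.integers(5))]
            val = getattr(node, coef) + float(rng.normal(0, config.coef_sigma))
            if node.func == "gauss" and coef == "d":
                val = max(abs(val), 0.05)
            setattr(node, coef, val)


def _mutate_direct(child: Genome, rng: np.random.Generator,
                   config: GenomeConfig) -> None:
    """Switch one workspace voxel to a different tissue label."""
    ws = child.phase_grid.shape
    key = tuple(int(rng.integers(n)) for n in ws)
    if key in child.overrides:
        current = child.overrides[key]
    else:
        base = develop(child, resolution=ws, config=config)
        current = int(base.grid[key])
    choices = [lbl for lbl in (EMPTY, PASSIVE, CONTRACTILE) if lbl != current]
    child.overrides[key] = int(choices[int(rng.integers(len(choices)))])


def mutate(genome: Genome, rng: np.random.Generator, mode: str = "second_pass",
           config: Optional[GenomeConfig] = None, resolution=None) -> Genome:
    """Return a mutated copy whose developed phenotype differs from the parent.

    Structure is always mutated (field graph in generative encoding, one
    voxel switch in direct encoding), resampling up to the configured
    retry budget until the phenotype at the working resolution changes in
    at least one voxel. In ``second_pass`` mode the clade phase grid is
    copied bit-for-bit; in ``first_pass`` mode phases may additionally
    receive clipped Gaussian perturbations. Clade identity and age are
    preserved.
    """
    if mode not in ("first_pass", "second_pass"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    config = config or GenomeConfig(workspace=genome.phase_grid.shape)
    resolution = tuple(resolution or config.workspace)
    parent_pheno = develop(genome, resolution, config)
    for _ in range(config.mutation_retries):
        child = genome.copy()
        if config.encoding == "direct":
            _mutate_direct(child, rng, config)
        else:
            _mutate_graph(child, rng, config)
        if mode == "first_pass" and rng.random() < config.phase_mutation_prob:
            noise = rng.normal(0.0, config.phase_mutation_sd,
                               size=child.phase_grid.shape)
            child.phase_grid = np.clip(child.phase_grid + noise,
                                       -PHASE_BOUND, PHASE_BOUND)
        child_pheno = develop(child, resolution, config)
        if not np.array_equal(child_pheno.grid, parent_pheno.grid):
            return child
    raise MutationFailureError(
        f"no phenotypic change after {config.mutation_retries} attempts")
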