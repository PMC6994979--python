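"""Robustness ranking and the manufacturability (build) filter."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import voxevo as V
from voxevo.errors import ConfigurationError, ContractViolationError
from voxevo.filters import concave_regions, report_to_dataframe


class TestPerturbPhases:
    def test_small_sd_limit_barely_moves_phases(self, rng):
        phases = np.zeros((4, 4, 4))
        out = V.perturb_phases(phases, rng, sd=1e-12)
        assert np.allclose(out, phases, atol=1e-10)
        assert out is not phases

    def test_input_untouched_and_bounded(self, rng):
        phases = np.linspace(-V.PHASE_BOUND, V.PHASE_BOUND, 64).reshape(4, 4, 4)
        before = phases.copy()
        out = V.perturb_phases(phases, rng, sd=math.pi)
        assert np.array_equal(phases, before)
        assert np.abs(out).max() <= V.PHASE_BOUND

    def test_additive_noise_sd_matches_configuration(self):
        """Monte-Carlo check of the sampler: pre-clip draws have SD 0.4*pi.

        Perturbing zero phases with a tiny fraction of the nominal SD
        avoids clipping, so the sample SD estimates the sampler's SD
        directly; scaling back up verifies the 0.4*pi configuration.
        """
        sd = 0.4 * math.pi
        rng = np.random.default_rng(0)
        scale = 1e-3  # keeps draws far from the +-pi/2 clip bounds
        out = V.perturb_phases(np.zeros(100_000), rng, sd=sd * scale)
        assert out.std() / scale == pytest.approx(sd, rel=0.01)

    def test_boundary_mass_grows_with_sd(self):
        phases = np.zeros(20_000)
        masses = []
        for sd in (0.1 * math.pi, 0.4 * math.pi, math.pi):
            out = V.perturb_phases(phases, np.random.default_rng(1), sd=sd)
            masses.append((np.abs(out) >= V.PHASE_BOUND - 1e-12).mean())
        assert masses[0] < masses[1] < masses[2]

    def test_nonpositive_sd_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            V.perturb_phases(np.zeros(3), rng, sd=0.0)


class TestRobustnessRank:
    def _cfg(self):
        return V.RobustnessConfig(
            n_noise_samples=3,
            env=V.EnvironmentConfig.aquatic(),
            sim=V.SimulationConfig(settle_time=0.3, eval_time=1.0))

    def test_singleton_gets_rank_one(self, solid_block):
        entries = V.robustness_rank([solid_block], self._cfg(), seed=0)
        assert entries[0].rank == 1

    def test_no_contractile_design_is_noise_invariant(self, solid_block):
        entries = V.robustness_rank([solid_block], self._cfg(), seed=0)
        assert entries[0].sd_displacement == pytest.approx(0.0, abs=1e-12)

    def test_ranking_matches_recomputed_means(self, walker, solid_block):
        entries = V.robustness_rank([solid_block, walker], self._cfg(), seed=3)
        means = {e.design_id: np.mean(e.displacements) for e in entries}
        assert entries[0].mean_displacement >= entries[1].mean_displacement
        for e in entries:
            assert e.mean_displacement == pytest.approx(means[e.design_id])
        assert sorted(e.rank for e in entries) == [1, 2]

    def test_permutation_invariance_up_to_ties(self, walker, solid_block):
        a = V.robustness_rank([solid_block, walker], self._cfg(), seed=3)
        b = V.robustness_rank([walker, solid_block], self._cfg(), seed=3)
        assert [e.design_id for e in a] == [e.design_id for e in b]


class TestMuscleFraction:
    def test_all_passive(self, solid_block):
        assert V.muscle_fraction(solid_block) == 0.0

    @pytest.mark.parametrize("n_muscle,expected", [(4, 0.5), (5, 0.625)])
    def test_counts(self, n_muscle, expected):
        grid = np.full((8, 1, 1), V.PASSIVE, dtype=np.int8)
        grid[:n_muscle] = V.CONTRACTILE
        d = V.VoxelDesign(grid, np.zeros(grid.shape))
        assert V.muscle_fraction(d) == pytest.approx(expected)


def oracle_min_concavity(occ):
    """Independent fill-and-measure: dual-form closing, explicit distances.

    A voxel x is *excluded* from the closing with a cube of half-width r
    iff some cube center c within Chebyshev distance r of x fits wholly
    outside the body (all body voxels farther than r from c). Distances
    are computed by explicit point-pair enumeration — no morphology or
    distance-transform routines.
    """
    occ = np.asarray(occ, dtype=bool)
    r_max = max(occ.shape) // 2 + 1
    pad = r_max + 2
    padded = np.pad(occ, pad)
    coords = np.argwhere(np.ones_like(padded)).astype(float)
    occ_pts = np.argwhere(padded).astype(float)
    d_to_occ = cdist(coords, occ_pts,
                     metric="chebyshev").min(axis=1).reshape(padded.shape)
    closed = padded.copy()
    for r in range(1, r_max + 1):
        centers = np.argwhere(d_to_occ > r).astype(float)
        d_to_centers = cdist(coords, centers,
                             metric="chebyshev").min(axis=1).reshape(padded.shape)
        closed |= ~(d_to_centers <= r)
    core = tuple(slice(pad, pad + n) for n in occ.shape)
    concave = closed[core] & ~occ
    if not concave.any():
        return None
    from voxevo.genome import face_connected_components
    n, labels = face_connected_components(concave)
    widths = []
    for lbl in range(1, n + 1):
        idx = np.argwhere(labels == lbl)
        widths.append(int((idx.max(axis=0) - idx.min(axis=0) + 1).min()))
    body = np.argwhere(occ)
    body_length = int((body.max(axis=0) - body.min(axis=0) + 1).max())
    return min(widths) / body_length


class TestMinConcavityWidth:
    def test_convex_block_has_none(self, solid_block):
        assert V.min_concavity_width(solid_block) is None

    @pytest.mark.parametrize("notch_width,expected", [(1, 0.10), (2, 0.20)])
    def test_notched_block_widths(self, notch_width, expected):
        d = V.make_fixture("notched_block", notch_width=notch_width)
        assert V.min_concavity_width(d) == pytest.approx(expected)

    def test_matches_brute_force_oracle_on_single_notch_grids(self):
        """Exhaustive single-notch bodies up to 5x5x5 against the oracle."""
        cases = 0
        for (nx, ny, nz) in [(5, 3, 3), (5, 5, 3), (4, 4, 4), (5, 5, 5),
                             (5, 4, 2), (3, 3, 3)]:
            for w in range(1, nx - 1):
                for depth in range(1, nz):
                    for x0 in range(1, nx - w):
                        occ = np.ones((nx, ny, nz), dtype=bool)
                        occ[x0:x0 + w, :, nz - depth:] = False
                        got = V.min_concavity_width(occ)
                        want = oracle_min_concavity(occ)
                        assert got == pytest.approx(want), (
                            (nx, ny, nz), w, depth, x0)
                        cases += 1
        assert cases > 50


class TestBuildFilter:
    def test_passive_convex_block_passes(self, solid_block):
        entries = V.build_filter([solid_block])
        assert entries[0].passed and entries[0].reasons == ()

    def test_exactly_half_muscle_passes(self):
        grid = np.full((8, 1, 1), V.PASSIVE, dtype=np.int8)
        grid[:4] = V.CONTRACTILE
        d = V.VoxelDesign(grid, np.zeros(grid.shape))
        assert V.build_filter([d])[0].passed

    def test_muscle_heavy_fails_with_reason(self):
        entries = V.build_filter([V.make_fixture("muscle_heavy")])
        assert not entries[0].passed
        assert "muscle_fraction" in entries[0].reasons

    def test_narrow_notch_fails_wide_notch_passes(self):
        narrow = V.make_fixture("notched_block", notch_width=1)
        wide = V.make_fixture("notched_block", notch_width=2)
        entries = V.build_filter([narrow, wide])
        assert not entries[0].passed and "concavity" in entries[0].reasons
        assert entries[1].passed

    def test_muscled_notched_design_fails_on_concavity_only(self):
        d = V.make_fixture("notched_block", notch_width=1)
        n_body = d.n_voxels
        flat = d.grid.reshape(-1)
        body_idx = np.flatnonzero(flat != V.EMPTY)[:int(0.4 * n_body)]
        flat[body_idx] = V.CONTRACTILE
        entries = V.build_filter([d])
        assert not entries[0].passed
        assert entries[0].reasons == ("concavity",)

    def test_idempotent_and_order_preserving(self, solid_block, walker):
        designs = [walker, solid_block]
        once = V.build_filter(designs)
        twice = V.build_filter(designs)
        assert [e.design_id for e in once] == [e.design_id for e in twice]
        assert [e.passed for e in once] == [e.passed for e in twice]

    def test_report_dataframe_schema(self, solid_block):
        df = report_to_dataframe(V.build_filter([solid_block]))
        assert list(df.columns) == ["design_id", "mean_disp", "sd_disp",
                                    "rank", "muscle_fraction",
                                    "min_concavity_fraction", "pass", "reasons"]
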