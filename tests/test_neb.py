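"""NEB path optimization, climbing image, saddle verification."""

import numpy as np
import pytest

from catdesc.neb import (
    NEBConfig,
    NEBError,
    NEBPath,
    barrier_from_path,
    interpolate_path,
    locate_ts,
    neb_optimize,
    relocate_endpoints,
    verify_saddle,
)
from catdesc.pes_models import MullerBrown, SN2Surrogate


MB_CONFIG = NEBConfig(
    n_images=12, spring_k=50.0, max_force_tol=1e-3, max_iter=5000,
    dt_init=0.002, dt_max=0.02, max_step=0.02,
)


def mb_path_between(mb_stationary_points, i, j, config=MB_CONFIG):
    minima = mb_stationary_points["minima"]
    start = minima[i].location
    end = minima[j].location
    return neb_optimize(MullerBrown(), interpolate_path(start, end, config.n_images),
                        config)


class TestInterpolate:
    def test_even_spacing_and_exact_endpoints(self):
        path = interpolate_path((0.0, 0.0), (1.0, 0.0), 5)
        assert np.allclose(path.images[:, 0], [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)
        assert path.images[0].tolist() == [0.0, 0.0]
        assert path.images[-1].tolist() == [1.0, 0.0]
        spacings = np.linalg.norm(np.diff(path.images, axis=0), axis=1)
        assert np.ptp(spacings) < 1e-12

    def test_too_few_images_rejected(self):
        with pytest.raises(NEBError, match=">= 4"):
            interpolate_path((0, 0), (1, 0), 3)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(NEBError, match="differ"):
            interpolate_path((1, 1), (1, 1), 6)


class TestOptimize:
    def test_symmetric_sn2_finds_closed_form_barrier(self):
        """On the symmetric double well the climbing image must sit at the
        origin and the barrier equal V0 exactly (closed form)."""
        pes = SN2Surrogate(V0=15.4, asym=0.0, k=1.0, c=0.0)
        path = neb_optimize(pes, interpolate_path((-1, 0), (1, 0), 12), NEBConfig())
        assert path.converged
        i_ts = locate_ts(path)
        assert abs(path.images[i_ts][0]) < 1e-3
        assert barrier_from_path(path, "start") == pytest.approx(15.4, abs=1e-3)
        assert barrier_from_path(path, "end") == pytest.approx(15.4, abs=1e-3)

    @pytest.mark.parametrize("pair", [(2, 1), (0, 2)], ids=["C-B", "A-C"])
    def test_muller_brown_climber_hits_oracle_saddle(self, mb_stationary_points, pair):
        path = mb_path_between(mb_stationary_points, *pair)
        assert path.converged
        i_ts = locate_ts(path)
        loc = path.images[i_ts]
        # the relevant oracle saddle is the one nearest the converged climber
        saddle = min(
            mb_stationary_points["saddles"],
            key=lambda s: np.linalg.norm(s.location - loc),
        )
        assert np.linalg.norm(loc - saddle.location) < 1e-2
        assert abs(path.energies[i_ts] - saddle.energy) < 1e-2
        report = verify_saddle(MullerBrown(), loc, tol=1e-2)
        assert report.is_saddle
        assert int(np.sum(report.eigenvalues < 0)) == 1

    def test_endpoints_never_move(self, mb_stationary_points):
        path = mb_path_between(mb_stationary_points, 2, 1)
        start = mb_stationary_points["minima"][2].location
        end = mb_stationary_points["minima"][1].location
        assert path.images[0].tolist() == start.tolist()
        assert path.images[-1].tolist() == end.tolist()

    def test_impossible_budget_reports_nonconvergence(self):
        pes = SN2Surrogate(V0=15.4)
        config = NEBConfig(max_iter=1)
        path = neb_optimize(pes, interpolate_path((-1, 0), (1, 0), 12), config)
        assert not path.converged
        assert path.iterations == 1

    def test_deterministic_iteration_history(self):
        pes = SN2Surrogate(V0=10.0, asym=1.0)
        config = NEBConfig(seed=123)
        p1 = neb_optimize(pes, interpolate_path((-1, 0), (1, 0), 10), config)
        p2 = neb_optimize(pes, interpolate_path((-1, 0), (1, 0), 10), config)
        assert p1.max_force_history == p2.max_force_history
        assert np.array_equal(p1.images, p2.images)

    def test_asymmetric_barrier_bookkeeping(self):
        """Forward minus reverse barrier equals the endpoint energy gap."""
        pes = SN2Surrogate(V0=10.0, asym=2.0, k=1.0, c=0.0)
        lo, hi = relocate_endpoints(pes, _sn2_saddle(pes), 0.1)
        path = neb_optimize(pes, interpolate_path(lo, hi, 12), NEBConfig())
        assert path.converged
        fwd = barrier_from_path(path, "start")
        rev = barrier_from_path(path, "end")
        gap = path.energies[-1] - path.energies[0]
        assert fwd != pytest.approx(rev, abs=1e-3)
        assert fwd - rev == pytest.approx(gap, abs=1e-9)


def _sn2_saddle(pes):
    # Newton from the origin onto the (tilted) saddle.
    from catdesc.pes_models import numerical_hessian

    p = np.zeros(2)
    for _ in range(50):
        g = pes.gradient(p)
        if np.linalg.norm(g) < 1e-12:
            break
        H, _ = numerical_hessian(pes, p)
        p = p + np.linalg.solve(H, -g)
    return p


class TestLocateTS:
    def test_interior_maximum(self):
        path = NEBPath(images=np.zeros((5, 2)), energies=np.array([0, 2, 5, 2, 0.0]))
        assert locate_ts(path) == 2  # third image

    def test_monotone_profile_has_no_barrier(self):
        path = NEBPath(images=np.zeros((4, 2)), energies=np.array([0, 1, 2, 3.0]))
        with pytest.raises(NEBError, match="no interior barrier"):
            locate_ts(path)

    def test_tie_breaks_low_with_warning(self):
        path = NEBPath(images=np.zeros((5, 2)),
                       energies=np.array([0, 5, 3, 5, 0.0]))
        with pytest.warns(UserWarning, match="maximum"):
            assert locate_ts(path) == 1


class TestVerifySaddle:
    def test_sn2_origin_is_saddle(self):
        report = verify_saddle(SN2Surrogate(V0=15.4), (0.0, 0.0))
        assert report.is_saddle
        assert report.gradient_norm < 1e-10

    def test_minimum_is_not_a_saddle(self, mb_stationary_points):
        m = mb_stationary_points["minima"][0]
        report = verify_saddle(MullerBrown(), m.location)
        assert not report.is_saddle
        assert np.all(report.eigenvalues > 0)

    def test_flat_region_is_not_a_saddle(self):
        class Flat:
            def energy(self, p):
                return 1.0

            def gradient(self, p):
                return np.zeros(2)

        report = verify_saddle(Flat(), (0.3, 0.7))
        assert report.gradient_norm == 0.0
        assert not report.is_saddle


class TestRelocateEndpoints:
    def test_symmetric_sn2_recovers_known_minima(self):
        pes = SN2Surrogate(V0=15.4)
        lo, hi = relocate_endpoints(pes, (0.0, 0.0), 0.1, tol=1e-6)
        ends = sorted([lo[0], hi[0]])
        assert ends[0] == pytest.approx(-1.0, abs=1e-3)
        assert ends[1] == pytest.approx(1.0, abs=1e-3)
        assert np.linalg.norm(pes.gradient(lo)) < 1e-6
        assert np.linalg.norm(pes.gradient(hi)) < 1e-6

    def test_muller_brown_saddles_connect_oracle_minima(self, mb_stationary_points):
        pes = MullerBrown()
        minima = [m.location for m in mb_stationary_points["minima"]]
        for saddle in mb_stationary_points["saddles"]:
            lo, hi = relocate_endpoints(pes, saddle.location, 0.05, tol=1e-6)
            for q in (lo, hi):
                nearest = min(np.linalg.norm(q - m) for m in minima)
                assert nearest < 1e-4
            assert not np.allclose(lo, hi)

    def test_displacement_sign_swaps_outputs(self, mb_stationary_points):
        pes = MullerBrown()
        s = mb_stationary_points["saddles"][0].location
        lo1, hi1 = relocate_endpoints(pes, s, 0.05)
        lo2, hi2 = relocate_endpoints(pes, s, -0.05)
        assert np.allclose(lo1, hi2, atol=1e-6)
        assert np.allclose(hi1, lo2, atol=1e-6)

    def test_non_saddle_input_rejected(self, mb_stationary_points):
        m = mb_stationary_points["minima"][0].location
        with pytest.raises(NEBError, match="no negative"):
            relocate_endpoints(MullerBrown(), m, 0.05)
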