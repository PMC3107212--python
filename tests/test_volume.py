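"""Volume methods against closed-form sphere and lens oracles."""

import numpy as np
import pytest

from clashscan import synth
from clashscan.volume import (
    OverlapMeasurement, overlap_volume, passes_overlap_filter, sas_method, ses_method,
    volume_sas_mc, volume_ses_grid,
)


def brute_force_grid_volume(centers, radii, spacing=0.05):
    """Independent oracle: dense lattice count over the union of spheres."""
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    lo = (centers - radii[:, None]).min(0) - 2 * spacing
    hi = (centers + radii[:, None]).max(0) + 2 * spacing
    axes = [np.arange(lo[k], hi[k], spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    inside = np.zeros(gx.shape, bool)
    for c, r in zip(centers, radii):
        inside |= ((pts - c) ** 2).sum(-1) <= r * r
    return inside.sum() * spacing ** 3


class TestSesGrid:
    def test_single_sphere_matches_closed_form(self):
        m = synth.make_sphere_model([[0.0, 0.0, 0.0]], 1.9)
        v = volume_ses_grid(m, ses_method(probe_radius=0.0, grid_spacing=0.2))
        assert v == pytest.approx(synth.sphere_volume(1.9), rel=0.02)

    def test_coincident_models_union_is_idempotent(self):
        m1 = synth.make_sphere_model([[1.0, 2.0, 3.0]], 2.0)
        m2 = synth.make_sphere_model([[1.0, 2.0, 3.0]], 2.0)
        method = ses_method(0.0, 0.2)
        v1 = volume_ses_grid(m1, method)
        v12 = volume_ses_grid([m1, m2], method)
        assert v12 == pytest.approx(v1, rel=1e-9)

    def test_grid_convergence_on_cluster(self):
        rng = np.random.default_rng(8)
        centers = rng.uniform(0, 8, size=(50, 3))
        m = synth.make_sphere_model(centers, 1.8)
        coarse = volume_ses_grid(m, ses_method(0.0, 0.4))
        fine = volume_ses_grid(m, ses_method(0.0, 0.2))
        assert abs(coarse - fine) / fine < 0.01

    def test_cluster_matches_independent_lattice_oracle(self):
        rng = np.random.default_rng(9)
        centers = rng.uniform(0, 5, size=(8, 3))
        m = synth.make_sphere_model(centers, 1.7)
        v = volume_ses_grid(m, ses_method(0.0, 0.15))
        oracle = brute_force_grid_volume(centers, np.full(8, 1.7))
        assert v == pytest.approx(oracle, rel=0.02)

    def test_empty_model_returns_zero(self):
        from clashscan.structio import Chain, StructureModel
        empty = StructureModel("e", 1, [Chain("A", [])])
        assert volume_ses_grid(empty, ses_method()) == 0.0

    def test_probe_closing_bridges_narrow_gap(self):
        # two spheres whose surface gap is below the probe diameter get
        # closed into one body: the union is larger than the sum of parts
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        m2 = synth.make_sphere_model([[6.0, 0.0, 0.0]], 2.0)  # 2 A gap < 2*probe
        method = ses_method(1.5, 0.2)
        v_union = volume_ses_grid([m1, m2], method)
        v_sum = volume_ses_grid(m1, method) + volume_ses_grid(m2, method)
        assert v_union > v_sum


class TestSasMc:
    def test_single_sphere_within_three_se(self):
        m = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        v, se = volume_sas_mc(m, sas_method(0.0, 1_000_000, seed=3))
        assert abs(v - synth.sphere_volume(2.0)) < 3 * se

    def test_disjoint_spheres_add(self):
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]], 1.0)
        v, se = volume_sas_mc(m1, sas_method(0.0, 1_000_000, seed=4))
        assert abs(v - 2 * synth.sphere_volume(1.0)) < 3 * se

    def test_probe_inflates_radii(self):
        m = synth.make_sphere_model([[0.0, 0.0, 0.0]], 1.0)
        v, se = volume_sas_mc(m, sas_method(1.4, 1_000_000, seed=5))
        assert abs(v - synth.sphere_volume(2.4)) < 3 * se

    def test_same_seed_is_deterministic(self):
        m = synth.make_sphere_model([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]], 1.5)
        assert volume_sas_mc(m, sas_method(0.0, 200_000, seed=6)) == \
            volume_sas_mc(m, sas_method(0.0, 200_000, seed=6))


class TestOverlap:
    def test_two_sphere_lens_both_methods(self):
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        m2 = synth.make_sphere_model([[2.0, 0.0, 0.0]], 2.0)
        analytic = synth.lens_volume(2.0, 2.0, 2.0)  # 10 pi / 3
        ses = overlap_volume(m1, m2, ses_method(0.0, 0.1))
        assert ses.overlap == pytest.approx(analytic, rel=0.05)
        sas = overlap_volume(m1, m2, sas_method(0.0, 2_000_000, seed=7))
        assert abs(sas.overlap - analytic) < 3 * sas.stderr

    def test_distant_spheres_do_not_overlap(self):
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        m2 = synth.make_sphere_model([[10.0, 0.0, 0.0]], 2.0)
        assert overlap_volume(m1, m2, ses_method(0.0, 0.2)).overlap == 0.0
        assert overlap_volume(m1, m2, sas_method(0.0, 500_000, seed=8)).overlap == 0.0

    def test_self_overlap_equals_own_volume(self):
        m = synth.make_sphere_model([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]], 2.0)
        ses = overlap_volume(m, m, ses_method(0.0, 0.1))
        assert ses.overlap == pytest.approx(ses.v_r, rel=1e-6)

    def test_overlap_identity_and_bounds(self):
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        m2 = synth.make_sphere_model([[1.0, 0.5, 0.0]], 1.8)
        for method in (ses_method(0.0, 0.1), sas_method(0.0, 1_000_000, seed=9)):
            m = overlap_volume(m1, m2, method)
            assert m.overlap == pytest.approx(m.v_r + m.v_s - m.v_union, abs=1e-6)
            assert m.v_union <= m.v_r + m.v_s + 1e-6
            assert -1e-6 <= m.overlap <= min(m.v_r, m.v_s) + 0.5

    def test_rigid_motion_invariance(self):
        """Moving R and S together changes the overlap only by grid error."""
        rng = np.random.default_rng(10)
        c1 = rng.uniform(0, 4, size=(5, 3))
        c2 = c1 + np.array([1.0, 0.0, 0.0])
        method = ses_method(0.0, 0.2)
        base = overlap_volume(synth.make_sphere_model(c1, 1.8),
                              synth.make_sphere_model(c2, 1.8), method).overlap
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        shift = np.array([3.3, -1.1, 2.2])
        moved = overlap_volume(synth.make_sphere_model(c1 @ rot.T + shift, 1.8),
                               synth.make_sphere_model(c2 @ rot.T + shift, 1.8),
                               method).overlap
        assert moved == pytest.approx(base, rel=0.02)

    def test_sas_overlap_monotone_under_approach(self):
        m1 = synth.make_sphere_model([[0.0, 0.0, 0.0]], 2.0)
        prev = None
        for d in (4.0, 3.0, 2.0, 1.0, 0.0):
            m2 = synth.make_sphere_model([[d, 0.0, 0.0]], 2.0)
            o = overlap_volume(m1, m2, sas_method(0.0, 400_000, seed=11)).overlap
            if prev is not None:
                assert o >= prev - 1e-9
            prev = o


class TestOverlapFilter:
    @pytest.mark.parametrize("ses,sas,expected", [
        (2500.0, 1900.0, False),
        (2215.0, 5368.0, True),
        (0.0, 0.0, False),
        (2000.0, 2000.0, True),
    ])
    def test_requires_both_methods(self, ses, sas, expected):
        m_ses = OverlapMeasurement("SES_GRID", 0, 0, 0, ses)
        m_sas = OverlapMeasurement("SAS_MC", 0, 0, 0, sas)
        assert passes_overlap_filter(m_ses, m_sas) is expected
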