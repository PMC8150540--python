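import numpy as np
import pytest

import mwablate as m
from mwablate.errors import ConfigError, ContractError, RankError
from mwablate.inversion import TSVDImager


class TestBuildKernel:
    def test_shape_matches_geometry(self, tiny):
        assert tiny.kernel.shape == (32, 891)

    def test_paper_scale_shape_without_assembly(self):
        assert m.make_fixture("paper").kernel_shape == (320, 50225)

    def test_zero_field_node_gives_zero_column(self, tiny):
        """Kernel entries are products of the two incident fields."""
        fields = tiny.fields.fields.copy()
        fields[:, :, 5, :] = 0.0
        fs = m.IncidentFieldSet(
            fields, tiny.fields.frequencies, tiny.grid, tiny.array, tiny.background
        )
        kern = m.build_kernel(fs, tiny.background)
        assert np.all(kern.matrix[:, 5] == 0)

    def test_single_node_scalar_oracle(self, tiny):
        """Hand-computed −j·ΔV·(E_p·E_q)/(4ωε_eq) matches one kernel entry."""
        fi, p, q, n = 1, 2, 3, 100
        f = tiny.fields.frequencies[fi]
        omega = 2 * np.pi * f
        eps_eq = tiny.background.complex_permittivity(f).value
        dv = (tiny.grid.spacing * 1e-3) ** 3
        ep = tiny.fields.fields[p, fi, n]
        eq_ = tiny.fields.fields[q, fi, n]
        expected = -1j * dv / (4 * omega * eps_eq) * np.dot(ep, eq_)
        row = tiny.kernel.row_index.index((fi, p, q))
        assert tiny.kernel.matrix[row, n] == pytest.approx(expected, rel=1e-12)


class TestComputeSvd:
    def test_diagonal_toy_matrix(self):
        svd = m.compute_svd(np.diag([3.0, 1.0]).astype(complex))
        assert np.allclose(svd.s, [3.0, 1.0])

    def test_reconstruction_residual(self, tiny):
        svd = tiny.svd
        K = tiny.kernel.matrix
        approx = (svd.U * svd.s) @ svd.Vh
        rel = np.linalg.norm(K - approx) / np.linalg.norm(K)
        assert rel <= 1e-8

    def test_homogeneity_of_singular_values(self, tiny):
        doubled = m.compute_svd(2.0 * tiny.kernel.matrix)
        assert np.allclose(doubled.s, 2.0 * tiny.svd.s, rtol=1e-10)

    def test_cache_round_trip(self, tiny, tmp_path):
        path = tmp_path / "svd.h5"
        first = m.compute_svd(tiny.kernel, cache_path=path, cache_key="abc")
        again = m.compute_svd(tiny.kernel, cache_path=path, cache_key="abc")
        assert np.array_equal(first.s, again.s)
        assert np.array_equal(first.U, again.U)


def _piecewise_db_spectrum(slopes_and_lengths):
    """Singular values whose dB curve is piecewise linear; returns s."""
    sdb = [0.0]
    for slope, length in slopes_and_lengths:
        for _ in range(length):
            sdb.append(sdb[-1] + slope)
    return 10 ** (np.asarray(sdb) / 20.0)


class TestThresholdSelection:
    def test_single_knee_above_noise(self):
        """One slope change at 1-based index 40, well above −15 dB."""
        s = _piecewise_db_spectrum([(-0.1, 39), (-1.5, 60)])
        sel = m.threshold_candidates(s, noise_db=-15.0)
        assert sel.candidates == [40]
        assert sel.selected == 40
        assert not sel.used_fallback

    def test_largest_candidate_above_noise_wins(self):
        """Knees at 30 and 50, both above the noise level: pick 50."""
        s = _piecewise_db_spectrum([(-0.02, 29), (-0.62, 20), (-2.0, 50)])
        sel = m.threshold_candidates(s, noise_db=-15.0)
        assert 30 in sel.candidates and 50 in sel.candidates
        assert sel.selected == 50

    def test_knee_below_noise_excluded(self):
        """A knee whose singular value is already below the noise level loses."""
        s = _piecewise_db_spectrum([(-0.02, 29), (-1.0, 30), (-3.0, 40)])
        sel = m.threshold_candidates(s, noise_db=-15.0)
        # second knee at 60 sits near -30 dB -> only the knee at 30 qualifies
        assert sel.selected == 30

    def test_flat_spectrum_falls_back(self):
        s = np.ones(50)
        with pytest.warns(UserWarning, match="falling back"):
            sel = m.threshold_candidates(s, noise_db=-15.0)
        assert sel.used_fallback
        assert sel.selected == 50  # everything above noise

    def test_smooth_decay_falls_back_to_noise_crossing(self):
        s = _piecewise_db_spectrum([(-0.5, 99)])
        with pytest.warns(UserWarning):
            sel = m.threshold_candidates(s, noise_db=-15.0)
        assert sel.used_fallback
        assert sel.selected == 31  # last 1-based index with sigma_db >= -15

    def test_too_few_values_rejected(self):
        with pytest.raises(ConfigError):
            m.threshold_candidates(np.ones(5))


class TestTsvdSolve:
    def test_single_mode_data_recovers_right_vector(self, tiny):
        svd = tiny.svd
        data = svd.s[0] * svd.U[:, 0]
        for nu in (1, 4, svd.rank):
            rec = m.tsvd_solve(svd, data, nu, tiny.grid)
            assert np.allclose(rec.values, svd.Vh[0].conj(), atol=1e-10)

    def test_matches_ideal_projection_for_every_nu(self, tiny, tiny_contrast, tiny_data):
        """Central oracle: TSVD of noiseless K·Δx equals V_ν V_νᴴ Δx."""
        svd = tiny.svd
        scale = np.linalg.norm(tiny_contrast.values)
        for nu in range(1, svd.rank + 1):
            rec = m.tsvd_solve(svd, tiny_data, nu, tiny.grid)
            proj = m.ideal_reconstruction(svd, tiny_contrast, nu)
            assert np.linalg.norm(rec.values - proj.values) <= 1e-6 * scale

    def test_nu_one_residual_orthogonal_to_first_left_vector(self, tiny, tiny_data):
        svd = tiny.svd
        rec = m.tsvd_solve(svd, tiny_data, 1, tiny.grid)
        residual = tiny_data - tiny.kernel.matrix @ rec.values
        assert abs(svd.U[:, 0].conj() @ residual) <= 1e-8 * np.linalg.norm(tiny_data)

    def test_noiseless_error_nonincreasing_in_nu(self, tiny, tiny_contrast, tiny_data):
        svd = tiny.svd
        full_proj = m.ideal_reconstruction(svd, tiny_contrast, svd.rank).values
        errs = [
            np.linalg.norm(m.tsvd_solve(svd, tiny_data, nu).values - full_proj)
            for nu in range(1, svd.rank + 1)
        ]
        assert np.all(np.diff(errs) <= 1e-9 * errs[0])

    def test_rank_errors(self, tiny, tiny_data):
        with pytest.raises(RankError):
            m.tsvd_solve(tiny.svd, tiny_data, 0)
        with pytest.raises(RankError):
            m.tsvd_solve(tiny.svd, tiny_data, 33)
        with pytest.raises(ContractError):
            m.tsvd_solve(tiny.svd, tiny_data[:-1], 2)


class TestIdealReconstruction:
    def test_basis_vector_reproduced_exactly(self, tiny):
        svd = tiny.svd
        v3 = m.ContrastImage(svd.Vh[2].conj(), "band", tiny.grid)
        for nu in (3, 10):
            out = m.ideal_reconstruction(svd, v3, nu)
            assert np.allclose(out.values, v3.values, atol=1e-12)

    def test_orthogonal_truth_projects_to_zero(self, tiny):
        svd = tiny.svd
        # a vector orthogonal to span(V_2): the 5th right singular vector
        x = m.ContrastImage(svd.Vh[4].conj(), "band", tiny.grid)
        out = m.ideal_reconstruction(svd, x, 2)
        assert np.linalg.norm(out.values) <= 1e-10

    def test_projection_is_contraction(self, tiny, tiny_contrast):
        for nu in (1, 5, 20):
            out = m.ideal_reconstruction(tiny.svd, tiny_contrast, nu)
            assert np.linalg.norm(out.values) <= np.linalg.norm(tiny_contrast.values) * (1 + 1e-12)


class TestTSVDImagerEstimator:
    def test_fit_transform_matches_function_path(self, tiny, tiny_data):
        imager = TSVDImager(nu=8).fit(tiny.kernel)
        out = imager.transform(tiny_data)
        ref = m.tsvd_solve(tiny.svd, tiny_data, 8)
        assert out.shape == (1, tiny.grid.n_nodes)
        assert np.allclose(out[0], ref.values)

    def test_project_truth_matches_ideal(self, tiny, tiny_contrast):
        imager = TSVDImager(nu=8).fit(tiny.kernel)
        out = imager.project_truth(tiny_contrast.values)
        ref = m.ideal_reconstruction(tiny.svd, tiny_contrast, 8)
        assert np.allclose(out[0], ref.values)

    def test_sklearn_param_interface(self):
        imager = TSVDImager(nu=5, noise_db=-20.0)
        assert imager.get_params()["nu"] == 5
        imager.set_params(nu=7)
        assert imager.nu == 7

    def test_automatic_selection_populates_attributes(self, tiny):
        imager = TSVDImager(noise_db=-40.0).fit(tiny.kernel)
        assert 1 <= imager.nu_ <= tiny.svd.rank
        assert imager.n_features_in_ == 32

    def test_batch_transform_shape(self, tiny, tiny_data):
        imager = TSVDImager(nu=4).fit(tiny.kernel)
        batch = np.stack([tiny_data, 2 * tiny_data])
        out = imager.transform(batch)
        assert out.shape == (2, tiny.grid.n_nodes)
        assert np.allclose(out[1], 2 * out[0])
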