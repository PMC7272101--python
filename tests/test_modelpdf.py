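"""Model pdf: grids, characteristic functions, FFT vs expansion oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwasmix.ldstruct import LdHistogram
from gwasmix.modelpdf import (
    ModelParams,
    ZGrid,
    count_compositions,
    environment_characteristic_function,
    fourier_kernel_Aw,
    genetic_characteristic_function,
    idealized_mixture_pdf,
    invert_characteristic,
    pdf_convolution,
    pdf_convolution_batch,
    pdf_multinomial,
)


class TestZGrid:
    def test_default_constants(self, zgrid):
        assert zgrid.n_points == 1024
        assert zgrid.z1 == -38.0
        assert zgrid.dz == pytest.approx(0.07421875)
        assert zgrid.z_values[zgrid.n_points // 2] == 0.0
        assert zgrid.z_values[-1] == pytest.approx(-zgrid.z1 - zgrid.dz)

    def test_fourier_duality(self, zgrid):
        assert zgrid.dz * zgrid.dk == pytest.approx(1.0 / zgrid.n_points)
        assert zgrid.k_values[zgrid.n_points // 2] == 0.0
        assert zgrid.k_values[0] == pytest.approx(-zgrid.f_c)

    @pytest.mark.parametrize("n", [3, 100, 1000])
    def test_rejects_non_power_of_two(self, n):
        with pytest.raises(ValueError):
            ZGrid(n_points=n)


class TestModelParams:
    def test_transform_round_trip(self):
        p = ModelParams(3e-3, 5.5e-5, 1.14)
        q = ModelParams.from_transformed(p.to_transformed())
        assert q.pi1 == pytest.approx(p.pi1)
        assert q.sigma_beta2 == pytest.approx(p.sigma_beta2)
        assert q.sigma0_2 == pytest.approx(p.sigma0_2)

    def test_sigma_tilde(self):
        p = ModelParams(0.1, 2e-4, 1.5)
        assert p.sigma_tilde_beta2 == pytest.approx(3e-4)

    @pytest.mark.parametrize("bad", [(-0.1, 1e-4, 1.0), (0.5, 1e-4, 0.0), (1.5, 1e-4, 1.0)])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            ModelParams(*bad)


class TestIdealizedMixture:
    def test_null_component(self, zgrid):
        p = ModelParams(0.1, 1e-4, 1.3)
        vals = idealized_mixture_pdf(zgrid.z_values, 0, 1.0, 0.5, 1e5, p)
        assert np.allclose(vals, stats.norm.pdf(zgrid.z_values, 0, math.sqrt(1.3)))

    def test_variance_arithmetic(self):
        # k=1, r2=1, H=0.5, N=4, sigma_tilde_beta2=0.5, sigma0_2=1 -> var 2
        p = ModelParams(1.0, 0.5, 1.0)
        val = idealized_mixture_pdf(0.0, 1, 1.0, 0.5, 4, p)
        assert val == pytest.approx(stats.norm.pdf(0, 0, math.sqrt(2.0)))

    def test_normalised(self, zgrid):
        p = ModelParams(0.3, 1e-3, 1.0)
        vals = idealized_mixture_pdf(zgrid.z_values, 2, 0.7, 0.4, 1e4, p, alpha=0.3)
        assert vals @ np.full_like(vals, zgrid.dz) == pytest.approx(1.0, abs=1e-9)


class TestFourierKernel:
    def test_zero_inputs(self):
        assert fourier_kernel_Aw(0, 0.25, 0.5, 1e-4) == 0.0
        assert fourier_kernel_Aw(1e5, 0.0, 0.5, 1e-4) == 0.0

    def test_printed_value(self):
        # N=1e5, H=0.25, r2=0.5, sigma_tilde=1e-4 -> -2 pi^2 * 1.25
        assert fourier_kernel_Aw(1e5, 0.25, 0.5, 1e-4) == pytest.approx(-24.674, abs=1e-3)

    def test_monotone_in_each_argument(self):
        base = fourier_kernel_Aw(1e5, 0.25, 0.5, 1e-4)
        assert fourier_kernel_Aw(2e5, 0.25, 0.5, 1e-4) < base
        assert fourier_kernel_Aw(1e5, 0.4, 0.5, 1e-4) < base
        assert fourier_kernel_Aw(1e5, 0.25, 0.9, 1e-4) < base
        assert fourier_kernel_Aw(1e5, 0.25, 0.5, 2e-4) < base


class TestCharacteristicFunctions:
    def test_pure_null_genetic_part(self, zgrid, small_histogram):
        p = ModelParams(0.0, 1e-4, 1.0)
        G = genetic_characteristic_function(zgrid.k_values, small_histogram, 1e5, p)
        assert np.allclose(G, 1.0)

    def test_single_window_single_gaussian(self, zgrid):
        h = LdHistogram(
            counts=np.array([1.0]), mean_het=np.array([0.3]),
            mean_r2=np.array([1.0]), total_ld=1.0, block_size=1.0,
        )
        p = ModelParams(1.0, 1e-4, 1.0)
        G = genetic_characteristic_function(zgrid.k_values, h, 1e5, p)
        A = fourier_kernel_Aw(1e5, 0.3, 1.0, p.sigma_tilde_beta2)
        assert np.allclose(G, np.exp(A * zgrid.k_values**2))

    def test_log_domain_matches_direct_product(self, zgrid, small_histogram, default_params):
        G = genetic_characteristic_function(
            zgrid.k_values, small_histogram, 1e5, default_params
        )
        direct = np.ones_like(zgrid.k_values)
        for nw, Hw, rw in zip(
            small_histogram.counts, small_histogram.mean_het, small_histogram.mean_r2
        ):
            A = fourier_kernel_Aw(1e5, Hw, rw, default_params.sigma_tilde_beta2)
            direct *= (
                default_params.pi1 * np.exp(A * zgrid.k_values**2)
                + 1 - default_params.pi1
            ) ** nw
        assert np.allclose(G, direct, atol=1e-12)
        assert G[zgrid.n_points // 2] == pytest.approx(1.0)
        assert np.all(G > 0) and np.all(G <= 1 + 1e-12)

    def test_environment_is_gaussian(self, zgrid):
        E = environment_characteristic_function(zgrid.k_values, 1.0)
        assert E[zgrid.n_points // 2] == 1.0
        vals = invert_characteristic(E, zgrid)
        assert np.allclose(vals, stats.norm.pdf(zgrid.z_values), atol=1e-12)

    def test_environment_decay_with_sigma0(self, zgrid):
        k = zgrid.k_values
        e1 = environment_characteristic_function(k, 1.0)
        e2 = environment_characteristic_function(k, 2.0)
        off = (k != 0) & (e2 > 0)
        assert off.any()
        assert np.all(e2[off] < e1[off])


class TestPdfConvolution:
    def test_null_limit(self, zgrid, small_histogram):
        p = ModelParams(0.0, 1e-4, 1.2)
        pdf = pdf_convolution(small_histogram, 1e5, p, zgrid)
        ref = stats.norm.pdf(zgrid.z_values, 0, math.sqrt(1.2))
        assert np.abs(pdf.values - ref).max() < 1e-8

    def test_isolated_snp_matches_two_component_mixture(self, zgrid, isolated_histogram):
        p = ModelParams(0.05, 1e-4, 1.1)
        pdf = pdf_convolution(isolated_histogram, 1e5, p, zgrid)
        ref = idealized_mixture_pdf(
            zgrid.z_values, 1, 1.0, 0.3, 1e5, p, alpha=p.pi1
        )
        assert np.abs(pdf.values - ref).max() < 1e-8

    def test_normalization_and_symmetry(self, zgrid, small_histogram, default_params):
        pdf = pdf_convolution(small_histogram, 1e5, default_params, zgrid)
        assert abs(pdf.integral() - 1.0) < 1e-6
        v = pdf.values
        # z grid is [-38, 38): index 1..n-1 mirrors around n/2
        assert np.allclose(v[1:], v[1:][::-1], atol=1e-10)
        assert v.min() >= 0

    def test_variance_identity(self, zgrid, small_histogram, default_params):
        # law of total variance: var = sigma0_2 + N*sigma_tilde*pi1*sum n_w H_w r2_w
        N = 1e4
        pdf = pdf_convolution(small_histogram, N, default_params, zgrid)
        expected = default_params.sigma0_2 + (
            N * default_params.sigma_tilde_beta2 * default_params.pi1
            * (small_histogram.counts * small_histogram.mean_het * small_histogram.mean_r2).sum()
        )
        assert pdf.variance() == pytest.approx(expected, rel=1e-4)

    def test_inflation_rescaling(self, small_histogram):
        # z = sigma0 * z_u: the inflated-model pdf is (1/sigma0) times the
        # uninflated pdf at z/sigma0 (sigma_beta2 is shared; the genetic
        # variance already carries sigma0^2 through sigma_tilde_beta2)
        sigma0 = 2.0
        g = ZGrid(1024, -38.0)
        p_infl = ModelParams(0.05, 2e-5, sigma0**2)
        p_unit = ModelParams(0.05, 2e-5, 1.0)
        pdf1 = pdf_convolution(small_histogram, 1e4, p_infl, g).values
        pdf2 = pdf_convolution(small_histogram, 1e4, p_unit, g).values
        # z_i/sigma0 lands back on the grid for even i: index i/2 + n/4
        i = np.arange(0, g.n_points, 2)
        j = i // 2 + g.n_points // 4
        assert np.abs(pdf1[i] - pdf2[j] / sigma0).max() < 1e-8

    def test_batch_matches_single(self, zgrid, small_histogram, default_params):
        batch = pdf_convolution_batch(
            np.vstack([small_histogram.counts, small_histogram.counts * 0 + 1]),
            np.vstack([small_histogram.mean_het, small_histogram.mean_het]),
            small_histogram.mean_r2,
            1e5,
            default_params,
            zgrid,
        )
        single = pdf_convolution(small_histogram, 1e5, default_params, zgrid)
        assert np.abs(batch[0] - single.values).max() < 1e-10


class TestMultinomialExpansion:
    def test_composition_count_printed(self):
        assert count_compositions(10, 10) == 92_378

    def test_single_snp_two_terms(self, zgrid, isolated_histogram):
        p = ModelParams(0.2, 1e-4, 1.0)
        pdf = pdf_multinomial(isolated_histogram, 1e5, p, zgrid)
        ref = idealized_mixture_pdf(
            zgrid.z_values, 1, 1.0, 0.3, 1e5, p, alpha=p.pi1
        )
        assert np.abs(pdf.values - ref).max() < 1e-12

    def test_weight_sum_near_one(self, zgrid, small_histogram, default_params):
        pdf = pdf_multinomial(small_histogram, 1e5, default_params, zgrid)
        assert pdf.metadata["weight_sum"] >= 1 - 1e-6

    def test_instance_too_large(self, zgrid):
        h = LdHistogram(
            counts=np.full(20, 100.0), mean_het=np.full(20, 0.2),
            mean_r2=np.linspace(0.07, 0.97, 20), total_ld=500.0, block_size=2000.0,
        )
        with pytest.raises(ValueError, match="oracle"):
            pdf_multinomial(h, 1e5, ModelParams(0.01, 1e-4, 1.0), zgrid)

    @pytest.mark.parametrize(
        "counts,het,r2,pi1",
        [
            ([1, 2, 3], [0.1, 0.3, 0.45], [0.1, 0.5, 0.9], 0.1),
            ([4, 4, 2], [0.25, 0.25, 0.25], [0.2, 0.6, 0.95], 0.05),
            ([10], [0.4], [0.8], 0.02),
            ([2, 2], [0.05, 0.5], [0.3, 1.0], 0.1),
        ],
    )
    def test_fft_equals_expansion(self, zgrid, counts, het, r2, pi1):
        """FFT convolution and the explicit expansion agree to 1e-6 on
        small LD blocks (n <= 10, w <= 3)."""
        h = LdHistogram(
            counts=np.array(counts, float), mean_het=np.array(het),
            mean_r2=np.array(r2), total_ld=float(np.sum(counts)),
            block_size=float(np.sum(counts)),
        )
        p = ModelParams(pi1, 3e-4, 1.1)
        a = pdf_convolution(h, 1e5, p, zgrid).values
        b = pdf_multinomial(h, 1e5, p, zgrid).values
        assert np.abs(a - b).max() < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 4), min_size=1, max_size=3).filter(lambda c: sum(c) >= 1),
    pi1=st.floats(1e-4, 0.1),
    seed=st.integers(0, 10_000),
)
def test_pdf_properties_random_instances(counts, pi1, seed):
    """Normalization, non-negativity, symmetry and oracle agreement hold
    on randomly drawn small LD structures."""
    rng = np.random.default_rng(seed)
    w = len(counts)
    h = LdHistogram(
        counts=np.array(counts, float),
        mean_het=rng.uniform(0.01, 0.5, w),
        mean_r2=np.sort(rng.uniform(0.05, 1.0, w)),
        total_ld=float(sum(counts)),
        block_size=float(sum(counts)),
    )
    zgrid = ZGrid()
    p = ModelParams(pi1, float(rng.uniform(1e-5, 5e-4)), float(rng.uniform(0.9, 1.5)))
    pdf = pdf_convolution(h, 1e5, p, zgrid)
    assert abs(pdf.integral() - 1.0) < 1e-6
    assert pdf.values.min() >= 0.0
    assert np.allclose(pdf.values[1:], pdf.values[1:][::-1], atol=1e-9)
    oracle = pdf_multinomial(h, 1e5, p, zgrid)
    assert np.abs(pdf.values - oracle.values).max() < 1e-6
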