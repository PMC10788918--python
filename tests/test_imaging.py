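"""Pixel-wise TRAST maps, PDF construction and two-species unmixing."""

import numpy as np
import pytest

from trastkit.imaging import (
    Pdf2d,
    TrastImage,
    TrastImageStack,
    build_pdfs,
    compose_species_images,
    correct_and_normalize,
    fit_pixelwise,
    smooth_gaussian,
    unmix_map,
    unmix_pixel,
)
from trastkit.synthetic import gen_cell_stack
from trastkit.trast import MonoexpTrastParams, default_width_grid, mean_pulse_fluorescence


def uniform_stack(a=0.45, tau=12.4e-6, intensity=1e4, background=0.0,
                  shape=(6, 6)):
    widths = default_width_grid(20)
    params = MonoexpTrastParams(a_trast=a, tau_trast=tau)
    means = np.asarray(mean_pulse_fluorescence(params, None, widths))
    frames = intensity * means[:, None, None] * np.ones((1, *shape)) + background
    bg = np.full(shape, background) if background else None
    return TrastImageStack(frames=frames, widths=widths, w0=widths.min(),
                           background=bg), params


class TestCorrectAndNormalize:
    def test_normalization_only_without_background(self):
        stack, params = uniform_stack()
        curves = correct_and_normalize(stack)
        means = np.asarray(
            mean_pulse_fluorescence(params, None, stack.widths)
        )
        assert np.allclose(curves[0, 0], means / means[0], rtol=1e-12)

    def test_uniform_background_cancels_exactly(self):
        clean, _ = uniform_stack(background=0.0)
        dirty, _ = uniform_stack(background=500.0)
        assert np.allclose(
            correct_and_normalize(dirty), correct_and_normalize(clean),
            rtol=1e-12,
        )

    def test_monoexponential_bleach_corrected(self):
        # 1%/frame bleaching, bracketing w0 references: geometric
        # interpolation inverts the attenuation
        stack, params = uniform_stack()
        n = stack.frames.shape[0]
        beta = 0.99
        ref0 = stack.frames[0].copy()  # w0 frame, value ~ intensity
        bleached = stack.frames * (beta ** np.arange(1, n + 1))[:, None, None]
        stack_b = TrastImageStack(
            frames=bleached, widths=stack.widths, w0=stack.w0,
            w0_refs=(ref0 * beta**0, ref0 * beta ** (n + 1)),
        )
        truth = correct_and_normalize(stack)
        corrected = correct_and_normalize(stack_b)
        assert np.abs(corrected - truth).max() < 0.005

    def test_negative_intensities_clipped_with_warning(self):
        stack, _ = uniform_stack()
        stack.background = np.full(stack.frames.shape[1:], 1e9)
        with pytest.warns(UserWarning, match="clipped"):
            correct_and_normalize(stack)

    def test_w0_must_be_covered(self):
        with pytest.raises(ValueError):
            TrastImageStack(frames=np.ones((3, 4, 4)),
                            widths=np.array([1e-6, 1e-5, 1e-4]), w0=1e-7)


class TestSmoothing:
    def test_kernel_preserves_constants(self):
        img = np.full((9, 9), 3.7)
        assert np.allclose(smooth_gaussian(img), img, rtol=1e-12)

    def test_impulse_response_sums_to_one(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = smooth_gaussian(img)
        assert out.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(out[3:6, 3:6] > 0)
        assert out[0, 0] == 0.0

    def test_white_noise_variance_reduction(self, rng):
        from trastkit.imaging import _KERNEL3

        img = rng.standard_normal((400, 400))
        out = smooth_gaussian(img)
        expected = np.sum(_KERNEL3**2)
        assert out.var() == pytest.approx(expected * img.var(), rel=0.05)


class TestPixelwiseFit:
    def test_noiseless_uniform_exact(self):
        stack, params = uniform_stack()
        curves = correct_and_normalize(stack)
        img = fit_pixelwise(curves, stack.widths, stack.w0)
        assert np.all(img.converged)
        assert np.allclose(img.a_map, params.a_trast, atol=1e-6)
        assert np.allclose(img.tau_map, params.tau_trast, rtol=1e-5)

    def test_masked_pixels_nan(self):
        stack, _ = uniform_stack(shape=(4, 4))
        curves = correct_and_normalize(stack)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        img = fit_pixelwise(curves, stack.widths, stack.w0, mask=mask)
        assert img.converged.sum() == 1
        assert np.isnan(img.a_map[1, 1])

    def test_dual_region_medians_at_shot_noise(self):
        stack, truth = gen_cell_stack(seed=21)
        curves = correct_and_normalize(stack)
        mask = truth["rim"] | truth["filaments"]
        img = fit_pixelwise(curves, stack.widths, stack.w0, mask=mask)
        for region, a_true, tau_true in [
            ("rim", 0.2, 2.5e-6),
            ("filaments", 0.45, 30e-6),
        ]:
            ok = img.converged & truth[region]
            assert np.median(img.a_map[ok]) == pytest.approx(a_true, rel=0.10)
            assert np.median(img.tau_map[ok]) == pytest.approx(tau_true, rel=0.10)


class TestPdfs:
    def delta_image(self, a, tau, n=50):
        m = np.full((n, n), a)
        t = np.full((n, n), tau)
        return TrastImage(a_map=m, tau_map=t, intensity_map=np.ones((n, n)),
                          quality_map=np.zeros((n, n)))

    def test_projections_unit_area(self):
        pdf = build_pdfs(self.delta_image(0.45, 30e-6))
        assert np.sum(pdf.pdf_a * np.diff(pdf.a_edges)) == pytest.approx(
            1.0, abs=1e-10
        )
        assert np.sum(
            pdf.pdf_tau * np.diff(np.log10(pdf.tau_edges))
        ) == pytest.approx(1.0, abs=1e-10)

    def test_bimodal_projection_modes(self, rng):
        a1 = 0.15 + 0.01 * rng.standard_normal(2000)
        a2 = 0.60 + 0.01 * rng.standard_normal(2000)
        img = TrastImage(
            a_map=np.r_[a1, a2].reshape(80, 50),
            tau_map=np.full((80, 50), 1e-5),
            intensity_map=np.ones((80, 50)),
            quality_map=np.zeros((80, 50)),
        )
        pdf = build_pdfs(img)
        centers = 0.5 * (pdf.a_edges[:-1] + pdf.a_edges[1:])
        lo = pdf.pdf_a[centers < 0.4]
        hi = pdf.pdf_a[centers >= 0.4]
        assert centers[np.argmax(pdf.pdf_a)] == pytest.approx(0.15, abs=0.05)
        assert hi.max() > 0.3 * lo.max()  # second mode present

    def test_no_converged_pixels_raises(self):
        empty = TrastImage(
            a_map=np.full((4, 4), np.nan), tau_map=np.full((4, 4), np.nan),
            intensity_map=np.zeros((4, 4)), quality_map=np.zeros((4, 4)),
        )
        with pytest.raises(ValueError):
            build_pdfs(empty)


class TestUnmixing:
    def reference_pdfs(self):
        d = TestPdfs()
        pdf_cy5 = build_pdfs(d.delta_image(0.45, 30e-6))
        pdf_as = build_pdfs(d.delta_image(0.2, 2.5e-6))
        return pdf_cy5, pdf_as

    def test_pure_supports(self):
        pdf_cy5, pdf_as = self.reference_pdfs()
        assert unmix_pixel(0.45, 30e-6, pdf_cy5, pdf_as) == pytest.approx(
            1.0, abs=1e-3
        )
        assert unmix_pixel(0.2, 2.5e-6, pdf_cy5, pdf_as) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_degenerate_and_outside_flags(self):
        pdf_cy5, _ = self.reference_pdfs()
        r, flag = unmix_pixel(0.45, 30e-6, pdf_cy5, pdf_cy5, return_flag=True)
        assert flag == "degenerate" and r == 0.5
        _, pdf_as = self.reference_pdfs()
        r, flag = unmix_pixel(0.99, 0.9e-3, pdf_cy5, pdf_as, return_flag=True)
        assert flag == "outside" and np.isnan(r)

    def test_objective_variants_agree_on_pure_pixels(self):
        pdf_cy5, pdf_as = self.reference_pdfs()
        for obj in ("product", "sum"):
            assert unmix_pixel(0.45, 30e-6, pdf_cy5, pdf_as, objective=obj) > 0.99
        with pytest.raises(ValueError):
            unmix_pixel(0.45, 30e-6, pdf_cy5, pdf_as, objective="bogus")

    def test_grid_refinement_matches_fine_grid_oracle(self, rng):
        # broadened, overlapping references; maximizer vs 1e-3 grid search
        a1 = np.clip(0.4 + 0.08 * rng.standard_normal(3000), 0, 1)
        a2 = np.clip(0.25 + 0.08 * rng.standard_normal(3000), 0, 1)
        t1 = 30e-6 * np.exp(0.3 * rng.standard_normal(3000))
        t2 = 4e-6 * np.exp(0.3 * rng.standard_normal(3000))

        def img(a, t):
            return TrastImage(a_map=a.reshape(60, 50), tau_map=t.reshape(60, 50),
                              intensity_map=np.ones((60, 50)),
                              quality_map=np.zeros((60, 50)))

        pdf1 = build_pdfs(img(a1, t1))
        pdf2 = build_pdfs(img(a2, t2))
        for a, tau in [(0.3, 1e-5), (0.35, 2e-5), (0.28, 6e-6)]:
            r = unmix_pixel(a, tau, pdf1, pdf2)
            grid = np.linspace(0, 1, 1001)
            p1 = np.array([pdf1.eval_a(a), pdf1.eval_tau(tau)])
            p2 = np.array([pdf2.eval_a(a), pdf2.eval_tau(tau)])
            obj = np.prod(
                grid[:, None] * p1[None, :] + (1 - grid[:, None]) * p2[None, :],
                axis=1,
            )
            assert abs(r - grid[np.argmax(obj)]) < 2e-3

    def test_end_to_end_synthetic_cells(self):
        # pure-species stacks build the references; a dual-label stack with
        # disjoint truth masks is unmixed to mean R > 0.9 / < 0.1
        def fitted(which, seed):
            s, t = gen_cell_stack(seed=seed)
            c = correct_and_normalize(s)
            return fit_pixelwise(c, s.widths, s.w0, mask=t[which]), t

        img_cy5, _ = fitted("filaments", 31)
        img_as, _ = fitted("rim", 32)
        pdf_cy5 = build_pdfs(img_cy5)
        pdf_as = build_pdfs(img_as)
        s, truth = gen_cell_stack(seed=33)
        c = correct_and_normalize(s)
        dual = fit_pixelwise(c, s.widths, s.w0,
                             mask=truth["rim"] | truth["filaments"])
        r_map, flags = unmix_map(dual, pdf_cy5, pdf_as)
        informative = np.isfinite(r_map)
        err = np.abs(r_map[informative] - truth["r_map"][informative])
        assert err.mean() < 0.15
        assert np.nanmean(r_map[truth["filaments"]]) > 0.9
        assert np.nanmean(r_map[truth["rim"]]) < 0.1


class TestCompose:
    def test_endpoints(self):
        intensity = np.arange(12.0).reshape(3, 4)
        cy5, as635 = compose_species_images(np.ones((3, 4)), intensity)
        assert np.array_equal(cy5, intensity) and np.all(as635 == 0)
        cy5, as635 = compose_species_images(np.full((3, 4), 0.5), intensity)
        assert np.allclose(cy5, as635)

    def test_conservation_random_maps(self, rng):
        r = rng.uniform(size=(20, 20))
        intensity = rng.uniform(0, 1e4, size=(20, 20))
        cy5, as635 = compose_species_images(r, intensity)
        assert np.abs(cy5 + as635 - intensity).max() < 1e-12 * intensity.max()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compose_species_images(np.ones((2, 2)), np.ones((3, 3)))
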