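"""Pixel-wise TRAST imaging and two-fluorophore unmixing.

A TRAST image stack holds one frame per pulse-train setting.  After
background subtraction, bleach correction and w0-normalization, every
pixel carries its own TRAST curve, which is fitted to the monoexponential
emissive-state model to yield per-pixel maps of the relaxation amplitude
A_TRAST and relaxation time tau_TRAST.  Cumulative 2-D histograms of
(A_TRAST, tau_TRAST) from single-labelled reference cells, projected to
per-axis probability density functions, then let a dual-labelled pixel be
unmixed into its two species' intensity fractions by maximizing the
likelihood of an R-weighted PDF mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter1d
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "TrastImageStack",
    "TrastImage",
    "Pdf2d",
    "correct_and_normalize",
    "smooth_gaussian",
    "fit_pixelwise",
    "build_pdfs",
    "unmix_pixel",
    "unmix_map",
    "compose_species_images",
]


@dataclass
class TrastImageStack:
    """One camera frame per pulse width, with acquisition metadata.

    ``background`` is a static ambient-background frame (or None for
    zero); ``w0_refs`` optionally holds two reference frames recorded at
    the normalization width w0 immediately before and after the series,
    bracketing the acquisition for bleach correction.
    """

    frames: np.ndarray  # (n_widths, H, W)
    widths: np.ndarray  # (n_widths,)
    w0: float
    duty_cycle: float = 0.01
    t_ill: float = 5e-3
    background: np.ndarray | None = None
    w0_refs: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_widths, H, W) array")
        if self.frames.shape[0] != self.widths.size:
            raise ValueError("one frame per pulse width required")
        if not np.any(np.isclose(self.widths, self.w0)):
            raise ValueError("widths must cover the normalization width w0")

    @property
    def w0_index(self) -> int:
        return int(np.argmin(np.abs(self.widths - self.w0)))


@dataclass
class TrastImage:
    """Per-pixel TRAST parameter maps; NaN where the fit did not converge."""

    a_map: np.ndarray
    tau_map: np.ndarray
    intensity_map: np.ndarray
    quality_map: np.ndarray

    @property
    def converged(self) -> np.ndarray:
        return np.isfinite(self.a_map) & np.isfinite(self.tau_map)


def correct_and_normalize(stack: TrastImageStack) -> np.ndarray:
    """Background-subtract, bleach-correct and w0-normalize the stack.

    Returns per-pixel TRAST curves as an (H, W, n_widths) array.  Bleach
    correction assumes the two w0 reference frames bracket the series in
    acquisition order (indices 0 and n+1, frames at 1..n) and interpolates
    the per-pixel attenuation geometrically, which inverts a
    monoexponential per-frame bleach exactly.  Negative background-
    corrected intensities are clipped at zero (warning reports the count).
    """
    frames = stack.frames.copy()
    n = frames.shape[0]
    if stack.background is not None:
        frames -= stack.background[None, :, :]
    refs = stack.w0_refs
    if refs is not None:
        before = np.asarray(refs[0], dtype=float)
        after = np.asarray(refs[1], dtype=float)
        if stack.background is not None:
            before = before - stack.background
            after = after - stack.background
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(before > 0, after / before, 1.0)
        ratio = np.clip(ratio, 1e-3, 1e3)
        for j in range(n):
            frames[j] /= ratio ** ((j + 1) / (n + 1))
    n_neg = int(np.sum(frames < 0))
    if n_neg:
        warnings.warn(
            f"clipped {n_neg} negative background-corrected intensities to 0",
            stacklevel=2,
        )
        frames = np.clip(frames, 0.0, None)
    ref = frames[stack.w0_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        curves = np.where(ref[None] > 0, frames / ref[None], np.nan)
    return np.moveaxis(curves, 0, -1)


# 3x3 Gaussian kernel (sigma = 1 px), normalized to unit sum
_G1 = np.exp(-np.array([1.0, 0.0, 1.0]) / 2.0)
_KERNEL3 = np.outer(_G1, _G1) / np.outer(_G1, _G1).sum()


def smooth_gaussian(image: np.ndarray, kernel: np.ndarray = _KERNEL3) -> np.ndarray:
    """3x3 Gaussian smoothing of a frame or stack; kernel sums to one."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return convolve(image, kernel, mode="nearest")
    if image.ndim == 3:
        return np.stack([convolve(f, kernel, mode="nearest") for f in image])
    raise ValueError("expected a 2-D frame or 3-D stack")


def _monoexp_curve(widths: np.ndarray, w0: float, a: float, tau: float) -> np.ndarray:
    x = widths / tau
    frac = np.where(x > 1e-12, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0 - x / 2)
    m = 1.0 - a + a * frac
    x0 = w0 / tau
    m0 = 1.0 - a + a * (-np.expm1(-x0) / x0 if x0 > 1e-12 else 1.0 - x0 / 2)
    return m / m0


def fit_pixelwise(
    curves: np.ndarray,
    widths: np.ndarray,
    w0: float,
    mask: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
    tau_bounds: tuple[float, float] = (1e-8, 1e-2),
) -> TrastImage:
    """Fit the monoexponential TRAST model to every masked pixel curve.

    (A_TRAST, tau_TRAST) are the only free parameters per pixel.  Pixels
    outside the mask, with non-finite curves, or with non-converged fits
    are NaN in the output maps; per-pixel failures never raise.
    """
    curves = np.asarray(curves, dtype=float)
    h, w_dim, n_w = curves.shape
    widths = np.asarray(widths, dtype=float)
    if mask is None:
        mask = np.ones((h, w_dim), dtype=bool)
    if intensity is None:
        intensity = np.nansum(curves, axis=-1)
    a_map = np.full((h, w_dim), np.nan)
    tau_map = np.full((h, w_dim), np.nan)
    quality = np.full((h, w_dim), np.nan)
    log_w = np.log(widths)
    for i in range(h):
        for j in range(w_dim):
            if not mask[i, j]:
                continue
            y = curves[i, j]
            if not np.all(np.isfinite(y)):
                continue
            a0 = float(np.clip(1.0 - y.min(), 0.02, 0.98))
            # initial tau: width where the curve is halfway down
            half = 1.0 - 0.5 * a0
            k = int(np.searchsorted(-y, -half))
            tau0 = float(np.exp(log_w[min(k, n_w - 1)]))
            tau0 = float(np.clip(tau0, *tau_bounds))
            try:
                res = least_squares(
                    lambda p: _monoexp_curve(widths, w0, p[0], p[1]) - y,
                    x0=[a0, tau0],
                    bounds=([0.0, tau_bounds[0]], [1.0, tau_bounds[1]]),
                    method="trf",
                    xtol=1e-10,
                )
            except Exception:
                continue
            if not res.success:
                continue
            a_map[i, j], tau_map[i, j] = res.x
            quality[i, j] = 2.0 * res.cost
    return TrastImage(
        a_map=a_map, tau_map=tau_map, intensity_map=np.asarray(intensity),
        quality_map=quality,
    )


@dataclass
class Pdf2d:
    """2-D (A_TRAST, tau_TRAST) histogram with unit-area axis projections.

    The amplitude axis is linear on [0, 1]; the relaxation-time axis is
    logarithmic.  ``pdf_a`` is a density per unit A, ``pdf_tau`` a density
    per unit log10(tau), each integrating to one over its axis.
    """

    a_edges: np.ndarray
    tau_edges: np.ndarray
    counts: np.ndarray
    pdf_a: np.ndarray = field(init=False)
    pdf_tau: np.ndarray = field(init=False)
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("no converged pixels: empty histogram")
        proj_a = counts.sum(axis=1)
        proj_tau = counts.sum(axis=0)
        if self.smooth_sigma > 0:
            proj_a = gaussian_filter1d(proj_a, self.smooth_sigma)
            proj_tau = gaussian_filter1d(proj_tau, self.smooth_sigma)
        da = np.diff(self.a_edges)
        dlt = np.diff(np.log10(self.tau_edges))
        self.pdf_a = proj_a / (proj_a * da).sum()
        self.pdf_tau = proj_tau / (proj_tau * dlt).sum()

    def eval_a(self, a: float) -> float:
        """PDF value at amplitude a (0 outside the binned range)."""
        idx = np.searchsorted(self.a_edges, a, side="right") - 1
        if idx < 0 or idx >= self.pdf_a.size:
            return 0.0
        return float(self.pdf_a[idx])

    def eval_tau(self, tau: float) -> float:
        """PDF value at relaxation time tau (0 outside the binned range)."""
        idx = np.searchsorted(self.tau_edges, tau, side="right") - 1
        if idx < 0 or idx >= self.pdf_tau.size:
            return 0.0
        return float(self.pdf_tau[idx])


def build_pdfs(
    images: list[TrastImage] | TrastImage,
    n_a_bins: int = 50,
    n_tau_bins: int = 60,
    tau_range: tuple[float, float] = (0.5e-6, 1e-3),
    smooth_sigma: float = 1.0,
) -> Pdf2d:
    """Cumulative 2-D (A, tau) histogram over one or more TRAST images."""
    if isinstance(images, TrastImage):
        images = [images]
    a_vals, tau_vals = [], []
    for img in images:
        ok = img.converged
        a_vals.append(img.a_map[ok])
        tau_vals.append(img.tau_map[ok])
    a_vals = np.concatenate(a_vals)
    tau_vals = np.concatenate(tau_vals)
    if a_vals.size == 0:
        raise ValueError("no converged pixels in any input image")
    a_edges = np.linspace(0.0, 1.0, n_a_bins + 1)
    tau_edges = np.geomspace(tau_range[0], tau_range[1], n_tau_bins + 1)
    counts, _, _ = np.histogram2d(a_vals, tau_vals, bins=[a_edges, tau_edges])
    return Pdf2d(a_edges=a_edges, tau_edges=tau_edges, counts=counts,
                 smooth_sigma=smooth_sigma)


def _mixture_objective(r, p_cy5, p_as, objective):
    terms = r * p_cy5 + (1.0 - r) * p_as
    if objective == "product":
        return float(np.prod(terms))
    return float(np.sum(terms))


def unmix_pixel(
    a: float,
    tau: float,
    pdf_cy5: Pdf2d,
    pdf_as635: Pdf2d,
    objective: str = "product",
    return_flag: bool = False,
):
    """Cyanine intensity fraction R maximizing the PDF-mixture likelihood.

    The likelihood is the product over the two projected axes of
    R*PDF_Cy5 + (1-R)*PDF_AS635 evaluated at the pixel's (A, tau)
    (``objective='sum'`` switches to the additive variant).  Maximized on
    a coarse R grid followed by bounded local refinement.  Pixels where
    both species are equally likely return 0.5; pixels outside both
    supports return NaN.  Flags: 'ok', 'degenerate', 'outside'.
    """
    if objective not in {"product", "sum"}:
        raise ValueError("objective must be 'product' or 'sum'")
    p_cy5 = np.array([pdf_cy5.eval_a(a), pdf_cy5.eval_tau(tau)])
    p_as = np.array([pdf_as635.eval_a(a), pdf_as635.eval_tau(tau)])
    informative = (p_cy5 > 0) | (p_as > 0)
    if not informative.any():
        r, flag = np.nan, "outside"
    elif np.allclose(p_cy5[informative], p_as[informative], rtol=1e-9):
        r, flag = 0.5, "degenerate"
    else:
        pc, pa = p_cy5[informative], p_as[informative]
        grid = np.linspace(0.0, 1.0, 101)
        vals = [_mixture_objective(g, pc, pa, objective) for g in grid]
        best = grid[int(np.argmax(vals))]
        lo, hi = max(0.0, best - 0.01), min(1.0, best + 0.01)
        res = minimize_scalar(
            lambda x: -_mixture_objective(x, pc, pa, objective),
            bounds=(lo, hi), method="bounded",
        )
        r = float(res.x) if res.fun <= -max(vals) else float(best)
        flag = "ok"
    return (r, flag) if return_flag else r


def unmix_map(
    image: TrastImage,
    pdf_cy5: Pdf2d,
    pdf_as635: Pdf2d,
    objective: str = "product",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel unmixing of a fitted TRAST image; returns (R_map, flags)."""
    h, w = image.a_map.shape
    r_map = np.full((h, w), np.nan)
    flags = np.full((h, w), "unfit", dtype=object)
    for i in range(h):
        for j in range(w):
            if not image.converged[i, j]:
                continue
            r, fl = unmix_pixel(
                image.a_map[i, j], image.tau_map[i, j], pdf_cy5, pdf_as635,
                objective=objective, return_flag=True,
            )
            r_map[i, j], flags[i, j] = r, fl
    return r_map, flags


def compose_species_images(
    r_map: np.ndarray, intensity_map: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split total intensity into the two species' images; sum is conserved."""
    r_map = np.asarray(r_map, dtype=float)
    intensity_map = np.asarray(intensity_map, dtype=float)
    if r_map.shape != intensity_map.shape:
        raise ValueError("r_map and intensity_map shapes must match")
    image_cy5 = r_map * intensity_map
    return image_cy5, intensity_map - image_cy5
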