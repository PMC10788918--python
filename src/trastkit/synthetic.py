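"""Synthetic data with known ground truth for all four readout modalities.

Every generator drives the package's own forward models and corrupts them
with the noise a real measurement would show: Poisson shot noise on
photon counts for TRAST points and image frames (applied before
normalization, so the reference point's noise propagates exactly as in a
real w0-normalization), lag-dependent multiplicative noise mimicking
correlator statistics for FCS, and multiplicative camera noise for flow
profiles.  All randomness flows from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import trast as _trast
from .fcs import FcsCurve, FcsModelParams, fcs_model, multispecies_fcs, multitau_lags
from .flow import CurtainField, FlowConfig, FlowProfile, mixture_profile, predict_profile
from .imaging import TrastImageStack
from .photophysics import Excitation, FluorophoreModel, preset
from .trast import MonoexpTrastParams, PulseTrain, TrastCurve, default_width_grid

__all__ = [
    "SyntheticSpec",
    "gen_trast_curve",
    "gen_fcs_curve",
    "gen_fcs_set",
    "gen_flow_profile",
    "gen_flow_set",
    "gen_cell_stack",
    "scenario",
]


@dataclass
class SyntheticSpec:
    """Declarative recipe for one synthetic data set (used by the CLI)."""

    scenario: str
    seed: int = 0
    options: dict = dc_field(default_factory=dict)


def gen_trast_curve(
    model: FluorophoreModel | MonoexpTrastParams,
    exc: Excitation | None = None,
    widths: np.ndarray | None = None,
    photon_budget: float = 1e5,
    duty_cycle: float = 0.01,
    seed: int = 0,
) -> tuple[TrastCurve, dict]:
    """Shot-noise-corrupted TRAST curve plus its generating truth.

    Expected photon counts per point are ``photon_budget`` times the
    pulse-averaged relative fluorescence; each point (including the w0
    reference) is Poisson-sampled and the noisy series normalized by its
    noisy w0 point.  ``photon_budget=inf`` (or 0) returns the exact model
    curve.
    """
    rng = np.random.default_rng(seed)
    if widths is None:
        widths = default_width_grid()
    trains = PulseTrain.series(widths, duty_cycle=duty_cycle)
    clean = _trast.trast_curve(model, exc, trains)
    truth = {"model": model, "excitation": exc, "values": clean.values.copy()}
    if not np.isfinite(photon_budget) or photon_budget <= 0:
        return clean, truth
    expected = photon_budget * clean.values
    counts = rng.poisson(expected).astype(float)
    i0 = int(np.argmin(np.abs(clean.widths - clean.w0)))
    ref = max(counts[i0], 1.0)
    values = counts / ref
    sd = values * np.sqrt(1.0 / np.maximum(counts, 1.0) + 1.0 / ref)
    return TrastCurve(widths=clean.widths, values=values, sd=sd, w0=clean.w0), truth


def gen_fcs_curve(
    params: FcsModelParams | list,
    lags: np.ndarray | None = None,
    noise_level: float = 0.02,
    irradiance: float | None = None,
    seed: int = 0,
) -> tuple[FcsCurve, dict]:
    """Noisy FCS curve from the single- or multi-species forward model.

    Noise is multiplicative with a relative standard deviation of
    ``noise_level / sqrt(lag_index + 1)`` — larger at short lags, as for a
    multi-tau correlator averaging fewer samples there.
    """
    rng = np.random.default_rng(seed)
    if lags is None:
        lags = multitau_lags()
    if isinstance(params, FcsModelParams):
        clean = fcs_model(params, lags)
    else:
        clean = multispecies_fcs(params, lags)
    truth = {"params": params, "g": clean.g.copy()}
    rel_sd = noise_level / np.sqrt(np.arange(lags.size) + 1.0)
    g = clean.g * (1.0 + rel_sd * rng.standard_normal(lags.size))
    sd = np.abs(clean.g) * rel_sd
    return (
        FcsCurve(lags=lags, g=g, sd=sd, irradiance=irradiance),
        truth,
    )


def gen_fcs_set(
    model: FluorophoreModel,
    irradiances,
    diff: FcsModelParams | None = None,
    lags: np.ndarray | None = None,
    noise_level: float = 0.02,
    wavelength: float = 640.0,
    seed: int = 0,
) -> tuple[list[FcsCurve], dict]:
    """Irradiance series of FCS curves from one photophysical scheme.

    The dark term of each curve follows from the scheme's effective rates
    at that irradiance; diffusion parameters are shared.  This is the
    standard input for the global power-series fit.
    """
    from .fcs import dark_terms_from_model

    if diff is None:
        diff = FcsModelParams(n_mol=2.0, tau_d=1e-4)
    if lags is None:
        lags = multitau_lags()
    rng = np.random.default_rng(seed)
    curves = []
    for phi in irradiances:
        exc = Excitation(irradiance=phi, wavelength=wavelength)
        a, tau_dark = dark_terms_from_model(model, exc)
        p = FcsModelParams(
            n_mol=diff.n_mol, tau_d=diff.tau_d, a_dark=a,
            tau_dark=tau_dark if np.isfinite(tau_dark) else 1.0,
            structure=diff.structure,
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        curve, _ = gen_fcs_curve(
            p, lags=lags, noise_level=noise_level, irradiance=phi, seed=sub_seed
        )
        curve.wavelength = wavelength
        curves.append(curve)
    truth = {"model": model, "diff": diff, "irradiances": list(irradiances)}
    return curves, truth


def gen_flow_profile(
    species,
    field: CurtainField,
    flow: FlowConfig,
    noise_level: float = 0.01,
    r_cy5: float | None = None,
    q_ratio: float = 2.2,
    seed: int = 0,
) -> tuple[FlowProfile, dict]:
    """Noisy flow-TRAST profile for a pure species or a two-species mixture.

    ``species`` is an isomerization model or ``'non_isomerizing'``; when
    ``r_cy5`` is given, the brightness-weighted mixture of the model
    profile and the excitation profile is generated instead.
    """
    rng = np.random.default_rng(seed)
    if r_cy5 is not None:
        cy5 = predict_profile(species, field, flow, label="cy5")
        cf = predict_profile("non_isomerizing", field, flow, t_grid=cy5.t,
                             label="cf")
        clean = mixture_profile(r_cy5, q_ratio, cy5, cf, label=f"mix R={r_cy5}")
    else:
        clean = predict_profile(species, field, flow)
    truth = {"species": species, "r_cy5": r_cy5, "f_norm": clean.f_norm.copy()}
    f = clean.f_norm * (1.0 + noise_level * rng.standard_normal(clean.f_norm.size))
    return (
        FlowProfile(t=clean.t, f_norm=np.clip(f, 0.0, None), label=clean.label,
                    velocity=clean.velocity),
        truth,
    )


def gen_flow_set(
    model,
    field: CurtainField,
    rates_ul_min,
    noise_level: float = 0.01,
    seed: int = 0,
) -> tuple[list[FlowProfile], list[FlowConfig], dict]:
    """Pure-dye profiles across a series of pump rates (uL/min)."""
    rng = np.random.default_rng(seed)
    profiles, flows = [], []
    for rate in rates_ul_min:
        cfg = FlowConfig.from_ul_per_min(rate)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        prof, _ = gen_flow_profile(model, field, cfg, noise_level=noise_level,
                                   seed=sub_seed)
        prof.label = f"{rate:g} uL/min"
        profiles.append(prof)
        flows.append(cfg)
    return profiles, flows, {"model": model, "rates_ul_min": list(rates_ul_min)}


# ---------------------------------------------------------------------------
# Dual-label cell image stacks


def _cell_masks(shape: tuple[int, int], rng) -> tuple[np.ndarray, np.ndarray]:
    """Nuclear-rim mask (rhodamine-like label) and filament mask (cyanine)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    ry, rx = h * 0.22, w * 0.26
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    rim = (r2 > 0.72) & (r2 < 1.3)
    filaments = np.zeros(shape, dtype=bool)
    from skimage.draw import line

    for _ in range(6):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        r1, c1 = rng.integers(0, h), rng.integers(0, w)
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        filaments[rr, cc] = True
    from scipy.ndimage import binary_dilation

    filaments = binary_dilation(filaments, iterations=1)
    filaments &= ~rim  # disjoint labels: per-pixel truth R in {0, 1}
    return rim, filaments


def gen_cell_stack(
    shape: tuple[int, int] = (48, 48),
    widths: np.ndarray | None = None,
    cy5_params: MonoexpTrastParams | None = None,
    as635_params: MonoexpTrastParams | None = None,
    photon_budget: float = 2e4,
    background: float = 20.0,
    bleach_per_frame: float = 0.0,
    duty_cycle: float = 0.01,
    seed: int = 0,
) -> tuple[TrastImageStack, dict]:
    """Synthetic dual-label cell TRAST stack with per-pixel ground truth.

    Emulates a cell with a nuclear rim carrying a triplet-like label
    (small amplitude, tau below 5 us) and cytoskeletal filaments carrying
    an isomerization-like label (large amplitude, tau of tens of us).
    Frames are Poisson photon counts on top of a constant background;
    optional monoexponential bleaching attenuates successive frames and
    is recorded in two bracketing w0 reference frames.  Truth maps carry
    per-pixel species fraction, amplitude, relaxation time and intensity.
    """
    rng = np.random.default_rng(seed)
    if widths is None:
        widths = default_width_grid()
    widths = np.asarray(widths, dtype=float)
    w0 = float(widths.min())
    if cy5_params is None:
        cy5_params = MonoexpTrastParams(a_trast=0.45, tau_trast=30e-6)
    if as635_params is None:
        as635_params = MonoexpTrastParams(a_trast=0.2, tau_trast=2.5e-6)
    rim, filaments = _cell_masks(shape, rng)
    a_true = np.full(shape, np.nan)
    tau_true = np.full(shape, np.nan)
    r_true = np.full(shape, np.nan)
    a_true[rim], tau_true[rim], r_true[rim] = (
        as635_params.a_trast, as635_params.tau_trast, 0.0,
    )
    a_true[filaments], tau_true[filaments], r_true[filaments] = (
        cy5_params.a_trast, cy5_params.tau_trast, 1.0,
    )
    intensity = np.zeros(shape)
    intensity[rim] = photon_budget * rng.uniform(0.6, 1.0, rim.sum())
    intensity[filaments] = photon_budget * rng.uniform(0.6, 1.0, filaments.sum())

    mean_cy5 = np.asarray(
        _trast.mean_pulse_fluorescence(cy5_params, None, widths)
    )
    mean_as = np.asarray(
        _trast.mean_pulse_fluorescence(as635_params, None, widths)
    )
    n_frames = widths.size
    frames = np.empty((n_frames, *shape))
    # acquisition order: w0 ref (idx 0), frames 1..n, w0 ref (idx n+1)
    bleach = lambda idx: (1.0 - bleach_per_frame) ** idx
    expect0 = intensity * (rim * 1.0 + filaments * 1.0)  # w0 value ~ 1
    ref_before = rng.poisson(expect0 * bleach(0) + background).astype(float)
    for k in range(n_frames):
        expect = intensity * (rim * mean_as[k] + filaments * mean_cy5[k])
        frames[k] = rng.poisson(expect * bleach(k + 1) + background)
    ref_after = rng.poisson(expect0 * bleach(n_frames + 1) + background).astype(
        float
    )
    stack = TrastImageStack(
        frames=frames,
        widths=widths,
        w0=w0,
        duty_cycle=duty_cycle,
        background=np.full(shape, background),
        w0_refs=(ref_before, ref_after),
    )
    truth = {
        "a_map": a_true,
        "tau_map": tau_true,
        "r_map": r_true,
        "intensity": intensity,
        "rim": rim,
        "filaments": filaments,
        "cy5_params": cy5_params,
        "as635_params": as635_params,
    }
    return stack, truth


def scenario(name: str, seed: int = 0) -> dict:
    """Shipped scenario presets mirroring the study's measurement series."""
    if name == "fig2g_mixtures":
        params = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        out = {"curves": [], "r_values": [0.0, 0.25, 0.5, 0.75, 1.0],
               "q_ratio": 2.7, "params_cy5": params}
        widths = default_width_grid()
        trains = PulseTrain.series(widths)
        rng = np.random.default_rng(seed)
        for r in out["r_values"]:
            clean = _trast.mixture_trast_curve(params, r, out["q_ratio"], trains)
            counts = rng.poisson(1e5 * clean.values).astype(float)
            ref = max(counts[0], 1.0)
            out["curves"].append(
                TrastCurve(widths=clean.widths, values=counts / ref, w0=clean.w0)
            )
        return out
    if name == "fig3a_flowrates":
        field = CurtainField(peak_irradiance=1.3e3)
        model = preset("cy5_free")
        model = type(model)(
            sigma_n=model.sigma_n, sigma_biso=model.sigma_biso, k_iso=model.k_iso,
            k_biso_th=0.0016e6, k10=model.k10, name="cy5_flow",
        )
        profiles, flows, truth = gen_flow_set(
            model, field, [200, 400, 600, 800, 1000], seed=seed
        )
        return {"profiles": profiles, "flows": flows, "field": field,
                "model": model, "truth": truth}
    if name == "fig5_cells":
        stack, truth = gen_cell_stack(seed=seed)
        return {"stack": stack, "truth": truth}
    raise KeyError(f"unknown scenario {name!r}")
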