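# trastkit

Simulation and fitting of photoinduced **dark-state kinetics** of
fluorophores — the reversible blinking into long-lived nonemissive states
that limits single-molecule brightness but also carries an orthogonal,
spectrally independent identification signal.  `trastkit` implements the
computational core of dark-state "bar-coding": telling spectrally
near-identical fluorophores apart (a cyanine such as Cy5 versus rhodamines
such as CF640R or Abberior Star 635) through their very different dark-state
transitions, across four readout modalities:

- **stationary TRAST curves** — normalized pulse-train-averaged fluorescence
  ⟨F_exc(w)⟩ versus pulse width w;
- **FCS autocorrelation curves** — dark-state relaxation terms on top of the
  diffusion decay;
- **microfluidic flow-TRAST profiles** — fluorescence of species flowing
  through two excitation curtains, with incomplete dark-state recovery in
  between;
- **pixel-wise TRAST images** — per-pixel (A_TRAST, τ_TRAST) maps and
  PDF-based two-species unmixing.

It is aimed at biophysicists and microscopists who want to model these
measurements, test identifiability of rate constants, or prototype analysis
pipelines on realistic synthetic data with known ground truth.

## The models

**Cyanine (trans–cis photoisomerization).**  A fluorescent all-*trans*
state N and a dark *cis* photoisomer P exchange with effective rates

```
k'_iso  = k_exc/(k_exc + k10) · k_iso          (excitation-driven)
k'_biso = σ_biso · Φ·λ/(hc)   + k_biso^Th      (photo-driven + thermal)
k_exc   = σ_N · Φ·λ/(hc)
```

Because σ_P, k_biso and the *cis* excited-state decay cannot be determined
individually, the photo-driven return path is lumped into the single cross
section σ_biso.  With both directions excitation-driven, the dark-state
amplitude A = k'_iso/(k'_iso + k'_biso) is nearly irradiance-independent —
the cyanine's fingerprint.

**Rhodamine (triplet crossing).**  Intersystem crossing
k'_isc = k_exc/(k_exc + k10)·k_isc populates a triplet that decays at the
excitation-*independent* rate k_T, so A grows with irradiance and vanishes
at low power.

During a rectangular excitation pulse the emissive-state population relaxes
as [S](t) = 1 − A(1 − e^(−t/τ)), giving the closed-form TRAST point

```
⟨F_exc(w)⟩ = 1 − A + (Aτ/w)(1 − e^(−w/τ))
```

and the FCS curve G(τ) = (1/N_m)·G_diff(τ)·(1 + A/(1−A)·e^(−τ/τ_dark)).
Mixtures enter FCS weighted by molecular brightness squared and TRAST/flow
profiles weighted linearly.

## Worked example

```python
from trastkit.photophysics import preset, Excitation, steady_state
from trastkit.synthetic import gen_trast_curve, gen_fcs_set
from trastkit.trast import MonoexpTrastParams, MonoexpTrastModel
from trastkit.fcs import FcsGlobalModel

# dark cis fraction of free Cy5 at a typical FCS irradiance
steady_state(preset("cy5_free"), Excitation(16e3, 640))
# 0.5373675310861712   -> about half the molecules are dark at steady state

# fit a shot-noise-corrupted synthetic TRAST curve (truth: A=0.45, tau=12.4 us)
curve, _ = gen_trast_curve(MonoexpTrastParams(0.45, 12.4e-6),
                           photon_budget=1e5, seed=1)
print(MonoexpTrastModel(curve).fit().summary())
```

```
monoexp TRAST results
==========================================================
converged: True   nfev: 14   red. chi^2: 0.3496
----------------------------------------------------------
parameter                        value         std err
a_trast                       0.449915     0.000714755
tau_trast                  1.24252e-05     9.66616e-08
==========================================================
```

The amplitude and relaxation time come back at 0.450 and 12.43 μs with
sub-percent standard errors — the blinking kinetics are read off the
time-averaged signal alone, with no time-resolved detection.

A global FCS fit shares the photophysical rates across an irradiance
series while diffusion time and molecule number stay free per curve:

```python
curves, _ = gen_fcs_set(preset("cy5_free"), [10e3, 30e3, 100e3],
                        noise_level=0.02, seed=1)
res = FcsGlobalModel(curves, "isomerization", sigma=6.2e-16).fit()
res.params["k_iso_us"], res.params["sigma_biso_e16"]
# (29.0371, 0.150369)   -> generating truth was (29, 0.15)
```

## Command line

A thin CLI wraps the library:

```
trastkit trast simulate --model cy5_free --irradiance 1e3 --out curve.csv
trastkit trast fit curve.csv
trastkit fcs simulate --model cy5_free --irradiance 10e3 --irradiance 100e3 --out fcsdir/
trastkit fcs fit fcsdir/manifest.json
trastkit flow simulate --rate 1000 --out prof.csv
trastkit flow fit prof.csv --rate 1000
trastkit synth fig5_cells --seed 1 --out cells/
trastkit image fit cells/cells.tif --out maps.tif
trastkit run session.yaml        # exit codes: 0 ok, 2 config, 3 non-convergence
```

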