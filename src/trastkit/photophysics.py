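"""Fluorophore dark-state schemes and excitation-driven rate constants.

Two electronic-state schemes are modelled.  Cyanines such as Cy5 switch
between a fluorescent all-*trans* state N and a dark *cis* photoisomer P;
both the forward isomerization (via S1 of N) and the photo-driven part of
the back-isomerization are excitation-driven, while a slow thermal channel
``k_biso_th`` returns P to N in the dark.  Because the *cis*-side cross
section, back-isomerization rate and *cis* excited-state lifetime are not
individually identifiable, the photo-driven return path is lumped into a
single effective cross section ``sigma_biso``.  Rhodamines such as CF640R
instead populate a triplet state T by intersystem crossing from S1, with an
excitation-independent decay ``k_T`` back to the singlet manifold.

All cross sections are stored in cm^2, irradiances in W/cm^2 and rates in
s^-1; helper constructors accept the field-customary us^-1 where noted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.constants import c as _c_light, h as _h_planck
from scipy.linalg import expm

__all__ = [
    "Excitation",
    "IsomerizationModel",
    "TripletModel",
    "excitation_rate",
    "effective_iso_rates",
    "effective_isc_rate",
    "steady_state",
    "evolve_population",
    "rate_matrix",
    "load_model",
    "dump_model",
    "preset",
    "PRESETS",
]

US = 1e-6  # one microsecond in seconds


@dataclass(frozen=True)
class Excitation:
    """Constant excitation condition: irradiance (W/cm^2) and wavelength (nm)."""

    irradiance: float
    wavelength: float = 640.0

    def __post_init__(self) -> None:
        if self.irradiance < 0:
            raise ValueError(f"irradiance must be >= 0, got {self.irradiance}")
        if not 300.0 <= self.wavelength <= 1000.0:
            raise ValueError(
                f"wavelength must be in [300, 1000] nm, got {self.wavelength}"
            )

    @property
    def photon_flux(self) -> float:
        """Photon flux density (photons cm^-2 s^-1) = Phi * lambda / (h c)."""
        return self.irradiance * self.wavelength * 1e-9 / (_h_planck * _c_light)


@dataclass(frozen=True)
class IsomerizationModel:
    """Trans-cis photoisomerization scheme (N <-> P) of a cyanine dye.

    Parameters
    ----------
    sigma_n : float
        Excitation cross section of the fluorescent trans state N (cm^2).
    sigma_biso : float
        Lumped photo-driven back-isomerization cross section (cm^2).
    k_iso : float
        Isomerization rate from S1 of N (s^-1).
    k_biso_th : float
        Thermal (dark) back-isomerization rate P -> N (s^-1).
    k10 : float
        S1 -> S0 decay rate of N (s^-1); default 1e9 (1 ns lifetime).
    k_isc, k_t : float, optional
        Triplet branch rates (s^-1) used by the high-irradiance
        three-state extension (N, P, T).
    triplet_threshold : float
        Irradiance (W/cm^2) above which the triplet branch is switched on;
        a minor triplet buildup only matters above ~100 kW/cm^2.
    """

    sigma_n: float
    sigma_biso: float
    k_iso: float
    k_biso_th: float = 0.0
    k10: float = 1e9
    k_isc: float | None = None
    k_t: float | None = None
    triplet_threshold: float = 100e3
    name: str = "isomerization"
    scheme: str = field(default="isomerization", init=False)

    def __post_init__(self) -> None:
        for attr in ("sigma_n", "sigma_biso", "k_iso", "k_biso_th", "k10"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.k10 <= self.k_iso:
            raise ValueError("k10 must exceed k_iso (fluorescence decay dominates)")
        if self.sigma_biso > self.sigma_n:
            raise ValueError("sigma_biso must not exceed sigma_n")

    def triplet_active(self, exc: Excitation) -> bool:
        return (
            self.k_isc is not None
            and self.k_t is not None
            and exc.irradiance > self.triplet_threshold
        )


@dataclass(frozen=True)
class TripletModel:
    """Singlet-triplet scheme (S <-> T) of a rhodamine-like dye."""

    sigma_s: float
    k_isc: float
    k_t: float
    k10: float = 1e9
    name: str = "triplet"
    scheme: str = field(default="triplet", init=False)

    def __post_init__(self) -> None:
        for attr in ("sigma_s", "k_isc", "k_t", "k10"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.k_isc >= self.k10:
            raise ValueError("k_isc must be smaller than k10")


FluorophoreModel = IsomerizationModel | TripletModel


def excitation_rate(sigma: float, exc: Excitation) -> float:
    """Photon absorption rate k_exc = sigma * Phi * lambda / (h c), in s^-1."""
    if sigma < 0:
        raise ValueError(f"cross section must be >= 0, got {sigma}")
    return sigma * exc.photon_flux


def effective_iso_rates(
    model: IsomerizationModel, exc: Excitation
) -> tuple[float, float]:
    """Effective isomerization / back-isomerization rates (s^-1) of N <-> P.

    The forward rate is the S1 branching ratio times the isomerization
    rate, k'_iso = k_exc/(k_exc + k10) * k_iso, saturating at k_iso.  The
    return rate combines the lumped photo-driven channel with the thermal
    one, k'_biso = sigma_biso * photon_flux + k_biso_th.
    """
    k_exc = excitation_rate(model.sigma_n, exc)
    k_iso_eff = k_exc / (k_exc + model.k10) * model.k_iso if k_exc > 0 else 0.0
    k_biso_eff = model.sigma_biso * exc.photon_flux + model.k_biso_th
    return k_iso_eff, k_biso_eff


def effective_isc_rate(model: TripletModel, exc: Excitation) -> float:
    """Effective intersystem-crossing rate k'_isc = k_exc/(k_exc+k10) * k_isc."""
    k_exc = excitation_rate(model.sigma_s, exc)
    if k_exc == 0.0:
        return 0.0
    return k_exc / (k_exc + model.k10) * model.k_isc


def on_off_rates(model: FluorophoreModel, exc: Excitation) -> tuple[float, float]:
    """(dark-on, dark-off) rate pair of the two-state reduction, in s^-1."""
    if isinstance(model, IsomerizationModel):
        return effective_iso_rates(model, exc)
    if isinstance(model, TripletModel):
        return effective_isc_rate(model, exc), model.k_t
    raise TypeError(f"unsupported model type {type(model)!r}")


def steady_state(model: FluorophoreModel, exc: Excitation) -> float:
    """Steady-state dark fraction k_on / (k_on + k_off) of the two-state scheme."""
    k_on, k_off = on_off_rates(model, exc)
    if k_on + k_off == 0.0:
        raise ValueError("all rates vanish; steady state undefined")
    return k_on / (k_on + k_off)


def rate_matrix(model: FluorophoreModel, exc: Excitation) -> np.ndarray:
    """First-order rate matrix M with dp/dt = M p.

    State order is (bright, dark) for the two-state reduction, or
    (N, P, T) when the isomerization model's triplet branch is active at
    this irradiance.
    """
    if isinstance(model, IsomerizationModel) and model.triplet_active(exc):
        k_iso_eff, k_biso_eff = effective_iso_rates(model, exc)
        k_exc = excitation_rate(model.sigma_n, exc)
        k_isc_eff = k_exc / (k_exc + model.k10) * model.k_isc if k_exc else 0.0
        return np.array(
            [
                [-(k_iso_eff + k_isc_eff), k_biso_eff, model.k_t],
                [k_iso_eff, -k_biso_eff, 0.0],
                [k_isc_eff, 0.0, -model.k_t],
            ]
        )
    k_on, k_off = on_off_rates(model, exc)
    return np.array([[-k_on, k_off], [k_on, -k_off]])


def evolve_population(
    model: FluorophoreModel,
    exc: Excitation,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Occupancies over time under constant excitation, starting all-bright.

    Returns an array of shape (len(t_grid), n_states); column 0 is the
    bright (emissive singlet manifold) occupancy.  Solved by matrix
    exponential of the rate matrix, which is exact for these linear
    schemes.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or (t.size and t[0] < 0):
        raise ValueError("t_grid must be a sorted 1-D array of times >= 0")
    m = rate_matrix(model, exc)
    n = m.shape[0]
    p0 = np.zeros(n)
    p0[0] = 1.0
    if n == 2:
        # closed form: bright(t) = ss_bright + (1 - ss_bright) e^{-lam t}
        k_on, k_off = -m[0, 0], m[0, 1]
        lam = k_on + k_off
        if lam == 0.0:
            return np.tile(p0, (t.size, 1))
        ss_bright = k_off / lam
        bright = ss_bright + (1.0 - ss_bright) * np.exp(-lam * t)
        return np.column_stack([bright, 1.0 - bright])
    occ = np.array([expm(m * ti) @ p0 for ti in t])
    # the rate matrix conserves probability exactly; strip expm roundoff
    return occ / occ.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Presets and serialization

PRESETS: dict[str, FluorophoreModel] = {
    # Free Cy5 in aqueous solution; globally fitted isomerization kinetics.
    # Triplet branch parameters enter only above the saturation threshold.
    "cy5_free": IsomerizationModel(
        sigma_n=6.2e-16,
        sigma_biso=0.15e-16,
        k_iso=29.0 / US,
        k_biso_th=0.0,
        k10=1e9,
        k_isc=1.1 / US,
        k_t=0.5 / US,
        name="cy5_free",
    ),
    # Cy5 on single-labelled small unilamellar vesicles: slower isomerization.
    "cy5_suv": IsomerizationModel(
        sigma_n=6.2e-16,
        sigma_biso=0.042e-16,
        k_iso=6.2 / US,
        k_biso_th=0.0,
        k10=1e9,
        name="cy5_suv",
    ),
    "cf640r": TripletModel(
        sigma_s=4.0e-16,
        k_isc=0.7 / US,
        k_t=0.5 / US,
        k10=1e9,
        name="cf640r",
    ),
}


def preset(name: str) -> FluorophoreModel:
    """Return a shipped fluorophore preset by (case-insensitive) name."""
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[key]


def dump_model(model: FluorophoreModel, path: str | Path) -> None:
    """Serialize a fluorophore model to a JSON (or YAML) record."""
    record = {"name": model.name, "scheme": model.scheme, "parameters": {}}
    params = asdict(model)
    params.pop("name")
    params.pop("scheme")
    record["parameters"] = params
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(record))
    else:
        path.write_text(json.dumps(record, indent=2))


def load_model(path: str | Path) -> FluorophoreModel:
    """Load a fluorophore model from a JSON/YAML record written by dump_model."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        record = yaml.safe_load(path.read_text())
    else:
        record = json.loads(path.read_text())
    cls = {"isomerization": IsomerizationModel, "triplet": TripletModel}[
        record["scheme"]
    ]
    return cls(name=record.get("name", record["scheme"]), **record["parameters"])
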