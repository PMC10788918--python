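"""Session configs: one YAML file describing a complete fitting run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._results import FitResults
from .fcs import FcsGlobalModel
from .flow import CurtainField, FlowConfig, FlowModel
from .io import read_curve
from .photophysics import preset
from .trast import MonoexpTrastModel

__all__ = ["SessionConfig", "SessionConfigError", "FitConvergenceError", "run_session"]


class SessionConfigError(ValueError):
    """Invalid or incomplete session configuration."""


class FitConvergenceError(RuntimeError):
    """The optimizer reported non-convergence."""


@dataclass
class SessionConfig:
    """Declarative description of one fitting session."""

    modality: str
    inputs: list[str]
    model: str | None = None
    scheme: str | None = None
    sigma: float | None = None
    seed: int = 0
    output: str | None = None
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SessionConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SessionConfigError(f"{path}: unknown keys {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise SessionConfigError(f"{path}: {exc}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.modality not in {"trast", "fcs", "flow"}:
            raise SessionConfigError(
                f"modality must be trast/fcs/flow, got {self.modality!r}"
            )
        if not self.inputs:
            raise SessionConfigError("inputs list is empty")
        for p in self.inputs:
            if not Path(p).exists():
                raise SessionConfigError(f"input file not found: {p}")
        if self.modality == "fcs":
            if self.scheme not in {"isomerization", "triplet"}:
                raise SessionConfigError(
                    "fcs sessions need scheme: isomerization|triplet"
                )
            if self.sigma is None:
                raise SessionConfigError("fcs sessions need sigma (cm^2)")


def _fit_results_payload(res: FitResults) -> dict:
    payload = res.to_dict()
    payload["residual_rms"] = float(np.sqrt(np.mean(res.residual**2)))
    return payload


def run_session(config: SessionConfig | str | Path) -> dict:
    """Execute a session and return (and optionally write) its report.

    The report echoes the config and seed and records estimates,
    uncertainties and a residual summary, making the run reproducible
    from the report alone.  Raises :class:`SessionConfigError` for bad
    configs and :class:`FitConvergenceError` for flagged fits.
    """
    if not isinstance(config, SessionConfig):
        config = SessionConfig.from_yaml(config)
    config.validate()
    np.random.seed(config.seed % 2**31)

    if config.modality == "trast":
        results = []
        for p in config.inputs:
            curve = read_curve(p, "trast")
            res = MonoexpTrastModel(curve).fit(**config.options.get("start", {}))
            results.append((p, res))
    elif config.modality == "fcs":
        curves = [read_curve(p, "fcs") for p in config.inputs]
        irr = config.options.get("irradiances")
        if irr is not None:
            for c, phi in zip(curves, irr):
                c.irradiance = phi
        model = FcsGlobalModel(
            curves, scheme=config.scheme, sigma=config.sigma,
            structure=config.options.get("structure", 5.0),
        )
        results = [("global", model.fit(**config.options.get("start", {})))]
    else:  # flow
        profiles = [read_curve(p, "flow") for p in config.inputs]
        base = preset(config.model or "cy5_free")
        field_cfg = config.options.get("field", {})
        field_obj = CurtainField(
            peak_irradiance=field_cfg.get("peak_irradiance", 1.3e3),
            centers=tuple(field_cfg.get("centers", (0.0, 50e-6))),
            e_radius=field_cfg.get("e_radius", 15e-6),
        )
        rates = config.options.get("rates_ul_min")
        if rates is None:
            raise SessionConfigError("flow sessions need options.rates_ul_min")
        flows = [FlowConfig.from_ul_per_min(r) for r in rates]
        r_fixed = config.options.get("r_fixed", [1.0] * len(profiles))
        r_fixed = [None if r == "free" else r for r in r_fixed]
        model = FlowModel(
            profiles, base, field_obj, flows,
            q_ratio=config.options.get("q_ratio", 2.2), r_fixed=r_fixed,
        )
        results = [("global", model.fit())]

    failed = [name for name, res in results if not res.success]
    report = {
        "software": {"name": "trastkit", "version": __version__},
        "seed": config.seed,
        "config": {
            "modality": config.modality,
            "inputs": list(config.inputs),
            "model": config.model,
            "scheme": config.scheme,
            "sigma": config.sigma,
            "options": config.options,
        },
        "results": {name: _fit_results_payload(res) for name, res in results},
    }
    if config.output:
        Path(config.output).parent.mkdir(parents=True, exist_ok=True)
        Path(config.output).write_text(json.dumps(report, indent=2))
    if failed:
        raise FitConvergenceError(
            f"fit(s) {failed} did not converge (partial report "
            f"{'written' if config.output else 'returned'})"
        )
    return report
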