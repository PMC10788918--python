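"""Lightweight Results wrapper shared by all fitting models."""

from __future__ import annotations

import numpy as np


class FitResults:
    """Holds estimates, uncertainties and diagnostics of one least-squares fit.

    Thin, uniform wrapper around an :mod:`lmfit` minimizer result.  Access
    point estimates via :attr:`params`, 1-sigma uncertainties via
    :attr:`stderr`; :attr:`success` is False when the optimizer did not
    converge (non-convergence is flagged, never silent).
    """

    def __init__(self, lmfit_result, model_name: str = "fit") -> None:
        self._raw = lmfit_result
        self.model_name = model_name
        self.params = {k: p.value for k, p in lmfit_result.params.items()}
        self.stderr = {k: p.stderr for k, p in lmfit_result.params.items()}
        self.residual = np.asarray(lmfit_result.residual)
        self.success = bool(lmfit_result.success)
        self.message = getattr(lmfit_result, "message", "")
        self.redchi = getattr(lmfit_result, "redchi", np.nan)
        self.nfev = getattr(lmfit_result, "nfev", -1)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def summary(self) -> str:
        """Formatted table of estimates and 1-sigma uncertainties."""
        lines = [
            f"{self.model_name} results",
            "=" * 58,
            f"converged: {self.success}   nfev: {self.nfev}   "
            f"red. chi^2: {self.redchi:.4g}",
            "-" * 58,
            f"{'parameter':<22}{'value':>16}{'std err':>16}",
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            se_s = f"{se:>16.6g}" if se is not None else f"{'--':>16}"
            lines.append(f"{k:<22}{v:>16.6g}{se_s}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "success": self.success,
            "message": self.message,
            "redchi": None if np.isnan(self.redchi) else float(self.redchi),
            "params": {k: float(v) for k, v in self.params.items()},
            "stderr": {
                k: (None if v is None else float(v)) for k, v in self.stderr.items()
            },
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {self.model_name}: {pstr}>"
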