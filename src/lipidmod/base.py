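"""Shared machinery for Model/Results pairs.

Every fitted analysis in the package follows the same pattern: a model
object is built from data, ``fit()`` returns a results object carrying the
point estimates, their standard errors where the fit provides them, and
goodness-of-fit diagnostics, with a ``summary()`` table for the console.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np


class FitResults:
    """Base results container.

    Parameters
    ----------
    params : mapping of parameter name -> estimate
    bse : mapping of parameter name -> standard error (may be missing or
        NaN for parameters whose uncertainty is not identified)
    nobs : number of observations used in the fit
    rmse : root-mean-square residual of the fit
    """

    _title = "Fit results"

    def __init__(
        self,
        params: Mapping[str, float],
        bse: Optional[Mapping[str, float]] = None,
        nobs: int = 0,
        rmse: float = np.nan,
    ):
        self.params = dict(params)
        self.bse = dict(bse) if bse is not None else {k: np.nan for k in params}
        self.nobs = int(nobs)
        self.rmse = float(rmse)

    def __getattr__(self, name):
        # convenience: results.ec50 instead of results.params["ec50"]
        params = self.__dict__.get("params", {})
        if name in params:
            return params[name]
        raise AttributeError(name)

    def summary(self) -> str:
        lines = [self._title, "=" * len(self._title)]
        lines.append(f"{'parameter':<16}{'estimate':>14}{'std err':>14}")
        for name, value in self.params.items():
            se = self.bse.get(name, np.nan)
            se_str = f"{se:>14.5g}" if np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<16}{value:>14.6g}{se_str}")
        lines.append(f"n obs: {self.nobs}    rmse: {self.rmse:.5g}")
        extra = self._summary_extra()
        if extra:
            lines.append(extra)
        return "\n".join(lines)

    def _summary_extra(self) -> str:
        return ""

    def __repr__(self):  # pragma: no cover - cosmetic
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {pstr}>"


def stderr_from_covariance(pcov: np.ndarray) -> np.ndarray:
    """Standard errors from a curve_fit covariance matrix, NaN where the
    covariance is not finite (unidentified directions)."""
    diag = np.diag(pcov).astype(float)
    out = np.full_like(diag, np.nan)
    ok = np.isfinite(diag) & (diag >= 0)
    out[ok] = np.sqrt(diag[ok])
    return out
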