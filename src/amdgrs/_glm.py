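"""Shared maximum-likelihood logistic fitting helper."""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .errors import FitError


def logit_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
              maxiter: int = 100):
    """Newton ML logistic fit (statsmodels) with strict convergence checks.

    Raises :class:`FitError` on non-convergence or non-finite estimates
    (the usual symptom of complete separation).
    """
    model = sm.Logit(y, X)
    with np.errstate(all="ignore"):
        res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0,
                        warn_convergence=False)
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
        raise FitError("non-finite estimates (separation?)")
    return res
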