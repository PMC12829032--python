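"""Methylation-expression association: Yeo-Johnson scales + robust regression.

Both variables — the per-sample mean methylation level (mean over retained
reads of n_methylated/K by default; the high-methylation score via config)
and the calibrated relative expression — are Yeo-Johnson transformed with
per-variable maximum-likelihood lambda, then related by a Huber M-estimated
line.  The fit quality is summarized as the squared Pearson correlation
between fitted and observed transformed responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def yeo_johnson(y, lam: float):
    """The Yeo-Johnson transformation, defined for all real y.

    y >= 0: ((y+1)^lam - 1)/lam, or log(y+1) at lam = 0;
    y <  0: -((-y+1)^(2-lam) - 1)/(2-lam), or -log(-y+1) at lam = 2.
    Strictly increasing in y for every lambda.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    # expm1/log1p forms keep the branches numerically continuous at lam -> 0
    # and lam -> 2, where the plain power expression underflows
    if abs(lam) < 1e-10:
        out[pos] = np.log1p(y[pos])
    else:
        out[pos] = np.expm1(lam * np.log1p(y[pos])) / lam
    if abs(2.0 - lam) < 1e-10:
        out[~pos] = -np.log1p(-y[~pos])
    else:
        out[~pos] = -np.expm1((2.0 - lam) * np.log1p(-y[~pos])) / (2.0 - lam)
    return out if out.shape else float(out)


def _profile_loglik(y: np.ndarray, lam: float) -> float:
    """Gaussian profile log-likelihood of lambda (up to constants)."""
    t = yeo_johnson(y, lam)
    n = y.size
    var = np.var(t)
    if var <= 0 or not np.isfinite(var):
        return -np.inf
    # Jacobian: sum (lam-1) sign-adjusted log terms
    jac = (lam - 1.0) * np.sum(np.sign(y) * np.log1p(np.abs(y)))
    return -0.5 * n * np.log(var) + jac


def fit_lambda(values, bounds: tuple[float, float] = (-5.0, 5.0),
               tol: float = 1e-6) -> tuple[float, bool]:
    """Maximum-likelihood Yeo-Johnson lambda by golden-section search.

    Returns ``(lambda, flagged)``; constant input cannot identify lambda and
    falls back to 1 (identity) with the flag set.
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 5:
        raise ValueError("need at least 5 finite values to fit lambda")
    if np.ptp(y) == 0:
        return 1.0, True
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = bounds
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = _profile_loglik(y, c), _profile_loglik(y, d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _profile_loglik(y, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _profile_loglik(y, d)
    return float((a + b) / 2.0), False


@dataclass
class RobustFit:
    """Huber M-estimated line on transformed scales."""

    slope: float
    intercept: float
    scale: float
    n_iter: int
    r2: float  # squared Pearson correlation of fitted vs observed
    n_used: int
    lambda_x: float = 1.0
    lambda_y: float = 1.0

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "scale": self.scale,
                "r2": self.r2, "n_used": self.n_used,
                "lambda_x": self.lambda_x, "lambda_y": self.lambda_y}


def robust_regress(x, y, tuning: float = 1.345, loss: str = "huber",
                   maxiter: int = 100, tol: float = 1e-8) -> RobustFit:
    """Robust simple linear regression via IRLS M-estimation.

    Huber loss (tuning constant 1.345) with MAD scale by default; Tukey
    bisquare available via ``loss="bisquare"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("need >=3 pairs with distinct x")
    if loss == "huber":
        norm = sm.robust.norms.HuberT(t=tuning)
    elif loss == "bisquare":
        norm = sm.robust.norms.TukeyBiweight()
    else:
        raise ValueError(f"unknown loss {loss!r}")
    model = sm.RLM(y, sm.add_constant(x), M=norm)
    res = model.fit(maxiter=maxiter, tol=tol, scale_est="mad")
    fitted = res.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return RobustFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     scale=float(res.scale), n_iter=int(res.fit_history["iteration"]),
                     r2=r2, n_used=int(x.size))


def fit_association(methylation, expression, transform: bool = True,
                    loss: str = "huber") -> RobustFit:
    """The full association analysis on paired per-sample values.

    Yeo-Johnson transforms each variable with its own ML lambda, then fits
    the robust line of transformed expression on transformed methylation.
    """
    x = np.asarray(methylation, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if transform:
        lam_x, _ = fit_lambda(x)
        lam_y, _ = fit_lambda(y)
        xt, yt = yeo_johnson(x, lam_x), yeo_johnson(y, lam_y)
    else:
        lam_x = lam_y = 1.0
        xt, yt = x, y
    fit = robust_regress(xt, yt, loss=loss)
    fit.lambda_x, fit.lambda_y = lam_x, lam_y
    return fit


def transformed_pairs(methylation, expression, fit: RobustFit) -> pd.DataFrame:
    """Scatter-with-fit table on the transformed scales, for plotting."""
    x = yeo_johnson(np.asarray(methylation, dtype=float), fit.lambda_x)
    y = yeo_johnson(np.asarray(expression, dtype=float), fit.lambda_y)
    return pd.DataFrame({"x_t": x, "y_t": y, "y_fit": fit.intercept + fit.slope * x})
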