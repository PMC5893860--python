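"""Gamma-CDF coverage model, the Nd sequence-diversity index, and
sequencing-effort projection.

The rarefied coverage curve is fitted to the cumulative distribution
function of a gamma distribution on log-transformed effort,

    Ĉ(LR) = γ[α, β·ln(LR + 1)] / Γ(α),

with shape α > 0 and rate β > 0; γ/Γ is the regularized lower incomplete
gamma function. The mode of that gamma distribution,

    Nd = (α − 1)/β      (natural-log base-pair units),

locates the inflection point of the sigmoid and serves as a
database-independent index of community sequence diversity. Inverting
the CDF projects the sequencing effort needed to reach any target
coverage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .rarefy import RarefactionCurve

logger = logging.getLogger(__name__)

#: variance floor for weighted least squares (coverage units squared)
VARIANCE_FLOOR = 1e-4
#: multi-start grid over the gamma shape
ALPHA_GRID = (1.5, 3.0, 5.0, 10.0, 20.0)


class FitError(RuntimeError):
    """Curve cannot be fitted (too few usable points or no signal)."""


@dataclass
class CoverageModel:
    """Fitted gamma-CDF coverage model."""

    alpha: float
    beta: float
    fit_sse: float
    n_points_used: int
    converged: bool

    @property
    def nd(self) -> float:
        return nd(self)

    def coverage(self, effort_bp: float | np.ndarray) -> float | np.ndarray:
        return gamma_model_coverage(effort_bp, self.alpha, self.beta)

    def summary(self, curve: RarefactionCurve | None = None) -> dict:
        out = {
            "alpha": self.alpha,
            "beta": self.beta,
            "nd": self.nd,
            "lr_95": project_effort(self, 0.95),
            "lr_99": project_effort(self, 0.99),
            "converged": self.converged,
        }
        if curve is not None:
            out["coverage"] = coverage_at_actual_effort(self, curve)
            out["coverage_raw_last_point"] = float(curve.coverage_mean[-1])
        return out


def gamma_model_coverage(
    effort_bp: float | np.ndarray, alpha: float, beta: float
) -> float | np.ndarray:
    """Model coverage Ĉ at sequencing effort LR (bp): γ[α, β·ln(LR+1)]/Γ(α)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive, got {alpha}, {beta}")
    lr = np.asarray(effort_bp, dtype=float)
    if np.any(lr < 0):
        raise ValueError("effort must be >= 0")
    out = special.gammainc(alpha, beta * np.log1p(lr))
    return float(out) if np.isscalar(effort_bp) else out


def _weights(curve: RarefactionCurve) -> np.ndarray:
    """WLS weights: 1/max(sd², floor) for interior points; exact-0/exact-1
    points are demoted to the smallest interior weight so the saturated
    tails cannot dominate the fit.
    """
    var = np.maximum(curve.coverage_sd**2, VARIANCE_FLOOR)
    w = 1.0 / var
    interior = (curve.coverage_mean > 0.0) & (curve.coverage_mean < 1.0)
    if interior.any() and (~interior).any():
        w[~interior] = w[interior].min()
    return w


def fit_model(curve: RarefactionCurve) -> CoverageModel:
    """Weighted nonlinear least-squares fit of the gamma-CDF model.

    Deterministic: a fixed grid of shape starting values, each paired with
    a rate chosen so the model's median matches the curve's half-coverage
    effort, is refined by trust-region least squares in log-parameter
    space; the best weighted SSE wins.
    """
    x = np.log1p(curve.efforts_bp)
    y = curve.coverage_mean
    usable = (y > 0.0) & (y < 1.0)
    if int(usable.sum()) < 3:
        raise FitError(
            f"need >= 3 curve points with coverage strictly inside (0, 1); "
            f"have {int(usable.sum())}"
        )
    if np.all(y <= 0.0):
        raise FitError("insufficient coverage signal (all-zero curve)")
    w = np.sqrt(_weights(curve))

    def residuals(log_params: np.ndarray) -> np.ndarray:
        alpha, beta = np.exp(log_params)
        return w * (special.gammainc(alpha, beta * x) - y)

    # effort at which the curve crosses half its maximum coverage
    y_max = y.max()
    half_idx = int(np.argmin(np.abs(y - 0.5 * y_max)))
    x_half = max(x[half_idx], 1e-6)

    best = None
    for alpha0 in ALPHA_GRID:
        median_x = special.gammaincinv(alpha0, 0.5)
        beta0 = median_x / x_half
        try:
            result = optimize.least_squares(
                residuals,
                x0=np.log([alpha0, beta0]),
                method="lm",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=2000,
            )
        except Exception:  # singular start; other starts may still succeed
            continue
        sse = float(np.sum(result.fun**2))
        if best is None or sse < best[0]:
            best = (sse, result)
    if best is None:
        raise FitError("all optimizer starts failed")
    sse, result = best
    alpha, beta = np.exp(result.x)
    unweighted_sse = float(
        np.sum((special.gammainc(alpha, beta * x) - y) ** 2)
    )
    return CoverageModel(
        alpha=float(alpha),
        beta=float(beta),
        fit_sse=unweighted_sse,
        n_points_used=int(x.size),
        converged=bool(result.status > 0),
    )


def nd(model: CoverageModel) -> float:
    """Sequence-diversity index Nd = (α − 1)/β, in ln-bp units.

    For α <= 1 the gamma mode sits at the origin and Nd is reported as 0.
    """
    if model.alpha <= 1.0:
        logger.warning(
            "alpha=%.4g <= 1: gamma mode at origin, reporting Nd = 0", model.alpha
        )
        return 0.0
    return (model.alpha - 1.0) / model.beta


def project_effort(model: CoverageModel, target_coverage: float = 0.95) -> float:
    """Sequencing effort LR* (bp) projected to reach ``target_coverage``.

    Exact inverse of the model: LR* = exp(Qγ(target; α)/β) − 1 where Qγ is
    the gamma quantile function.
    """
    if not 0 < target_coverage < 1:
        if target_coverage == 1.0:
            return math.inf
        raise ValueError(
            f"target coverage must be in (0, 1), got {target_coverage}"
        )
    x = special.gammaincinv(model.alpha, target_coverage)
    return float(np.expm1(x / model.beta))


def coverage_at_actual_effort(model: CoverageModel, curve: RarefactionCurve) -> float:
    """Headline coverage: the fitted model evaluated at the dataset's full
    raw sequencing effort (total bp from the curve metadata)."""
    return float(gamma_model_coverage(curve.total_bp, model.alpha, model.beta))


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
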