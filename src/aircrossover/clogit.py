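"""Conditional (matched-set) logistic regression for case-crossover strata.

Each stratum contributes the probability that its observed case day, rather
than one of its referent days, was the event day:

    l(beta) = sum_s [ eta_case(s) - log sum_{j in s} exp(eta_j) ],
    eta_j = x_j' beta.

Stratum-constant covariates cancel from the likelihood, which is exactly why
the case-crossover design removes individual-level time-invariant
confounding.  The likelihood is maximised by Newton-Raphson with analytic
gradient and Hessian and step-halving; the covariance of the estimate is
the inverse observed information at the maximum.

Effects are reported as percent change in the odds of death,
(OR - 1) x 100 per reporting unit (10 ug/m3 for gaseous/particulate
pollutants, 1 mg/m3 for CO); nested models are compared with likelihood
ratio chi-square tests; BIC uses the number of strata as the sample size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClogitDesign",
    "FitResult",
    "EffectEstimate",
    "conditional_loglik",
    "fit_clogit",
    "percent_change",
    "likelihood_ratio_test",
]

Z975 = 1.959964  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    pass


class RankDeficiencyError(RuntimeError):
    pass


@dataclass
class ClogitDesign:
    """Design matrix with stratum structure for the conditional likelihood.

    Rows must be grouped so that each stratum is contiguous; construction
    from a stratum table enforces this and validates that every stratum has
    exactly one case and at least one control, with no missing entries.
    """

    X: np.ndarray          # (n, p) float
    y: np.ndarray          # (n,) 0/1 case indicator
    starts: np.ndarray     # (S,) start offset of each stratum
    columns: list[str]
    n_strata: int = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.n_strata = self.starts.size
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains missing entries")
        counts = np.diff(np.append(self.starts, self.X.shape[0]))
        if np.any(counts < 2):
            raise ValueError("every stratum needs the case plus >= 1 control")
        case_per = np.add.reduceat(self.y.astype(np.int64), self.starts)
        if np.any(case_per != 1):
            raise ValueError("every stratum needs exactly one case")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates: list[str]) -> "ClogitDesign":
        """Build from a long table with stratum_id / is_case / covariate columns."""
        df = df.sort_values(["stratum_id", "date"], kind="mergesort") if "date" in df else df
        codes, _ = pd.factorize(df["stratum_id"], sort=False)
        order = np.argsort(codes, kind="mergesort")
        codes = codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        return cls(
            X=df[covariates].to_numpy(dtype=float)[order],
            y=df["is_case"].to_numpy()[order],
            starts=starts,
            columns=list(covariates),
        )


def conditional_loglik(beta: np.ndarray, design: ClogitDesign):
    """Conditional log-likelihood with analytic gradient and Hessian.

    Returns (loglik, gradient, hessian).  The computation subtracts the
    per-stratum maximum of eta before exponentiating, so it is stable and —
    like the likelihood itself — exactly invariant to adding any
    stratum-constant vector to the covariates of a stratum.
    """
    X, y, starts = design.X, design.y, design.starts
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    # per-stratum log-sum-exp
    seg = np.repeat(np.arange(design.n_strata), np.diff(np.append(starts, X.shape[0])))
    mx = np.maximum.reduceat(eta, starts)
    e = np.exp(eta - mx[seg])
    denom = np.add.reduceat(e, starts)
    ll = float(np.sum(eta[y == 1]) - np.sum(mx + np.log(denom)))
    p = e / denom[seg]
    # gradient: sum over strata of (x_case - E_p[x])
    resid = y.astype(float) - p
    grad = X.T @ resid
    # Hessian: -(X' diag(p) X - sum_s m_s m_s') with m_s = sum_{j in s} p_j x_j
    PX = X * p[:, None]
    M = np.add.reduceat(PX, starts, axis=0)
    H = -(X.T @ PX - M.T @ M)
    return ll, grad, H


def fit_clogit(
    design: ClogitDesign,
    *,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-12,
) -> "FitResult":
    """Maximise the conditional likelihood by Newton-Raphson.

    Convergence when max |gradient| < 1e-8 or the relative log-likelihood
    change < 1e-12.  Diverging coefficients (|beta| > 50) raise
    SeparationError naming the offending covariate; a singular information
    matrix raises RankDeficiencyError (e.g. a covariate constant within
    every stratum carries no within-stratum contrast).
    """
    p = design.X.shape[1]
    beta = np.zeros(p)
    ll, grad, H = conditional_loglik(beta, design)
    info = -H
    _check_information(info, design)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError("singular information matrix") from exc
        # step-halving line search on the (concave) log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, H_new = conditional_loglik(cand, design)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll_prev, ll = cand, ll, ll_new
        grad, H = grad_new, H_new
        info = -H
        if np.max(np.abs(beta)) > 50:
            worst = design.columns[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"possible separation: coefficient for {worst!r} diverges"
            )
        gnorm = float(np.max(np.abs(grad))) if p else 0.0
        if gnorm < grad_tol or abs(ll - ll_prev) < ll_tol * (abs(ll_prev) + 1.0):
            break
    else:
        raise SeparationError("Newton-Raphson failed to converge in 100 iterations")
    _check_information(info, design)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    S = design.n_strata
    bic = -2.0 * ll + p * np.log(S)
    return FitResult(
        params=pd.Series(beta, index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=ll,
        n_strata=S,
        n_params=p,
        bic=float(bic),
        n_iter=it,
        grad_norm=gnorm,
    )


def _check_information(info: np.ndarray, design: ClogitDesign) -> None:
    if info.size == 0:
        raise RankDeficiencyError("empty design")
    diag = np.diag(info)
    scale = max(float(diag.max()), 1e-300)
    if np.any(diag <= 1e-10 * scale) or np.any(diag <= 0):
        worst = design.columns[int(np.argmin(diag))]
        raise RankDeficiencyError(
            f"covariate {worst!r} has no within-stratum variation"
        )
    if np.linalg.matrix_rank(info) < info.shape[0]:
        raise RankDeficiencyError("rank-deficient information matrix")


@dataclass
class FitResult:
    """Maximised conditional-logit fit: coefficients, covariance, fit stats."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_strata: int
    n_params: int
    bic: float
    n_iter: int
    grad_norm: float

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.params.to_dict(),
                "covariance": self.cov.to_dict(),
                "loglik": self.loglik,
                "n_strata": self.n_strata,
                "n_params": self.n_params,
                "bic": self.bic,
                "convergence": {"iterations": self.n_iter, "grad_norm": self.grad_norm},
            },
            sort_keys=True,
        )


@dataclass
class EffectEstimate:
    """Percent change in odds per reporting unit, with Wald 95% CI."""

    pollutant: str
    lag: str
    percent: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "adjusted"
    n_strata: int = 0

    def covers(self, truth_percent: float) -> bool:
        return self.ci_low <= truth_percent <= self.ci_high

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "pollutant": self.pollutant,
            "lag": self.lag,
            "percent_change": self.percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_strata": self.n_strata,
        }


def percent_change(
    fit: FitResult,
    covariate: str,
    unit_scale: float = 1.0,
    *,
    pollutant: str | None = None,
    lag: str = "",
    model: str = "adjusted",
) -> EffectEstimate:
    """Percent change in odds for a ``unit_scale`` increase of a covariate.

    point = (exp(beta*u) - 1) x 100; CI endpoints transform beta +/- 1.96 se.
    When pollutant terms are pre-scaled to their reporting unit, u = 1.
    """
    if covariate not in fit.params.index:
        raise KeyError(f"unknown covariate {covariate!r}")
    if unit_scale <= 0:
        raise ValueError("unit scale must be positive")
    b = float(fit.params[covariate])
    se = fit.se(covariate)
    z = b / se if se > 0 else np.inf
    pct = lambda bb: (np.exp(bb * unit_scale) - 1.0) * 100.0
    return EffectEstimate(
        pollutant=pollutant or covariate,
        lag=lag,
        percent=pct(b),
        ci_low=pct(b - Z975 * se),
        ci_high=pct(b + Z975 * se),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        model=model,
        n_strata=fit.n_strata,
    )


def likelihood_ratio_test(full: FitResult, reduced: FitResult):
    """LR chi-square between nested conditional-logit fits.

    Returns (statistic, df, p).  The reduced model's covariates must be a
    subset of the full model's and both fits must use the same strata.
    """
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("models are not nested (covariates not a subset)")
    if full.n_strata != reduced.n_strata:
        raise ValueError("models fitted on different strata")
    df = full.n_params - reduced.n_params
    if df == 0:
        return 0.0, 0, 1.0
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-8:
        raise ValueError("full model has lower likelihood; fits are inconsistent")
    stat = max(stat, 0.0)
    return float(stat), int(df), float(stats.chi2.sf(stat, df))
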