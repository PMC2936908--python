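"""Logistic regression of niche difference on split age, and helpers.

The headline statistic of the sister-pair analysis is the fitted logistic
curve

    P(different | age) = 1 / (1 + exp(-(b0 + b1 * age)))

evaluated at split age 0: the probability that a *freshly* split pair
already occupies non-overlapping niches, i.e. the fraction of speciation
events plausibly triggered by a resource shift.  The raw proportion of
niche-different pairs overestimates this because post-speciational shifts
accumulate with age.

The fitter is a Newton/IRLS maximizer of the Bernoulli log-likelihood
with Wald standard errors from the observed information; likelihood-ratio
p-values are reported alongside.  Complete or quasi-complete separation
is detected and flagged instead of silently returning huge coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "predict_probability",
    "chi_square_independence",
    "tally_hosts",
]


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of a binary label on split age."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    p0: float
    p1: float
    log_likelihood: float
    n: int
    converged: bool
    separated: bool = False
    n_iter: int = 0
    #: likelihood-ratio p-value for the age effect (vs intercept-only)
    lr_p1: float | None = None

    def as_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se0": self.se0,
            "se1": self.se1,
            "p0": self.p0,
            "p1": self.p1,
            "lr_p1": self.lr_p1,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "converged": self.converged,
            "separated": self.separated,
        }


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int,
    tol_score: float,
    tol_step: float,
    beta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    beta = np.zeros(X.shape[1]) if beta_init is None else beta_init.astype(float)
    converged = False
    info = np.eye(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(score)) < tol_score or np.max(np.abs(step)) < tol_step:
            converged = True
            break
    return beta, info, converged, it


def fit_logistic(
    dataset: pd.DataFrame,
    intercept_only: bool = False,
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_step: float = 1e-10,
) -> LogisticFit:
    """Fit P(niche_different) ~ logistic(b0 + b1 * split_age) by Newton/IRLS.

    With ``intercept_only`` the slope is fixed at zero and the intercept
    has the closed-form MLE logit(mean(y)); the Newton iteration converges
    to it and the closed form is used as the starting point.

    Raises ``ValueError`` when the dataset has fewer than 3 rows or only
    one label class.  Separation (labels perfectly ordered by age) is
    reported via ``separated``/``converged`` flags, not as an exception.
    """
    y = np.asarray(dataset["niche_different"], dtype=float)
    age = np.asarray(dataset["split_age"], dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 pairs to fit a logistic regression")
    if y.min() == y.max():
        raise ValueError("all pairs share one label; logistic fit undefined")

    if intercept_only:
        X = np.ones((n, 1))
        # logit of the sample proportion is the exact MLE; Newton polishes it
        ybar = y.mean()
        beta_init = np.array([np.log(ybar / (1.0 - ybar))])
    else:
        X = np.column_stack([np.ones(n), age])
        beta_init = None

    beta, info, converged, n_iter = _newton(
        X, y, max_iter, tol_score, tol_step, beta_init=beta_init
    )
    eta = X @ beta

    # Complete separation: every observation on its own side of the
    # decision boundary drives |beta| to infinity.
    separated = bool(np.all((2.0 * y - 1.0) * eta > 0)) or (
        not converged and np.max(np.abs(beta)) > 1e3
    )
    if separated:
        converged = False
        logger.warning("logistic fit: separation detected; estimates diverge")

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    ll = _log_likelihood(y, eta)

    if intercept_only:
        fit = LogisticFit(
            beta0=float(beta[0]), beta1=0.0,
            se0=float(se[0]), se1=float("nan"),
            p0=float(pvals[0]), p1=float("nan"),
            log_likelihood=ll, n=n, converged=converged,
            separated=separated, n_iter=n_iter,
        )
        return fit

    # LR test for the age effect against the intercept-only null.
    p_null = y.mean()
    eta_null = np.full(n, np.log(p_null / (1.0 - p_null)))
    ll_null = _log_likelihood(y, eta_null)
    lr_stat = max(0.0, 2.0 * (ll - ll_null))
    lr_p1 = float(sps.chi2.sf(lr_stat, df=1))

    return LogisticFit(
        beta0=float(beta[0]), beta1=float(beta[1]),
        se0=float(se[0]), se1=float(se[1]),
        p0=float(pvals[0]), p1=float(pvals[1]),
        log_likelihood=ll, n=n, converged=converged,
        separated=separated, n_iter=n_iter, lr_p1=lr_p1,
    )


def predict_probability(fit: LogisticFit, age: float) -> float:
    """Fitted probability of niche difference at a given relative split age.

    At ``age = 0`` this is the model's estimate of the fraction of
    speciation events coinciding with a niche shift.
    """
    eta = fit.beta0 + fit.beta1 * age
    return float(1.0 / (1.0 + np.exp(-eta)))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for an r x c count table.

    No continuity correction is applied.  Raises ``ValueError`` when a row
    or column margin is zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def tally_hosts(species_records) -> pd.DataFrame:
    """Per-clade host-genus species tallies with oligophages counted per genus.

    ``species_records`` is an iterable of ``(clade, genera)`` where
    ``genera`` is a nonempty collection of plant-genus labels used by one
    species.  A species using g genera contributes one count to each of
    them, so clade totals are inflated relative to true species numbers;
    proportions are normalized by the inflated total and sum to 1 within
    each clade.
    """
    rows = []
    for clade, genera in species_records:
        genera = list(genera)
        if not genera:
            raise ValueError(f"species record in clade {clade!r} has no genera")
        for genus in set(genera):
            rows.append({"clade": clade, "genus": genus})
    df = pd.DataFrame(rows)
    counts = df.groupby(["clade", "genus"]).size().rename("count").reset_index()
    totals = counts.groupby("clade")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts.sort_values(["clade", "genus"]).reset_index(drop=True)
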