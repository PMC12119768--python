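"""ROC analysis, Youden cut-off selection, probit fits and predictive curves.

The acute-stress intensity score (ASDS total, 19-95) is evaluated as a
continuous predictor of later PTSD three ways:

* a full ROC curve over every integer threshold, with the rank (Mann-Whitney)
  AUC, its Hanley-McNeil standard error and a normal test against 0.5;
* Youden-index maximisation (J = sensitivity + specificity - 1) to select a
  screening cut-off, with a report comparing named candidate cut-offs;
* probit regression of the outcome on (a) the ASD diagnosis alone and (b)
  diagnosis plus intensity score, from which model-based PPV(s) and NPV(s)
  curves across the score are derived:

      PPV(s) = Phi(b0 + b1 + b2*s)      (diagnosis-positive arm)
      NPV(s) = 1 - Phi(b0 + b2*s)       (diagnosis-negative arm)

The probit likelihood is maximised by Newton-Raphson with an explicit
perfect-separation check; an empirical binned curve is provided alongside
the model-based one for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PerfectSeparationError",
    "PredictiveCurve",
    "ProbitFit",
    "RocCurve",
    "YoudenSelection",
    "empirical_predictive_curve",
    "fit_probit",
    "predictive_curves",
    "roc",
    "youden_select",
]

_PHI = stats.norm.cdf
_PHI_INV = stats.norm.ppf


@dataclass(frozen=True)
class RocCurve:
    """ROC over integer thresholds; positive test means score >= threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_pvalue: float
    n_cases: int
    n_noncases: int


def _rank_auc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """AUC by the rank (pair-counting) definition, ties counted half."""
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    u = ranks[outcome].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc(
    scores: Sequence[int],
    outcome: Sequence[bool],
    thresholds: Sequence[int] | None = None,
) -> RocCurve:
    """Build the ROC curve of a score against a binary outcome.

    By default the thresholds are every integer in the theoretical score
    range [19, 95] (reproducible regardless of which scores were observed).
    The AUC uses the rank definition with ties counted half; its standard
    error is Hanley-McNeil and the p-value is a two-sided normal test of
    AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcome must be aligned 1-d sequences")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires at least one case and one non-case")
    if thresholds is None:
        thresholds = np.arange(19, 96)
    thr = np.asarray(thresholds)
    sens = np.array([(s[y] >= t).mean() for t in thr])
    spec = np.array([(s[~y] < t).mean() for t in thr])

    auc = _rank_auc(s, y)
    # Hanley & McNeil (1982) SE
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_pvalue=p,
        n_cases=n1,
        n_noncases=n0,
    )


@dataclass(frozen=True)
class YoudenSelection:
    """Youden-index maximisation over the ROC thresholds."""

    best_cutoff: int
    best_j: float
    thresholds: np.ndarray
    j_per_threshold: np.ndarray

    def compare(self, *cutoffs: int) -> dict[int, float]:
        """J at user-named candidate cut-offs (e.g. 56 vs 58)."""
        out = {}
        for c in cutoffs:
            idx = np.nonzero(self.thresholds == c)[0]
            if idx.size == 0:
                raise ValueError(f"cut-off {c} is not on the threshold grid")
            out[int(c)] = float(self.j_per_threshold[idx[0]])
        return out


def youden_select(curve: RocCurve) -> YoudenSelection:
    """Select the screening cut-off maximising J = sensitivity + specificity - 1.

    Ties are broken toward the smallest threshold (which favours sensitivity).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximiser
    return YoudenSelection(
        best_cutoff=int(curve.thresholds[best]),
        best_j=float(j[best]),
        thresholds=curve.thresholds,
        j_per_threshold=j,
    )


class PerfectSeparationError(RuntimeError):
    """The probit likelihood is unbounded: a predictor separates the outcome."""


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood probit fit: P(y=1 | x) = Phi(x' beta)."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_obs: int
    n_iter: int
    names: tuple[str, ...]

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _PHI(X @ self.coefficients)


def _probit_loglike(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log Phi via scipy's log-cdf keeps the tails finite
    return float(
        np.sum(stats.norm.logcdf(np.where(y, eta, -eta)))
    )


def fit_probit(
    X: Sequence[Sequence[float]],
    y: Sequence[bool],
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    ll_rtol: float = 1e-10,
    grad_tol: float = 1e-8,
) -> ProbitFit:
    """Fit a probit model by Newton-Raphson.

    ``X`` must include the intercept column explicitly.  Convergence is
    declared when the relative log-likelihood change falls below ``ll_rtol``
    or the gradient norm below ``grad_tol``.  Diverging coefficients (a sign
    of perfect separation) raise :class:`PerfectSeparationError` naming the
    offending predictor.
    """
    X = np.asarray(X, dtype=float)
    yb = np.asarray(y, dtype=bool)
    if X.ndim != 2 or X.shape[0] != yb.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite values")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))

    s = np.where(yb, 1.0, -1.0)
    beta = np.zeros(p)
    ll = _probit_loglike(beta, X, yb)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        # inverse Mills ratio; lambda_i = s_i * phi(eta)/Phi(s_i * eta)
        lam = s * np.exp(stats.norm.logpdf(eta) - stats.norm.logcdf(s * eta))
        grad = X.T @ lam
        w = lam * (lam + eta)  # observed-information weights, always >= 0
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                "singular information matrix (collinear or separating predictors)"
            ) from exc
        new_beta = beta + step
        # step-halve if the likelihood would decrease
        new_ll = _probit_loglike(new_beta, X, yb)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = _probit_loglike(new_beta, X, yb)
            halvings += 1
        beta, prev_ll, ll = new_beta, ll, new_ll
        if np.max(np.abs(beta)) > 1e4:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise PerfectSeparationError(
                f"coefficients diverging; predictor {worst!r} appears to "
                "perfectly separate the outcome"
            )
        if np.linalg.norm(X.T @ (s * np.exp(
            stats.norm.logpdf(X @ beta) - stats.norm.logcdf(s * (X @ beta))
        ))) < grad_tol:
            converged = True
            break
        if abs(ll - prev_ll) < ll_rtol * (abs(prev_ll) + 1e-300):
            converged = True
            break

    # a likelihood indistinguishable from its supremum of 0 means every
    # observation is fitted perfectly: the hallmark of complete separation
    if ll > -1e-6:
        contrib = np.abs(beta) * X.std(axis=0)
        worst = names[int(np.argmax(contrib))]
        raise PerfectSeparationError(
            f"perfect fit reached; predictor {worst!r} appears to "
            "perfectly separate the outcome"
        )

    eta = X @ beta
    lam = s * np.exp(stats.norm.logpdf(eta) - stats.norm.logcdf(s * eta))
    w = lam * (lam + eta)
    hess = (X * w[:, None]).T @ X
    cov = np.linalg.inv(hess)
    cov = (cov + cov.T) / 2.0
    return ProbitFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n_obs=n,
        n_iter=it,
        names=tuple(names),
    )


@dataclass(frozen=True)
class PredictiveCurve:
    """Model-based PPV(s) and NPV(s) across the intensity score grid."""

    scores: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray


def predictive_curves(
    fit: ProbitFit,
    score_range: tuple[float, float] = (19, 95),
) -> PredictiveCurve:
    """PPV/NPV curves from the diagnosis-plus-score probit model.

    The fit must be the three-coefficient model (intercept, diagnosis
    indicator, score).  At score s, a diagnosis-positive subject's predicted
    PTSD probability is Phi(b0 + b1 + b2*s) — the model-based PPV — and a
    diagnosis-negative subject's probability of *no* PTSD is
    1 - Phi(b0 + b2*s) — the model-based NPV.
    """
    if not fit.converged:
        raise ValueError("predictive curves require a converged probit fit")
    if fit.coefficients.shape[0] != 3:
        raise ValueError(
            "predictive curves need the (intercept, diagnosis, score) model; "
            f"fit has {fit.coefficients.shape[0]} coefficients"
        )
    b0, b1, b2 = fit.coefficients
    lo, hi = score_range
    if not lo <= hi:
        raise ValueError("score_range must satisfy s_min <= s_max")
    grid = np.arange(int(np.floor(lo)), int(np.ceil(hi)) + 1, dtype=float)
    return PredictiveCurve(
        scores=grid,
        ppv=_PHI(b0 + b1 + b2 * grid),
        npv=1.0 - _PHI(b0 + b2 * grid),
    )


def empirical_predictive_curve(
    scores: Sequence[int],
    diagnosis: Sequence[bool],
    outcome: Sequence[bool],
    bin_width: int = 5,
) -> dict[str, np.ndarray]:
    """Binned empirical analogue of :func:`predictive_curves`.

    Within score bins, PPV is the outcome rate among diagnosis-positive
    subjects and NPV the no-outcome rate among diagnosis-negative subjects;
    empty cells are NaN.  Used to sanity-check the model-based curves.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(diagnosis, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    edges = np.arange(19, 96 + bin_width, bin_width, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    ppv = np.full(len(centers), np.nan)
    npv = np.full(len(centers), np.nan)
    for k in range(len(centers)):
        in_bin = (s >= edges[k]) & (s < edges[k + 1])
        pos = in_bin & d
        neg = in_bin & ~d
        if pos.any():
            ppv[k] = y[pos].mean()
        if neg.any():
            npv[k] = (~y[neg]).mean()
    return {"centers": centers, "ppv": ppv, "npv": npv}
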