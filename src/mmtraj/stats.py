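"""Classical statistical procedures, implemented self-contained.

Every procedure the trajectory analysis relies on is implemented here from its
defining formulas so each can be verified against brute-force oracles and
reference libraries in the test suite:

* :func:`wilcoxon_rank_sum` — exact (full enumeration) or tie-corrected normal
  approximation, midranks for ties;
* :func:`mann_kendall` — trend test with tie-corrected variance and
  continuity correction;
* :class:`CoxPH` / :func:`cox_ph` — proportional-hazards partial likelihood,
  Breslow tie handling, Newton-Raphson;
* :class:`PoissonRR` / :func:`poisson_rr` — log-linear Poisson model by IRLS
  with a sandwich (robust) covariance, the standard device for estimating
  relative risks from binary outcomes;
* :func:`benjamini_hochberg` — step-up false-discovery-rate control.

Conventions: two-sided p-values throughout; Wald intervals; convergence when
the gradient max-norm drops below 1e-8 within 100 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class ConvergenceError(RuntimeError):
    """A model fit failed to converge (including monotone-likelihood designs)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: int | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class FitResult:
    """Fitted-model results: estimates, covariances, diagnostics.

    ``cov`` is the model-based covariance; ``cov_robust`` the sandwich
    covariance where the model provides one.  ``conf_int`` and ``summary``
    report on the exp scale when ``exp=True`` (hazard ratios / relative
    risks).
    """

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    converged: bool
    n_iter: int
    loglik: float
    method: str
    cov_robust: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def se(self, robust: bool = False) -> pd.Series:
        cov = self._pick_cov(robust)
        return pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=self.params.index)

    def _pick_cov(self, robust: bool) -> pd.DataFrame:
        if robust:
            if self.cov_robust is None:
                raise ValueError(f"{self.method} has no robust covariance")
            return self.cov_robust
        return self.cov

    def conf_int(
        self, alpha: float = 0.05, robust: bool = False, exp: bool = False
    ) -> pd.DataFrame:
        zcrit = sps.norm.ppf(1 - alpha / 2)
        se = self.se(robust=robust)
        lo = self.params - zcrit * se
        hi = self.params + zcrit * se
        if exp:
            lo, hi = np.exp(lo), np.exp(hi)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def p_values(self, robust: bool = False) -> pd.Series:
        z = self.params / self.se(robust=robust)
        return pd.Series(2 * sps.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self, robust: bool | None = None, exp: bool = False) -> str:
        robust = self.cov_robust is not None if robust is None else robust
        se = self.se(robust=robust)
        ci = self.conf_int(robust=robust, exp=exp)
        est = np.exp(self.params) if exp else self.params
        tab = pd.DataFrame(
            {
                "exp(coef)" if exp else "coef": est,
                "se(coef)": se,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
                "p": self.p_values(robust=robust),
            }
        )
        head = (
            f"{self.method}  (n_obs={self.n_obs}, converged={self.converged}, "
            f"iterations={self.n_iter}, loglik={self.loglik:.4f}, "
            f"{'robust' if robust else 'model-based'} SE)"
        )
        return head + "\n" + tab.to_string(float_format=lambda v: f"{v:.4f}")


# ---------------------------------------------------------------------------
# rank / trend tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon rank-sum test on two independent samples.

    The statistic is the sum of the (mid)ranks of ``x`` in the pooled sample.
    With ``mode='exact'`` (or ``'auto'`` and n_x + n_y <= 12) the p-value is
    computed by full enumeration of all rank assignments; otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0

    exact = mode == "exact" or (mode == "auto" and n <= 12)
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode: {mode!r}")
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n_x + n_y <= 20")
        idx = np.array(list(combinations(range(n), nx)), dtype=np.intp)
        sums = ranks[idx].sum(axis=1)
        tol = 1e-9
        if alternative == "greater":
            p = float(np.mean(sums >= w - tol))
        elif alternative == "less":
            p = float(np.mean(sums <= w + tol))
        else:
            p = float(np.mean(np.abs(sums - mu) >= abs(w - mu) - tol))
        return TestResult(w, min(p, 1.0), "wilcoxon rank-sum (exact)", n=n)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return TestResult(w, 1.0, "wilcoxon rank-sum (normal)", n=n, z=0.0)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(w - mu) - 0.5) / sd
        z = max(z, 0.0)
        p = float(2 * sps.norm.sf(z))
    return TestResult(w, min(p, 1.0), "wilcoxon rank-sum (normal)", n=n, z=float(z))


def mann_kendall(values: Sequence[float]) -> TestResult:
    """Mann-Kendall trend test on an ordered sequence.

    S counts concordant minus discordant pairs; the variance carries the
    standard tie correction and Z the +/-1 continuity correction.  Two-sided
    p-value.  A constant sequence yields S = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("mann_kendall requires a sequence of length >= 3")
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i])))
    _, counts = np.unique(x, return_counts=True)
    tie = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var = (n * (n - 1) * (2 * n + 5) - tie) / 18.0
    if var <= 0:
        return TestResult(float(s), 1.0, "mann-kendall", n=n, z=0.0)
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(float(s), min(p, 1.0), "mann-kendall", n=n, z=float(z))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

class CoxPH:
    """Cox proportional-hazards model with Breslow tie handling.

    Parameters
    ----------
    time, event
        Follow-up times (nonnegative) and event indicators (0/1).
    X
        Design matrix (no intercept — the baseline hazard absorbs it);
        a DataFrame supplies coefficient names.
    """

    def __init__(self, time, event, X, names: Sequence[str] | None = None):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if isinstance(X, pd.DataFrame):
            names = list(X.columns) if names is None else list(names)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.time.size:
            X = X.T
        self.X = X
        self.names = (
            list(names) if names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        if np.any(self.time < 0):
            raise ValueError("negative follow-up times")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        if np.any(np.ptp(self.X, axis=0) == 0):
            raise ValueError(
                "degenerate design: a covariate is identical for all subjects"
            )
        self._order = np.argsort(self.time, kind="mergesort")

    def _scan(self, beta: np.ndarray):
        """One pass over the data: (loglik, gradient, information) at beta.

        Vectorized Breslow accumulation: with rows in ascending time order, the
        risk-set sums S0, S1, S2 at each distinct time are suffix sums taken at
        the first row of that time's tied block.
        """
        order = self._order
        t = self.time[order]
        d = self.event[order].astype(float)
        x = self.X[order]
        eta = x @ beta
        w = np.exp(eta)

        first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])  # block starts
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1][first]
        xx = x[:, :, None] * x[:, None, :]
        s2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1][first]
        d_t = np.add.reduceat(d, first)

        events = d_t > 0
        s0e, d_e = s0[events], d_t[events]
        m1 = s1[events] / s0e[:, None]
        loglik = float((eta * d).sum() - (d_e * np.log(s0e)).sum())
        grad = (x * d[:, None]).sum(axis=0) - d_e @ m1
        info = (
            np.einsum("t,tij->ij", d_e / s0e, s2[events])
            - np.einsum("t,ti,tj->ij", d_e, m1, m1)
        )
        return loglik, grad, info

    def loglik(self, beta) -> float:
        """Breslow log partial likelihood at an arbitrary coefficient vector."""
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        return self._scan(beta)[0]

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> FitResult:
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._scan(beta)
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("singular information matrix") from exc
            # a Newton step below tolerance means the gradient is at its
            # floating-point noise floor: accept the current maximum
            if np.max(np.abs(step)) < tol:
                converged = True
                break
            # step-halving to guarantee ascent
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new, grad_new, info_new = self._scan(cand)
                if ll_new >= ll - 1e-12:
                    break
                alpha /= 2.0
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            if np.max(np.abs(beta)) > 50:
                raise ConvergenceError(
                    "monotone partial likelihood (complete separation): "
                    "coefficient diverging"
                )
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"cox_ph did not converge in {max_iter} iterations")
        if np.max(np.abs(beta)) > 15:
            # the gradient of a monotone partial likelihood also decays below
            # tolerance as beta diverges; an absurd coefficient is the tell
            raise ConvergenceError(
                "monotone partial likelihood (complete separation): "
                f"|coef| = {np.max(np.abs(beta)):.1f} at convergence"
            )
        cov = np.linalg.inv(info)
        idx = pd.Index(self.names)
        return FitResult(
            params=pd.Series(beta, index=idx),
            cov=pd.DataFrame(cov, index=idx, columns=idx),
            n_obs=self.time.size,
            converged=converged,
            n_iter=it,
            loglik=ll,
            method="cox_ph (Breslow)",
            extra={"n_events": int(self.event.sum())},
        )


def cox_ph(time, event, X, names=None, max_iter=100, tol=1e-8) -> FitResult:
    """Fit a Cox model; see :class:`CoxPH`."""
    return CoxPH(time, event, X, names=names).fit(max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# Poisson regression with sandwich variance
# ---------------------------------------------------------------------------

class PoissonRR:
    """Log-linear Poisson model with a sandwich covariance.

    Fitting a Poisson model to a binary outcome with robust standard errors is
    the standard way to estimate relative risks directly: exp(coefficient) is
    a risk ratio, and the sandwich covariance
    ``information^-1 (sum score score^T) information^-1`` remains valid even
    though binary data are not Poisson.

    ``freq_weights`` are frequency (replication) weights: a row with weight w
    counts as w identical observations, in the likelihood and in the sandwich.
    """

    def __init__(self, y, X, names: Sequence[str] | None = None,
                 offset=None, freq_weights=None):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("outcomes must be nonnegative integers")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns) if names is None else list(names)
            X = X.to_numpy(dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        self.names = (
            list(names) if names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.offset = (
            np.zeros(self.y.size) if offset is None
            else np.asarray(offset, dtype=float)
        )
        self.fw = (
            np.ones(self.y.size) if freq_weights is None
            else np.asarray(freq_weights, dtype=float)
        )
        if np.sum(self.fw * self.y) == 0:
            raise ValueError("all outcomes are zero: no events to model")

    def _loglik(self, mu: np.ndarray) -> float:
        # log-gamma term omitted: constant in beta
        return float(np.sum(self.fw * (self.y * np.log(mu) - mu)))

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> FitResult:
        X, y, fw = self.X, self.y, self.fw
        p = X.shape[1]
        beta = np.zeros(p)
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            eta = X @ beta + self.offset
            mu = np.exp(np.clip(eta, -500, 500))
            grad = X.T @ (fw * (y - mu))
            info = (X * (fw * mu)[:, None]).T @ X
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("singular information matrix") from exc
            beta = beta + step
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            if np.max(np.abs(beta)) > 500:
                raise ConvergenceError(
                    "poisson_rr coefficients diverging (separation or empty cell)"
                )
        if not converged:
            raise ConvergenceError(
                f"poisson_rr did not converge in {max_iter} iterations"
            )
        eta = X @ beta + self.offset
        mu = np.exp(eta)
        info = (X * (fw * mu)[:, None]).T @ X
        bread = np.linalg.inv(info)
        resid = fw * (y - mu)
        # meat: sum_i fw_i s_i s_i^T with s_i = x_i (y_i - mu_i)
        meat = (X * (fw * (y - mu) ** 2)[:, None]).T @ X
        cov_robust = bread @ meat @ bread
        idx = pd.Index(self.names)
        return FitResult(
            params=pd.Series(beta, index=idx),
            cov=pd.DataFrame(bread, index=idx, columns=idx),
            n_obs=int(np.sum(fw)),
            converged=converged,
            n_iter=it,
            loglik=self._loglik(mu),
            method="poisson_rr (IRLS, sandwich variance)",
            cov_robust=pd.DataFrame(cov_robust, index=idx, columns=idx),
            extra={"gradient_norm": float(np.max(np.abs(resid @ X)))},
        )


def poisson_rr(y, X, names=None, offset=None, freq_weights=None,
               max_iter=100, tol=1e-8) -> FitResult:
    """Fit a Poisson relative-risk model; see :class:`PoissonRR`."""
    model = PoissonRR(y, X, names=names, offset=offset, freq_weights=freq_weights)
    return model.fit(max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Rejects all ordered p-values up to the largest index i with
    p(i) <= i*q/m.  Returns ``(reject, q_values)`` aligned with the input;
    q-values are the standard monotone cumulative-minimum adjusted values
    (ties share their adjusted value).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    i = np.arange(1, m + 1)
    below = ranked <= i * q / m
    reject_sorted = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.max(np.flatnonzero(below)))
        reject_sorted[: kmax + 1] = True
    qvals_sorted = np.minimum.accumulate((ranked * m / i)[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    qvals = np.zeros(m)
    reject[order] = reject_sorted
    qvals[order] = qvals_sorted
    return reject, qvals
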