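"""Distance-sampling (DS) detection functions fitted by maximum likelihood.

The detection function g(x; z) gives the probability that a school at
perpendicular distance x is seen, conditional on g = 1 at the trackline.
Two key forms are supported:

* half-normal:  g(x) = exp(-x^2 / (2 sigma(z)^2))
* hazard-rate:  g(x) = 1 - exp(-(x / sigma(z))^(-b)),  b > 1

with a log-linear covariate model on the scale, sigma(z) = exp(b0 + sum
b_m z_m). Continuous covariates are centred and scaled on the training data
before entering the scale model. The conditional likelihood of the observed
distances inside the truncation window [left, right] is maximised by
quasi-Newton iteration from several jittered starts.

Model comparison follows the survey-analysis convention: rank candidate fits
by AIC, break exact AIC ties by goodness of fit (Kolmogorov-Smirnov then
Cramer-von Mises p) and then by the coefficient of variation of the
resulting abundance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "DetectionFunction",
    "GOFResult",
    "fit_ds",
    "rank_models",
    "forward_model_search",
]

_GL_NODES = 61  # Gauss-Legendre nodes for the hazard-rate strip integral


class FitError(RuntimeError):
    """Raised when no optimiser start converges."""


def _halfnormal_esw(sigma, left, right):
    """Closed form: integral of exp(-u^2/(2 s^2)) du over [left, right]."""
    rt2 = np.sqrt(2.0)
    return sigma * np.sqrt(np.pi / 2.0) * (
        special.erf(right / (rt2 * sigma)) - special.erf(left / (rt2 * sigma))
    )


@dataclass
class GOFResult:
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float
    ks_p_asymptotic: float
    cvm_p_asymptotic: float
    qq_points: np.ndarray  # (n, 2): fitted CDF vs empirical quantile


class DetectionFunction(BaseEstimator):
    """Covariate-scaled detection function, fitted to truncated distances.

    Parameters
    ----------
    form : {'hazard_rate', 'half_normal'}
        Key function.
    covariates : tuple of str
        Column names entering the log-scale model.
    left, right : float
        Truncation window in metres (closed interval).
    n_starts : int
        Jittered optimiser starts; the best converged solution wins.
    min_sightings : int
        Refuse to fit below this many records.
    random_state : int
        Seed for start jitter (fits are deterministic given it).

    Attributes
    ----------
    coef_ : ndarray
        Scale coefficients [b0, b_1..b_m] on the standardized covariate scale.
    shape_ : float or None
        Hazard-rate shape b (> 1); None for half-normal.
    loglik_, aic_ : float
    covariance_ : ndarray
        Inverse observed information of the full parameter vector
        (scale coefficients plus, for hazard-rate, eta = log(b - 1)).
    esw_ : ndarray
        Per-sighting effective strip half-width (m).
    """

    def __init__(self, form="hazard_rate", covariates=(), left=71.0, right=570.0,
                 n_starts=5, min_sightings=10, random_state=0):
        self.form = form
        self.covariates = covariates
        self.left = left
        self.right = right
        self.n_starts = n_starts
        self.min_sightings = min_sightings
        self.random_state = random_state

    # -- parameter layout: theta = [beta (1+m), eta?] with b = 1 + exp(eta)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        Z = np.ones((n, 1 + len(self.covariates)))
        for k, name in enumerate(self.covariates):
            z = np.asarray(X[name], dtype=float)
            Z[:, 1 + k] = (z - self._cov_mean_[k]) / self._cov_scale_[k]
        return Z

    def _sigma(self, theta, Z):
        nb = Z.shape[1]
        return np.exp(Z @ theta[:nb])

    def _g(self, x, sigma, b):
        if self.form == "half_normal":
            return np.exp(-(x ** 2) / (2.0 * sigma ** 2))
        with np.errstate(over="ignore"):
            r = np.where(x > 0, (np.maximum(x, 1e-12) / sigma) ** (-b), np.inf)
        return -np.expm1(-r)

    def _esw(self, sigma, b):
        """Integral of g over the re-zeroed strip [0, right - left]."""
        if self.form == "half_normal":
            return _halfnormal_esw(sigma, 0.0, self.right - self.left)
        nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
        half = 0.5 * (self.right - self.left)
        mid = half
        u = mid + half * nodes  # (q,)
        gu = self._g(u[None, :], np.atleast_1d(sigma)[:, None], b)
        return half * gu @ weights

    def _unpack(self, theta):
        nb = 1 + len(self.covariates)
        b = 1.0 + np.exp(theta[nb]) if self.form == "hazard_rate" else None
        return theta[:nb], b

    def _negloglik(self, theta, x, Z):
        _, b = self._unpack(theta)
        sigma = self._sigma(theta, Z)
        esw = self._esw(sigma, b)
        if np.any(esw <= 0) or not np.all(np.isfinite(esw)):
            return 1e10
        g = self._g(x, sigma, b)
        if np.any(g <= 0):
            return 1e10
        ll = np.sum(np.log(g) - np.log(esw))
        return -ll if np.isfinite(ll) else 1e10

    def fit(self, X: pd.DataFrame, y=None):
        """Fit to a truncated unique-sighting table (perp_distance_m column)."""
        if self.form not in ("half_normal", "hazard_rate"):
            raise ValueError(f"unknown key form {self.form!r}")
        x = np.asarray(X["perp_distance_m"], dtype=float)
        if len(x) < self.min_sightings:
            raise FitError(f"need >= {self.min_sightings} sightings, got {len(x)}")
        if np.any((x < self.left) | (x > self.right)):
            raise ValueError("distances must be truncated to [left, right] first")
        # the strip is re-zeroed at the left boundary so the key's g(0) = 1
        # coincides with the distance at which the MR component estimates p(0)
        x = x - self.left

        self._cov_mean_, self._cov_scale_ = [], []
        for name in self.covariates:
            z = np.asarray(X[name], dtype=float)
            sd = z.std(ddof=0)
            self._cov_mean_.append(z.mean())
            self._cov_scale_.append(sd if sd > 0 else 1.0)
        Z = self._design(X)

        nb = Z.shape[1]
        dim = nb + (1 if self.form == "hazard_rate" else 0)
        theta0 = np.zeros(dim)
        # scale start: spread of the shifted distances
        theta0[0] = np.log(max(np.std(x, ddof=0), 10.0))
        if self.form == "hazard_rate":
            theta0[nb] = np.log(1.5)  # b = 2.5

        rng = np.random.default_rng(self.random_state)
        best = None
        for s in range(self.n_starts):
            start = theta0 if s == 0 else theta0 + rng.normal(0, 0.3, dim)
            res = optimize.minimize(
                self._negloglik, start, args=(x, Z), method="BFGS",
                options={"gtol": 1e-8, "maxiter": 500},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or best.fun >= 1e9:
            raise FitError(f"detection fit failed to converge ({self.form})")

        theta = best.x
        self.theta_ = theta
        beta, b = self._unpack(theta)
        self.coef_ = beta
        self.shape_ = b
        self.n_params_ = dim
        self.loglik_ = -best.fun
        self.aic_ = 2 * dim - 2 * self.loglik_
        self.covariance_, self.covariance_flag_ = self._information_inverse(theta, x, Z)
        sigma = self._sigma(theta, Z)
        self.sigma_ = sigma
        self.esw_ = np.atleast_1d(self._esw(sigma, b))
        self.n_ = len(x)
        self._x_ = x + self.left   # original scale, for GOF
        self._Z_ = Z
        return self

    def _information_inverse(self, theta, x, Z):
        h = 1e-4
        dim = len(theta)
        H = np.zeros((dim, dim))
        f0 = self._negloglik(theta, x, Z)
        for i in range(dim):
            for j in range(i, dim):
                ei = np.zeros(dim); ei[i] = h
                ej = np.zeros(dim); ej[j] = h
                fpp = self._negloglik(theta + ei + ej, x, Z)
                fpm = self._negloglik(theta + ei - ej, x, Z)
                fmp = self._negloglik(theta - ei + ej, x, Z)
                fmm = self._negloglik(theta - ei - ej, x, Z)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            cov = np.linalg.inv(H)
            flag = "ok" if np.all(np.diag(cov) > 0) else "nonpositive-variance"
        except np.linalg.LinAlgError:
            cov = np.full((dim, dim), np.nan)
            flag = "singular-information"
        if flag != "ok":
            warnings.warn(f"detection covariance flagged: {flag}")
        _ = f0
        return cov, flag

    # -- post-fit evaluation

    def detection_probability(self, x, X=None):
        """g at original distance x (g = 1 at the left boundary).

        With X=None uses covariate means (standardized zero)."""
        x = np.asarray(x, dtype=float) - self.left
        if X is None:
            sigma = np.exp(self.coef_[0])
            return self._g(x, sigma, self.shape_)
        Z = self._design(X)
        sigma = self._sigma(self.theta_, Z)
        return self._g(x, sigma, self.shape_)

    def esw(self, X=None):
        """Effective strip half-width (m), per row of X or at covariate means."""
        if X is None:
            sigma = np.exp(self.coef_[0])
        else:
            sigma = self._sigma(self.theta_, self._design(X))
        return np.atleast_1d(self._esw(np.atleast_1d(sigma), self.shape_))

    def average_cdf(self, x):
        """Fitted distance CDF averaged over the training covariates
        (x on the original, unshifted scale)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        x = np.clip(x - self.left, 0.0, self.right - self.left)
        sigma, b = self.sigma_, self.shape_
        if self.form == "half_normal":
            num = _halfnormal_esw(sigma[:, None], 0.0, x[None, :])
        else:
            q = 31
            nodes, weights = np.polynomial.legendre.leggauss(q)
            half = 0.5 * x      # (k,)
            mid = half
            u = mid[None, :, None] + half[None, :, None] * nodes[None, None, :]
            gu = self._g(u, sigma[:, None, None], b)
            num = half[None, :] * np.einsum("nkq,q->nk", gu, weights)
        return (num / self.esw_[:, None]).mean(axis=0)

    def sample(self, n, rng):
        """Draw n original-scale distances from the fitted model
        (covariates resampled with replacement)."""
        idx = rng.integers(0, self.n_, n)
        sigma = self.sigma_[idx]
        grid = np.linspace(0.0, self.right - self.left, 513)
        out = np.empty(n)
        # inverse CDF per sigma via interpolation on a common grid
        for s in np.unique(sigma):
            m = sigma == s
            if self.form == "half_normal":
                cdf = _halfnormal_esw(s, 0.0, grid)
            else:
                g = self._g(grid, s, self.shape_)
                cdf = np.concatenate([[0.0], np.cumsum(
                    0.5 * (g[1:] + g[:-1]) * np.diff(grid))])
            cdf = cdf / cdf[-1]
            out[m] = np.interp(rng.uniform(size=m.sum()), cdf, grid)
        return out + self.left

    def gof(self, n_boot=199, random_state=0) -> GOFResult:
        """Goodness of fit of the fitted distance distribution.

        KS and Cramer-von Mises statistics are computed against the
        covariate-averaged fitted CDF. Because the parameters were estimated
        from the same data, p-values come from a parametric bootstrap
        (refitting on samples drawn from the fitted model); the invalid
        asymptotic p-values are reported alongside for reference.
        """
        x = np.sort(self._x_)
        n = len(x)
        if n < 5:
            warnings.warn("too few sightings for GOF tests")
            return GOFResult(*([np.nan] * 6), np.empty((0, 2)))
        F = self.average_cdf
        ks = stats.kstest(x, F)
        cvm = stats.cramervonmises(x, F)
        qq = np.column_stack([F(x), (np.arange(1, n + 1) - 0.5) / n])

        ks_p, cvm_p = ks.pvalue, cvm.pvalue
        if n_boot and n_boot > 0:
            rng = np.random.default_rng(random_state)
            ks_ge = cvm_ge = 0
            nb = 0
            for _ in range(n_boot):
                xb = self.sample(n, rng)
                boot = DetectionFunction(
                    form=self.form, covariates=(), left=self.left,
                    right=self.right, n_starts=1, min_sightings=2,
                    random_state=0,
                )
                try:
                    boot.fit(pd.DataFrame({"perp_distance_m": xb}))
                except FitError:
                    continue
                nb += 1
                ksb = stats.kstest(np.sort(xb), boot.average_cdf).statistic
                cvmb = stats.cramervonmises(xb, boot.average_cdf).statistic
                ks_ge += ksb >= ks.statistic
                cvm_ge += cvmb >= cvm.statistic
            if nb > 0:
                ks_p = (1 + ks_ge) / (nb + 1)
                cvm_p = (1 + cvm_ge) / (nb + 1)
        return GOFResult(ks.statistic, ks_p, cvm.statistic, cvm_p,
                         ks.pvalue, cvm.pvalue, qq)


def fit_ds(sightings: pd.DataFrame, form="hazard_rate", covariates=(),
           left=71.0, right=570.0, **kwargs) -> DetectionFunction:
    """Convenience wrapper: fit one DS model to a truncated sighting table."""
    return DetectionFunction(form=form, covariates=tuple(covariates),
                             left=left, right=right, **kwargs).fit(sightings)


def rank_models(fits, gofs=None, cvs=None):
    """Order candidate DS fits: ascending AIC; among AIC ties (< 1e-6) prefer
    the best goodness of fit (largest KS p, then largest CvM p), then the
    smallest estimate CV."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    gofs = list(gofs) if gofs is not None else [None] * len(fits)
    cvs = list(cvs) if cvs is not None else [np.nan] * len(fits)

    def key(i):
        g = gofs[i]
        ks_p = g.ks_p if g is not None and np.isfinite(g.ks_p) else 0.0
        cvm_p = g.cvm_p if g is not None and np.isfinite(g.cvm_p) else 0.0
        cv = cvs[i] if np.isfinite(cvs[i]) else np.inf
        return (round(fits[i].aic_ / 1e-6) * 1e-6, -ks_p, -cvm_p, cv)

    order = sorted(range(len(fits)), key=key)
    return [fits[i] for i in order], order


def forward_model_search(sightings, covariate_pool, left=71.0, right=570.0,
                         forms=("half_normal", "hazard_rate"), **kwargs):
    """Systematic key x covariate search, adding scale covariates one by one.

    For each key form, starts from the covariate-free model and greedily adds
    the single covariate that lowers AIC the most, stopping when no addition
    improves. Returns all fitted candidates and the AIC-best fit; the ledger
    of every candidate (form, covariates, AIC) comes back as a DataFrame so
    the selection is auditable.
    """
    candidates = []
    rows = []
    for form in forms:
        selected: list[str] = []
        current = fit_ds(sightings, form, (), left, right, **kwargs)
        candidates.append(current)
        rows.append({"form": form, "covariates": "", "aic": current.aic_})
        pool = list(covariate_pool)
        while pool:
            trials = []
            for c in pool:
                try:
                    f = fit_ds(sightings, form, (*selected, c), left, right, **kwargs)
                except FitError:
                    continue
                candidates.append(f)
                rows.append({"form": form, "covariates": "+".join((*selected, c)),
                             "aic": f.aic_})
                trials.append((f.aic_, c, f))
            if not trials:
                break
            trials.sort(key=lambda t: t[0])
            best_aic, best_cov, best_fit = trials[0]
            if best_aic < current.aic_ - 1e-9:
                current = best_fit
                selected.append(best_cov)
                pool.remove(best_cov)
            else:
                break
    ranked, _ = rank_models(candidates)
    return ranked[0], candidates, pd.DataFrame(rows)
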