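"""Mark-recapture (MR) component and point-independence combination.

With two observer platforms, detection probability on the trackline — g(0),
assumed 1 in conventional distance sampling — can be estimated. Each
platform's conditional detection probability (detecting a school given the
other platform saw it) is modelled as a logistic GLM in perpendicular
distance. Under point independence the platforms are assumed independent
only at the closest observable distance; there

    p(0)_combined = 1 - (1 - p(0)_mid) (1 - p(0)_rear)

and each sighting's unconditional inclusion probability in the covered strip
becomes

    p_i = p(0)_combined * esw_i / (right - left),

with esw_i the per-sighting effective strip half-width from the DS
component. Distance enters the MR model re-zeroed at the left-truncation
boundary, so "zero distance" means the inner edge of the visible strip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = ["MarkRecaptureModel", "CombinedDetection", "combine_point_independence"]


class SeparationError(RuntimeError):
    """Perfect separation in a conditional-detection GLM."""


@dataclass
class CombinedDetection:
    """Per-sighting detection probabilities under point independence."""

    p: np.ndarray          # p_i per sighting, in (0, 1]
    p0_combined: float
    average_p: float       # n / sum(1/p_i), the HT-consistent average

    def __post_init__(self):
        if np.any(self.p < 0.01):
            warnings.warn(
                "detection probabilities below 0.01: Horvitz-Thompson "
                "estimates may be unstable"
            )


class MarkRecaptureModel(BaseEstimator):
    """Conditional logistic models of each platform's trackline detection.

    Fit twice on duplicate-flagged unique sightings: mid given rear detected,
    and rear given mid detected, each with linear predictor
    a0 + a1 * (x - left) (distance standardized). An optional platform
    indicator is supported but the default follows the distance-only layout.

    Attributes
    ----------
    p0_mid_, p0_rear_ : float
        Conditional detection probabilities at the left-truncation boundary.
    p0_combined_ : float
        1 - (1 - p0_mid)(1 - p0_rear).
    p0_combined_se_ : float
        Delta-method standard error (treats the two conditional fits as
        independent; they share duplicate records, so this is approximate).
    coef_ : dict
        Per-platform GLM coefficients on the standardized-distance scale.
    """

    def __init__(self, left=71.0, distance_covariate=True):
        self.left = left
        self.distance_covariate = distance_covariate

    def _fit_conditional(self, x, y):
        if y.all() or not y.any():
            # degenerate: all or none redetected
            p0 = float(y.mean()) if y.any() else 1e-8
            return {"coef": np.array([np.inf if y.all() else -np.inf, 0.0]),
                    "cov": np.zeros((2, 2)), "p0": p0, "p0_var": 0.0,
                    "X": None, "resid": None, "degenerate": True}
        xs = (x - self.left) / self._x_scale_
        X = sm.add_constant(xs) if self.distance_covariate else np.ones((len(x), 1))
        model = sm.GLM(y.astype(float), X, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover
            raise SeparationError(
                "conditional GLM failed; check for complete separation "
                "(e.g. all duplicates at short distances)"
            ) from exc
        coef = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(cov)) or np.abs(coef).max() > 30:
            raise SeparationError(
                "conditional GLM shows complete separation; pool covariates "
                "or refit with distance omitted"
            )
        eta0 = coef[0]  # x' = 0 at the left boundary
        p0 = 1.0 / (1.0 + np.exp(-eta0))
        p0_var = (p0 * (1 - p0)) ** 2 * cov[0, 0]
        fitted = np.asarray(res.fittedvalues)
        return {"coef": coef, "cov": cov, "p0": float(p0),
                "p0_var": float(p0_var), "X": np.atleast_2d(X),
                "resid": y.astype(float) - fitted, "degenerate": False}

    def fit(self, X: pd.DataFrame, y=None):
        """Fit to a truncated unique-sighting table with both platform flags."""
        mid = np.asarray(X["detected_mid"], dtype=bool)
        rear = np.asarray(X["detected_rear"], dtype=bool)
        if not (mid | rear).all():
            raise ValueError("every unique sighting must be seen by a platform")
        if not mid.any() or not rear.any():
            raise ValueError("need at least one detection per platform")
        x = np.asarray(X["perp_distance_m"], dtype=float)
        self._x_scale_ = max(np.std(x - self.left, ddof=0), 1.0)

        # mid detections conditional on rear having detected, and vice versa
        fit_mid = self._fit_conditional(x[rear], mid[rear])
        fit_rear = self._fit_conditional(x[mid], rear[mid])
        if fit_mid["degenerate"] and fit_rear["degenerate"]:
            warnings.warn("all sightings are duplicates: p0 = 1 with zero variance")
        self.p0_mid_ = fit_mid["p0"]
        self.p0_rear_ = fit_rear["p0"]
        self.p0_combined_ = 1.0 - (1.0 - self.p0_mid_) * (1.0 - self.p0_rear_)
        # delta method; the two conditional fits share the duplicate records,
        # so their cross-covariance (stacked-score sandwich over the shared
        # rows) enters alongside the marginal variances
        var = ((1 - self.p0_rear_) ** 2 * fit_mid["p0_var"]
               + (1 - self.p0_mid_) ** 2 * fit_rear["p0_var"])
        cov_p0 = self._p0_cross_covariance(fit_mid, fit_rear, mid, rear)
        var += 2 * (1 - self.p0_rear_) * (1 - self.p0_mid_) * cov_p0
        self.p0_combined_se_ = float(np.sqrt(max(var, 0.0)))
        self.coef_ = {"mid": fit_mid["coef"], "rear": fit_rear["coef"]}
        self.covariance_ = {"mid": fit_mid["cov"], "rear": fit_rear["cov"]}
        self._fits_ = {"mid": fit_mid, "rear": fit_rear}
        return self

    def _p0_cross_covariance(self, fit_mid, fit_rear, mid, rear):
        """cov(p0_mid, p0_rear) through the duplicate records both
        conditional likelihoods use: Cov(theta1, theta2) = A1^-1 B12 A2^-1
        with B12 the cross outer-product of the per-record scores."""
        if fit_mid["degenerate"] or fit_rear["degenerate"]:
            return 0.0
        dup = mid & rear
        # positions of the duplicate rows inside each conditional sample
        in_mid_model = np.flatnonzero(rear)   # rows the mid|rear model used
        in_rear_model = np.flatnonzero(mid)
        pos1 = np.searchsorted(in_mid_model, np.flatnonzero(dup))
        pos2 = np.searchsorted(in_rear_model, np.flatnonzero(dup))
        s1 = fit_mid["X"][pos1] * fit_mid["resid"][pos1][:, None]
        s2 = fit_rear["X"][pos2] * fit_rear["resid"][pos2][:, None]
        B12 = s1.T @ s2
        cov12 = fit_mid["cov"] @ B12 @ fit_rear["cov"]
        g1 = self.p0_mid_ * (1 - self.p0_mid_)    # d p0 / d intercept
        g2 = self.p0_rear_ * (1 - self.p0_rear_)
        return float(g1 * g2 * cov12[0, 0])

    def conditional_probability(self, platform: str, x):
        """p(platform detects | other platform detected) at distance x (m)."""
        coef = self.coef_[platform]
        xs = (np.asarray(x, dtype=float) - self.left) / self._x_scale_
        eta = coef[0] + (coef[1] * xs if self.distance_covariate else 0.0)
        return 1.0 / (1.0 + np.exp(-eta))

    def report(self) -> dict:
        return {
            "p0_mid": self.p0_mid_,
            "p0_rear": self.p0_rear_,
            "p0_combined": self.p0_combined_,
            "p0_combined_se": self.p0_combined_se_,
            "coefficients": {k: v.tolist() for k, v in self.coef_.items()},
        }


def combine_point_independence(ds, mr, sightings: pd.DataFrame) -> CombinedDetection:
    """Per-sighting detection probability under the IO point-independence model.

    The DS component supplies the shape of detection with distance (through
    each sighting's effective strip half-width); the MR component supplies
    the trackline intercept p(0). Independence between platforms is assumed
    only at zero (boundary) distance — never at x > 0, where positive
    correlation between observers is expected.
    """
    esw = ds.esw(sightings)
    width = ds.right - ds.left
    p = mr.p0_combined_ * esw / width
    p = np.clip(p, 1e-12, 1.0)
    avg = len(p) / np.sum(1.0 / p)
    return CombinedDetection(p=p, p0_combined=mr.p0_combined_, average_p=float(avg))
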