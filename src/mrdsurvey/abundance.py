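"""Stratified Horvitz-Thompson abundance, density and school-size estimation.

Each detected school i, with detection probability p_i from the combined
MRDS model, represents 1/p_i schools (s_i/p_i animals) in the covered strip
of area a = 2 (right - left) L, where L is the stratum's total line length.
Scaling by the stratum area A gives

    N_schools = (A / a) sum_i 1 / p_i
    N_animals = (A / a) sum_i s_i / p_i
    D         = N_animals / A
    E[s]      = N_animals / N_schools

Variance has two parts: a detection component propagated by the delta
method through the DS and MR parameter covariances, and an encounter-rate
component treating transect lines as the sampling units (Innes-type,
applied to detection-corrected per-line totals). Confidence intervals are
log-normal, the convention for strictly positive abundance estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey import Stratum, TransectEffort

__all__ = [
    "StratumEstimate",
    "ht_estimate",
    "variance_components",
    "lognormal_ci",
    "pool_strata",
    "estimate_stratum",
]

Z_95 = 1.959964  # two-sided 95% normal quantile, fixed for reproducibility


@dataclass
class StratumEstimate:
    """Abundance and density for one stratum (or a pooled total)."""

    stratum_id: str
    area_km2: float
    effort_km: float
    n_sightings: int
    n_schools: float
    n_animals: float
    density: float                      # animals / km^2
    mean_school_size: float
    var_schools: float = np.nan
    var_animals: float = np.nan
    cov_schools_animals: float = np.nan
    cv_schools: float = np.nan
    cv_animals: float = np.nan
    cv_mean_size: float = np.nan
    ci_schools: tuple = (np.nan, np.nan)
    ci_animals: tuple = (np.nan, np.nan)
    ci_density: tuple = (np.nan, np.nan)
    detail: dict = field(default_factory=dict)

    @property
    def cv_density(self) -> float:
        return self.cv_animals  # area is a constant

    def to_dict(self) -> dict:
        return {
            "stratum_id": self.stratum_id,
            "area_km2": self.area_km2,
            "effort_km": self.effort_km,
            "n_sightings": self.n_sightings,
            "n_schools": self.n_schools,
            "n_animals": self.n_animals,
            "density": self.density,
            "mean_school_size": self.mean_school_size,
            "cv_schools": self.cv_schools,
            "cv_animals": self.cv_animals,
            "cv_mean_size": self.cv_mean_size,
            "ci_schools_low": self.ci_schools[0],
            "ci_schools_high": self.ci_schools[1],
            "ci_animals_low": self.ci_animals[0],
            "ci_animals_high": self.ci_animals[1],
            "ci_density_low": self.ci_density[0],
            "ci_density_high": self.ci_density[1],
        }


def _covered_area_km2(left_m: float, right_m: float, effort_km: float) -> float:
    return 2.0 * (right_m - left_m) / 1000.0 * effort_km


def ht_estimate(stratum: Stratum, effort: list[TransectEffort],
                sightings: pd.DataFrame, p: np.ndarray,
                window: tuple[float, float]) -> StratumEstimate:
    """Horvitz-Thompson point estimates for one stratum.

    ``sightings`` holds the stratum's truncated unique sightings; ``p`` their
    detection probabilities. A stratum with zero sightings yields zero point
    estimates (a real survey outcome, not an error).
    """
    left, right = window
    L = sum(e.length_km for e in effort)
    if L <= 0:
        raise ValueError(f"stratum {stratum.id}: no effort")
    a = _covered_area_km2(left, right, L)
    A = stratum.area_km2
    if A < a:
        warnings.warn(f"stratum {stratum.id}: covered area exceeds stratum area")
    n = len(sightings)
    if n == 0:
        return StratumEstimate(stratum.id, A, L, 0, 0.0, 0.0, 0.0, 0.0,
                               var_schools=0.0, var_animals=0.0,
                               cov_schools_animals=0.0,
                               cv_schools=0.0, cv_animals=0.0, cv_mean_size=0.0,
                               ci_schools=(0.0, 0.0), ci_animals=(0.0, 0.0),
                               ci_density=(0.0, 0.0))
    p = np.asarray(p, dtype=float)
    if len(p) != n:
        raise ValueError("one detection probability per sighting required")
    s = np.asarray(sightings["school_size"], dtype=float)
    ns = (A / a) * np.sum(1.0 / p)
    na = (A / a) * np.sum(s / p)
    return StratumEstimate(
        stratum.id, A, L, n,
        n_schools=float(ns), n_animals=float(na),
        density=float(na / A),
        mean_school_size=float(na / ns),
    )


def _per_line_totals(stratum, effort, sightings, p, window):
    """Detection-corrected HT animal/school totals per transect line."""
    left, right = window
    L = sum(e.length_km for e in effort)
    a = _covered_area_km2(left, right, L)
    A = stratum.area_km2
    s = np.asarray(sightings["school_size"], dtype=float)
    p = np.asarray(p, dtype=float)
    tid = sightings["transect_id"].astype(str).to_numpy()
    totals = []
    for e in effort:
        m = tid == str(e.transect_id)
        totals.append((
            e.length_km,
            (A / a) * np.sum(1.0 / p[m]) if m.any() else 0.0,
            (A / a) * np.sum(s[m] / p[m]) if m.any() else 0.0,
        ))
    return totals


def _encounter_cov(totals, L):
    """Innes-type between-line (co)variance of the HT totals.

    With per-line totals T_k on lines of length l_k and T = sum T_k,
    var = [K/(K-1)] (L/K) sum_k l_k (T_k/l_k - T/L)^2, lines as sampling
    units; the cross term uses the same weights.
    """
    K = len(totals)
    if K < 2:
        return None
    lk = np.array([t[0] for t in totals])
    Ts = np.array([t[1] for t in totals])
    Ta = np.array([t[2] for t in totals])
    rs, ra = Ts / lk, Ta / lk
    rbar_s, rbar_a = Ts.sum() / L, Ta.sum() / L
    w = (K / (K - 1)) * (L / K) * lk
    return {
        "schools": float(np.sum(w * (rs - rbar_s) ** 2)),
        "animals": float(np.sum(w * (ra - rbar_a) ** 2)),
        "cross": float(np.sum(w * (rs - rbar_s) * (ra - rbar_a))),
    }


def variance_components(stratum: Stratum, effort: list[TransectEffort],
                        sightings: pd.DataFrame, ds, mr,
                        window: tuple[float, float]) -> dict:
    """Detection + encounter-rate variance of the stratum HT estimates.

    The detection component propagates the joint uncertainty of the DS scale
    / shape parameters and the MR conditional-GLM coefficients through the
    abundance functional with central finite differences (the component
    covariances are block-diagonal: the two model fits share no parameters).
    The encounter component applies the between-line estimator to the
    detection-corrected per-line totals.
    """
    n = len(sightings)
    L = sum(e.length_km for e in effort)
    if n == 0:
        return {"var_detection_animals": 0.0, "var_encounter_animals": 0.0,
                "var_animals": 0.0, "cv_animals": 0.0,
                "var_detection_schools": 0.0, "var_encounter_schools": 0.0,
                "var_schools": 0.0, "cv_schools": 0.0, "cov_schools_animals": 0.0}

    left, right = window
    a = _covered_area_km2(left, right, L)
    A = stratum.area_km2
    s = np.asarray(sightings["school_size"], dtype=float)

    # -- detection component: gradient of N w.r.t. (ds.theta_, mr coefs)
    def estimates(ds_theta, mr_coef_mid, mr_coef_rear):
        beta_dim = 1 + len(ds.covariates)
        sigma = np.exp(ds._design(sightings) @ ds_theta[:beta_dim])
        b = 1.0 + np.exp(ds_theta[beta_dim]) if ds.form == "hazard_rate" else None
        esw = np.atleast_1d(ds._esw(sigma, b))
        p0m = 1.0 / (1.0 + np.exp(-mr_coef_mid[0]))
        p0r = 1.0 / (1.0 + np.exp(-mr_coef_rear[0]))
        p0 = 1.0 - (1.0 - p0m) * (1.0 - p0r)
        p = np.clip(p0 * esw / (right - left), 1e-12, 1.0)
        return np.array([(A / a) * np.sum(1.0 / p), (A / a) * np.sum(s / p)])

    theta0 = ds.theta_.copy()
    cm0 = mr.coef_["mid"].copy()
    cr0 = mr.coef_["rear"].copy()
    params = [("ds", i) for i in range(len(theta0))]
    mr_ok_mid = np.all(np.isfinite(cm0)) and not mr._fits_["mid"]["degenerate"]
    mr_ok_rear = np.all(np.isfinite(cr0)) and not mr._fits_["rear"]["degenerate"]
    if mr_ok_mid:
        params += [("mid", i) for i in range(len(cm0))]
    if mr_ok_rear:
        params += [("rear", i) for i in range(len(cr0))]

    h = 1e-5
    grads = np.zeros((2, len(params)))
    for k, (blk, i) in enumerate(params):
        tp, tm = theta0.copy(), theta0.copy()
        cmp_, cmm = cm0.copy(), cm0.copy()
        crp, crm = cr0.copy(), cr0.copy()
        if blk == "ds":
            step = h * max(abs(theta0[i]), 1.0)
            tp[i] += step; tm[i] -= step
        elif blk == "mid":
            step = h * max(abs(cm0[i]), 1.0)
            cmp_[i] += step; cmm[i] -= step
        else:
            step = h * max(abs(cr0[i]), 1.0)
            crp[i] += step; crm[i] -= step
        grads[:, k] = (estimates(tp, cmp_, crp) - estimates(tm, cmm, crm)) / (2 * step)

    blocks = [ds.covariance_]
    if mr_ok_mid:
        blocks.append(mr.covariance_["mid"])
    if mr_ok_rear:
        blocks.append(mr.covariance_["rear"])
    dim = sum(b.shape[0] for b in blocks)
    C = np.zeros((dim, dim))
    off = 0
    for b in blocks:
        d = b.shape[0]
        C[off:off + d, off:off + d] = b
        off += d
    if not np.all(np.isfinite(C)):
        warnings.warn("non-finite parameter covariance; detection variance omitted")
        C = np.zeros_like(C)
    det_cov = grads @ C @ grads.T  # 2x2: (schools, animals)

    # -- encounter component
    totals = _per_line_totals(stratum, effort, sightings, _current_p(ds, mr, sightings),
                              window)
    enc = _encounter_cov(totals, L)
    if enc is None:
        warnings.warn(f"stratum {stratum.id}: single transect, encounter "
                      "variance undefined")
        enc = {"schools": np.nan, "animals": np.nan, "cross": np.nan}

    N = estimates(theta0, cm0, cr0)
    var_s = det_cov[0, 0] + enc["schools"]
    var_a = det_cov[1, 1] + enc["animals"]
    cov_sa = det_cov[0, 1] + enc["cross"]
    return {
        "var_detection_schools": float(det_cov[0, 0]),
        "var_detection_animals": float(det_cov[1, 1]),
        "var_encounter_schools": enc["schools"],
        "var_encounter_animals": enc["animals"],
        "var_schools": float(var_s),
        "var_animals": float(var_a),
        "cov_schools_animals": float(cov_sa),
        "cv_schools": float(np.sqrt(var_s) / N[0]) if N[0] > 0 else np.nan,
        "cv_animals": float(np.sqrt(var_a) / N[1]) if N[1] > 0 else np.nan,
    }


def _current_p(ds, mr, sightings):
    esw = ds.esw(sightings)
    return np.clip(mr.p0_combined_ * esw / (ds.right - ds.left), 1e-12, 1.0)


def lognormal_ci(point: float, cv: float, level: float = 0.95) -> tuple[float, float]:
    """Log-normal confidence interval (point / C, point * C) with
    C = exp(z sqrt(ln(1 + cv^2)))."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if point < 0:
        raise ValueError("point estimate must be non-negative")
    if cv == 0 or point == 0:
        return (point, point)
    from scipy.stats import norm
    z = Z_95 if level == 0.95 else norm.ppf(0.5 + level / 2)
    c = math.exp(z * math.sqrt(math.log1p(cv ** 2)))
    return (point / c, point * c)


def _finish(est: StratumEstimate, var: dict, level=0.95) -> StratumEstimate:
    """Attach variance, CVs and log-normal CIs to point estimates."""
    est.var_schools = var["var_schools"]
    est.var_animals = var["var_animals"]
    est.cov_schools_animals = var["cov_schools_animals"]
    est.cv_schools = var["cv_schools"]
    est.cv_animals = var["cv_animals"]
    if est.n_schools > 0 and est.n_animals > 0:
        # ratio delta method for E[s] = N_animals / N_schools
        cv2 = (var["cv_animals"] ** 2 + var["cv_schools"] ** 2
               - 2 * var["cov_schools_animals"] / (est.n_animals * est.n_schools))
        est.cv_mean_size = float(np.sqrt(max(cv2, 0.0)))
    else:
        est.cv_mean_size = 0.0
    if np.isfinite(est.cv_schools):
        est.ci_schools = lognormal_ci(est.n_schools, est.cv_schools, level)
    if np.isfinite(est.cv_animals):
        est.ci_animals = lognormal_ci(est.n_animals, est.cv_animals, level)
        est.ci_density = tuple(c / est.area_km2 for c in est.ci_animals)
    return est


def estimate_stratum(stratum, effort, sightings, ds, mr, window,
                     level=0.95) -> StratumEstimate:
    """Point estimates plus variance for one stratum in a single call."""
    p = _current_p(ds, mr, sightings) if len(sightings) else np.empty(0)
    est = ht_estimate(stratum, effort, sightings, p, window)
    if len(sightings):
        var = variance_components(stratum, effort, sightings, ds, mr, window)
        est = _finish(est, var, level)
        est.detail = {k: var[k] for k in ("var_detection_animals",
                                          "var_encounter_animals")}
    return est


def pool_strata(estimates: list[StratumEstimate], level=0.95) -> StratumEstimate:
    """Pool non-overlapping strata: totals sum, variances add (independent
    strata), overall density is total animals over total area, and the
    pooled mean school size is the ratio of pooled totals."""
    ids = [e.stratum_id for e in estimates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stratum ids in pool")
    if len(estimates) == 1:
        return estimates[0]
    A = sum(e.area_km2 for e in estimates)
    L = sum(e.effort_km for e in estimates)
    ns = sum(e.n_schools for e in estimates)
    na = sum(e.n_animals for e in estimates)
    var_s = float(np.nansum([e.var_schools for e in estimates]))
    var_a = float(np.nansum([e.var_animals for e in estimates]))
    cov_sa = float(np.nansum([e.cov_schools_animals for e in estimates]))
    pooled = StratumEstimate(
        "total", A, L, sum(e.n_sightings for e in estimates),
        n_schools=ns, n_animals=na,
        density=na / A, mean_school_size=(na / ns) if ns > 0 else 0.0,
    )
    var = {"var_schools": var_s, "var_animals": var_a,
           "cov_schools_animals": cov_sa,
           "cv_schools": np.sqrt(var_s) / ns if ns > 0 else 0.0,
           "cv_animals": np.sqrt(var_a) / na if na > 0 else 0.0}
    return _finish(pooled, var, level)
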