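"""Horvitz-Thompson estimation, Innes-type variance, intervals, pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrdsurvey import (
    MarkRecaptureModel,
    Stratum,
    TransectEffort,
    estimate_stratum,
    fit_ds,
    ht_estimate,
    lognormal_ci,
    pool_strata,
    variance_components,
)
from mrdsurvey.abundance import StratumEstimate, _encounter_cov, _per_line_totals
from .conftest import halfnormal_sample, make_sightings

WINDOW = (71.0, 570.0)


def _stratum(area=10000.0):
    return Stratum("s1", "test", area)


def _effort(lengths, stratum="s1"):
    return [TransectEffort(f"T{i}", stratum, l) for i, l in enumerate(lengths)]


class TestHTEstimate:
    def test_census_identity(self):
        """p = 1 everywhere and covered area equal to the stratum returns
        the plain sum of school sizes."""
        lengths = [50.0]
        a = 2 * (WINDOW[1] - WINDOW[0]) / 1000 * sum(lengths)
        st_ = _stratum(area=a)
        rng = np.random.default_rng(0)
        s = make_sightings(rng.uniform(71, 570, 40),
                           sizes=rng.integers(1, 8, 40).astype(float))
        est = ht_estimate(st_, _effort(lengths), s, np.ones(40), WINDOW)
        assert est.n_animals == pytest.approx(s["school_size"].sum())
        assert est.n_schools == pytest.approx(40)
        assert est.mean_school_size == pytest.approx(s["school_size"].mean())

    def test_zero_sightings_row(self):
        """A stratum with no sightings reports zeros, not an error."""
        est = ht_estimate(_stratum(), _effort([100.0, 120.0]),
                          make_sightings(np.empty(0)), np.empty(0), WINDOW)
        assert est.n_animals == 0.0 and est.n_schools == 0.0
        assert est.density == 0.0 and est.mean_school_size == 0.0
        assert est.cv_animals == 0.0
        assert est.ci_animals == (0.0, 0.0)

    def test_identities_density_and_mean_size(self):
        rng = np.random.default_rng(1)
        n = 60
        s = make_sightings(rng.uniform(71, 570, n),
                           sizes=rng.integers(1, 10, n).astype(float))
        p = rng.uniform(0.3, 1.0, n)
        est = ht_estimate(_stratum(), _effort([80.0, 90.0]), s, p, WINDOW)
        assert est.density == pytest.approx(est.n_animals / est.area_km2)
        assert est.mean_school_size == pytest.approx(
            est.n_animals / est.n_schools)

    @given(st.floats(min_value=1.1, max_value=5.0))
    @settings(max_examples=20, derandomize=True)
    def test_scale_equivariance_in_school_size(self, factor):
        rng = np.random.default_rng(2)
        n = 30
        x = rng.uniform(71, 570, n)
        sizes = rng.integers(1, 6, n).astype(float)
        p = rng.uniform(0.4, 1.0, n)
        base = ht_estimate(_stratum(), _effort([100.0]),
                           make_sightings(x, sizes=sizes), p, WINDOW)
        scaled = ht_estimate(_stratum(), _effort([100.0]),
                             make_sightings(x, sizes=sizes * factor), p, WINDOW)
        assert scaled.n_animals == pytest.approx(base.n_animals * factor)
        assert scaled.mean_school_size == pytest.approx(
            base.mean_school_size * factor)
        assert scaled.n_schools == pytest.approx(base.n_schools)


class TestEncounterVariance:
    def test_equal_rates_give_zero(self):
        totals = [(10.0, 5.0, 12.0), (20.0, 10.0, 24.0), (15.0, 7.5, 18.0)]
        enc = _encounter_cov(totals, L=45.0)
        assert enc["schools"] == pytest.approx(0.0, abs=1e-20)
        assert enc["animals"] == pytest.approx(0.0, abs=1e-20)

    def test_single_transect_undefined(self):
        rng = np.random.default_rng(3)
        s = make_sightings(halfnormal_sample(30, 230, 71, 570, rng))
        ds = fit_ds(s, "half_normal", (), *WINDOW, n_starts=1)
        s2 = s.copy()
        s2["detected_rear"] = rng.uniform(size=30) < 0.6
        mr = MarkRecaptureModel(left=71).fit(s2)
        with pytest.warns(UserWarning, match="encounter"):
            var = variance_components(_stratum(), _effort([100.0]), s2, ds, mr,
                                      WINDOW)
        assert np.isnan(var["var_encounter_animals"])

    def test_detection_variance_additivity(self):
        """Zeroing the parameter covariances leaves the encounter-only CV."""
        rng = np.random.default_rng(4)
        n = 80
        s = make_sightings(halfnormal_sample(n, 230, 71, 570, rng),
                           sizes=rng.integers(1, 5, n).astype(float))
        s["transect_id"] = [f"T{i % 4}" for i in range(n)]
        s["detected_rear"] = rng.uniform(size=n) < 0.6
        ds = fit_ds(s, "half_normal", (), *WINDOW, n_starts=1)
        mr = MarkRecaptureModel(left=71).fit(s)
        eff = _effort([100.0, 100.0, 100.0, 100.0])
        var = variance_components(_stratum(), eff, s, ds, mr, WINDOW)
        assert var["var_animals"] == pytest.approx(
            var["var_detection_animals"] + var["var_encounter_animals"])
        ds.covariance_ = np.zeros_like(ds.covariance_)
        mr.covariance_ = {k: np.zeros_like(v)
                          for k, v in mr.covariance_.items()}
        frozen = variance_components(_stratum(), eff, s, ds, mr, WINDOW)
        assert frozen["var_detection_animals"] == pytest.approx(0.0, abs=1e-12)
        assert frozen["var_animals"] == pytest.approx(
            var["var_encounter_animals"])

    def test_against_transect_bootstrap(self):
        """Innes-type encounter CV within 20% of a 500-resample bootstrap
        over transects (detection frozen)."""
        rng = np.random.default_rng(5)
        K, per = 12, 110
        rows = []
        for k in range(K):
            nk = rng.poisson(per / 10)
            x = halfnormal_sample(max(nk, 1), 230, 71, 570, rng)
            df = make_sightings(x, sizes=rng.integers(1, 5, len(x)).astype(float),
                                transect=f"T{k}")
            rows.append(df)
        s = pd.concat(rows, ignore_index=True)
        p = np.full(len(s), 0.55)
        eff = _effort([100.0] * K)
        stratum = _stratum(area=30000.0)
        totals = _per_line_totals(stratum, eff, s, p, WINDOW)
        enc = _encounter_cov(totals, L=100.0 * K)
        est = ht_estimate(stratum, eff, s, p, WINDOW)
        cv_est = np.sqrt(enc["animals"]) / est.n_animals

        Ta = np.array([t[2] for t in totals])
        boots = np.empty(500)
        for b in range(500):
            idx = rng.integers(0, K, K)
            boots[b] = Ta[idx].sum()
        cv_boot = boots.std(ddof=1) / est.n_animals
        assert cv_est == pytest.approx(cv_boot, rel=0.20)


class TestLognormalCI:
    def test_zero_cv_degenerate(self):
        assert lognormal_ci(100.0, 0.0) == (100.0, 100.0)

    def test_documented_values(self):
        """point 100, cv 0.2, 95%: C = exp(1.959964 sqrt(ln 1.04))."""
        low, high = lognormal_ci(100.0, 0.2)
        c = np.exp(1.959964 * np.sqrt(np.log(1.04)))
        assert low == pytest.approx(100 / c, rel=1e-9)
        assert high == pytest.approx(100 * c, rel=1e-9)
        assert low == pytest.approx(67.83, abs=0.05)
        assert high == pytest.approx(147.43, abs=0.05)

    def test_simulation_cross_check(self):
        """The closed form matches quantiles of a matched log-normal MC."""
        rng = np.random.default_rng(6)
        point, cv = 100.0, 0.2
        s2 = np.log(1 + cv ** 2)
        draws = np.exp(rng.normal(np.log(point), np.sqrt(s2), 400000))
        low, high = lognormal_ci(point, cv)
        geo_med = np.exp(np.log(draws).mean())
        ql, qh = np.quantile(draws, [0.025, 0.975])
        assert ql / geo_med * point == pytest.approx(low, rel=0.01)
        assert qh / geo_med * point == pytest.approx(high, rel=0.01)

    @given(st.floats(min_value=0.0, max_value=2.0),
           st.floats(min_value=1.0, max_value=1e5))
    @settings(max_examples=50, derandomize=True)
    def test_contains_point(self, cv, point):
        low, high = lognormal_ci(point, cv)
        assert low <= point <= high

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            lognormal_ci(10.0, -0.1)


class TestPooling:
    def _estimate(self, sid, area, animals, schools, var_a=0.0, var_s=0.0):
        e = StratumEstimate(sid, area, 100.0, 10, schools, animals,
                            animals / area,
                            animals / schools if schools else 0.0)
        e.var_animals, e.var_schools, e.cov_schools_animals = var_a, var_s, 0.0
        e.cv_animals = np.sqrt(var_a) / animals if animals else 0.0
        e.cv_schools = np.sqrt(var_s) / schools if schools else 0.0
        return e

    def test_totals_and_density(self):
        pooled = pool_strata([
            self._estimate("1", 10000.0, 2000.0, 800.0, 400.0**2, 150.0**2),
            self._estimate("2", 5000.0, 1000.0, 500.0, 300.0**2, 120.0**2),
        ])
        assert pooled.n_animals == pytest.approx(3000.0)
        assert pooled.n_schools == pytest.approx(1300.0)
        assert pooled.density == pytest.approx(3000.0 / 15000.0)
        assert pooled.mean_school_size == pytest.approx(3000.0 / 1300.0)
        assert pooled.var_animals == pytest.approx(400.0**2 + 300.0**2)

    def test_zero_stratum_contributes_nothing(self):
        base = self._estimate("2", 10000.0, 2000.0, 800.0, 400.0**2, 150.0**2)
        zero = self._estimate("1", 9000.0, 0.0, 0.0)
        pooled = pool_strata([zero, base])
        assert pooled.n_animals == pytest.approx(base.n_animals)
        assert pooled.n_schools == pytest.approx(base.n_schools)
        assert pooled.var_animals == pytest.approx(base.var_animals)

    def test_single_stratum_identity(self):
        e = self._estimate("1", 10000.0, 2000.0, 800.0, 400.0**2, 150.0**2)
        assert pool_strata([e]) is e

    def test_duplicate_ids_rejected(self):
        e1 = self._estimate("1", 10000.0, 2000.0, 800.0)
        e2 = self._estimate("1", 5000.0, 100.0, 50.0)
        with pytest.raises(ValueError):
            pool_strata([e1, e2])


class TestEndToEndStratum:
    def test_estimate_stratum_consistency(self, default_survey):
        """Full stratum estimate: CI brackets the point, identities hold."""
        from mrdsurvey import match_duplicates, truncate
        sim = default_survey
        uni = match_duplicates(sim["mid"], sim["rear"])
        trunc = truncate(uni, *WINDOW)
        ds = fit_ds(trunc, "half_normal", (), *WINDOW, n_starts=2)
        mr = MarkRecaptureModel(left=71).fit(trunc)
        tid_to_stratum = {e.transect_id: e.stratum_id for e in sim["effort"]}
        sid = trunc["transect_id"].astype(str).map(tid_to_stratum)
        st2 = next(s for s in sim["strata"] if s.id == "2")
        eff = [e for e in sim["effort"] if e.stratum_id == "2"]
        sub = trunc[sid == "2"]
        est = estimate_stratum(st2, eff, sub, ds, mr, WINDOW)
        assert est.ci_animals[0] <= est.n_animals <= est.ci_animals[1]
        assert est.density == pytest.approx(est.n_animals / st2.area_km2)
        assert est.cv_animals > 0
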