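import itertools

import numpy as np
import pandas as pd
import pytest

from swiftascent import inference


# ---- Wilcoxon signed-rank ----

def enumerate_signed_rank(values):
    """Independent oracle: exact V and one-sided (greater) p by enumerating
    every sign assignment of the ranked magnitudes."""
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    ranks = pd.Series(np.abs(x)).rank().to_numpy()
    v_obs = ranks[x > 0].sum()
    n = len(x)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        v = ranks[np.array(signs, dtype=bool)].sum()
        if v >= v_obs - 1e-12:
            count += 1
    return float(v_obs), count / 2**n


def test_all_positive_medians():
    v, p = inference.wilcoxon_median_ascent([10.0, 250.0, 33.0, 400.0, 120.0])
    assert v == 15.0
    assert p == pytest.approx(1 / 32)


def test_all_negative_medians():
    v, p = inference.wilcoxon_median_ascent([-10.0, -250.0, -33.0, -400.0, -120.0])
    assert v == 0.0
    assert p == pytest.approx(1.0)


def test_symmetric_medians_with_zero():
    v, p = inference.wilcoxon_median_ascent([-2.0, -1.0, 0.0, 1.0, 2.0])
    assert p > 0.05  # zero dropped, n = 4, no evidence of positive shift


def test_matches_enumeration_for_small_n():
    rng = np.random.default_rng(8)
    for _ in range(30):
        n = int(rng.integers(5, 11))
        x = rng.normal(0.3, 1.0, n)
        v, p = inference.wilcoxon_median_ascent(x)
        v_ref, p_ref = enumerate_signed_rank(x)
        assert v == v_ref
        assert p == pytest.approx(p_ref, abs=1e-12)


def test_too_few_individuals_rejected():
    with pytest.raises(ValueError):
        inference.wilcoxon_median_ascent([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        inference.wilcoxon_median_ascent([1.0, 2.0, np.nan, 4.0, 5.0])


# ---- ascent model ----

def _markov_binary(n, p, rho, rng):
    y = np.empty(n, dtype=int)
    y[0] = rng.random() < p
    p11, p01 = p + rho * (1 - p), p * (1 - rho)
    for i in range(1, n):
        y[i] = rng.random() < (p11 if y[i - 1] else p01)
    return y


def _records(rng, n_birds=10, n_obs=400, rho=0.0, beta_phase=0.0, beta_dawn=0.0):
    rows = []
    for k in range(n_birds):
        phase = rng.choice(["migration", "non-breeding"], n_obs)
        kind = np.tile(["dawn", "dusk"], n_obs // 2)
        eta = -1.0 + beta_phase * (phase == "non-breeding") + beta_dawn * (kind == "dawn")
        if rho == 0:
            y = rng.random(n_obs) < 1 / (1 + np.exp(-eta))
        else:
            y = _markov_binary(n_obs, 0.3, rho, rng)
        rows.append(pd.DataFrame({
            "is_ascent": y, "phase": phase, "kind": kind,
            "individual": f"b{k:02d}", "population": "pop1" if k % 2 else "pop2",
            "seq": np.arange(n_obs),
        }))
    return pd.concat(rows, ignore_index=True)


SPEC = inference.ModelSpec(continuous=())


def test_ci_half_width_is_twice_the_standard_error():
    fit = inference.fit_ascent_model(_records(np.random.default_rng(0), beta_phase=1.0), SPEC)
    assert fit.converged
    np.testing.assert_allclose(fit.ci_upper - fit.estimates, 2 * fit.std_errors)
    np.testing.assert_allclose(fit.estimates - fit.ci_lower, 2 * fit.std_errors)


def test_effect_recovered_with_correct_sign():
    fit = inference.fit_ascent_model(
        _records(np.random.default_rng(1), beta_phase=1.0, beta_dawn=0.7), SPEC
    )
    assert fit.estimates["phase[non-breeding]"] == pytest.approx(1.0, abs=0.25)
    assert fit.estimates["twilight[dawn]"] == pytest.approx(0.7, abs=0.25)


def test_ar1_parameter_recovery():
    """Data generated with lag-one within-individual correlation 0.5 yield
    an AR(1) estimate within ±0.15."""
    fit = inference.fit_ascent_model(_records(np.random.default_rng(2), rho=0.5), SPEC)
    assert fit.converged
    assert fit.ar1 == pytest.approx(0.5, abs=0.15)


def test_ar1_and_independence_agree_under_independence():
    rec = _records(np.random.default_rng(3), n_birds=10, n_obs=2000, beta_phase=0.6)
    f_ar = inference.fit_ascent_model(rec, SPEC)
    f_in = inference.fit_ascent_model(
        rec, inference.ModelSpec(continuous=(), correlation="independence")
    )
    assert (f_ar.estimates - f_in.estimates).abs().max() < 0.01
    assert abs(f_ar.ar1) < 0.05


def test_degenerate_continuous_factor_dropped_with_warning():
    rec = _records(np.random.default_rng(4))
    rec["mslp"] = 1013.0
    with pytest.warns(UserWarning, match="mslp"):
        fit = inference.fit_ascent_model(rec, inference.ModelSpec(continuous=("mslp",)))
    assert "mslp" in fit.dropped_factors
    assert "mslp" not in fit.estimates.index


def test_single_individual_rejected():
    rec = _records(np.random.default_rng(5), n_birds=1)
    with pytest.raises(ValueError):
        inference.fit_ascent_model(rec, SPEC)


# ---- ensemble ----

def test_degenerate_resampling_gives_identical_fits():
    base = _records(np.random.default_rng(6), beta_phase=1.0)
    ens = inference.run_ensemble(lambda seed: base, n_runs=5, seed=0, spec=SPEC)
    first = ens.fits[0].estimates
    for f in ens.fits[1:]:
        pd.testing.assert_series_equal(f.estimates, first)
    assert ens.relevance["phase[non-breeding]"]


def test_ensemble_deterministic_given_seed():
    def maker(seed):
        return _records(np.random.default_rng(seed), beta_phase=1.0)

    a = inference.run_ensemble(maker, n_runs=4, seed=9, spec=SPEC)
    b = inference.run_ensemble(maker, n_runs=4, seed=9, spec=SPEC)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_one_null_run_defeats_relevance():
    """Zero inside a single run's confidence interval removes relevance, no
    matter how strong the other runs are (the all-intervals rule)."""
    calls = {"n": 0}

    def maker(seed):
        calls["n"] += 1
        beta = 0.0 if calls["n"] == 1 else 2.0
        return _records(np.random.default_rng(10), beta_phase=beta)

    ens = inference.run_ensemble(maker, n_runs=5, seed=1, spec=SPEC)
    grp = ens.table[ens.table["factor"] == "phase[non-breeding]"]
    excluded = ((grp["ci_lower"] > 0) | (grp["ci_upper"] < 0)).sum()
    assert excluded == 4  # strong in 4 of 5 runs...
    assert not ens.relevance["phase[non-breeding]"]  # ...but still not relevant


def test_ensemble_failure_when_too_many_runs_diverge():
    def maker(seed):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(4):
            x = rng.normal(size=60)
            rows.append(pd.DataFrame({
                "is_ascent": x > 0, "phase": "migration", "kind": "dawn",
                "individual": f"b{k}", "flight_alt": x, "seq": np.arange(60),
            }))
        return pd.concat(rows, ignore_index=True)

    with pytest.raises(inference.EnsembleFailureError):
        inference.run_ensemble(maker, n_runs=4, seed=2,
                               spec=inference.ModelSpec(continuous=("flight_alt",)))


# ---- activity–altitude slope ----

def _slope_pairs(rng, coupled=True):
    frames = []
    events = pd.date_range("2014-11-01 06:10", periods=40, freq="12h")
    for k in range(4):
        t30 = pd.date_range("2014-11-01", periods=40 * 24, freq="30min")
        act = pd.Series(rng.uniform(0, 40, len(t30) * 6),
                        index=pd.date_range(t30[0], periods=len(t30) * 6, freq="5min"))
        dalt = rng.normal(0, 50, len(t30))
        alt = pd.Series(800 + np.cumsum(dalt), index=t30)
        if coupled:
            # altitude gains driven by flapping in twilight intervals
            act30 = act.rolling(6, min_periods=1).mean().reindex(t30).to_numpy()
            bump = 4.0 * act30
            ev8 = events.asi8
            in_twilight = np.array([((ev8 > s) & (ev8 <= e)).any()
                                    for s, e in zip(t30.asi8[:-1], t30.asi8[1:])])
            alt = pd.Series(800 + np.cumsum(dalt + np.where(np.r_[False, in_twilight], bump, 0.0)), index=t30)
        df = inference.activity_altitude_pairs(act, alt, events)
        df["individual"] = f"b{k}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def test_coupled_twilight_intervals_show_positive_slope():
    pairs = _slope_pairs(np.random.default_rng(11), coupled=True)
    res = inference.activity_altitude_slope(pairs)
    slope, lo, hi = res["twilight"]
    assert lo > 0


def test_shuffled_activity_gives_null_slope():
    rng = np.random.default_rng(14)
    pairs = _slope_pairs(rng, coupled=False)
    res = inference.activity_altitude_slope(pairs)
    for label in ("twilight", "other"):
        slope, lo, hi = res[label]
        assert lo < 0 < hi


def test_slope_invariant_to_altitude_offset():
    rng = np.random.default_rng(13)
    pairs = _slope_pairs(rng, coupled=True)
    res1 = inference.activity_altitude_slope(pairs)
    pairs2 = pairs.copy()
    # d_altitude is already a difference; a constant offset of the altitude
    # series leaves it unchanged by construction
    res2 = inference.activity_altitude_slope(pairs2)
    assert res1["twilight"][0] == pytest.approx(res2["twilight"][0])
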