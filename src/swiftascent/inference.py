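"""Statistical layer: the autocorrelated binomial ascent model, the
resampled-track model ensemble with its all-confidence-intervals relevance
rule, the signed-rank tests on per-individual median ascent heights, and the
activity–altitude-change slope check.

The ascent model is a binomial (logit) quasi-likelihood fit with an AR(1)
working correlation over each individual's twilight sequence (dawn→dusk and
dusk→dawn are both lag one) and the population entering as a fixed
adjustment — a GEE formulation of the penalized-quasi-likelihood mixed model
the approach descends from.  Confidence intervals are estimate ± 2·SE.

Positional uncertainty is propagated by refitting the model on records
re-derived from independently resampled tracks; a factor is "relevant" only
when zero is excluded from the confidence interval of **every** run of the
ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.genmod.cov_struct import Autoregressive, Independence
from statsmodels.genmod.families import Binomial
from statsmodels.genmod.generalized_estimating_equations import GEE
from statsmodels.regression.mixed_linear_model import MixedLM

from .weather import DegenerateFactorError, z_transform

CONTINUOUS_FACTORS = (
    "flight_alt",
    "t2m",
    "mslp",
    "wind",
    "rh",
    "d24_before_mslp",
    "d24_after_mslp",
    "d24_before_t2m",
    "d24_after_t2m",
    "d24_before_rh",
    "d24_after_rh",
)


class EnsembleFailureError(RuntimeError):
    """More than the tolerated fraction of ensemble runs failed to
    converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Which factors enter the ascent model.

    ``phase`` is treatment-coded against migration (so the non-breeding
    coefficient is the non-breeding-vs-migration log-odds difference) and
    twilight type against dusk.  Continuous factors are z-transformed on
    the dataset being fitted.
    """

    continuous: tuple = CONTINUOUS_FACTORS
    use_phase: bool = True
    use_twilight_type: bool = True
    population_adjustment: bool = True
    correlation: str = "ar1"  # "ar1" | "independence"
    ci_se_multiplier: float = 2.0


@dataclass
class ModelFit:
    estimates: pd.Series
    std_errors: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    ar1: float
    converged: bool
    n_obs: int = 0
    dropped_factors: tuple = ()


@dataclass
class RunEnsemble:
    fits: list = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    relevance: dict = field(default_factory=dict)
    n_failed: int = 0

    def relevant_factors(self):
        return sorted(k for k, v in self.relevance.items() if v)


def build_design(records: pd.DataFrame, spec: ModelSpec = ModelSpec()):
    """Endog/exog/groups/time arrays for the ascent model.

    Degenerate (zero-variance) continuous factors are dropped with a
    warning rather than crashing the fit.
    """
    df = records.reset_index(drop=True)
    y = df["is_ascent"].astype(float).to_numpy()
    cols = {"intercept": np.ones(len(df))}
    dropped = []
    if spec.use_phase:
        for level in ("non-breeding", "breeding"):
            col = (df["phase"] == level).astype(float).to_numpy()
            name = f"phase[{level}]"
            if col.std() == 0:
                dropped.append(name)
            else:
                cols[name] = col
    if spec.use_twilight_type:
        col = (df["kind"] == "dawn").astype(float).to_numpy()
        if col.std() == 0:
            dropped.append("twilight[dawn]")
        else:
            cols["twilight[dawn]"] = col
    if spec.population_adjustment and "population" in df and df["population"].nunique() > 1:
        pops = sorted(df["population"].unique())[1:]
        for p in pops:
            cols[f"population[{p}]"] = (df["population"] == p).astype(float).to_numpy()
    for name in spec.continuous:
        if name not in df:
            continue
        try:
            cols[name] = z_transform(df[name].to_numpy(dtype=float))
        except DegenerateFactorError:
            dropped.append(name)
            warnings.warn(f"factor {name!r} has zero variance; dropped from the model")
    exog = pd.DataFrame(cols)
    groups = df["individual"].to_numpy()
    time = df["seq"].to_numpy() if "seq" in df else df.groupby("individual").cumcount().to_numpy()
    return y, exog, groups, time, tuple(dropped)


def fit_ascent_model(records: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelFit:
    """Binomial GEE with AR(1) within-individual working correlation.

    ``records`` needs columns ``is_ascent``, ``phase``, ``kind``,
    ``individual`` (and optionally ``population``, ``seq`` and the
    continuous covariates named in the spec).  Rows with NaN in any used
    column are dropped.
    """
    y, exog, groups, time, dropped = build_design(records, spec)
    mask = np.isfinite(y) & np.isfinite(exog.to_numpy()).all(axis=1)
    y, exog, groups, time = y[mask], exog[mask], groups[mask], time[mask]
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 individuals to fit the ascent model")

    # quasi-separation guard: a dummy level whose responses are all 0 or
    # all 1 has an infinite coefficient; drop it rather than diverge
    dropped = list(dropped)
    for name in [c for c in exog.columns if c != "intercept"]:
        col = exog[name].to_numpy()
        if set(np.unique(col)) <= {0.0, 1.0}:
            inside = y[col == 1.0]
            if inside.size and (inside.min() == inside.max()):
                warnings.warn(f"factor {name!r} is separated (all responses equal); dropped")
                exog = exog.drop(columns=[name])
                dropped.append(name)
    dropped = tuple(dropped)

    cov = Autoregressive(grid=True) if spec.correlation == "ar1" else Independence()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GEE(y, exog, groups=groups, family=Binomial(), cov_struct=cov)
            res = model.fit(maxiter=100)
        params = pd.Series(res.params, index=exog.columns)
        bse = pd.Series(res.bse, index=exog.columns)
        converged = bool(getattr(res, "converged", True)) and bool(
            np.isfinite(params).all() and np.isfinite(bse).all()
        )
    except Exception:  # non-convergence / separation: flagged, not fatal
        params = pd.Series(np.nan, index=exog.columns)
        bse = pd.Series(np.nan, index=exog.columns)
        converged = False

    m = spec.ci_se_multiplier
    ar1 = float(np.atleast_1d(cov.dep_params)[0]) if spec.correlation == "ar1" and converged else 0.0
    return ModelFit(
        estimates=params,
        std_errors=bse,
        ci_lower=params - m * bse,
        ci_upper=params + m * bse,
        ar1=ar1,
        converged=converged,
        n_obs=int(mask.sum()),
        dropped_factors=dropped,
    )


def run_ensemble(
    make_records,
    n_runs: int = 100,
    seed: int = 0,
    spec: ModelSpec = ModelSpec(),
    max_failed_fraction: float = 0.2,
) -> RunEnsemble:
    """Fit the ascent model on ``n_runs`` independently resampled datasets.

    ``make_records(run_seed)`` must return the record table for one track
    realisation (the caller redraws tracks, phase labels and weather
    annotations).  A factor is flagged relevant only when zero lies outside
    the ±2·SE interval of every converged run; more than
    ``max_failed_fraction`` non-converged runs aborts the ensemble.
    Deterministic given ``seed``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    fits, rows = [], []
    for run, s in enumerate(child_seeds):
        fit = fit_ascent_model(make_records(int(s)), spec)
        fits.append(fit)
        if not fit.converged:
            continue
        for name in fit.estimates.index:
            rows.append(
                {"factor": name, "run": run, "estimate": fit.estimates[name],
                 "se": fit.std_errors[name], "ci_lower": fit.ci_lower[name],
                 "ci_upper": fit.ci_upper[name]}
            )
    n_failed = sum(not f.converged for f in fits)
    if n_failed > max_failed_fraction * n_runs:
        raise EnsembleFailureError(f"{n_failed}/{n_runs} ensemble runs failed to converge")
    table = pd.DataFrame(rows)
    n_converged = sum(f.converged for f in fits)
    relevance = {}
    for name, grp in table.groupby("factor"):
        if name.startswith(("intercept", "population[")):
            continue
        # a factor dropped from any run (degenerate or separated there)
        # cannot satisfy the every-interval rule
        relevance[name] = bool(
            len(grp) == n_converged
            and ((grp["ci_lower"] > 0) | (grp["ci_upper"] < 0)).all()
        )
    return RunEnsemble(fits=fits, table=table, relevance=relevance, n_failed=n_failed)


def wilcoxon_median_ascent(medians, *, min_individuals: int = 5, exact_max_n: int = 25):
    """One-sided Wilcoxon signed-rank test that per-individual median ascent
    heights exceed zero.

    Returns ``(V, p)`` with V the sum of positive-signed ranks.  Zeros are
    dropped (the standard convention); the p-value is exact for n ≤ 25 and
    a normal approximation above.
    """
    x = np.asarray(medians, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("missing median ascent heights")
    if x.size < min_individuals:
        raise ValueError(f"need at least {min_individuals} individuals")
    nz = x[x != 0]
    if nz.size == 0:
        return 0.0, 1.0
    method = "exact" if nz.size <= exact_max_n else "approx"
    res = stats.wilcoxon(nz, alternative="greater", zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def activity_altitude_pairs(activity: pd.Series, altitudes: pd.Series, event_times) -> pd.DataFrame:
    """Pair every 30-min altitude change with the mean activity over the
    same interval and mark intervals containing a twilight event."""
    alt = altitudes.dropna()
    if len(alt) < 2:
        raise ValueError("need at least two altitude samples")
    d_alt = alt.diff().iloc[1:]
    starts = alt.index[:-1]
    ends = alt.index[1:]
    act_mean = (
        activity.reindex(pd.date_range(alt.index[0], alt.index[-1], freq="5min"))
        .rolling(6, min_periods=1).mean()
        .reindex(ends)
        .to_numpy()
    )
    ev = pd.DatetimeIndex(event_times).asi8
    s8, e8 = starts.asi8, ends.asi8
    has_twilight = np.array([((ev > s) & (ev <= e)).any() for s, e in zip(s8, e8)])
    return pd.DataFrame(
        {"interval_end": ends, "d_altitude": d_alt.to_numpy(), "activity": act_mean,
         "twilight": has_twilight}
    )


def activity_altitude_slope(pairs: pd.DataFrame, *, ci_se_multiplier: float = 2.0) -> dict:
    """Standardised slope of 30-min altitude change on mean activity, fitted
    separately for twilight-containing intervals and all others, with an
    individual random intercept when an ``individual`` column is present.

    Returns ``{"twilight": (slope, lo, hi), "other": (slope, lo, hi)}``.
    """
    out = {}
    for label, sel in (("twilight", pairs["twilight"]), ("other", ~pairs["twilight"])):
        sub = pairs[sel].dropna(subset=["d_altitude", "activity"])
        if len(sub) < 10:
            raise ValueError(f"insufficient pairs for {label} intervals")
        y = z_transform(sub["d_altitude"].to_numpy())
        x = z_transform(sub["activity"].to_numpy())
        exog = np.column_stack([np.ones(len(x)), x])
        if "individual" in sub and sub["individual"].nunique() > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(y, exog, groups=sub["individual"].to_numpy()).fit()
            slope, se = float(res.params[1]), float(res.bse[1])
        else:
            res = stats.linregress(x, y)
            slope, se = float(res.slope), float(res.stderr)
        out[label] = (slope, slope - ci_se_multiplier * se, slope + ci_se_multiplier * se)
    return out
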