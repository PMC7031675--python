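"""Regression models linking wind to flight performance and direction.

The speed models regress per-segment ground (or air) speed on wind
support, crosswind and their interaction, with a per-track random
intercept; segments within a track are serially correlated, which is
summarized by a residual MA(1) coefficient estimated from the
within-track lag-1 residual autocorrelation.  Fitting maximizes the
full likelihood (not REML) so AIC is comparable across models that
share a response, which is what the seven-way flight-altitude
comparison needs.  When the mixed fit fails to converge the model
degrades to ordinary least squares with cluster-robust (by track)
standard errors, and the fit records which estimator ran.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "SpeedModelFit",
    "TrackLengthFit",
    "DirectionFits",
    "fit_speed_model",
    "select_flight_altitude",
    "mean_first_half_ws",
    "fit_track_length_model",
    "fit_direction_models",
]


@dataclass
class SpeedModelFit:
    level: str
    response: str  # "ground" or "air"
    coefficients: dict  # intercept, wind_support, crosswind, interaction
    stderrs: dict
    random_intercept_var: float
    ma1_coef: float
    aic: float
    llf: float
    n_segments: int
    n_tracks: int
    track_ids: frozenset
    estimator: str  # "mixed" or "ols-cluster"


def _ma1_from_residuals(resid: np.ndarray, groups: np.ndarray) -> float:
    """MA(1) coefficient implied by the pooled within-group lag-1
    autocorrelation rho, via rho = theta / (1 + theta**2)."""
    num = den = 0.0
    for g in np.unique(groups):
        r = resid[groups == g]
        if len(r) < 3:
            continue
        r = r - r.mean()
        num += float(np.sum(r[:-1] * r[1:]))
        den += float(np.sum(r * r))
    if den == 0:
        return 0.0
    rho = np.clip(num / den, -0.499, 0.499)
    if rho == 0:
        return 0.0
    return float((1.0 - np.sqrt(1.0 - 4.0 * rho**2)) / (2.0 * rho))


def fit_speed_model(
    segments: pd.DataFrame,
    level: str,
    response: str = "ground",
    interaction: bool = True,
    estimator: str = "mixed",
) -> SpeedModelFit:
    """Fit speed ~ wind_support + crosswind (+ interaction) with a
    per-track random intercept.

    ``segments`` must be an annotation table at the stated level (one
    level only) covering at least two tracks.  ``response`` selects
    ground or air speed.
    """
    seg_levels = set(segments["level"].unique())
    if seg_levels != {level}:
        raise ValueError(f"segments annotated at {sorted(seg_levels)}, expected {level!r}")
    groups = segments["track_id"].to_numpy()
    track_ids = frozenset(np.unique(groups))
    if len(track_ids) < 2:
        raise ValueError("random intercept unidentifiable with a single track")
    y = segments["ground_speed" if response == "ground" else "air_speed"].to_numpy(float)
    if response not in {"ground", "air"}:
        raise ValueError(f"unknown response {response!r}")

    cols = {"wind_support": segments["wind_support"].to_numpy(float),
            "crosswind": segments["crosswind"].to_numpy(float)}
    if interaction:
        cols["interaction"] = cols["wind_support"] * cols["crosswind"]
    X = pd.DataFrame(cols)
    for name in X.columns:
        if np.std(X[name].to_numpy()) < 1e-12:
            raise ValueError(f"collinear/constant term: {name}")
    exog = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax()
        raise ValueError(f"rank-deficient design; collinear term: {worst}")

    used = estimator
    result = None
    if estimator == "mixed":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=groups)
                result = model.fit(reml=False, method="lbfgs")
            if not result.converged or not np.isfinite(result.llf):
                result = None
        except (np.linalg.LinAlgError, ValueError):
            result = None
        if result is None:
            used = "ols-cluster"
    elif estimator != "ols-cluster":
        raise ValueError(f"unknown estimator {estimator!r}")

    if used == "ols-cluster" or result is None:
        used = "ols-cluster"
        result = sm.OLS(y, exog).fit(cov_type="cluster", cov_kwds={"groups": groups})
        re_var = 0.0
        llf = float(result.llf)
        k = exog.shape[1] + 1  # + residual variance
        aic = -2.0 * llf + 2.0 * k
        params = result.params
        bse = result.bse
        resid = result.resid
    else:
        re_var = float(result.cov_re.iloc[0, 0])
        llf = float(result.llf)
        k = exog.shape[1] + 2  # + random-intercept and residual variances
        aic = -2.0 * llf + 2.0 * k
        params = result.params[: exog.shape[1]]
        bse = result.bse[: exog.shape[1]]
        resid = np.asarray(result.resid)

    names = list(exog.columns)
    coef = {("intercept" if n == "const" else n): float(p) for n, p in zip(names, params)}
    errs = {("intercept" if n == "const" else n): float(b) for n, b in zip(names, bse)}
    return SpeedModelFit(
        level=level,
        response=response,
        coefficients=coef,
        stderrs=errs,
        random_intercept_var=re_var,
        ma1_coef=_ma1_from_residuals(np.asarray(resid, float), groups),
        aic=float(aic),
        llf=llf,
        n_segments=len(segments),
        n_tracks=len(track_ids),
        track_ids=track_ids,
        estimator=used,
    )


def select_flight_altitude(fits: list[SpeedModelFit]) -> tuple[str, pd.DataFrame]:
    """Pick the altitude whose wind best explains the observed speeds.

    Expects seven fits (six fixed levels plus the hourly max-support
    profile) on identical track sets and segment counts.  Returns the
    argmin-AIC level (ties to the lower altitude, fixed levels before
    the max-support profile) and a dAIC table.
    """
    if len(fits) != 7:
        raise ValueError(f"expected 7 fits (6 fixed levels + maxWs), got {len(fits)}")
    ref = fits[0]
    for f in fits[1:]:
        if f.track_ids != ref.track_ids or f.n_segments != ref.n_segments:
            raise ValueError("fits were made on non-identical track/segment sets")

    def sort_key(f: SpeedModelFit):
        if f.level == "maxWs":
            return (1, 0.0)
        return (0, float(f.level.rstrip("m")))

    ordered = sorted(fits, key=sort_key)
    aics = np.array([f.aic for f in ordered])
    best = int(np.argmin(aics))  # first minimum -> lower altitude on tie
    table = pd.DataFrame(
        {
            "level": [f.level for f in ordered],
            "aic": aics,
            "delta_aic": aics - aics.min(),
            "estimator": [f.estimator for f in ordered],
        }
    )
    return ordered[best].level, table


def mean_first_half_ws(segments: pd.DataFrame) -> pd.Series:
    """Per-track mean wind support over the first half of the track length.

    A segment counts toward the first half if it starts before the
    halfway point of the cumulative track length.
    """
    out = {}
    for tid, g in segments.groupby("track_id"):
        cum = g["cum_length_km"].to_numpy(float)
        seg_len = np.diff(np.concatenate([[0.0], cum]))
        prev_cum = cum - seg_len
        half = cum[-1] / 2.0
        sel = prev_cum < half
        out[tid] = float(g["wind_support"].to_numpy(float)[sel].mean())
    return pd.Series(out, name="mean_first_half_ws")


@dataclass
class TrackLengthFit:
    """Linear model: track length (km) on mean first-half wind support,
    with a separate intercept per flight class."""

    slope: float  # km per (m/s of wind support)
    slope_se: float
    intercepts: dict  # per flight class, km
    n_tracks: int
    classes: list
    dropped_classes: list = field(default_factory=list)
    result: object = None


def fit_track_length_model(data: pd.DataFrame) -> TrackLengthFit:
    """Fit track_length_km ~ mean_first_half_ws + C(flight_class).

    ``data`` has one row per track with columns ``track_length_km``,
    ``mean_first_half_ws`` and ``flight_class``.  Classes with fewer
    than three tracks are dropped with a warning (the class intercept
    would be near-unidentified).
    """
    counts = data["flight_class"].value_counts()
    dropped = [c for c in counts.index if counts[c] < 3]
    if dropped:
        warnings.warn(f"dropping flight classes with <3 tracks: {dropped}", stacklevel=2)
        data = data[~data["flight_class"].isin(dropped)]
    if len(data) < 3:
        raise ValueError("need at least 3 tracks after class filtering")
    classes = sorted(data["flight_class"].unique())
    if len(classes) > 1:
        res = smf.ols(
            "track_length_km ~ mean_first_half_ws + C(flight_class)", data=data
        ).fit()
        base = float(res.params["Intercept"])
        intercepts = {classes[0]: base}
        for c in classes[1:]:
            intercepts[c] = base + float(res.params[f"C(flight_class)[T.{c}]"])
    else:
        res = smf.ols("track_length_km ~ mean_first_half_ws", data=data).fit()
        intercepts = {classes[0]: float(res.params["Intercept"])}
    return TrackLengthFit(
        slope=float(res.params["mean_first_half_ws"]),
        slope_se=float(res.bse["mean_first_half_ws"]),
        intercepts=intercepts,
        n_tracks=len(data),
        classes=classes,
        dropped_classes=dropped,
        result=res,
    )


def _wrap_deg(x):
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)


def _circular_mean_deg(angles) -> float:
    rad = np.radians(np.asarray(angles, float))
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)


def circular_correlation(a, b) -> float:
    """Jammalamadaka-Sarma circular correlation between two angle samples."""
    a = np.radians(np.asarray(a, float) - _circular_mean_deg(a))
    b = np.radians(np.asarray(b, float) - _circular_mean_deg(b))
    den = np.sqrt(np.sum(np.sin(a) ** 2) * np.sum(np.sin(b) ** 2))
    if den == 0:
        return float("nan")
    return float(np.sum(np.sin(a) * np.sin(b)) / den)


@dataclass
class DirectionFit:
    params: dict
    stderrs: dict
    circular_corr: float
    n_tracks: int
    estimator: str


@dataclass
class DirectionFits:
    initial_vs_wind: DirectionFit
    final_vs_initial: DirectionFit


def _night_centred(df: pd.DataFrame, col: str) -> np.ndarray:
    """Deviation (deg, wrapped) of an angle column from its night's circular mean."""
    centred = np.empty(len(df))
    for night, g in df.groupby("night"):
        m = _circular_mean_deg(g[col])
        centred[df.index.get_indexer(g.index)] = _wrap_deg(g[col].to_numpy(float) - m)
    return centred


def _mixed_or_ols(formula: str, data: pd.DataFrame, groups: str):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data, groups=data[groups]).fit(method="lbfgs")
        if res.converged and np.isfinite(res.llf):
            return res, "mixed"
    except (np.linalg.LinAlgError, ValueError):
        pass
    return smf.ols(formula, data).fit(), "ols"


def fit_direction_models(data: pd.DataFrame) -> DirectionFits:
    """Direction models: wind -> initial direction, initial -> final.

    ``data`` has one row per track with columns ``initial_direction``,
    ``final_direction``, ``wind_direction_to`` and ``wind_speed`` (mean
    over the first 50 km) and ``night`` (departure night, the random
    intercept group).  Angles are unwrapped to deviations from each
    night's circular mean before linear fitting; a circular correlation
    is reported alongside as a model-free diagnostic.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 tracks for the direction models")
    for col in ("initial_direction", "final_direction", "wind_direction_to"):
        if np.std(_wrap_deg(data[col] - data[col].iloc[0])) < 1e-9:
            raise ValueError(f"degenerate input: {col} identical for all tracks")
    df = data.reset_index(drop=True).copy()
    df["init_dev"] = _night_centred(df, "initial_direction")
    df["final_dev"] = _night_centred(df, "final_direction")
    df["wind_dev"] = _night_centred(df, "wind_direction_to")

    res1, est1 = _mixed_or_ols("init_dev ~ wind_dev * wind_speed", df, "night")
    fit1 = DirectionFit(
        params={k: float(v) for k, v in res1.params.items() if k != "Group Var"},
        stderrs={k: float(v) for k, v in res1.bse.items() if k != "Group Var"},
        circular_corr=circular_correlation(df["initial_direction"], df["wind_direction_to"]),
        n_tracks=len(df),
        estimator=est1,
    )
    res2, est2 = _mixed_or_ols("final_dev ~ init_dev", df, "night")
    fit2 = DirectionFit(
        params={k: float(v) for k, v in res2.params.items() if k != "Group Var"},
        stderrs={k: float(v) for k, v in res2.bse.items() if k != "Group Var"},
        circular_corr=circular_correlation(df["final_direction"], df["initial_direction"]),
        n_tracks=len(df),
        estimator=est2,
    )
    return DirectionFits(initial_vs_wind=fit1, final_vs_initial=fit2)
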