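"""Prognostic Cox models with centroid-distance expression features.

The expression subtype enters survival models not as a categorical label
but as three continuous features: the Euclidean distance of each sample's
signature-gene vector to each subtype centroid.  Nine model variants
combine tumor stage, driver mutations/fusions, histologic grade and the
centroid distances; each is fitted by Cox partial likelihood (Efron tie
handling) on a training cohort, its coefficients are applied unchanged to
a test cohort, and both cohorts are scored by Harrell's concordance index.
Likelihood-ratio tests quantify what the expression subtype adds on top of
each single-modality model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy.stats import chi2

from .containers import ExpressionMatrix, validate_survival_table
from .signature import CentroidSignature, classify_nearest_centroid

__all__ = [
    "RiskModelFit",
    "MODEL_REGISTRY",
    "centroid_distance_features",
    "fit_cox",
    "concordance_index",
    "likelihood_ratio_test",
    "run_model_registry",
    "kaplan_meier",
    "truncate_follow_up",
]

DISTANCE_PREFIX = "dist_"

# the nine named covariate sets; "expression" expands to the centroid
# distances, "mutations" to the four driver flags
MODEL_REGISTRY: dict[str, dict] = {
    "A": {"name": "Stage", "groups": ["stage"]},
    "B": {"name": "Mutations", "groups": ["mutations"]},
    "C": {"name": "Expression subtype", "groups": ["expression"]},
    "D": {"name": "Grade", "groups": ["grade"]},
    "E": {"name": "Stage + mutations", "groups": ["stage", "mutations"]},
    "F": {"name": "Expression + stage", "groups": ["expression", "stage"]},
    "G": {"name": "Expression + mutations",
          "groups": ["expression", "mutations"]},
    "H": {"name": "Expression + grade", "groups": ["expression", "grade"]},
    "I": {"name": "Expression + stage + mutations",
          "groups": ["expression", "stage", "mutations"]},
}

GROUP_COLUMNS = {
    "stage": ["stage"],
    "mutations": ["tp53", "egfr", "kras", "alk_fusion"],
    "grade": ["grade"],
}

# nested single-modality model used for the LRT "what does expression add"
NESTED_MODEL = {"F": "A", "G": "B", "H": "D", "I": "E"}


@dataclass
class RiskModelFit:
    coefficients: pd.DataFrame        # coef, se, p per covariate
    log_likelihood: float
    train_cindex: float
    risk_scores: pd.Series            # linear predictor on training samples
    test_cindex: float = float("nan")
    converged: bool = True
    penalizer: float = 0.0
    fitter: CoxPHFitter = field(default=None, repr=False)  # type: ignore


def centroid_distance_features(sig: CentroidSignature,
                               expr: ExpressionMatrix) -> pd.DataFrame:
    """Euclidean distance of each sample to each class centroid.

    Columns are ``dist_<class>`` in the signature's class order; consistent
    with :func:`classify_nearest_centroid` (a sample's nearest-centroid
    label is the argmin column).
    """
    res = classify_nearest_centroid(sig, expr)
    return res.drop(columns="label")


def fit_cox(data: pd.DataFrame, features: list[str],
            ridge_fallback: float = 1e-4) -> RiskModelFit:
    """Cox proportional-hazards fit (Efron ties) on the named features.

    On non-convergence (e.g. monotone likelihood from perfect separation)
    the fit is retried once with a small L2 penalty and flagged via
    ``converged=False`` / ``penalizer``.
    """
    validate_survival_table(data, required=("time", "event"))
    missing = [f for f in features if f not in data.columns]
    if missing:
        raise ValueError(f"survival table lacks features: {missing}")
    if data["event"].sum() < 1:
        raise ValueError("no events in the data; Cox model undefined")
    sub = data[["time", "event", *features]].astype(float)
    if sub[features].isna().any().any():
        raise ValueError("missing values in model features")
    penalizer = 0.0
    converged = True
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col="time", event_col="event")
    except ConvergenceError:
        penalizer = ridge_fallback
        converged = False
        cph = CoxPHFitter(penalizer=penalizer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col="time", event_col="event")
    coefs = cph.summary[["coef", "se(coef)", "p"]].rename(
        columns={"se(coef)": "se"})
    risk = pd.Series(cph.predict_log_partial_hazard(sub).to_numpy().ravel(),
                     index=sub.index, name="risk")
    cidx = concordance_index(risk, sub["time"], sub["event"])
    return RiskModelFit(coefficients=coefs,
                        log_likelihood=float(cph.log_likelihood_),
                        train_cindex=cidx, risk_scores=risk,
                        converged=converged, penalizer=penalizer,
                        fitter=cph)


def predict_risk(fit: RiskModelFit, data: pd.DataFrame) -> pd.Series:
    """Linear predictor on new data using the trained coefficients."""
    feats = list(fit.coefficients.index)
    missing = [f for f in feats if f not in data.columns]
    if missing:
        raise ValueError(f"test data lacks features: {missing}")
    lp = data[feats].astype(float).to_numpy() @ \
        fit.coefficients["coef"].to_numpy()
    return pd.Series(lp, index=data.index, name="risk")


def concordance_index(risk, time, event) -> float:
    """Harrell's c-index for a risk score (higher risk = earlier failure).

    Pairs are comparable when the earlier time is an observed event; ties
    in the risk score count one half.  NaN when no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    try:
        # lifelines scores "higher predicted value = longer survival"
        return float(_lifelines_cindex(time, -risk, event))
    except ZeroDivisionError:
        return float("nan")


def likelihood_ratio_test(fit_full: RiskModelFit,
                          fit_nested: RiskModelFit) -> tuple[float, float]:
    """LRT statistic and p-value for the full vs nested Cox model."""
    df = len(fit_full.coefficients) - len(fit_nested.coefficients)
    if df <= 0:
        raise ValueError("full model must have more covariates than nested")
    stat = 2.0 * (fit_full.log_likelihood - fit_nested.log_likelihood)
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def _model_columns(groups: list[str], classes) -> list[str]:
    cols: list[str] = []
    for g in groups:
        if g == "expression":
            cols.extend(f"{DISTANCE_PREFIX}{c}" for c in classes)
        else:
            cols.extend(GROUP_COLUMNS[g])
    return cols


def run_model_registry(train: pd.DataFrame, test: pd.DataFrame,
                       sig: CentroidSignature,
                       train_expr: ExpressionMatrix,
                       test_expr: ExpressionMatrix,
                       models: list[str] | None = None) -> pd.DataFrame:
    """Train models A-I on ``train``, transfer coefficients to ``test``.

    ``train`` / ``test`` are survival tables (time, event plus whatever
    covariates the requested models need); centroid-distance features are
    computed here from the signature and the expression matrices.  Models
    whose covariates are absent from the training table are skipped with a
    reason; models whose extra covariates are missing only in the test
    table (e.g. histologic grade) are trained and evaluated on the
    training cohort alone.  For models that add the expression distances
    to a single-modality model the likelihood-ratio p-value against that
    nested model is reported (for model C, against the null model).
    """
    if models is None:
        models = list(MODEL_REGISTRY)
    train = train.copy()
    test = test.copy()
    for df, expr in ((train, train_expr), (test, test_expr)):
        dists = centroid_distance_features(sig, expr)
        for col in dists.columns:
            df[col] = dists[col].reindex(df.index)

    fits: dict[str, RiskModelFit] = {}
    rows = []
    for mid in models:
        spec = MODEL_REGISTRY[mid]
        cols = _model_columns(spec["groups"], sig.classes)
        missing_train = [c for c in cols if c not in train.columns
                         or train[c].isna().any()]
        if missing_train:
            rows.append({"model": mid, "name": spec["name"],
                         "train_cindex": np.nan, "test_cindex": np.nan,
                         "lrt_p": np.nan,
                         "status": f"skipped: train lacks {missing_train}"})
            continue
        fit = fit_cox(train, cols)
        fits[mid] = fit
        missing_test = [c for c in cols if c not in test.columns
                        or test[c].isna().any()]
        if missing_test:
            test_c = np.nan
            status = f"train only: test lacks {missing_test}"
        else:
            risk_te = predict_risk(fit, test)
            test_c = concordance_index(risk_te, test["time"], test["event"])
            status = "ok"
        fit.test_cindex = test_c
        lrt_p = np.nan
        if mid == "C":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lrt_p = float(fit.fitter.log_likelihood_ratio_test().p_value)
        elif mid in NESTED_MODEL and NESTED_MODEL[mid] in fits:
            _, lrt_p = likelihood_ratio_test(fit, fits[NESTED_MODEL[mid]])
        rows.append({"model": mid, "name": spec["name"],
                     "train_cindex": fit.train_cindex,
                     "test_cindex": test_c, "lrt_p": lrt_p,
                     "status": status})
    return pd.DataFrame(rows).set_index("model")


def kaplan_meier(data: pd.DataFrame, groups) -> pd.DataFrame:
    """Product-limit survival curves per group, as step coordinates.

    Returns a long DataFrame with columns group, time, survival; each
    curve starts at (0, 1) and is non-increasing and right-continuous.
    """
    validate_survival_table(data, required=("time", "event"))
    g = pd.Series(groups, index=data.index if not isinstance(groups, pd.Series)
                  else groups.index).reindex(data.index)
    frames = []
    for name, idx in g.groupby(g).groups.items():
        km = KaplanMeierFitter()
        km.fit(data.loc[idx, "time"], data.loc[idx, "event"])
        sf = km.survival_function_
        frames.append(pd.DataFrame({
            "group": name,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float)}))
    return pd.concat(frames, ignore_index=True)


def truncate_follow_up(data: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative censoring at ``horizon`` (months).

    Samples followed beyond the horizon are censored there; a horizon at
    or beyond the last observed time changes nothing.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = data.copy()
    late = out["time"] > horizon
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out
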