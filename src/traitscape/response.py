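"""Linear models of functional structure against current and past landscapes.

Each response (species richness always; CWV of non-random traits; CWM of
convergent traits) is regressed on the landscape predictors measured at each
of the three map years — one full OLS model per year, never a pooled model,
because the same predictor at different years is strongly collinear. Plant
groups use four predictors (the two heterogeneity components plus their own
habitat's amount and isolation); birds, sampled across the whole window, use
all six. The best year is then chosen by small-sample-corrected Akaike
information criterion: every year within ΔAICc < 2 of the minimum *and* with
normal residuals (Shapiro-Wilk p >= 0.05) is selected. A delayed (lagged)
response shows up as a past year being selected over the current one.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .landscape import PREDICTOR_NAMES
from .nullmodels import NullAnalysisResult, significance_stars

#: predictor subset per species group
GROUP_PREDICTORS: dict[str, tuple[str, ...]] = {
    "hedgerow_plants": (
        "compositional_heterogeneity",
        "configurational_heterogeneity",
        "hedgerow_amount",
        "hedgerow_isolation",
    ),
    "grassland_plants": (
        "compositional_heterogeneity",
        "configurational_heterogeneity",
        "grassland_amount",
        "grassland_isolation",
    ),
    "birds": PREDICTOR_NAMES,
}


@dataclasses.dataclass
class ModelFit:
    """One OLS fit of a response on one year's predictors."""

    response: str
    group: str
    year: str
    n: int
    coefficients: pd.Series  # includes "intercept"
    p_values: pd.Series
    r_squared: float
    aic: float
    aicc: float
    shapiro_p: float


def fit_year_model(
    response: pd.Series,
    predictors: pd.DataFrame,
    year: str,
    group: str = "group",
    response_name: str = "response",
) -> ModelFit:
    """Ordinary least squares of one response on one year's predictors.

    Complete cases only (windows with a missing predictor — absent habitat —
    are dropped listwise). AICc = AIC + 2k(k+1)/(n-k-1) with k counting all
    coefficients including the intercept. Raises on a singular design,
    naming a perfectly collinear predictor pair when one exists.
    """
    df = pd.concat([response.rename("_y"), predictors], axis=1, join="inner").dropna()
    k = predictors.shape[1] + 1
    if len(df) < k + 3:
        raise ValueError(
            f"{response_name}/{year}: need >= {k + 3} complete windows, have {len(df)}"
        )
    x = sm.add_constant(df[predictors.columns], has_constant="add")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        for a, b in itertools.combinations(predictors.columns, 2):
            r = np.corrcoef(df[a], df[b])[0, 1]
            if not np.isfinite(r) or abs(r) > 1 - 1e-12:
                raise ValueError(
                    f"singular design for {response_name}/{year}: "
                    f"{a!r} and {b!r} are collinear"
                )
        raise ValueError(f"singular design for {response_name}/{year}")
    fit = sm.OLS(df["_y"], x).fit()
    n = int(fit.nobs)
    aicc = fit.aic + 2 * k * (k + 1) / (n - k - 1)
    coefs = fit.params.rename(index={"const": "intercept"})
    pvals = fit.pvalues.rename(index={"const": "intercept"})
    return ModelFit(
        response=response_name,
        group=group,
        year=year,
        n=n,
        coefficients=coefs,
        p_values=pvals,
        r_squared=float(fit.rsquared),
        aic=float(fit.aic),
        aicc=float(aicc),
        shapiro_p=float(stats.shapiro(fit.resid).pvalue),
    )


@dataclasses.dataclass
class ModelSelection:
    """AICc comparison of one response's fits across years."""

    response: str
    fits: list[ModelFit]
    delta_aicc: dict[str, float]
    selected_years: list[str]


def select_best_year(
    fits: Sequence[ModelFit],
    delta_threshold: float = 2.0,
    normality_alpha: float = 0.05,
) -> ModelSelection:
    """Select the year(s) whose model best explains the response.

    All fits within ``delta_threshold`` AICc of the minimum are candidates;
    a candidate is selected only if its residuals pass the Shapiro-Wilk
    normality gate (a low-AICc model with non-normal residuals is reported
    but not selected).
    """
    if not fits:
        raise ValueError("no successful fits to select among")
    best = min(f.aicc for f in fits)
    delta = {f.year: f.aicc - best for f in fits}
    selected = [
        f.year
        for f in fits
        if delta[f.year] < delta_threshold and f.shapiro_p >= normality_alpha
    ]
    return ModelSelection(fits[0].response, list(fits), delta, selected)


# ---------------------------------------------------------------------------
# whole-stage driver


def _gated_traits(null_result) -> tuple[list[str], list[str]]:
    """CWV / CWM trait lists from a NullAnalysisResult or a bare gating table."""
    if hasattr(null_result, "gating"):
        return null_result.cwv_traits(), null_result.cwm_traits()
    g = null_result  # a gating DataFrame as written by the null-model stage
    return (
        list(g.loc[g["model_cwv"], "trait"]),
        list(g.loc[g["model_cwm"], "trait"]),
    )


def _responses_for_group(
    indices: pd.DataFrame, null_result
) -> dict[str, pd.Series]:
    """Response vectors: richness, gated CWVs, gated CWMs (occurrence mode)."""
    occ = indices[indices["mode"] == "occurrence_rate"]
    responses: dict[str, pd.Series] = {}
    richness = occ.drop_duplicates("window").set_index("window")["richness"]
    responses["richness"] = richness.astype(float)
    cwv_traits, cwm_traits = _gated_traits(null_result)
    for trait in cwv_traits:
        sub = occ[occ["trait"] == trait].set_index("window")
        responses[f"cwv_{trait}"] = sub["cwv"]
    for trait in cwm_traits:
        sub = occ[occ["trait"] == trait].set_index("window")
        responses[f"cwm_{trait}"] = sub["cwm"]
    return responses


def run_response_stage(
    indices_by_group: Mapping[str, pd.DataFrame],
    null_results: Mapping[str, NullAnalysisResult],
    landscape_vars: pd.DataFrame,
    years: Sequence[str],
    delta_threshold: float = 2.0,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every gated response at every year for every group.

    Returns a long table with one row per (group, response, year, term),
    where ``term`` is a predictor, "intercept", or one of the model-level
    rows (aicc, delta_aicc, r_squared, shapiro_p, n, selected). Predictor
    rows carry significance stars; this is the long-format source from which
    wide per-group tables are rendered.
    """
    rows = []
    for group, indices in indices_by_group.items():
        predictors = list(GROUP_PREDICTORS[group])
        responses = _responses_for_group(indices, null_results[group])
        for name, y in responses.items():
            fits = []
            for year in years:
                pred = (
                    landscape_vars[landscape_vars["year"] == year]
                    .set_index("window")[predictors]
                )
                try:
                    fits.append(
                        fit_year_model(y, pred, year, group=group, response_name=name)
                    )
                except ValueError:
                    continue
            if not fits:
                rows.append(
                    {
                        "group": group,
                        "response": name,
                        "year": "",
                        "term": "unmodelled",
                        "value": np.nan,
                        "p_value": np.nan,
                        "stars": "",
                        "selected": False,
                    }
                )
                continue
            sel = select_best_year(fits, delta_threshold, normality_alpha)
            for f in sel.fits:
                chosen = f.year in sel.selected_years
                model_rows = {
                    "aicc": f.aicc,
                    "delta_aicc": sel.delta_aicc[f.year],
                    "intercept": float(f.coefficients["intercept"]),
                    "r_squared": f.r_squared,
                    "shapiro_p": f.shapiro_p,
                    "n": float(f.n),
                }
                for term, value in model_rows.items():
                    rows.append(
                        {
                            "group": group,
                            "response": name,
                            "year": f.year,
                            "term": term,
                            "value": value,
                            "p_value": np.nan,
                            "stars": "",
                            "selected": chosen,
                        }
                    )
                for term in predictors:
                    p = float(f.p_values[term])
                    rows.append(
                        {
                            "group": group,
                            "response": name,
                            "year": f.year,
                            "term": term,
                            "value": float(f.coefficients[term]),
                            "p_value": p,
                            "stars": significance_stars(p),
                            "selected": chosen,
                        }
                    )
    return pd.DataFrame(rows)


def render_group_table(results: pd.DataFrame, group: str) -> pd.DataFrame:
    """Wide table for one group: rows = year x term, columns = responses.

    Predictor estimates print with their stars; entries that are not
    significant print as "–", mirroring the study's reporting convention.
    Model-level rows (AICc, intercept, R², Shapiro p) print for every fitted
    year; selected models are flagged in a dedicated row.
    """
    sub = results[results["group"] == group]
    order_terms = [
        "aicc",
        "delta_aicc",
        "intercept",
        "r_squared",
        "shapiro_p",
        "n",
        "selected",
    ] + list(GROUP_PREDICTORS[group])
    responses = list(dict.fromkeys(sub["response"]))
    years = list(dict.fromkeys(sub["year"]))
    out = {}
    for resp in responses:
        col = {}
        rsub = sub[sub["response"] == resp]
        for year in years:
            ysub = rsub[rsub["year"] == year].set_index("term")
            if ysub.empty:
                continue
            for term in order_terms:
                key = (year, term)
                if term == "selected":
                    col[key] = "yes" if ysub["selected"].any() else ""
                elif term in ysub.index:
                    row = ysub.loc[term]
                    if term in GROUP_PREDICTORS[group]:
                        if np.isfinite(row["p_value"]) and row["p_value"] < 0.05:
                            col[key] = f"{row['value']:.3g}{row['stars']}"
                        else:
                            col[key] = "–"
                    else:
                        col[key] = f"{row['value']:.3g}"
                else:
                    col[key] = "–"
        out[resp] = col
    table = pd.DataFrame(out)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["year", "term"])
    return table
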