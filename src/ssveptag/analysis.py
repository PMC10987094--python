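"""Statistical battery: condition effects on behaviour, SSVEP, mu-beta
and alpha, with task-exposure binning.

All models are trial-level with a per-subject intercept and no other
random effects. Identity-link models are linear mixed models (REML,
random subject intercept); fixed effects are tested with Wald F using
residual denominator degrees of freedom (labelled ``df_method``, the
documented fallback when the engine provides no Satterthwaite
approximation). Binary responses use a logistic model with per-subject
fixed intercepts and Wald chi-square tests. Pairwise condition
contrasts are uncorrected.

Inclusion rules: behaviour and evidence-locked SSVEP models keep trials
with RT > 100 ms; the SSVEP-to-behaviour models keep RT > 680 ms (the
measurement window must precede the response); pre-evidence mu-beta and
alpha models keep all trials. Pulse type and target tag frequency enter
the behaviour and evidence-locked SSVEP models as control fixed
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
import yaml


# ---------------------------------------------------------------------------
# task-exposure binning

def bin_task_exposure(df: pd.DataFrame, n_bins: int = 5,
                      order_col: str = "trial_order",
                      subject_col: str = "subject_id") -> pd.Series:
    """Equal-count (±1) chronological quintiles per subject, labels 1..n.

    Remainder trials go to the earliest bins, so bin sizes are
    non-increasing and ordering is preserved (every trial in bin k
    precedes every trial in bin k+1).
    """
    out = pd.Series(index=df.index, dtype=int)
    for _, sub in df.groupby(subject_col):
        n = len(sub)
        if n < n_bins:
            raise ValueError(f"need at least {n_bins} trials per subject, got {n}")
        base, rem = divmod(n, n_bins)
        sizes = [base + (1 if k < rem else 0) for k in range(n_bins)]
        labels = np.repeat(np.arange(1, n_bins + 1), sizes)
        order = sub[order_col].argsort(kind="stable")
        idx = sub.index[order]
        out.loc[idx] = labels
    return out


# ---------------------------------------------------------------------------
# mixed-model fitting

@dataclass
class EffectTable:
    """Fixed-effect tests and pairwise contrasts for one fitted model."""

    model: str
    effects: pd.DataFrame    # term, F, df1, df2, p, df_method
    contrasts: pd.DataFrame  # factor, level_a, level_b, delta, p
    coefficients: pd.DataFrame  # name, estimate, se, p

    def effect(self, term: str) -> pd.Series:
        m = self.effects[self.effects["term"] == term]
        if m.empty:
            raise KeyError(f"no effect named {term!r} in model {self.model}; "
                           f"have {list(self.effects['term'])}")
        return m.iloc[0]

    def contrast(self, level_a: str, level_b: str) -> pd.Series:
        c = self.contrasts
        m = c[(c["level_a"] == level_a) & (c["level_b"] == level_b)]
        if m.empty:
            raise KeyError(f"no contrast {level_a} vs {level_b} in {self.model}")
        return m.iloc[0]


def _term_slices(design_info):
    return {name: design_info.slice(name) for name in design_info.term_names}


def _wald_f(params, cov, sl, df_resid):
    L = np.zeros((sl.stop - sl.start, len(params)))
    for i, j in enumerate(range(sl.start, sl.stop)):
        L[i, j] = 1.0
    lb = L @ params
    lcov = L @ cov @ L.T
    q = L.shape[0]
    try:
        stat = float(lb @ np.linalg.solve(lcov, lb)) / q
    except np.linalg.LinAlgError:
        return 0.0, q, df_resid, 1.0
    stat = max(stat, 0.0)
    p = scipy.stats.f.sf(stat, q, df_resid) if np.isfinite(df_resid) else \
        scipy.stats.chi2.sf(stat * q, q)
    return stat, q, df_resid, float(p)


def _pairwise(params, cov, design_info, factor_col, levels, df_resid):
    """Uncorrected pairwise contrasts of a treatment-coded factor."""
    names = design_info.column_names
    vecs = {}
    for lev in levels:
        v = np.zeros(len(names))
        for i, nm in enumerate(names):
            if factor_col in nm and f"[T.{lev}]" in nm and ":" not in nm:
                v[i] = 1.0
        vecs[lev] = v
    rows = []
    for a in levels:
        for b in levels:
            if a >= b:
                continue
            d = vecs[a] - vecs[b]
            est = float(d @ params)
            se = float(np.sqrt(d @ cov @ d))
            if se == 0:
                rows.append({"factor": factor_col, "level_a": a, "level_b": b,
                             "delta": est, "p": 1.0})
                continue
            t = est / se
            if np.isfinite(df_resid):
                p = 2 * scipy.stats.t.sf(abs(t), df_resid)
            else:
                p = 2 * scipy.stats.norm.sf(abs(t))
            rows.append({"factor": factor_col, "level_a": a, "level_b": b,
                         "delta": est, "p": float(p)})
    return pd.DataFrame(rows, columns=["factor", "level_a", "level_b", "delta", "p"])


def fit_mixed(
    table: pd.DataFrame,
    response: str,
    fixed: str,
    link: str = "identity",
    groups: str = "subject_id",
    pairwise_factor: Optional[str] = None,
    model_name: str = "model",
) -> EffectTable:
    """Fit one model of the battery and summarise its fixed effects.

    ``fixed`` is a patsy right-hand side. Identity link: linear mixed
    model with a random subject intercept (Wald F, residual df; refit as
    plain OLS with a warning if the intercept variance is singular).
    Logit link: binomial GLM with per-subject fixed intercepts (Wald
    chi-square reported on the F scale with infinite denominator df).
    A constant response short-circuits to an all-zero table.
    """
    if link not in ("identity", "logit"):
        raise ValueError("link must be 'identity' or 'logit'")
    # artifact-rejected trials carry NaN measures; drop them before patsy
    data = table.dropna(subset=[response]).reset_index(drop=True).copy()
    if data.empty:
        raise ValueError(f"{model_name}: no usable trials for response {response!r}")

    if np.allclose(data[response].var(), 0.0):
        import patsy
        di = patsy.dmatrix(fixed, data, return_type="dataframe").design_info
        eff = pd.DataFrame(
            [{"term": t, "F": 0.0,
              "df1": max(di.slice(t).stop - di.slice(t).start, 1),
              "df2": np.inf, "p": 1.0, "df_method": "degenerate"}
             for t in di.term_names if t != "Intercept"])
        contr = pd.DataFrame(columns=["factor", "level_a", "level_b", "delta", "p"])
        if pairwise_factor is not None:
            levels = sorted(data[pairwise_factor].unique())
            contr = pd.DataFrame(
                [{"factor": pairwise_factor, "level_a": a, "level_b": b,
                  "delta": 0.0, "p": 1.0}
                 for a in levels for b in levels if a < b])
        coefs = pd.DataFrame(columns=["name", "estimate", "se", "p"])
        return EffectTable(model_name, eff, contr, coefs)

    if link == "identity":
        md = smf.mixedlm(f"{response} ~ {fixed}", data, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True)
        singular = (not res.converged) or float(np.asarray(res.cov_re).ravel()[0]) < 1e-10
        if singular:
            warnings.warn(f"{model_name}: singular random-intercept variance; "
                          "refitting with a fixed intercept only")
            ols = smf.ols(f"{response} ~ {fixed}", data).fit()
            params = ols.params.to_numpy()
            cov = ols.cov_params().to_numpy()
            design_info = ols.model.data.design_info
            df_resid = float(ols.df_resid)
            df_method = "residual-ols"
            ses = ols.bse.to_numpy()
            pvals = ols.pvalues.to_numpy()
            names = list(ols.params.index)
        else:
            params = res.fe_params.to_numpy()
            k = len(params)
            cov = np.asarray(res.cov_params())[:k, :k]
            design_info = md.data.design_info
            df_resid = float(len(data) - k - 1)
            df_method = "residual"
            ses = np.sqrt(np.diag(cov))
            pvals = 2 * scipy.stats.t.sf(np.abs(params / ses), df_resid)
            names = list(res.fe_params.index)
    else:
        formula = f"{response} ~ {fixed} + C({groups})"
        md = smf.glm(formula, data, family=sm.families.Binomial())
        res = md.fit()
        design_info = md.data.design_info
        keep = [i for i, nm in enumerate(design_info.column_names)
                if f"C({groups})" not in nm]
        params = res.params.to_numpy()
        cov = res.cov_params().to_numpy()
        df_resid = np.inf
        df_method = "wald-fixed-intercept"
        ses = res.bse.to_numpy()
        pvals = res.pvalues.to_numpy()
        names = list(res.params.index)

    slices = _term_slices(design_info)
    rows = []
    for term, sl in slices.items():
        if term == "Intercept" or term.startswith(f"C({groups})"):
            continue
        F, df1, df2, p = _wald_f(params, cov, sl, df_resid)
        rows.append({"term": term, "F": F, "df1": df1, "df2": df2,
                     "p": p, "df_method": df_method})
    effects = pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p", "df_method"])

    contrasts = pd.DataFrame(columns=["factor", "level_a", "level_b", "delta", "p"])
    if pairwise_factor is not None:
        levels = sorted(str(v) for v in table[pairwise_factor].unique())
        contrasts = _pairwise(params, cov, design_info, pairwise_factor,
                              levels, df_resid)
    coefs = pd.DataFrame({"name": names, "estimate": params, "se": ses, "p": pvals})
    return EffectTable(model_name, effects, contrasts, coefs)


# ---------------------------------------------------------------------------
# the model registry

def load_registry(path=None) -> dict:
    """The shipped analyses.yaml registry (or one from ``path``)."""
    if path is None:
        text = resources.files("ssveptag").joinpath("analyses.yaml").read_text()
    else:
        text = open(path).read()
    return yaml.safe_load(text)


def _subset(table: pd.DataFrame, rule: Optional[str]) -> pd.DataFrame:
    if not rule:
        return table
    return table.query(rule)


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the columns the battery expects from the base measures."""
    t = table.copy()
    if "cue_directional" not in t:
        t["cue_directional"] = np.where(t["cue"] == "neutral", "neutral", "cued")
    if "task_exposure_bin" not in t and "trial_order" in t:
        t["task_exposure_bin"] = bin_task_exposure(t)
    if ("ssvep_prepost_diff" not in t
            and {"ssvep_pre_response", "ssvep_post_response"} <= set(t.columns)):
        t["ssvep_prepost_diff"] = t["ssvep_post_response"] - t["ssvep_pre_response"]
    return t


def run_model(table: pd.DataFrame, name: str, spec: dict) -> EffectTable:
    if spec["response"] == "ssvep_amplitude" and "ssvep_amplitude" not in table:
        table = _target_nontarget_long(table)
    data = _subset(table, spec.get("subset"))
    return fit_mixed(
        data,
        response=spec["response"],
        fixed=spec["fixed"],
        link=spec.get("link", "identity"),
        pairwise_factor=spec.get("pairwise"),
        model_name=name,
    )


def focal_pvalue(et: EffectTable, spec: dict) -> float:
    """p-value of the term carrying a model's scientific question."""
    focal = spec["focal"]
    matches = [
        r for _, r in et.effects.iterrows()
        if all(c in r["term"] for c in focal["contains"])
        and (":" in r["term"]) == bool(focal.get("interaction"))
    ]
    if len(matches) != 1:
        raise KeyError(f"focal term of {et.model} matched {len(matches)} effects")
    return float(matches[0]["p"])


def run_battery(table: pd.DataFrame, registry: dict = None,
                models: Optional[Sequence[str]] = None) -> dict[str, EffectTable]:
    registry = registry or load_registry()
    table = prepare_table(table)
    out = {}
    for name, spec in registry["models"].items():
        if models is not None and name not in models:
            continue
        out[name] = run_model(table, name, spec)
    return out


# grouped entry points mirroring the analysis plan ---------------------------

BEHAVIOUR_MODELS = ["rt_by_validity_accuracy", "rt_correct", "rt_error", "accuracy"]
SSVEP_MODELS = ["ssvep_evidence", "ssvep_evidence_exposure", "ssvep_baseline",
                "ssvep_target_nontarget", "ssvep_prepost_response"]
LINK_MODELS = ["ssvep_accuracy_link", "ssvep_rt_link"]
MB_ALPHA_MODELS = ["mb_lateralization", "alpha_engagement"]


def behaviour_analysis(table: pd.DataFrame) -> dict[str, EffectTable]:
    """Full RT model, split correct/error RT models, logistic accuracy."""
    return run_battery(table, models=BEHAVIOUR_MODELS)


def ssvep_analyses(table: pd.DataFrame) -> dict[str, EffectTable]:
    """Evidence-window, baseline, target/non-target and pre/post-response
    marginal-SSVEP models."""
    return run_battery(table, models=SSVEP_MODELS)


def _target_nontarget_long(table: pd.DataFrame) -> pd.DataFrame:
    """Long format with one row per trial per signal role."""
    need = {"ssvep_target_evidence", "ssvep_nontarget_evidence"}
    if not need <= set(table.columns):
        # fall back: reconstruct from the marginal (role difference only)
        t = table.copy()
        t["ssvep_target_evidence"] = t["marginal_ssvep_evidence"] / 2
        t["ssvep_nontarget_evidence"] = -t["marginal_ssvep_evidence"] / 2
        table = t
    rows = []
    for role in ("target", "nontarget"):
        sub = table.copy()
        sub["signal_role"] = role
        sub["ssvep_amplitude"] = table[f"ssvep_{role}_evidence"]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def ssvep_behaviour_link(table: pd.DataFrame) -> dict[str, EffectTable]:
    """Trial-by-trial SSVEP → accuracy (logit) and RT (identity), RT > 680 ms."""
    return run_battery(table, models=LINK_MODELS)


def mb_alpha_analyses(table: pd.DataFrame) -> dict[str, EffectTable]:
    """Pre-evidence motor lateralization and alpha engagement models."""
    return run_battery(table, models=MB_ALPHA_MODELS)


# ---------------------------------------------------------------------------
# titration trend across task exposure

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    F: float
    df1: int
    df2: int
    p: float
    r_squared: float


def marginal_contrast_trend(table: pd.DataFrame) -> RegressionResult:
    """Simple linear regression of mean marginal contrast on exposure bin.

    One point per subject per bin (the per-subject-per-bin mean marginal
    contrast), as in the session-titration trend analysis.
    """
    means = (table.groupby(["subject_id", "task_exposure_bin"])
             ["marginal_contrast_pct"].mean().reset_index())
    x = means["task_exposure_bin"].to_numpy(dtype=float)
    y = means["marginal_contrast_pct"].to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0):
        return RegressionResult(0.0, float(y.mean()), 0.0, 1, len(y) - 2, 1.0, 0.0)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        F=float(res.fvalue), df1=1, df2=int(res.df_resid),
        p=float(res.f_pvalue), r_squared=float(res.rsquared),
    )


def effect_tables_to_frame(tables: dict[str, EffectTable]) -> pd.DataFrame:
    """Flatten a battery result into the fixed CSV schema."""
    rows = []
    for name, et in tables.items():
        for _, r in et.effects.iterrows():
            rows.append({"model": name, "term": r["term"], "F": r["F"],
                         "df1": r["df1"], "df2": r["df2"], "p": r["p"],
                         "contrast": "", "delta": np.nan, "p_contrast": np.nan})
        for _, c in et.contrasts.iterrows():
            rows.append({"model": name, "term": c["factor"], "F": np.nan,
                         "df1": np.nan, "df2": np.nan, "p": np.nan,
                         "contrast": f"{c['level_a']} - {c['level_b']}",
                         "delta": c["delta"], "p_contrast": c["p"]})
    return pd.DataFrame(rows, columns=["model", "term", "F", "df1", "df2", "p",
                                       "contrast", "delta", "p_contrast"])
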