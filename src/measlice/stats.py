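"""Multilevel statistical comparison of the input-output features.

Two model families, fitted with statsmodels:

* **Linear mixed model** for the continuous responses (fPSP1 slope, fPSP2
  slope, paired-pulse ratio, PS1/PS2 amplitude): fixed effects group,
  intensity, and group-by-intensity interaction, with slice-level random
  intercept and random intensity-slope nested in animal (variance
  components) plus an animal-level random intercept.  Intensity is coded in
  250 mV step units so the fixed-effect gains read directly as
  'per 250 mV'.  Models are fitted by maximum likelihood so AICs are
  comparable; a reduced random-intercept-only fit is reported alongside for
  model selection.
* **GEE logistic regression** for the dichotomous PS occurrence: binomial
  trials/events aggregated per cluster (animal for the input-output
  analysis, slice-in-animal for the spatial analysis), exchangeable working
  correlation over within-cluster intensity repeats, robust standard errors.

Two-tailed alpha = 0.05; no multiple-testing correction is applied across
the five continuous responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["ModelFit", "build_io_table", "fit_lmm", "aggregate_binomial",
           "fit_gee_logistic", "replicate_lmm", "replicate_gee", "RESPONSES"]

RESPONSES = ("slope1", "slope2", "ppr", "ps1_amp", "ps2_amp")

_TERMS = {"Intercept": "intercept", "group[T.IHKA]": "group", "step": "step",
          "group[T.IHKA]:step": "group_x_step"}


@dataclass
class ModelFit:
    """Fixed-effect estimates with robust/model SEs, CIs and p-values."""

    model: str
    response: str
    params: pd.DataFrame          # index: term; est, se, ci_low, ci_high, p
    random_variances: dict = field(default_factory=dict)
    aic: float | None = None
    aic_reduced: float | None = None
    converged: bool = True
    flags: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]

    @property
    def interaction(self) -> pd.Series:
        return self.params.loc["group_x_step"]

    def to_dict(self) -> dict:
        return {
            "model": self.model, "response": self.response,
            "params": {t: {k: (None if not np.isfinite(v) else float(v))
                           for k, v in row.items()}
                       for t, row in self.params.iterrows()},
            "random_variances": {k: float(v) for k, v in self.random_variances.items()},
            "aic": self.aic, "aic_reduced": self.aic_reduced,
            "converged": self.converged, "flags": list(self.flags),
        }


def _params_frame(names, est, se, ci, p) -> pd.DataFrame:
    df = pd.DataFrame({"est": est, "se": se, "ci_low": ci[:, 0],
                       "ci_high": ci[:, 1], "p": p}, index=names)
    df.index = [_TERMS.get(n, n) for n in df.index]
    return df


def _prep(df: pd.DataFrame) -> pd.DataFrame:
    d = df.copy()
    d["group"] = pd.Categorical(d["group"], categories=["control", "IHKA"])
    # slice coded within animal so variance components nest correctly
    d["slice_in_animal"] = d.groupby("animal_id")["slice_id"].transform(
        lambda s: pd.factorize(s)[0])
    return d


def build_io_table(features: pd.DataFrame) -> pd.DataFrame:
    """Long input-output table: one row per slice x intensity x response.

    ``features`` is the wide per-slice table (one row per slice and
    intensity, columns per response); missing PPR/PS values propagate as
    missing, never as zero.  Duplicate slice x intensity rows are an error.
    """
    key = ["slice_id", "intensity_mv"]
    if features.duplicated(subset=key).any():
        dup = features[features.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate slice x intensity rows: "
                         f"{dup[key].drop_duplicates().values.tolist()}")
    id_cols = ["animal_id", "slice_id", "group", "region", "intensity_mv", "step"]
    present = [r for r in RESPONSES if r in features.columns]
    long = features.melt(id_vars=[c for c in id_cols if c in features.columns],
                         value_vars=present, var_name="response", value_name="value")
    return long.sort_values(["response", "slice_id", "intensity_mv"]).reset_index(drop=True)


def fit_lmm(io_table: pd.DataFrame, response: str,
            random: str = "slice_nested", reml: bool = True) -> ModelFit:
    """Fit the linear mixed model for one continuous response.

    ``io_table`` is the long table from :func:`build_io_table` (or a wide
    frame containing the response column).  ``random``: 'slice_nested'
    (default — slice-level random intercept and random intensity-slope
    variance components nested in an animal-level random intercept),
    'animal' (animal-level random intercept + slope), or 'intercept'.
    Inference uses REML by default (the convention of standard mixed-model
    software); the AIC is computed from the fit's log-likelihood and
    parameter count and is comparable across random structures with
    identical fixed effects.  Non-convergence falls back to the reduced
    random structure with a flag.
    """
    if "response" in io_table.columns:
        d = io_table[io_table.response == response].rename(columns={"value": "y"})
    else:
        d = io_table.rename(columns={response: "y"})
    d = _prep(d[["animal_id", "slice_id", "group", "step", "y"]].dropna(subset=["y"]))
    if d.group.nunique() < 2 or d.step.nunique() < 2:
        raise ValueError("need >= 2 groups and >= 2 intensities")
    flags: list[str] = []

    # degenerate data (zero residual variance) cannot carry a mixed model
    resid = smf.ols("y ~ group*step", d).fit()
    if resid.ssr / len(d) < 1e-14:
        ci = resid.conf_int().to_numpy()
        params = _params_frame(resid.params.index, resid.params.to_numpy(),
                               resid.bse.to_numpy(), ci, resid.pvalues.to_numpy())
        return ModelFit("lmm(ols-degenerate)", response, params,
                        aic=float(resid.aic), flags=["degenerate_zero_variance"])

    def _fit(kind: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if kind == "slice_nested":
                md = smf.mixedlm("y ~ group*step", d, groups="animal_id",
                                 re_formula="1",
                                 vc_formula={"slice": "0 + C(slice_in_animal)",
                                             "slice_slope": "0 + C(slice_in_animal):step"})
            elif kind == "slice_nested_intercept":
                md = smf.mixedlm("y ~ group*step", d, groups="animal_id",
                                 re_formula="1",
                                 vc_formula={"slice": "0 + C(slice_in_animal)"})
            elif kind == "animal":
                md = smf.mixedlm("y ~ group*step", d, groups="animal_id",
                                 re_formula="1 + step")
            else:
                md = smf.mixedlm("y ~ group*step", d, groups="animal_id")
            return md.fit(reml=reml, maxiter=200, method="lbfgs")

    def _aic(result) -> float:
        k = len(result.params)   # fixed effects + covariance parameters
        return float(-2.0 * result.llf + 2.0 * k)

    order = {"slice_nested": ["slice_nested", "slice_nested_intercept", "intercept"],
             "animal": ["animal", "intercept"]}.get(random, [random])
    res = None
    for kind in order:
        try:
            res = _fit(kind)
            if res.converged:
                break
            flags.append(f"non_convergence:{kind}")
        except Exception:
            flags.append(f"fit_error:{kind}")
            res = None
    if res is None:
        raise RuntimeError(f"LMM failed for response '{response}'")
    fe = res.fe_params
    names = list(fe.index)
    se = res.bse[names].to_numpy()
    ci = res.conf_int().loc[names].to_numpy()
    p = res.pvalues[names].to_numpy()
    params = _params_frame(names, fe.to_numpy(), se, ci, p)
    rv = {"animal_intercept": float(np.asarray(res.cov_re)[0, 0])
          if res.cov_re.size else 0.0,
          "residual": float(res.scale)}
    for name, v in zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)):
        rv[name] = float(v)
    # reduced model (random intercept only) for AIC comparison
    aic_reduced = None
    try:
        red = _fit("slice_nested_intercept" if random == "slice_nested" else "intercept")
        aic_reduced = _aic(red)
    except Exception:
        flags.append("reduced_fit_error")
    return ModelFit("lmm(" + kind + ")", response, params, random_variances=rv,
                    aic=_aic(res), aic_reduced=aic_reduced,
                    converged=bool(res.converged), flags=flags)


def aggregate_binomial(df: pd.DataFrame, level: str = "animal",
                       pulse: int = 1) -> pd.DataFrame:
    """Binomial trials/events aggregates for the GEE analyses.

    ``level='animal'`` (input-output analysis): one row per animal x
    intensity; trials = number of slices with a defined PS status, events =
    slices showing a PS (column ``ps{pulse}_present``).  ``level='slice'``
    (spatial analysis): rows already hold per-slice channel counts and are
    passed through with the slice as the cluster.
    """
    if level == "animal":
        col = f"ps{pulse}_present"
        sub = df.dropna(subset=[col])
        g = (sub.groupby(["animal_id", "group", "step", "intensity_mv"],
                         observed=True)[col]
             .agg(trials="count", events="sum").reset_index())
        g["events"] = g["events"].astype(int)
        g = g[g.trials >= 1].rename(columns={"animal_id": "cluster"})
        return g.sort_values(["cluster", "step"]).reset_index(drop=True)
    if level == "slice":
        d = df.copy()
        d["cluster"] = d["slice_id"]
        if "step" not in d.columns:
            d["step"] = (d["intensity_mv"] - 500) // 250
        keep = d[d.trials >= 1]
        return keep.sort_values(["cluster", "step"]).reset_index(drop=True)
    raise ValueError("level must be 'animal' or 'slice'")


def _expand_bernoulli(agg: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in agg.iterrows():
        for i in range(int(r.trials)):
            rows.append({"cluster": r.cluster, "group": r.group,
                         "step": r.step, "y": 1 if i < int(r.events) else 0})
    return pd.DataFrame(rows)


def fit_gee_logistic(agg: pd.DataFrame, cov: str = "exchangeable") -> ModelFit:
    """Marginal logistic model on binomial aggregates.

    Fixed effects group, intensity step, and group-by-intensity interaction;
    clusters as subjects with exchangeable (or independence) working
    correlation; robust standard errors.  Complete separation (all events or
    none, overall or within a group) yields a flagged fit instead of a
    silent failure.
    """
    for g in ("IHKA", "control"):
        sub = agg[agg.group == g]
        if sub.cluster.nunique() < 2:
            raise ValueError(f"need >= 2 clusters per group (group '{g}')")
    d = _expand_bernoulli(agg)
    d["group"] = pd.Categorical(d["group"], categories=["control", "IHKA"])
    flags = []
    rate = d.groupby("group", observed=True).y.mean()
    if (rate <= 0).any() or (rate >= 1).any():
        flags.append("separation")
        names = ["Intercept", "group[T.IHKA]", "step", "group[T.IHKA]:step"]
        nan = np.full(len(names), np.nan)
        params = _params_frame(names, nan, nan, np.column_stack([nan, nan]), nan)
        return ModelFit("gee_logistic", "ps_present", params, converged=False,
                        flags=flags)
    cov_struct = (sm.cov_struct.Exchangeable() if cov == "exchangeable"
                  else sm.cov_struct.Independence())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.gee("y ~ group*step", groups="cluster", data=d,
                     family=sm.families.Binomial(), cov_struct=cov_struct)
        res = md.fit()
    names = list(res.params.index)
    params = _params_frame(names, res.params.to_numpy(), res.bse.to_numpy(),
                           res.conf_int().to_numpy(), res.pvalues.to_numpy())
    return ModelFit(f"gee_logistic({cov})", "ps_present", params,
                    converged=bool(res.converged), flags=flags)


# ---------------------------------------------------------------------------
# replicate simulation helpers (parameter recovery / power / type-I error)
# ---------------------------------------------------------------------------

def replicate_lmm(cfg, n_reps: int, seed: int, response: str = "slope1"
                  ) -> pd.DataFrame:
    """Fit the LMM on ``n_reps`` freshly sampled cohorts; one row per fit."""
    from .synthetic import sample_cohort_features
    rows = []
    for r in range(n_reps):
        feats, _ = sample_cohort_features(cfg, seed=seed + r)
        fit = fit_lmm(feats, response)
        it = fit.interaction
        rows.append({"rep": r, "est": it.est, "se": it.se, "p": it.p,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def replicate_gee(cfg, n_reps: int, seed: int, pulse: int = 1) -> pd.DataFrame:
    """Fit the GEE on ``n_reps`` freshly sampled cohorts; one row per fit."""
    from .synthetic import sample_cohort_features
    rows = []
    for r in range(n_reps):
        feats, _ = sample_cohort_features(cfg, seed=seed + r)
        agg = aggregate_binomial(feats, level="animal", pulse=pulse)
        fit = fit_gee_logistic(agg)
        it = fit.interaction
        rows.append({"rep": r, "est": it.est, "se": it.se, "p": it.p,
                     "flags": ";".join(fit.flags)})
    return pd.DataFrame(rows)
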