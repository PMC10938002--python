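"""Mixed-effects inference on pupil features and behavioural estimates.

Both models are Gaussian identity-link linear mixed models with crossed
random intercepts, fitted via variance components on a single group.
Fixed effects are tested with marginal (type-III-style) Wald F statistics
using residual degrees of freedom ``n_obs - k_fixed``.

- pupil model: peak constriction ~ numerosity (continuous) + adaptation
  condition (2 levels) + pre-test pupil, random intercepts for participant,
  experiment and realized-luminance level;
- behaviour model: estimate ~ numerosity (5-level categorical) x adaptation
  condition, random intercepts for participant and experiment, after a
  3-SD outlier rule per participant x condition x numerosity cell.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance or too few pairs)."""


class EmptyCellError(ValueError):
    """A design cell became empty after outlier removal."""


@dataclass
class TermTest:
    name: str
    coefficients: dict[str, float]
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class ModelResult:
    """Fixed-effect tests and variance components of one fitted mixed model."""

    terms: list[TermTest]
    random_variances: dict[str, float]
    residual_variance: float
    n_obs: int
    formula: str
    metadata: dict = field(default_factory=dict)

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n_obs": self.n_obs,
            "residual_variance": self.residual_variance,
            "random_variances": self.random_variances,
            "fixed_effects": [
                {
                    "term": t.name,
                    "coefficients": t.coefficients,
                    "F": t.f_stat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.p_value,
                }
                for t in self.terms
            ],
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=1, **kwargs)


def _fit_vc_model(
    formula: str, data: pd.DataFrame, vc_candidates: dict[str, str], metadata: dict
) -> "MixedLMResultsWrapper":
    """Fit a single-group variance-components mixed model with fallback.

    Random terms whose grouping column has fewer than two levels are dropped
    up front; on numerical failure the last-listed remaining term is dropped
    and the model refitted (down to a plain OLS-equivalent fit), with every
    drop logged in ``metadata``.
    """
    vc = {}
    for name, column in vc_candidates.items():
        if data[column].nunique() >= 2:
            vc[name] = f"0 + C({column})"
        else:
            metadata.setdefault("dropped_random_terms", []).append(
                {"term": name, "reason": "single level"}
            )
    order = list(vc)
    while True:
        model = MixedLM.from_formula(
            formula,
            data=data,
            groups=np.ones(len(data)),
            re_formula="0",
            vc_formula=vc if vc else None,
        )
        try:
            with warnings.catch_warnings(), np.errstate(
                divide="ignore", invalid="ignore"
            ):
                # variance components legitimately hit the zero boundary
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                result = model.fit(reml=True, method=["lbfgs"])
            if np.all(np.isfinite(result.fe_params)) and np.all(
                np.isfinite(np.asarray(result.cov_params()))
            ):
                return result
            raise np.linalg.LinAlgError("non-finite fit")
        except (np.linalg.LinAlgError, ValueError) as err:
            if not vc:
                raise
            dropped = order.pop()
            vc.pop(dropped)
            metadata.setdefault("dropped_random_terms", []).append(
                {"term": dropped, "reason": f"fit failure: {err}"}
            )


def _wald_terms(result, data_design_info) -> list[TermTest]:
    """Marginal Wald F test for every non-intercept fixed-effect term."""
    k_fe = result.model.k_fe
    names = result.model.exog_names
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    n_obs = result.model.nobs
    df_den = int(n_obs - k_fe)
    terms = []
    for term_name, sl in data_design_info.term_name_slices.items():
        if term_name == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            f_stat = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            f_stat = float("nan")
        p = float(sps.f.sf(f_stat, q, df_den)) if np.isfinite(f_stat) else float("nan")
        terms.append(
            TermTest(
                name=term_name,
                coefficients={names[i]: float(beta[i]) for i in idx},
                f_stat=f_stat,
                df_num=q,
                df_den=df_den,
                p_value=p,
            )
        )
    return terms


def _build_result(result, formula: str, metadata: dict) -> ModelResult:
    design_info = result.model.data.design_info
    vcomp = {}
    if result.model.exog_vc.names:
        for name, var in zip(result.model.exog_vc.names, np.asarray(result.vcomp)):
            vcomp[name] = float(var)
    return ModelResult(
        terms=_wald_terms(result, design_info),
        random_variances=vcomp,
        residual_variance=float(result.scale),
        n_obs=int(result.model.nobs),
        formula=formula,
        metadata=metadata,
    )


def fit_pupil_model(features: pd.DataFrame) -> ModelResult:
    """Mixed model of per-trial peak constriction.

    Fixed: numerosity (continuous), adaptation condition, pre-test pupil.
    Random intercepts: participant, experiment, luminance level.  Trials
    with missing features are dropped and counted; a zero-variance pre-test
    covariate is removed deterministically and flagged.
    """
    metadata: dict = {}
    required = ["peak_constriction", "pretest_pupil", "numerosity", "condition"]
    data = features.copy()
    if "luminance" not in data.columns:
        from .features import luminance_label

        data["luminance"] = luminance_label(data["experiment"], data["numerosity"])
    n_in = len(data)
    data = data.dropna(subset=["peak_constriction", "pretest_pupil"]).reset_index(
        drop=True
    )
    metadata["n_dropped_missing"] = int(n_in - len(data))

    rhs = ["numerosity", "C(condition)"]
    if data["pretest_pupil"].nunique() > 1:
        rhs.append("pretest_pupil")
    else:
        metadata["dropped_fixed_terms"] = [
            {"term": "pretest_pupil", "reason": "zero variance"}
        ]
    formula = "peak_constriction ~ " + " + ".join(rhs)
    vc_candidates = {
        "participant": "participant_id",
        "experiment": "experiment",
        "luminance": "luminance",
    }
    result = _fit_vc_model(formula, data, vc_candidates, metadata)
    return _build_result(result, formula, metadata)


def remove_outlier_estimates(
    estimates: pd.DataFrame,
    n_sd: float = 3.0,
    by: Sequence[str] = ("participant_id", "condition", "numerosity"),
) -> tuple[pd.DataFrame, int]:
    """Drop estimates more than ``n_sd`` sample SDs from their cell mean."""
    grp = estimates.groupby(list(by))["estimate"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (sd == 0) | ((estimates["estimate"] - mean).abs() <= n_sd * sd)
    return estimates[keep].reset_index(drop=True), int((~keep).sum())


def fit_behavior_model(estimates: pd.DataFrame) -> ModelResult:
    """Mixed model of verbal estimates with the numerosity x adaptation
    interaction, after per-cell 3-SD outlier exclusion."""
    metadata: dict = {}
    data, n_removed = remove_outlier_estimates(estimates)
    metadata["n_outliers_removed"] = n_removed
    cells = data.groupby(["condition", "numerosity"]).size()
    expected = {
        (c, n)
        for c in estimates["condition"].unique()
        for n in estimates["numerosity"].unique()
    }
    missing = expected - set(cells.index)
    if missing:
        raise EmptyCellError(f"empty condition x numerosity cells: {sorted(missing)}")
    formula = "estimate ~ C(numerosity) * C(condition)"
    vc_candidates = {"participant": "participant_id", "experiment": "experiment"}
    result = _fit_vc_model(formula, data, vc_candidates, metadata)
    return _build_result(result, formula, metadata)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    pairs: pd.DataFrame

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p_value, "n": self.n}


def correlate_effects(
    pupil_effects: pd.DataFrame, behavior_effects: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of per-participant pupil and behaviour effects."""
    pairs = pupil_effects.merge(behavior_effects, on="participant_id").dropna()
    if len(pairs) < 3:
        raise UndefinedCorrelationError(f"need >= 3 paired participants, got {len(pairs)}")
    x = pairs["pupil_effect"].to_numpy(float)
    y = pairs["behavior_effect"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the effect vectors")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(pairs), pairs=pairs)
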