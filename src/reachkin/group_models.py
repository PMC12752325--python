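"""Group-level linear mixed-effects models for the endpoint design.

Two models are fit on the long analysis table (one row per participant x day
x block on the 2x2 endpoint grid): one for palm BVE and one for mean palm
speed.  Fixed effects are Day and Block (two-level treatment-coded factors,
first level as reference), trunk BVE, shoulder BVE, FMA-UE, the Day x Block
interaction and the trunk x shoulder BVE interaction, entered uncentered.
Random effects are two variance components: a participant intercept and a
day-within-participant intercept.  Estimation is REML; confidence intervals
and p-values for fixed effects are Wald-z.

Report fields follow the conventional mixed-model summary: residual variance
sigma^2, variance components tau_00 per random intercept, the intraclass
correlation ICC = sum(tau_00) / (sum(tau_00) + sigma^2), and
marginal/conditional R^2 by variance decomposition (fixed-effects variance
over total; fixed plus random over total).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .aggregation import BlockSummary, summaries_to_frame
from .errors import RankDeficientDesignError, ValidationError
from .landmark_io import ParticipantInfo

log = logging.getLogger(__name__)

DEFAULT_FIXED_EFFECTS = (
    "C(day)",
    "C(block)",
    "bve_trunk",
    "bve_shoulder",
    "fma_ue",
    "C(day):C(block)",
    "bve_trunk:bve_shoulder",
)

MODEL_OUTCOMES = ("bve_palm", "mean_speed_palm")


@dataclass
class LmeSpec:
    """Specification of one mixed model: outcome, fixed-effect terms and the
    two random intercepts (participant; day nested within participant)."""

    outcome: str
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS
    center_covariates: bool = False

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.fixed_effects)


@dataclass
class FixedEffect:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LmeFit:
    """Fitted-model report mirroring a standard mixed-model summary table."""

    outcome: str
    fixed_effects: list[FixedEffect]
    sigma2: float
    tau_participant: float
    tau_participant_day: float
    icc: float
    n_participants: int
    n_days: int
    n_observations: int
    n_dropped_rows: int
    r2_marginal: float
    r2_conditional: float
    converged: bool

    def effect(self, term: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.term == term:
                return fe
        raise KeyError(term)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LmeFit":
        d = dict(d)
        d["fixed_effects"] = [FixedEffect(**fe) for fe in d["fixed_effects"]]
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LmeFit":
        text = Path(source).read_text() if isinstance(source, Path) else source
        return cls.from_dict(json.loads(text))


def build_model_table(
    summaries: Sequence[BlockSummary] | pd.DataFrame,
    participants: Sequence[ParticipantInfo],
    days: Sequence[int] = (1, 5),
    blocks: Sequence[int] = (1, 5),
) -> pd.DataFrame:
    """Long analysis table: one row per (participant, day, block) on the
    analysis grid, outcomes plus covariates, Day/Block as 2-level factors."""
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    df = df[df["day"].isin(days) & df["block"].isin(blocks)].copy()
    fma = {p.participant_id: p.fma_ue for p in participants}
    missing = sorted(set(df["participant_id"]) - set(fma))
    if missing:
        raise ValidationError(f"participants without metadata: {missing}")
    if len(df):
        df["fma_ue"] = df["participant_id"].map(fma).astype(float)
    else:
        df["fma_ue"] = pd.Series(dtype=float)
    cols = [
        "participant_id", "day", "block",
        "bve_palm", "bve_shoulder", "bve_trunk", "mean_speed_palm", "fma_ue",
    ]
    out = df[cols].sort_values(["participant_id", "day", "block"]).reset_index(drop=True)
    return out


def _check_rank(formula: str, table: pd.DataFrame) -> None:
    _, exog = patsy.dmatrices(formula, table, return_type="dataframe")
    X = exog.to_numpy()
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name columns that are linear combinations of the preceding ones
    collinear = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            collinear.append(exog.columns[j])
        rank = r
    raise RankDeficientDesignError(collinear)


def fit_lme(table: pd.DataFrame, spec: LmeSpec) -> LmeFit:
    """Fit one mixed model (REML) with participant and day-within-participant
    random intercepts.

    Incomplete rows are removed listwise (count logged and reported).  A fit
    that fails to converge or hits a singular variance estimate is returned
    with ``converged=False`` and a warning, never as a silent success; a
    rank-deficient fixed-effects design raises
    :class:`~reachkin.errors.RankDeficientDesignError` naming the collinear
    columns.
    """
    needed = {"participant_id", "day", spec.outcome, "bve_trunk", "bve_shoulder", "fma_ue"}
    missing_cols = needed - set(table.columns)
    if missing_cols:
        raise ValidationError(f"analysis table missing column(s): {sorted(missing_cols)}")
    if table["participant_id"].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 participants")
    data = table.copy()
    if spec.center_covariates:
        for c in ("bve_trunk", "bve_shoulder", "fma_ue"):
            data[c] = data[c] - data[c].mean()
    before = len(data)
    data = data.dropna(subset=[c for c in data.columns if c != "participant_id"])
    n_dropped = before - len(data)
    if n_dropped:
        log.info("listwise deletion removed %d incomplete row(s)", n_dropped)
    if not len(data):
        raise ValidationError("analysis table is empty after listwise deletion")

    _check_rank(spec.formula, data)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            spec.formula,
            data=data,
            groups=data["participant_id"],
            re_formula="1",
            vc_formula={"day": "0 + C(day)"},
        )
        res = model.fit(reml=True)
    warned = any(issubclass(w.category, (ConvergenceWarning, RuntimeWarning)) for w in caught)
    converged = bool(res.converged) and not warned
    if not converged:
        warnings.warn(
            f"mixed model for {spec.outcome!r} did not converge cleanly; "
            "treat estimates with caution",
            ConvergenceWarning,
            stacklevel=2,
        )

    fe_names = list(res.fe_params.index)
    ci = res.conf_int()
    fixed = [
        FixedEffect(
            term=name,
            estimate=float(res.fe_params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(res.pvalues[name]),
        )
        for name in fe_names
    ]
    sigma2 = float(res.scale)
    tau_p = float(np.asarray(res.cov_re)[0, 0])
    tau_pd = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    icc = (tau_p + tau_pd) / (tau_p + tau_pd + sigma2)
    var_f = float(np.var(model.exog @ res.fe_params.to_numpy()))
    total = var_f + tau_p + tau_pd + sigma2
    fit = LmeFit(
        outcome=spec.outcome,
        fixed_effects=fixed,
        sigma2=sigma2,
        tau_participant=tau_p,
        tau_participant_day=tau_pd,
        icc=float(icc),
        n_participants=int(data["participant_id"].nunique()),
        n_days=int(data["day"].nunique()),
        n_observations=int(len(data)),
        n_dropped_rows=int(n_dropped),
        r2_marginal=float(var_f / total),
        r2_conditional=float((var_f + tau_p + tau_pd) / total),
        converged=converged,
    )
    return fit


def fit_both_models(
    table: pd.DataFrame, center_covariates: bool = False
) -> dict[str, LmeFit]:
    """Fit the palm-BVE and mean-palm-speed models with the default spec."""
    return {
        outcome: fit_lme(table, LmeSpec(outcome, center_covariates=center_covariates))
        for outcome in MODEL_OUTCOMES
    }


def report(fit: LmeFit) -> str:
    """Plain-text rendering of an LmeFit (JSON rendering via LmeFit.to_json)."""
    lines = []
    if not fit.converged:
        lines.append("*** WARNING: model did not converge; estimates unreliable ***")
    lines.append(f"Linear mixed model — outcome: {fit.outcome}")
    lines.append(f"{'Predictor':<32}{'Estimate':>10}{'95% CI':>22}{'p':>9}")
    for fe in fit.fixed_effects:
        star = " *" if fe.p_value < 0.05 else ""
        ci = f"[{fe.ci_low:.2f}, {fe.ci_high:.2f}]"
        lines.append(f"{fe.term:<32}{fe.estimate:>10.2f}{ci:>22}{fe.p_value:>9.3f}{star}")
    lines.append(f"Residual variance sigma^2        {fit.sigma2:.2f}")
    lines.append(f"tau_00 participant               {fit.tau_participant:.2f}")
    lines.append(f"tau_00 participant:day           {fit.tau_participant_day:.2f}")
    lines.append(f"ICC                              {fit.icc:.2f}")
    lines.append(f"N participants / days / obs      "
                 f"{fit.n_participants} / {fit.n_days} / {fit.n_observations}")
    lines.append(f"Marginal R^2 / Conditional R^2   "
                 f"{fit.r2_marginal:.3f} / {fit.r2_conditional:.3f}")
    if fit.n_dropped_rows:
        lines.append(f"(listwise deletion removed {fit.n_dropped_rows} incomplete rows)")
    return "\n".join(lines)
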