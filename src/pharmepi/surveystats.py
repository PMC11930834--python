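"""Design-based estimation for complex-survey data.

Point estimates come from the weighted logistic likelihood, maximised by
iteratively reweighted least squares; variances come from Taylor
linearization: per-record score contributions are aggregated to PSU totals,
their between-PSU variance is taken within strata, and the pieces are
assembled into the usual sandwich.  Confidence intervals and Wald tests use a
t reference with design degrees of freedom ``(#PSUs − #strata)``.

The covariate tiers mirror a three-model adjustment series:

* model1 — exposure only (crude);
* model2 — model1 + age, gender, race, education;
* model3 — model2 + moderate activity, diabetes, hypertension, caffeine,
  alcohol, sugar (fully adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import RACE_LEVELS, EDU_LEVELS
from .cohort import age_bin, bmi_bin

__all__ = [
    "SurveyDesign",
    "ModelSpec",
    "FitResult",
    "fit_weighted_logistic",
    "model_series",
    "subgroup_analysis",
    "interaction_test",
    "weighted_descriptives",
    "MODEL_TIERS",
    "SeparationError",
    "DegenerateOutcomeError",
    "NonConvergenceError",
]

MODEL_TIERS: dict[str, tuple[str, ...]] = {
    "model1": (),
    "model2": ("age", "gender", "race", "education"),
    "model3": (
        "age", "gender", "race", "education",
        "moderate_activity", "diabetes", "hypertension",
        "caffeine", "alcohol", "sugar",
    ),
}

# Reference level first; remaining levels get dummy columns.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "race": RACE_LEVELS,
    "education": EDU_LEVELS,
    "smoking": ("never", "smoker"),
    "age_group": ("20-39", "40-60", ">60"),
    "bmi_group": ("<25", "25-30", ">30"),
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: coefficients diverged."""


class DegenerateOutcomeError(ValueError):
    """The outcome has a single observed class."""


class NonConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class SurveyDesign:
    """Per-record design variables: sampling weight, stratum, PSU in stratum."""

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray
    lonely_psu: str = "certainty"  # or "error"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        if (self.weight <= 0).any() or not np.isfinite(self.weight).all():
            raise ValueError("survey weights must be positive and finite")
        if not len(self.weight) == len(self.stratum) == len(self.psu):
            raise ValueError("design variables must have equal length")
        if self.lonely_psu not in ("certainty", "error"):
            raise ValueError("lonely_psu must be 'certainty' or 'error'")
        lonely = [
            s for s in np.unique(self.stratum)
            if len(np.unique(self.psu[self.stratum == s])) < 2
        ]
        if lonely:
            if self.lonely_psu == "error":
                raise ValueError(f"strata with a single PSU: {lonely}")
            warnings.warn(
                f"lonely PSU in strata {lonely}: treated as certainty units "
                "(zero between-PSU variance contribution)",
                stacklevel=2,
            )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        weight: str = "survey_weight",
        stratum: str = "stratum",
        psu: str = "psu",
        lonely_psu: str = "certainty",
    ) -> "SurveyDesign":
        return cls(
            df[weight].to_numpy(float),
            df[stratum].to_numpy(),
            df[psu].to_numpy(),
            lonely_psu,
        )

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        d = SurveyDesign.__new__(SurveyDesign)
        d.weight = self.weight[mask]
        d.stratum = self.stratum[mask]
        d.psu = self.psu[mask]
        d.lonely_psu = self.lonely_psu
        return d

    @property
    def df_design(self) -> int:
        """Design degrees of freedom: number of PSUs minus number of strata."""
        pairs = {(s, p) for s, p in zip(self.stratum, self.psu)}
        return len(pairs) - len(np.unique(self.stratum))


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, exposure and covariate tier for one logistic fit."""

    outcome: str = "outcome"
    exposure: str = "exposure"
    tier: str = "model3"
    drop_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier not in MODEL_TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(c for c in MODEL_TIERS[self.tier] if c not in self.drop_covariates)


@dataclass
class FitResult:
    """A fitted design-based logistic model."""

    params: pd.Series
    cov: pd.DataFrame
    df_design: int
    n_obs: int
    iterations: int
    deviance: float
    final_deviance_change: float
    converged: bool
    spec: ModelSpec | None = None
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        tcrit = stats.t.ppf(0.975, self.df_design) if self.df_design > 0 else np.nan
        beta = self.params.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = beta / se
        p = 2 * stats.t.sf(np.abs(tval), self.df_design) if self.df_design > 0 else np.full_like(beta, np.nan)
        self.summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "odds_ratio": np.exp(beta),
                "ci_low": np.exp(beta - tcrit * se),
                "ci_high": np.exp(beta + tcrit * se),
                "p_value": p,
            },
            index=self.params.index,
        )

    def term(self, name: str) -> pd.Series:
        """One row of the OR/CI/p summary (e.g. the exposure term)."""
        return self.summary.loc[name]


def _encode_column(df: pd.DataFrame, col: str) -> pd.DataFrame:
    """Numeric column → itself; categorical → dummy block, first level reference."""
    if col in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[col]
        values = df[col].astype(str)
        unknown = set(values.unique()) - set(levels)
        if unknown:
            raise ValueError(f"column {col!r} has unknown levels {sorted(unknown)}")
        return pd.DataFrame(
            {f"{col}[{lv}]": (values == lv).astype(float) for lv in levels[1:]},
            index=df.index,
        )
    return pd.DataFrame({col: pd.to_numeric(df[col]).astype(float)}, index=df.index)


def build_design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Intercept + exposure indicator + encoded covariates; returns (X, y)."""
    y = (cohort[spec.outcome].astype(str) == "memory_loss").to_numpy(float)
    blocks = [pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index)]
    blocks.append(
        pd.DataFrame(
            {spec.exposure: (cohort[spec.exposure].astype(str) == "exposed").astype(float)},
            index=cohort.index,
        )
    )
    for cov in spec.covariates:
        blocks.append(_encode_column(cohort, cov))
    X = pd.concat(blocks, axis=1)
    return X, y


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, int, float, float]:
    """Weighted logistic IRLS. Returns (beta, fitted p, iters, deviance, last change)."""
    n, k = X.shape
    beta = np.zeros(k)
    dev = np.inf
    change = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        wls = w * p * (1 - p)
        z = eta + (y - p) / (p * (1 - p))
        XtW = X.T * wls
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix: {err}") from err
        if np.abs(beta_new).max() > separation_bound:
            raise SeparationError(
                "diverging coefficients (|beta| > "
                f"{separation_bound}): possible complete separation"
            )
        beta = beta_new
        eta = X @ beta
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        new_dev = -2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))
        change = abs(dev - new_dev)
        dev = new_dev
        if change < tol:
            return beta, p, it, dev, change
    raise NonConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def linearized_covariance(
    scores: np.ndarray, design: SurveyDesign
) -> np.ndarray:
    """Between-PSU-within-stratum covariance of summed score contributions.

    ``scores`` is n×k; rows are per-record contributions (already weighted).
    Strata with a single PSU contribute zero under the certainty policy.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(design.weight):
        scores = scores.T
    k = scores.shape[1]
    G = np.zeros((k, k))
    for s in np.unique(design.stratum):
        in_s = design.stratum == s
        psus = np.unique(design.psu[in_s])
        n_h = len(psus)
        if n_h < 2:
            continue  # certainty unit
        totals = np.vstack(
            [scores[in_s & (design.psu == p)].sum(axis=0) for p in psus]
        )
        centered = totals - totals.mean(axis=0)
        G += (n_h / (n_h - 1)) * centered.T @ centered
    return G


def fit_weighted_logistic(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FitResult:
    """Design-based logistic regression.

    Raises :class:`DegenerateOutcomeError` if the outcome has one class,
    :class:`SeparationError` on diverging coefficients, and
    :class:`NonConvergenceError` past the iteration budget.
    """
    Xdf, y = build_design_matrix(cohort, spec)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome is single-class in this cohort")
    X = Xdf.to_numpy(float)
    w = design.weight
    beta, p, iters, dev, change = _irls(X, y, w, tol=tol, max_iter=max_iter)

    info = (X.T * (w * p * (1 - p))) @ X
    scores = (w * (y - p))[:, None] * X
    G = linearized_covariance(scores, design)
    Ainv = np.linalg.inv(info)
    V = Ainv @ G @ Ainv
    return FitResult(
        params=pd.Series(beta, index=Xdf.columns),
        cov=pd.DataFrame(V, index=Xdf.columns, columns=Xdf.columns),
        df_design=design.df_design,
        n_obs=len(y),
        iterations=iters,
        deviance=dev,
        final_deviance_change=change,
        converged=True,
        spec=spec,
    )


def model_series(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    tiers: tuple[str, ...] = ("model1", "model2", "model3"),
    outcome: str = "outcome",
    exposure: str = "exposure",
    drop_covariates: tuple[str, ...] = (),
) -> dict[str, FitResult]:
    """Fit the nested adjustment series and return one FitResult per tier."""
    return {
        tier: fit_weighted_logistic(
            cohort,
            design,
            ModelSpec(outcome=outcome, exposure=exposure, tier=tier,
                      drop_covariates=drop_covariates),
        )
        for tier in tiers
    }


def series_summary(fits: dict[str, FitResult], exposure: str = "exposure") -> pd.DataFrame:
    """Exposure row of each model, shaped like a model-series table."""
    rows = {}
    for tier, fit in fits.items():
        t = fit.term(exposure)
        rows[tier] = {
            "odds_ratio": t["odds_ratio"],
            "ci_low": t["ci_low"],
            "ci_high": t["ci_high"],
            "p_value": t["p_value"],
            "n": fit.n_obs,
        }
    return pd.DataFrame(rows).T


_STRATIFIERS: dict[str, tuple[str, str | None]] = {
    # name -> (column to group on, covariate to drop from its own tier)
    "gender": ("gender", "gender"),
    "age": ("age_group", "age"),
    "bmi": ("bmi_group", None),
    "smoking": ("smoking", None),
    "hypertension": ("hypertension", "hypertension"),
    "activity": ("moderate_activity", "moderate_activity"),
    "diabetes": ("diabetes", "diabetes"),
}


def _stratifier_values(cohort: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "age":
        return cohort["age"].map(age_bin)
    if stratifier == "bmi":
        return cohort["bmi"].map(bmi_bin)
    col = _STRATIFIERS[stratifier][0]
    return cohort[col].astype(str)


def subgroup_analysis(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    stratifier: str,
    tiers: tuple[str, ...] = ("model1", "model2", "model3"),
    min_size: int = 50,
) -> dict[str, dict[str, FitResult]]:
    """Refit the model series within each level of a stratifying variable.

    The stratifier is removed from its own covariate tier.  Levels with fewer
    than ``min_size`` records, or with a single outcome class, are skipped
    with a warning.
    """
    if stratifier not in _STRATIFIERS:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; choose from {sorted(_STRATIFIERS)}"
        )
    drop = _STRATIFIERS[stratifier][1]
    values = _stratifier_values(cohort, stratifier)
    levels = sorted(values.unique())
    if len(levels) == 1:
        warnings.warn(f"stratifier {stratifier!r} is constant; single stratum returned")
    out: dict[str, dict[str, FitResult]] = {}
    for level in levels:
        mask = (values == level).to_numpy()
        if mask.sum() < min_size:
            warnings.warn(f"subgroup {stratifier}={level}: n={mask.sum()} < {min_size}, skipped")
            continue
        sub = cohort.loc[mask].reset_index(drop=True)
        sub_design = design.subset(mask)
        fits: dict[str, FitResult] = {}
        for tier in tiers:
            try:
                fits[tier] = fit_weighted_logistic(
                    sub,
                    sub_design,
                    ModelSpec(tier=tier, drop_covariates=(drop,) if drop else ()),
                )
            except (DegenerateOutcomeError, SeparationError, NonConvergenceError) as err:
                warnings.warn(f"subgroup {stratifier}={level} {tier}: {err}; skipped")
        if fits:
            out[str(level)] = fits
    return out


def interaction_test(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    modifier: str,
    tier: str = "model3",
) -> float:
    """Wald p-value for exposure×modifier product terms added to the tier model.

    The product-term block is tested with an F reference
    ``F(q, df_design − q + 1)`` where q is the block size.
    """
    spec = ModelSpec(tier=tier)
    if modifier == spec.exposure:
        raise ValueError("modifier identical to exposure: product term is collinear")
    Xdf, y = build_design_matrix(cohort, spec)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome is single-class")
    if modifier in _STRATIFIERS and modifier not in cohort.columns:
        mod_block = _encode_column(
            cohort.assign(**{_STRATIFIERS[modifier][0]: _stratifier_values(cohort, modifier)}),
            _STRATIFIERS[modifier][0],
        )
    else:
        if modifier in ("age", "bmi"):
            mod_block = _encode_column(
                cohort.assign(**{f"{modifier}_group": _stratifier_values(cohort, modifier)}),
                f"{modifier}_group",
            )
        else:
            mod_block = _encode_column(cohort, modifier)
    exp_col = Xdf[spec.exposure].to_numpy()
    inter = mod_block.to_numpy(float) * exp_col[:, None]
    inter_names = [f"{spec.exposure}:{c}" for c in mod_block.columns]
    # main effects of the modifier must be present for a valid product test
    for c in mod_block.columns:
        if c not in Xdf.columns:
            Xdf[c] = mod_block[c].to_numpy()
    full = Xdf.copy()
    for name, col in zip(inter_names, inter.T):
        full[name] = col
    Xfull = full.to_numpy(float)
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError("rank-deficient design: interaction collinear with main effects")

    w = design.weight
    beta, p, *_ = _irls(Xfull, y, w)
    info = (Xfull.T * (w * p * (1 - p))) @ Xfull
    scores = (w * (y - p))[:, None] * Xfull
    G = linearized_covariance(scores, design)
    Ainv = np.linalg.inv(info)
    V = Ainv @ G @ Ainv
    idx = [full.columns.get_loc(n) for n in inter_names]
    b = beta[idx]
    Vbb = V[np.ix_(idx, idx)]
    q = len(idx)
    W = float(b @ np.linalg.solve(Vbb, b))
    df2 = design.df_design - q + 1
    if df2 <= 0:
        return float(stats.chi2.sf(W, q))
    F = W / q
    return float(stats.f.sf(F, q, df2))


# ---------------------------------------------------------------------------
# Weighted descriptives


def _domain_mean_influence(
    x: np.ndarray, dom: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Ratio-estimator domain mean and per-record influence values."""
    W = np.sum(w * dom)
    mu = np.sum(w * dom * x) / W
    z = w * dom * (x - mu) / W
    return mu, z


def weighted_descriptives(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    group: str = "outcome",
    continuous: tuple[str, ...] = ("age", "bmi", "sugar", "caffeine", "alcohol"),
    categorical: tuple[str, ...] = (
        "gender", "race", "education", "smoking",
        "hypertension", "diabetes", "moderate_activity", "exposure",
    ),
) -> pd.DataFrame:
    """Baseline-characteristics table by group.

    Continuous variables: weighted mean (weighted SD), design-adjusted Wald
    t-test on the two-group mean difference.  Categorical variables:
    unweighted counts with weighted percentages, design-adjusted Wald
    chi-square over the proportion-difference vector with a Thomas–Rao-style
    F reference (a Rao–Scott-type correction).  All statistics are invariant
    to rescaling the weights.
    """
    w = design.weight
    g = cohort[group].astype(str)
    glevels = sorted(g.unique())
    if len(glevels) != 2:
        raise ValueError("descriptives group comparison requires exactly 2 groups")
    doms = [(g == lv).to_numpy(float) for lv in glevels]
    df_des = design.df_design
    rows = []

    for col in continuous:
        x = pd.to_numeric(cohort[col]).to_numpy(float)
        cells = {}
        mus, zs = [], []
        for lv, dom in zip(glevels, doms):
            mu, z = _domain_mean_influence(x, dom, w)
            W = np.sum(w * dom)
            sd = np.sqrt(np.sum(w * dom * (x - mu) ** 2) / W)
            cells[lv] = f"{mu:.1f} ({sd:.1f})"
            mus.append(mu)
            zs.append(z)
        overall = np.sum(w * x) / np.sum(w)
        osd = np.sqrt(np.sum(w * (x - overall) ** 2) / np.sum(w))
        var = linearized_covariance((zs[0] - zs[1])[:, None], design)[0, 0]
        tstat = (mus[0] - mus[1]) / np.sqrt(var) if var > 0 else np.nan
        pval = 2 * stats.t.sf(abs(tstat), df_des) if np.isfinite(tstat) else np.nan
        rows.append(
            {
                "variable": col, "level": "", "overall": f"{overall:.1f} ({osd:.1f})",
                **cells, "p_value": pval,
            }
        )

    for col in categorical:
        v = cohort[col].astype(str)
        levels = sorted(v.unique())
        # stack influence of p-hat differences for the first L-1 levels
        dvec, zlist = [], []
        for lv in levels[:-1]:
            ind = (v == lv).to_numpy(float)
            m0, z0 = _domain_mean_influence(ind, doms[0], w)
            m1, z1 = _domain_mean_influence(ind, doms[1], w)
            dvec.append(m0 - m1)
            zlist.append(z0 - z1)
        dvec = np.array(dvec)
        Z = np.column_stack(zlist)
        V = linearized_covariance(Z, design)
        q = len(dvec)
        try:
            W_stat = float(dvec @ np.linalg.solve(V, dvec))
            df2 = df_des - q + 1
            pval = (
                float(stats.f.sf(W_stat / q, q, df2))
                if df2 > 0
                else float(stats.chi2.sf(W_stat, q))
            )
        except np.linalg.LinAlgError:
            pval = np.nan
        first = True
        for lv in levels:
            ind = (v == lv).to_numpy(float)
            cells = {}
            for glv, dom in zip(glevels, doms):
                count = int((ind * dom).sum())
                pct = 100 * np.sum(w * ind * dom) / np.sum(w * dom)
                cells[glv] = f"{count:,} ({pct:.1f}%)"
            opct = 100 * np.sum(w * ind) / np.sum(w)
            rows.append(
                {
                    "variable": col, "level": lv,
                    "overall": f"{int(ind.sum()):,} ({opct:.1f}%)",
                    **cells, "p_value": pval if first else np.nan,
                }
            )
            first = False
    return pd.DataFrame(rows)
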