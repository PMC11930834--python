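"""Post-fit robustness checks: E-values and ROC/AUC.

The E-value is the minimum strength of association, on the risk-ratio scale,
that an unmeasured confounder would need with both exposure and outcome to
explain away an observed association:  E = RR + sqrt(RR · (RR − 1)).
Odds ratios are first moved to the risk-ratio scale (identity for a rare
outcome, square-root for a common one) and protective estimates are
reciprocated onto the ≥ 1 scale.

AUC uses the rank (Mann–Whitney) formulation with half-credit for ties; its
confidence interval comes from the DeLong placement-value variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = ["EValueResult", "RocResult", "evalue", "predicted_scores", "roc_auc"]


@dataclass(frozen=True)
class EValueResult:
    evalue_point: float
    evalue_ci: float
    conversion: str  # "rare-outcome" or "square-root"
    rr_point: float  # risk-ratio-scale estimate after reciprocation


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    se: float


def _evalue_from_rr(rr: float) -> float:
    """Closed form for RR >= 1."""
    if rr <= 1.0:
        return 1.0
    return rr + np.sqrt(rr * (rr - 1.0))


def evalue(
    or_point: float,
    ci: tuple[float, float],
    outcome_common: bool = False,
) -> EValueResult:
    """E-value for an odds ratio and its confidence interval.

    ``outcome_common=False`` treats the OR as a risk ratio (rare-outcome
    approximation); ``True`` applies the square-root conversion.  The CI
    E-value is computed on the limit nearer the null and set to 1 when the
    interval crosses 1.
    """
    lo, hi = ci
    if or_point <= 0 or lo <= 0 or hi <= 0:
        raise ValueError("odds ratios and CI limits must be positive")
    if not lo <= or_point <= hi:
        raise ValueError(f"point estimate {or_point} outside CI ({lo}, {hi})")
    conv = "square-root" if outcome_common else "rare-outcome"

    def to_rr(x: float) -> float:
        return float(np.sqrt(x)) if outcome_common else float(x)

    protective = or_point < 1.0
    rr = to_rr(1.0 / or_point) if protective else to_rr(or_point)
    point = _evalue_from_rr(rr)
    if lo <= 1.0 <= hi:
        ci_e = 1.0
    else:
        # limit closer to the null, reciprocated for protective estimates
        limit = 1.0 / hi if protective else lo
        ci_e = _evalue_from_rr(to_rr(limit))
    return EValueResult(
        evalue_point=float(point), evalue_ci=float(ci_e), conversion=conv, rr_point=rr
    )


def predicted_scores(fit, cohort: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor per record.

    ``fit`` is a :class:`pharmepi.surveystats.FitResult`; the cohort must
    contain the columns the model was built from.
    """
    from .surveystats import build_design_matrix

    if fit.spec is None:
        raise ValueError("fit carries no model spec")
    try:
        Xdf, _ = build_design_matrix(cohort, fit.spec)
    except KeyError as err:
        raise ValueError(f"cohort is missing model column: {err}") from err
    if list(Xdf.columns) != list(fit.params.index):
        raise ValueError(
            "cohort columns do not reproduce the fitted design matrix: "
            f"{list(Xdf.columns)} vs {list(fit.params.index)}"
        )
    eta = Xdf.to_numpy(float) @ fit.params.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
) -> RocResult:
    """AUC with a DeLong confidence interval.

    ``labels`` are 0/1 (or boolean).  With ``weights``, placements are
    weight-averaged and the variance uses weighted placement dispersion with
    effective sample sizes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = labels == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if weights is None:
        w = np.ones(len(scores))
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")

    # mid-rank placements: for each positive, the (weighted) fraction of
    # negatives scoring below it, ties counted half
    order_all = rankdata(scores, method="average")
    rank_within_pos = rankdata(scores[pos], method="average")
    rank_within_neg = rankdata(scores[neg], method="average")
    if weights is None:
        # placement of each positive among negatives and vice versa
        v10 = (order_all[pos] - rank_within_pos) / n_neg
        v01 = 1.0 - (order_all[neg] - rank_within_neg) / n_pos
        auc = float(v10.mean())
        s10 = v10.var(ddof=1) if n_pos > 1 else 0.0
        s01 = v01.var(ddof=1) if n_neg > 1 else 0.0
        var = s10 / n_pos + s01 / n_neg
        npos_eff, nneg_eff = n_pos, n_neg
    else:
        sp, sn = scores[pos], scores[neg]
        wp, wn = w[pos], w[neg]
        # O(n log n) weighted placements via sorted cumulative weights
        v10 = _weighted_placements(sp, sn, wn)
        v01 = 1.0 - _weighted_placements(sn, sp, wp)
        Wp, Wn = wp.sum(), wn.sum()
        auc = float(np.sum(wp * v10) / Wp)
        npos_eff = Wp**2 / np.sum(wp**2)
        nneg_eff = Wn**2 / np.sum(wn**2)
        s10 = np.sum(wp * (v10 - auc) ** 2) / Wp * npos_eff / max(npos_eff - 1, 1)
        mu01 = np.sum(wn * v01) / Wn
        s01 = np.sum(wn * (v01 - mu01) ** 2) / Wn * nneg_eff / max(nneg_eff - 1, 1)
        var = s10 / npos_eff + s01 / nneg_eff
    se = float(np.sqrt(var))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - zcrit * se)
    hi = min(1.0, auc + zcrit * se)
    return RocResult(auc=auc, ci=(float(lo), float(hi)), n_pos=n_pos, n_neg=n_neg, se=se)


def _weighted_placements(x: np.ndarray, ref: np.ndarray, ref_w: np.ndarray) -> np.ndarray:
    """For each x, weighted fraction of ref strictly below plus half the ties."""
    order = np.argsort(ref, kind="mergesort")
    rs, rw = ref[order], ref_w[order]
    cum = np.concatenate([[0.0], np.cumsum(rw)])
    total = cum[-1]
    below = cum[np.searchsorted(rs, x, side="left")]
    upto = cum[np.searchsorted(rs, x, side="right")]
    return (below + 0.5 * (upto - below)) / total
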