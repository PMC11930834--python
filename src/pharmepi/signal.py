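"""Spontaneous-report disproportionality analysis: ROR and BCPNN IC025.

For each adverse-event term a fourfold table is built against the target-drug
flag:

=============  ===========  ===========
cell           target drug  other drugs
=============  ===========  ===========
target event   a            c
other events   b            d
=============  ===========  ===========

Two measures are computed per term and combined into a dual-criterion rule:

* the reporting odds ratio ROR = (a·d)/(b·c) with the log-normal 95% CI
  exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)); signal requires a ≥ 3 and
  CI lower limit > 1;
* the Bayesian confidence propagation neural network (BCPNN) information
  component, IC = log2 of the ratio of observed to expected joint reporting
  probability under a shrinkage prior, flagged when its lower credibility
  bound IC025 = E(IC) − 2·SD(IC) exceeds 0.

A term is a signal only when both rules fire.

Two evaluation methods are available for the IC moments.  ``approx`` is the
classic closed form (log of ratios of posterior means and the matching
three-term variance); it is the conventional screening statistic and the
default.  ``exact`` evaluates the true posterior mean and variance of
log2(p11/(p1·p2)) with digamma/trigamma functions under the same independent
Beta posteriors; the two agree in the large-count limit, but the closed form
is biased upward by roughly 1/(2·a·ln 2) bits when a is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "BcpnnPriors",
    "build_contingency",
    "ror",
    "bcpnn_ic",
    "flag_signal",
    "screen_all_terms",
    "ZeroCellError",
]

_LN2 = np.log(2.0)


class ZeroCellError(ValueError):
    """A fourfold-table cell is zero and no continuity correction was requested."""


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold drug×event table (a, b, c, d); N = a+b+c+d."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, add: float = 0.5) -> "ContingencyTable":
        """Haldane continuity correction: add to every cell."""
        return ContingencyTable(self.a + add, self.b + add, self.c + add, self.d + add)


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN shrinkage prior (standard defaults)."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, table: ContingencyTable) -> float:
        """Data-dependent joint prior total keeping the prior IC centred on 0."""
        t, N = table, table.n
        return (
            self.gamma11
            * (N + self.alpha)
            * (N + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


@dataclass
class SignalResult:
    event_term: str
    a: int
    n_drug: int
    ror: float
    ror_ci: tuple[float, float]
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    ror_flag: bool
    bcpnn_flag: bool
    signal: bool
    corrected: bool = False  # Haldane correction applied to the ROR


def build_contingency(reports: pd.DataFrame, event_term: str) -> ContingencyTable:
    """Count the fourfold table for one event term.

    ``reports`` must carry ``is_target_drug`` (bool) and ``event_term``
    columns; each row is one report.
    """
    if reports is None or len(reports) == 0:
        raise ValueError("empty report table")
    drug = reports["is_target_drug"].to_numpy(bool)
    ev = (reports["event_term"].astype(str) == event_term).to_numpy()
    a = int((drug & ev).sum())
    b = int((drug & ~ev).sum())
    c = int((~drug & ev).sum())
    d = int((~drug & ~ev).sum())
    return ContingencyTable(a, b, c, d)


def ror(
    table: ContingencyTable, haldane: bool = False, z: float = 1.96
) -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal confidence interval.

    Raises :class:`ZeroCellError` on zero cells unless ``haldane`` enables the
    +0.5 continuity correction.
    """
    t = table
    if min(t.a, t.b, t.c, t.d) == 0:
        if not haldane:
            raise ZeroCellError(
                f"zero cell in ({t.a}, {t.b}, {t.c}, {t.d}); "
                "enable the Haldane correction to proceed"
            )
        t = t.corrected()
    if t.b * t.c == 0 or t.a * t.d == 0:
        raise ZeroCellError("degenerate table after correction")
    est = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = float(np.exp(np.log(est) - z * se))
    hi = float(np.exp(np.log(est) + z * se))
    return float(est), lo, hi


def bcpnn_ic(
    table: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    method: str = "approx",
) -> tuple[float, float, float, float]:
    """Information component moments: returns (ic, e_ic, v_ic, ic025).

    ``method='approx'`` uses the conventional closed forms; ``'exact'`` the
    digamma/trigamma posterior moments (see module docstring).  ``ic`` is
    reported as E(IC) and ``ic025 = E(IC) − 2·sqrt(V(IC))``.
    """
    t, pr = table, priors
    N = t.n
    g = pr.gamma(t)
    s11 = t.a + pr.gamma11
    s1 = t.a + t.b + pr.alpha1
    s2 = t.a + t.c + pr.beta1
    if method == "approx":
        e_ic = np.log2(s11 * (N + pr.alpha) * (N + pr.beta) / ((N + g) * s1 * s2))
        v_ic = (
            (N - t.a + g - pr.gamma11) / (s11 * (1 + N + g))
            + (N - t.a - t.b + pr.alpha - pr.alpha1) / (s1 * (1 + N + pr.alpha))
            + (N - t.a - t.c + pr.beta - pr.beta1) / (s2 * (1 + N + pr.beta))
        ) / _LN2**2
    elif method == "exact":
        e_ic = (
            psi(s11) - psi(N + g)
            - psi(s1) + psi(N + pr.alpha)
            - psi(s2) + psi(N + pr.beta)
        ) / _LN2
        v_ic = (
            polygamma(1, s11) - polygamma(1, N + g)
            + polygamma(1, s1) - polygamma(1, N + pr.alpha)
            + polygamma(1, s2) - polygamma(1, N + pr.beta)
        ) / _LN2**2
    else:
        raise ValueError(f"unknown method {method!r}")
    e_ic = float(e_ic)
    v_ic = float(v_ic)
    ic025 = e_ic - 2.0 * np.sqrt(v_ic)
    return e_ic, e_ic, v_ic, float(ic025)


def flag_signal(
    ror_result: tuple[float, float, float],
    ic_result: tuple[float, float, float, float],
    a: int,
    min_a: int = 3,
    ror_ci_bound: float = 1.0,
    ic025_cut: float = 0.0,
    event_term: str = "",
    n_drug: int = 0,
    corrected: bool = False,
) -> SignalResult:
    """Apply the dual-criterion rule: both ROR and BCPNN thresholds must pass."""
    est, lo, hi = ror_result
    ic, e_ic, v_ic, ic025 = ic_result
    ror_flag = bool(a >= min_a and lo > ror_ci_bound)
    bcpnn_flag = bool(ic025 > ic025_cut)
    return SignalResult(
        event_term=event_term,
        a=int(a),
        n_drug=int(n_drug),
        ror=est,
        ror_ci=(lo, hi),
        ic=ic,
        e_ic=e_ic,
        v_ic=v_ic,
        ic025=ic025,
        ror_flag=ror_flag,
        bcpnn_flag=bcpnn_flag,
        signal=ror_flag and bcpnn_flag,
        corrected=corrected,
    )


def screen_all_terms(
    reports: pd.DataFrame,
    haldane: bool = False,
    min_a: int = 3,
    priors: BcpnnPriors = BcpnnPriors(),
    ic_method: str = "approx",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every event term and rank by IC025 (descending).

    Returns ``(signals, composition)``: one row per term with counts, ROR,
    CI, IC moments and flags; and a composition table of target-drug report
    counts and percentages per term.  Terms whose table has a zero cell get
    a NaN ROR (with ``ror_flag`` False) unless ``haldane`` is set.
    """
    if reports is None or len(reports) == 0:
        raise ValueError("empty report table")
    drug = reports["is_target_drug"].to_numpy(bool)
    n_drug = int(drug.sum())
    counts = (
        reports.assign(is_target_drug=drug)
        .groupby(["event_term", "is_target_drug"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[True, False], fill_value=0)
    )
    total = len(reports)
    results = []
    for term in counts.index:
        a = int(counts.loc[term, True])
        c = int(counts.loc[term, False])
        table = ContingencyTable(a, n_drug - a, c, total - n_drug - c)
        try:
            ror_res = ror(table, haldane=haldane)
            corrected = haldane and min(table.a, table.b, table.c, table.d) == 0
        except ZeroCellError:
            ror_res = (np.nan, np.nan, np.nan)
            corrected = False
        ic_res = bcpnn_ic(table, priors=priors, method=ic_method)
        res = flag_signal(
            ror_res, ic_res, a, min_a=min_a,
            event_term=str(term), n_drug=n_drug, corrected=corrected,
        )
        if np.isnan(ror_res[0]):
            res.ror_flag = False
            res.signal = False
        results.append(res)
    results.sort(key=lambda r: r.ic025, reverse=True)
    signals = pd.DataFrame(
        {
            "event_term": [r.event_term for r in results],
            "a": [r.a for r in results],
            "ror": [r.ror for r in results],
            "ror_ci_low": [r.ror_ci[0] for r in results],
            "ror_ci_high": [r.ror_ci[1] for r in results],
            "e_ic": [r.e_ic for r in results],
            "v_ic": [r.v_ic for r in results],
            "ic025": [r.ic025 for r in results],
            "ror_flag": [r.ror_flag for r in results],
            "bcpnn_flag": [r.bcpnn_flag for r in results],
            "signal": [r.signal for r in results],
            "haldane_corrected": [r.corrected for r in results],
        }
    )
    comp = signals[["event_term", "a"]].copy()
    comp["drug_report_pct"] = 100.0 * comp["a"] / max(n_drug, 1)
    comp = comp.sort_values("a", ascending=False).reset_index(drop=True)
    return signals, comp
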