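"""Discrimination and calibration machinery for the risk equations:
Harrell's C for censored data, Gronnesby-Borgan expected event counts
(observed minus martingale residual = model cumulative hazard over the
at-risk interval), and the modified Hosmer-Lemeshow chi-square over
deciles of predicted risk."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .equations import RiskEquation

__all__ = [
    "ConcordanceResult",
    "HLResult",
    "ValidationReport",
    "harrell_c",
    "interval_cumulative_hazard",
    "expected_events",
    "modified_hl_test",
    "validate_predictions",
]

_DF_OFFSET = {"fitted": 2, "conservative": 1, "external": 0}


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with a jackknife (Noether-type) confidence interval.

    The CI method for the published statistic is unstated at source, so
    the method used here is recorded in ``ci_method``.
    """

    c: float
    se: float
    ci: tuple[float, float]
    n_pairs: int
    n_concordant: float
    n_tied: int
    ci_method: str = "leave-one-out jackknife"


def harrell_c(scores, times, events, level=0.95) -> ConcordanceResult:
    """Censoring-aware concordance of risk scores with event times.

    A pair is comparable when the subject with the shorter follow-up had
    an event (tied times count when exactly one member had an event).
    Concordant pairs are those where the earlier-failing subject has the
    higher score; score ties count one half.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must have equal length")
    n = len(scores)
    # pairwise comparison in row blocks: O(n^2) time, O(block*n) memory
    U = 0.0
    M = 0
    total_conc = 0.0
    total_tied = 0
    u_k = np.zeros(n)
    m_k = np.zeros(n, dtype=np.int64)
    block = 512
    for start in range(0, n, block):
        idx = np.arange(start, min(start + block, n))
        t_i = times[idx, None]
        # comparable with i as the earlier-failing member
        comp = events[idx, None] & ((t_i < times) | ((t_i == times) & ~events))
        comp[idx - start, idx] = False
        conc = comp & (scores[idx, None] > scores)
        tied = comp & (scores[idx, None] == scores)
        W = conc + 0.5 * tied
        U += float(W.sum())
        M += int(comp.sum())
        total_conc += float(conc.sum())
        total_tied += int(tied.sum())
        u_k[idx] += W.sum(axis=1)
        u_k += W.sum(axis=0)
        m_k[idx] += comp.sum(axis=1)
        m_k += comp.sum(axis=0)
    if M == 0:
        raise ValueError("no comparable pairs (check censoring pattern)")
    c = U / M
    keep = m_k < M
    c_loo = np.full(n, c)
    c_loo[keep] = (U - u_k[keep]) / (M - m_k[keep])
    var = (n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)
    se = float(np.sqrt(var))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    ci = (max(0.0, c - z * se), min(1.0, c + z * se))
    return ConcordanceResult(
        c=float(c), se=se, ci=ci, n_pairs=M,
        n_concordant=total_conc, n_tied=total_tied,
    )


def interval_cumulative_hazard(eq: RiskEquation, data: pd.DataFrame) -> np.ndarray:
    """Per-row model cumulative hazard over [entry, exit).

    Vectorised piecewise closed form across step time thresholds;
    row-wise quadrature when the equation has continuous time terms.
    """
    entry = data["entry"].to_numpy(dtype=float)
    exit_ = data["exit"].to_numpy(dtype=float)
    if (entry < 0).any() or (entry > exit_).any():
        raise ValueError("need 0 <= entry <= exit in every row")
    if any(tt.form == "linear" for tt in eq.time_terms):
        return np.array(
            [eq.cumulative_hazard(row, a, b)
             for (_, row), a, b in zip(data.iterrows(), entry, exit_)]
        )
    p = eq.shape
    lp0 = np.asarray(eq._static_lp(data), dtype=float)
    steps = [tt for tt in eq.time_terms if tt.form == "step"]
    bounds = [0.0] + sorted({tt.threshold for tt in steps}) + [np.inf]
    H = np.zeros(len(data))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        a = np.clip(entry, lo, hi)
        b = np.clip(exit_, lo, hi)
        mask = b > a
        if not mask.any():
            continue
        mid = lo + 1.0 if np.isinf(hi) else 0.5 * (lo + hi)
        s = 0.0
        for tt in steps:
            s = s + tt.contribution(data, mid)
        s = np.broadcast_to(np.asarray(s, dtype=float), H.shape)
        H[mask] += np.exp(lp0[mask] + s[mask]) * (b[mask] ** p - a[mask] ** p)
    return H


def expected_events(eq: RiskEquation, data: pd.DataFrame):
    """Gronnesby-Borgan expected event count per subject.

    ``expected_i = observed_i - martingale_i`` equals the model
    cumulative hazard over the subject's at-risk intervals; summing the
    per-interval hazard realises that identity on counting-process data.
    Returns a Series indexed by ``patient_id`` when that column is
    present, else a per-row array.
    """
    dH = interval_cumulative_hazard(eq, data)
    if "patient_id" in data.columns:
        return pd.Series(dH, index=data["patient_id"]).groupby(level=0).sum()
    return dH


@dataclass(frozen=True)
class HLResult:
    """Modified Hosmer-Lemeshow calibration test over risk-score groups."""

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    convention: str


def modified_hl_test(scores, observed, expected, n_groups=10,
                     df_convention="fitted") -> HLResult:
    """Grouped observed-versus-expected chi-square calibration test.

    Subjects are grouped into ``n_groups`` near-equal-count groups by
    predicted risk score (ties broken by stable input order); the
    statistic is ``sum (O_g - E_g)^2 / E_g``.  Groups with zero expected
    events are merged into their upper neighbour.  The degrees of
    freedom follow ``df_convention``: ``fitted`` (g - 2, the D'Agostino
    convention for a model estimated on the evaluated data),
    ``conservative`` (g - 1), or ``external`` (g, for a model specified
    independently of the evaluated data).
    """
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if not (len(scores) == len(observed) == len(expected)):
        raise ValueError("scores, observed and expected must have equal length")
    if n_groups < 3:
        raise ValueError("need at least 3 groups")
    if df_convention not in _DF_OFFSET:
        raise ValueError(f"unknown df convention {df_convention!r}")
    order = np.argsort(scores, kind="stable")
    groups = [g for g in np.array_split(order, n_groups) if len(g)]
    rows = [
        {"group": i + 1, "n": len(g),
         "mean_score": float(scores[g].mean()),
         "observed": float(observed[g].sum()),
         "expected": float(expected[g].sum())}
        for i, g in enumerate(groups)
    ]
    merged = []
    for row in rows:  # merge empty-expected groups upward
        if merged and merged[-1]["expected"] <= 0:
            last = merged.pop()
            row = {"group": last["group"], "n": last["n"] + row["n"],
                   "mean_score": row["mean_score"],
                   "observed": last["observed"] + row["observed"],
                   "expected": last["expected"] + row["expected"]}
        merged.append(row)
    if merged and merged[-1]["expected"] <= 0 and len(merged) > 1:
        last = merged.pop()
        merged[-1]["n"] += last["n"]
        merged[-1]["observed"] += last["observed"]
        merged[-1]["expected"] += last["expected"]
    if len(merged) < 3 or any(r["expected"] <= 0 for r in merged):
        raise ValueError("too few groups with positive expected counts")
    table = pd.DataFrame(merged)
    stat = float((((table["observed"] - table["expected"]) ** 2) / table["expected"]).sum())
    df = max(len(merged) - _DF_OFFSET[df_convention], 1)
    return HLResult(
        statistic=stat, df=df, p_value=float(chi2.sf(stat, df)),
        table=table, convention=df_convention,
    )


@dataclass
class ValidationReport:
    """Discrimination + calibration summary for one equation/process."""

    concordance: ConcordanceResult
    hl: HLResult
    n: int
    n_events: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_events": self.n_events,
            "c_statistic": self.concordance.c,
            "c_se": self.concordance.se,
            "c_ci": list(self.concordance.ci),
            "c_ci_method": self.concordance.ci_method,
            "hl_statistic": self.hl.statistic,
            "hl_df": self.hl.df,
            "hl_p_value": self.hl.p_value,
            "hl_df_convention": self.hl.convention,
            "deciles": self.hl.table.to_dict("records"),
            "metadata": self.metadata,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def validate_predictions(scores, times, events, expected, n_groups=10,
                         df_convention="fitted", metadata=None) -> ValidationReport:
    """Assemble a validation report from per-subject risk scores,
    follow-up times, event indicators and model-expected event counts."""
    conc = harrell_c(scores, times, events)
    observed = np.asarray(events, dtype=float)
    hl = modified_hl_test(scores, observed, expected,
                          n_groups=n_groups, df_convention=df_convention)
    return ValidationReport(
        concordance=conc, hl=hl, n=len(np.asarray(scores)),
        n_events=int(observed.sum()), metadata=dict(metadata or {}),
    )
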