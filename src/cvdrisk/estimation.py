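"""Maximum-likelihood estimation of Weibull proportional-hazards models
on counting-process data.

The likelihood handles delayed entry (left truncation), right censoring
and piecewise-constant (annually updated) covariates through the
standard counting-process decomposition: a subject contributes, for each
interval [t0, t1) with covariate vector x,

    event * [log p + (p - 1) log t1 + x'beta]  -  exp(x'beta) (t1^p - t0^p)

with the event term only on intervals that end in an event.  The shape
is parameterised as log(p) for unconstrained optimisation; standard
errors come from the inverse observed information (numerical Hessian of
the analytic score).  Second-event (gap-time) data are fitted exactly
the same way on their own time scale, which realises the
Prentice-Williams-Peterson stratification as separate first/second fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .equations import (
    CONTINUOUS_COVARIATES,
    EquationConfigError,
    InteractionTerm,
    RiskEquation,
    SplineTerm,
    TimeTerm,
    spline_transform,
)

__all__ = [
    "SurvivalInterval",
    "CountingProcessError",
    "ModelSpec",
    "FitResult",
    "read_counting_process",
    "design_matrix",
    "weibull_ph_loglik",
    "weibull_ph_score",
    "fit",
    "backward_select",
]

REQUIRED_COLUMNS = ("patient_id", "entry", "exit", "event")


@dataclass(frozen=True)
class SurvivalInterval:
    """One counting-process record on a stated time scale."""

    patient_id: int
    entry: float
    exit: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.entry < self.exit:
            raise ValueError(
                f"invalid interval for patient {self.patient_id}: "
                f"[{self.entry}, {self.exit})"
            )
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


class CountingProcessError(ValueError):
    """Counting-process data violate the format contract."""


def read_counting_process(path_or_df, covariates=None) -> pd.DataFrame:
    """Read and validate counting-process data (CSV path or DataFrame).

    Checks column presence, ``0 <= entry < exit``, 0/1 event flags, and
    that each patient's intervals abut without overlap after canonical
    (patient, entry) sorting.  Violations are reported with the
    offending row numbers of the input.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CountingProcessError(f"missing required columns: {missing}")
    if covariates:
        absent = [c for c in covariates if c not in df.columns]
        if absent:
            raise CountingProcessError(f"missing covariate columns: {absent}")
    for col in ("entry", "exit"):
        bad = df.index[~np.isfinite(df[col])].tolist()
        if bad:
            raise CountingProcessError(f"non-finite {col!r} at rows {bad[:10]}")
    bad = df.index[(df["entry"] < 0) | (df["entry"] >= df["exit"])].tolist()
    if bad:
        raise CountingProcessError(
            f"intervals must satisfy 0 <= entry < exit; violated at rows {bad[:10]}"
        )
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])].tolist()
        raise CountingProcessError(f"event flag must be 0/1; violated at rows {bad[:10]}")
    df["_row"] = df.index
    df = df.sort_values(["patient_id", "entry"], kind="stable")
    same = df["patient_id"].to_numpy()[1:] == df["patient_id"].to_numpy()[:-1]
    gap = df["entry"].to_numpy()[1:] - df["exit"].to_numpy()[:-1]
    overlap = same & (gap < -1e-9)
    hole = same & (gap > 1e-9)
    if overlap.any():
        i = int(np.argmax(overlap))
        r0, r1 = df["_row"].to_numpy()[i], df["_row"].to_numpy()[i + 1]
        raise CountingProcessError(f"overlapping intervals at rows {r0} and {r1}")
    if hole.any():
        i = int(np.argmax(hole))
        r0, r1 = df["_row"].to_numpy()[i], df["_row"].to_numpy()[i + 1]
        raise CountingProcessError(f"gap between intervals at rows {r0} and {r1}")
    return df.drop(columns="_row").reset_index(drop=True)


@dataclass
class ModelSpec:
    """Structure of a Weibull PH model: which terms enter the linear
    predictor, mirroring the equation config minus coefficient values.

    Continuous covariates are mean-centred; ``None`` centering constants
    are filled from the data at design-matrix time and recorded in the
    fit result.  Step-form time terms are supported provided no data
    interval straddles the threshold; continuous covariate-by-time
    products are not estimable with this closed-form likelihood.
    """

    terms: list[str] = field(default_factory=list)
    splines: list[SplineTerm] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    step_time_terms: list[tuple[str | None, float]] = field(default_factory=list)
    centering: dict[str, float | None] = field(default_factory=dict)
    event: str = "ami"
    order: str = "first"

    @classmethod
    def from_equation(cls, eq: RiskEquation) -> "ModelSpec":
        if any(tt.form == "linear" for tt in eq.time_terms):
            raise EquationConfigError(
                f"{eq.key}: continuous covariate-by-time terms are not supported "
                "by the estimation module"
            )
        return cls(
            terms=sorted(eq.coefficients),
            splines=list(eq.splines),
            interactions=[tuple(it.covariates) for it in eq.interactions],
            step_time_terms=[(tt.covariate, tt.threshold) for tt in eq.time_terms],
            centering=dict(eq.centering),
            event=eq.event,
            order=eq.order,
        )

    def column_names(self) -> list[str]:
        names = ["constant"] + list(self.terms)
        for s in self.splines:
            names += [f"{s.covariate}<= {s.knot:g}", f"{s.covariate}>{s.knot:g}"]
        names += ["*".join(pair) for pair in self.interactions]
        for cov, thr in self.step_time_terms:
            names.append(f"{cov or 'baseline'}*t>{thr:g}")
        return names


def design_matrix(data: pd.DataFrame, spec: ModelSpec):
    """Build the (n_intervals, k) design matrix.

    Returns ``(X, names, centering_used)``.  Raises on rank deficiency,
    naming the collinear columns, and on intervals straddling a step
    threshold.
    """
    n = len(data)
    cols, names = [], spec.column_names()
    centering_used = dict(spec.centering)
    cols.append(np.ones(n))

    def centred(name):
        x = data[name].to_numpy(dtype=float)
        if name in CONTINUOUS_COVARIATES:
            c = centering_used.get(name)
            if c is None:
                c = float(x.mean())
                centering_used[name] = c
            return x - c
        return x

    for name in spec.terms:
        if name not in data.columns:
            raise CountingProcessError(f"data has no covariate column {name!r}")
        cols.append(centred(name))
    for s in spec.splines:
        low, high = spline_transform(data[s.covariate].to_numpy(dtype=float), s.knot)
        cols.append(low - s.center_low)
        cols.append(high - s.center_high)
    for a, b in spec.interactions:
        cols.append(centred(a) * centred(b))
    entry = data["entry"].to_numpy(dtype=float)
    exit_ = data["exit"].to_numpy(dtype=float)
    for cov, thr in spec.step_time_terms:
        straddle = (entry < thr - 1e-9) & (exit_ > thr + 1e-9)
        if straddle.any():
            raise CountingProcessError(
                f"intervals straddle the time threshold {thr} at rows "
                f"{data.index[straddle].tolist()[:10]}; split them first"
            )
        ind = (0.5 * (entry + exit_) > thr).astype(float)
        cols.append(ind if cov is None else ind * data[cov].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        dep = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {dep or names}"
        )
    return X, names, centering_used


def weibull_ph_loglik(params, X, entry, exit_, event):
    """Log-likelihood at ``params = (beta..., log p)``."""
    beta, logp = params[:-1], params[-1]
    p = np.exp(logp)
    lp = X @ beta
    H = np.exp(lp) * (exit_**p - entry**p)
    ll = event @ (logp + (p - 1.0) * np.log(exit_) + lp) - H.sum()
    return float(ll)


def weibull_ph_score(params, X, entry, exit_, event):
    """Analytic gradient of :func:`weibull_ph_loglik`."""
    beta, logp = params[:-1], params[-1]
    p = np.exp(logp)
    lp = X @ beta
    elp = np.exp(lp)
    dH = elp * (exit_**p - entry**p)
    g_beta = X.T @ (event - dH)
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = np.where(entry > 0, entry**p * np.log(entry), 0.0)
    dll_dp = event @ (1.0 / p + np.log(exit_)) - elp @ (exit_**p * np.log(exit_) - e0)
    return np.append(g_beta, p * dll_dp)


def _numeric_hessian(params, X, entry, exit_, event, h=1e-5):
    k = len(params)
    H = np.empty((k, k))
    for j in range(k):
        step = h * max(1.0, abs(params[j]))
        up, dn = params.copy(), params.copy()
        up[j] += step
        dn[j] -= step
        gu = weibull_ph_score(up, X, entry, exit_, event)
        gd = weibull_ph_score(dn, X, entry, exit_, event)
        H[:, j] = (gu - gd) / (2 * step)
    return 0.5 * (H + H.T)


@dataclass
class FitResult:
    """Estimates and diagnostics from a Weibull PH fit."""

    params: dict[str, float]
    shape: float
    se: dict[str, float]
    shape_se: float
    loglik: float
    converged: bool
    n_iter: int
    n_events: int
    n_intervals: int
    names: list[str]
    covariance: np.ndarray
    centering: dict[str, float]
    spec: ModelSpec

    def confint(self, level=0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        rows = []
        for name in self.names:
            est, se = self.params[name], self.se[name]
            rows.append({"term": name, "estimate": est, "se": se,
                         "lower": est - z * se, "upper": est + z * se})
        rows.append({"term": "shape", "estimate": self.shape, "se": self.shape_se,
                     "lower": self.shape * np.exp(-z * self.shape_se / self.shape),
                     "upper": self.shape * np.exp(z * self.shape_se / self.shape)})
        return pd.DataFrame(rows).set_index("term")

    def to_equation(self) -> RiskEquation:
        """Package the fit as a risk equation usable by the engine."""
        spec = self.spec
        splines = []
        for s in spec.splines:
            splines.append(
                replace(
                    s,
                    coef_low=self.params[f"{s.covariate}<= {s.knot:g}"],
                    coef_high=self.params[f"{s.covariate}>{s.knot:g}"],
                )
            )
        time_terms = [
            TimeTerm(coefficient=self.params[f"{cov or 'baseline'}*t>{thr:g}"],
                     covariate=cov, form="step", threshold=thr)
            for cov, thr in spec.step_time_terms
        ]
        interactions = [
            InteractionTerm(tuple(pair), self.params["*".join(pair)])
            for pair in spec.interactions
        ]
        return RiskEquation(
            event=spec.event,
            order=spec.order,
            constant=self.params["constant"],
            shape=self.shape,
            coefficients={t: self.params[t] for t in spec.terms},
            splines=splines,
            interactions=interactions,
            time_terms=time_terms,
            centering={k: v for k, v in self.centering.items()
                       if k in CONTINUOUS_COVARIATES},
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "shape": self.shape,
            "se": self.se,
            "shape_se": self.shape_se,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_events": self.n_events,
            "n_intervals": self.n_intervals,
            "centering": self.centering,
        }


def fit(data, spec: ModelSpec, start=None, gtol=1e-6, maxiter=500) -> FitResult:
    """Fit a Weibull PH model to counting-process data by maximum
    likelihood.

    Quasi-Newton (BFGS) on ``(beta, log p)`` with the analytic score,
    polished by Newton steps using the observed information until the
    score's infinity norm drops below ``gtol`` (absolute, on the score
    scale).  Standard errors are from the inverse observed information.
    Non-convergence is flagged on the result, never silent.
    """
    df = read_counting_process(data, covariates=spec.terms)
    if df["event"].sum() < 1:
        raise ValueError("data contain no events")
    X, names, centering_used = design_matrix(df, spec)
    entry = df["entry"].to_numpy(dtype=float)
    exit_ = df["exit"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float)
    if (event.astype(bool) & (exit_ <= 0)).any():
        raise CountingProcessError("an event is flagged at time 0")

    if start is None:
        # start the intercept at the exponential-rate MLE (p = 1) so the
        # first quasi-Newton step stays in a numerically sane region
        x0 = np.zeros(X.shape[1] + 1)
        rate = max(event.sum() / max((exit_ - entry).sum(), 1e-12), 1e-12)
        x0[0] = np.log(rate)
    else:
        x0 = np.asarray(start, dtype=float)

    def nll(params):
        with np.errstate(over="ignore", invalid="ignore"):
            v = -weibull_ph_loglik(params, X, entry, exit_, event)
        return v if np.isfinite(v) else 1e300

    def grad(params):
        with np.errstate(over="ignore", invalid="ignore"):
            g = -weibull_ph_score(params, X, entry, exit_, event)
        return np.nan_to_num(g, nan=0.0, posinf=1e12, neginf=-1e12)

    res = minimize(nll, x0, jac=grad, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})
    params = res.x
    hess = -_numeric_hessian(params, X, entry, exit_, event)
    # Newton polish: BFGS stalls around |score| ~ 1e-4 on large datasets;
    # a few information-matrix steps reach machine-precision optima.
    for _ in range(8):
        g = weibull_ph_score(params, X, entry, exit_, event)
        if np.abs(g).max() < gtol:
            break
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            break
        cand = params + step
        if not np.isfinite(nll(cand)) or nll(cand) > nll(params) + 1e-9:
            break
        params = cand
        hess = -_numeric_hessian(params, X, entry, exit_, event)
    g_final = weibull_ph_score(params, X, entry, exit_, event)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.diag(cov))
        ok_se = bool(np.all(np.isfinite(se_all)))
    except np.linalg.LinAlgError:
        cov = np.full((len(params), len(params)), np.nan)
        se_all = np.full(len(params), np.nan)
        ok_se = False
    p = float(np.exp(params[-1]))
    converged = bool(np.abs(g_final).max() < max(gtol, 1e-5)) and ok_se
    return FitResult(
        params=dict(zip(names, params[:-1].tolist())),
        shape=p,
        se=dict(zip(names, se_all[:-1].tolist())),
        shape_se=p * float(se_all[-1]),  # delta method from log-shape
        loglik=weibull_ph_loglik(params, X, entry, exit_, event),
        converged=converged,
        n_iter=int(res.nit),
        n_events=int(event.sum()),
        n_intervals=len(df),
        names=names,
        covariance=cov,
        centering=centering_used,
        spec=spec,
    )


def backward_select(data, spec: ModelSpec, alpha=0.05, protected=("constant",)):
    """Optional backward elimination by likelihood-ratio tests.

    Drops, one at a time, the plain term whose removal is least
    significant until every remaining term is significant at ``alpha``.
    Splines, interactions and time terms are kept as fitted blocks.
    Returns ``(final FitResult, dropped term names)``.
    """
    current = spec
    dropped = []
    result = fit(data, current)
    while True:
        candidates = [t for t in current.terms if t not in protected]
        best = None
        for term in candidates:
            trial = replace(current, terms=[t for t in current.terms if t != term])
            try:
                r = fit(data, trial)
            except np.linalg.LinAlgError:
                continue
            if not r.converged:
                continue
            lr = 2 * (result.loglik - r.loglik)
            pval = chi2.sf(max(lr, 0.0), df=1)
            if best is None or pval > best[0]:
                best = (pval, term, r)
        if best is None or best[0] < alpha:
            return result, dropped
        _, term, result = best
        current = result.spec
        dropped.append(term)
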