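"""Weibull proportional-hazards risk equations for first and second
cardiovascular events in type 2 diabetes.

Each equation models the hazard of one event type (acute myocardial
infarction, heart failure, stroke, or non-acute ischaemic heart disease)
of a given order (first event after diagnosis, or second event of the
same type) as

    h(t) = exp(LP(x, t)) * p * t**(p - 1)

where ``p`` is the Weibull shape parameter and ``LP`` is a linear
predictor built from mean-centred continuous covariates, binary
indicators, linear-spline pieces, covariate interactions, and
covariate-by-time interactions.  First-event equations run on time since
diabetes diagnosis; second-event equations follow the
Prentice-Williams-Peterson gap-time convention and run on time since the
first event of the same type, with the clock starting at zero.

The eight published equations ship with the package as a YAML config
(``data/equations_ndr2013.yaml``); see :class:`EquationLibrary`.
"""

from __future__ import annotations

import hashlib
import io
import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "EVENT_TYPES",
    "ORDERS",
    "CONTINUOUS_COVARIATES",
    "BINARY_COVARIATES",
    "EquationConfigError",
    "IncompleteProfileError",
    "ReferenceProfileError",
    "SplineTerm",
    "TimeTerm",
    "InteractionTerm",
    "RiskEquation",
    "EquationLibrary",
    "spline_transform",
    "centering_from_cohort",
    "worked_example_profile",
    "read_profiles",
]

EVENT_TYPES = ("ami", "hf", "stroke", "naihd")
ORDERS = ("first", "second")

#: Continuous covariates: these require a centering constant wherever a
#: plain (non-spline) coefficient references them.
CONTINUOUS_COVARIATES = frozenset(
    {
        "age_at_diagnosis",
        "hba1c",
        "systolic_bp",
        "diastolic_bp",
        "ldl",
        "tc_hdl_ratio",
        "bmi",
        "duration_at_first_event",
    }
)

#: 0/1 indicators.  ``*_history`` flags are events before diabetes
#: diagnosis; ``*_since_diagnosis`` flags are time-varying indicators of
#: events after diagnosis but before the event an equation predicts.
BINARY_COVARIATES = frozenset(
    {
        "female",
        "smoker",
        "macroalbuminuria",
        "microalbuminuria",
        "ami_history",
        "hf_history",
        "stroke_history",
        "naihd_history",
        "ami_since_diagnosis",
        "hf_since_diagnosis",
        "stroke_since_diagnosis",
        "naihd_since_diagnosis",
    }
)


class EquationConfigError(ValueError):
    """An equation definition is incomplete or inconsistent."""


class IncompleteProfileError(LookupError):
    """A covariate profile lacks a covariate the equation references."""


class ReferenceProfileError(ValueError):
    """A hazard ratio was requested for a covariate whose effect depends
    on other covariates or on time, without a reference profile."""


def spline_transform(x, knot):
    """Split ``x`` into linear-spline pieces around ``knot``.

    Returns ``(min(x, knot), max(x - knot, 0))``.  The two pieces sum to
    ``x`` and the transform is continuous at the knot, where the high
    piece contributes zero.
    """
    x = np.asarray(x, dtype=float)
    low = np.minimum(x, knot)
    high = np.maximum(x - knot, 0.0)
    if low.ndim == 0:
        return float(low), float(high)
    return low, high


def _get(profile, name):
    try:
        return profile[name]
    except KeyError:
        raise IncompleteProfileError(
            f"profile is missing covariate {name!r}"
        ) from None


def _center(value, name, centering, ignore_centering):
    """Apply mean-centering to a continuous covariate value."""
    if name not in CONTINUOUS_COVARIATES:
        return value
    if ignore_centering:
        return value
    c = centering.get(name)
    if c is None:
        raise EquationConfigError(
            f"centering constant for continuous covariate {name!r} is not "
            "set; supply it in the equation config or via "
            "centering_from_cohort() before evaluating absolute risks"
        )
    return value - c


@dataclass(frozen=True)
class SplineTerm:
    """A linear spline on one covariate with a single knot.

    The low piece ``min(x, knot)`` gets ``coef_low`` per unit, the high
    piece ``max(x - knot, 0)`` gets ``coef_high`` per unit.  Spline
    pieces enter the linear predictor uncentred by default (centering is
    described for *linear* continuous covariates only, and uncentred
    pieces are the only reading consistent with the published event
    rates); nonzero centering constants can be supplied per piece.
    """

    covariate: str
    knot: float
    coef_low: float
    coef_high: float
    center_low: float = 0.0
    center_high: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.knot):
            raise EquationConfigError(f"spline knot for {self.covariate!r} must be finite")

    def contribution(self, profile, ignore_centering=False):
        low, high = spline_transform(_get(profile, self.covariate), self.knot)
        cl = ch = 0.0
        if not ignore_centering:
            cl, ch = self.center_low, self.center_high
        return self.coef_low * (low - cl) + self.coef_high * (high - ch)


@dataclass(frozen=True)
class TimeTerm:
    """A covariate-by-time interaction on the equation's own time scale.

    ``form="step"`` contributes ``coefficient * x * 1{t > threshold}``
    (e.g. "time since first event >1 year"); ``form="linear"``
    contributes ``coefficient * x * t``.  ``covariate=None`` means a pure
    time effect (x = 1).
    """

    coefficient: float
    covariate: str | None = None
    form: str = "step"
    threshold: float | None = None

    def __post_init__(self):
        if self.form not in ("step", "linear"):
            raise EquationConfigError(f"unknown time-term form {self.form!r}")
        if self.form == "step":
            if self.threshold is None or self.threshold <= 0:
                raise EquationConfigError("step time terms need a positive threshold")
        elif self.threshold is not None:
            raise EquationConfigError("linear time terms take no threshold")

    def multiplier(self, profile):
        """The time-independent factor ``coefficient * x``."""
        if self.covariate is None:
            return self.coefficient
        return self.coefficient * np.asarray(_get(profile, self.covariate), dtype=float)

    def contribution(self, profile, t):
        m = self.multiplier(profile)
        if self.form == "linear":
            return m * t
        return m * (np.asarray(t, dtype=float) > self.threshold)


@dataclass(frozen=True)
class InteractionTerm:
    """Product of two covariates (continuous ones centred)."""

    covariates: tuple[str, str]
    coefficient: float

    def contribution(self, profile, centering, ignore_centering=False):
        out = self.coefficient
        for name in self.covariates:
            v = np.asarray(_get(profile, name), dtype=float)
            out = out * _center(v, name, centering, ignore_centering)
        return out


@dataclass
class RiskEquation:
    """One event-specific Weibull proportional-hazards equation.

    Parameters
    ----------
    event, order
        Event type (``ami``/``hf``/``stroke``/``naihd``) and order
        (``first``/``second``).
    constant
        Intercept on the log-hazard scale (value of the linear predictor
        when every covariate sits at its centering constant and every
        indicator is zero).
    shape
        Weibull shape ``p``; hazard increases with time when ``p > 1``
        and decreases when ``p < 1``.
    coefficients
        Plain per-unit log-hazard coefficients keyed by covariate name.
    splines, interactions, time_terms
        Structured terms; see the term classes.
    centering
        Centering constants for continuous covariates.  ``None`` marks a
        constant that is not published; hazard ratios remain computable
        but absolute risks raise :class:`EquationConfigError`.
    """

    event: str
    order: str
    constant: float
    shape: float
    coefficients: dict[str, float] = field(default_factory=dict)
    splines: list[SplineTerm] = field(default_factory=list)
    interactions: list[InteractionTerm] = field(default_factory=list)
    time_terms: list[TimeTerm] = field(default_factory=list)
    centering: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.event not in EVENT_TYPES:
            raise EquationConfigError(f"unknown event type {self.event!r}")
        if self.order not in ORDERS:
            raise EquationConfigError(f"unknown event order {self.order!r}")
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise EquationConfigError("shape parameter must be positive and finite")
        if not np.isfinite(self.constant):
            raise EquationConfigError("constant must be finite")
        for name, coef in self.coefficients.items():
            if not np.isfinite(coef):
                raise EquationConfigError(f"coefficient for {name!r} is not finite")

    # -- metadata ------------------------------------------------------

    @property
    def key(self) -> str:
        return f"{self.event}:{self.order}"

    @property
    def time_scale(self) -> str:
        """``since_diagnosis`` for first events, ``since_first_event``
        (gap time) for second events."""
        return "since_diagnosis" if self.order == "first" else "since_first_event"

    def required_covariates(self) -> set[str]:
        names = set(self.coefficients)
        names.update(s.covariate for s in self.splines)
        for it in self.interactions:
            names.update(it.covariates)
        names.update(tt.covariate for tt in self.time_terms if tt.covariate)
        return names

    # -- linear predictor ---------------------------------------------

    def _static_lp(self, profile, ignore_centering=False):
        lp = self.constant if not ignore_centering else 0.0
        for name, coef in self.coefficients.items():
            v = np.asarray(_get(profile, name), dtype=float)
            lp = lp + coef * _center(v, name, self.centering, ignore_centering)
        for s in self.splines:
            lp = lp + s.contribution(profile, ignore_centering)
        for it in self.interactions:
            lp = lp + it.contribution(profile, self.centering, ignore_centering)
        return lp

    def _time_lp(self, profile, t):
        out = 0.0
        for tt in self.time_terms:
            out = out + tt.contribution(profile, t)
        return out

    def linear_predictor(self, profile, t=0.0):
        """Log-hazard offset ``LP(x, t)`` at time ``t`` on the equation's
        own time scale."""
        return self._static_lp(profile) + self._time_lp(profile, t)

    # -- hazard and risk ----------------------------------------------

    def hazard_rate(self, profile, t):
        """Instantaneous hazard (events per person-year) at time ``t``."""
        t = float(t)
        if t < 0:
            raise ValueError("time must be nonnegative")
        if t == 0 and self.shape < 1:
            raise ValueError("hazard is unbounded at t=0 when shape < 1")
        return np.exp(self.linear_predictor(profile, t)) * self.shape * t ** (self.shape - 1)

    def _breakpoints(self, profile, t0, t1):
        cuts = {float(t0), float(t1)}
        for tt in self.time_terms:
            if tt.form == "step" and t0 < tt.threshold < t1:
                cuts.add(float(tt.threshold))
        return sorted(cuts)

    def cumulative_hazard(self, profile, t0, t1):
        """Integrated hazard over ``[t0, t1]`` with covariates held fixed.

        Closed form (piecewise in the presence of step time terms)
        whenever the linear predictor is piecewise constant in time;
        adaptive quadrature otherwise.  Additive over abutting intervals.
        """
        t0, t1 = float(t0), float(t1)
        if t0 < 0 or t1 < 0:
            raise ValueError("times must be nonnegative")
        if t0 > t1:
            raise ValueError(f"interval is reversed: t0={t0} > t1={t1}")
        lp0 = self._static_lp(profile)
        if t0 == t1:
            return 0.0 * lp0
        p = self.shape
        linear = [tt for tt in self.time_terms if tt.form == "linear"]
        steps = [tt for tt in self.time_terms if tt.form == "step"]
        if not linear:
            H = 0.0
            cuts = self._breakpoints(profile, t0, t1)
            for a, b in itertools.pairwise(cuts):
                mid = 0.5 * (a + b)
                s = sum(tt.contribution(profile, mid) for tt in steps)
                H = H + np.exp(lp0 + s) * (b**p - a**p)
            return H if np.ndim(H) else float(H)

        # Continuous covariate-by-time terms: exp(gamma*t) * p * t**(p-1)
        # has no elementary antiderivative.  Substitute u = t**p so the
        # integrand is smooth even for p < 1, and split at step
        # thresholds so it is also continuous on each panel.
        def _scalar(profile_i):
            gammas = [(tt, tt.multiplier(profile_i)) for tt in linear]
            sprs = [(tt, tt.multiplier(profile_i)) for tt in steps]
            lp_i = self._static_lp(profile_i)

            def integrand(u):
                t = u ** (1.0 / p)
                lp = lp_i + sum(g * t for _, g in gammas)
                lp += sum(m * (t > tt.threshold) for tt, m in sprs)
                return np.exp(lp)

            total = 0.0
            for a, b in itertools.pairwise(self._breakpoints(profile_i, t0, t1)):
                val, _ = quad(integrand, a**p, b**p, epsabs=1e-9, epsrel=1e-10, limit=200)
                total += val
            return total

        if np.ndim(lp0) == 0:
            return _scalar(profile)
        n = np.shape(lp0)[0]
        rows = (
            profile.iloc if isinstance(profile, pd.DataFrame) else
            [{k: np.asarray(v)[i] for k, v in profile.items()} for i in range(n)]
        )
        return np.array([_scalar(rows[i]) for i in range(n)])

    def interval_risk(self, profile, t0, t1):
        """Probability of the event in ``[t0, t1]`` given event-free
        survival to ``t0``: ``1 - exp(-cumulative_hazard)``."""
        return -np.expm1(-self.cumulative_hazard(profile, t0, t1))

    def cumulative_hazard_curve(self, profile, t0, t1, step):
        """Cumulative hazard sampled on a grid; returns an (m, 2) array
        of ``(t, H(t0, t))`` ending exactly at ``t1``."""
        if step <= 0:
            raise ValueError("step must be positive")
        ts = np.arange(float(t0), float(t1), float(step))
        ts = np.append(ts, float(t1))
        H = np.empty_like(ts)
        H[0] = 0.0
        for i in range(1, len(ts)):
            H[i] = H[i - 1] + self.cumulative_hazard(profile, ts[i - 1], ts[i])
        return np.column_stack([ts, H])

    def hazard_ratio(self, covariate, delta, profile=None, t=None):
        """Hazard ratio for a ``delta``-unit difference in ``covariate``.

        Plain terms reduce to ``exp(coefficient * delta)``, for which no
        centering or reference is needed (centering constants cancel in
        the difference).  Covariates entering splines, interactions or
        time terms need a reference ``profile`` (and ``t`` when time is
        involved); the log-ratio is then the structural difference
        ``LP(x + delta, t) - LP(x, t)``: spline pieces difference their
        transforms (centering cancels), an interaction with another
        covariate contributes ``coefficient * delta * (other - center)``,
        and time terms contribute ``coefficient * delta * f(t)``.
        """
        if covariate not in self.required_covariates():
            raise KeyError(f"{covariate!r} does not enter equation {self.key}")
        if delta == 0:
            return 1.0
        structured = (
            any(s.covariate == covariate for s in self.splines)
            or any(covariate in it.covariates for it in self.interactions)
            or any(tt.covariate == covariate for tt in self.time_terms)
        )
        diff = self.coefficients.get(covariate, 0.0) * delta
        if not structured:
            return float(np.exp(diff))
        if profile is None:
            raise ReferenceProfileError(
                f"{covariate!r} has spline/interaction/time terms in {self.key}; "
                "a reference profile (and time, if applicable) is required"
            )
        if any(tt.covariate == covariate for tt in self.time_terms) and t is None:
            raise ReferenceProfileError(
                f"{covariate!r} interacts with time in {self.key}; pass t="
            )
        x0 = float(_get(profile, covariate))
        for s in self.splines:
            if s.covariate == covariate:
                low0, high0 = spline_transform(x0, s.knot)
                low1, high1 = spline_transform(x0 + delta, s.knot)
                diff += s.coef_low * (low1 - low0) + s.coef_high * (high1 - high0)
        for it in self.interactions:
            if covariate in it.covariates:
                other = it.covariates[1] if it.covariates[0] == covariate else it.covariates[0]
                ov = float(_get(profile, other))
                diff += it.coefficient * delta * float(
                    _center(ov, other, self.centering, False)
                )
        for tt in self.time_terms:
            if tt.covariate == covariate:
                f_t = float(t) if tt.form == "linear" else float(float(t) > tt.threshold)
                diff += tt.coefficient * delta * f_t
        return float(np.exp(diff))

    def invert_cumulative_hazard(self, profile, t0, target):
        """Smallest ``t >= t0`` with ``cumulative_hazard(t0, t) = target``.

        Used by the microsimulator's inverse-transform sampling.  Exact
        piecewise closed form when the linear predictor is piecewise
        constant in time; Brent root-finding otherwise.
        """
        if target < 0:
            raise ValueError("target cumulative hazard must be nonnegative")
        if target == 0:
            return float(t0)
        p = self.shape
        if not any(tt.form == "linear" for tt in self.time_terms):
            steps = [tt for tt in self.time_terms if tt.form == "step"]
            a = float(t0)
            remaining = float(target)
            thresholds = sorted(tt.threshold for tt in steps if tt.threshold > a)
            panels = thresholds + [np.inf]
            lp0 = float(self._static_lp(profile))
            for b in panels:
                mid = a + 0.5 if np.isinf(b) else 0.5 * (a + b)
                s = float(sum(tt.contribution(profile, mid) for tt in steps))
                rate = np.exp(lp0 + s)
                span = rate * ((b**p if np.isfinite(b) else np.inf) - a**p)
                if remaining <= span:
                    return float((a**p + remaining / rate) ** (1.0 / p))
                remaining -= span
                a = b
            raise RuntimeError("unreachable: infinite final panel")  # pragma: no cover
        # quadrature case: bracket then Brent
        hi = max(float(t0), 1.0)
        while self.cumulative_hazard(profile, t0, hi) < target:
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError("failed to bracket event time")
        return float(
            brentq(
                lambda t: self.cumulative_hazard(profile, t0, t) - target,
                float(t0),
                hi,
                xtol=1e-12,
                rtol=1e-12,
            )
        )

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "event": self.event,
            "order": self.order,
            "constant": self.constant,
            "shape": self.shape,
            "terms": dict(sorted(self.coefficients.items())),
            "splines": [
                {
                    "covariate": s.covariate,
                    "knot": s.knot,
                    "coef_low": s.coef_low,
                    "coef_high": s.coef_high,
                    "center_low": s.center_low,
                    "center_high": s.center_high,
                }
                for s in self.splines
            ],
            "interactions": [
                {"covariates": list(it.covariates), "coefficient": it.coefficient}
                for it in self.interactions
            ],
            "time_terms": [
                {
                    "covariate": tt.covariate,
                    "form": tt.form,
                    "threshold": tt.threshold,
                    "coefficient": tt.coefficient,
                }
                for tt in self.time_terms
            ],
            "centering": dict(sorted(self.centering.items())),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping, path: str = "equation") -> "RiskEquation":
        def req(key):
            if key not in d or d[key] is None:
                raise EquationConfigError(f"{path}.{key}: required field missing")
            return d[key]

        event, order = req("event"), req("order")
        shape = req("shape")
        if not isinstance(shape, (int, float)) or shape <= 0:
            raise EquationConfigError(f"{path}.shape: must be a positive number")
        terms = dict(d.get("terms") or {})
        known = CONTINUOUS_COVARIATES | BINARY_COVARIATES
        for name in terms:
            if name not in known:
                raise EquationConfigError(f"{path}.terms.{name}: unknown covariate")
        splines = [
            SplineTerm(
                covariate=s["covariate"],
                knot=float(s["knot"]),
                coef_low=float(s["coef_low"]),
                coef_high=float(s["coef_high"]),
                center_low=float(s.get("center_low") or 0.0),
                center_high=float(s.get("center_high") or 0.0),
            )
            for s in (d.get("splines") or [])
        ]
        for i, s in enumerate(splines):
            if s.covariate not in known:
                raise EquationConfigError(f"{path}.splines[{i}].covariate: unknown covariate")
        interactions = [
            InteractionTerm(tuple(it["covariates"]), float(it["coefficient"]))
            for it in (d.get("interactions") or [])
        ]
        time_terms = [
            TimeTerm(
                coefficient=float(tt["coefficient"]),
                covariate=tt.get("covariate"),
                form=tt.get("form", "step"),
                threshold=tt.get("threshold"),
            )
            for tt in (d.get("time_terms") or [])
        ]
        return cls(
            event=event,
            order=order,
            constant=float(req("constant")),
            shape=float(shape),
            coefficients={k: float(v) for k, v in terms.items()},
            splines=splines,
            interactions=interactions,
            time_terms=time_terms,
            centering=dict(d.get("centering") or {}),
        )


@dataclass
class EquationLibrary:
    """A keyed collection of risk equations with provenance metadata."""

    equations: dict[tuple[str, str], RiskEquation]
    name: str = "unnamed"
    version: str = "0"
    source: str = ""

    def __getitem__(self, key) -> RiskEquation:
        if isinstance(key, str):
            event, _, order = key.partition(":")
            key = (event, order)
        return self.equations[tuple(key)]

    def __contains__(self, key) -> bool:
        try:
            self[key]
            return True
        except KeyError:
            return False

    def __iter__(self):
        return iter(self.equations.values())

    def __len__(self):
        return len(self.equations)

    def subset(self, keys: Iterable) -> "EquationLibrary":
        eqs = {}
        for k in keys:
            eq = self[k]
            eqs[(eq.event, eq.order)] = eq
        return replace(self, equations=eqs)

    def validate_complete(self):
        """Require all eight (event, order) combinations."""
        missing = [
            f"{e}:{o}"
            for e in EVENT_TYPES
            for o in ORDERS
            if (e, o) not in self.equations
        ]
        if missing:
            raise EquationConfigError(f"library is missing equations: {missing}")

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "library": self.name,
            "version": self.version,
            "source": self.source,
            "equations": [
                eq.to_dict()
                for _, eq in sorted(self.equations.items())
            ],
        }

    def dumps(self) -> str:
        """Canonical YAML serialization (stable key order, so that
        save -> load -> save is byte-identical)."""
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def content_hash(self) -> str:
        return hashlib.sha256(self.dumps().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: Mapping) -> "EquationLibrary":
        if "equations" not in d:
            raise EquationConfigError("config: missing top-level 'equations' list")
        eqs = {}
        for i, ed in enumerate(d["equations"]):
            eq = RiskEquation.from_dict(ed, path=f"equations[{i}]")
            key = (eq.event, eq.order)
            if key in eqs:
                raise EquationConfigError(f"equations[{i}]: duplicate equation {eq.key}")
            eqs[key] = eq
        return cls(
            equations=eqs,
            name=str(d.get("library", "unnamed")),
            version=str(d.get("version", "0")),
            source=str(d.get("source", "")),
        )

    @classmethod
    def load(cls, path_or_stream) -> "EquationLibrary":
        if hasattr(path_or_stream, "read"):
            d = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def default(cls) -> "EquationLibrary":
        """The eight published equations (shipped config)."""
        text = resources.files("cvdrisk.data").joinpath("equations_ndr2013.yaml").read_text()
        lib = cls.load(io.StringIO(text))
        lib.validate_complete()
        return lib


def centering_from_cohort(obj, cohort: pd.DataFrame):
    """Fill missing centering constants from a cohort's sample means.

    For each continuous covariate with a plain coefficient whose
    centering constant is ``None``, the constant becomes the cohort
    column mean (the convention used when the equations were estimated).
    Spline pieces are untouched: they enter uncentred.  Already-set
    constants are kept.  Returns a new equation or library; the input is
    not modified.
    """
    if isinstance(obj, EquationLibrary):
        eqs = {k: centering_from_cohort(eq, cohort) for k, eq in obj.equations.items()}
        return replace(obj, equations=eqs)
    eq: RiskEquation = obj
    centering = dict(eq.centering)
    for name in set(eq.coefficients) & CONTINUOUS_COVARIATES:
        if centering.get(name) is None:
            if name not in cohort.columns:
                raise EquationConfigError(
                    f"cannot derive centering for {name!r}: column absent from cohort"
                )
            centering[name] = float(cohort[name].mean())
    # interaction terms may reference continuous covariates too
    for it in eq.interactions:
        for name in it.covariates:
            if name in CONTINUOUS_COVARIATES and centering.get(name) is None:
                centering[name] = float(cohort[name].mean())
    return replace(eq, centering=centering)


def worked_example_profile() -> dict:
    """The illustrative patient used throughout the docs and tests: a
    non-smoking 58-year-old male, diabetes duration 10 years (so age at
    diagnosis 48), HbA1c 8.0%, systolic BP 150 mmHg, TC/HDL 4.3, LDL 2.0
    mmol/L, macroalbuminuria, no event history.  For second-event
    equations the first event is assumed to occur in the 10th year after
    diagnosis (``duration_at_first_event`` = 10)."""
    return {
        "female": 0,
        "age_at_diagnosis": 48.0,
        "diabetes_duration": 10.0,
        "hba1c": 8.0,
        "systolic_bp": 150.0,
        "diastolic_bp": 80.0,
        "ldl": 2.0,
        "tc_hdl_ratio": 4.3,
        "bmi": 28.0,
        "smoker": 0,
        "macroalbuminuria": 1,
        "microalbuminuria": 0,
        "ami_history": 0,
        "hf_history": 0,
        "stroke_history": 0,
        "naihd_history": 0,
        "ami_since_diagnosis": 0,
        "hf_since_diagnosis": 0,
        "stroke_since_diagnosis": 0,
        "naihd_since_diagnosis": 0,
        "duration_at_first_event": 10.0,
    }


def read_profiles(path) -> pd.DataFrame:
    """Read patient covariate profiles from CSV (one row per patient).

    Columns follow :func:`worked_example_profile`; indicator columns are
    0/1.  Missing indicator columns default to 0 with a warning-free
    fill, since absent history columns conventionally mean "no history".
    """
    df = pd.read_csv(path)
    for name in BINARY_COVARIATES:
        if name not in df.columns:
            df[name] = 0
    return df
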