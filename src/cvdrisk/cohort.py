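"""Synthetic baseline cohorts with the register's marginal structure.

The generator reproduces published per-sex means/SDs of continuous
covariates and prevalences of smoking and albuminuria, so downstream
modules (microsimulation, estimation, validation) are testable without
any register data.  Continuous covariates are drawn from moment-matched
truncated normals: the underlying normal parameters are solved so that
the *truncated* distribution has exactly the requested mean and SD
inside physiologic bounds.  A Gaussian copula imposes an optional
correlation structure; covariates are independent by default because
only marginals were published.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "PHYSIOLOGIC_BOUNDS",
    "IMMUTABLE_COVARIATES",
    "CohortSpec",
    "Drift",
    "generate_baseline",
    "annual_covariate_update",
]

#: Plausible physiologic ranges; draws are truncated to these and drift
#: updates are clipped to them.
PHYSIOLOGIC_BOUNDS = {
    "age_at_diagnosis": (30.0, 75.0),  # register inclusion criterion
    "diabetes_duration": (0.0, 50.0),
    "hba1c": (4.0, 16.0),
    "bmi": (15.0, 60.0),
    "systolic_bp": (80.0, 250.0),
    "diastolic_bp": (40.0, 140.0),
    "tc_hdl_ratio": (1.5, 15.0),
    "ldl": (0.3, 10.0),
}

#: Fields an annual update may never touch.
IMMUTABLE_COVARIATES = frozenset(
    {
        "patient_id",
        "female",
        "age_at_diagnosis",
        "diabetes_duration",
        "ami_history",
        "hf_history",
        "stroke_history",
        "naihd_history",
    }
)

EVENTS = ("ami", "hf", "stroke", "naihd")


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) such that a normal truncated to [lo, hi]
    has the requested mean and SD."""
    if sd <= 0:
        raise ValueError("SD must be positive")
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} outside bounds ({lo}, {hi})")

    def resid(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = least_squares(resid, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14)
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6 * max(sd, 1.0):
        raise ValueError(
            f"cannot match mean={mean}, sd={sd} with a normal truncated to [{lo}, {hi}]"
        )
    return float(mu), sigma


def _truncnorm_ppf(u, mean, sd, lo, hi):
    mu, sigma = _matched_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


@dataclass
class CohortSpec:
    """Marginal structure of a baseline cohort.

    ``continuous`` maps covariate -> {"male": {"mean", "sd"},
    "female": {...}}; ``smoking`` and ``albuminuria`` are per-sex
    prevalences (albuminuria as a three-level none/micro/macro
    categorical); ``history`` is the per-event prevalence of
    pre-diagnosis events (sex-independent).  ``correlation`` is an
    optional covariate-pair -> rho mapping applied through a Gaussian
    copula.
    """

    proportion_female: float
    continuous: dict[str, dict[str, dict[str, float]]]
    smoking: dict[str, float]
    albuminuria: dict[str, dict[str, float]]
    history: dict[str, float] = field(default_factory=lambda: {e: 0.0 for e in EVENTS})
    correlation: dict[tuple[str, str], float] | None = None
    name: str = "unnamed"

    def __post_init__(self):
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must be in [0, 1]")
        for sex, p in self.smoking.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"smoking prevalence for {sex} must be in [0, 1]")
        for sex, d in self.albuminuria.items():
            macro, micro = d["macro"], d["micro"]
            if min(macro, micro) < 0 or macro + micro > 1.0:
                raise ValueError(
                    f"albuminuria prevalences for {sex} must be nonnegative with macro+micro <= 1"
                )
        for ev, p in self.history.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"history prevalence for {ev} must be in [0, 1]")
        for cov, by_sex in self.continuous.items():
            for sex, ms in by_sex.items():
                if ms["sd"] <= 0:
                    raise ValueError(f"SD for {cov}/{sex} must be positive")

    @classmethod
    def from_dict(cls, d) -> "CohortSpec":
        corr = None
        if d.get("correlation"):
            corr = {tuple(sorted((a, b))): float(r) for (a, b), r in
                    ((tuple(item["pair"]), item["rho"]) for item in d["correlation"])}
        return cls(
            proportion_female=float(d["proportion_female"]),
            continuous=d["continuous"],
            smoking=d["smoking"],
            albuminuria=d["albuminuria"],
            history={e: float(d.get("history", {}).get(e, 0.0)) for e in EVENTS},
            correlation=corr,
            name=str(d.get("name", "unnamed")),
        )

    @classmethod
    def load(cls, path_or_stream) -> "CohortSpec":
        if hasattr(path_or_stream, "read"):
            d = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def default(cls) -> "CohortSpec":
        """The published training-sample baseline distributions."""
        text = resources.files("cvdrisk.data").joinpath("table1_training.yaml").read_text()
        return cls.load(io.StringIO(text))

    def pooled_mean(self, covariate: str) -> float:
        """Sex-pooled mean of a continuous covariate."""
        pf = self.proportion_female
        by_sex = self.continuous[covariate]
        return (1 - pf) * by_sex["male"]["mean"] + pf * by_sex["female"]["mean"]


def _copula_normals(spec: CohortSpec, names: list[str], n: int, rng) -> np.ndarray:
    """Standard-normal draws (n, len(names)); correlated if requested."""
    k = len(names)
    if not spec.correlation:
        return rng.standard_normal((n, k))
    R = np.eye(k)
    idx = {name: i for i, name in enumerate(names)}
    for (a, b), rho in spec.correlation.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    # ensure positive definite before Cholesky
    np.linalg.cholesky(R)
    return rng.multivariate_normal(np.zeros(k), R, size=n, method="cholesky")


def generate_baseline(spec: CohortSpec, n: int, seed=None) -> pd.DataFrame:
    """Draw a baseline cohort of ``n`` covariate profiles.

    Reproducible given ``seed`` (an int or a ``numpy`` Generator).
    Albuminuria is a single three-level categorical draw, so macro- and
    microalbuminuria are never simultaneously 1.  Dynamic
    ``*_since_diagnosis`` flags start at 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    female = (rng.random(n) < spec.proportion_female).astype(int)

    names = sorted(spec.continuous)
    z = _copula_normals(spec, names, n, rng)
    u = stats.norm.cdf(z)

    df = pd.DataFrame({"patient_id": np.arange(n), "female": female})
    for j, name in enumerate(names):
        lo, hi = PHYSIOLOGIC_BOUNDS[name]
        x = np.empty(n)
        for sex, mask in (("male", female == 0), ("female", female == 1)):
            ms = spec.continuous[name][sex]
            if mask.any():
                x[mask] = _truncnorm_ppf(u[mask, j], ms["mean"], ms["sd"], lo, hi)
        df[name] = x

    smoke_p = np.where(female == 1, spec.smoking["female"], spec.smoking["male"])
    df["smoker"] = (rng.random(n) < smoke_p).astype(int)

    macro_p = np.where(female == 1, spec.albuminuria["female"]["macro"],
                       spec.albuminuria["male"]["macro"])
    micro_p = np.where(female == 1, spec.albuminuria["female"]["micro"],
                       spec.albuminuria["male"]["micro"])
    ua = rng.random(n)
    df["macroalbuminuria"] = (ua < macro_p).astype(int)
    df["microalbuminuria"] = ((ua >= macro_p) & (ua < macro_p + micro_p)).astype(int)

    for ev in EVENTS:
        df[f"{ev}_history"] = (rng.random(n) < spec.history[ev]).astype(int)
        df[f"{ev}_since_diagnosis"] = 0
    return df


@dataclass(frozen=True)
class Drift:
    """Annual update model for one continuous covariate.

    ``random_walk``: x <- x + N(0, sd).  ``ar1``: x <- mean + rho*(x -
    mean) + N(0, sd).  Updated values are clipped to physiologic bounds.
    """

    kind: str = "random_walk"
    sd: float = 0.0
    rho: float = 1.0
    mean: float | None = None

    def __post_init__(self):
        if self.kind not in ("random_walk", "ar1"):
            raise ValueError(f"unknown drift kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("drift sd must be nonnegative")
        if self.kind == "ar1" and self.mean is None:
            raise ValueError("ar1 drift needs a long-run mean")


def annual_covariate_update(profiles, drift: dict[str, Drift] | None, rng) -> pd.DataFrame:
    """Advance time-varying continuous covariates by one year.

    ``profiles`` is a DataFrame (or single dict-like profile); a copy is
    returned, indicators and immutable fields untouched.  With
    ``drift=None`` or an empty mapping the profiles are returned
    unchanged (identity update).
    """
    single = not isinstance(profiles, pd.DataFrame)
    df = pd.DataFrame([profiles]) if single else profiles.copy()
    for name, d in (drift or {}).items():
        if name in IMMUTABLE_COVARIATES:
            raise ValueError(f"covariate {name!r} is immutable under annual updates")
        if name not in df.columns:
            raise KeyError(f"profiles have no covariate {name!r}")
        x = df[name].to_numpy(dtype=float)
        noise = rng.normal(0.0, d.sd, size=len(df)) if d.sd > 0 else 0.0
        if d.kind == "random_walk":
            x = x + noise
        else:
            x = d.mean + d.rho * (x - d.mean) + noise
        if name in PHYSIOLOGIC_BOUNDS:
            lo, hi = PHYSIOLOGIC_BOUNDS[name]
            x = np.clip(x, lo, hi)
        df[name] = x
    if single:
        return df.iloc[0].to_dict()
    return df
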