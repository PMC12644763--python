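"""Multi-center synthetic sepsis-like cohort generator.

Emulates the statistical structure the rest of the package assumes,
without any real patient data: a minority 28-day mortality class driven
by a latent logistic model on the eight routine markers, per-center
covariate shift, an optional two-component marker subpopulation mixture
(a low- and a high-severity coagulation-inflammatory profile), and
survival times that are exactly consistent with the binary outcome,
with stratum-dependent treatment effects on the hazard.

Model
-----
Markers are drawn per patient from configurable families: count-type
markers (WBC, NEUT, LYM, MON, PLT) are log-normal, APTT / INR / age are
truncated normal — positive, right-skewed marginals typical of routine
labs.  After center shifts and subpopulation shifts, the markers are
z-standardized within the cohort and a linear predictor

    eta_i = b0 + sum_j beta_j * z_ij

defines the death probability ``p_i = expit(eta_i)``; the intercept
``b0`` is solved numerically so that ``mean(p) = mortality_rate``.
Survival is exponential with per-patient rate ``lambda_i`` chosen so
that ``P(T <= horizon) = p_i`` (hence the binary outcome and the
survival time are mutually consistent); treated patients have their
hazard multiplied by the stratum's hazard multiplier.  Administrative
censoring at the horizon (default 28 days).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from sepstrat.io import COHORT_COLUMNS, MARKER_COLUMNS, validate_cohort

__all__ = [
    "ConfigError",
    "MarkerSpec",
    "SubpopConfig",
    "TreatmentConfig",
    "GeneratorConfig",
    "generate_cohort",
    "inject_domain_shift",
    "make_two_subpopulations",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class MarkerSpec:
    """Marginal distribution of one marker.

    ``lognormal``: ``loc`` is the natural-scale median, ``scale`` the
    log-space standard deviation.  ``truncnorm``: ``loc``/``scale`` are
    the mean/sd of the underlying normal, truncated to
    ``[lower, upper]``.
    """

    family: str  # "lognormal" | "truncnorm"
    loc: float
    scale: float
    lower: float = 0.0
    upper: float = np.inf

    def validate(self, name: str) -> None:
        if self.family not in ("lognormal", "truncnorm"):
            raise ConfigError(f"marker_params[{name!r}].family: unknown family {self.family!r}")
        if not np.isfinite(self.loc):
            raise ConfigError(f"marker_params[{name!r}].loc must be finite")
        if not (self.scale > 0):
            raise ConfigError(f"marker_params[{name!r}].scale must be > 0")
        if not self.lower < self.upper:
            raise ConfigError(f"marker_params[{name!r}]: lower must be < upper")

    def sample(self, n: int, rng: np.random.Generator, shift_scale_units: float = 0.0) -> np.ndarray:
        """Draw ``n`` values, shifting the location by ``shift_scale_units``
        scale parameters in the family's sampling space (log space for
        log-normal markers, so positivity is preserved)."""
        if self.family == "lognormal":
            mu = np.log(self.loc) + shift_scale_units * self.scale
            x = np.exp(rng.normal(mu, self.scale, size=n))
            return np.clip(x, self.lower if self.lower > 0 else 1e-3, None)
        mu = self.loc + shift_scale_units * self.scale
        a = (self.lower - mu) / self.scale
        b = (self.upper - mu) / self.scale
        return stats.truncnorm.rvs(a, b, loc=mu, scale=self.scale, size=n, random_state=rng)


@dataclass(frozen=True)
class SubpopConfig:
    """Two-component marker mixture: per-marker shift of component 2's
    location relative to component 1, in scale-parameter units, and the
    mixing weight of component 2."""

    shift: Mapping[str, float]
    weight: float = 0.2

    def validate(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigError("subpop_mixture.weight must be in [0, 1]")
        unknown = sorted(set(self.shift) - set(MARKER_COLUMNS))
        if unknown:
            raise ConfigError(
                f"subpop_mixture.shift: unknown markers {unknown}; valid: {MARKER_COLUMNS}"
            )


@dataclass(frozen=True)
class TreatmentConfig:
    """Bernoulli treatment assignment (randomized-like by default) with
    per-stratum hazard multipliers.  With more than one multiplier,
    patients are assigned to equal-sized strata by quantiles of the
    latent linear predictor (recorded in a ``treat_stratum`` column)."""

    p_treat: float = 0.5
    hazard_multipliers: Sequence[float] = (1.0,)
    confounding: float = 0.0  # logit shift of p_treat per unit of eta z-score

    def validate(self) -> None:
        if not (0.0 <= self.p_treat <= 1.0):
            raise ConfigError("treatment.p_treat must be in [0, 1]")
        if len(self.hazard_multipliers) < 1 or any(m <= 0 for m in self.hazard_multipliers):
            raise ConfigError("treatment.hazard_multipliers must be positive and nonempty")


def _default_marker_params() -> dict[str, MarkerSpec]:
    return {
        "age": MarkerSpec("truncnorm", 64.0, 16.0, lower=18.0, upper=100.0),
        "aptt": MarkerSpec("truncnorm", 38.0, 12.0, lower=10.0, upper=300.0),
        "inr": MarkerSpec("truncnorm", 1.4, 0.4, lower=0.5, upper=20.0),
        "wbc": MarkerSpec("lognormal", 12.0, 0.50, lower=0.05),
        "neut": MarkerSpec("lognormal", 9.0, 0.55, lower=0.02),
        "lym": MarkerSpec("lognormal", 1.0, 0.60, lower=0.01),
        "mon": MarkerSpec("lognormal", 0.5, 0.60, lower=0.005),
        "plt": MarkerSpec("lognormal", 180.0, 0.50, lower=1.0),
    }


def _default_risk_coefficients() -> dict[str, float]:
    # Directions mirror clinical severity: prolonged clotting (APTT, INR),
    # leukocytosis / neutrophilia, lymphopenia, thrombocytopenia, old age.
    return {
        "age": 0.7,
        "aptt": 0.8,
        "inr": 0.6,
        "wbc": 0.5,
        "neut": 0.4,
        "lym": -0.5,
        "mon": 0.3,
        "plt": -0.6,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_per_center: int = 1000
    n_centers: int = 1
    mortality_rate: float = 0.25
    marker_params: Mapping[str, MarkerSpec] = field(default_factory=_default_marker_params)
    risk_coefficients: Mapping[str, float] = field(default_factory=_default_risk_coefficients)
    subpop_mixture: SubpopConfig | None = None
    center_shift: Sequence[Mapping[str, tuple[float, float]]] | None = None
    center_shift_sd: float = 0.15  # auto-generated per-center (loc, log-scale) jitter, in sd units
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    censor_horizon: float = 28.0
    extended: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_center < 1:
            raise ConfigError("n_per_center must be >= 1")
        if self.n_centers < 1:
            raise ConfigError("n_centers must be >= 1")
        if not (0.0 < self.mortality_rate < 1.0):
            raise ConfigError("mortality_rate must be in (0, 1)")
        if self.censor_horizon <= 0:
            raise ConfigError("censor_horizon must be > 0")
        missing = sorted(set(MARKER_COLUMNS) - set(self.marker_params))
        if missing:
            raise ConfigError(f"marker_params missing markers {missing}")
        for name, spec in self.marker_params.items():
            spec.validate(name)
        unknown = sorted(set(self.risk_coefficients) - set(MARKER_COLUMNS))
        if unknown:
            raise ConfigError(f"risk_coefficients: unknown markers {unknown}")
        if self.subpop_mixture is not None:
            self.subpop_mixture.validate()
        self.treatment.validate()
        if self.center_shift is not None and len(self.center_shift) != self.n_centers:
            raise ConfigError("center_shift must list one mapping per center")


_EXTENDED_CATEGORIES = ("hep", "ren", "gas", "ery")  # hepatic, renal, blood gas, erythrocyte


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table; deterministic for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_center * config.n_centers

    # --- latent subpopulation labels ----------------------------------
    if config.subpop_mixture is not None:
        w2 = config.subpop_mixture.weight
        subpop = (rng.random(n) < w2).astype(int)  # 1 = high-severity component
        shift_map = dict(config.subpop_mixture.shift)
    else:
        subpop = np.zeros(n, dtype=int)
        w2, shift_map = 0.0, {}

    # --- markers ------------------------------------------------------
    markers = {}
    for name in MARKER_COLUMNS:
        spec = config.marker_params[name]
        delta = shift_map.get(name, 0.0)
        # component means at -w2*delta and +(1-w2)*delta keep the overall
        # location approximately fixed as the mixing weight varies
        shift_per_row = np.where(subpop == 1, (1.0 - w2) * delta, -w2 * delta)
        col = np.empty(n)
        for value in (0, 1):
            idx = np.flatnonzero(subpop == value)
            if idx.size:
                s = shift_per_row[idx[0]]
                col[idx] = spec.sample(idx.size, rng, shift_scale_units=s)
        markers[name] = col

    # --- per-center covariate shift (natural scale, affine) -----------
    center_id = np.repeat(np.arange(config.n_centers), config.n_per_center)
    for c in range(config.n_centers):
        if config.center_shift is not None:
            shifts = config.center_shift[c]
        elif config.n_centers > 1:
            shifts = {
                name: (
                    float(np.exp(rng.normal(0.0, config.center_shift_sd / 2))),
                    float(rng.normal(0.0, config.center_shift_sd)
                          * np.std(markers[name], ddof=0)),
                )
                for name in MARKER_COLUMNS
            }
        else:
            shifts = {}
        mask = center_id == c
        for name, (scale, loc) in shifts.items():
            spec = config.marker_params[name]
            markers[name][mask] = np.clip(
                scale * markers[name][mask] + loc, max(spec.lower, 1e-3), None
            )

    X = np.column_stack([markers[m] for m in MARKER_COLUMNS])

    # --- latent logistic mortality model on standardized markers ------
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    beta = np.array([config.risk_coefficients.get(m, 0.0) for m in MARKER_COLUMNS])
    score = Z @ beta

    def excess(b0: float) -> float:
        return float(np.mean(special.expit(b0 + score))) - config.mortality_rate

    b0 = optimize.brentq(excess, -40.0, 40.0)
    eta = b0 + score
    p = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)

    # --- treatment assignment and strata ------------------------------
    tr = config.treatment
    if abs(tr.confounding) > 0:
        zeta = (eta - eta.mean()) / (eta.std(ddof=0) or 1.0)
        p_tr = special.expit(special.logit(np.clip(tr.p_treat, 1e-9, 1 - 1e-9))
                             + tr.confounding * zeta)
    else:
        p_tr = np.full(n, tr.p_treat)
    treated = (rng.random(n) < p_tr).astype(int)

    mult = np.asarray(tr.hazard_multipliers, dtype=float)
    if mult.size > 1:
        # equal-sized strata by quantiles of the latent linear predictor
        qs = np.quantile(eta, np.linspace(0, 1, mult.size + 1)[1:-1])
        stratum = np.searchsorted(qs, eta, side="right")
    else:
        stratum = np.zeros(n, dtype=int)
    hazard_mult = np.where(treated == 1, mult[stratum], 1.0)

    # --- survival: exponential rate tied to the logistic model --------
    lam = -np.log1p(-p) / config.censor_horizon * hazard_mult
    T = rng.exponential(1.0, size=n) / lam
    event = (T <= config.censor_horizon).astype(int)
    survival = np.minimum(T, config.censor_horizon)

    cohort = pd.DataFrame({
        "patient_id": np.arange(n),
        "center_id": center_id,
        **{m: markers[m] for m in MARKER_COLUMNS},
        "died_28d": event,
        "survival_days": survival,
        "event": event,
        "treated": treated,
    })[COHORT_COLUMNS]
    if config.subpop_mixture is not None:
        cohort["latent_subpop"] = subpop
    if mult.size > 1:
        cohort["treat_stratum"] = stratum

    if config.extended:
        for cat in _EXTENDED_CATEGORIES:
            factor = rng.normal(size=n)
            for j in range(7):
                noise = rng.normal(size=n)
                cohort[f"x_{cat}{j + 1}"] = np.exp(
                    0.6 * factor + 0.7 * noise + 0.15 * (eta - eta.mean())
                )

    cohort.attrs["generator_seed"] = config.seed
    cohort.attrs["latent_intercept"] = float(b0)
    return validate_cohort(cohort)


def cohort_to_csv_bytes(cohort: pd.DataFrame) -> bytes:
    """Canonical CSV serialization (used by the byte-determinism contract)."""
    buf = _io.StringIO()
    cohort.to_csv(buf, index=False)
    return buf.getvalue().encode()


def inject_domain_shift(
    cohort: pd.DataFrame,
    shift: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Apply per-feature affine shifts ``x' = scale * x + loc``.

    ``shift`` maps marker column names to ``(scale, loc)`` pairs.
    Outcome columns are untouched; the shift is recorded in
    ``result.attrs["domain_shift"]``.
    """
    unknown = sorted(set(shift) - set(MARKER_COLUMNS))
    if unknown:
        raise ValueError(
            f"unknown marker columns {unknown}; valid columns: {MARKER_COLUMNS}"
        )
    out = cohort.copy()
    for name, (scale, loc) in shift.items():
        out[name] = scale * out[name].to_numpy(dtype=float) + loc
    out.attrs = dict(cohort.attrs)
    out.attrs["domain_shift"] = {k: tuple(v) for k, v in shift.items()}
    return out


#: Per-marker direction of the high-severity coagulation-inflammatory
#: profile: prolonged APTT/INR, raised leukocyte lineages, lower PLT.
CIS2_DIRECTION = {
    "aptt": 1.0,
    "inr": 1.0,
    "wbc": 1.0,
    "neut": 1.0,
    "lym": 1.0,
    "mon": 1.0,
    "plt": -1.0,
}


def make_two_subpopulations(
    config: GeneratorConfig,
    separation: float,
    weight: float | None = None,
) -> pd.DataFrame:
    """Generate a cohort with two latent marker subpopulations.

    ``separation`` is the per-marker mean shift between the components,
    in units of each marker's scale parameter, applied along the
    high-severity profile direction (latent label 1 = higher APTT, INR
    and leukocyte counts, lower PLT).
    """
    if separation < 0:
        raise ConfigError("separation must be >= 0")
    sub = SubpopConfig(
        shift={m: s * separation for m, s in CIS2_DIRECTION.items()},
        weight=weight if weight is not None else (
            config.subpop_mixture.weight if config.subpop_mixture else 0.2
        ),
    )
    return generate_cohort(replace(config, subpop_mixture=sub))
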