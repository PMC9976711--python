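"""Configuration objects for the simulation and analysis pipeline.

``SimConfig`` fully determines a synthetic family panel (seeded);
``PipelineConfig`` wraps it together with the analysis options and output
paths used by the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration block fails validation."""


# Structural paths of the social model: three parenting predictors
# (father quality ``fq``, mother quality ``mq``, monitoring ``mon``) to each
# of three mediators, plus six predictors of the resistance outcome.
MEDIATORS = ("peer", "partner", "soc")
PARENT_PREDICTORS = ("fq", "mq", "mon")
STRUCTURAL_PATHS = tuple(
    f"{m}~{p}" for m in MEDIATORS for p in PARENT_PREDICTORS
) + tuple(f"resist~{v}" for v in PARENT_PREDICTORS + MEDIATORS)
EXOG_COVS = ("fq~~mq", "fq~~mon", "mq~~mon")

_DEFAULT_PATHS: dict[str, float] = {
    # mediator block (loosely in the range of the published standardized effects)
    "peer~fq": -0.05,
    "peer~mq": -0.15,
    "peer~mon": -0.10,
    "partner~fq": -0.10,
    "partner~mq": -0.05,
    "partner~mon": -0.10,
    "soc~fq": 0.10,
    "soc~mq": 0.10,
    "soc~mon": 0.05,
    # outcome block: positive = onset sooner than expected (lower resistance)
    "resist~fq": -0.15,
    "resist~mq": -0.05,
    "resist~mon": -0.05,
    "resist~peer": 0.20,
    "resist~partner": 0.10,
    "resist~soc": 0.05,
    # exogenous correlations
    "fq~~mq": 0.50,
    "fq~~mon": 0.30,
    "mq~~mon": 0.30,
}

_DEFAULT_LOADINGS = {
    "father": (0.85, 0.75, 0.60, 0.55),
    "mother": (0.85, 0.75, 0.60, 0.55),
}

_DEFAULT_LOG_HR = {
    "initiation": {"liability": 0.30, "prs": 0.10, "resist": 0.35},
    "hed": {"liability": 0.35, "prs": 0.10, "resist": 0.35},
}


def _as_phenotype_dict(value: Any, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {str(k): float(v) for k, v in value.items()}
        missing = {"initiation", "hed"} - set(out)
        if missing:
            raise ConfigError(f"{name} must define both phenotypes; missing {sorted(missing)}")
        return out
    return {"initiation": float(value), "hed": float(value)}


@dataclass
class SimConfig:
    """Parameters of the synthetic family-panel generator.

    The seed fully determines the output: every stage derives its own
    ``numpy`` generator from ``(seed, stage-tag)`` so that re-running any
    stage reproduces its draws bit-identically.
    """

    n_families: int = 300
    mean_family_size: float = 2.0
    mean_relatives: float = 4.0
    relatedness_mix: tuple[float, float] = (0.6, 0.4)
    h2_liability: float = 0.5
    prs_r2: float = 0.15
    loadings: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_LOADINGS.items()}
    )
    path_matrix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PATHS))
    hazard_shape: float = 3.0
    hazard_scale: Any = field(default_factory=lambda: {"initiation": 17.0, "hed": 21.0})
    log_hr: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LOG_HR.items()}
    )
    censor_age_range: tuple[float, float] = (18.0, 30.0)
    aud_prev_target: float = 0.12
    missing_rate_per_stage: float = 0.25
    discretize_items: bool = True
    item_reliability: float = 0.75
    relative_symptom_intercept: float = -0.2
    relative_symptom_slope: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError("n_families must be non-negative")
        if self.mean_family_size <= 0:
            raise ConfigError("mean_family_size must be positive")
        mix = tuple(float(x) for x in self.relatedness_mix)
        if len(mix) != 2 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError("relatedness_mix must be two non-negative proportions summing to 1")
        self.relatedness_mix = mix
        for name in ("h2_liability", "prs_r2", "aud_prev_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.missing_rate_per_stage < 1.0:
            raise ConfigError("missing_rate_per_stage must lie in [0, 1)")
        if not 0.0 < self.item_reliability <= 1.0:
            raise ConfigError("item_reliability must lie in (0, 1]")
        if self.hazard_shape <= 0:
            raise ConfigError("hazard_shape must be positive")
        self.hazard_scale = _as_phenotype_dict(self.hazard_scale, "hazard_scale")
        if any(s <= 0 for s in self.hazard_scale.values()):
            raise ConfigError("hazard_scale values must be positive")
        for pheno, hrs in self.log_hr.items():
            for k, v in hrs.items():
                if not np.isfinite(v):
                    raise ConfigError(f"log_hr[{pheno!r}][{k!r}] must be finite, got {v}")
        lo, hi = (float(x) for x in self.censor_age_range)
        if not 0 < lo <= hi:
            raise ConfigError("censor_age_range must satisfy 0 < min <= max")
        self.censor_age_range = (lo, hi)
        self.loadings = {k: tuple(float(x) for x in v) for k, v in self.loadings.items()}
        for parent, lams in self.loadings.items():
            if len(lams) != 4:
                raise ConfigError(f"loadings[{parent!r}] must have 4 entries")
            if any(not 0.0 < lam < 1.0 for lam in lams):
                raise ConfigError(f"loadings[{parent!r}] must lie in the open interval (0, 1)")
        unknown = set(self.path_matrix) - set(STRUCTURAL_PATHS) - set(EXOG_COVS)
        if unknown:
            raise ConfigError(f"unknown path_matrix entries: {sorted(unknown)}")
        self._check_social_covariance()

    def _check_social_covariance(self) -> None:
        """The implied covariance of (latents, mediators, outcome) must be PD."""
        sigma = self.social_covariance()
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals.min() <= 1e-10:
            raise ConfigError(
                "implied covariance of the social block (fq, mq, mon, peer, partner, "
                f"soc, resist) is not positive definite (min eigenvalue {eigvals.min():.3g}); "
                "reduce path coefficients or exogenous correlations"
            )

    # -- derived quantities ----------------------------------------------
    def social_covariance(self) -> np.ndarray:
        """Model-implied covariance of the standardized social-block variables.

        Order: fq, mq, mon, peer, partner, soc, resist.  All variables are
        unit-variance by construction (standardized structural coefficients
        with disturbance variance chosen to complete each variance to 1).
        """
        order = list(PARENT_PREDICTORS) + list(MEDIATORS) + ["resist"]
        k = len(order)
        idx = {v: i for i, v in enumerate(order)}
        A = np.zeros((k, k))
        for key in STRUCTURAL_PATHS:
            lhs, rhs = key.split("~")
            A[idx[lhs], idx[rhs]] = self.path_matrix.get(key, 0.0)
        psi = np.zeros((k, k))
        for i in range(3):
            psi[i, i] = 1.0
        for key in EXOG_COVS:
            a, b = key.split("~~")
            psi[idx[a], idx[b]] = psi[idx[b], idx[a]] = self.path_matrix.get(key, 0.0)
        binv = np.linalg.inv(np.eye(k) - A)
        # complete disturbance variances so every variable has unit variance
        for i in range(3, k):
            partial = binv @ psi @ binv.T
            resid = 1.0 - partial[i, i]
            if resid <= 0:
                raise ConfigError(
                    f"standardized paths into {order[i]!r} imply explained variance "
                    f">= 1 ({partial[i, i]:.3f}); shrink the coefficients"
                )
            # recursive model in topological order: binv[i, i] == 1 and the
            # disturbance of i feeds no upstream variable, so the residual
            # completes the variance of variable i to exactly 1
            psi[i, i] = resid
        return binv @ psi @ binv.T

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "little"))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["relatedness_mix"] = list(self.relatedness_mix)
        d["censor_age_range"] = list(self.censor_age_range)
        d["loadings"] = {k: list(v) for k, v in self.loadings.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "relatedness_mix" in kwargs:
            kwargs["relatedness_mix"] = tuple(kwargs["relatedness_mix"])
        if "censor_age_range" in kwargs:
            kwargs["censor_age_range"] = tuple(kwargs["censor_age_range"])
        if "loadings" in kwargs:
            kwargs["loadings"] = {k: tuple(v) for k, v in kwargs["loadings"].items()}
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Options for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "out"
    input_subjects: str | None = None  # if set, skip simulation and read CSVs
    input_relatives: str | None = None
    cluster_mode: str = "gamma_frailty"  # or "robust"
    fhd_form: str = "weighted_mean"  # or "weighted_sum"
    fhd_log_base: str = "natural"  # or "log10"
    quadrature_nodes: int = 15
    sem_starts: int = 3
    alpha: float = 0.05
    residual_frailty: str = "conditional"  # or "marginal"
    tie_method: str = "breslow"  # or "efron"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.cluster_mode not in ("gamma_frailty", "robust"):
            raise ConfigError("cluster_mode must be 'gamma_frailty' or 'robust'")
        if self.fhd_form not in ("weighted_mean", "weighted_sum"):
            raise ConfigError("fhd_form must be 'weighted_mean' or 'weighted_sum'")
        if self.fhd_log_base not in ("natural", "log10"):
            raise ConfigError("fhd_log_base must be 'natural' or 'log10'")
        if self.quadrature_nodes < 2:
            raise ConfigError("quadrature_nodes must be >= 2")
        if self.sem_starts < 1:
            raise ConfigError("sem_starts must be >= 1")
        if self.residual_frailty not in ("conditional", "marginal"):
            raise ConfigError("residual_frailty must be 'conditional' or 'marginal'")
        if self.tie_method not in ("breslow", "efron"):
            raise ConfigError("tie_method must be 'breslow' or 'efron'")
        if isinstance(self.sim, Mapping):
            self.sim = SimConfig.from_dict(self.sim)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d
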