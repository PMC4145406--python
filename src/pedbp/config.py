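"""Study configuration: every model parameter with its published default,
serializable to/from YAML without loss.

The defaults reproduce the generating model of the simulated study:
covariate effects, heritability targets (0.279 SBP, 0.317 DBP, 0.68 Q1),
treatment and smoking rates, environmental correlations, the 1000-variant
polygenic background, and the study design of 20 extended families with
~849 phenotyped individuals over 200 replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .traits import DEFAULT_ENV_CORR, CovariateParams, Q1Params
from .treatment import TreatmentParams

__all__ = ["StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    # study design
    n_families: int = 20
    family_size_range: tuple[int, int] = (21, 76)
    n_mz_pairs: int = 2
    n_individuals: int = 849  # phenotyped subsample target
    n_replicates: int = 200
    base_seed: int = 0
    # genetic model
    h2_sbp: float = 0.279
    h2_dbp: float = 0.317
    n_background: int = 1000
    n_background_candidates: int = 2000
    # phenotypic variances used as variance-explained denominators,
    # calibrated once so the largest catalog variant reproduces its
    # published percentage under Hardy-Weinberg dosage variance
    sigma2_sbp: float = 217.5
    sigma2_dbp: float = 104.0
    # sub-models
    covariates: CovariateParams = field(default_factory=CovariateParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    q1: Q1Params = field(default_factory=Q1Params)
    env_corr: list = field(default_factory=lambda: DEFAULT_ENV_CORR.tolist())
    # output
    output_dir: str = "pedbp_study"
    debug: bool = False

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_families < 1:
            raise ConfigError("n_replicates and n_families must be positive")
        if not (0 < self.h2_sbp < 1 and 0 < self.h2_dbp < 1):
            raise ConfigError("heritability targets must be in (0, 1)")
        arr = np.asarray(self.env_corr, dtype=float)
        if arr.shape != (6, 6):
            raise ConfigError("env_corr must be a 6x6 matrix")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["family_size_range"] = list(self.family_size_range)
        d["treatment"]["treat_prob_by_exam"] = list(self.treatment.treat_prob_by_exam)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        if "family_size_range" in data:
            data["family_size_range"] = tuple(data["family_size_range"])
        for key, sub in (("covariates", CovariateParams), ("treatment", TreatmentParams), ("q1", Q1Params)):
            if key in data and isinstance(data[key], dict):
                subdata = dict(data[key])
                subknown = {f.name for f in dataclasses.fields(sub)}
                bad = sorted(set(subdata) - subknown)
                if bad:
                    raise ConfigError(f"unknown config keys under {key}: {bad}")
                if "treat_prob_by_exam" in subdata:
                    subdata["treat_prob_by_exam"] = tuple(subdata["treat_prob_by_exam"])
                data[key] = sub(**subdata)
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def digest(self) -> str:
        """Stable hash of the full configuration (for manifests)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
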