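"""Study configuration: nested configs, TOML loading, seed derivation.

A single master seed in :class:`StudyConfig` feeds every stochastic stage
through a stage-name-keyed derivation scheme, so each stage is independently
reproducible and insensitive to the order in which other stages run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import ClassificationRules
from .cutoffs import BootstrapConfig, SplitConfig
from .exceptions import ConfigurationError
from .indices import ConversionConfig

__all__ = ["StudyConfig", "derive_seed", "derive_rng"]

_ALL_STRATA = ("combined", "male", "female")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed (stays < 2^31)."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))


@dataclass
class StudyConfig:
    """All tunables of the end-to-end cut-off study."""

    conversion: ConversionConfig = field(default_factory=ConversionConfig)
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    split: SplitConfig = field(default_factory=SplitConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    cutoff_method: str = "percentile"          # percentile | roc_youden
    ir_definition: str = "t2d_all"             # t2d_all | t2d_newly_diagnosed
    strata: tuple[str, ...] = _ALL_STRATA
    run_sensitivity_newdx: bool = True
    bootstrap_resample: str = "whole"          # whole | is_only
    quantile_method: str = "linear"
    min_reference: int = 20
    fasting_missing_policy: str = "strict"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_method not in ("percentile", "roc_youden"):
            raise ConfigurationError(f"unknown cutoff_method {self.cutoff_method!r}")
        if self.ir_definition not in ("t2d_all", "t2d_newly_diagnosed"):
            raise ConfigurationError(f"unknown ir_definition {self.ir_definition!r}")
        unknown = set(self.strata) - set(_ALL_STRATA)
        if unknown:
            raise ConfigurationError(f"unknown strata: {sorted(unknown)}")
        # the split and bootstrap seeds are slaved to the master seed
        object.__setattr__(
            self, "split",
            dataclasses.replace(self.split, seed=derive_seed(self.seed, "split")),
        )
        object.__setattr__(
            self, "bootstrap",
            dataclasses.replace(
                self.bootstrap, seed=derive_seed(self.seed, "bootstrap")
            ),
        )

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        """Build a config from a TOML file with [conversion]/[rules]/[split]/
        [bootstrap]/[study] tables; absent keys keep their defaults."""
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)

        def _sub(cls_, key):
            kwargs = doc.get(key, {})
            # TOML arrays come back as lists; tuple-typed fields need tuples
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v for k, v in kwargs.items()
            }
            return cls_(**kwargs)

        study = doc.get("study", {})
        if "strata" in study:
            study["strata"] = tuple(study["strata"])
        return cls(
            conversion=_sub(ConversionConfig, "conversion"),
            rules=_sub(ClassificationRules, "rules"),
            split=_sub(SplitConfig, "split"),
            bootstrap=_sub(BootstrapConfig, "bootstrap"),
            **study,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["strata"] = list(self.strata)
        return out

    def hash(self) -> str:
        """Stable content hash so reports are never compared across configs."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
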