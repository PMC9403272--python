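"""Run configuration shared by the CLI entry points."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

logger = logging.getLogger("scfaprof")


@dataclass
class RunConfig:
    identity_threshold: float = 90.0
    coverage_threshold: float = 0.75
    carrier_threshold: float = 0.5
    sigma_mode: str = "sqrt"  # sqrt | raw
    variability_mode: str = "gini"  # gini | population | sample
    trim_m: float = 0.30
    trim_a: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in [0, 100]")
        for name in ("coverage_threshold", "carrier_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("trim_m", "trim_a"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.sigma_mode not in ("sqrt", "raw"):
            raise ValueError("sigma_mode must be 'sqrt' or 'raw'")
        if self.variability_mode not in ("gini", "population", "sample"):
            raise ValueError("variability_mode must be gini|population|sample")
        return self

    def log(self) -> None:
        logging.basicConfig(level=getattr(logging, self.log_level.upper(), logging.INFO))
        logger.info("resolved run config: %s", asdict(self))
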