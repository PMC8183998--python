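"""Pipeline configuration: the analysis thresholds in one place.

Defaults are the values the analyses are defined with: imbalance and
heterogeneity FDR 0.10; depth >= 10 in both conditions and >= 3
observations per allele; MAF > 0.05; 5 Mb locus window with r^2 > 0.1;
99% credible sets; Wakefield prior variance 0.04; colocalization priors
(1e-4, 1e-4, 1e-5) with a shared-PP call threshold of 0.80; 1 Mb
enrichment windows; 100 kb proximity window; 100,000 permutations for
the reporter test. Config files are flat ``key = value`` text; unknown
keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    imbalance_fdr: float = 0.10
    heterogeneity_fdr: float = 0.10
    min_depth: int = 10
    min_allele_obs: int = 3
    proximity_window: int = 100_000
    enrichment_window: int = 1_000_000
    locus_window: int = 5_000_000
    r2_min: float = 0.1
    maf_threshold: float = 0.05
    credible_level: float = 0.99
    coloc_threshold: float = 0.80
    prior_variance: float = 0.04
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    n_perm: int = 100_000
    seed: int = 0

    def __post_init__(self):
        checks = {
            "imbalance_fdr": 0 < self.imbalance_fdr < 1,
            "heterogeneity_fdr": 0 < self.heterogeneity_fdr < 1,
            "min_depth": self.min_depth >= 0,
            "min_allele_obs": self.min_allele_obs >= 0,
            "proximity_window": self.proximity_window >= 0,
            "enrichment_window": self.enrichment_window > 0,
            "locus_window": self.locus_window > 0,
            "r2_min": 0 <= self.r2_min < 1,
            "maf_threshold": 0 <= self.maf_threshold < 0.5,
            "credible_level": 0 < self.credible_level <= 1,
            "coloc_threshold": 0 <= self.coloc_threshold < 1,
            "prior_variance": self.prior_variance > 0,
            "coloc_p1": 0 < self.coloc_p1 < 1,
            "coloc_p2": 0 < self.coloc_p2 < 1,
            "coloc_p12": 0 < self.coloc_p12 < 1,
            "n_perm": self.n_perm >= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config values out of domain: {bad}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for key, value in d.items():
            default = getattr(cls, key)
            coerced[key] = type(default)(value)
        return cls(**coerced)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat ``key = value`` text; '#' starts a comment."""
        d = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            d[key] = value
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
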