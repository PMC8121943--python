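"""Run configuration: thresholds, paths, seed.

Defaults are the analysis constants of the method: analysed SNPs need
MAF > 0.005; the correlation-estimation pool is MAF < 5e-4; the KS
uniformity screen keeps SNPs with p < 0.1; phenotypes correlated above
0.9 are pruned; decorrelation keeps 90% of the eigenvalue mass; EM runs
at most 9999 iterations; loci with theta-hat > 2 are highlighted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from .sumstats import PhenotypeMeta


class ConfigError(ValueError):
    """A configuration key is unknown or outside its documented domain."""


@dataclass
class RunConfig:
    sumstat_files: list = field(default_factory=list)
    phenotype_table: Optional[str] = None
    out_dir: str = "tgca_out"
    min_maf: float = 0.005
    lowmaf_max: float = 5e-4
    ks_alpha: float = 0.1
    corr_prune: float = 0.9
    corr_shrinkage: Optional[str] = "auto"
    info_cut: float = 0.9
    report_theta: float = 2.0
    max_iter: int = 9999
    tol: float = 1e-8
    n_starts: int = 5
    min_nonmissing: int = 50_000
    min_cases: int = 1_000
    seed: int = 0

    def validate(self) -> "RunConfig":
        checks = {
            "min_maf": 0 <= self.min_maf < 0.5,
            "lowmaf_max": 0 < self.lowmaf_max < 0.5,
            "ks_alpha": 0 < self.ks_alpha <= 1,
            "corr_prune": 0 < self.corr_prune <= 1,
            "corr_shrinkage": self.corr_shrinkage in (None, "auto"),
            "info_cut": 0 < self.info_cut <= 1,
            "report_theta": self.report_theta >= 0,
            "max_iter": self.max_iter >= 1,
            "tol": self.tol > 0,
            "n_starts": self.n_starts >= 1,
            "min_nonmissing": self.min_nonmissing >= 0,
            "min_cases": self.min_cases >= 0,
        }
        for key, ok in checks.items():
            if not ok:
                raise ConfigError(
                    f"config key {key!r} = {getattr(self, key)!r} is outside "
                    "its documented domain"
                )
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(f"{path}: unknown config key {key!r}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_phenotype_table(path) -> list[PhenotypeMeta]:
    """Tab-separated phenotype metadata: phenotype_id, trait_type, n_total,
    n_cases (blank for non-binary), domain_label."""
    df = pd.read_csv(path, sep="\t")
    metas = []
    for _, row in df.iterrows():
        n_cases = row.get("n_cases")
        n_cases = None if pd.isna(n_cases) or n_cases == "" else int(n_cases)
        domain = row.get("domain_label")
        domain = None if pd.isna(domain) or domain == "" else str(domain)
        metas.append(
            PhenotypeMeta(
                phenotype_id=str(row["phenotype_id"]),
                trait_type=str(row["trait_type"]),
                n_total=int(row["n_total"]),
                n_cases=n_cases,
                domain_label=domain,
            )
        )
    return metas
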