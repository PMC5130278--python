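"""Run configuration: one validated block per pipeline stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from longprs.assoc import FilterSpec
from longprs.mrpower import PowerQuery
from longprs.prs import DEFAULT_THRESHOLDS
from longprs.simcohort import (CohortDesign, GeneticArchitecture,
                               VarianceComponents, mother_design,
                               offspring_design)

__all__ = ["CohortConfig", "RunConfig", "default_config"]


@dataclass
class CohortConfig:
    """Simulation settings for one cohort."""

    name: str
    design: CohortDesign
    architecture: GeneticArchitecture
    variance: VarianceComponents = field(default_factory=VarianceComponents)
    n_pcs: int = 10
    n_confounders: int = 48


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs, validated up front."""

    seed: int
    cohorts: list
    panel_m: int = 89
    filters: FilterSpec = field(default_factory=FilterSpec)
    thresholds: tuple = DEFAULT_THRESHOLDS
    train_fraction: float = 0.8
    repeats: int = 5
    avengeme_pi0: float | str = 0.0
    mr_queries: tuple = ()
    outdir: str = "longprs_run"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.cohorts:
            raise ValueError("at least one cohort block is required")
        for t in self.thresholds:
            if not 0 < t <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if isinstance(self.avengeme_pi0, str) and self.avengeme_pi0 != "estimate":
            raise ValueError("avengeme_pi0 must be a number or 'estimate'")

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration (output path excluded),
        stamped into every artifact."""
        payload = _to_jsonable(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cohorts = []
        for cb in raw.get("cohorts", []):
            base = mother_design if cb.get("cohort", "mother") == "mother" else offspring_design
            design = base(cb.get("n_individuals", 2000),
                          **cb.get("design_overrides", {}))
            arch = GeneticArchitecture(
                m=raw.get("panel_m", 89),
                vg=cb.get("vg", 0.10), pi0=cb.get("pi0", 0.5),
                seed=cb.get("effect_seed", raw.get("seed", 0)))
            vc = VarianceComponents(**cb.get("variance", {}))
            cohorts.append(CohortConfig(
                name=cb.get("name", cb.get("cohort", "mother")),
                design=design, architecture=arch, variance=vc,
                n_pcs=cb.get("n_pcs", 10),
                n_confounders=cb.get("n_confounders", 48)))
        filters = FilterSpec(**raw.get("filters", {}))
        queries = tuple(PowerQuery(**q) for q in raw.get("mr_queries", []))
        return cls(
            seed=raw["seed"], cohorts=cohorts,
            panel_m=raw.get("panel_m", 89),
            filters=filters,
            thresholds=tuple(raw.get("thresholds", DEFAULT_THRESHOLDS)),
            train_fraction=raw.get("train_fraction", 0.8),
            repeats=raw.get("repeats", 5),
            avengeme_pi0=raw.get("avengeme_pi0", 0.0),
            mr_queries=queries,
            outdir=raw.get("outdir", "longprs_run"),
        )


def default_config(seed: int = 1, outdir: str = "longprs_run") -> RunConfig:
    """Demo configuration: both cohorts, 89 SNPs, vg = 0.10, pi0 = 0.5."""
    cohorts = [
        CohortConfig(
            name="mother", design=mother_design(2000),
            architecture=GeneticArchitecture(m=89, vg=0.10, pi0=0.5, seed=seed)),
        CohortConfig(
            name="offspring", design=offspring_design(1500),
            architecture=GeneticArchitecture(m=89, vg=0.10, pi0=0.5, seed=seed + 1)),
    ]
    queries = (
        PowerQuery(odds_ratio=0.75, r2=0.003),
        PowerQuery(odds_ratio=0.75, r2=0.007),
        PowerQuery(odds_ratio=0.71, r2=0.003),
        PowerQuery(odds_ratio=0.71, r2=0.007),
    )
    return RunConfig(seed=seed, cohorts=cohorts, mr_queries=queries, outdir=outdir)


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
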