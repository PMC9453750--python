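"""Run configuration: YAML round-trip and seed fan-out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .collab_training import TrainPlan


@dataclass
class RunConfig:
    # pool source: either a synthetic profile YAML (or "canonical") or a tidy CSV
    pool_source: str = "canonical"
    size_scale: float = 1.0
    truncate_T: int = 95
    split_fraction: float = 0.8
    seed: int = 0
    plans: list[TrainPlan] = field(default_factory=list)
    evaluate: bool = True
    simulate: bool = True
    n_off_policy_trials: int = 30
    out_dir: str = "runs/out"

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global one (stable by stage name)."""
        import zlib

        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(h.generate_state(1)[0] % 2**31)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        plans = [TrainPlan(**p) for p in d.pop("plans", [])]
        return cls(plans=plans, **d)


def default_plans(seed: int = 0) -> list[TrainPlan]:
    """The eight collaborative models: CL, FL, and IL/CIL in three orders."""
    plans = [
        TrainPlan(paradigm="CL", seed=seed),
        TrainPlan(paradigm="FL", seed=seed),
    ]
    for order in ("ascending", "descending", "random"):
        plans.append(TrainPlan(paradigm="IL", ordering=order, seed=seed))
        plans.append(TrainPlan(paradigm="CIL", ordering=order, seed=seed))
    return plans


def plan_label(plan: TrainPlan) -> str:
    if plan.paradigm in ("IL", "CIL"):
        short = {"ascending": "asc", "descending": "desc", "random": "rand"}[plan.ordering]
        return f"{plan.paradigm}_{short}"
    return plan.paradigm
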