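"""Top-level design pipeline: evolve, rank by robustness, screen, analyze.

``run_pipeline`` chains the stages end to end, mirroring the
generator-and-filter architecture: independent evolutionary trials
produce one champion each; champions are ranked by robustness to
actuation noise; the ranked list is screened by the build filter; and
every surviving design runs the repeated-evaluation protocol, writing
trajectory files.

All outputs are plain text under a fixed layout (designs/,
trajectories/, reports/, manifest.yaml, log.txt) and are byte-identical
across reruns with the same master seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import filters as F
from . import io as vio
from .analysis import evaluate_protocol
from .errors import ConfigurationError
from .evolution import EvolutionConfig, run_trials
from .physics import GRAVITY_REFERENCE


@dataclasses.dataclass
class PipelineConfig:
    evolution: EvolutionConfig = dataclasses.field(default_factory=EvolutionConfig)
    robustness: F.RobustnessConfig = dataclasses.field(
        default_factory=F.RobustnessConfig)
    build: F.BuildFilterConfig = dataclasses.field(
        default_factory=F.BuildFilterConfig)
    protocol_evals: int = 25
    protocol_time: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        self.evolution.validate()
        self.robustness.validate()
        self.build.validate()
        if self.protocol_evals < 1 or self.protocol_time <= 0:
            raise ConfigurationError("protocol needs >=1 evals and time > 0")

    def resolved(self) -> dict:
        """Every constant affecting results, for the manifest."""

        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = plain(dataclasses.asdict(self))
        d["gravity_reference"] = GRAVITY_REFERENCE
        d["format_version"] = vio.FORMAT_VERSION
        return d


def _dataclass_from_dict(cls, data):
    if data is None:
        return cls()
    kwargs = {}
    for field in dataclasses.fields(cls):
        if field.name not in data:
            continue
        value = data[field.name]
        if dataclasses.is_dataclass(field.type) and isinstance(value, dict):
            value = _dataclass_from_dict(field.type, value)
        elif isinstance(value, dict) and hasattr(field.default_factory, "__call__"):
            proto = field.default_factory()
            if dataclasses.is_dataclass(proto):
                value = _dataclass_from_dict(type(proto), value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[field.name] = value
    return cls(**kwargs)


def load_pipeline_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _dataclass_from_dict(PipelineConfig, data)
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig, out_dir,
                 seed: Optional[int] = None) -> Path:
    """Execute the full pipeline and return the output directory.

    Stage order: run_trials -> robustness_rank -> build_filter ->
    evaluate_protocol on passers. Partial outputs are flushed stage by
    stage, so a failure leaves earlier stages on disk.
    """
    config.validate()
    if seed is not None:
        config.seed = int(seed)
    config.evolution.seed = config.seed
    out = Path(out_dir)
    for sub in ("designs", "trajectories", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    events: list = []

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    stage = ["evolution"]
    try:
        return _run_stages(config, out, events, stage)
    except Exception as exc:
        # Halt naming the stage; partial outputs of earlier stages remain.
        (out / "log.txt").write_text(
            "\n".join(events + [f"pipeline halted in stage {stage[0]}: {exc}"])
            + "\n")
        raise


def _run_stages(config: PipelineConfig, out: Path, events: list,
                stage: list) -> Path:
    # Stage 1: evolutionary trials.
    stage[0] = "evolution"
    results = run_trials(config.evolution, events=events)
    champions = []
    for i, res in enumerate(results):
        champ = res.champion
        champ.design.name = f"champion_{i:03d}"
        vio.write_design(champ.design, out / "designs" / f"champion_{i:03d}.txt")
        vio.write_genome(champ.genome, out / "designs" / f"champion_{i:03d}.genome.txt")
        res.log_dataframe().to_csv(
            out / "reports" / f"trial_{i:03d}_log.csv", index=False,
            float_format="%.9g")
        champions.append(champ.design)

    # Stage 2+3: robustness ranking, then manufacturability screen on the
    # ranked order.
    stage[0] = "robustness_filter"
    rng = np.random.default_rng(config.seed)
    ranked = F.robustness_rank(champions, config.robustness,
                               seed=int(rng.integers(2**31 - 1)), log=events)
    by_id = {d.name: d for d in champions}
    ranked_designs = [by_id[e.design_id] for e in ranked]
    stage[0] = "build_filter"
    entries = F.build_filter(ranked_designs, config.build, entries=ranked)
    F.report_to_dataframe(entries).to_csv(out / "reports" / "filter_report.csv",
                                          index=False, float_format="%.9g")

    # Stage 4: repeated-evaluation protocol on build-filter passers.
    stage[0] = "protocol"
    for entry, design in zip(entries, ranked_designs):
        if not entry.passed:
            continue
        sims = evaluate_protocol(
            design, n_evals=config.protocol_evals,
            eval_time=config.protocol_time,
            seed=int(rng.integers(2**31 - 1)),
            env=config.robustness.env, sim=config.robustness.sim,
            act=config.robustness.act,
            phase_noise_sd=config.robustness.phase_noise_sd)
        for j, res in enumerate(sims):
            vio.write_trajectory(
                res, out / "trajectories" / f"{entry.design_id}_eval{j:02d}.csv")

    (out / "log.txt").write_text("\n".join(events) + "\n" if events else "")
    return out
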