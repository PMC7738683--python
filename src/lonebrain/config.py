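"""Pipeline configuration, stage seeding, and logging setup."""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .deconfound import DEFAULT_CONFOUNDS
from .simulate import GeneratorConfig

__all__ = ["PipelineConfig", "stage_seed", "setup_logging", "load_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stable hash of the stage name mixed with
    the master seed (kept below 2**31)."""
    h = zlib.crc32(stage.encode("utf-8"))
    return int(
        np.random.SeedSequence([master_seed, h]).generate_state(1, np.uint32)[0]
        % (2**31)
    )


@dataclass
class VolumeModelConfig:
    kind: str = "network_level"
    chains: int = 4
    tune: int = 1000
    draws: int = 1000
    sigma_scale: float = 1.0
    lkj_eta: float = 2.0
    diagonal: bool = False
    target_accept: float = 0.8
    max_treedepth: int = 10
    paper_settings: bool = False


@dataclass
class PipelineConfig:
    """One config drives simulate -> deconfound -> three analysis arms.

    Exactly one of ``simulate`` (generator settings) or ``inputs`` (paths to
    the four cohort tables) must be provided.
    """

    out_dir: str = "lonebrain_out"
    seed: int = 0
    simulate: GeneratorConfig | None = None
    inputs: dict[str, str] | None = None
    confounds: tuple[str, ...] = DEFAULT_CONFOUNDS
    volume_model: VolumeModelConfig = field(default_factory=VolumeModelConfig)
    n_permutations: int = 1000
    n_bootstrap: int = 100
    stratify_sex: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulate' or 'inputs'")

    def to_yaml(self) -> str:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return yaml.safe_dump(d, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ValueError(f"{path}: empty config")
    sim = raw.pop("simulate", None)
    if sim is not None:
        for key in ("sigma_per_network",):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        sim = GeneratorConfig(**sim)
    vm = raw.pop("volume_model", None)
    vm = VolumeModelConfig(**vm) if vm is not None else VolumeModelConfig()
    if "confounds" in raw:
        raw["confounds"] = tuple(raw["confounds"])
    return PipelineConfig(simulate=sim, volume_model=vm, **raw)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Structured logging to stderr and optionally a logfile."""
    logger = logging.getLogger("lonebrain")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
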