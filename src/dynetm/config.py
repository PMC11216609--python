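"""Run configuration, YAML round-tripping, logging and seed fan-out."""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .inference import TrainConfig


def substream_seed(seed: int, name: str) -> int:
    """Derive a named, stable sub-seed (< 2**31) from the global seed.

    Stages (simulate / split / train / classify / embed) get independent
    reproducible streams, so any stage can be re-run in isolation.
    """
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) % (2 ** 31)


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run."""

    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    train: TrainConfig = field(default_factory=TrainConfig)
    p_coherence: int = 10
    p_diversity: int = 25
    window: int = 5
    measures: tuple[str, ...] = ("ca", "cp", "npmi")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["measures"] = list(self.measures)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        train = TrainConfig(**d.pop("train", {}))
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(train=train, **d)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text(encoding="utf-8"))


def setup_run_dir(cfg: RunConfig) -> Path:
    """Create the output directory, write the resolved config, attach a log file."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml(), encoding="utf-8")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dynetm")
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    root.addHandler(handler)
    return out
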