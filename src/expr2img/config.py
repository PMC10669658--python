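"""Pipeline configuration: one document drives every stage.

The file is YAML with one level of stage namespacing; every field has the
published default, so a bundled synthetic run needs zero flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .ingest import TASKS
from .simdata import SimConfig


@dataclass
class PipelineConfig:
    # io
    outdir: str = "runs/out"
    input_tsvs: list[str] = field(default_factory=list)  # empty -> simulate
    # simulate
    sim: SimConfig = field(default_factory=SimConfig)
    # select
    lam: float = 1e-6
    # map
    n_categories: int = 15
    resolution: tuple[int, int] = (50, 50)
    # train
    feature_dim: int = 32
    learning_rate: float = 1e-4
    batch_size: int = 30
    min_epochs_before_stop: int = 250
    patience: int = 10
    max_epochs: int = 2000
    # evaluate
    task: str = "AD_vs_NC"
    folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if self.lam <= 0:
            raise ConfigError("lambda must be > 0")
        if self.n_categories < 2:
            raise ConfigError("categories must be >= 2")
        rows, cols = self.resolution
        if rows < 2 or cols < 2:
            raise ConfigError("resolution must be at least 2x2")
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; known: {sorted(TASKS)}")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")

    # -- YAML round trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        io = doc.get("io", {})
        cfg.outdir = io.get("outdir", cfg.outdir)
        cfg.input_tsvs = list(io.get("input_tsvs", []))
        sim = doc.get("simulate", {})
        if sim:
            base = asdict(cfg.sim)
            for key in ("batch_scale_range", "batch_offset_range", "classes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            unknown = set(sim) - set(base)
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
            base.update(sim)
            cfg.sim = SimConfig(**base)
        sel = doc.get("select", {})
        cfg.lam = float(sel.get("lambda", cfg.lam))
        mp = doc.get("map", {})
        cfg.n_categories = int(mp.get("categories", cfg.n_categories))
        cfg.resolution = tuple(mp.get("resolution", cfg.resolution))
        tr = doc.get("train", {})
        cfg.feature_dim = int(tr.get("feature_dim", cfg.feature_dim))
        cfg.learning_rate = float(tr.get("learning_rate", cfg.learning_rate))
        cfg.batch_size = int(tr.get("batch_size", cfg.batch_size))
        cfg.min_epochs_before_stop = int(
            tr.get("min_epochs_before_stop", cfg.min_epochs_before_stop)
        )
        cfg.patience = int(tr.get("patience", cfg.patience))
        cfg.max_epochs = int(tr.get("max_epochs", cfg.max_epochs))
        ev = doc.get("evaluate", {})
        cfg.task = str(ev.get("task", cfg.task))
        cfg.folds = int(ev.get("folds", cfg.folds))
        cfg.seed = int(doc.get("seed", cfg.seed))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "io": {"outdir": self.outdir, "input_tsvs": self.input_tsvs},
            "simulate": asdict(self.sim),
            "select": {"lambda": self.lam},
            "map": {"categories": self.n_categories, "resolution": list(self.resolution)},
            "train": {
                "feature_dim": self.feature_dim,
                "learning_rate": self.learning_rate,
                "batch_size": self.batch_size,
                "min_epochs_before_stop": self.min_epochs_before_stop,
                "patience": self.patience,
                "max_epochs": self.max_epochs,
            },
            "evaluate": {"task": self.task, "folds": self.folds},
            "seed": self.seed,
        }
        for key in ("batch_scale_range", "batch_offset_range", "classes"):
            doc["simulate"][key] = list(doc["simulate"][key])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
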