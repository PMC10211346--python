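"""Configuration schema, seeding, and artifact readers/writers.

One ``RunConfig`` captures every parameter of a pipeline run and round-trips
through YAML; a single master seed deterministically derives all stage
seeds.  Trial tables are TSV, epoch arrays are HDF5 with a JSON sidecar,
screen results are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, DataError
from .synth_meg import (
    CrossTrialCoupling,
    EffectRule,
    EffectTemplate,
    EpochSet,
    NoiseParams,
    default_templates,
)
from .task_sim import AgentParams, TaskConfig
from .tfr import TfrParams

TRIAL_COLUMNS = [
    "subject_id", "block", "trial", "scheme", "choice", "outcome", "points", "rt_ms",
]


@dataclass
class RunConfig:
    """Complete, serializable description of a pipeline run."""

    n_subjects: int = 20
    master_seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    layout_n: int = 102
    layout_seed: int = 0
    templates: tuple[EffectTemplate, ...] = field(default_factory=default_templates)
    noise: NoiseParams = field(default_factory=NoiseParams)
    cross: CrossTrialCoupling | None = None
    tfr: TfrParams = field(default_factory=TfrParams)
    epoch_span_ms: tuple[float, float] = (-1750.0, 2750.0)
    baseline_span_ms: tuple[float, float] = (-750.0, 500.0)
    baseline_window_ms: tuple[float, float] = (-350.0, -50.0)
    sfreq: float = 300.0
    windows_ms: dict = field(
        default_factory=lambda: {
            "decision": (-900.0, -300.0),
            "early_feedback": (1100.0, 1500.0),
            "late_feedback": (1500.0, 1900.0),
        }
    )
    window_effects: dict = field(
        default_factory=lambda: {
            "decision": "choice_type",
            "early_feedback": "choice_type",
            "late_feedback": "interaction",
        }
    )
    q_fdr: float = 0.05
    ddf_method: str = "between-within"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = enc(self)
        d["templates"] = [dataclasses.asdict(t) for t in self.templates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            task = dict(d["task"])
            if task.get("schemes"):
                from .task_sim import ReinforcementScheme

                task["schemes"] = tuple(
                    ReinforcementScheme(**s) if isinstance(s, dict) else s
                    for s in task["schemes"]
                )
            d["task"] = TaskConfig(**task)
        if "agent" in d and isinstance(d["agent"], dict):
            d["agent"] = AgentParams(**d["agent"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        if "tfr" in d and isinstance(d["tfr"], dict):
            t = dict(d["tfr"])
            if "freqs_hz" in t:
                t["freqs_hz"] = tuple(t["freqs_hz"])
            d["tfr"] = TfrParams(**t)
        if d.get("cross") is not None and isinstance(d["cross"], dict):
            c = dict(d["cross"])
            for k in ("source_window_ms", "target_window_ms"):
                if k in c:
                    c[k] = tuple(c[k])
            d["cross"] = CrossTrialCoupling(**c)
        if "templates" in d:
            tpls = []
            for t in d["templates"]:
                if isinstance(t, EffectTemplate):
                    tpls.append(t)
                    continue
                t = dict(t)
                t["rules"] = tuple(
                    EffectRule(**r) if isinstance(r, dict) else r for r in t["rules"]
                )
                t["window_ms"] = tuple(t["window_ms"])
                tpls.append(EffectTemplate(**t))
            d["templates"] = tuple(tpls)
        for k in ("epoch_span_ms", "baseline_span_ms", "baseline_window_ms"):
            if k in d:
                d[k] = tuple(d[k])
        if "windows_ms" in d:
            d["windows_ms"] = {k: tuple(v) for k, v in d["windows_ms"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, np.random.SeedSequence]:
        """Derive one independent seed sequence per pipeline stage."""
        root = np.random.SeedSequence(self.master_seed)
        names = ("behavior", "epochs", "baseline", "layout")
        return dict(zip(names, root.spawn(len(names))))


def validate_config(cfg: RunConfig) -> list[str]:
    """Cross-field validation; returns a list of violations (empty if valid)."""
    errors = cfg.task.validate() + cfg.agent.validate()
    if cfg.n_subjects < 2:
        errors.append("n_subjects: must be >= 2")
    if cfg.layout_n < 4:
        errors.append("layout_n: must be >= 4")
    if not 0 < cfg.q_fdr < 1:
        errors.append("q_fdr: must be in (0, 1)")
    if cfg.ddf_method not in ("between-within", "residual"):
        errors.append("ddf_method: must be 'between-within' or 'residual'")
    if cfg.sfreq < 2 * max(cfg.tfr.freqs_hz):
        errors.append("sfreq: below Nyquist for the highest analysis frequency")
    try:
        cfg.tfr.common_window_duration_s()
    except ConfigError as e:
        errors.append(f"tfr: {e}")
    half_support = cfg.tfr.common_window_duration_s() * 1000.0 / 2.0
    lo = cfg.epoch_span_ms[0] + half_support
    hi = cfg.epoch_span_ms[1] - half_support
    for name, (a, b) in cfg.windows_ms.items():
        if a >= b:
            errors.append(f"windows_ms.{name}: start must precede end")
        if a - 100.0 < lo or b + 100.0 > hi + 1e-9:
            errors.append(
                f"windows_ms.{name}: window ({a}, {b}) ms exceeds the supported "
                f"epoch range [{lo}, {hi}] ms (with frame margins)"
            )
    for name in cfg.windows_ms:
        if cfg.window_effects.get(name) not in ("choice_type", "feedback", "interaction"):
            errors.append(f"window_effects.{name}: unknown or missing effect")
    a, b = cfg.baseline_window_ms
    if a < cfg.baseline_span_ms[0] + half_support or b > cfg.baseline_span_ms[1] - half_support:
        errors.append("baseline_window_ms: lacks full window support within baseline_span_ms")
    for tpl in cfg.templates:
        if tpl.window_ms[0] < cfg.epoch_span_ms[0] or tpl.window_ms[1] > cfg.epoch_span_ms[1]:
            errors.append(f"templates.{tpl.name}: window outside the epoch span")
        if not all(np.isfinite([r.delta_db for r in tpl.rules])):
            errors.append(f"templates.{tpl.name}: non-finite delta_db")
    return errors


# ---------------------------------------------------------------------------
# artifact persistence
# ---------------------------------------------------------------------------

def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trial table {path}: missing columns {missing}")
    return df


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """HDF5 array plus a JSON attribute sidecar (<path>.json)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("trial_rows", data=np.asarray(epochs.trial_rows, dtype=np.int64))
    sidecar = {
        "sfreq": epochs.sfreq,
        "t0_ms": epochs.t0_ms,
        "lock": epochs.lock,
        "schema_version": 1,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise DataError(f"read_epochs: missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("sfreq", "t0_ms", "lock"):
        if key not in sidecar:
            raise DataError(f"read_epochs: sidecar missing {key!r} (schema error)")
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        trial_rows = f["trial_rows"][()]
    return EpochSet(
        data=data,
        sfreq=float(sidecar["sfreq"]),
        t0_ms=float(sidecar["t0_ms"]),
        lock=str(sidecar["lock"]),
        trial_rows=trial_rows,
    )
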