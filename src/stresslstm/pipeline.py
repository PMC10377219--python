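"""End-to-end pipeline: simulate -> screen -> train -> evaluate.

One seeded run produces five artifacts in the output directory
(cohort.csv, report.json, model.ckpt.npz + sidecar, history.json,
metrics.json) plus a run manifest.  The screened feature subset flows
straight into the model: the trained model's sequence length T always
equals the number of selected variables.  All stage randomness is
derived from the single global seed through stage-name substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import io as _io
from .evaluation import confusion, metrics
from .model import save_checkpoint
from .screening import screen_features
from .synthetic import CohortSpec, default_spec, generate_cohort
from .training import TrainingConfig, fit, predict_cohort

__all__ = ["PipelineConfig", "PipelineError", "stage_seed", "run_pipeline"]

logger = logging.getLogger("stresslstm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    return (global_seed * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one full run."""

    out_dir: str | Path = "run"
    seed: int = 0
    alpha: float = 0.05
    training: TrainingConfig = field(default_factory=TrainingConfig)
    cohort_path: str | Path | None = None  # None -> simulate
    spec: CohortSpec | None = None  # None -> default spec
    verbosity: int = 1

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "alpha": self.alpha,
            "training": asdict(self.training),
            "cohort_path": None if self.cohort_path is None else str(self.cohort_path),
            "spec": None if self.spec is None else self.spec.to_dict(),
            "verbosity": self.verbosity,
        }
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    spec = config.spec or default_spec()
    cohort = generate_cohort(spec, seed=stage_seed(config.seed, "simulate"))
    _io.write_cohort(cohort, out / "cohort.csv")
    return cohort


@_stage("screen")
def _screen(config: PipelineConfig, cohort, out: Path):
    report = screen_features(cohort, alpha=config.alpha)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


@_stage("train")
def _train(config: PipelineConfig, cohort, features, out: Path):
    result = fit(
        cohort,
        config.training,
        seed=stage_seed(config.seed, "train"),
        feature_names=features,
    )
    save_checkpoint(
        out / "model.ckpt",
        result.params,
        result.scaler,
        meta={"seed": stage_seed(config.seed, "train"), "features": list(features)},
    )
    (out / "history.json").write_text(json.dumps(result.history.to_dict(), indent=2))
    return result


@_stage("evaluate")
def _evaluate(config: PipelineConfig, result, cohort, out: Path):
    eval_idx = result.val_index if result.val_index.size else result.train_index
    subset = cohort.iloc[eval_idx]
    prob = predict_cohort(result.params, result.scaler, subset,
                          steps=config.training.decoder_steps)
    pred = (prob >= config.training.threshold).astype(int)
    y = (subset["stress"] == "high").to_numpy(dtype=int)
    cm = confusion(y, pred)
    rep = metrics(cm)
    payload = {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "fractions": {
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
        },
        "percent": rep.as_percent(),
        "n_evaluated": int(len(subset)),
        "split": "validation" if result.val_index.size else "train",
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))
    return payload


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns paths of the written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path is None:
        cohort = _simulate(config, out)
    else:
        try:
            cohort = _io.read_cohort(config.cohort_path)
            _io.write_cohort(cohort, out / "cohort.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'load' failed: {exc}") from exc

    report = _screen(config, cohort, out)
    selected = report.selected_features
    if not selected:
        raise PipelineError("stage 'screen' failed: no variable passed the threshold")
    logger.info("screening selected %d/%d variables: %s",
                len(selected), 11, ", ".join(selected))

    result = _train(config, cohort, selected, out)
    _evaluate(config, result, cohort, out)

    artifacts = {
        "cohort": out / "cohort.csv",
        "report": out / "report.json",
        "model": out / "model.ckpt.npz",
        "history": out / "history.json",
        "metrics": out / "metrics.json",
    }
    _io.write_manifest(
        out / "manifest.json",
        seed=config.seed,
        config=config.to_dict(),
        artifacts={k: str(v) for k, v in artifacts.items()},
    )
    artifacts["manifest"] = out / "manifest.json"
    logger.info("pipeline complete: %s", out)
    return artifacts
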