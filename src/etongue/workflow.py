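"""End-to-end workflow: simulate -> compress -> select -> train -> evaluate.

One :class:`RunConfig` drives the whole pipeline with a single global
seed that fans out deterministically to the individual stages, so a rerun
with the same config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compression import WaveletSpec, build_feature_blocks
from .core_data import PotentialProgram, write_dataset
from .evaluate import compare_regression, nrmse
from .quantify import AnnTopology, predict, topology_search
from .selection import backward_eliminate
from .simulator import (
    DesignSpec,
    default_array_specs,
    random_test_points,
    simulate_mixture_dataset,
    simulate_selection_dataset,
    tilted_factorial,
)

__all__ = ["RunConfig", "WorkflowError", "run_full_workflow"]

_STAGES = (
    "array_specs",
    "selection_data",
    "selection",
    "train_mixtures",
    "test_mixtures",
    "ann_search",
)


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _default_grid() -> list[AnnTopology]:
    grid = []
    for n_hidden in (4, 6, 8):
        for hidden in ("purelin", "tansig"):
            for output in ("satlins", "purelin"):
                grid.append(AnnTopology(n_hidden, hidden, output))
    return grid


@dataclass
class RunConfig:
    """All knobs of the full workflow, with defaults mirroring the
    reference protocol (10 mV step / 424-point cycle, db4 level-4
    compression, 2 score components, 95% confidence, 27 + 11 mixture
    design, 250 µM stocks in 5 replicates)."""

    seed: int = 0
    n_informative: int = 4
    n_redundant: int = 2
    n_noisy: int = 2
    stock_uM: float = 250.0
    n_replicates: int = 5
    include_buffer: bool = True
    program: PotentialProgram = field(default_factory=PotentialProgram)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    score_method: str = "pca"
    n_score_components: int = 2
    tolerance_frac: float = 0.02
    min_sensors: int | None = None  # default floor: n_analytes + 1
    design: DesignSpec = field(default_factory=DesignSpec)
    topology_grid: list[AnnTopology] = field(default_factory=_default_grid)
    ann_max_iter: int = 2000
    confidence: float = 0.95

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        idx = _STAGES.index(stage)
        return (self.seed * 1_000_003 + idx * 7919 + 17) % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["program"] = dataclasses.asdict(self.program)
        d["wavelet"] = dataclasses.asdict(self.wavelet)
        d["design"] = dataclasses.asdict(self.design)
        d["design"]["analytes"] = list(self.design.analytes)
        d["design"]["low_uM"] = list(self.design.low_uM)
        d["design"]["high_uM"] = list(self.design.high_uM)
        d["topology_grid"] = [dataclasses.asdict(t) for t in self.topology_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "program" in d:
            d["program"] = PotentialProgram(**d["program"])
        if "wavelet" in d:
            d["wavelet"] = WaveletSpec(**d["wavelet"])
        if "design" in d:
            dd = dict(d["design"])
            for key in ("analytes", "low_uM", "high_uM"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = DesignSpec(**dd)
        if "topology_grid" in d:
            d["topology_grid"] = [AnnTopology(**t) for t in d["topology_grid"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_full_workflow(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the complete pipeline and write all artifacts to ``out_dir``.

    Artifacts: selection-set manifest, selection trace JSON + roster text
    + candidate-F CSV, mixture train/test manifests, topology-search
    results CSV, best ANN model JSON, metrics JSON (comparison
    regressions, EJCR flags, RMSE/NRMSE), and a reproducibility log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs, roles = _stage("array_specs")(default_array_specs)(
        cfg.n_informative, cfg.n_redundant, cfg.n_noisy,
        seed=cfg.stage_seed("array_specs"),
        analytes=cfg.design.analytes,
    )

    @_stage("selection_data")
    def make_selection():
        ds = simulate_selection_dataset(
            specs,
            program=cfg.program,
            analytes=cfg.design.analytes,
            stock_uM=cfg.stock_uM,
            n_replicates=cfg.n_replicates,
            include_buffer=cfg.include_buffer,
            seed=cfg.stage_seed("selection_data"),
        )
        write_dataset(ds, out / "selection_data")
        return ds

    sel_ds = make_selection()

    @_stage("selection")
    def run_selection():
        trace = backward_eliminate(
            sel_ds,
            wavelet=cfg.wavelet,
            n_score_components=cfg.n_score_components,
            tolerance_frac=cfg.tolerance_frac,
            min_sensors=cfg.min_sensors,
            method=cfg.score_method,
        )
        (out / "selection_trace.json").write_text(
            json.dumps(trace.to_dict(), indent=2, sort_keys=True)
        )
        (out / "selected_roster.txt").write_text("\n".join(trace.final_roster) + "\n")
        trace.candidate_table().to_csv(out / "candidate_f.csv")
        return trace

    trace = run_selection()
    selected = [s for s in specs if s.sensor_id in trace.final_roster]

    @_stage("train_mixtures")
    def make_train():
        conc = tilted_factorial(cfg.design)
        ds = simulate_mixture_dataset(
            selected, conc,
            analytes=cfg.design.analytes,
            program=cfg.program,
            seed=cfg.stage_seed("train_mixtures"),
            id_prefix="train",
        )
        write_dataset(ds, out / "train_data")
        return ds

    @_stage("test_mixtures")
    def make_test():
        conc = random_test_points(
            dataclasses.replace(cfg.design, seed=cfg.stage_seed("test_mixtures"))
        )
        ds = simulate_mixture_dataset(
            selected, conc,
            analytes=cfg.design.analytes,
            program=cfg.program,
            seed=cfg.stage_seed("test_mixtures") + 1,
            id_prefix="test",
        )
        write_dataset(ds, out / "test_data")
        return ds

    train_ds = make_train()
    test_ds = make_test()

    @_stage("ann_search")
    def run_ann():
        fb_train = build_feature_blocks(train_ds, cfg.wavelet)
        fb_test = build_feature_blocks(test_ds, cfg.wavelet)
        results, best = topology_search(
            fb_train, None, fb_test, None,
            grid=cfg.topology_grid,
            seed=cfg.stage_seed("ann_search"),
            max_iter=cfg.ann_max_iter,
        )
        results.to_csv(out / "topology_search.csv", index=False)
        best.to_json(out / "model.json")
        return fb_train, fb_test, best

    fb_train, fb_test, best = run_ann()

    metrics: dict = {"subsets": {}}
    for name, fb in (("training", fb_train), ("testing", fb_test)):
        pred = predict(best, fb)
        expected = fb.concentrations
        per_analyte, total = nrmse(expected, pred)
        sub = {"n": fb.n_samples, "total_nrmse": total, "analytes": {}}
        for j, analyte in enumerate(fb.analytes):
            rc = compare_regression(
                expected[:, j], pred[:, j],
                confidence=cfg.confidence, analyte=analyte, subset=name,
            )
            sub["analytes"][analyte] = {
                "slope": rc.slope,
                "slope_half_ci": rc.slope_half_ci,
                "intercept_uM": rc.intercept,
                "intercept_half_ci_uM": rc.intercept_half_ci,
                "r_squared": rc.r_squared,
                "rmse_uM": rc.rmse,
                "ejcr_contains_ideal": rc.contains_ideal,
            }
        metrics["subsets"][name] = sub
    metrics["selection"] = {
        "initial_roster": list(sel_ds.sensor_roster),
        "final_roster": list(trace.final_roster),
        "removed": trace.removed_sensors,
        "initial_f": trace.steps[0].reference_f,
        "final_f": trace.final_f,
        "ground_truth_roles": roles,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    (out / "run_log.txt").write_text(
        "\n".join(
            [
                f"etongue version: {__version__}",
                f"global seed: {cfg.seed}",
                f"config sha256: {cfg.config_hash()}",
                "stage seeds: "
                + ", ".join(f"{s}={cfg.stage_seed(s)}" for s in _STAGES),
            ]
        )
        + "\n"
    )
    return out
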