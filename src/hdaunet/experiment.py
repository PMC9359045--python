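"""End-to-end experiment orchestration.

One :class:`RunConfig` drives the full workflow: phantom cohort generation
(or loading a cohort manifest), training every requested architecture x
loss combination on one split, predicting the held-out test cases, writing
per-case metric reports, and a cross-method comparison table with
two-tailed t-test p-values — a desk-scale mirror of the multi-method,
multi-seed protocol used for full clinical studies.

Every run directory contains the resolved configuration that produced it,
so any artifact is reproducible from disk.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import PlanCase
from .dvh import DVHSpec, LossWeights
from .metrics import cohort_report, compare_methods, summarize_cohort
from .models import ArchConfig
from .phantom import PhantomSpec, generate_cohort
from .train import SplitSpec, TrainConfig, predict, split_cohort, structure_order_for, train

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Serializable description of one experiment."""

    out_dir: str = "runs/experiment"
    n_cases: int = 8
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    manifest: str | None = None  # load a cohort instead of generating one
    variants: list[str] = field(default_factory=lambda: ["hda"])
    losses: list[str] = field(default_factory=lambda: ["mse", "mse_dvh"])
    levels: int = 3
    growth_rate: int = 4
    ag_features: int = 8
    base_features: int = 8
    epochs: int = 5
    learning_rate: float = 1e-3
    seed: int = 0
    dtype: str = "float32"
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    target_name: str = "PTV"

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["phantom"]["grid_shape"] = list(self.phantom.grid_shape)
        data["phantom"]["spacing"] = list(self.phantom.spacing)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        ph = data.pop("phantom", {})
        for key in ("grid_shape", "spacing", "ptv_radius_range", "oar_radius_range"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(phantom=PhantomSpec(**ph), **data)


def _method_name(variant: str, loss: str) -> str:
    return f"{variant}_{loss}"


def _train_config(cfg: RunConfig, variant: str, loss: str, in_channels: int) -> TrainConfig:
    arch = ArchConfig(
        variant=variant,
        in_channels=in_channels,
        levels=cfg.levels,
        growth_rate=cfg.growth_rate,
        ag_features=cfg.ag_features,
        base_features=cfg.base_features,
    )
    return TrainConfig(
        arch=arch,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
        loss=loss,
        weights=LossWeights(),
        dvh=DVHSpec(),
        dtype=cfg.dtype,
    )


def run_experiment(cfg: RunConfig, cohort: list[PlanCase] | None = None) -> str:
    """Execute the experiment; returns the run directory path."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))

    if cohort is None:
        if cfg.manifest:
            from .io import read_cohort

            cohort, _ = read_cohort(cfg.manifest)
        else:
            cohort = generate_cohort(cfg.phantom, cfg.n_cases)
    order = structure_order_for(cohort)
    in_channels = 1 + len(order)

    split = SplitSpec(fractions=cfg.split_fractions, seed=cfg.seed)
    by_id = {c.case_id: c for c in cohort}
    _, _, test_ids = split_cohort(list(by_id), split)
    test_cases = [by_id[i] for i in test_ids]

    per_method_reports: dict[str, pd.DataFrame] = {}
    for variant in cfg.variants:
        for loss in cfg.losses:
            method = _method_name(variant, loss)
            sub = os.path.join(cfg.out_dir, method)
            os.makedirs(sub, exist_ok=True)
            tcfg = _train_config(cfg, variant, loss, in_channels)
            run = train(cohort, tcfg, split, structure_order=order)
            run.history.to_csv(os.path.join(sub, "history.csv"), index=False)
            preds = [predict(run, c) for c in test_cases]
            report = cohort_report(test_cases, preds, cfg.target_name)
            report.insert(0, "method", method)
            report.to_csv(os.path.join(sub, "metrics.csv"), index=False)
            summarize_cohort(report).to_csv(os.path.join(sub, "summary.csv"), index=False)
            np.savez(os.path.join(sub, "weights.npz"), **run.best_state)
            with open(os.path.join(sub, "run.yaml"), "w") as fh:
                yaml.safe_dump(
                    {
                        "method": method,
                        "best_epoch": int(run.best_epoch),
                        "structure_order": order,
                        "arch": tcfg.arch.to_dict(),
                        "seed": cfg.seed,
                    },
                    fh,
                    sort_keys=False,
                )
            per_method_reports[method] = report

    comparison = _comparison_table(per_method_reports)
    comparison.to_csv(os.path.join(cfg.out_dir, "comparison.csv"), index=False)
    return cfg.out_dir


def _plan_scores(report: pd.DataFrame, metric: str) -> np.ndarray:
    plan = report[report["structure"] == "plan"]
    return plan.sort_values("case_id")[metric].to_numpy()


def _comparison_table(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise t-tests between methods on the plan-level metrics."""
    methods = list(reports)
    metrics = ["D95", "Dmax", "H1", "H2", "CI", "vantRiet"]
    rows = []
    for metric in metrics:
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                sa, sb = _plan_scores(reports[a], metric), _plan_scores(reports[b], metric)
                row = {
                    "metric": metric,
                    "method_a": a,
                    "method_b": b,
                    "mean_a": sa.mean(),
                    "mean_b": sb.mean(),
                }
                if len(sa) >= 2 and len(sb) >= 2:
                    p = compare_methods(sa, sb)
                    row["p_value"] = p
                    row["significant"] = bool(p < 0.05)
                else:
                    row["p_value"] = np.nan
                    row["significant"] = False
                rows.append(row)
    return pd.DataFrame(rows)
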