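"""End-to-end experiment orchestration.

A run generates synthetic scene categories, trains the linear GIST classifier
per task on clean stimuli, assigns each simulated participant an individually
randomized stimulus sample per condition (the semi-random split), degrades
those stimuli (pink noise at fixed SNR, central occlusion, field-defect
mask), measures the classifier's estimated sensitivity and the simulated
observer's observed sensitivity on the same trials, and runs the
sensitivity-difference statistics with FDR correction.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import degrade as dg
from . import synthetic as syn
from .classify import (
    classifier_confusion,
    estimate_model_sensitivity,
    semi_random_split,
    train_classifier,
)
from .gist import build_filter_bank, gist_matrix
from .sdt import (
    bayes_ttest_one_sample,
    compute_bfi,
    compute_dprime,
    fdr_adjust,
    sensitivity_difference,
)
from .types import ConfusionCounts, SceneImage

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one simulated experiment."""

    size_px: int = 128
    tasks: Sequence[str] = ("naturalness",)
    snr_levels_db: Sequence[float] = dg.DEFAULT_SNR_LEVELS_DB
    vfd_conditions: Sequence[str] = ("none", "quad_right_up", "hemi_left")
    n_participants: int = 3
    n_trials_per_condition: int = 24
    n_train_per_class: int = 100
    n_pool_per_class: int = 300
    category_strength: float = 1.5
    spectral_exponent: float = 1.0
    regularization: float = 1.0
    central_occlusion_deg: float = 5.0
    central_occlusion_in_model: bool = True
    observer_mode: str = "model_rates"   # "model_rates" | "offset"
    observer_offset: float = 0.0         # used when observer_mode == "offset"
    sensitivity_method: str = "gaussian_decision_values"
    direction: str = "model_minus_observer"
    fdr_q: float = 0.05
    seed: int = 0
    out_dir: Optional[str] = None
    make_plots: bool = False

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_condition < 2:
            raise ValueError("need >= 1 participant and >= 2 trials/condition")
        if self.observer_mode not in ("model_rates", "offset"):
            raise ValueError(f"unknown observer_mode {self.observer_mode!r}")
        if self.size_px % 2:
            raise ValueError("size_px must be even")
        for v in self.vfd_conditions:
            if v not in syn.VFD_KINDS:
                raise ValueError(f"unknown VFD condition {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(self.tasks)
        d["snr_levels_db"] = [float(s) for s in self.snr_levels_db]
        d["vfd_conditions"] = list(self.vfd_conditions)
        return d


@dataclass
class RunResult:
    """Tidy outputs of one experiment run."""

    trials: pd.DataFrame          # one row per participant x condition
    stats: pd.DataFrame           # one row per condition (group test)
    config: RunConfig
    manifest: dict = field(default_factory=dict)


def _simulate_from_rates(
    hit_rate: float, fa_rate: float, labels: np.ndarray, rng: np.random.Generator
) -> ConfusionCounts:
    """Binomial observer whose response probabilities are given rates."""
    p = np.where(labels == 1, hit_rate, fa_rate)
    resp = (rng.random(labels.size) < p).astype(int)
    return ConfusionCounts(
        hits=int(np.sum((labels == 1) & (resp == 1))),
        misses=int(np.sum((labels == 1) & (resp == 0))),
        false_alarms=int(np.sum((labels == 0) & (resp == 1))),
        correct_rejections=int(np.sum((labels == 0) & (resp == 0))),
    )


def run_experiment(config: RunConfig) -> RunResult:
    config.validate()
    rng = np.random.default_rng(config.seed)
    bank = build_filter_bank(config.size_px)

    vfd_maps = {k: syn.generate_vfd(k, config.size_px) for k in config.vfd_conditions}
    bfi_by_vfd = {k: compute_bfi(m).bfi for k, m in vfd_maps.items()}

    rows = []
    for task in config.tasks:
        params_a = syn.SceneParams.cardinal(
            config.size_px, strength=config.category_strength,
            spectral_exponent=config.spectral_exponent,
        )
        params_b = syn.SceneParams.oblique(
            config.size_px, strength=config.category_strength,
            spectral_exponent=config.spectral_exponent,
        )
        train_seed = int(rng.integers(2 ** 31))
        pool_seed = int(rng.integers(2 ** 31))
        train_imgs = syn.generate_scene_set(
            params_a, params_b, config.n_train_per_class, train_seed, task=task
        )
        pool_imgs = syn.generate_scene_set(
            params_a, params_b, config.n_pool_per_class, pool_seed, task=task
        )
        train_imgs = dg.equalize_set(train_imgs)
        pool_imgs = dg.equalize_set(pool_imgs)
        set_mean = float(np.mean([im.pixels.mean() for im in pool_imgs]))

        X_train = gist_matrix(train_imgs, bank)
        y_train = np.array([im.label for im in train_imgs])
        model = train_classifier(
            X_train, y_train, regularization=config.regularization, task=task,
            manifest={"train_seed": train_seed,
                      "image_ids": [im.image_id for im in train_imgs]},
        )

        conditions = [
            f"{vfd}|snr{snr:g}"
            for vfd in config.vfd_conditions
            for snr in config.snr_levels_db
        ]
        pool_labels = [im.label for im in pool_imgs]
        split_seed = int(rng.integers(2 ** 31))
        participants = [f"S{i:02d}" for i in range(config.n_participants)]
        assignments = semi_random_split(
            pool_labels, participants, conditions,
            config.n_trials_per_condition, split_seed,
        )

        for assignment in assignments:
            for vfd_kind in config.vfd_conditions:
                for snr in config.snr_levels_db:
                    cond = f"{vfd_kind}|snr{snr:g}"
                    idx = assignment.stimuli[cond]
                    labels = np.array([pool_labels[i] for i in idx])
                    spec = dg.DegradationSpec(
                        snr_db=float(snr),
                        vfd=vfd_maps[vfd_kind],
                        central_occlusion_deg=(
                            config.central_occlusion_deg
                            if config.central_occlusion_in_model else 0.0
                        ),
                        fill_value=set_mean,
                    )
                    degraded = [
                        dg.degrade(pool_imgs[i], spec, set_mean=set_mean, rng=rng)
                        for i in idx
                    ]
                    X = gist_matrix(degraded, bank)
                    d_hat = estimate_model_sensitivity(
                        model, {cond: X}, {cond: labels},
                        method="gaussian_decision_values",
                    )[cond]
                    d_hat_rate = estimate_model_sensitivity(
                        model, {cond: X}, {cond: labels}, method="rate_based"
                    )[cond]

                    if config.observer_mode == "model_rates":
                        conf = classifier_confusion(model, X, labels)
                        hr = conf.hits / (conf.hits + conf.misses)
                        far = conf.false_alarms / (
                            conf.false_alarms + conf.correct_rejections
                        )
                        if hr in (0.0, 1.0) or far in (0.0, 1.0):
                            # same log-linear shrinkage compute_dprime applies
                            hr = (conf.hits + 0.5) / (conf.hits + conf.misses + 1.0)
                            far = (conf.false_alarms + 0.5) / (
                                conf.false_alarms + conf.correct_rejections + 1.0
                            )
                        obs_counts = _simulate_from_rates(hr, far, labels, rng)
                    else:
                        d_true = max(0.0, d_hat_rate + config.observer_offset)
                        obs_spec = syn.ObserverSpec(
                            dprime=d_true, criterion=0.0,
                            n_trials_per_condition=len(labels),
                        )
                        obs_counts = syn.simulate_observer(
                            obs_spec, {cond: labels}, rng=rng
                        ).counts[cond]
                    est = compute_dprime(obs_counts)
                    d_hat_used = (
                        d_hat if config.sensitivity_method
                        == "gaussian_decision_values" else d_hat_rate
                    )
                    rows.append({
                        "participant": assignment.participant_id,
                        "task": task,
                        "vfd": vfd_kind,
                        "snr_db": float(snr),
                        "bfi": bfi_by_vfd[vfd_kind],
                        "d_obs": est.d_prime,
                        "criterion": est.criterion_c,
                        "d_hat": d_hat,
                        "d_hat_rate": d_hat_rate,
                        "r_hat": sensitivity_difference(
                            d_hat_used, est.d_prime, config.direction
                        ),
                    })

    trials = pd.DataFrame(rows)
    stats = _condition_stats(trials, config.fdr_q)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    result = RunResult(trials=trials, stats=stats, config=config,
                       manifest=manifest)
    if config.out_dir:
        write_result(result, Path(config.out_dir))
    return result


def _condition_stats(trials: pd.DataFrame, q: float) -> pd.DataFrame:
    """Group-level sensitivity-difference test per condition, FDR-corrected."""
    rows = []
    for (task, vfd, snr), grp in trials.groupby(["task", "vfd", "snr_db"]):
        r = grp["r_hat"].to_numpy()
        if r.size >= 2 and r.std(ddof=1) > 0:
            res = bayes_ttest_one_sample(r, 0.0)
            rows.append({
                "task": task, "vfd": vfd, "snr_db": snr,
                "mean_r_hat": float(r.mean()), "n": r.size,
                "t": res.t_stat, "df": res.df, "p": res.p_value,
                "bf01": res.bf01, "ln_bf": res.ln_bf01,
            })
        else:
            rows.append({
                "task": task, "vfd": vfd, "snr_db": snr,
                "mean_r_hat": float(r.mean()), "n": r.size,
                "t": np.nan, "df": r.size - 1, "p": np.nan,
                "bf01": np.nan, "ln_bf": np.nan,
            })
    stats = pd.DataFrame(rows)
    valid = stats["p"].notna()
    stats["fdr_significant"] = False
    if valid.any():
        _, reject = fdr_adjust(stats.loc[valid, "p"].to_numpy(), q)
        stats.loc[valid, "fdr_significant"] = reject
    return stats


def report(result: RunResult) -> pd.DataFrame:
    """Per-participant categorization against the model prediction.

    Each participant's sensitivity differences across conditions are tested
    against zero; after FDR correction across participants a participant is
    classed as performing worse than, the same as, or better than the model
    predicts from the stimulus degradation alone.  With the
    model-minus-observer convention, positive mean difference means the
    observer underperforms the model.
    """
    if result.trials.empty:
        raise ValueError("incomplete result bundle: no trials")
    rows = []
    for pid, grp in result.trials.groupby("participant"):
        r = grp["r_hat"].to_numpy()
        if r.size >= 2 and r.std(ddof=1) > 0:
            res = bayes_ttest_one_sample(r, 0.0)
            rows.append({"participant": pid, "mean_r_hat": float(r.mean()),
                         "t": res.t_stat, "p": res.p_value,
                         "ln_bf": res.ln_bf01})
        else:
            rows.append({"participant": pid, "mean_r_hat": float(r.mean()),
                         "t": np.nan, "p": np.nan, "ln_bf": np.nan})
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    df["fdr_significant"] = False
    if valid.any():
        _, reject = fdr_adjust(df.loc[valid, "p"].to_numpy(),
                               result.config.fdr_q)
        df.loc[valid, "fdr_significant"] = reject
    sign = 1.0 if result.config.direction == "model_minus_observer" else -1.0

    def categorize(row):
        if not row["fdr_significant"]:
            return "same_as_model"
        return ("worse_than_model" if sign * row["mean_r_hat"] > 0
                else "better_than_model")

    df["category"] = df.apply(categorize, axis=1)
    return df


def write_result(result: RunResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(out_dir / "trials.csv", index=False)
    result.stats.to_csv(out_dir / "condition_stats.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    if result.config.make_plots:
        _write_plots(result, out_dir / "plots")


def _write_plots(result: RunResult, plot_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    for vfd, grp in result.trials.groupby("vfd"):
        med = grp.groupby("snr_db")["d_hat"].median()
        ax.plot(med.index, med.values, marker="o", label=vfd)
    ax.set_xlabel("SNR (dB)")
    ax.set_ylabel("estimated sensitivity $\\hat{d}'$")
    ax.legend(title="field defect")
    fig.tight_layout()
    fig.savefig(plot_dir / "sensitivity_vs_snr.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    piv = result.stats.pivot_table(index="snr_db", columns="vfd",
                                   values="mean_r_hat")
    piv.plot(kind="bar", ax=ax)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("mean sensitivity difference $\\hat{r}$")
    fig.tight_layout()
    fig.savefig(plot_dir / "sensitivity_difference.png", dpi=120)
    plt.close(fig)
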