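"""End-to-end workflow: synthesize -> split -> train -> evaluate -> simulate -> report.

Every artifact a figure would show is first written as a tidy CSV so the
report can be regenerated from CSVs alone; the manifest records seeds,
exposure counters and wall-clock per stage.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior_analysis import (
    block_learning_scores,
    deck_proportions,
    simulate_off_policy,
    simulate_on_policy,
    switch_probability,
)
from .collab_training import train
from .config import RunConfig, plan_label
from .data_model import (
    LabDataset,
    read_tidy_csv,
    split_lab,
    truncate_pool,
    write_pool_metadata,
    write_tidy_csv,
)
from .evaluation import accuracy_matrix
from .igt_task import build_scheme
from .synthetic_cohort import canonical_profiles, generate_pool, profiles_from_yaml


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_pool(config: RunConfig) -> list[LabDataset]:
    src = config.pool_source
    if src == "canonical":
        profiles = canonical_profiles(config.size_scale)
        return generate_pool(profiles, seed=config.stage_seed("pool"))
    if src.endswith((".yaml", ".yml")):
        return generate_pool(profiles_from_yaml(src), seed=config.stage_seed("pool"))
    return read_tidy_csv(src)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}
        return manifest["stages"][name]

    def finish(info):
        info["wall_clock_s"] = round(time.time() - info.pop("t_start"), 3)

    try:
        info = stage("data")
        pool = _load_pool(config)
        pool = truncate_pool(pool, config.truncate_T)
        split_seed = config.stage_seed("split")
        seeds = np.random.SeedSequence(split_seed).spawn(len(pool))
        train_sets, test_sets = [], []
        for ds, ss in zip(pool, seeds):
            tr, te = split_lab(
                ds, config.split_fraction, seed=int(ss.generate_state(1)[0] % 2**31)
            )
            train_sets.append(tr)
            test_sets.append(te)
        write_tidy_csv(pool, out / "pool.csv")
        write_pool_metadata(
            pool,
            out / "pool_meta.json",
            split_fraction=config.split_fraction,
            split_seed=split_seed,
            train_sizes={t.lab_id: len(t) for t in train_sets},
            test_sizes={t.lab_id: len(t) for t in test_sets},
        )
        info["n_train"] = sum(map(len, train_sets))
        info["n_test"] = sum(map(len, test_sets))
        finish(info)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", str(e)) from e

    models = {}
    for plan in config.plans:
        label = plan_label(plan)
        try:
            info = stage(f"train:{label}")
            res = train(train_sets, plan)
            models[label] = res.params
            res.params.save(out / f"model_{label}")
            pd.DataFrame({"loss": res.train_loss_history}).to_csv(
                out / f"loss_{label}.csv", index_label="step"
            )
            counts = sorted(set(res.exposures.values()))
            info["exposure_counts"] = counts
            info["budget_ok"] = counts == [plan.total_epoch_budget]
            finish(info)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"train:{label}", str(e)) from e

    if config.evaluate and models:
        try:
            info = stage("evaluate")
            mat = accuracy_matrix(models, test_sets)
            mat.to_csv(out / "accuracy_matrix.csv")
            finish(info)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("evaluate", str(e)) from e

    if config.simulate and models:
        try:
            info = stage("simulate")
            scheme = build_scheme("traditional")
            n_agents = sum(map(len, train_sets))
            subj_records = [r for ds in train_sets for r in ds.records]
            groups = {"SUBJ": subj_records}
            sim_seed = config.stage_seed("simulate")
            for i, (label, params) in enumerate(models.items()):
                groups[label] = simulate_on_policy(
                    params, scheme, n_agents, T=config.truncate_T, seed=sim_seed + i
                )
            _write_behavior_csvs(groups, out)
            traces = []
            for label, params in models.items():
                for deck in range(1, 5):
                    tr = simulate_off_policy(
                        params, deck, T=config.n_off_policy_trials, scheme=scheme
                    )
                    tr["model"] = label
                    tr["deck"] = "ABCD"[deck - 1]
                    traces.append(tr)
            pd.concat(traces, ignore_index=True).to_csv(out / "fig9_traces.csv", index=False)
            finish(info)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_behavior_csvs(groups: dict[str, list], out: Path) -> None:
    prop_rows, score_rows, switch_rows = [], [], []
    for label, seqs in groups.items():
        props, _, _ = deck_proportions(seqs)
        scores = block_learning_scores(seqs)
        sw = switch_probability(seqs)
        for i, s in enumerate(seqs):
            for d in range(4):
                prop_rows.append(
                    {"group": label, "subject": s.subject_id, "deck": "ABCD"[d],
                     "proportion": props[i, d]}
                )
            for b in range(scores.shape[1]):
                score_rows.append(
                    {"group": label, "subject": s.subject_id, "block": b + 1,
                     "score": scores[i, b]}
                )
            switch_rows.append(
                {"group": label, "subject": s.subject_id,
                 "p_switch_after_loss": sw[i, 0], "p_switch_after_no_loss": sw[i, 1]}
            )
    pd.DataFrame(prop_rows).to_csv(out / "fig6_proportions.csv", index=False)
    pd.DataFrame(score_rows).to_csv(out / "fig7_scores.csv", index=False)
    pd.DataFrame(switch_rows).to_csv(out / "fig8_switch.csv", index=False)


def make_report(out_dir: str | Path, fig_dir: str | Path | None = None) -> list[Path]:
    """Render figure analogs from the emitted CSVs alone (no checkpoints)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = Path(fig_dir) if fig_dir else out / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = []

    needed = ["accuracy_matrix.csv", "fig6_proportions.csv", "fig7_scores.csv",
              "fig8_switch.csv", "fig9_traces.csv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise PipelineError("report", f"missing artifacts: {', '.join(missing)}")

    mat = pd.read_csv(out / "accuracy_matrix.csv", index_col="model")
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(mat) + 2))
    im = ax.imshow(mat.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45)
    ax.set_yticks(range(len(mat)), mat.index)
    for (i, j), v in np.ndenumerate(mat.to_numpy()):
        ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7, color="w")
    fig.colorbar(im, label="accuracy")
    p = fig_dir / "accuracy_matrix.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    props = pd.read_csv(out / "fig6_proportions.csv")
    g = props.groupby(["group", "deck"])["proportion"].agg(["mean", "sem"]).reset_index()
    fig, ax = plt.subplots()
    for k, (grp, sub) in enumerate(g.groupby("group")):
        ax.errorbar(np.arange(4) + 0.08 * k, sub["mean"], yerr=sub["sem"],
                    fmt="o", label=grp)
    ax.set_xticks(range(4), list("ABCD"))
    ax.set_ylabel("P(choose deck)")
    ax.legend(fontsize=7)
    p = fig_dir / "deck_proportions.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    scores = pd.read_csv(out / "fig7_scores.csv")
    g = scores.groupby(["group", "block"])["score"].agg(["mean", "sem"]).reset_index()
    fig, ax = plt.subplots()
    for grp, sub in g.groupby("group"):
        ax.errorbar(sub["block"], sub["mean"], yerr=sub["sem"], marker="o", label=grp)
    ax.set_xlabel("block")
    ax.set_ylabel("learning score (good - bad)")
    ax.legend(fontsize=7)
    p = fig_dir / "learning_scores.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    sw = pd.read_csv(out / "fig8_switch.csv")
    g = sw.groupby("group")[["p_switch_after_loss", "p_switch_after_no_loss"]].mean()
    fig, ax = plt.subplots()
    xs = np.arange(len(g))
    ax.bar(xs - 0.2, g["p_switch_after_loss"], width=0.4, label="after loss")
    ax.bar(xs + 0.2, g["p_switch_after_no_loss"], width=0.4, label="after no loss")
    ax.set_xticks(xs, g.index, rotation=45)
    ax.set_ylabel("P(switch)")
    ax.legend()
    p = fig_dir / "switch_probability.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    traces = pd.read_csv(out / "fig9_traces.csv")
    decks = sorted(traces["deck"].unique())
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
    for ax, deck in zip(axes.ravel(), decks):
        sub = traces[traces["deck"] == deck]
        for model, m in sub.groupby("model"):
            ax.plot(m["trial"], m["p_stay"], label=model)
            lossy = m[m["loss_trial"]]
            ax.plot(lossy["trial"], lossy["p_stay"], "o", ms=4, color="tab:blue")
        ax.set_title(f"forced deck {deck}")
        ax.set_xlabel("trial")
        ax.set_ylabel("P(stay)")
    axes[0, 0].legend(fontsize=6)
    p = fig_dir / "off_policy_traces.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
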