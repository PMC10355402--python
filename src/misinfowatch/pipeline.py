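"""End-to-end pipeline: generate/load -> weak-label -> active-learn -> classify
-> summarize -> profile, with a run manifest for reproducibility.

Every stage writes plain-text outputs (CSV/JSON/JSONL) into the run
directory; the manifest records each file with a SHA-256 content hash so two
runs with identical config and seeds can be compared file-by-file. A stage
failure is recorded in the manifest and earlier outputs are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from misinfowatch import active_learning as al
from misinfowatch import account_profiling as profiling
from misinfowatch import geo_temporal as geo
from misinfowatch import labeling
from misinfowatch.data_model import Corpus, join_corpus, read_table, write_table
from misinfowatch.synthetic import GeneratorConfig, generate_corpus, make_oracle

logger = logging.getLogger(__name__)

STAGES = ("generate", "augment", "train_al", "classify", "summarize", "profile",
          "timelines")


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults exercise the synthetic world."""

    # input: either paths to tweet/user tables, or generator settings
    tweets_path: Optional[str] = None
    users_path: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # labeling
    criteria_path: Optional[str] = None
    include_terms: list[str] = field(default_factory=lambda: list(labeling.DEFAULT_INCLUDE_TERMS))
    exclude_terms: list[str] = field(default_factory=lambda: list(labeling.DEFAULT_EXCLUDE_TERMS))
    target_additions: int = 4000
    n_manual_seed: int = 5000
    # active learning
    batch_size: int = 100
    max_iterations: int = 50
    cv_folds: int = 5
    eval_mode: str = "cv"
    # profiling
    sample_fraction: float = 0.10
    bot_sample_size: int = 1000
    # misc
    seed: int = 0
    out_dir: str = "runs/run0"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        return cls(**raw)

    def scaled(self) -> "PipelineConfig":
        return dataclasses.replace(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data: dict = {
            "seeds": {"pipeline": config.seed, "generator": config.generator.seed},
            "stages": {},
            "files": {},
        }

    def record_file(self, stage: str, path: Path) -> None:
        rel = str(path.relative_to(self.out_dir))
        self.data["files"][rel] = _sha256(path)
        self.data["stages"].setdefault(stage, {"status": "ok", "outputs": []})
        self.data["stages"][stage]["outputs"].append(rel)

    def record_stage(self, stage: str, status: str, elapsed: float,
                     counts: Optional[dict] = None, error: Optional[str] = None) -> None:
        entry = self.data["stages"].setdefault(stage, {"outputs": []})
        entry.update({"status": status, "wall_time_s": round(elapsed, 3)})
        if counts:
            entry["counts"] = counts
        if error:
            entry["error"] = error

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
        return path


def _load_or_generate(config: PipelineConfig) -> tuple[Corpus, Optional[dict]]:
    if config.tweets_path and config.users_path:
        tweets = read_table(config.tweets_path, "tweet")
        users = read_table(config.users_path, "user")
        gaz = geo.Gazetteer.default()
        users = geo.map_user_locations(users, gaz)
        return join_corpus(tweets, users), None
    corpus, truth = generate_corpus(config.generator)
    return corpus, truth


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory. See the manifest for status."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out, config)
    state: dict = {}

    stages = [
        ("generate", _stage_generate),
        ("augment", _stage_augment),
        ("train_al", _stage_train_al),
        ("classify", _stage_classify),
        ("summarize", _stage_summarize),
        ("timelines", _stage_timelines),
        ("profile", _stage_profile),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            counts = fn(config, state, out, manifest)
            manifest.record_stage(name, "ok", time.perf_counter() - t0, counts)
            logger.info("stage %s ok (%.2fs) %s", name, time.perf_counter() - t0, counts)
        except Exception as e:  # partial outputs retained, failure recorded
            manifest.record_stage(name, "failed", time.perf_counter() - t0, error=str(e))
            logger.exception("stage %s failed", name)
            break
    manifest.save()
    return out


def _stage_generate(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus, truth = _load_or_generate(config)
    state["corpus"], state["truth"] = corpus, truth
    write_table(corpus.tweets, out / "tweets.csv", "tweet")
    write_table(corpus.users, out / "users.csv", "user")
    manifest.record_file("generate", out / "tweets.csv")
    manifest.record_file("generate", out / "users.csv")
    if truth is not None:
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh)
        manifest.record_file("generate", out / "truth.json")
    if corpus.demographics is not None:
        profiling.write_demographics_jsonl(corpus.demographics, out / "demographics.jsonl")
        manifest.record_file("generate", out / "demographics.jsonl")
    if corpus.bot_scores is not None:
        profiling.write_bot_scores_jsonl(corpus.bot_scores, out / "bot_scores.jsonl")
        manifest.record_file("generate", out / "bot_scores.jsonl")
    return {"tweets": len(corpus.tweets), "users": len(corpus.users),
            "unmatched": len(corpus.unmatched)}


def _stage_augment(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus, truth = state["corpus"], state["truth"]
    rng = np.random.default_rng(config.seed)
    n_seed = min(config.n_manual_seed, len(corpus.tweets))
    seed_idx = np.sort(rng.choice(len(corpus.tweets), size=n_seed, replace=False))
    seed_ids = corpus.tweets["id"].iloc[seed_idx].tolist()
    if truth is not None:
        manual = pd.DataFrame({"tweet_id": seed_ids,
                               "label": [truth[t] for t in seed_ids],
                               "source": "manual", "confidence": np.nan})
    else:
        raise ValueError("augment stage without ground truth requires a manual label file")
    pool_mask = ~corpus.tweets["id"].isin(set(seed_ids))
    pool = corpus.tweets[pool_mask]
    query = labeling.AugmentationQuery(include_terms=config.include_terms,
                                       exclude_terms=config.exclude_terms,
                                       target_additions=config.target_additions)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        augmented = labeling.keyword_augment(pool, query)
    merged, report = labeling.merge_label_sets(manual, augmented)
    state["labeled"] = merged
    state["balance"] = report
    write_table(merged, out / "labels_training.csv", "label")
    manifest.record_file("augment", out / "labels_training.csv")
    with open(out / "balance_report.json", "w", encoding="utf-8") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    manifest.record_file("augment", out / "balance_report.json")
    return report.as_dict()


def _stage_train_al(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus, truth = state["corpus"], state["truth"]
    labeled_df = state["labeled"]
    initial = dict(zip(labeled_df["tweet_id"], labeled_df["label"].astype(int)))
    texts = dict(zip(corpus.tweets["id"], corpus.tweets["text"]))
    pool = [t for t in corpus.tweets["id"] if t not in initial]
    oracle = make_oracle(truth)
    holdout = None
    if config.eval_mode == "holdout":
        # carve a truth-labeled evaluation set out of the pool (simulates an
        # expert-labeled test set; cheaper than CV at every iteration)
        rng = np.random.default_rng(config.seed + 1)
        k = max(1, len(pool) // 10)
        held_idx = set(rng.choice(len(pool), size=k, replace=False).tolist())
        held = [pool[i] for i in sorted(held_idx)]
        pool = [p for i, p in enumerate(pool) if i not in held_idx]
        holdout = ([texts[t] for t in held], [truth[t] for t in held])
    al_state, history = al.run_active_learning(
        initial, pool, texts, oracle, batch_size=config.batch_size,
        max_iterations=config.max_iterations, eval_mode=config.eval_mode,
        cv_folds=config.cv_folds, seed=config.seed, holdout=holdout)
    state["al_state"] = al_state
    al.save_model(out / "model.json", al_state.featurizer, al_state.model)
    manifest.record_file("train_al", out / "model.json")
    history.to_csv(out / "al_history.csv", index=False)
    manifest.record_file("train_al", out / "al_history.csv")
    # full expert-labeled set (initial + oracle-labeled batches), so a staged
    # classify run can prefer expert labels exactly like the monolithic one
    expert = pd.DataFrame({"tweet_id": sorted(al_state.labeled),
                           "label": [al_state.labeled[t] for t in sorted(al_state.labeled)],
                           "source": "oracle", "confidence": np.nan})
    write_table(expert, out / "labels_expert.csv", "label")
    manifest.record_file("train_al", out / "labels_expert.csv")
    return {"iterations": int(al_state.iteration),
            "oracle_queries": int(oracle.query_count),
            "n_labeled_final": len(al_state.labeled)}


def _stage_classify(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus = state["corpus"]
    al_state = state["al_state"]
    predicted = al.predict_corpus(al_state.featurizer, al_state.model, corpus)
    # expert labels win over model predictions for tweets the oracle saw
    final = predicted.copy()
    labeled_map = al_state.labeled
    mask = final["tweet_id"].isin(labeled_map)
    final.loc[mask, "label"] = [labeled_map[t] for t in final.loc[mask, "tweet_id"]]
    final.loc[mask, "source"] = "oracle"
    state["corpus"] = corpus.with_labels(final)
    write_table(final, out / "labels_final.csv", "label")
    manifest.record_file("classify", out / "labels_final.csv")
    prevalence = float(final["label"].mean())
    return {"n_predicted": len(predicted), "predicted_prevalence": round(prevalence, 4)}


def _stage_summarize(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus = state["corpus"]
    summaries = geo.country_summaries(corpus)
    summaries.to_csv(out / "country_summaries.csv", index=False)
    manifest.record_file("summarize", out / "country_summaries.csv")
    return {"countries": len(summaries),
            "total_tweets": int(summaries["n_tweets"].sum())}


def _stage_timelines(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus = state["corpus"]
    total = geo.weekly_series(corpus.tweets)
    misinfo = geo.weekly_series(corpus.tweets, labels=corpus.labels,
                                tweet_class="misinformation")
    geo.minmax_normalize(total).to_frame().to_csv(out / "weekly_total.csv", index=False)
    geo.minmax_normalize(misinfo).to_frame().to_csv(out / "weekly_misinformation.csv",
                                                    index=False)
    manifest.record_file("timelines", out / "weekly_total.csv")
    manifest.record_file("timelines", out / "weekly_misinformation.csv")
    peak_week, peak_count = geo.annotate_peak(misinfo)
    return {"weeks": len(total.weeks), "misinfo_peak_week": peak_week,
            "misinfo_peak_count": peak_count}


def _stage_profile(config, state, out: Path, manifest: RunManifest) -> dict:
    corpus = state["corpus"]
    sampled = profiling.sample_users(corpus.users, fraction=config.sample_fraction,
                                     seed=config.seed)
    assigned = None
    if corpus.demographics is not None:
        demo = corpus.demographics[corpus.demographics["user_id"].isin(set(sampled["id"]))]
        assigned = profiling.assign_demographics_table(demo)
    report = profiling.engagement_comparison(corpus, assigned=assigned)
    with open(out / "engagement_comparison.json", "w", encoding="utf-8") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    manifest.record_file("profile", out / "engagement_comparison.json")
    counts = {"dual_membership": report.dual_membership}
    if assigned is not None:
        ages = profiling.age_distribution(corpus, assigned=assigned)
        pd.Series(ages).rename_axis("age_group").rename("n_misinformation_tweets") \
            .to_csv(out / "age_distribution.csv")
        manifest.record_file("profile", out / "age_distribution.csv")
        counts["age_groups"] = len(ages)
    if corpus.bot_scores is not None:
        bots = profiling.bot_comparison(corpus, sample_size=config.bot_sample_size,
                                        seed=config.seed)
        bots.as_frame().to_csv(out / "bot_comparison.csv")
        manifest.record_file("profile", out / "bot_comparison.csv")
        counts["bot_sample_sizes"] = bots.sample_sizes
    return counts
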