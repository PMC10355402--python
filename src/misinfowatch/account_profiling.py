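"""Account-level profiling: demographics, engagement metrics, and bot scores.

Demographic attributes arrive as per-user probability vectors (age group,
gender, organization status) from an external multimodal inference service;
the assignment rule is per-dimension argmax. Bot scores are six categories
in [0, 1] (overall, astroturf, fake follower, self-declared, financial,
spammer) from an external bot-detection service. This module never computes
either from text or images — they are inputs.

An account belongs to the misinformation (fact) spreader class when it
authored at least one tweet with final label 1 (0); accounts can belong to
both classes and the dual-membership count is reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from misinfowatch.data_model import Corpus
from misinfowatch.synthetic import AGE_GROUPS, BOT_CATEGORIES, GENDERS, ORG_STATUSES

logger = logging.getLogger(__name__)

PROB_TOLERANCE = 1e-6


@dataclass
class DemographicInference:
    """Probability vectors over age, gender, and org status for one account."""

    age_probs: tuple[float, float, float, float]  # <=18, 19-29, 30-39, >=40
    gender_probs: tuple[float, float]  # male, female
    org_probs: tuple[float, float]  # org, non-org

    def __post_init__(self):
        for name, vec in (("age_probs", self.age_probs),
                          ("gender_probs", self.gender_probs),
                          ("org_probs", self.org_probs)):
            arr = np.asarray(vec, dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} entries must be in [0, 1]")
            if abs(arr.sum() - 1.0) > PROB_TOLERANCE:
                raise ValueError(f"{name} must sum to 1 within {PROB_TOLERANCE}, "
                                 f"got {arr.sum()}")


@dataclass
class AssignedDemographics:
    age_group: str
    gender: str
    org_status: str
    had_tie: bool = False


def _argmax_with_preference(probs, categories, preference) -> tuple[str, bool]:
    """Argmax; on ties pick the earliest category in ``preference`` order."""
    arr = np.asarray(probs, dtype=float)
    top = arr.max()
    winners = [c for c, p in zip(categories, arr) if p == top]
    if len(winners) == 1:
        return winners[0], False
    pick = min(winners, key=preference.index)
    return pick, True


def assign_demographics(inference: DemographicInference) -> AssignedDemographics:
    """Assign each attribute to its highest-probability category.

    Ties break by fixed category order — youngest age first, female first,
    org first — and are logged.
    """
    age, t1 = _argmax_with_preference(inference.age_probs, AGE_GROUPS, list(AGE_GROUPS))
    gender, t2 = _argmax_with_preference(inference.gender_probs, GENDERS,
                                         ["female", "male"])
    org, t3 = _argmax_with_preference(inference.org_probs, ORG_STATUSES,
                                      list(ORG_STATUSES))
    had_tie = t1 or t2 or t3
    if had_tie:
        logger.info("demographic tie broken by category order (age=%s gender=%s org=%s)",
                    age, gender, org)
    return AssignedDemographics(age_group=age, gender=gender, org_status=org,
                                had_tie=had_tie)


def inference_from_row(row: pd.Series) -> DemographicInference:
    """Build a DemographicInference from a demographics-table row."""
    return DemographicInference(
        age_probs=tuple(float(row[f"age_{g}"]) for g in AGE_GROUPS),
        gender_probs=(float(row["gender_male"]), float(row["gender_female"])),
        org_probs=(float(row["org_org"]), float(row["org_non-org"])))


def assign_demographics_table(demographics: pd.DataFrame) -> pd.DataFrame:
    """Argmax-assign every row; returns user_id, age_group, gender, org_status."""
    records = []
    for _, row in demographics.iterrows():
        a = assign_demographics(inference_from_row(row))
        records.append({"user_id": row["user_id"], "age_group": a.age_group,
                        "gender": a.gender, "org_status": a.org_status})
    return pd.DataFrame(records, columns=["user_id", "age_group", "gender", "org_status"])


def write_demographics_jsonl(demographics: pd.DataFrame, path) -> None:
    """One JSON object per user: three probability maps, mirroring the shape
    an external inference service emits."""
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in demographics.iterrows():
            rec = {
                "user_id": row["user_id"],
                "age": {g: float(row[f"age_{g}"]) for g in AGE_GROUPS},
                "gender": {"male": float(row["gender_male"]),
                           "female": float(row["gender_female"])},
                "org": {"org": float(row["org_org"]),
                        "non-org": float(row["org_non-org"])},
            }
            fh.write(json.dumps(rec) + "\n")


def read_demographics_jsonl(path) -> pd.DataFrame:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            flat = {"user_id": rec["user_id"]}
            for g in AGE_GROUPS:
                flat[f"age_{g}"] = rec["age"][g]
            flat["gender_male"] = rec["gender"]["male"]
            flat["gender_female"] = rec["gender"]["female"]
            flat["org_org"] = rec["org"]["org"]
            flat["org_non-org"] = rec["org"]["non-org"]
            records.append(flat)
    return pd.DataFrame(records)


def write_bot_scores_jsonl(bot_scores: pd.DataFrame, path) -> None:
    """One JSON object per user with the six named bot-score categories."""
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in bot_scores.iterrows():
            rec = {"user_id": row["user_id"]}
            rec.update({c: float(row[c]) for c in BOT_CATEGORIES})
            fh.write(json.dumps(rec) + "\n")


def read_bot_scores_jsonl(path) -> pd.DataFrame:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(json.loads(line))
    df = pd.DataFrame(records)
    bad = [(c, df[c].min(), df[c].max()) for c in BOT_CATEGORIES
           if len(df) and ((df[c] < 0).any() or (df[c] > 1).any())]
    if bad:
        raise ValueError(f"bot scores out of [0, 1]: {bad}")
    return df


def sample_users(users: pd.DataFrame, fraction: float = 0.10,
                 seed: int = 0) -> pd.DataFrame:
    """Seeded uniform sample (without replacement) of round(fraction * n) users.

    Emulates profiling only a fraction of accounts when external inference
    is expensive; default 10%.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(users)
    if n == 0:
        return users.copy()
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return users.iloc[idx].reset_index(drop=True)


def _class_members(corpus: Corpus) -> dict[str, set[str]]:
    """screen_name (lowercase) sets of misinformation- and fact-spreading authors."""
    if not len(corpus.labels):
        raise ValueError("corpus has no labels; classify first")
    label_map = dict(zip(corpus.labels["tweet_id"], corpus.labels["label"]))
    authors = corpus.tweets["username"].str.lower()
    labels = corpus.tweets["id"].map(label_map)
    known = set(corpus.users["screen_name"].str.lower())
    out = {}
    for cls, val in (("misinfo", 1), ("fact", 0)):
        names = set(authors[labels == val]) & known
        out[cls] = names
    return out


def _users_by_names(corpus: Corpus, names: set[str]) -> pd.DataFrame:
    return corpus.users[corpus.users["screen_name"].str.lower().isin(names)]


def age_distribution(corpus: Corpus, mode: str = "tweets",
                     assigned: Optional[pd.DataFrame] = None) -> dict[str, int]:
    """Misinformation volume per author age group.

    ``mode="tweets"`` (default) counts misinformation tweets whose author has
    an assigned age group; ``mode="users"`` counts unique spreader accounts.
    """
    if assigned is None:
        if corpus.demographics is None:
            raise ValueError("corpus has no demographics table")
        assigned = assign_demographics_table(corpus.demographics)
    user_age = dict(zip(assigned["user_id"], assigned["age_group"]))
    sn_to_id = dict(zip(corpus.users["screen_name"].str.lower(), corpus.users["id"]))
    label_map = dict(zip(corpus.labels["tweet_id"], corpus.labels["label"]))
    counts = {g: 0 for g in AGE_GROUPS}
    if mode == "tweets":
        for tid, author in zip(corpus.tweets["id"], corpus.tweets["username"].str.lower()):
            if label_map.get(tid) != 1:
                continue
            uid = sn_to_id.get(author)
            group = user_age.get(uid)
            if group is not None:
                counts[group] += 1
    elif mode == "users":
        members = _class_members(corpus)["misinfo"]
        for sn in members:
            group = user_age.get(sn_to_id.get(sn))
            if group is not None:
                counts[group] += 1
    else:
        raise ValueError("mode must be 'tweets' or 'users'")
    return counts


@dataclass
class ClassProfile:
    n_accounts: int
    verified_ratio: float  # verified : unverified
    male_female_ratio: Optional[float]
    nonorg_org_ratio: Optional[float]
    mean_followers: float
    mean_friends: float
    mean_favourites: float
    n_with_demographics: int = 0


@dataclass
class ComparisonReport:
    """Engagement/demographic comparison of fact vs misinformation spreaders.

    ``cross_ratios`` are fact / misinformation for each mean metric.
    """

    fact: Optional[ClassProfile]
    misinfo: Optional[ClassProfile]
    dual_membership: int = 0
    cross_ratios: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        def prof(p):
            return None if p is None else vars(p)
        return {"fact": prof(self.fact), "misinfo": prof(self.misinfo),
                "dual_membership": self.dual_membership, "cross_ratios": self.cross_ratios}


def _ratio(a: int, b: int) -> float:
    return float(a) / float(b) if b else (0.0 if a == 0 else float("inf"))


def _profile(users: pd.DataFrame, assigned: Optional[pd.DataFrame]) -> ClassProfile:
    verified = int(users["verified"].sum())
    unverified = len(users) - verified
    male_female = nonorg_org = None
    n_demo = 0
    if assigned is not None:
        sub = assigned[assigned["user_id"].isin(set(users["id"]))]
        n_demo = len(sub)
        if n_demo:
            males = int((sub["gender"] == "male").sum())
            females = n_demo - males
            orgs = int((sub["org_status"] == "org").sum())
            male_female = _ratio(males, females)
            nonorg_org = _ratio(n_demo - orgs, orgs)
    return ClassProfile(
        n_accounts=len(users),
        verified_ratio=_ratio(verified, unverified),
        male_female_ratio=male_female,
        nonorg_org_ratio=nonorg_org,
        mean_followers=float(users["followers_count"].mean()) if len(users) else float("nan"),
        mean_friends=float(users["friends_count"].mean()) if len(users) else float("nan"),
        mean_favourites=float(users["favourites_count"].mean()) if len(users) else float("nan"),
        n_with_demographics=n_demo)


def engagement_comparison(corpus: Corpus,
                          assigned: Optional[pd.DataFrame] = None) -> ComparisonReport:
    """Compare spreader classes on verified/gender/org ratios and engagement means.

    Demographic ratios are computed only over accounts with demographic data
    (the sampled fraction); the denominator count is reported.
    """
    if assigned is None and corpus.demographics is not None:
        assigned = assign_demographics_table(corpus.demographics)
    members = _class_members(corpus)
    dual = len(members["misinfo"] & members["fact"])
    profiles = {}
    for cls in ("fact", "misinfo"):
        users = _users_by_names(corpus, members[cls])
        profiles[cls] = _profile(users, assigned) if len(users) else None
    cross = {}
    if profiles["fact"] is not None and profiles["misinfo"] is not None:
        for metric in ("mean_followers", "mean_friends", "mean_favourites"):
            m = getattr(profiles["misinfo"], metric)
            f = getattr(profiles["fact"], metric)
            cross[metric] = f / m if m else float("inf")
    return ComparisonReport(fact=profiles["fact"], misinfo=profiles["misinfo"],
                            dual_membership=dual, cross_ratios=cross)


@dataclass
class BotComparisonReport:
    """Mean bot score per category for sampled accounts of each spreader class."""

    means: dict[str, dict[str, float]]  # class -> category -> mean
    sample_sizes: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means).rename_axis("category")


def bot_comparison(corpus: Corpus, sample_size: int = 1000,
                   seed: int = 0) -> BotComparisonReport:
    """Per-category mean bot scores on a seeded sample of accounts per class.

    If a class has fewer accounts than ``sample_size``, all are used (with a
    log warning). Requires ``corpus.bot_scores``.
    """
    if corpus.bot_scores is None:
        raise ValueError("corpus has no bot_scores table")
    members = _class_members(corpus)
    scores = corpus.bot_scores.set_index("user_id")
    rng = np.random.default_rng(seed)
    means: dict[str, dict[str, float]] = {}
    sizes: dict[str, int] = {}
    for cls in ("fact", "misinfo"):
        users = _users_by_names(corpus, members[cls])
        ids = [u for u in users["id"] if u in scores.index]
        if not ids:
            means[cls] = {c: float("nan") for c in BOT_CATEGORIES}
            sizes[cls] = 0
            continue
        if len(ids) > sample_size:
            idx = np.sort(rng.choice(len(ids), size=sample_size, replace=False))
            ids = [ids[i] for i in idx]
        else:
            logger.warning("class %s has only %d accounts with bot scores "
                           "(sample_size=%d); using all", cls, len(ids), sample_size)
        sub = scores.loc[ids]
        means[cls] = {c: float(sub[c].mean()) for c in BOT_CATEGORIES}
        sizes[cls] = len(ids)
    return BotComparisonReport(means=means, sample_sizes=sizes)
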