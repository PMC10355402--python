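"""Synthetic Twitter-like corpus generator.

Emulates the statistical structure of a COVID-19 vaccine tweet collection so
the whole pipeline is testable without platform access: ~6% misinformation
prevalence, class-discriminative vocabulary (indicator terms such as "5G",
"microchip", "hoax" concentrated in the misinformation class), a country
mixture dominated by English-speaking countries, weekly volume with
event-driven surges over 2020-W44..2021-W21, class-conditional account
engagement (fact-spreading accounts have ~5x the followers and more
favourites and verified badges; misinformation spreaders have ~25% more
friends), demographic probability vectors, and six-category bot-score
vectors with elevated astroturf scores (0.25 vs 0.12) in the misinformation
class.

Texts are bag-of-token samples: the downstream featurization is
order-insensitive, so lexical signal is all that matters. No retweet graph,
no realistic fluency.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from misinfowatch.data_model import Corpus, join_corpus
from misinfowatch.geo_temporal import Gazetteer, iter_weeks, map_location

AGE_GROUPS = ("<=18", "19-29", "30-39", ">=40")
GENDERS = ("male", "female")
ORG_STATUSES = ("org", "non-org")
BOT_CATEGORIES = ("overall", "astroturf", "fake_follower", "self_declared",
                  "financial", "spammer")

# Shared background vocabulary: generic vaccine-discussion tokens present in
# both classes.
BACKGROUND_VOCAB = (
    "covid vaccine vaccines coronavirus dose doses shot jab pfizer moderna "
    "astrazeneca appointment rollout booked got today news update health "
    "public country people week pandemic virus immunity second first arm "
    "clinic pharmacy waiting line happy relieved finally family grandma "
    "trial data effective safety approved emergency authorization fda who "
    "government minister announcement schedule eligible register online"
).split()

# Indicator terms concentrated in the misinformation class; the classifier
# should recover these among its largest positive weights.
MISINFO_INDICATORS = (
    "5g microchip hoax poison plandemic depopulation sterilize magnetic "
    "bioweapon sheeple tracking nanobots toxins experimental untested dna "
    "alter shedding cure zinc bleach"
).split()

# Fact-leaning terms (more frequent in the fact class).
FACT_LEANING = "efficacy peer reviewed study evidence protects science doctors nurses".split()

DEFAULT_COUNTRY_MIXTURE = {
    "US": 0.30,
    "UK": 0.10,
    "India": 0.06,
    "Canada": 0.06,
    "Australia": 0.025,
    "Nigeria": 0.02,
    "Ireland": 0.015,
    "South Africa": 0.012,
    "France": 0.010,
    "Japan": 0.008,
    "South Korea": 0.006,
    "Singapore": 0.004,
    # remainder: free-text locations the gazetteer cannot map
    "__unmappable__": 0.38,
}

UNMAPPABLE_LOCATIONS = [
    "", "earth", "somewhere nice", "the moon", "in my head", "worldwide",
    "she/her", "he/him", "wherever the wind blows", "127.0.0.1", "internet",
    "your heart", "hogwarts", "galaxy far far away", "around",
]

# (week, country-or-None-for-global, multiplier); defaults emulate the
# December emergency-authorization surge and the March volume peak.
DEFAULT_SURGES = [("2020-51", None, 4.0), ("2020-52", None, 3.0),
                  ("2021-02", None, 1.8), ("2021-10", None, 2.2)]


@dataclass
class ClassAccountParams:
    """Per-class account attribute distributions.

    Engagement counts are log-normal with the given arithmetic means;
    verified/org are Bernoulli; gender and age are categorical mixtures.
    """

    followers_mean: float
    friends_mean: float
    favourites_mean: float
    verified_prob: float
    org_prob: float
    male_prob: float
    age_mixture: tuple[float, float, float, float]
    log_sigma: float = 1.0


# Fact-spreading accounts: 5x followers, ~1.37x favourites (misinfo gives 27%
# fewer), 0.8x friends (misinfo makes 25% more), 3x verified badges.
DEFAULT_FACT_ACCOUNTS = ClassAccountParams(
    followers_mean=1500.0, friends_mean=400.0, favourites_mean=3000.0,
    verified_prob=0.03, org_prob=0.15, male_prob=0.56,
    age_mixture=(0.14, 0.30, 0.28, 0.28))
DEFAULT_MISINFO_ACCOUNTS = ClassAccountParams(
    followers_mean=300.0, friends_mean=500.0, favourites_mean=2190.0,
    verified_prob=0.01, org_prob=0.05, male_prob=0.52,
    age_mixture=(0.20, 0.18, 0.25, 0.37))

# Bot-score Beta means per class, concentration shared; astroturf 0.25 vs
# 0.12, overall elevated, self-declared and fake-follower next, financial and
# spammer similar across classes.
DEFAULT_BOT_MEANS = {
    "fact": {"overall": 0.20, "astroturf": 0.12, "fake_follower": 0.14,
             "self_declared": 0.10, "financial": 0.08, "spammer": 0.09},
    "misinfo": {"overall": 0.30, "astroturf": 0.25, "fake_follower": 0.20,
                "self_declared": 0.18, "financial": 0.08, "spammer": 0.10},
}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults encode the emulated study window."""

    n_tweets: int = 10_000
    misinfo_prevalence: float = 0.06
    start_week: str = "2020-44"
    end_week: str = "2021-21"
    country_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MIXTURE))
    surge_events: list[tuple[str, Optional[str], float]] = field(
        default_factory=lambda: list(DEFAULT_SURGES))
    vocab_background: list[str] = field(default_factory=lambda: list(BACKGROUND_VOCAB))
    vocab_misinfo: list[str] = field(default_factory=lambda: list(MISINFO_INDICATORS))
    vocab_fact: list[str] = field(default_factory=lambda: list(FACT_LEANING))
    #: probability that a token of a misinformation text is an indicator term
    misinfo_indicator_rate: float = 0.25
    fact_leaning_rate: float = 0.15
    #: rate at which fact texts contain a stray indicator term (hard negatives)
    fact_indicator_rate: float = 0.01
    text_len_range: tuple[int, int] = (8, 20)
    account_params: dict[str, ClassAccountParams] = field(default_factory=lambda: {
        "fact": DEFAULT_FACT_ACCOUNTS, "misinfo": DEFAULT_MISINFO_ACCOUNTS})
    bot_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BOT_MEANS.items()})
    bot_concentration: float = 20.0
    #: mean tweets per author; authorship weights are heavy-tailed (Pareto)
    tweets_per_user: float = 3.0
    demographic_sharpness: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 1:
            raise ValueError("n_tweets must be >= 1")
        if not (0.0 <= self.misinfo_prevalence <= 1.0):
            raise ValueError("misinfo_prevalence must be in [0, 1]")
        if not self.vocab_background or not self.vocab_misinfo:
            raise ValueError("vocabulary must be non-empty")
        total = sum(self.country_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"country_mixture must sum to 1, got {total}")
        for params in self.account_params.values():
            if abs(sum(params.age_mixture) - 1.0) > 1e-6:
                raise ValueError("age_mixture must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "account_params" in raw:
            raw["account_params"] = {
                k: ClassAccountParams(**v) for k, v in raw["account_params"].items()}
        if "surge_events" in raw:
            raw["surge_events"] = [tuple(e) for e in raw["surge_events"]]
        if "text_len_range" in raw:
            raw["text_len_range"] = tuple(raw["text_len_range"])
        for p in raw.get("account_params", {}).values():
            if isinstance(p, ClassAccountParams):
                p.age_mixture = tuple(p.age_mixture)
        return cls(**raw)


def _lognormal_params(mean: float, sigma: float) -> tuple[float, float]:
    # arithmetic mean of lognormal(mu, sigma) is exp(mu + sigma^2/2)
    return math.log(mean) - sigma ** 2 / 2.0, sigma


def _sample_counts(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    mu, s = _lognormal_params(mean, sigma)
    return np.floor(rng.lognormal(mu, s, size=n)).astype(np.int64)


def _make_users(rng: np.random.Generator, n_users: int, cls: str,
                params: ClassAccountParams, cfg: GeneratorConfig,
                gazetteer: Gazetteer, id_offset: int) -> pd.DataFrame:
    countries = list(cfg.country_mixture)
    weights = np.array([cfg.country_mixture[c] for c in countries])
    picked = rng.choice(len(countries), size=n_users, p=weights / weights.sum())
    term_cache = {c: gazetteer.unambiguous_terms(c) for c in countries
                  if c != "__unmappable__" and c in gazetteer.countries}
    locations = []
    for idx in picked:
        country = countries[idx]
        terms = term_cache.get(country)
        if country == "__unmappable__" or not terms:
            locations.append(UNMAPPABLE_LOCATIONS[rng.integers(len(UNMAPPABLE_LOCATIONS))])
        else:
            term = terms[rng.integers(len(terms))].title()
            # half the time decorate as "City, Country"
            if rng.random() < 0.5 and term.lower() != country.lower():
                locations.append(f"{term}, {country}")
            else:
                locations.append(term)
    ids = [f"u{cls[0]}{id_offset + i:07d}" for i in range(n_users)]
    return pd.DataFrame({
        "id": ids,
        "screen_name": [f"{cls}_{id_offset + i:07d}" for i in range(n_users)],
        "name": [f"User {id_offset + i}" for i in range(n_users)],
        "profile_location": locations,
        "description": [f"account {i} talking about vaccines" for i in range(n_users)],
        "followers_count": _sample_counts(rng, params.followers_mean, params.log_sigma, n_users),
        "friends_count": _sample_counts(rng, params.friends_mean, params.log_sigma, n_users),
        "favourites_count": _sample_counts(rng, params.favourites_mean, params.log_sigma, n_users),
        "verified": rng.random(n_users) < params.verified_prob,
        "country": "",  # filled by gazetteer mapping downstream
        "profile_image_ref": "",
    })


def _class_token_probs(cfg: GeneratorConfig, cls: str) -> tuple[np.ndarray, list[str]]:
    vocab = list(cfg.vocab_background) + list(cfg.vocab_misinfo) + list(cfg.vocab_fact)
    nb, nm, nf = len(cfg.vocab_background), len(cfg.vocab_misinfo), len(cfg.vocab_fact)
    p = np.zeros(nb + nm + nf)
    if cls == "misinfo":
        ind_rate, fact_rate = cfg.misinfo_indicator_rate, 0.02
    else:
        ind_rate, fact_rate = cfg.fact_indicator_rate, cfg.fact_leaning_rate
    p[:nb] = (1.0 - ind_rate - fact_rate) / nb
    p[nb:nb + nm] = ind_rate / nm
    if nf:
        p[nb + nm:] = fact_rate / nf
    return p / p.sum(), vocab


def _sample_texts(rng: np.random.Generator, n: int, cfg: GeneratorConfig, cls: str) -> list[str]:
    probs, vocab = _class_token_probs(cfg, cls)
    lo, hi = cfg.text_len_range
    lengths = rng.integers(lo, hi + 1, size=n)
    total = int(lengths.sum())
    tokens = rng.choice(len(vocab), size=total, p=probs)
    words = np.array(vocab, dtype=object)[tokens]
    texts, pos = [], 0
    for ln in lengths:
        texts.append(" ".join(words[pos:pos + ln]))
        pos += ln
    return texts


def _week_intensities(cfg: GeneratorConfig) -> tuple[list[str], np.ndarray]:
    weeks = iter_weeks(cfg.start_week, cfg.end_week)
    # gentle ramp from a quiet start toward steady volume
    base = np.linspace(0.4, 1.0, num=len(weeks))
    for week, scope, mult in cfg.surge_events:
        if scope is None and week in weeks:
            base[weeks.index(week)] *= mult
    return weeks, base / base.sum()


def _sample_dates(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> pd.Series:
    weeks, p = _week_intensities(cfg)
    starts = []
    for wk in weeks:
        y, w = wk.split("-")
        starts.append(dt.date.fromisocalendar(int(y), int(w), 1))
    idx = rng.choice(len(weeks), size=n, p=p)
    day = rng.integers(0, 7, size=n)
    sec = rng.integers(0, 86400, size=n)
    stamps = [
        pd.Timestamp(starts[i], tz="UTC") + pd.Timedelta(days=int(d), seconds=int(s))
        for i, d, s in zip(idx, day, sec)
    ]
    return pd.Series(stamps)


def _sample_demographics(rng: np.random.Generator, users: pd.DataFrame, cls: str,
                         params: ClassAccountParams, sharpness: float) -> pd.DataFrame:
    n = len(users)
    age_idx = rng.choice(4, size=n, p=np.asarray(params.age_mixture))
    male = rng.random(n) < params.male_prob
    org = rng.random(n) < params.org_prob

    age_probs = _dirichlet_rows(rng, _alpha(n, 4, age_idx, sharpness))
    gender_probs = _dirichlet_rows(rng, _alpha(n, 2, np.where(male, 0, 1), sharpness))
    org_probs = _dirichlet_rows(rng, _alpha(n, 2, np.where(org, 0, 1), sharpness))
    rec = {"user_id": users["id"].to_numpy()}
    for j, g in enumerate(AGE_GROUPS):
        rec[f"age_{g}"] = age_probs[:, j]
    rec["gender_male"] = gender_probs[:, 0]
    rec["gender_female"] = gender_probs[:, 1]
    rec["org_org"] = org_probs[:, 0]
    rec["org_non-org"] = org_probs[:, 1]
    return pd.DataFrame(rec)


def _alpha(n: int, k: int, hot: np.ndarray, sharpness: float) -> np.ndarray:
    alpha = np.ones((n, k))
    alpha[np.arange(n), hot] = sharpness
    return alpha


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(alpha)
    return g / g.sum(axis=1, keepdims=True)


def _sample_bot_scores(rng: np.random.Generator, users: pd.DataFrame,
                       means: dict[str, float], concentration: float) -> pd.DataFrame:
    n = len(users)
    rec = {"user_id": users["id"].to_numpy()}
    for cat in BOT_CATEGORIES:
        m = means[cat]
        rec[cat] = rng.beta(m * concentration, (1 - m) * concentration, size=n)
    return pd.DataFrame(rec)


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, dict[str, int]]:
    """Generate a corpus plus ground-truth labels (kept separate from the corpus).

    Deterministic given ``config.seed``: the same config produces
    byte-identical tables. Returns ``(corpus, truth)`` where ``truth`` maps
    tweet id to {0, 1}.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gaz = Gazetteer.default()

    n = config.n_tweets
    is_misinfo = rng.random(n) < config.misinfo_prevalence
    n_mis = int(is_misinfo.sum())
    n_fact = n - n_mis

    counts = {"misinfo": n_mis, "fact": n_fact}
    users_by_class: dict[str, pd.DataFrame] = {}
    offset = 0
    for cls in ("fact", "misinfo"):
        n_users = max(1, int(round(counts[cls] / config.tweets_per_user))) if counts[cls] else 0
        if n_users == 0 and counts[cls] == 0:
            users_by_class[cls] = _make_users(rng, 0, cls, config.account_params[cls],
                                              config, gaz, offset)
            continue
        users_by_class[cls] = _make_users(rng, n_users, cls, config.account_params[cls],
                                          config, gaz, offset)
        offset += n_users

    # heavy-tailed authorship weights within each class
    author_weights = {}
    for cls, u in users_by_class.items():
        if len(u):
            w = rng.pareto(1.5, size=len(u)) + 1.0
            author_weights[cls] = w / w.sum()

    texts = np.empty(n, dtype=object)
    authors = np.empty(n, dtype=object)
    for cls, mask in (("misinfo", is_misinfo), ("fact", ~is_misinfo)):
        cnt = int(mask.sum())
        if not cnt:
            continue
        texts[mask] = _sample_texts(rng, cnt, config, cls)
        pool = users_by_class[cls]
        picks = rng.choice(len(pool), size=cnt, p=author_weights[cls])
        authors[mask] = pool["screen_name"].to_numpy()[picks]

    dates = _sample_dates(rng, n, config)
    ids = [f"t{i:08d}" for i in range(n)]
    tweets = pd.DataFrame({
        "id": ids,
        "date": dates,
        "text": texts,
        "url": [f"https://twitter.example/{a}/status/{t}" for a, t in zip(authors, ids)],
        "username": authors,
        "outlinks": [[] for _ in range(n)],
        "retweet_count": rng.poisson(2.0, size=n).astype(np.int64),
        "reply_count": rng.poisson(1.0, size=n).astype(np.int64),
        "like_count": rng.poisson(5.0, size=n).astype(np.int64),
        "quote_count": rng.poisson(0.5, size=n).astype(np.int64),
    })
    tweets = tweets.sort_values("date", kind="stable").reset_index(drop=True)

    users = pd.concat([users_by_class["fact"], users_by_class["misinfo"]],
                      ignore_index=True)
    # resolve through the same gazetteer the pipeline uses
    loc_map = {loc: map_location(loc, gaz) for loc in users["profile_location"].unique()}
    users["country"] = users["profile_location"].map(loc_map)

    demo = pd.concat([
        _sample_demographics(rng, users_by_class["fact"], "fact",
                             config.account_params["fact"], config.demographic_sharpness),
        _sample_demographics(rng, users_by_class["misinfo"], "misinfo",
                             config.account_params["misinfo"], config.demographic_sharpness),
    ], ignore_index=True)
    bots = pd.concat([
        _sample_bot_scores(rng, users_by_class["fact"], config.bot_means["fact"],
                           config.bot_concentration),
        _sample_bot_scores(rng, users_by_class["misinfo"], config.bot_means["misinfo"],
                           config.bot_concentration),
    ], ignore_index=True)

    truth = dict(zip(tweets["id"],
                     [int(is_misinfo[int(t[1:])]) for t in tweets["id"]]))
    corpus = join_corpus(tweets, users, demographics=demo, bot_scores=bots)
    return corpus, truth


class Oracle:
    """Simulated human expert: a pure truth lookup that counts its queries."""

    def __init__(self, truth: dict[str, int]):
        self._truth = dict(truth)
        self.query_count = 0

    def __call__(self, tweet_id: str) -> int:
        if tweet_id not in self._truth:
            raise KeyError(f"oracle has no label for tweet id {tweet_id!r}")
        self.query_count += 1
        return self._truth[tweet_id]


def make_oracle(truth: dict[str, int]) -> Oracle:
    """Wrap a truth mapping as a query-counting labeling oracle."""
    return Oracle(truth)
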