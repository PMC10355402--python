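"""Location normalization, per-country summaries, and weekly time series.

Free-text profile locations are mapped to canonical country names with a
gazetteer (countries, regions, provinces, cities). Weekly aggregation uses
ISO-8601 weeks keyed ``"YYYY-WW"`` (e.g. ``"2020-44"``); misinformation
ratios per country are misinformation tweets over total tweets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from misinfowatch.data_model import UNMAPPED, Corpus


@dataclass
class Gazetteer:
    """Case-insensitive lookup of place terms to canonical country names.

    A term carried by more than one country (e.g. "Georgia") is kept and
    treated as ambiguous at lookup time.
    """

    terms: dict[str, frozenset[str]]  # lowercased term -> countries
    countries: frozenset[str] = field(default_factory=frozenset)
    #: longest term length in tokens, bound for n-gram matching
    max_tokens: int = 1

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Gazetteer":
        terms: dict[str, set[str]] = {}
        countries: set[str] = set()
        for term, country in pairs:
            terms.setdefault(term.strip().lower(), set()).add(country.strip())
            countries.add(country.strip())
        # every canonical country appears as its own term
        for c in countries:
            terms.setdefault(c.lower(), set()).add(c)
        frozen = {t: frozenset(cs) for t, cs in terms.items()}
        max_tokens = max((len(t.split()) for t in frozen), default=1)
        return cls(terms=frozen, countries=frozenset(countries), max_tokens=max_tokens)

    @classmethod
    def from_csv(cls, path) -> "Gazetteer":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if not {"term", "country"} <= set(df.columns):
            raise ValueError("gazetteer CSV needs 'term' and 'country' columns")
        return cls.from_pairs(zip(df["term"], df["country"]))

    @classmethod
    def default(cls) -> "Gazetteer":
        with resources.as_file(
            resources.files("misinfowatch.data").joinpath("gazetteer.csv")
        ) as p:
            return cls.from_csv(p)

    def unambiguous_terms(self, country: str) -> list[str]:
        """Terms (original lowercase) that map only to ``country``."""
        return sorted(t for t, cs in self.terms.items() if cs == frozenset({country}))


def map_location(profile_location: str, gazetteer: Gazetteer) -> str:
    """Map a free-text profile location to a canonical country, or UNMAPPED.

    The text is split on commas, each segment tokenized on whitespace, and
    gazetteer terms are matched longest-first within a segment. A single
    distinct matched country wins; no match or conflicting matches yield
    UNMAPPED.
    """
    if not profile_location or not str(profile_location).strip():
        return UNMAPPED
    matched: set[str] = set()
    ambiguous = False
    for segment in str(profile_location).lower().split(","):
        tokens = segment.replace("/", " ").split()
        i = 0
        while i < len(tokens):
            hit = None
            for n in range(min(gazetteer.max_tokens, len(tokens) - i), 0, -1):
                cand = " ".join(tokens[i:i + n])
                if cand in gazetteer.terms:
                    hit = gazetteer.terms[cand]
                    i += n
                    break
            if hit is None:
                i += 1
            else:
                if len(hit) == 1:
                    matched.add(next(iter(hit)))
                else:
                    ambiguous = True
    if len(matched) == 1:
        return next(iter(matched))
    if len(matched) == 0 and ambiguous:
        return UNMAPPED
    return UNMAPPED


def map_user_locations(users: pd.DataFrame, gazetteer: Gazetteer) -> pd.DataFrame:
    """Return the user table with ``country`` filled from ``profile_location``."""
    out = users.copy()
    out["country"] = [map_location(loc, gazetteer) for loc in out["profile_location"]]
    return out


def country_summaries(corpus: Corpus) -> pd.DataFrame:
    """Per-country tweet counts, misinformation counts, and ratios.

    One row per country with at least one tweet; tweets by users without a
    mapped country (or without a user record) aggregate under UNMAPPED.
    Columns: country, n_tweets, n_misinformation, misinformation_ratio,
    ratio_percent. Sorted by n_tweets descending.
    """
    if not len(corpus.labels):
        raise ValueError("corpus has no labels; classify first")
    user_country = dict(zip(corpus.users["screen_name"].str.lower(), corpus.users["country"]))
    countries = corpus.tweets["username"].str.lower().map(user_country).fillna(UNMAPPED)
    label_map = dict(zip(corpus.labels["tweet_id"], corpus.labels["label"]))
    is_misinfo = corpus.tweets["id"].map(label_map).fillna(0).astype(int)
    df = pd.DataFrame({"country": countries.values, "misinfo": is_misinfo.values})
    grouped = df.groupby("country", sort=False).agg(
        n_tweets=("misinfo", "size"), n_misinformation=("misinfo", "sum"))
    grouped = grouped.reset_index()
    grouped["misinformation_ratio"] = np.where(
        grouped["n_tweets"] > 0, grouped["n_misinformation"] / grouped["n_tweets"], 0.0)
    grouped["ratio_percent"] = grouped["misinformation_ratio"].map(format_ratio)
    return grouped.sort_values("n_tweets", ascending=False, kind="stable").reset_index(drop=True)


def format_ratio(ratio: float) -> str:
    """Render a ratio in [0, 1] as a percentage with one decimal, half-up.

    0.06953 -> "7.0%"; trailing ".0" is kept.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    pct = (Decimal(repr(float(ratio))) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


@dataclass
class WeeklySeries:
    """Ordered weekly counts, keys "YYYY-WW" (ISO week), with optional min-max values."""

    weeks: list[str]
    counts: np.ndarray
    normalized: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.weeks) != len(self.counts):
            raise ValueError("weeks and counts must have the same length")
        if list(self.weeks) != sorted(self.weeks, key=_week_sort_key):
            raise ValueError("week keys must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"week": self.weeks, "count": self.counts})
        if self.normalized is not None:
            df["normalized"] = self.normalized
        return df


def week_key(date) -> str:
    """ISO-week key of a date: 2020-11-01 -> "2020-44"."""
    iso = pd.Timestamp(date).isocalendar()
    return f"{iso.year}-{int(iso.week):02d}"


def _week_sort_key(key: str) -> tuple[int, int]:
    y, w = key.split("-")
    return int(y), int(w)


def iter_weeks(start: str, end: str) -> list[str]:
    """All ISO week keys from start to end inclusive, e.g. "2020-44".."2021-21"."""
    y, w = _week_sort_key(start)
    out = []
    current = dt.date.fromisocalendar(y, w, 1)
    stop = _week_sort_key(end)
    while True:
        iso = current.isocalendar()
        key = f"{iso.year}-{iso.week:02d}"
        out.append(key)
        if (iso.year, iso.week) >= stop:
            break
        current += dt.timedelta(weeks=1)
    return out


def weekly_series(tweets: pd.DataFrame, labels: Optional[pd.DataFrame] = None,
                  users: Optional[pd.DataFrame] = None, country: Optional[str] = None,
                  tweet_class: str = "all") -> WeeklySeries:
    """Bucket tweets by ISO week of their UTC date.

    ``tweet_class`` is "all" or "misinformation" (requires ``labels``);
    ``country`` filters on the author's mapped country (requires ``users``).
    Interior weeks with no tweets are filled with zero counts.
    """
    df = tweets
    if country is not None:
        if users is None:
            raise ValueError("country filter requires the user table")
        user_country = dict(zip(users["screen_name"].str.lower(), users["country"]))
        mask = df["username"].str.lower().map(user_country).fillna(UNMAPPED) == country
        df = df[mask]
    if tweet_class == "misinformation":
        if labels is None:
            raise ValueError("misinformation filter requires labels")
        misinfo_ids = set(labels.loc[labels["label"] == 1, "tweet_id"])
        df = df[df["id"].isin(misinfo_ids)]
    elif tweet_class != "all":
        raise ValueError(f"tweet_class must be 'all' or 'misinformation', got {tweet_class!r}")
    if not len(df):
        return WeeklySeries(weeks=[], counts=np.array([], dtype=np.int64))
    keys = [week_key(d) for d in df["date"]]
    counted = pd.Series(keys).value_counts()
    first = min(counted.index, key=_week_sort_key)
    last = max(counted.index, key=_week_sort_key)
    weeks = iter_weeks(first, last)
    counts = np.array([int(counted.get(w, 0)) for w in weeks], dtype=np.int64)
    return WeeklySeries(weeks=weeks, counts=counts)


def minmax_normalize(series: WeeklySeries) -> WeeklySeries:
    """Min-max rescale counts to [0, 1]; a constant series normalizes to all zeros."""
    if not series.weeks:
        raise ValueError("cannot normalize an empty series")
    v = series.counts.astype(float)
    lo, hi = v.min(), v.max()
    norm = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return WeeklySeries(weeks=list(series.weeks), counts=series.counts.copy(), normalized=norm)


def annotate_peak(series: WeeklySeries) -> tuple[str, int]:
    """The earliest week attaining the maximum raw count, with that count."""
    if not series.weeks:
        raise ValueError("cannot find a peak in an empty series")
    idx = int(np.argmax(series.counts))
    return series.weeks[idx], int(series.counts[idx])
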