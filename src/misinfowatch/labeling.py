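"""Weak labeling: guideline screening, keyword augmentation, and label merging.

The training set for the classifier is bootstrapped in two steps. A small
manually annotated seed set (label 1 = misinformation, 0 = fact) is first
expanded with weakly labeled positives selected by a keyword query: a tweet
qualifies if it contains at least one misinformation-indicator term ("5G",
"poison", "microchip", "hoax", ...) and none of the exclusion terms
("misleading", "conspiracy") that mark tweets *warning about*
misinformation rather than spreading it. Guideline criteria encode the
annotation handbook as advisory pattern matchers; they never override a
manual label.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from misinfowatch.data_model import LABEL_COLUMNS

DEFAULT_INCLUDE_TERMS = ["5G", "poison", "microchip", "hoax"]
DEFAULT_EXCLUDE_TERMS = ["misleading", "conspiracy"]


@dataclass
class GuidelineCriterion:
    """One annotation-guideline rule with best-effort machine patterns."""

    id: str
    polarity: str  # "misinformation" | "non-misinformation"
    description: str
    indicator_patterns: list[str] = field(default_factory=list)
    manual_only: bool = False

    def __post_init__(self):
        if self.polarity not in ("misinformation", "non-misinformation"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if not self.indicator_patterns and not self.manual_only:
            raise ValueError(f"criterion {self.id!r} has no patterns; mark it manual_only")
        self._compiled = [re.compile(p, re.IGNORECASE) for p in self.indicator_patterns]

    def matches(self, text: str) -> bool:
        return any(rx.search(text) for rx in self._compiled)


def load_criteria(path=None) -> list[GuidelineCriterion]:
    """Load criteria from a YAML file; default is the shipped guideline encoding."""
    if path is None:
        source = resources.files("misinfowatch.data").joinpath("criteria.yaml")
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return [GuidelineCriterion(**c) for c in raw["criteria"]]


@dataclass
class ScreeningResult:
    advisory_label: Optional[int]  # 1, 0, or None (no match / both polarities)
    matched: list[str]  # criterion ids
    both_polarities: bool = False


def screen_with_guidelines(text: str, criteria: list[GuidelineCriterion]) -> ScreeningResult:
    """Advisory screen of one tweet text against the guideline criteria.

    Returns the polarity of matched criteria as an advisory label (1 for
    misinformation, 0 otherwise), or no label when nothing matches or when
    criteria of both polarities match.
    """
    hits = [c for c in criteria if not c.manual_only and c.matches(text)]
    polarities = {c.polarity for c in hits}
    if not hits:
        return ScreeningResult(advisory_label=None, matched=[])
    if len(polarities) == 2:
        return ScreeningResult(advisory_label=None, matched=[c.id for c in hits],
                               both_polarities=True)
    label = 1 if polarities == {"misinformation"} else 0
    return ScreeningResult(advisory_label=label, matched=[c.id for c in hits])


@dataclass
class AugmentationQuery:
    """Include/exclude keyword query used to harvest weakly labeled positives."""

    include_terms: list[str] = field(default_factory=lambda: list(DEFAULT_INCLUDE_TERMS))
    exclude_terms: list[str] = field(default_factory=lambda: list(DEFAULT_EXCLUDE_TERMS))
    target_additions: int = 4000

    def __post_init__(self):
        inc = {t.lower() for t in self.include_terms}
        exc = {t.lower() for t in self.exclude_terms}
        if inc & exc:
            raise ValueError(f"include and exclude terms overlap: {sorted(inc & exc)}")


def _term_regex(term: str) -> re.Pattern:
    # word-boundary matching that treats digits as word characters:
    # "5G" matches "5g" but not "15GB"
    return re.compile(rf"(?<![0-9A-Za-z_]){re.escape(term)}(?![0-9A-Za-z_])", re.IGNORECASE)


def contains_term(text: str, term: str) -> bool:
    """Case-insensitive whole-word containment ("5G" in "no to 5g", not in "15GB")."""
    return bool(_term_regex(term).search(text))


def keyword_augment(pool: pd.DataFrame, query: Optional[AugmentationQuery] = None,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Select weakly labeled misinformation tweets from an unlabeled pool.

    A tweet is selected iff it contains >=1 include term and no exclude term
    (case-insensitive, word-boundary). At most ``target_additions`` records
    are returned, taken in pool order (or a seeded random subset when ``rng``
    is given). Returns a label table (label=1, source=keyword_augmented) plus
    ``attrs['matched_terms']`` mapping tweet_id -> matched include terms for
    manual review.
    """
    query = query or AugmentationQuery()
    inc = [_term_regex(t) for t in query.include_terms]
    exc = [_term_regex(t) for t in query.exclude_terms]
    selected: list[str] = []
    matched_terms: dict[str, list[str]] = {}
    for tid, text in zip(pool["id"], pool["text"]):
        hits = [t for t, rx in zip(query.include_terms, inc) if rx.search(text)]
        if hits and not any(rx.search(text) for rx in exc):
            selected.append(tid)
            matched_terms[tid] = hits
    if len(selected) > query.target_additions:
        if rng is not None:
            keep = sorted(rng.choice(len(selected), size=query.target_additions,
                                     replace=False))
            selected = [selected[i] for i in keep]
        else:
            selected = selected[:query.target_additions]
    elif len(selected) < query.target_additions:
        warnings.warn(f"keyword query matched only {len(selected)} tweets "
                      f"(target was {query.target_additions}); returning all matches")
    out = pd.DataFrame({
        "tweet_id": selected,
        "label": np.ones(len(selected), dtype=np.int64),
        "source": "keyword_augmented",
        "confidence": np.nan,
    }, columns=LABEL_COLUMNS)
    out.attrs["matched_terms"] = {t: matched_terms[t] for t in selected}
    return out


@dataclass
class BalanceReport:
    """Class balance of a merged labeled set."""

    counts: dict[int, int]
    total: int
    overlap: int  # augmented ids that were already manually labeled (manual wins)

    def as_dict(self) -> dict:
        return {"0": self.counts.get(0, 0), "1": self.counts.get(1, 0),
                "total": self.total, "overlap": self.overlap}


def merge_label_sets(manual: pd.DataFrame, augmented: pd.DataFrame
                     ) -> tuple[pd.DataFrame, BalanceReport]:
    """Merge manual and keyword-augmented labels; manual wins on overlap.

    Conflicting duplicate *manual* labels for a tweet are a hard error.
    Returns the merged label table and a per-class balance report.
    """
    dup = manual[manual["tweet_id"].duplicated(keep=False)]
    if len(dup):
        conflicting = dup.groupby("tweet_id")["label"].nunique()
        bad = conflicting[conflicting > 1].index.tolist()
        if bad:
            raise ValueError(f"conflicting duplicate manual labels for tweet ids: {bad[:5]}")
        manual = manual.drop_duplicates("tweet_id")
    manual_ids = set(manual["tweet_id"])
    overlap = int(augmented["tweet_id"].isin(manual_ids).sum())
    merged = pd.concat([manual, augmented[~augmented["tweet_id"].isin(manual_ids)]],
                       ignore_index=True)
    counts = merged["label"].value_counts().to_dict()
    report = BalanceReport(counts={int(k): int(v) for k, v in counts.items()},
                           total=int(len(merged)), overlap=overlap)
    return merged, report
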