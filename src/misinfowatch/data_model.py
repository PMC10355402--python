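"""Core domain tables: tweets, user accounts, labels, and the joined corpus.

Tables are pandas DataFrames with canonical snake_case columns. Readers
accept both the raw platform camelCase field names (``retweetCount``,
``screenName`` ...) and snake_case, normalizing to snake_case internally.
Timestamps are stored timezone-aware UTC; naive inputs are assumed UTC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

UNMAPPED = "UNMAPPED"

#: label values: 1 = misinformation, 0 = fact
LABEL_MISINFO = 1
LABEL_FACT = 0

LABEL_SOURCES = ("manual", "keyword_augmented", "oracle", "predicted")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


class RowError(ValueError):
    """One or more rows failed validation; carries (row_number, message) pairs."""

    def __init__(self, schema: str, rows: list[tuple[int, str]]):
        self.schema = schema
        self.rows = rows
        preview = "; ".join(f"row {i}: {msg}" for i, msg in rows[:5])
        more = f" (+{len(rows) - 5} more)" if len(rows) > 5 else ""
        super().__init__(f"{len(rows)} malformed row(s) in {schema} table: {preview}{more}")


# canonical column -> accepted aliases (camelCase per the raw API, plus the
# 'tweet' text field name)
_TWEET_ALIASES = {
    "id": ["id"],
    "date": ["date"],
    "text": ["text", "tweet"],
    "url": ["url"],
    "username": ["username"],
    "outlinks": ["outlinks"],
    "retweet_count": ["retweet_count", "retweetCount"],
    "reply_count": ["reply_count", "replyCount"],
    "like_count": ["like_count", "likeCount"],
    "quote_count": ["quote_count", "quoteCount"],
}

_USER_ALIASES = {
    "id": ["id"],
    "screen_name": ["screen_name", "screenName"],
    "name": ["name"],
    "profile_location": ["profile_location", "profileLocation"],
    "description": ["description"],
    "followers_count": ["followers_count", "followersCount"],
    "friends_count": ["friends_count", "friendsCount"],
    "favourites_count": ["favourites_count", "favouritesCount"],
    "verified": ["verified"],
}
_USER_OPTIONAL = {"country": ["country"], "profile_image_ref": ["profile_image_ref"]}

_LABEL_ALIASES = {
    "tweet_id": ["tweet_id", "tweetId"],
    "label": ["label"],
    "source": ["source"],
}
_LABEL_OPTIONAL = {"confidence": ["confidence"]}

TWEET_COLUMNS = list(_TWEET_ALIASES)
USER_COLUMNS = list(_USER_ALIASES) + list(_USER_OPTIONAL)
LABEL_COLUMNS = list(_LABEL_ALIASES) + list(_LABEL_OPTIONAL)

_COUNT_COLS = {
    "tweet": ["retweet_count", "reply_count", "like_count", "quote_count"],
    "user": ["followers_count", "friends_count", "favourites_count"],
}


@dataclass
class Corpus:
    """A joined analysis corpus.

    ``tweets``/``users``/``labels`` are DataFrames in canonical schema;
    ``demographics`` and ``bot_scores`` are optional per-user tables keyed by
    user id (see :mod:`misinfowatch.account_profiling` for their shapes).
    ``unmatched`` lists tweet ids whose author has no user record; those
    tweets stay in the corpus (usable for content analysis) but are excluded
    from account profiling.
    """

    tweets: pd.DataFrame
    users: pd.DataFrame
    labels: pd.DataFrame = field(default_factory=lambda: empty_table("label"))
    demographics: Optional[pd.DataFrame] = None
    bot_scores: Optional[pd.DataFrame] = None
    unmatched: list[str] = field(default_factory=list)

    def with_labels(self, labels: pd.DataFrame) -> "Corpus":
        return replace(self, labels=labels.reset_index(drop=True))


def empty_table(schema: str) -> pd.DataFrame:
    cols = {"tweet": TWEET_COLUMNS, "user": USER_COLUMNS, "label": LABEL_COLUMNS}[schema]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _resolve_columns(present: list[str], schema: str) -> dict[str, str]:
    """Map canonical column -> actual column name in the input; raise on missing."""
    required, optional = {
        "tweet": (_TWEET_ALIASES, {}),
        "user": (_USER_ALIASES, _USER_OPTIONAL),
        "label": (_LABEL_ALIASES, _LABEL_OPTIONAL),
    }[schema]
    mapping: dict[str, str] = {}
    for canon, aliases in required.items():
        hit = next((a for a in aliases if a in present), None)
        if hit is None:
            raise SchemaError(f"{schema} table is missing required column '{canon}' "
                              f"(accepted names: {aliases})")
        mapping[canon] = hit
    for canon, aliases in optional.items():
        hit = next((a for a in aliases if a in present), None)
        if hit is not None:
            mapping[canon] = hit
    return mapping


def _parse_outlinks(value) -> list[str]:
    if isinstance(value, list):
        return [str(v) for v in value]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s:
        return []
    parsed = json.loads(s)  # CSV carries outlinks as a JSON array string
    if not isinstance(parsed, list):
        raise ValueError("outlinks must be a JSON array")
    return [str(v) for v in parsed]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0", ""):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _validate_tweets(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    errors: list[tuple[int, str]] = []
    out = df.copy()
    out["id"] = out["id"].astype(str)
    out["text"] = out["text"].fillna("").astype(str)
    out["url"] = out["url"].fillna("").astype(str)
    out["username"] = out["username"].fillna("").astype(str)

    dates = pd.to_datetime(out["date"], errors="coerce", utc=True, format="mixed")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        errors.append((int(i), f"unparseable date {out['date'].iloc[i]!r}"))
    out["date"] = dates

    links = []
    for i, v in enumerate(out["outlinks"]):
        try:
            links.append(_parse_outlinks(v))
        except (ValueError, json.JSONDecodeError) as e:
            errors.append((i, f"bad outlinks: {e}"))
            links.append([])
    out["outlinks"] = links

    for col in _COUNT_COLS["tweet"]:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((int(i), f"{col} must be a non-negative integer, got {out[col].iloc[i]!r}"))
        out[col] = vals.fillna(0).astype(np.int64)

    dup = out["id"].duplicated()
    for i in np.flatnonzero(dup.to_numpy()):
        errors.append((int(i), f"duplicate tweet id {out['id'].iloc[i]!r}"))
    return out[TWEET_COLUMNS], errors


def _validate_users(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    errors: list[tuple[int, str]] = []
    out = df.copy()
    for col in ("id", "screen_name", "name", "profile_location", "description"):
        out[col] = out[col].fillna("").astype(str)
    for col in _COUNT_COLS["user"]:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((int(i), f"{col} must be a non-negative integer, got {out[col].iloc[i]!r}"))
        out[col] = vals.fillna(0).astype(np.int64)
    flags = []
    for i, v in enumerate(out["verified"]):
        try:
            flags.append(_parse_bool(v))
        except ValueError as e:
            errors.append((i, str(e)))
            flags.append(False)
    out["verified"] = flags
    if "country" not in out.columns:
        out["country"] = UNMAPPED
    else:
        out["country"] = out["country"].fillna(UNMAPPED).replace("", UNMAPPED).astype(str)
    if "profile_image_ref" not in out.columns:
        out["profile_image_ref"] = ""
    else:
        out["profile_image_ref"] = out["profile_image_ref"].fillna("").astype(str)

    dup = out["screen_name"].str.lower().duplicated()
    for i in np.flatnonzero(dup.to_numpy()):
        errors.append((int(i), f"duplicate screen_name {out['screen_name'].iloc[i]!r}"))
    return out[USER_COLUMNS], errors


def _validate_labels(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    errors: list[tuple[int, str]] = []
    out = df.copy()
    out["tweet_id"] = out["tweet_id"].astype(str)
    labels = pd.to_numeric(out["label"], errors="coerce")
    bad = ~labels.isin([LABEL_FACT, LABEL_MISINFO])
    for i in np.flatnonzero(bad.to_numpy()):
        errors.append((int(i), f"label must be 0 or 1, got {out['label'].iloc[i]!r}"))
    out["label"] = labels.fillna(0).astype(np.int64)
    out["source"] = out["source"].fillna("").astype(str)
    bad_src = ~out["source"].isin(LABEL_SOURCES)
    for i in np.flatnonzero(bad_src.to_numpy()):
        errors.append((int(i), f"unknown label source {out['source'].iloc[i]!r}"))
    if "confidence" not in out.columns:
        out["confidence"] = np.nan
    else:
        out["confidence"] = pd.to_numeric(out["confidence"], errors="coerce")
    return out[LABEL_COLUMNS], errors


_VALIDATORS = {"tweet": _validate_tweets, "user": _validate_users, "label": _validate_labels}


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith(".jsonl") or p.endswith(".ndjson"):
        return "jsonl"
    if p.endswith(".csv"):
        return "csv"
    raise ValueError(f"cannot infer format from {path!r}; pass format='jsonl' or 'csv'")


def read_table(
    path,
    schema: Literal["tweet", "user", "label"],
    format: Optional[Literal["jsonl", "csv"]] = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read and validate a tweet / user / label table from JSONL or CSV.

    Column names may be camelCase (raw API names) or snake_case. With
    ``strict=True`` (default) any malformed row raises :class:`RowError`
    listing the offending row numbers; with ``strict=False`` malformed rows
    are dropped and the error is attached to ``df.attrs['row_errors']``.
    """
    if schema not in _VALIDATORS:
        raise ValueError(f"unknown schema {schema!r}")
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        raw = pd.DataFrame(records)
        if raw.empty:
            return empty_table(schema)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    mapping = _resolve_columns(list(raw.columns), schema)
    df = raw[[mapping[c] for c in mapping]].copy()
    df.columns = list(mapping)
    if df.empty:
        return empty_table(schema)
    validated, errors = _VALIDATORS[schema](df)
    if errors:
        if strict:
            raise RowError(schema, errors)
        bad_rows = sorted({i for i, _ in errors})
        validated = validated.drop(index=validated.index[bad_rows]).reset_index(drop=True)
        validated.attrs["row_errors"] = errors
    return validated.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, schema: Literal["tweet", "user", "label"],
                format: Optional[Literal["jsonl", "csv"]] = None) -> None:
    """Write a canonical table as UTF-8 JSONL or CSV (outlinks as JSON array string)."""
    fmt = _infer_format(path, format)
    out = df.copy()
    if schema == "tweet" and len(out):
        out["date"] = out["date"].map(lambda d: d.strftime("%Y-%m-%dT%H:%M:%S+00:00"))
    if fmt == "csv":
        if schema == "tweet" and len(out):
            out["outlinks"] = out["outlinks"].map(lambda l: json.dumps(list(l)))
        out.to_csv(path, index=False, encoding="utf-8")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in out.to_dict(orient="records"):
                if schema == "tweet":
                    rec["outlinks"] = list(rec["outlinks"])
                if schema == "label":
                    conf = rec.get("confidence")
                    if conf is not None and isinstance(conf, float) and np.isnan(conf):
                        rec["confidence"] = None
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def join_corpus(tweets: pd.DataFrame, users: pd.DataFrame,
                labels: Optional[pd.DataFrame] = None,
                demographics: Optional[pd.DataFrame] = None,
                bot_scores: Optional[pd.DataFrame] = None) -> Corpus:
    """Join tweets to their authors on username <-> screen_name (case-insensitive).

    Tweets whose author has no user record are recorded in ``corpus.unmatched``
    but retained. Duplicate screen names in the user table are a hard error
    because they make the join ambiguous.
    """
    keys = users["screen_name"].str.lower()
    dups = keys[keys.duplicated()].unique().tolist()
    if dups:
        raise SchemaError(f"duplicate screen_name(s) in user table: {dups[:5]}")
    known = set(keys)
    mask = ~tweets["username"].str.lower().isin(known)
    unmatched = tweets.loc[mask, "id"].tolist()
    labels = labels if labels is not None else empty_table("label")
    if len(labels):
        stray = set(labels["tweet_id"]) - set(tweets["id"])
        if stray:
            raise SchemaError(f"labels reference unknown tweet ids: {sorted(stray)[:5]}")
    return Corpus(tweets=tweets.reset_index(drop=True), users=users.reset_index(drop=True),
                  labels=labels, demographics=demographics, bot_scores=bot_scores,
                  unmatched=unmatched)
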