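"""Complaint-table reading, cleaning, mechanical compression, tokenization
and stop-word filtering.

The cleaning contract mirrors how hospital complaint exports are triaged:
records whose free-text content is missing are excluded (and counted),
while records with unparseable dates are kept with the sentinel "—" in
place of the date — a bad timestamp does not invalidate a complaint.

Mechanical compression removes machine-pasted adjacent repeats
("好好好好" → "好", "abcabcabc" → "abc") before segmentation, leaving
natural prose untouched.
"""

from __future__ import annotations

import io
import unicodedata
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .errors import ConfigError, InputError

DATE_SENTINEL = "—"  # "—"

_CHANNELS = {"internal", "external"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ComplaintRecord:
    """One complaint or follow-up entry."""

    record_id: str
    date: str  # ISO-8601 "YYYY-MM-DD" or the sentinel "—"
    channel: Optional[str]
    raw_text: str
    tokens: list[str] = field(default_factory=list)
    group: Optional[str] = None
    extra: dict = field(default_factory=dict)


@dataclass
class CleaningSummary:
    """Accounting of a read: rows_read = len(records) + rows_dropped."""

    rows_read: int
    rows_dropped: int
    dates_sentineled: int


@dataclass
class TableDialect:
    """Column mapping and delimiter for a complaint table.

    ``delimiter=None`` auto-detects (comma vs tab) from the header line.
    """

    id_col: str = "id"
    text_col: str = "text"
    date_col: Optional[str] = "date"
    channel_col: Optional[str] = "channel"
    group_col: Optional[str] = None
    delimiter: Optional[str] = None


class StopList:
    """Exact-membership stop list; tokens NFC-normalized on both sides."""

    def __init__(self, entries: Iterable[str] = ()):
        self.entries = {unicodedata.normalize("NFC", e) for e in entries}

    def __contains__(self, token: str) -> bool:
        return unicodedata.normalize("NFC", token) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __or__(self, other: "StopList") -> "StopList":
        return StopList(self.entries | other.entries)


def load_stoplist(path: str | Path) -> StopList:
    """Read a stop list: one token per line, '#' comments, blank lines ignored."""
    entries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        entries.append(line)
    return StopList(entries)


# ---------------------------------------------------------------------------
# reading & cleaning
# ---------------------------------------------------------------------------

def parse_date(value: object) -> tuple[str, bool]:
    """Normalize a date cell to ISO-8601, or the sentinel "—".

    Accepts ISO-8601 (YYYY-MM-DD) and YYYY/MM/DD. Anything else — including
    impossible calendar dates — yields the sentinel, never an error.
    Returns (normalized, was_sentineled).
    """
    if value is None:
        return DATE_SENTINEL, True
    text = str(value).strip()
    if not text or text == DATE_SENTINEL:
        return DATE_SENTINEL, True
    candidate = text.replace("/", "-")
    try:
        parsed = _date.fromisoformat(candidate)
    except ValueError:
        return DATE_SENTINEL, True
    return parsed.isoformat(), False


def read_complaints(
    path: str | Path, dialect: TableDialect | None = None
) -> tuple[list[ComplaintRecord], CleaningSummary]:
    """Read a delimited complaint table into cleaned records.

    Rows with missing or blank text are dropped and counted; unparseable
    dates are replaced by the sentinel "—". File order is preserved.

    Raises :class:`ConfigError` naming any missing required column and
    :class:`InputError` with the byte offset for undecodable bytes.
    """
    dialect = dialect or TableDialect()
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise InputError(
            f"{path}: undecodable byte at offset {exc.start}"
        ) from exc

    sep = dialect.delimiter
    if sep is None:
        header = text.split("\n", 1)[0]
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)

    for required in (dialect.id_col, dialect.text_col):
        if required not in frame.columns:
            raise ConfigError(
                f"{path}: required column {required!r} not found "
                f"(columns: {list(frame.columns)})"
            )

    known = {dialect.id_col, dialect.text_col, dialect.date_col,
             dialect.channel_col, dialect.group_col}
    extra_cols = [c for c in frame.columns if c not in known]

    records: list[ComplaintRecord] = []
    dropped = 0
    sentineled = 0
    for _, row in frame.iterrows():
        body = str(row[dialect.text_col]).strip()
        if not body:
            dropped += 1
            continue
        if dialect.date_col and dialect.date_col in frame.columns:
            date_str, was_sent = parse_date(row[dialect.date_col])
            sentineled += int(was_sent)
        else:
            date_str = DATE_SENTINEL
        channel = None
        if dialect.channel_col and dialect.channel_col in frame.columns:
            value = str(row[dialect.channel_col]).strip().lower()
            channel = value if value in _CHANNELS else (value or None)
        group = None
        if dialect.group_col and dialect.group_col in frame.columns:
            group = str(row[dialect.group_col]).strip() or None
        records.append(
            ComplaintRecord(
                record_id=str(row[dialect.id_col]),
                date=date_str,
                channel=channel,
                raw_text=body,
                group=group,
                extra={c: row[c] for c in extra_cols},
            )
        )
    summary = CleaningSummary(
        rows_read=len(frame), rows_dropped=dropped, dates_sentineled=sentineled
    )
    return records, summary


# ---------------------------------------------------------------------------
# mechanical compression
# ---------------------------------------------------------------------------

def _compress_once(text: str, max_unit: int) -> str:
    out: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        collapsed = False
        for unit in range(1, max_unit + 1):
            chunk = text[i : i + unit]
            if len(chunk) < unit or text[i + unit : i + 2 * unit] != chunk:
                continue
            # maximal run of this unit starting at i
            j = i + unit
            while text[j : j + unit] == chunk:
                j += unit
            out.append(chunk)
            i = j
            collapsed = True
            break
        if not collapsed:
            out.append(text[i])
            i += 1
    return "".join(out)


def mechanical_compress(text: str, max_unit: int = 5) -> str:
    """Collapse adjacent repeats of any unit of length ≤ ``max_unit``.

    Scans left to right, shortest repeating unit first, and re-applies the
    pass until a fixed point, so nested repeats ("aabaab" → "ab") resolve.
    Idempotent by construction; never lengthens the text.
    """
    if max_unit < 1:
        raise ConfigError(f"max_unit must be >= 1, got {max_unit}")
    current = text
    while True:
        reduced = _compress_once(current, max_unit)
        if reduced == current:
            return reduced
        current = reduced


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _whitespace_segment(text: str) -> list[str]:
    return text.split()


_CJK_TOY_DICT = ("态度", "服务", "环境", "医生", "医院", "病人", "不好", "很差")


def _simple_cjk_segment(text: str) -> list[str]:
    """Greedy longest-match segmentation over a small built-in dictionary.

    CJK runs are matched against the dictionary (longest first) with a
    single-character fallback; non-CJK runs split on whitespace. A compact,
    dependency-free segmenter adequate for synthetic corpora and tests.
    """
    max_len = max(len(w) for w in _CJK_TOY_DICT)
    words = set(_CJK_TOY_DICT)
    tokens: list[str] = []
    buf: list[str] = []

    def flush_latin():
        if buf:
            tokens.extend("".join(buf).split())
            buf.clear()

    i = 0
    while i < len(text):
        ch = text[i]
        if "一" <= ch <= "鿿":
            flush_latin()
            for length in range(min(max_len, len(text) - i), 0, -1):
                if length == 1 or text[i : i + length] in words:
                    tokens.append(text[i : i + length])
                    i += length
                    break
        else:
            buf.append(ch)
            i += 1
    flush_latin()
    return tokens


SEGMENTERS: dict[str, Callable[[str], list[str]]] = {
    "whitespace": _whitespace_segment,
    "simple-cjk": _simple_cjk_segment,
}

try:  # optional adapter; not required by anything in the test suite
    import jieba as _jieba  # type: ignore

    SEGMENTERS["jieba"] = lambda text: [t for t in _jieba.lcut(text) if t.strip()]
except ImportError:
    pass


def tokenize(text: str, segmenter: str = "whitespace") -> list[str]:
    """Segment NFC-normalized text with a registered segmenter."""
    if segmenter not in SEGMENTERS:
        raise ConfigError(
            f"unknown segmenter {segmenter!r}; available: {sorted(SEGMENTERS)}"
        )
    return SEGMENTERS[segmenter](unicodedata.normalize("NFC", text))


def remove_stopwords(tokens: list[str], stoplist: StopList) -> list[str]:
    """Drop stop-list members, preserving order. Idempotent."""
    return [t for t in tokens if t not in stoplist]


def preprocess_records(
    records: list[ComplaintRecord],
    stoplist: StopList | None = None,
    segmenter: str = "whitespace",
    max_unit: int = 5,
) -> list[ComplaintRecord]:
    """Full text pipeline per record: compress → tokenize → filter. In place."""
    stoplist = stoplist or StopList()
    for rec in records:
        compressed = mechanical_compress(rec.raw_text, max_unit=max_unit)
        rec.tokens = remove_stopwords(tokenize(compressed, segmenter), stoplist)
    return records
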