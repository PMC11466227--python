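"""Chronic-health-condition (CHC) phenotype code lists and event ascertainment.

A CHC is ascertained from ICD-10 diagnosis codes recorded in hospital
inpatient episodes.  A curated code list maps each qualifying ICD-10 code to
one of nine body-system subtype groups; the first recorded instance of a
matching code per child (in any of the up-to-20 diagnostic positions,
including the birth episode) is the incident event, both overall ("any" CHC)
and per subtype.

Matching semantics: both record and list codes are normalized to at most four
characters (uppercase, dot stripped).  A record code matches a list entry if
they are equal, or if the record code's 3-character truncation equals a
3-character list entry.  Where a 3- and a 4-character list entry both match,
the more specific 4-character entry wins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel subtype for the "any CHC" composite event
ANY = "any"

#: canonical body-system subtype groups
SUBTYPES = (
    "cancer/blood",
    "cardiovascular",
    "respiratory",
    "neurological",
    "mental health/behavioural",
    "metabolic and other",
    "musculoskeletal/skin",
    "chronic infections",
    "non-specific",
)

# accepted spellings in input CSVs -> canonical label
_SUBTYPE_ALIASES: dict[str, str] = {
    "cancer/blood": "cancer/blood",
    "cancer_blood": "cancer/blood",
    "cancer and blood": "cancer/blood",
    "cardiovascular": "cardiovascular",
    "respiratory": "respiratory",
    "neurological": "neurological",
    "mental health/behavioural": "mental health/behavioural",
    "mental_health": "mental health/behavioural",
    "mental health": "mental health/behavioural",
    "metabolic and other": "metabolic and other",
    "metabolic_other": "metabolic and other",
    "metabolic-and-other": "metabolic and other",
    "metabolic/endocrine/digestive/renal/genitourinary": "metabolic and other",
    "musculoskeletal/skin": "musculoskeletal/skin",
    "musculoskeletal_skin": "musculoskeletal/skin",
    "chronic infections": "chronic infections",
    "chronic_infections": "chronic infections",
    "non-specific": "non-specific",
    "non_specific": "non-specific",
    "nonspecific": "non-specific",
}

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")


class InvalidCodeError(ValueError):
    """Raised when a string cannot be normalized to a valid ICD-10 code."""


class CodeListError(ValueError):
    """Raised on malformed code-list input (bad code, duplicate, bad group)."""


def normalize_code(raw: str) -> str:
    """Normalize a raw ICD-10 string: uppercase, dot stripped, first 4 chars.

    Idempotent.  Raises :class:`InvalidCodeError` if the result does not look
    like an ICD-10 code (letter + two digits + optional alphanumeric).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidCodeError(f"empty or non-string code: {raw!r}")
    code = raw.strip().upper().replace(".", "")[:4]
    if not _CODE_RE.match(code):
        raise InvalidCodeError(f"{raw!r} does not normalize to an ICD-10 code")
    return code


@dataclass(frozen=True)
class CodeListEntry:
    code: str  # normalized, 3 or 4 characters
    description: str
    subtype: str  # one of SUBTYPES


@dataclass
class CodeList:
    """A CHC phenotype list with exact and 3-character-prefix lookup."""

    entries: dict[str, CodeListEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._three_char = {c for c in self.entries if len(c) == 3}

    def add(self, entry: CodeListEntry) -> None:
        if entry.code in self.entries:
            raise CodeListError(f"duplicate code {entry.code!r}")
        if entry.subtype not in SUBTYPES:
            raise CodeListError(
                f"unknown subtype {entry.subtype!r}; allowed: {list(SUBTYPES)}"
            )
        self.entries[entry.code] = entry
        if len(entry.code) == 3:
            self._three_char.add(entry.code)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def match(self, code: str) -> str | None:
        """Subtype for a normalized record code, or ``None`` for no match.

        A 4-character record code matches its exact entry first (specificity
        tie rule), then a 3-character list entry by prefix.  A 3-character
        record code matches only an exact 3-character entry.
        """
        entry = self.entries.get(code)
        if entry is not None:
            return entry.subtype
        if len(code) == 4 and code[:3] in self._three_char:
            return self.entries[code[:3]].subtype
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.code, e.description, e.subtype) for e in self.entries.values()],
            columns=["code", "description", "group"],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def match_code(code: str, code_list: CodeList) -> str | None:
    """Functional form of :meth:`CodeList.match`."""
    return code_list.match(code)


def canonical_subtype(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _SUBTYPE_ALIASES:
        raise CodeListError(
            f"unknown subtype label {label!r}; allowed: {list(SUBTYPES)}"
        )
    return _SUBTYPE_ALIASES[key]


def load_code_list(path) -> CodeList:
    """Read a code-list CSV with columns ``code,description,group``.

    Codes are normalized and deduplicated; subtype labels are canonicalized.
    Malformed codes or unknown groups raise :class:`CodeListError` naming the
    offending row.  An empty file (header only) yields an empty list with a
    warning.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"code", "description", "group"} - set(df.columns)
    if missing:
        raise CodeListError(f"code list {path} missing columns: {sorted(missing)}")
    clist = CodeList()
    for i, row in df.iterrows():
        try:
            code = normalize_code(row["code"])
        except InvalidCodeError as exc:
            raise CodeListError(f"row {i + 2} of {path}: {exc}") from exc
        try:
            subtype = canonical_subtype(row["group"])
        except CodeListError as exc:
            raise CodeListError(f"row {i + 2} of {path}: {exc}") from exc
        desc = "" if pd.isna(row["description"]) else str(row["description"])
        try:
            clist.add(CodeListEntry(code, desc, subtype))
        except CodeListError as exc:
            raise CodeListError(f"row {i + 2} of {path}: {exc}") from exc
    if len(clist) == 0:
        logger.warning("code list %s is empty (header only)", path)
    return clist


@dataclass(frozen=True)
class DiagnosisRecord:
    """One inpatient episode's diagnoses for one child.

    ``episode_day`` is days since the child's birth; ``codes`` holds the raw
    primary + secondary ICD-10 strings (1-20 positions).
    """

    child_id: str
    episode_day: int
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.episode_day < 0:
            raise ValueError(f"episode day {self.episode_day} < 0")
        if not 1 <= len(self.codes) <= 20:
            raise ValueError(
                f"episode carries {len(self.codes)} codes; 1-20 allowed"
            )


@dataclass(frozen=True)
class ChcEvent:
    child_id: str
    subtype: str  # a SUBTYPES member or ANY
    age_days: int  # minimum matching episode day
    code: str  # matched (normalized) code at that age


def extract_events(
    records: Iterable[DiagnosisRecord], code_list: CodeList
) -> list[ChcEvent]:
    """First-instance CHC events (per subtype and "any") from episode records.

    Order-invariant: the input stream may be unsorted.  Diagnosis position is
    ignored; non-matching and unparseable codes are skipped.  One episode with
    several matching codes can yield several subtype events on the same day.
    """
    # (child, subtype) -> (age_days, code)
    firsts: dict[tuple[str, str], tuple[int, str]] = {}
    for rec in records:
        for raw in rec.codes:
            try:
                code = normalize_code(raw)
            except InvalidCodeError:
                continue
            subtype = code_list.match(code)
            if subtype is None:
                continue
            # ties on the same day resolved to the lexicographically smallest
            # code so the result is independent of input order
            for key in ((rec.child_id, subtype), (rec.child_id, ANY)):
                prev = firsts.get(key)
                if prev is None or (rec.episode_day, code) < prev:
                    firsts[key] = (rec.episode_day, code)
    return [
        ChcEvent(child, subtype, day, code)
        for (child, subtype), (day, code) in sorted(firsts.items())
    ]


def extract_events_frame(episodes: pd.DataFrame, code_list: CodeList) -> pd.DataFrame:
    """Vectorized ascertainment over an episode table.

    ``episodes`` needs ``child_id``, ``age_days`` and diagnosis columns
    ``diag_01`` ... ``diag_20`` (missing/blank positions allowed beyond the
    first).  Returns a tidy frame with one row per first-instance event:
    ``child_id, subtype, age_days, code`` — including a ``subtype == "any"``
    row per affected child.
    """
    diag_cols = [c for c in episodes.columns if c.startswith("diag_")]
    long = episodes.melt(
        id_vars=["child_id", "age_days"],
        value_vars=diag_cols,
        value_name="raw",
    ).dropna(subset=["raw"])
    long = long[long["raw"].astype(str).str.strip() != ""]
    if long.empty:
        return pd.DataFrame(columns=["child_id", "subtype", "age_days", "code"])
    norm = (
        long["raw"].astype(str).str.strip().str.upper().str.replace(".", "", regex=False).str[:4]
    )
    valid = norm.str.match(_CODE_RE.pattern)
    long = long.assign(code=norm)[valid.values]

    exact = {c: e.subtype for c, e in code_list.entries.items()}
    prefix = {c: e.subtype for c, e in code_list.entries.items() if len(c) == 3}
    subtype = long["code"].map(exact)
    is4 = long["code"].str.len() == 4
    fallback = long["code"].str[:3].map(prefix)
    subtype = subtype.where(subtype.notna() | ~is4, fallback)
    long = long.assign(subtype=subtype).dropna(subset=["subtype"])
    if long.empty:
        return pd.DataFrame(columns=["child_id", "subtype", "age_days", "code"])

    long = long.sort_values(["age_days", "code"], kind="stable")
    per_subtype = long.groupby(["child_id", "subtype"], as_index=False).first()
    any_rows = (
        long.groupby("child_id", as_index=False)
        .first()
        .assign(subtype=ANY)
    )
    out = pd.concat([per_subtype, any_rows], ignore_index=True)
    out["age_days"] = out["age_days"].astype(int)
    return out[["child_id", "subtype", "age_days", "code"]].sort_values(
        ["child_id", "subtype"], ignore_index=True
    )
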