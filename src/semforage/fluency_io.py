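"""Reading and writing fluency datasets and category dictionaries.

The canonical on-disk format for fluency data is a long, comma-delimited,
UTF-8 table with one produced response per row and columns
``participant,trial,position,item,rt_ms``.  ``rt_ms`` is the *inter-item*
latency in milliseconds (for the first response of a trial it is the latency
from trial start).  A :class:`Dialect` maps differently named columns onto
this schema so exports from other acquisition software can be read directly.

Category dictionaries ("lexicons") are two-column CSVs ``category,member``;
an item may appear under several categories (e.g. *dog* under both *Pets*
and *Canine*) and memberships are unioned.
"""

from __future__ import annotations

import dataclasses
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .coding import normalize_item

__all__ = [
    "Response",
    "FluencyList",
    "Lexicon",
    "Dialect",
    "ReadReport",
    "FormatError",
    "read_fluency_table",
    "fluency_lists_from_frame",
    "read_lexicon",
    "lexicon_from_pairs",
    "cumulative_to_interitem",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass(frozen=True)
class Response:
    """One produced word with its inter-item latency.

    ``rt_ms`` may be NaN when the source row lacked a usable response time;
    such responses are retained here and dealt with by the exclusion rules.
    """

    participant_id: str
    trial_index: int
    position: int
    item_raw: str
    item_norm: str
    rt_ms: float

    def has_rt(self) -> bool:
        return not math.isnan(self.rt_ms)


@dataclass
class FluencyList:
    """The ordered responses of one participant on one trial."""

    participant_id: str
    trial_index: int
    responses: list[Response]

    def __post_init__(self) -> None:
        for r in self.responses:
            if r.participant_id != self.participant_id or r.trial_index != self.trial_index:
                raise ValueError("all responses must share participant_id and trial_index")
        self.responses.sort(key=lambda r: r.position)

    def __len__(self) -> int:
        return len(self.responses)


@dataclass
class Lexicon:
    """Mapping from normalized item to its (non-empty) set of category labels."""

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for item, cats in self.entries.items():
            if not cats or any(not c for c in cats):
                raise ValueError(f"item {item!r} must have >=1 non-empty category")

    @property
    def n_categories(self) -> int:
        cats: set[str] = set()
        for c in self.entries.values():
            cats |= c
        return len(cats)

    def categories_of(self, item_norm: str) -> frozenset[str]:
        """Categories of an item; empty set for unknown items (intrusions)."""
        return self.entries.get(item_norm, frozenset())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping onto the canonical fluency schema.

    ``position`` is optional in the source file: when absent, row order
    within each (participant, trial) group defines it.
    """

    participant: str = "participant"
    trial: str = "trial"
    item: str = "item"
    rt: str = "rt_ms"
    position: str | None = "position"


@dataclass
class ReadReport:
    """Accounting attached to every read: nothing is dropped silently."""

    rows_read: int = 0
    responses_stored: int = 0
    rows_rejected: int = 0
    lists_formed: int = 0
    missing_rt_rows: int = 0
    row_errors: list[str] = field(default_factory=list)


def read_fluency_table(
    path: str | Path, dialect: Dialect | Mapping[str, str] | None = None
) -> tuple[dict[str, list[FluencyList]], ReadReport]:
    """Read a long-format fluency CSV into FluencyLists grouped by participant.

    Returns ``(lists_by_participant, report)``.  Rows whose response time is
    missing are retained with ``rt_ms = NaN`` (the preprocessing rules decide
    their fate); rows whose rt is present but non-numeric are rejected and
    recorded in the report.
    """
    if dialect is None:
        dialect = Dialect()
    elif isinstance(dialect, Mapping):
        dialect = Dialect(**dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    required = {"participant": dialect.participant, "trial": dialect.trial,
                "item": dialect.item, "rt": dialect.rt}
    for role, col in required.items():
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} (role: {role})")
    report = ReadReport(rows_read=len(df))

    rt_raw = df[dialect.rt]
    rt = pd.to_numeric(rt_raw, errors="coerce")
    bad = rt.isna() & rt_raw.notna()
    for idx in df.index[bad]:
        report.row_errors.append(
            f"row {idx}: non-numeric rt {rt_raw.loc[idx]!r}"
        )
    keep = ~bad
    report.rows_rejected = int(bad.sum())
    report.missing_rt_rows = int((rt.isna() & ~bad).sum())

    work = pd.DataFrame(
        {
            "participant": df[dialect.participant][keep].astype(str),
            "trial": pd.to_numeric(df[dialect.trial][keep]).astype(int),
            "item": df[dialect.item][keep].fillna("").astype(str),
            "rt_ms": rt[keep].astype(float),
        }
    )
    if dialect.position is not None and dialect.position in df.columns:
        work["position"] = pd.to_numeric(df[dialect.position][keep]).astype(int)
    else:
        work["position"] = work.groupby(["participant", "trial"]).cumcount() + 1

    lists = fluency_lists_from_frame(work)
    report.lists_formed = sum(len(v) for v in lists.values())
    report.responses_stored = sum(len(fl) for v in lists.values() for fl in v)
    return lists, report


def fluency_lists_from_frame(frame: pd.DataFrame) -> dict[str, list[FluencyList]]:
    """Build the in-memory data model from a canonical long-format frame.

    Expects columns ``participant, trial, position, item, rt_ms``.
    """
    out: dict[str, list[FluencyList]] = {}
    for (pid, trial), grp in frame.groupby(["participant", "trial"], sort=True):
        grp = grp.sort_values("position")
        responses = [
            Response(
                participant_id=str(pid),
                trial_index=int(trial),
                position=int(row.position),
                item_raw=str(row.item),
                item_norm=normalize_item(str(row.item)),
                rt_ms=float(row.rt_ms),
            )
            for row in grp.itertuples()
        ]
        out.setdefault(str(pid), []).append(
            FluencyList(str(pid), int(trial), responses)
        )
    for pid in out:
        out[pid].sort(key=lambda fl: fl.trial_index)
    return out


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a ``category,member`` CSV into a :class:`Lexicon`.

    Members are normalized exactly like fluency responses; multi-category
    membership is unioned across rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("category", "member"):
        if col not in df.columns:
            raise FormatError(f"lexicon file must have a {col!r} column")
    if len(df) == 0:
        raise FormatError("lexicon file contains no entries")
    return lexicon_from_pairs(zip(df["category"], df["member"]))


def lexicon_from_pairs(pairs: Iterable[tuple[str, str]]) -> Lexicon:
    entries: dict[str, set[str]] = {}
    for category, member in pairs:
        category = str(category).strip()
        if not category:
            raise FormatError(f"member {member!r} has an empty category label")
        norm = normalize_item(str(member))
        if not norm:
            raise FormatError(f"category {category!r} has an empty member")
        entries.setdefault(norm, set()).add(category)
    return Lexicon({k: frozenset(v) for k, v in entries.items()})


def cumulative_to_interitem(frame: pd.DataFrame, time_col: str = "rt_ms") -> pd.DataFrame:
    """Convert cumulative within-trial timestamps to inter-item latencies.

    The first response of each (participant, trial) keeps its timestamp as
    the latency from trial start; later responses get successive differences.
    """
    out = frame.sort_values(["participant", "trial", "position"]).copy()
    diffed = out.groupby(["participant", "trial"])[time_col].diff()
    out[time_col] = diffed.fillna(out[time_col])
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    float_format: str = "%.6f",
) -> list[Path]:
    """Write result tables as CSVs plus a run-metadata YAML.

    Column order is whatever the table defines (deterministic); floats are
    written with fixed precision so repeated runs produce byte-identical
    files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, float_format=float_format)
        written.append(p)
    meta = {
        "config": _plain(config) if config is not None else None,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": sorted(t for t in tables),
    }
    meta_path = out_dir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(meta_path)
    return written


def _plain(obj):
    """Recursively convert dataclasses/paths/numpy scalars to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
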