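"""Event-table and FASTA I/O plus the read-length filter.

The canonical exchange format is a tab-separated event table with one row per
re-squiggled signal event, i.e. per (read, reference position) pair.  Columns
(exactly, in order)::

    read_id  ref_name  ref_pos  ref_base  ev_mean  ev_median  ev_sd  dwell

``ev_mean``/``ev_median`` are normalized current levels (z-score-like scale),
``ev_sd`` is the within-event current standard deviation, and ``dwell`` is the
event length in raw-signal samples.  Coordinates are 0-based on the reference
transcript; direct RNA is single-stranded so only the template strand exists,
and U is written as T throughout (basecaller convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateEventError,
    EventTableFormatError,
    EventTableParseError,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "read_id",
    "ref_name",
    "ref_pos",
    "ref_base",
    "ev_mean",
    "ev_median",
    "ev_sd",
    "dwell",
]

_BASES = frozenset("ACGT")
_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class EventRecord:
    """One signal event aligned to one reference position of one read."""

    read_id: str
    ref_name: str
    ref_pos: int
    ref_base: str
    ev_mean: float
    ev_median: float
    ev_sd: float
    dwell: int

    def __post_init__(self):
        if self.ref_pos < 0:
            raise ValueError(f"ref_pos must be >= 0, got {self.ref_pos}")
        if self.ref_base not in _BASES:
            raise ValueError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        if self.ev_sd < 0:
            raise ValueError(f"ev_sd must be >= 0, got {self.ev_sd}")
        if self.dwell < 1:
            raise ValueError(f"dwell must be >= 1, got {self.dwell}")


@dataclass
class ReadEvents:
    """All events of one read on one reference, sorted by position.

    Positions are strictly increasing but may have gaps (reference positions
    the re-squiggle skipped).  ``sample_label`` records the sample of origin
    when known: 1 = modified (100% 5moU pool), 0 = unmodified, None = unknown.
    """

    read_id: str
    ref_name: str
    events: list[EventRecord] = field(default_factory=list)
    sample_label: int | None = None

    def __post_init__(self):
        for ev in self.events:
            if ev.read_id != self.read_id or ev.ref_name != self.ref_name:
                raise ValueError(
                    f"event ({ev.read_id}, {ev.ref_name}) does not belong to "
                    f"read ({self.read_id}, {self.ref_name})"
                )
        positions = [ev.ref_pos for ev in self.events]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"event positions of read {self.read_id} not strictly increasing")

    @property
    def aligned_length(self) -> int:
        """Reference span covered by the read: max ref_pos - min ref_pos + 1."""
        if not self.events:
            return 0
        return self.events[-1].ref_pos - self.events[0].ref_pos + 1

    def __len__(self) -> int:
        return len(self.events)


def read_event_table(path: str | Path) -> list[ReadEvents]:
    """Parse a canonical event TSV into one :class:`ReadEvents` per read.

    The whole file is validated before anything is returned: a malformed
    header, a non-numeric signal field, a dwell below 1 or a duplicated
    (read_id, ref_pos) rejects the file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in EVENT_COLUMNS]
        raise EventTableFormatError(
            f"{path}: bad event-table header; missing columns {missing}, "
            f"unexpected columns {extra}, expected exactly {EVENT_COLUMNS}"
        )
    if df.empty:
        return []

    # header is line 1, first data row line 2
    def _numeric(col: str, as_int: bool) -> pd.Series:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() | (raw.str.strip() == "")
        if as_int:
            bad |= ~out.isna() & (out != out.round())
        if bad.any():
            i = int(bad.idxmax())
            raise EventTableParseError(
                f"column {col!r}: cannot parse value {raw.iloc[i]!r}", line=i + 2
            )
        return out.astype(int) if as_int else out.astype(float)

    parsed = pd.DataFrame(
        {
            "read_id": df["read_id"],
            "ref_name": df["ref_name"],
            "ref_pos": _numeric("ref_pos", as_int=True),
            "ref_base": df["ref_base"],
            "ev_mean": _numeric("ev_mean", as_int=False),
            "ev_median": _numeric("ev_median", as_int=False),
            "ev_sd": _numeric("ev_sd", as_int=False),
            "dwell": _numeric("dwell", as_int=True),
        }
    )

    for col, ok in [
        ("ref_pos", parsed["ref_pos"] >= 0),
        ("ref_base", parsed["ref_base"].isin(list(_BASES))),
        ("ev_sd", parsed["ev_sd"] >= 0),
        ("dwell", parsed["dwell"] >= 1),
    ]:
        bad = ~ok
        if bad.any():
            i = int(bad.idxmax())
            raise EventTableParseError(
                f"column {col!r}: invalid value {df[col].iloc[i]!r}", line=i + 2
            )

    dup = parsed.duplicated(subset=["read_id", "ref_name", "ref_pos"])
    if dup.any():
        i = int(dup.idxmax())
        raise DuplicateEventError(
            f"{path}: duplicate event for read {parsed['read_id'].iloc[i]!r} at "
            f"ref_pos {parsed['ref_pos'].iloc[i]} (line {i + 2})"
        )

    parsed = parsed.sort_values(["read_id", "ref_name", "ref_pos"], kind="mergesort")
    reads: list[ReadEvents] = []
    for (read_id, ref_name), grp in parsed.groupby(["read_id", "ref_name"], sort=True):
        events = [
            EventRecord(
                read_id=read_id,
                ref_name=ref_name,
                ref_pos=int(r.ref_pos),
                ref_base=r.ref_base,
                ev_mean=float(r.ev_mean),
                ev_median=float(r.ev_median),
                ev_sd=float(r.ev_sd),
                dwell=int(r.dwell),
            )
            for r in grp.itertuples(index=False)
        ]
        reads.append(ReadEvents(read_id=read_id, ref_name=ref_name, events=events))
    logger.debug("read %d reads (%d events) from %s", len(reads), len(parsed), path)
    return reads


def write_event_table(reads: list[ReadEvents], path: str | Path) -> Path:
    """Write reads to the canonical TSV: sorted by (read_id, ref_pos), fixed float format.

    The format is canonical in the round-trip sense: write -> read -> write is
    byte-identical.
    """
    path = Path(path)
    lines = ["\t".join(EVENT_COLUMNS)]
    for read in sorted(reads, key=lambda r: (r.read_id, r.ref_name)):
        for ev in read.events:
            lines.append(
                "\t".join(
                    (
                        ev.read_id,
                        ev.ref_name,
                        str(ev.ref_pos),
                        ev.ref_base,
                        _FLOAT_FMT % ev.ev_mean,
                        _FLOAT_FMT % ev.ev_median,
                        _FLOAT_FMT % ev.ev_sd,
                        str(ev.dwell),
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def filter_reads(reads: list[ReadEvents], min_len: int = 200) -> list[ReadEvents]:
    """Keep reads whose aligned reference span is at least ``min_len`` bases.

    The threshold is inclusive: a read spanning exactly ``min_len`` positions
    is retained.  Input order is preserved; the number of removed reads is
    logged.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    kept = [r for r in reads if r.aligned_length >= min_len]
    logger.info(
        "length filter (min_len=%d): kept %d / %d reads, removed %d",
        min_len,
        len(kept),
        len(reads),
        len(reads) - len(kept),
    )
    return kept


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load reference transcript sequences as an id -> uppercase-string map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path
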