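"""NNUNN window identification and the per-5-mer feature matrix.

Every reference position carrying a T (U in RNA space) with two flanking
positions on each side defines an NNUNN window.  For a read whose re-squiggle
covers all five positions of a window, the four per-position signal summaries
are collected into a 20-column feature row, ordered::

    mean_1..mean_5  mdintense_1..mdintense_5  sd_1..sd_5  L_1..L_5

(mean / median / standard deviation of the normalized current, and dwell time
in raw samples; position 3 is the central U).  Rows are grouped by reference
5-mer because modification models are trained strictly per 5-mer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, LabellingError, UsageError
from .io_events import ReadEvents

logger = logging.getLogger(__name__)

_STATS = ("mean", "mdintense", "sd", "L")
FEATURE_NAMES: list[str] = [f"{stat}_{i}" for stat in _STATS for i in range(1, 6)]

#: Columns retained by each feature-selection scheme.  ``all`` keeps the full
#: 20-column matrix; ``mid`` the four statistics of the central position;
#: ``midn`` the centre and its immediate neighbours (positions 2-4, 12 columns).
SCHEME_COLUMNS: dict[str, list[str]] = {
    "all": list(FEATURE_NAMES),
    "mid": [f"{stat}_3" for stat in _STATS],
    "midn": [f"{stat}_{i}" for stat in _STATS for i in (2, 3, 4)],
}

META_COLUMNS = ["read_id", "ref_name", "center_pos", "kmer"]


@dataclass(frozen=True)
class FeatureVector:
    """The 20-column signal-feature row for one NNUNN window of one read."""

    read_id: str
    ref_name: str
    center_pos: int
    kmer: str
    features: np.ndarray
    label: int | None = None

    def __post_init__(self):
        if len(self.kmer) != 5 or self.kmer[2] != "T":
            raise ValueError(f"kmer must be a 5-mer with central T, got {self.kmer!r}")
        feats = np.asarray(self.features, dtype=float)
        if feats.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got shape {feats.shape}")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "features", feats)


@dataclass
class KmerDataset:
    """All labelled feature rows sharing one reference 5-mer.

    ``X`` holds one column per feature (a subset of :data:`FEATURE_NAMES`),
    ``y`` the 0/1 labels (or -1 where unknown), ``meta`` the provenance
    columns of :data:`META_COLUMNS`.
    """

    kmer: str
    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.X.index, columns=META_COLUMNS)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == 0))

    def __len__(self) -> int:
        return len(self.y)


def extract_windows(read: ReadEvents, reference: str) -> list[FeatureVector]:
    """Extract every complete NNUNN feature row a read supports.

    A window is emitted for each reference position ``p`` with
    ``reference[p] == 'T'``, ``2 <= p <= len(reference) - 3``, whose five
    positions ``p-2 .. p+2`` all have an event in the read (windows with any
    gap are dropped: incomplete signal context is unverifiable).  The 5-mer
    identity is read from the reference, not from basecalls.
    """
    reference = reference.upper()
    if read.events and read.events[-1].ref_pos >= len(reference):
        raise CoordinateError(
            f"read {read.read_id}: event at ref_pos {read.events[-1].ref_pos} but "
            f"reference is only {len(reference)} bases"
        )
    by_pos = {ev.ref_pos: ev for ev in read.events}
    out: list[FeatureVector] = []
    for p in sorted(by_pos):
        if reference[p] != "T" or p < 2 or p > len(reference) - 3:
            continue
        window = [by_pos.get(q) for q in range(p - 2, p + 3)]
        if any(ev is None for ev in window):
            continue
        feats = np.array(
            [ev.ev_mean for ev in window]
            + [ev.ev_median for ev in window]
            + [ev.ev_sd for ev in window]
            + [float(ev.dwell) for ev in window]
        )
        out.append(
            FeatureVector(
                read_id=read.read_id,
                ref_name=read.ref_name,
                center_pos=p,
                kmer=reference[p - 2 : p + 3],
                features=feats,
                label=read.sample_label,
            )
        )
    return out


def extract_all_windows(reads, references: dict[str, str]) -> list[FeatureVector]:
    """Run :func:`extract_windows` over a read collection against its references."""
    out = []
    for read in reads:
        if read.ref_name not in references:
            raise CoordinateError(f"no reference sequence named {read.ref_name!r}")
        out.extend(extract_windows(read, references[read.ref_name]))
    return out


def build_kmer_datasets(windows: list[FeatureVector]) -> dict[str, KmerDataset]:
    """Partition labelled windows into one :class:`KmerDataset` per expressed 5-mer."""
    unlabelled = sum(1 for w in windows if w.label is None)
    if unlabelled:
        raise LabellingError(
            f"{unlabelled} of {len(windows)} windows have no modified/unmodified label"
        )
    frame = windows_to_frame(windows)
    datasets: dict[str, KmerDataset] = {}
    for kmer, grp in frame.groupby("kmer", sort=True):
        grp = grp.reset_index(drop=True)
        datasets[kmer] = KmerDataset(
            kmer=kmer,
            X=grp[FEATURE_NAMES].copy(),
            y=grp["label"].to_numpy(dtype=int),
            meta=grp[META_COLUMNS].copy(),
        )
    logger.info(
        "built %d k-mer datasets from %d windows: %s",
        len(datasets),
        len(windows),
        {k: len(d) for k, d in sorted(datasets.items())},
    )
    return datasets


def feature_subset(dataset: KmerDataset, scheme: str) -> KmerDataset:
    """Reduce a dataset to the columns of a feature-selection scheme.

    ``all`` is the identity (20 columns); ``mid`` keeps the central position
    only (4 columns); ``midn`` the centre and one neighbour on each side
    (12 columns).
    """
    if scheme not in SCHEME_COLUMNS:
        raise UsageError(f"unknown feature scheme {scheme!r}; choose from {sorted(SCHEME_COLUMNS)}")
    if scheme == "midn":
        logger.debug("scheme 'midn' keeps 12 columns (4 statistics x positions 2-4)")
    cols = [c for c in SCHEME_COLUMNS[scheme] if c in dataset.X.columns]
    if cols != SCHEME_COLUMNS[scheme]:
        missing = sorted(set(SCHEME_COLUMNS[scheme]) - set(dataset.X.columns))
        raise UsageError(f"dataset for {dataset.kmer} lacks columns {missing} for scheme {scheme!r}")
    return KmerDataset(kmer=dataset.kmer, X=dataset.X[cols].copy(), y=dataset.y.copy(), meta=dataset.meta.copy())


def windows_to_frame(windows: list[FeatureVector]) -> pd.DataFrame:
    """Flatten windows to a DataFrame: meta columns, 20 features, label (-1 = unknown)."""
    rows = []
    for w in windows:
        row = {
            "read_id": w.read_id,
            "ref_name": w.ref_name,
            "center_pos": w.center_pos,
            "kmer": w.kmer,
        }
        row.update(zip(FEATURE_NAMES, w.features))
        row["label"] = -1 if w.label is None else int(w.label)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES + ["label"])


def frame_to_windows(frame: pd.DataFrame) -> list[FeatureVector]:
    out = []
    for r in frame.itertuples(index=False):
        d = r._asdict()
        label = int(d["label"])
        out.append(
            FeatureVector(
                read_id=str(d["read_id"]),
                ref_name=str(d["ref_name"]),
                center_pos=int(d["center_pos"]),
                kmer=str(d["kmer"]),
                features=np.array([d[c] for c in FEATURE_NAMES], dtype=float),
                label=None if label == -1 else label,
            )
        )
    return out


def write_feature_table(windows: list[FeatureVector], path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_feature_table(path) -> list[FeatureVector]:
    return frame_to_windows(pd.read_csv(path, sep="\t"))
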