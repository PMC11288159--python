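"""Read-level modification profiling and stoichiometry estimation.

Trained per-5-mer models are applied along reads to produce one modification
probability per (read, NNUNN site).  Windows whose 5-mer has no trained model
are counted and skipped — models are strictly per-5-mer, so there is no
pooled fallback.  Sample-level stoichiometry (the modified fraction) is the
fraction of window probabilities at or above a threshold; the mean probability
is reported as a secondary estimator.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimateError, SamplingError, UsageError
from .features import extract_windows
from .io_events import ReadEvents
from .metrics import MetricsReport, evaluate_scores
from .models import TrainedKmerModel, predict_proba

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadSiteProbability:
    """Modification probability for one NNUNN site of one read."""

    read_id: str
    ref_name: str
    center_pos: int
    kmer: str
    probability: float
    model_algorithm: str
    label: int | None = None  # ground truth where known (simulated / curated data)


@dataclass
class Profile:
    """Output of :func:`profile_reads`: scored sites plus skip accounting."""

    records: list[ReadSiteProbability]
    skipped_kmers: Counter = field(default_factory=Counter)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped_kmers.values())

    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.__dict__ for r in self.records],
            columns=["read_id", "ref_name", "center_pos", "kmer", "probability",
                     "model_algorithm", "label"],
        )


def profile_reads(
    models: dict[str, TrainedKmerModel],
    reads: list[ReadEvents],
    reference: str | dict[str, str],
) -> Profile:
    """Score every modelled NNUNN window of every read.

    All models must share one algorithm and one feature scheme (mixing
    calibrations would make probabilities incomparable across sites).
    """
    if not models:
        raise UsageError("profile_reads needs at least one trained model")
    algorithms = {m.algorithm for m in models.values()}
    schemes = {m.scheme for m in models.values()}
    if len(algorithms) > 1 or len(schemes) > 1:
        raise UsageError(
            f"models must share one algorithm and scheme, got {algorithms} x {schemes}"
        )
    algorithm = algorithms.pop()
    refs = reference if isinstance(reference, dict) else None

    windows = []
    for read in reads:
        ref = refs[read.ref_name] if refs is not None else reference
        windows.extend(extract_windows(read, ref))

    skipped: Counter = Counter()
    by_kmer: dict[str, list] = {}
    for w in windows:
        if w.kmer in models:
            by_kmer.setdefault(w.kmer, []).append(w)
        else:
            skipped[w.kmer] += 1

    records = []
    for kmer in sorted(by_kmer):
        ws = by_kmer[kmer]
        proba = predict_proba(models[kmer], ws)
        for w, p in zip(ws, proba):
            records.append(
                ReadSiteProbability(
                    read_id=w.read_id,
                    ref_name=w.ref_name,
                    center_pos=w.center_pos,
                    kmer=w.kmer,
                    probability=float(p),
                    model_algorithm=algorithm,
                    label=w.label,
                )
            )
    records.sort(key=lambda r: (r.read_id, r.center_pos))
    if skipped:
        logger.info("profiling skipped %d windows over unmodelled k-mers: %s",
                    sum(skipped.values()), dict(skipped))
    return Profile(records=records, skipped_kmers=skipped)


@dataclass(frozen=True)
class RatioEstimate:
    """Sample-level modified fraction, with the mean-probability secondary estimator."""

    fraction: float         # fraction of windows with probability >= threshold
    mean_probability: float
    threshold: float
    n: int


def estimate_ratio(profile, threshold: float = 0.5) -> RatioEstimate:
    """Estimate the modified fraction from a profile (or a bare probability array)."""
    if isinstance(profile, Profile):
        proba = profile.probabilities()
    else:
        proba = np.asarray(profile, dtype=float)
    if proba.size == 0:
        raise EstimateError("cannot estimate a modification ratio from an empty profile")
    return RatioEstimate(
        fraction=float(np.mean(proba >= threshold)),
        mean_probability=float(np.mean(proba)),
        threshold=threshold,
        n=int(proba.size),
    )


def curate_mixture(
    modified: list[ReadEvents],
    unmodified: list[ReadEvents],
    ratio: tuple[int, int],
    n: int,
    seed: int = 0,
) -> list[ReadEvents]:
    """Sample a labelled mixture with an exact modified:unmodified composition.

    ``round(n * a / (a + b))`` modified reads (ties rounded half away from
    zero) and the remainder unmodified, drawn without replacement,
    deterministic given ``seed``.  Ground-truth ``sample_label`` is set on
    every returned read.
    """
    a, b = ratio
    if a < 0 or b < 0 or a + b == 0:
        raise UsageError(f"invalid ratio {ratio}")
    if n < 1:
        raise UsageError("mixture size must be >= 1")
    n_mod = int(np.floor(n * a / (a + b) + 0.5))  # round half away from zero (counts >= 0)
    n_unmod = n - n_mod
    if n_mod > len(modified):
        raise SamplingError(
            f"modified pool has {len(modified)} reads, {n_mod} requested"
        )
    if n_unmod > len(unmodified):
        raise SamplingError(
            f"unmodified pool has {len(unmodified)} reads, {n_unmod} requested"
        )
    rng = np.random.default_rng(seed)
    pick_mod = rng.choice(len(modified), size=n_mod, replace=False)
    pick_unmod = rng.choice(len(unmodified), size=n_unmod, replace=False)
    out = []
    for i in sorted(pick_mod):
        r = modified[i]
        out.append(ReadEvents(r.read_id, r.ref_name, r.events, sample_label=1))
    for i in sorted(pick_unmod):
        r = unmodified[i]
        out.append(ReadEvents(r.read_id, r.ref_name, r.events, sample_label=0))
    ids = [r.read_id for r in out]
    if len(set(ids)) != len(ids):
        raise SamplingError("modified and unmodified pools share read_ids; disambiguate first")
    return out


@dataclass(frozen=True)
class MixtureEvaluation:
    """Read-level classification metrics plus the stoichiometry estimate for one mixture."""

    ratio: tuple[int, int]
    true_fraction: float
    estimate: RatioEstimate
    metrics: MetricsReport
    n_windows: int
    n_skipped: int


def evaluate_mixture(
    models: dict[str, TrainedKmerModel],
    mixture: list[ReadEvents],
    reference: str | dict[str, str],
    ratio: tuple[int, int] | None = None,
    threshold: float = 0.5,
    aggregate: str = "window",
) -> MixtureEvaluation:
    """Profile a labelled mixture and score it against its ground truth.

    ``aggregate='window'`` treats each scored window as an instance (the
    read-level framing used throughout); ``aggregate='read'`` averages window
    probabilities per read first.
    """
    if aggregate not in ("window", "read"):
        raise UsageError(f"aggregate must be 'window' or 'read', got {aggregate!r}")
    labels = [r.sample_label for r in mixture]
    if any(lab is None for lab in labels):
        raise UsageError("mixture reads must carry ground-truth sample labels")
    true_fraction = float(np.mean([lab == 1 for lab in labels]))

    profile = profile_reads(models, mixture, reference)
    frame = profile.to_frame()
    if frame.empty:
        raise EstimateError("no modelled windows in the mixture")
    if aggregate == "read":
        frame = (
            frame.groupby("read_id", as_index=False)
            .agg(probability=("probability", "mean"), label=("label", "first"))
        )
    metrics = MetricsReport.single(
        evaluate_scores(frame["label"].to_numpy(int), frame["probability"].to_numpy(float),
                        threshold=threshold)
    )
    est = estimate_ratio(frame["probability"].to_numpy(float), threshold=threshold)
    return MixtureEvaluation(
        ratio=ratio if ratio is not None else (-1, -1),
        true_fraction=true_fraction,
        estimate=est,
        metrics=metrics,
        n_windows=len(frame),
        n_skipped=profile.n_skipped,
    )
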