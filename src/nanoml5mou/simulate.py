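"""Synthetic nanopore event-table generator.

Emulates the statistical structure the pipeline assumes about re-squiggled
direct-RNA data: each 5-mer occupying the pore has a characteristic current
level, events scatter around that level, dwell times are roughly log-normal,
and a 5moU at the central position perturbs mean/median/sd/dwell not only at
the modified base but (attenuated) at its neighbours.

The generator does NOT simulate raw squiggles, basecalling error, alignment
error or re-squiggle mis-assignment: its events are clean summaries drawn
from the per-k-mer laws, so results on synthetic data bound what the
downstream models could do on ideal input, not what they do on real flowcell
output.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_events import EventRecord, ReadEvents, write_event_table, write_fasta

logger = logging.getLogger(__name__)

_BASES = "ACGT"
OFFSETS = (-2, -1, 0, 1, 2)


def all_nnunn_kmers() -> list[str]:
    """Enumerate the NNUNN pattern space: every 5-mer with a central T."""
    return [
        f"{a}{b}T{d}{e}"
        for a, b, d, e in itertools.product(_BASES, repeat=4)
    ]


@dataclass
class PoreModel:
    """Per-5-mer baseline current response, generated deterministically from a seed.

    Every one of the 1024 5-mers gets a baseline current mean ``mu`` (spread
    ``level_spread`` across k-mers, z-score-like scale), an event-to-event
    noise sd ``sigma``, and a within-event current-sd level.  Dwell times are
    log-normal with ``dwell_log_mean``/``dwell_log_sd`` (raw samples).
    """

    seed: int = 0
    level_spread: float = 1.0
    sigma_range: tuple[float, float] = (0.25, 0.45)
    sd_level_range: tuple[float, float] = (0.15, 0.35)
    dwell_log_mean: float = 2.2
    dwell_log_sd: float = 0.5
    median_jitter: float = 0.15  # sd of (median - mean), in units of sigma

    _mu: np.ndarray = field(init=False, repr=False)
    _sigma: np.ndarray = field(init=False, repr=False)
    _sd_level: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.sigma_range[0] <= 0 or self.sd_level_range[0] <= 0:
            raise ValueError("sigma and sd-level ranges must be positive")
        if self.dwell_log_sd <= 0:
            raise ValueError("dwell_log_sd must be > 0")
        rng = np.random.default_rng(self.seed)
        n = 4**5
        self._mu = rng.normal(0.0, self.level_spread, n)
        self._sigma = rng.uniform(*self.sigma_range, n)
        self._sd_level = rng.uniform(*self.sd_level_range, n)

    @staticmethod
    def kmer_index(kmer: str) -> int:
        idx = 0
        for base in kmer:
            idx = idx * 4 + _BASES.index(base)
        return idx

    def level(self, kmer: str) -> tuple[float, float, float]:
        """(baseline mean, event noise sd, within-event sd level) for a 5-mer."""
        i = self.kmer_index(kmer)
        return float(self._mu[i]), float(self._sigma[i]), float(self._sd_level[i])


@dataclass(frozen=True)
class ModEffect:
    """Perturbation a central 5moU applies at window offsets -2..+2.

    ``delta_mean`` is additive in units of the local baseline sigma;
    ``sd_scale`` and ``dwell_scale`` are multiplicative.  Arrays are indexed
    by offset -2..+2.  Effects from nearby modified Us compose (deltas add,
    scales multiply).
    """

    delta_mean: tuple[float, ...] = (0.0,) * 5
    sd_scale: tuple[float, ...] = (1.0,) * 5
    dwell_scale: tuple[float, ...] = (1.0,) * 5

    def __post_init__(self):
        for name, arr in (("delta_mean", self.delta_mean), ("sd_scale", self.sd_scale),
                          ("dwell_scale", self.dwell_scale)):
            if len(arr) != 5:
                raise ValueError(f"{name} must give one value per offset -2..+2")
        if any(s < 0 for s in self.sd_scale):
            raise ValueError("sd_scale must be >= 0")
        if any(s <= 0 for s in self.dwell_scale):
            raise ValueError("dwell_scale must be > 0")

    @classmethod
    def null(cls) -> "ModEffect":
        """Zero effect: modified and unmodified reads are draws from the same law."""
        return cls()

    @classmethod
    def from_center(cls, delta_mean: float, sd_scale: float = 1.0,
                    dwell_scale: float = 1.0, neighbor_frac: float = 0.5) -> "ModEffect":
        """Central effect with attenuated neighbours (default: half strength)."""
        nd = neighbor_frac * delta_mean
        ns = 1.0 + neighbor_frac * (sd_scale - 1.0)
        nw = 1.0 + neighbor_frac * (dwell_scale - 1.0)
        return cls(
            delta_mean=(nd, nd, delta_mean, nd, nd),
            sd_scale=(ns, ns, sd_scale, ns, ns),
            dwell_scale=(nw, nw, dwell_scale, nw, nw),
        )

    @classmethod
    def strong(cls) -> "ModEffect":
        """A clearly detectable modification: 2-sigma centre shift, 1-sigma neighbours."""
        return cls.from_center(delta_mean=2.0, sd_scale=1.25, dwell_scale=1.5)

    @classmethod
    def weak(cls) -> "ModEffect":
        """A marginal modification signal: 0.5-sigma centre shift."""
        return cls.from_center(delta_mean=0.5, sd_scale=1.05, dwell_scale=1.1)


EFFECT_PRESETS = {"null": ModEffect.null, "weak": ModEffect.weak, "strong": ModEffect.strong}


def make_template(length: int, seed: int = 0, u_density: float = 0.25) -> str:
    """Random reference transcript with T at the requested density."""
    if length < 5:
        raise ValueError(f"template length must be >= 5, got {length}")
    if not 0.0 <= u_density <= 1.0:
        raise ValueError("u_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    other = (1.0 - u_density) / 3.0
    return "".join(rng.choice(list("ACGT"), size=length, p=[other, other, other, u_density]))


def _template_laws(pore: PoreModel, template: str, effect: ModEffect | None):
    """Per-position (mu, sigma, sd_level, delta, sd_scale, dwell_scale) arrays."""
    L = len(template)
    padded = "A" * 2 + template + "A" * 2
    mu = np.empty(L)
    sigma = np.empty(L)
    sd_level = np.empty(L)
    for q in range(L):
        mu[q], sigma[q], sd_level[q] = pore.level(padded[q : q + 5])
    delta = np.zeros(L)
    sd_scale = np.ones(L)
    dwell_scale = np.ones(L)
    if effect is not None:
        for p, base in enumerate(template):
            if base != "T":
                continue
            for k, off in enumerate(OFFSETS):
                q = p + off
                if 0 <= q < L:
                    delta[q] += effect.delta_mean[k]
                    sd_scale[q] *= effect.sd_scale[k]
                    dwell_scale[q] *= effect.dwell_scale[k]
    return mu, sigma, sd_level, delta, sd_scale, dwell_scale


def simulate_reads(
    pore: PoreModel,
    template: str,
    n_reads: int,
    modified: int,
    effect: ModEffect | None = None,
    read_len_law: tuple[int, int] | None = None,
    seed: int = 0,
    ref_name: str = "tpl",
    read_prefix: str | None = None,
) -> list[ReadEvents]:
    """Draw labelled reads over a template.

    Each covered position yields one event: mean ~ N(mu + delta*sigma, sigma),
    median = mean + N(0, median_jitter*sigma), sd = sd_level * sd_scale *
    lognormal jitter, dwell = round(lognormal * dwell_scale), floored at 1.
    Modified reads (``modified=1``) carry the :class:`ModEffect` at every
    window centred on a template T; unmodified reads never do.  ``read_len_law
    = (lo, hi)`` samples aligned spans uniformly with random start positions;
    the default is full-length reads (IVT transcripts).
    """
    if modified not in (0, 1):
        raise ValueError("modified must be 0 or 1")
    template = template.upper()
    if len(template) < 5:
        raise ValueError("template must be at least 5 bases")
    if effect is None:
        effect = ModEffect.null()
    rng = np.random.default_rng(seed)
    mu, sigma, sd_level, delta, sd_scale, dwell_scale = _template_laws(
        pore, template, effect if modified else None
    )
    L = len(template)
    prefix = read_prefix if read_prefix is not None else ("m1_" if modified else "m0_")
    reads = []
    for i in range(n_reads):
        if read_len_law is None:
            start, end = 0, L
        else:
            lo, hi = read_len_law
            span = int(rng.integers(min(lo, L), min(hi, L) + 1))
            start = int(rng.integers(0, L - span + 1))
            end = start + span
        idx = np.arange(start, end)
        m = mu[idx] + delta[idx] * sigma[idx]
        ev_mean = m + rng.normal(0.0, sigma[idx])
        ev_median = ev_mean + rng.normal(0.0, pore.median_jitter * sigma[idx])
        ev_sd = sd_level[idx] * sd_scale[idx] * np.exp(rng.normal(0.0, 0.25, idx.size))
        dwell = np.maximum(
            1,
            np.round(
                np.exp(rng.normal(pore.dwell_log_mean, pore.dwell_log_sd, idx.size))
                * dwell_scale[idx]
            ).astype(int),
        )
        read_id = f"{prefix}{i:05d}"
        events = [
            EventRecord(
                read_id=read_id,
                ref_name=ref_name,
                ref_pos=int(q),
                ref_base=template[q],
                ev_mean=float(ev_mean[j]),
                ev_median=float(ev_median[j]),
                ev_sd=float(ev_sd[j]),
                dwell=int(dwell[j]),
            )
            for j, q in enumerate(idx)
        ]
        reads.append(
            ReadEvents(read_id=read_id, ref_name=ref_name, events=events, sample_label=modified)
        )
    return reads


def simulate_kmer_dataset(kmer: str, n_per_class: int, effect: ModEffect,
                          seed: int = 0, pore: PoreModel | None = None):
    """Convenience: paired modified/unmodified reads over a single-window template.

    The template is the 5-mer itself, so every read contributes exactly one
    window of that k-mer.  Returns a labelled :class:`~nanoml5mou.features.KmerDataset`.
    """
    from .features import build_kmer_datasets, extract_windows

    if len(kmer) != 5 or kmer[2] != "T":
        raise ValueError(f"kmer must be NNUNN (central T), got {kmer!r}")
    pore = pore if pore is not None else PoreModel(seed=seed)
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    mod = simulate_reads(pore, kmer, n_per_class, modified=1, effect=effect, seed=int(ss[0]))
    unmod = simulate_reads(pore, kmer, n_per_class, modified=0, effect=effect, seed=int(ss[1]))
    windows = []
    for read in mod + unmod:
        windows.extend(extract_windows(read, kmer))
    return build_kmer_datasets(windows)[kmer]


BENCHMARK_PRESETS: dict[str, dict] = {
    # end-to-end fixture small enough for interactive use
    "smoke": {"template_length": 40, "n_reads": 60, "effect": "strong", "u_density": 0.25},
    "null": {"template_length": 40, "n_reads": 60, "effect": "null", "u_density": 0.25},
    "standard": {"template_length": 60, "n_reads": 200, "effect": "strong", "u_density": 0.25},
}


def make_benchmark(out_dir: str | Path, seed: int = 0, preset: str = "smoke",
                   template_length: int | None = None, n_reads: int | None = None,
                   effect: str | ModEffect | None = None, u_density: float | None = None) -> dict:
    """Write a paired modified/unmodified benchmark: event TSVs, FASTA, truth JSON."""
    if preset not in BENCHMARK_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(BENCHMARK_PRESETS)}")
    cfg = dict(BENCHMARK_PRESETS[preset])
    if template_length is not None:
        cfg["template_length"] = template_length
    if n_reads is not None:
        cfg["n_reads"] = n_reads
    if effect is not None:
        cfg["effect"] = effect
    if u_density is not None:
        cfg["u_density"] = u_density

    eff = cfg["effect"]
    effect_name = eff if isinstance(eff, str) else "custom"
    if isinstance(eff, str):
        eff = EFFECT_PRESETS[eff]()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    template = make_template(cfg["template_length"], seed=int(ss[0]), u_density=cfg["u_density"])
    pore = PoreModel(seed=int(ss[1]))
    mod = simulate_reads(pore, template, cfg["n_reads"], modified=1, effect=eff, seed=int(ss[2]))
    unmod = simulate_reads(pore, template, cfg["n_reads"], modified=0, effect=eff, seed=int(ss[3]))

    write_fasta({"tpl": template}, out_dir / "template.fa")
    write_event_table(mod, out_dir / "modified.tsv")
    write_event_table(unmod, out_dir / "unmodified.tsv")
    truth = {
        "preset": preset,
        "seed": seed,
        "effect": effect_name,
        "template_length": cfg["template_length"],
        "u_density": cfg["u_density"],
        "n_modified_reads": len(mod),
        "n_unmodified_reads": len(unmod),
        "files": {"template": "template.fa", "modified": "modified.tsv",
                  "unmodified": "unmodified.tsv"},
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    logger.info("benchmark %s written to %s", preset, out_dir)
    return truth
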