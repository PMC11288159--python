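"""End-to-end workflow: simulate -> filter -> extract -> compare -> train -> quantify.

A :class:`RunConfig` is validated up front; every source of randomness derives
from the single root seed, so two runs with the same config produce identical
outputs.  Each stage writes its artifacts under the run directory and the run
closes with a machine-readable ``manifest.json`` (no timestamps, by design:
manifests of identical runs are identical).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .features import SCHEME_COLUMNS, build_kmer_datasets, extract_all_windows, write_feature_table
from .io_events import filter_reads, read_fasta, write_event_table
from .models import ALGORITHMS, save_models, train_kmer_models
from .profiling import curate_mixture, evaluate_mixture
from .simulate import EFFECT_PRESETS, ModEffect, PoreModel, make_template, simulate_reads
from .stats import compare_features, results_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; validated before any stage executes."""

    out_dir: str
    seed: int = 0
    scheme: str = "all"
    algorithm: str = "gbt"
    min_len: int = 200
    min_per_class: int = 20
    threshold: float = 0.5
    ratios: list[tuple[int, int]] = field(
        default_factory=lambda: [(8, 2), (2, 8), (6, 4), (4, 6)]
    )
    effect: str = "strong"
    template_length: int = 60
    u_density: float = 0.25
    n_train_reads: int = 120
    n_validation_reads: int = 160
    mix_n_reads: int = 100

    def validate(self) -> None:
        if self.scheme not in SCHEME_COLUMNS:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        if self.effect not in EFFECT_PRESETS:
            raise ConfigError(f"unknown effect preset {self.effect!r}")
        if self.min_len < 1 or self.min_per_class < 1:
            raise ConfigError("min_len and min_per_class must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError("threshold must be in [0, 1]")
        if self.template_length < 5:
            raise ConfigError("template_length must be >= 5")
        if not 0.0 <= self.u_density <= 1.0:
            raise ConfigError("u_density must be in [0, 1]")
        for r in self.ratios:
            if len(r) != 2 or min(r) < 0 or sum(r) == 0:
                raise ConfigError(f"invalid ratio {r}")
        if min(self.n_train_reads, self.n_validation_reads, self.mix_n_reads) < 1:
            raise ConfigError("read counts must be >= 1")
        if self.mix_n_reads > self.n_validation_reads:
            raise ConfigError("mix_n_reads cannot exceed the validation pool size")

    @classmethod
    def smoke(cls, out_dir: str, seed: int = 0) -> "RunConfig":
        """A small configuration that exercises every stage quickly.

        Simulated templates are short (40 nt), so the read-length filter is
        scaled to the template instead of the 200-base default used for
        real-scale event tables.
        """
        return cls(
            out_dir=out_dir,
            seed=seed,
            min_len=20,
            template_length=40,
            n_train_reads=60,
            n_validation_reads=80,
            mix_n_reads=60,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "ratios" in raw:
            raw["ratios"] = [tuple(r) for r in raw["ratios"]]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    seeds = {name: int(s) for name, s in zip(
        ["template", "pore", "train_mod", "train_unmod", "val_mod", "val_unmod",
         "model", "mixture"], children)}
    effect: ModEffect = EFFECT_PRESETS[config.effect]()

    # --- simulate ---
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    template = make_template(config.template_length, seed=seeds["template"],
                             u_density=config.u_density)
    pore = PoreModel(seed=seeds["pore"])
    pools = {
        "train_modified": simulate_reads(pore, template, config.n_train_reads, 1, effect,
                                         seed=seeds["train_mod"], read_prefix="tr1_"),
        "train_unmodified": simulate_reads(pore, template, config.n_train_reads, 0, effect,
                                           seed=seeds["train_unmod"], read_prefix="tr0_"),
        "val_modified": simulate_reads(pore, template, config.n_validation_reads, 1, effect,
                                       seed=seeds["val_mod"], read_prefix="va1_"),
        "val_unmodified": simulate_reads(pore, template, config.n_validation_reads, 0, effect,
                                         seed=seeds["val_unmod"], read_prefix="va0_"),
    }
    from .io_events import write_fasta

    write_fasta({"tpl": template}, sim_dir / "template.fa")
    for name, reads in pools.items():
        write_event_table(reads, sim_dir / f"{name}.tsv")

    # --- filter ---
    counts = {}
    filtered = {}
    for name, reads in pools.items():
        kept = filter_reads(reads, min_len=config.min_len)
        filtered[name] = kept
        counts[name] = {"before_filter": len(reads), "after_filter": len(kept)}
        write_event_table(kept, sim_dir / f"{name}.filtered.tsv")

    # --- extract ---
    refs = read_fasta(sim_dir / "template.fa")
    train_windows = extract_all_windows(
        filtered["train_modified"] + filtered["train_unmodified"], refs
    )
    write_feature_table(train_windows, out / "train_features.tsv")
    datasets = build_kmer_datasets(train_windows)
    counts["kmer_datasets"] = {k: len(d) for k, d in sorted(datasets.items())}

    # --- compare (Mann-Whitney per feature, per k-mer) ---
    frames = [results_to_frame(compare_features(d)) for d in datasets.values()]
    mw = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    mw.to_csv(out / "mw_report.tsv", sep="\t", index=False, float_format="%.6g")

    # --- train ---
    models = train_kmer_models(
        datasets, config.algorithm, config.scheme,
        seed=seeds["model"], min_per_class=config.min_per_class,
    )
    if not models:
        raise ConfigError("no k-mer reached min_per_class; enlarge the training pools")
    save_models(models, out / "models")
    counts["kmers_modelled"] = sorted(models)

    # --- mix + profile + quantify ---
    rows = []
    for j, ratio in enumerate(config.ratios):
        mixture = curate_mixture(
            pools["val_modified"], pools["val_unmodified"], ratio,
            n=config.mix_n_reads, seed=seeds["mixture"] + j,
        )
        ev = evaluate_mixture(models, mixture, refs["tpl"], ratio=ratio,
                              threshold=config.threshold)
        rows.append(
            {
                "ratio": f"{ratio[0]}:{ratio[1]}",
                "true_fraction": ev.true_fraction,
                "estimated_fraction": ev.estimate.fraction,
                "mean_probability": ev.estimate.mean_probability,
                "abs_error": abs(ev.estimate.fraction - ev.true_fraction),
                "auroc": ev.metrics.auroc[0],
                "n_windows": ev.n_windows,
                "n_skipped": ev.n_skipped,
            }
        )
    quantify = pd.DataFrame(rows)
    quantify.to_csv(out / "quantify.tsv", sep="\t", index=False, float_format="%.6f")

    manifest = {
        "package_version": _pkg_version("nanoml5mou"),
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "counts": counts,
        "quantify": rows,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
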