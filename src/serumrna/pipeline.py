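"""End-to-end pipeline binding the analysis stages.

Every output is regenerable from the config plus its seed alone; stage
tables carry a provenance header (tool version, seed, config hash) and a
rerun with an identical config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as srio
from .annotate import (
    annotate_library,
    collapse_reads,
    compute_class_proportions,
    length_distribution,
)
from .concordance import all_category_concordance
from .de import run_de
from .fragments import coverage_profile, detect_peaks, tsrna_composition, \
    ysrna_composition
from .reference import build_default_reference, write_reference_fasta
from .signature import FeatureFilterCriteria, evaluate_panels
from .simulate import (
    CohortConfig,
    default_aml_effects,
    default_mixture_config,
    sample_fragments,
    simulate_cohort,
)

log = logging.getLogger(__name__)

STAGES = ("reference", "composition", "characterize", "de", "signature",
          "concordance")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 1
    reads: Optional[str] = None          # external reads; None -> simulate
    n_reads: int = 100_000
    max_mismatch: int = 0
    discovery_aml: int = 30
    discovery_control: int = 12
    validation_aml: int = 20
    validation_control: int = 10
    paired_aml: int = 10
    paired_control: int = 2
    library_size_range: Tuple[int, int] = (40_000, 60_000)
    # Paired PBS/BMS libraries are profiled deeper so counting noise does not
    # mask subject-level co-variation.
    paired_library_size_range: Tuple[int, int] = (200_000, 300_000)
    nb_dispersion: float = 0.05
    # Residual (non-subject) overdispersion of paired libraries; subject
    # biology is carried by the explicit latent vector in the paired design.
    paired_nb_dispersion: float = 0.02
    bms_shared_signal_fraction: float = 0.8
    min_mean_expression: float = 10.0
    logreg_alpha: float = 0.05
    n_trees: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.reads is not None and not Path(self.reads).exists():
            raise ConfigError(f"reads path does not exist: {self.reads}")
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if self.max_mismatch not in (0, 1):
            raise ConfigError("max_mismatch must be 0 or 1")
        for name in ("discovery_aml", "discovery_control", "validation_aml",
                     "validation_control", "paired_aml", "paired_control"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def demo_config(outdir: str = "results/demo") -> PipelineConfig:
    """Small configuration exercising every stage in well under a minute."""
    return PipelineConfig(
        outdir=outdir, seed=7, n_reads=20_000,
        discovery_aml=6, discovery_control=4,
        validation_aml=4, validation_control=3,
        paired_aml=4, paired_control=2,
        library_size_range=(15_000, 25_000), n_trees=100,
    )


def run_pipeline(cfg: PipelineConfig,
                 stages: Sequence[str] = STAGES) -> Dict[str, object]:
    """Run the requested stages (dependencies included automatically)."""
    cfg.validate()
    conf = cfg.as_dict()
    conf.pop("outdir", None)        # hash the science, not the destination
    chash = srio.config_hash(conf)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: Dict[str, object] = {}
    wanted = set(stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    # Later stages need earlier state: close over dependencies.
    deps = {"composition": {"reference"}, "characterize": {"reference",
            "composition"}, "de": {"reference"}, "signature": {"reference",
            "de"}, "concordance": {"reference"}}
    for stage in STAGES:
        if stage in wanted:
            wanted |= deps.get(stage, set())
    for stage in STAGES:
        if stage not in wanted:
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, outdir, chash, state)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(stage, exc) from exc
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    return state


def _stage_reference(cfg, outdir, chash, state):
    ref = build_default_reference(cfg.seed)
    write_reference_fasta(ref, outdir / "reference.fasta",
                          outdir / "reference.tsv")
    state["reference"] = ref
    state["mixture"] = default_mixture_config(seed=cfg.seed)


def _stage_composition(cfg, outdir, chash, state):
    ref = state["reference"]
    mcfg = state["mixture"]
    if cfg.reads is None:
        truth = sample_fragments(mcfg, ref, cfg.n_reads, seed=cfg.seed + 41)
        srio.write_reads(truth, outdir / "reads.fasta")
        srio.write_tsv(truth, outdir / "truth.tsv", cfg.seed, chash,
                       index=False)
        sequences = truth["sequence"]
    else:
        sequences = (s for _, s in srio.read_sequences(cfg.reads))
    reads = collapse_reads(sequences)
    lib = annotate_library(reads, ref, max_mismatch=cfg.max_mismatch)
    props = compute_class_proportions(lib)
    srio.write_tsv(pd.Series(props, name="fraction").rename_axis("category")
                   .to_frame(), outdir / "class_proportions.tsv", cfg.seed,
                   chash)
    srio.write_tsv(lib.feature_counts.rename("count").rename_axis("feature")
                   .to_frame().join(lib.feature_categories.rename("category")),
                   outdir / "feature_counts.tsv", cfg.seed, chash)
    hists = {
        cat: length_distribution(lib.records, cat, lib.mapped_total)
        for cat in ("miRNA", "tsRNA", "rsRNA", "ysRNA")
    }
    hist_df = pd.DataFrame(hists, index=pd.Index(range(15, 46), name="length"))
    srio.write_tsv(hist_df, outdir / "length_distributions.tsv", cfg.seed,
                   chash)
    state["library"] = lib


def _stage_characterize(cfg, outdir, chash, state):
    ref = state["reference"]
    lib = state["library"]
    peak_rows = []
    for parent in ("18S", "28S"):
        prof = coverage_profile(lib.records, parent, ref)
        srio.write_tsv(pd.DataFrame({"position": np.arange(1, prof.length + 1),
                                     "depth": prof.depth}),
                       outdir / f"profile_{parent}.tsv", cfg.seed, chash,
                       index=False)
        for i, pk in enumerate(detect_peaks(prof), start=1):
            peak_rows.append((parent, i, pk.start, pk.end, pk.summit,
                              pk.mean_height, pk.share))
    peaks = pd.DataFrame(peak_rows, columns=["parent", "peak", "start", "end",
                                             "summit", "mean_height", "share"])
    srio.write_tsv(peaks, outdir / "peaks.tsv", cfg.seed, chash, index=False)
    with open(outdir / "peaks.bed", "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED convention)\n")
        for row in peaks.itertuples():
            fh.write(f"{row.parent}\t{row.start - 1}\t{row.end}\t"
                     f"{row.parent}#{row.peak}\n")
    comp = tsrna_composition(lib.records, ref, lib.mapped_total)
    srio.write_tsv(comp, outdir / "tsrna_composition.tsv", cfg.seed, chash)
    ys = ysrna_composition(lib.records, ref)
    srio.write_tsv(ys, outdir / "ysrna_composition.tsv", cfg.seed, chash)
    state["peaks"] = peaks


def _discovery_cohort(cfg, state, seed_offset=0):
    return CohortConfig(
        n_control=cfg.discovery_control, n_aml=cfg.discovery_aml,
        de_effects=default_aml_effects(), nb_dispersion=cfg.nb_dispersion,
        library_size_range=cfg.library_size_range,
        seed=cfg.seed + 100 + seed_offset,
    )


def _stage_de(cfg, outdir, chash, state):
    ref = state["reference"]
    cohort = simulate_cohort(_discovery_cohort(cfg, state), state["mixture"],
                             ref)
    biological = cohort.counts.drop(index="cel-miR-39")
    de = run_de(biological, cohort.samples["group"],
                feature_meta=cohort.features)
    srio.write_tsv(de, outdir / "de_table.tsv", cfg.seed, chash)
    state["discovery"] = cohort
    state["de"] = de


def _stage_signature(cfg, outdir, chash, state):
    ref = state["reference"]
    validation = simulate_cohort(
        CohortConfig(
            n_control=cfg.validation_control, n_aml=cfg.validation_aml,
            de_effects=default_aml_effects(), nb_dispersion=cfg.nb_dispersion,
            library_size_range=cfg.library_size_range, seed=cfg.seed + 200,
        ),
        state["mixture"], ref)
    discovery = state["discovery"]
    val_counts = validation.counts.drop(index="cel-miR-39")
    val_counts.columns = [f"V-{c}" for c in val_counts.columns]
    val_labels = pd.Series(validation.samples["group"].to_numpy(),
                           index=val_counts.columns)
    disc_counts = discovery.counts.drop(index="cel-miR-39")
    reports = evaluate_panels(
        disc_counts, discovery.samples["group"], state["de"],
        discovery.features, val_counts, val_labels,
        criteria=FeatureFilterCriteria(
            min_mean_expression=cfg.min_mean_expression,
            logreg_alpha=cfg.logreg_alpha),
        n_trees=cfg.n_trees, seed=cfg.seed,
    )
    srio.write_json({cat: rep.to_dict() for cat, rep in reports.items()},
                    outdir / "signature_report.json", cfg.seed, chash)
    state["reports"] = reports


def _stage_concordance(cfg, outdir, chash, state):
    ref = state["reference"]
    cohort = simulate_cohort(
        CohortConfig(
            n_control=cfg.paired_control, n_aml=cfg.paired_aml,
            paired_bms=True,
            bms_shared_signal_fraction=cfg.bms_shared_signal_fraction,
            nb_dispersion=cfg.paired_nb_dispersion,
            library_size_range=cfg.paired_library_size_range,
            seed=cfg.seed + 300,
        ),
        state["mixture"], ref)
    counts = cohort.counts.drop(index="cel-miR-39")
    table = all_category_concordance(counts, cohort.samples, cohort.features)
    srio.write_tsv(table, outdir / "concordance.tsv", cfg.seed, chash)
    state["concordance"] = table


_STAGE_FUNCS = {
    "reference": _stage_reference,
    "composition": _stage_composition,
    "characterize": _stage_characterize,
    "de": _stage_de,
    "signature": _stage_signature,
    "concordance": _stage_concordance,
}
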