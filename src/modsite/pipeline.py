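"""End-to-end pipelines: simulate a fixture bundle, detect outliers, calibrate.

Files are the interface between stages: every run writes its intermediate
TSVs plus a manifest JSON (tool version, config hash, seed), and a rerun
with the same configuration and inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .errors import InvalidArgumentError
from .feature_sets import build_features
from .outlier_detection import (
    LOFConfig,
    ModificationMap,
    OutlierReport,
    call_outliers,
    label_positions,
    lof_scores,
    median_prefilter,
)
from .pairwise_scoring import score_positions
from .pileup_io import AlignmentFilterConfig, downsample_bam, pileup_from_bam
from .stoichiometry import (
    DEFAULT_RATIOS,
    CalibrationCurve,
    _sub_seed,
    build_calibration,
    estimate_level,
)
from .synthetic_data import (
    ModProfile,
    SimConfig,
    load_profile_tsv,
    make_reference,
    simulate_reads,
)


@dataclass
class PipelineConfig:
    """Configuration of one detection run.

    `basecalling_mode` tags (fast/hac) are metadata only, but the two
    conditions must have been basecalled identically — differing tags make
    the run refuse to start, since basecaller-specific error profiles would
    masquerade as modification signal.
    """

    cond1_bams: list[str]
    cond2_bams: list[str]
    out_dir: str
    reference_fasta: str | None = None
    n_reads: int = 1000
    seed: int = 0
    feature_set: str = "M"
    lof: LOFConfig = field(default_factory=LOFConfig)
    map_path: str | None = None
    cond1_basecalling_mode: str = "hac"
    cond2_basecalling_mode: str = "hac"
    labels: tuple[str, str] = ("cond1", "cond2")
    filters: AlignmentFilterConfig = field(default_factory=AlignmentFilterConfig)

    def validate(self) -> None:
        if self.n_reads < 1:
            raise InvalidArgumentError("n_reads must be >= 1")
        if self.cond1_basecalling_mode != self.cond2_basecalling_mode:
            raise InvalidArgumentError(
                "conditions were basecalled differently "
                f"({self.cond1_basecalling_mode} vs {self.cond2_basecalling_mode}); "
                "all samples must be basecalled identically"
            )
        for p in [*self.cond1_bams, *self.cond2_bams]:
            if not Path(p).exists():
                raise InvalidArgumentError(f"input not found: {p}")

    def config_hash(self) -> str:
        payload = {
            "cond1_bams": self.cond1_bams,
            "cond2_bams": self.cond2_bams,
            "n_reads": self.n_reads,
            "seed": self.seed,
            "feature_set": self.feature_set,
            "lof": asdict(self.lof),
            "map_path": self.map_path,
            "filters": asdict(self.filters),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, cfg_hash: str, seed: int, extra: dict | None = None) -> Path:
    manifest = {
        "tool": "modsite",
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
        **(extra or {}),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_detect(cfg: PipelineConfig) -> OutlierReport:
    """Full detection pipeline.

    downsample -> pileup -> score (pooled + pairwise) -> features ->
    median prefilter -> LOF -> call -> post-hoc label.  All intermediates
    are written under ``cfg.out_dir``.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    stamp = f"modsite {__version__} config={cfg_hash} seed={cfg.seed}"

    pileups = {}
    for ci, bams in enumerate([cfg.cond1_bams, cfg.cond2_bams]):
        reps = []
        for ri, bam in enumerate(bams):
            ds = downsample_bam(
                bam, cfg.n_reads, _sub_seed(cfg.seed, ci, ri),
                out_dir / f"{cfg.labels[ci]}_rep{ri}.ds.bam", cfg.filters,
            )
            reps.append(pileup_from_bam(ds, cfg.reference_fasta, cfg.filters))
        pileups[ci] = reps

    pooled = score_positions(pileups[0], pileups[1], mode="pooled", labels=cfg.labels)
    pooled.to_tsv(out_dir / "scores_pooled.tsv", header_comment=stamp)
    pairwise = score_positions(pileups[0], pileups[1], mode="pairwise", labels=cfg.labels)
    for t in pairwise:
        t.to_tsv(out_dir / f"scores_{t.comparison_id}.tsv", header_comment=stamp)

    candidates = median_prefilter(pooled)
    X = build_features(pairwise, cfg.feature_set)
    X = X.loc[X.index.intersection(candidates)]
    X.to_csv(out_dir / "features.tsv", sep="\t")

    lof = lof_scores(X, k=cfg.lof.k)
    report = call_outliers(
        lof,
        X.index.to_numpy(),
        cfg.lof,
        score_mis=pooled.score("mismatch").reindex(X.index).to_numpy(),
    )
    mod_map = ModificationMap()
    if cfg.map_path:
        path = Path(cfg.map_path)
        mod_map = (
            ModificationMap.from_bed(path)
            if path.suffix.lower() == ".bed"
            else ModificationMap.from_tsv(path)
        )
    report = label_positions(report, mod_map)
    report.to_tsv(out_dir / "outliers.tsv", header_comment=stamp)
    _write_manifest(
        out_dir, cfg_hash, cfg.seed,
        {"n_candidates": int(len(X)), "n_flagged": int(report.data["is_outlier"].sum())},
    )
    return report


@dataclass
class SimulateConfig:
    """Fixture-bundle generation: reference, WT/KO replicate BAMs, truth map.

    Defaults mimic a targeted 18S run: a 1869-nt reference, 1000 reads per
    replicate, three replicates per condition.
    """

    out_dir: str
    length: int = 1869
    depth: int = 1000
    n_replicates: int = 3
    gc: float = 0.5
    kappa: float = 2000.0
    seed: int = 0
    profiles: list[ModProfile] = field(default_factory=list)
    profile_tsv: str | None = None
    stoichiometries: Sequence[float] | None = None  # None -> plain WT (s=1) vs KO (s=0)


def run_simulate(cfg: SimulateConfig) -> dict:
    """Emit a self-describing bundle directly consumable by :func:`run_detect`.

    Contents: reference FASTA, `wt_rep*.bam` (modified at the profiled
    sites), `ko_rep*.bam` (unmodified), truth BED, and optionally one
    extra BAM set per requested stoichiometry ratio.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = list(cfg.profiles)
    if cfg.profile_tsv:
        profiles += load_profile_tsv(cfg.profile_tsv)
    ref = make_reference(cfg.length, cfg.gc, seed=_sub_seed(cfg.seed, 0))
    fasta = ref.to_fasta(out_dir / "reference.fa")
    sim = lambda s, seed_tag, prefix: simulate_reads(  # noqa: E731
        ref, profiles, s,
        SimConfig(cfg.depth, cfg.n_replicates, cfg.kappa, _sub_seed(cfg.seed, seed_tag)),
        out_dir, prefix=prefix,
    )
    bundle = {
        "reference": str(fasta),
        "wt": [str(p) for p in sim(1.0, 1, "wt")],
        "ko": [str(p) for p in sim(0.0, 2, "ko")],
    }
    truth = ModificationMap(sites={p.site: p.class_label for p in profiles})
    truth.to_bed(out_dir / "truth.bed", ref.name)
    bundle["truth"] = str(out_dir / "truth.bed")
    if cfg.stoichiometries is not None:
        bundle["mixtures"] = {}
        for k, s in enumerate(cfg.stoichiometries):
            paths = sim(float(s), 100 + k, f"mix{s:g}")
            bundle["mixtures"][float(s)] = [str(p) for p in paths]
    (out_dir / "bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return bundle


def run_calibrate(
    wt_bam: str,
    ko_bam: str,
    comparator_bams: Sequence[str],
    site: int,
    out_dir: str,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    n_reads: int = 1000,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    reference_fasta: str | None = None,
    observed: float | None = None,
) -> CalibrationCurve:
    """Build a calibration curve, write it, optionally invert an observed score."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve = build_calibration(
        wt_bam, ko_bam, comparator_bams, site,
        ratios=ratios, n_reads=n_reads, seeds=seeds, reference_fasta=reference_fasta,
    )
    stamp = f"modsite {__version__} seeds={list(seeds)}"
    curve.to_tsv(out / "calibration.tsv", header_comment=stamp)
    if observed is not None:
        level, (lo, hi) = estimate_level(curve, observed)
        (out / "estimate.json").write_text(
            json.dumps(
                {"observed": observed, "level": level, "interval": [lo, hi]}, indent=2
            )
            + "\n"
        )
    return curve
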