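"""Modification-level calibration by in-silico mixing, and coverage robustness.

A site's divergence score grows with the fraction of modified molecules,
but the relationship is nonlinear and saturates, so absolute modification
levels cannot be read off a score directly.  Instead, a calibration curve
is built by mixing reads from a fully modified (WT) and an unmodified
(KO/MUT) pool at known ratios, scoring each mixture against the unmodified
comparator, and recording the site score per ratio over several sampling
seeds.  The mean curve, monotonized by isotonic regression, is then
inverted by piecewise-linear interpolation to estimate the modification
level behind an observed score; scores below the 0%-curve map to 0,
scores above the 100%-curve to 1 (saturation clip).

The same machinery quantifies robustness to read depth: both conditions
are downsampled to a grid of read counts and the site's score distance to
the median, plus its normalized LOF distance, are tracked per depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import InvalidArgumentError, UnidentifiableError
from .outlier_detection import LOFConfig, lof_scores, median_prefilter, normalized_lof_distance
from .pairwise_scoring import Channel, ScoreTable, score_positions
from .pileup_io import AlignmentFilterConfig, downsample_bam, mix_bams, pileup_from_bam

DEFAULT_RATIOS = (0.0, 0.005, 0.05, 0.10, 0.25, 0.50, 0.75, 1.0)
DEFAULT_READ_GRID = (300, 500, 1000, 5000, 10000)


def _sub_seed(base: int, *tags: int) -> int:
    """Derive an independent child seed from a base seed and integer tags."""
    return int(np.random.SeedSequence([int(base), *map(int, tags)]).generate_state(1)[0] % (2**31))


@dataclass
class CalibrationCurve:
    """Site score as a function of modification stoichiometry.

    `ratios` ascending in [0, 1]; `mean`/`sd` of the site score over
    sampling seeds at each ratio.  `monotone_mean` is the isotonic
    (non-decreasing) projection of the mean, used for inversion.
    """

    ratios: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_seeds: int
    site: int
    channel: Channel = "mismatch"
    per_seed: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.ratios.size == self.mean.size == self.sd.size):
            raise InvalidArgumentError("ratios, mean and sd must align")
        if self.ratios.size and not np.all(np.diff(self.ratios) > 0):
            raise InvalidArgumentError("ratios must be strictly ascending")

    @property
    def monotone_mean(self) -> np.ndarray:
        iso = IsotonicRegression(increasing=True)
        return iso.fit_transform(self.ratios, self.mean)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        df = pd.DataFrame(
            {
                "ratio": self.ratios,
                "mean": self.mean,
                "sd": self.sd,
                "n_seeds": self.n_seeds,
                "site": self.site,
                "channel": self.channel,
            }
        )
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path, sep="\t", comment="#").sort_values("ratio")
        return cls(
            ratios=df["ratio"].to_numpy(),
            mean=df["mean"].to_numpy(),
            sd=df["sd"].to_numpy(),
            n_seeds=int(df["n_seeds"].iloc[0]),
            site=int(df["site"].iloc[0]),
            channel=str(df["channel"].iloc[0]),
        )


def build_calibration(
    wt_bam: str | Path,
    ko_bam: str | Path,
    comparator_bams: Sequence[str | Path],
    site: int,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    n_reads: int = 1000,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    channel: Channel = "mismatch",
    reference_fasta: str | Path | None = None,
    comparator_n_reads: int | None = None,
    filters: AlignmentFilterConfig | None = None,
    workdir: str | Path | None = None,
) -> CalibrationCurve:
    """Score-vs-stoichiometry calibration from WT and KO read pools.

    For every ratio r and seed: mix ``round(r * n_reads)`` WT reads with
    the complement of KO reads, pile up, and score the mixture against the
    unmodified comparator replicates; record the site score.  Rows of the
    returned curve are the ratios, each with mean/sd over seeds.
    """
    import tempfile

    ratios = sorted(float(r) for r in ratios)
    if len(ratios) < 2:
        raise InvalidArgumentError("need at least 2 ratios")
    if len(seeds) < 2:
        raise InvalidArgumentError("need at least 2 seeds for an sd estimate")
    comp_pileups = []
    for cb in comparator_bams:
        if comparator_n_reads is None:
            comp_pileups.append(pileup_from_bam(cb, reference_fasta, filters))
    records = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        if comparator_n_reads is not None:
            for i, cb in enumerate(comparator_bams):
                p = downsample_bam(
                    cb, comparator_n_reads, _sub_seed(seeds[0], 997, i), tmp / f"comp{i}.bam", filters
                )
                comp_pileups.append(pileup_from_bam(p, reference_fasta, filters))
        for r in ratios:
            for si, seed in enumerate(seeds):
                try:
                    mix = mix_bams(
                        wt_bam, ko_bam, n_reads, r, _sub_seed(seed, int(r * 1e6)),
                        tmp / f"mix_{r}_{si}.bam", filters,
                    )
                except InvalidArgumentError as exc:
                    raise InvalidArgumentError(f"ratio {r}: {exc}") from exc
                mix_pileup = pileup_from_bam(mix, reference_fasta, filters)
                table = score_positions([mix_pileup], comp_pileups, mode="pooled")
                score = table.score(channel).get(site, np.nan)
                records.append({"ratio": r, "seed": seed, "score": float(score)})
    per_seed = pd.DataFrame(records)
    agg = per_seed.groupby("ratio")["score"].agg(["mean", "std"]).reset_index()
    return CalibrationCurve(
        ratios=agg["ratio"].to_numpy(),
        mean=agg["mean"].to_numpy(),
        sd=agg["std"].to_numpy(),
        n_seeds=len(seeds),
        site=site,
        channel=channel,
        per_seed=per_seed,
    )


def _invert_monotone(ratios: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Invert a non-decreasing curve; plateaus map to their ratio midpoint."""
    if observed <= y[0]:
        return float(ratios[0])
    if observed >= y[-1]:
        eq = np.isclose(y, y[-1])
        if eq.sum() > 1 and np.isclose(observed, y[-1]):
            lo = ratios[eq][0]
            return float((lo + ratios[-1]) / 2.0)
        return float(ratios[-1])
    eq = np.isclose(y, observed)
    if eq.any():
        return float((ratios[eq][0] + ratios[eq][-1]) / 2.0)
    i = int(np.searchsorted(y, observed) - 1)
    frac = (observed - y[i]) / (y[i + 1] - y[i])
    return float(ratios[i] + frac * (ratios[i + 1] - ratios[i]))


def estimate_level(
    curve: CalibrationCurve, observed: float
) -> tuple[float, tuple[float, float]]:
    """Modification level behind an observed site score, with a +/-1 sd interval.

    The mean curve is monotonized by isotonic regression and inverted by
    piecewise-linear interpolation; observations below the 0-ratio score
    clip to the lowest ratio, above the 1-ratio score to the highest.
    The interval comes from inverting the mean +/- sd bands.

    Raises :class:`UnidentifiableError` when the curve is flat relative to
    its seed-to-seed noise (no usable score-level relationship).
    """
    if curve.ratios.size < 3:
        raise InvalidArgumentError("curve needs at least 3 ratios for inversion")
    y = curve.monotone_mean
    span = y[-1] - y[0]
    noise = float(np.nanmedian(curve.sd)) if np.isfinite(curve.sd).any() else 0.0
    if span <= 0 or span <= 2.0 * noise:
        raise UnidentifiableError(
            "calibration curve is flat relative to its noise; "
            "modification level is not identifiable from this site/channel"
        )
    level = _invert_monotone(curve.ratios, y, float(observed))
    iso = IsotonicRegression(increasing=True)
    sd = np.nan_to_num(curve.sd, nan=0.0)
    y_hi = iso.fit_transform(curve.ratios, curve.mean + sd)
    y_lo = iso.fit_transform(curve.ratios, curve.mean - sd)
    # a higher curve inverts to a lower level and vice versa
    bound_a = _invert_monotone(curve.ratios, y_hi, float(observed))
    bound_b = _invert_monotone(curve.ratios, y_lo, float(observed))
    lo, hi = sorted((bound_a, bound_b))
    return level, (lo, hi)


@dataclass
class DownsamplingReport:
    """Site detectability across read depths.

    `cells`: one row per (n_reads, seed) with the site's raw score distance
    to the median and its normalized LOF distance.  `summary`: mean +/- sd
    per n_reads.
    """

    cells: pd.DataFrame
    site: int

    @property
    def summary(self) -> pd.DataFrame:
        return (
            self.cells.groupby("n_reads")[["score_distance", "norm_lof_distance"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.cells.to_csv(fh, sep="\t", index=False)


def downsampling_report(
    cond1_bam: str | Path,
    cond2_bam: str | Path,
    site: int,
    read_grid: Sequence[int] = DEFAULT_READ_GRID,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    lof_cfg: LOFConfig | None = None,
    channel: Channel = "mismatch",
    reference_fasta: str | Path | None = None,
    filters: AlignmentFilterConfig | None = None,
    workdir: str | Path | None = None,
) -> DownsamplingReport:
    """Robustness of site detection to read depth.

    Per (n_reads, seed): both conditions are downsampled to n_reads, scored
    position-wise (pooled), and two detectability measures recorded — the
    site score minus the median score, and the normalized LOF distance of
    the site over the median-prefiltered candidates (NaN when the site does
    not survive the prefilter).
    """
    import tempfile

    lof_cfg = lof_cfg or LOFConfig()
    records = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        for n in read_grid:
            for seed in seeds:
                b1 = downsample_bam(cond1_bam, n, _sub_seed(seed, n, 1), tmp / "d1.bam", filters)
                b2 = downsample_bam(cond2_bam, n, _sub_seed(seed, n, 2), tmp / "d2.bam", filters)
                p1 = pileup_from_bam(b1, reference_fasta, filters)
                p2 = pileup_from_bam(b2, reference_fasta, filters)
                table = score_positions([p1], [p2], mode="pooled")
                scores = table.score(channel).dropna()
                if site not in scores.index:
                    raise InvalidArgumentError(f"site {site} has zero depth at n={n}")
                score_dist = float(scores[site] - scores.median())
                try:
                    candidates = median_prefilter(table, channel)
                    X = scores.loc[candidates].to_numpy()[:, None]
                    lof = lof_scores(X, k=min(lof_cfg.k, X.shape[0] - 1))
                    nld = normalized_lof_distance(lof, candidates, site)
                except InvalidArgumentError:
                    nld = float("nan")
                records.append(
                    {
                        "n_reads": n,
                        "seed": seed,
                        "score_distance": score_dist,
                        "norm_lof_distance": nld,
                    }
                )
    return DownsamplingReport(cells=pd.DataFrame(records), site=site)
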