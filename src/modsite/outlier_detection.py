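"""Local-Outlier-Factor calling of differentially modified positions.

Candidate positions (pooled mismatch score above the median) are ranked by
the Local Outlier Factor over the pairwise-comparison feature matrix; the
top ``ceil(contamination * n_candidates)`` positions are flagged and then
labelled post hoc against a map of known modification sites as modified,
neighbour (within +/-2 of a known site) or non-modified.

LOF measures the density deviation of each point with respect to its k
nearest neighbours (k-distance, reachability distance, local reachability
density, LOF = mean lrd of neighbours / own lrd); values well above 1 mark
points in sparser neighbourhoods than their neighbours.  The computation is
delegated to scikit-learn's ``LocalOutlierFactor`` with Euclidean distance;
coincident points (k-distance 0) get LOF = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .errors import EmptyInputError, InvalidArgumentError
from .pairwise_scoring import ScoreTable

MOD_CLASSES = ("psU", "Nm", "ac4C", "m6A", "m7G", "m26A", "m1acp3psU", "other")
NEIGHBOUR_RADIUS = 2  # post-hoc neighbour label: within +/-2 of a known site


@dataclass(frozen=True)
class LOFConfig:
    """Neighbourhood size and flagged fraction for outlier calling.

    Defaults follow common practice for targets with one or two expected
    differential sites on an rRNA-length reference: neighbourhood size 20
    and a strict contamination of 0.001 (0.1% of candidates).
    """

    k: int = 20
    contamination: float = 0.001

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if not 0.0 < self.contamination <= 0.5:
            raise InvalidArgumentError("contamination must lie in (0, 0.5]")


@dataclass
class ModificationMap:
    """Known modified positions (1-based) with chemical class labels."""

    sites: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, cls in self.sites.items():
            if pos < 1:
                raise InvalidArgumentError("map positions are 1-based and must be >= 1")
            if cls not in MOD_CLASSES:
                raise InvalidArgumentError(f"unknown modification class {cls!r}")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array(sorted(self.sites), dtype=int)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ModificationMap":
        """BED (0-based half-open); the name column carries the class."""
        sites = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidArgumentError(f"malformed BED line: {line!r}")
            start, end = int(parts[1]), int(parts[2])
            cls_label = parts[3] if len(parts) > 3 else "other"
            for pos0 in range(start, end):
                sites[pos0 + 1] = cls_label
        return cls(sites=sites)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationMap":
        """Two-column TSV: 1-based position, class label (header optional)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["position", "class"])
        if str(df.iloc[0, 0]).lower() in ("position", "pos"):
            df = df.iloc[1:]
        return cls(sites={int(p): str(c) for p, c in zip(df["position"], df["class"])})

    def to_bed(self, path: str | Path, reference: str) -> None:
        lines = [
            f"{reference}\t{pos - 1}\t{pos}\t{self.sites[pos]}" for pos in sorted(self.sites)
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class OutlierReport:
    """Per-candidate LOF scores, flags and post-hoc labels.

    `data` columns: ``pos, lof, score_mis, rank, is_outlier`` and, after
    :func:`label_positions`, ``label``.
    """

    data: pd.DataFrame
    config: LOFConfig | None = None

    @property
    def flagged(self) -> pd.DataFrame:
        return self.data[self.data["is_outlier"]]

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, sep="\t", index=False)


def median_prefilter(score_table: ScoreTable, channel: str = "mismatch") -> np.ndarray:
    """Candidate positions: pooled score strictly above the median.

    Median is taken over non-missing positions; all-equal scores yield an
    empty candidate set (nothing is strictly above).
    """
    scores = score_table.score(channel)
    valid = scores.dropna()
    if len(valid) == 0:
        raise EmptyInputError("all positions are missing; nothing to prefilter")
    if len(valid) < 4:
        raise InvalidArgumentError("need at least 4 scored positions for the median prefilter")
    med = float(valid.median())
    return valid.index[valid > med].to_numpy()


def lof_scores(X: pd.DataFrame | np.ndarray, k: int = 20) -> np.ndarray:
    """LOF score per row of the candidate feature matrix (Euclidean metric)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if n <= k:
        raise InvalidArgumentError(
            f"LOF needs more than k rows (got {n} rows, k={k}); use a smaller k"
        )
    lof = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    lof.fit(arr)
    return -lof.negative_outlier_factor_


def call_outliers(
    lof: np.ndarray,
    positions: np.ndarray,
    cfg: LOFConfig,
    score_mis: np.ndarray | None = None,
) -> OutlierReport:
    """Flag the ``ceil(contamination * n)`` candidates with the highest LOF.

    Ties on LOF are broken by higher pooled mismatch score, then by lower
    position index.  Ranks are unique, 1 = most outlying.
    """
    lof = np.asarray(lof, dtype=float)
    positions = np.asarray(positions, dtype=int)
    if lof.shape != positions.shape:
        raise InvalidArgumentError("lof and positions must align")
    n = lof.size
    score_mis = np.zeros(n) if score_mis is None else np.asarray(score_mis, dtype=float)
    n_flag = min(n, math.ceil(cfg.contamination * n))
    order = np.lexsort((positions, -score_mis, -lof))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    data = pd.DataFrame(
        {
            "pos": positions,
            "lof": lof,
            "score_mis": score_mis,
            "rank": rank,
            "is_outlier": rank <= n_flag,
        }
    ).sort_values("rank", ignore_index=True)
    return OutlierReport(data=data, config=cfg)


def label_positions(report: OutlierReport, mod_map: ModificationMap) -> OutlierReport:
    """Post-hoc labels: modified site, neighbour (-2..+2) or non-modified."""
    if len(mod_map) == 0:
        labels = ["unannotated"] * len(report.data)
    else:
        known = mod_map.positions
        labels = []
        for pos in report.data["pos"]:
            if pos in mod_map.sites:
                labels.append("modified")
            elif np.abs(known - pos).min() <= NEIGHBOUR_RADIUS:
                labels.append("neighbour")
            else:
                labels.append("non-modified")
    out = report.data.copy()
    out["label"] = labels
    return OutlierReport(data=out, config=report.config)


def normalized_lof_distance(
    lof: np.ndarray, positions: np.ndarray, site: int
) -> float:
    """(lof(site) - median(lof)) / max(lof): scale-free outlyingness of a site.

    Used to compare outlier strength across analyses whose LOF scales
    differ (e.g. different read depths).  Raises if the site was filtered
    out of the candidate set.
    """
    positions = np.asarray(positions, dtype=int)
    lof = np.asarray(lof, dtype=float)
    idx = np.nonzero(positions == site)[0]
    if idx.size == 0:
        raise InvalidArgumentError(
            f"site {site} is not among the candidates (filtered out by the median prefilter)"
        )
    return float((lof[idx[0]] - np.median(lof)) / lof.max())
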