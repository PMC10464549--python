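"""Per-position error-profile divergence between two conditions.

For each reference position, three divergence channels are scored between a
pair of conditions (e.g. WT vs KO, or a mixture vs an unmodified
comparator):

* mismatch — the 4-vector of called-base counts (A, C, G, T),
* deletion — (deleted, not deleted),
* insertion — (reads with an insertion after the position, reads without).

The score is the multinomial log-likelihood-ratio (G) statistic: it is zero
when and only when the two conditions have identical category proportions,
grows with the divergence of their error profiles, and is asymptotically
chi-squared with K-1 degrees of freedom under the null, which makes the
score distribution over unmodified positions directly checkable.  Replicate
handling mirrors a two-condition caller: `pooled` sums counts within each
condition for one headline score per position; `pairwise` emits one score
table per (replicate_i, replicate_j) single-replicate comparison, which
downstream outlier detection uses as its feature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import InvalidArgumentError
from .pileup_io import PileupMatrix

Channel = Literal["mismatch", "deletion", "insertion"]
CHANNELS: tuple[Channel, ...] = ("mismatch", "deletion", "insertion")


@dataclass
class ScoreTable:
    """Per-position divergence scores for one condition comparison.

    `data` columns: ``pos`` (1-based), ``score_mis``, ``score_del``,
    ``score_ins``, ``depth_1``, ``depth_2``.  Positions with zero depth in
    either condition carry NaN scores (missing, not zero).
    """

    reference: str
    comparison_id: str
    data: pd.DataFrame
    meta: dict | None = None

    @property
    def positions(self) -> np.ndarray:
        return self.data["pos"].to_numpy()

    def score(self, channel: Channel = "mismatch") -> pd.Series:
        col = {"mismatch": "score_mis", "deletion": "score_del", "insertion": "score_ins"}[channel]
        return self.data.set_index("pos")[col]

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        df = self.data.copy()
        df.insert(0, "comparison_id", self.comparison_id)
        df.insert(0, "ref", self.reference)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)


def channel_counts(pileup: PileupMatrix, channel: Channel, position: int) -> np.ndarray | None:
    """Count vector for one channel at one 1-based position.

    mismatch -> (n_A, n_C, n_G, n_T); deletion -> (n_del, depth - n_del);
    insertion -> (n_ins, depth - n_ins).  Returns None at zero depth
    (missing marker).
    """
    if not 1 <= position <= pileup.length:
        raise InvalidArgumentError(f"position {position} outside [1, {pileup.length}]")
    row = pileup.counts[position - 1]
    depth = int(row[:5].sum())
    if depth == 0:
        return None
    if channel == "mismatch":
        return row[:4].copy()
    if channel == "deletion":
        return np.array([row[4], depth - row[4]])
    if channel == "insertion":
        return np.array([row[5], depth - row[5]])
    raise InvalidArgumentError(f"unknown channel {channel!r}")


def g_score(counts_1: np.ndarray, counts_2: np.ndarray) -> float:
    """Multinomial log-likelihood-ratio (G) statistic between two count vectors.

    ``G = 2 * [sum c1 ln(c1/n1) + sum c2 ln(c2/n2) - sum (c1+c2) ln((c1+c2)/(n1+n2))]``
    with ``0 ln 0 := 0``.  Symmetric; zero iff the proportions are equal.
    Returns NaN (missing) when either vector has zero total.
    """
    c1 = np.asarray(counts_1, dtype=float)
    c2 = np.asarray(counts_2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or c1.size < 2:
        raise InvalidArgumentError("count vectors must share a length K >= 2")
    n1, n2 = c1.sum(), c2.sum()
    if n1 == 0 or n2 == 0:
        return float("nan")
    tot = c1 + c2
    ll = (
        xlogy(c1, c1).sum() - xlogy(n1, n1)
        + xlogy(c2, c2).sum() - xlogy(n2, n2)
        - xlogy(tot, tot).sum() + xlogy(n1 + n2, n1 + n2)
    )
    return max(0.0, 2.0 * ll)


def _g_score_columns(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Vectorised G over rows of two (L, K) count matrices; NaN at zero totals."""
    c1 = c1.astype(float)
    c2 = c2.astype(float)
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    tot = c1 + c2
    ll = (
        xlogy(c1, c1).sum(axis=1) - xlogy(n1, n1)
        + xlogy(c2, c2).sum(axis=1) - xlogy(n2, n2)
        - xlogy(tot, tot).sum(axis=1) + xlogy(n1 + n2, n1 + n2)
    )
    g = np.maximum(0.0, 2.0 * ll)
    g[(n1 == 0) | (n2 == 0)] = np.nan
    return g


def _score_pair(p1: PileupMatrix, p2: PileupMatrix, comparison_id: str) -> ScoreTable:
    d1 = p1.depth.astype(float)
    d2 = p2.depth.astype(float)
    mis = _g_score_columns(p1.counts[:, :4], p2.counts[:, :4])
    dele = _g_score_columns(
        np.column_stack([p1.counts[:, 4], d1 - p1.counts[:, 4]]),
        np.column_stack([p2.counts[:, 4], d2 - p2.counts[:, 4]]),
    )
    ins = _g_score_columns(
        np.column_stack([p1.counts[:, 5], d1 - p1.counts[:, 5]]),
        np.column_stack([p2.counts[:, 5], d2 - p2.counts[:, 5]]),
    )
    data = pd.DataFrame(
        {
            "pos": np.arange(1, p1.length + 1),
            "score_mis": mis,
            "score_del": dele,
            "score_ins": ins,
            "depth_1": d1.astype(int),
            "depth_2": d2.astype(int),
        }
    )
    return ScoreTable(reference=p1.reference, comparison_id=comparison_id, data=data)


def pool_pileups(pileups: Sequence[PileupMatrix]) -> PileupMatrix:
    """Sum counts across replicates of one condition."""
    if not pileups:
        raise InvalidArgumentError("no pileups to pool")
    pooled = pileups[0]
    for p in pileups[1:]:
        pooled = pooled + p
    return pooled


def score_positions(
    cond1: Sequence[PileupMatrix],
    cond2: Sequence[PileupMatrix],
    mode: Literal["pooled", "pairwise"] = "pooled",
    labels: tuple[str, str] = ("cond1", "cond2"),
) -> ScoreTable | list[ScoreTable]:
    """Score all positions between two replicated conditions.

    pooled: counts are summed within each condition -> one ScoreTable.
    pairwise: one ScoreTable per (replicate_i of cond1, replicate_j of
    cond2) single-replicate comparison -> r1*r2 tables, the feature set for
    outlier detection.
    """
    if not cond1 or not cond2:
        raise InvalidArgumentError("both conditions need at least one pileup")
    ref = cond1[0].reference
    length = cond1[0].length
    for p in list(cond1) + list(cond2):
        if p.reference != ref or p.length != length:
            raise InvalidArgumentError("all pileups must share one reference")
    if mode == "pooled":
        return _score_pair(
            pool_pileups(cond1), pool_pileups(cond2), f"{labels[0]}_vs_{labels[1]}:pooled"
        )
    if mode == "pairwise":
        tables = []
        for i, p1 in enumerate(cond1, start=1):
            for j, p2 in enumerate(cond2, start=1):
                tables.append(_score_pair(p1, p2, f"{labels[0]}{i}_vs_{labels[1]}{j}"))
        return tables
    raise InvalidArgumentError(f"unknown mode {mode!r}")
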