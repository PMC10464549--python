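"""Feature matrices for outlier detection.

Four feature sets reflect that rRNA modifications cluster and that the pore
reads 5-mers, so the error signature of one modification spreads over
neighbouring positions:

* ``M``        — mismatch score of the site (1 feature per comparison)
* ``MDI``      — mismatch, deletion and insertion scores of the site (3)
* ``M_Con_DI`` — mismatch scores across the 5-mer context (site centred,
                 offsets -2..+2) plus site deletion/insertion scores (7)
* ``MDI_Con``  — all three channels across the 5-mer context (15)

With pairwise replicate comparisons as input, the feature count multiplies
by the number of comparisons (e.g. 3x3 replicates, MDI_Con -> 135 columns).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .pairwise_scoring import ScoreTable

FEATURE_SETS = ("M", "MDI", "M_Con_DI", "MDI_Con")

_SCORE_COL = {"mismatch": "score_mis", "deletion": "score_del", "insertion": "score_ins"}


def feature_set_dims(set_name: str, context_width: int = 5) -> int:
    """Features per comparison for a given set."""
    w = context_width
    return {"M": 1, "MDI": 3, "M_Con_DI": w + 2, "MDI_Con": 3 * w}[set_name]


def _context_columns(scores: pd.Series, offsets: Sequence[int]) -> np.ndarray:
    """Per-offset score columns; offsets falling outside [1, L] contribute 0."""
    pos = scores.index.to_numpy()
    vals = scores.to_numpy()
    n = vals.size
    out = np.zeros((n, len(offsets)))
    # positions are a contiguous 1..L range in a ScoreTable
    for k, off in enumerate(offsets):
        shifted = np.zeros(n)
        if off == 0:
            shifted = vals
        elif off > 0:
            shifted[: n - off] = vals[off:]
        else:
            shifted[-off:] = vals[: n + off]
        out[:, k] = shifted
    return out


def build_features(
    score_tables: Sequence[ScoreTable],
    set_name: str,
    context_width: int = 5,
    sum_context: bool = False,
) -> pd.DataFrame:
    """Assemble the positions-by-features matrix for a named feature set.

    Context features are the per-offset scores at offsets -(w-1)/2..+(w-1)/2
    concatenated (site at the centre); `sum_context=True` instead sums each
    channel over the context window.  Positions with any missing (zero
    depth) score are dropped; the dropped positions are recorded in
    ``result.attrs["dropped_positions"]``.

    Returns a DataFrame indexed by 1-based position with deterministic
    column names ``<comparison_id>|<channel>|off<+k>``.
    """
    if not score_tables:
        raise InvalidArgumentError("need at least one score table")
    if set_name not in FEATURE_SETS:
        raise InvalidArgumentError(f"feature set must be one of {FEATURE_SETS}")
    if context_width < 1 or context_width % 2 == 0:
        raise InvalidArgumentError("context_width must be odd and >= 1")
    ref = score_tables[0].reference
    npos = len(score_tables[0].data)
    for t in score_tables:
        if t.reference != ref or len(t.data) != npos:
            raise InvalidArgumentError("score tables must be aligned to the same reference")

    half = (context_width - 1) // 2
    ctx_offsets = list(range(-half, half + 1))
    channel_offsets: dict[str, list[int]] = {
        "M": {"mismatch": [0]},
        "MDI": {"mismatch": [0], "deletion": [0], "insertion": [0]},
        "M_Con_DI": {"mismatch": ctx_offsets, "deletion": [0], "insertion": [0]},
        "MDI_Con": {"mismatch": ctx_offsets, "deletion": ctx_offsets, "insertion": ctx_offsets},
    }[set_name]

    blocks = []
    names = []
    for table in score_tables:
        for channel, offsets in channel_offsets.items():
            scores = table.data.set_index("pos")[_SCORE_COL[channel]]
            cols = _context_columns(scores, offsets)
            if sum_context and len(offsets) > 1:
                blocks.append(cols.sum(axis=1, keepdims=True))
                names.append(f"{table.comparison_id}|{channel}|ctxsum")
            else:
                blocks.append(cols)
                names.extend(f"{table.comparison_id}|{channel}|off{o:+d}" for o in offsets)
    X = pd.DataFrame(
        np.hstack(blocks), index=score_tables[0].data["pos"].to_numpy(), columns=names
    )
    X.index.name = "pos"
    keep = ~X.isna().any(axis=1)
    dropped = X.index[~keep].tolist()
    X = X.loc[keep]
    X.attrs["feature_set"] = set_name
    X.attrs["dropped_positions"] = dropped
    return X
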