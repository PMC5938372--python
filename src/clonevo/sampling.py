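"""Biopsy saturation curves and the two-biopsy downsampling simulation.

Saturation: for each subset size s, the mean number of distinct events
detected in at least one of s biopsies, enumerated exhaustively when
C(n, s) is below a cap (default 18 million) and by Monte-Carlo draws of
subsets with possible repetition otherwise.

Downsampling: over all C(n, 2) biopsy pairs, the mean number of events
missed by both members ("false negatives") and the mean number of
events subclonal in the full biopsy set but present in both members
("illusion of clonality").
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd

__all__ = ["saturation_curve", "biopsies_for_detection", "downsample_pairs"]


def saturation_curve(
    presence: pd.DataFrame,
    max_subsets: int = 18_000_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean distinct events detected per biopsy-subset size.

    ``presence`` is a binary events × biopsies frame.  For each size
    s = 1..n the mean is exhaustive over all C(n, s) subsets when
    C(n, s) < ``max_subsets`` (strict), else over ``max_subsets`` random
    subsets drawn with possible repetition (requires ``rng``).

    Returns a frame with columns size, mean_detected, mode.
    """
    mat = presence.to_numpy(dtype=bool)
    n = mat.shape[1]
    if n < 1:
        raise ValueError("saturation_curve requires at least one biopsy")
    rows = []
    for s in range(1, n + 1):
        total = comb(n, s)
        if total < max_subsets:
            acc = 0
            for cols in itertools.combinations(range(n), s):
                acc += int(mat[:, cols].any(axis=1).sum())
            mean = acc / total
            mode = "exhaustive"
        else:
            if rng is None:
                raise ValueError("Monte-Carlo saturation mode requires an rng")
            acc = 0
            # chunked to bound memory at large draw counts; each row of
            # the random matrix yields one subset without replacement
            remaining = max_subsets
            while remaining > 0:
                chunk = min(remaining, 50_000)
                cols = np.argsort(rng.random((chunk, n)), axis=1)[:, :s]
                detected = mat[:, cols].any(axis=2)  # events × chunk
                acc += int(detected.sum())
                remaining -= chunk
            mean = acc / max_subsets
            mode = "monte_carlo"
        rows.append({"size": s, "mean_detected": mean, "mode": mode})
    return pd.DataFrame(rows, columns=["size", "mean_detected", "mode"])


def biopsies_for_detection(curve: pd.DataFrame, threshold: float) -> int:
    """Smallest subset size whose mean detected fraction of all events
    reaches ``threshold`` (relative to the full-set count)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    total = float(curve["mean_detected"].iloc[-1])
    if total == 0:
        return 1
    for rec in curve.itertuples():
        if rec.mean_detected / total >= threshold:
            return int(rec.size)
    return int(curve["size"].iloc[-1])


def downsample_pairs(
    presence: pd.DataFrame,
    tumor_clonality: pd.Series,
) -> tuple[float, float]:
    """Two-biopsy error rates for one tumor.

    ``presence`` is events × biopsies binary; ``tumor_clonality`` gives
    clonal/subclonal per event (full-set determination).  Returns
    (mean_missed, mean_illusion) over all biopsy pairs: events absent
    from both members, and events subclonal in the full set but present
    in both members.
    """
    mat = presence.to_numpy(dtype=bool)
    n = mat.shape[1]
    if n < 2:
        raise ValueError("downsample_pairs requires at least two biopsies")
    subclonal = (
        tumor_clonality.loc[presence.index].to_numpy()
        == "subclonal"
    )
    missed_total = 0
    illusion_total = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        in_either = mat[:, i] | mat[:, j]
        in_both = mat[:, i] & mat[:, j]
        missed_total += int((~in_either).sum())
        illusion_total += int((in_both & subclonal).sum())
        n_pairs += 1
    return missed_total / n_pairs, illusion_total / n_pairs
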