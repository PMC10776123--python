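"""Muscle fiber cross-sectional-area categories and per-category sampling.

Fibers are small below 1000 um^2, medium between 1000 and 2600 um^2
(inclusive on both ends), and large above 2600 um^2.  A seeded sampler
draws a fixed number of fibers per category for downstream manual
scoring, taking everything (with a flag) when a category is exhausted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FIBER_CATEGORIES", "classify_fibers", "sample_per_category"]

FIBER_CATEGORIES = ("small", "medium", "large")
SMALL_MAX = 1000.0   # exclusive
LARGE_MIN = 2600.0   # exclusive


def classify_fibers(areas):
    """Categorize fiber areas (um^2) and tally the categories.

    Returns ``(fibers, counts)``: a DataFrame with ``fiber_id``, ``area``
    and ``category``, and a dict of per-category counts.  Boundary areas
    1000 and 2600 are medium.  Nonpositive areas are an error naming the
    offending index.
    """
    if isinstance(areas, pd.Series):
        ids = list(areas.index)
        arr = areas.to_numpy(float)
    else:
        arr = np.asarray(list(areas), float)
        ids = list(range(len(arr)))
    bad = np.where(arr <= 0)[0]
    if len(bad):
        raise ValueError(f"nonpositive fiber area at index {ids[bad[0]]}")
    cats = np.where(arr < SMALL_MAX, "small", np.where(arr <= LARGE_MIN, "medium", "large"))
    fibers = pd.DataFrame({"fiber_id": ids, "area": arr, "category": cats})
    counts = {c: int((cats == c).sum()) for c in FIBER_CATEGORIES}
    return fibers, counts


def sample_per_category(fibers: pd.DataFrame, n_per_category: int, seed: int):
    """Uniform without-replacement sample of fibers from each size category.

    Deterministic given the seed.  Categories holding fewer fibers than
    requested contribute everything and are flagged.  Returns
    ``(sample, exhausted)`` with ``exhausted`` the set of short categories.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    chunks = []
    exhausted = set()
    for cat in FIBER_CATEGORIES:
        pool = fibers[fibers["category"] == cat]
        if len(pool) <= n_per_category:
            if len(pool) < n_per_category:
                exhausted.add(cat)
            chunks.append(pool)
        else:
            pick = rng.choice(len(pool), size=n_per_category, replace=False)
            chunks.append(pool.iloc[np.sort(pick)])
    sample = pd.concat(chunks) if chunks else fibers.iloc[:0]
    return sample.reset_index(drop=True), exhausted
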