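"""Deduplication of putative metabolite identifications and log transforms."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import AbundanceTable

logger = logging.getLogger(__name__)


def deduplicate(table: AbundanceTable, tie_metric: str = "mean") -> AbundanceTable:
    """Keep one record per putative name: highest confidence wins.

    Confidence ties are broken by maximum intensity — by default the mean
    intensity across all samples (``tie_metric="mean"``); ``"max"`` uses the
    single largest value instead.  Remaining ties fall back to metabolite_id
    order, making the result deterministic.  Idempotent.
    """
    if table.scale != "raw":
        raise ValueError("deduplicate expects a raw-scale table")
    if tie_metric not in ("mean", "max"):
        raise ValueError(f"tie_metric must be 'mean' or 'max', got {tie_metric!r}")
    intensity = (
        table.values.mean(axis=1) if tie_metric == "mean" else table.values.max(axis=1)
    )
    rank = pd.DataFrame(
        {
            "name": table.metabolites["putative_name"],
            "confidence": table.metabolites["confidence"],
            "intensity": intensity,
        }
    )
    keep = (
        rank.sort_values(
            ["name", "confidence", "intensity"],
            ascending=[True, False, False],
            kind="stable",
        )
        .groupby("name", sort=False)
        .head(1)
        .index
    )
    keep = [m for m in table.values.index if m in set(keep)]  # original order
    dropped = table.n_metabolites - len(keep)
    if dropped:
        logger.info("deduplicate: dropped %d duplicate record(s)", dropped)
    return AbundanceTable(
        table.values.loc[keep],
        table.metabolites.loc[keep],
        table.samples,
        table.scale,
    )


def log_transform(
    table: AbundanceTable, base: int = 2, zero_policy: str = "half_min"
) -> AbundanceTable:
    """Log-transform raw intensities (base 2 for trend work, 10 for comparative).

    Zeros are either an error (``zero_policy="error"``) or imputed as half
    the smallest positive intensity of that metabolite before the log
    (``"half_min"``, default).
    """
    if table.scale != "raw":
        raise ValueError("log_transform expects a raw-scale table")
    if base not in (2, 10):
        raise ValueError(f"base must be 2 or 10, got {base}")
    if zero_policy not in ("error", "half_min"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    values = table.values.to_numpy(float).copy()
    zero_rows = np.where((values == 0).any(axis=1))[0]
    if len(zero_rows):
        if zero_policy == "error":
            met = table.values.index[zero_rows[0]]
            raise ValueError(f"zero intensity for metabolite {met!r} with zero_policy='error'")
        n_imputed = 0
        for i in zero_rows:
            row = values[i]
            positive = row[row > 0]
            if len(positive) == 0:
                met = table.values.index[i]
                raise ValueError(
                    f"metabolite {met!r} is zero in every sample; cannot impute"
                )
            n_imputed += int((row == 0).sum())
            row[row == 0] = positive.min() / 2.0
        logger.info("log_transform: imputed %d zero value(s) as half-minimum", n_imputed)

    out = np.log2(values) if base == 2 else np.log10(values)
    frame = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return table.with_values(frame, scale=f"log{base}")
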