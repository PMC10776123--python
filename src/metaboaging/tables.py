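"""Core tabular container for metabolite abundance data.

An :class:`AbundanceTable` bundles three aligned pandas objects: the
intensity matrix (metabolites x samples), per-metabolite records
(putative name and identification confidence), and per-sample metadata
(ordered group label and replicate index).  The ``scale`` attribute
tracks whether intensities are raw or log-transformed; transforms are
one-way (raw -> log2 or raw -> log10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALES = ("raw", "log2", "log10")


def make_sample_frame(
    sample_ids, groups, group_order=None, replicate_index=None
) -> pd.DataFrame:
    """Build a validated sample-metadata frame.

    ``groups`` become an ordered categorical; the order is ``group_order``
    when given, otherwise order of first appearance.
    """
    sample_ids = list(sample_ids)
    groups = list(groups)
    if len(sample_ids) != len(groups):
        raise ValueError("sample_ids and groups differ in length")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    cat = pd.Categorical(groups, categories=list(group_order), ordered=True)
    if cat.isna().any():
        missing = sorted({g for g, c in zip(groups, cat.codes) if c < 0})
        raise ValueError(f"groups not in group_order: {missing}")
    if replicate_index is None:
        counters: dict = {}
        replicate_index = []
        for g in groups:
            counters[g] = counters.get(g, 0) + 1
            replicate_index.append(counters[g])
    frame = pd.DataFrame(
        {"group": cat, "replicate_index": np.asarray(replicate_index, dtype=int)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = frame["group"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"each group needs at least 2 samples; too few in: {sorted(thin.index)}"
        )
    return frame


@dataclass
class AbundanceTable:
    """Metabolite intensity matrix with aligned metabolite/sample metadata.

    Parameters
    ----------
    values
        DataFrame of intensities, index = metabolite_id, columns = sample_id.
    metabolites
        DataFrame indexed by metabolite_id with columns ``putative_name``
        and ``confidence`` (identification confidence score, >= 0).
    samples
        DataFrame indexed by sample_id with columns ``group`` (ordered
        categorical) and ``replicate_index``.
    scale
        One of ``raw``, ``log2``, ``log10``.
    """

    values: pd.DataFrame
    metabolites: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.equals(self.metabolites.index):
            raise ValueError("values index does not match metabolite records")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns do not match sample metadata")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"NaN intensity for metabolite {self.values.index[i]!r} "
                f"in sample {self.values.columns[j]!r}"
            )
        if self.scale == "raw" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative raw intensity for metabolite {self.values.index[i]!r} "
                f"in sample {self.values.columns[j]!r}"
            )
        for col in ("putative_name", "confidence"):
            if col not in self.metabolites.columns:
                raise ValueError(f"metabolite records lack column {col!r}")
        if (self.metabolites["confidence"].to_numpy() < 0).any():
            raise ValueError("confidence scores must be >= 0")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_order(self) -> list:
        return list(self.samples["group"].cat.categories)

    def group_columns(self) -> dict:
        """Map each group label to the list of its sample ids, in order."""
        return {
            g: list(self.samples.index[self.samples["group"] == g])
            for g in self.group_order
        }

    def group_arrays(self, metabolite_id) -> list:
        """Per-group intensity vectors for one metabolite, in group order."""
        row = self.values.loc[metabolite_id]
        return [row[cols].to_numpy(float) for cols in self.group_columns().values()]

    def with_values(self, values: pd.DataFrame, scale=None) -> "AbundanceTable":
        return replace(self, values=values, scale=self.scale if scale is None else scale)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.values.copy(), self.metabolites.copy(), self.samples.copy(), self.scale
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable({self.n_metabolites} metabolites x "
            f"{self.n_samples} samples, groups={self.group_order}, scale={self.scale})"
        )
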