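"""Reading and writing of abundance tables, survival data and networks.

All tabular formats are plain CSV/TSV (delimiter sniffed from the file
extension, overridable); networks are written as GraphML or whitespace
edge lists.  Every validation error names the offending record.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .mortality import SurvivalData
from .tables import AbundanceTable, make_sample_frame

_META_COLS = ("metabolite_id", "putative_name", "confidence")


def _sep_for(path, sep=None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_abundance_table(path, meta_path, sep=None, group_order=None) -> AbundanceTable:
    """Read an intensity table plus sample metadata.

    The abundance file must have columns ``metabolite_id, putative_name,
    confidence`` followed by one column per sample.  The metadata file maps
    every ``sample_id`` to a ``group`` (and optionally ``replicate_index``);
    group order is taken from ``group_order`` or first appearance in the
    metadata file.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path, sep))
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{meta_path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    known = set(meta["sample_id"].astype(str))
    for s in sample_cols:
        if str(s) not in known:
            raise ValueError(f"sample {s!r} has no metadata mapping")
    meta = meta.set_index("sample_id").loc[[str(s) for s in sample_cols]]

    values = df[sample_cols].copy()
    for col in sample_cols:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna()
        if bad.any():
            row = df.loc[bad.idxmax(), "metabolite_id"]
            raise ValueError(
                f"non-numeric intensity for metabolite {row!r} in column {col!r}"
            )
        if numeric.isna().any():
            row = df.loc[numeric.isna().idxmax(), "metabolite_id"]
            raise ValueError(f"missing intensity for metabolite {row!r} in column {col!r}")
        values[col] = numeric.astype(float)
    values.index = pd.Index(df["metabolite_id"].astype(str), name="metabolite_id")

    metabolites = pd.DataFrame(
        {
            "putative_name": df["putative_name"].astype(str).to_numpy(),
            "confidence": pd.to_numeric(df["confidence"]).to_numpy(float),
        },
        index=values.index,
    )
    samples = make_sample_frame(
        [str(s) for s in sample_cols],
        meta["group"].tolist(),
        group_order=group_order,
        replicate_index=meta["replicate_index"].tolist()
        if "replicate_index" in meta.columns
        else None,
    )
    return AbundanceTable(values, metabolites, samples, scale="raw")


def write_abundance_table(table: AbundanceTable, path, meta_path, sep=None) -> None:
    """Write a table and its sample metadata in the layout read_abundance_table expects."""
    out = table.metabolites.reset_index()[list(_META_COLS)].copy()
    out = pd.concat([out, table.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=_sep_for(path, sep), index=False)
    meta = table.samples.reset_index()
    meta.to_csv(meta_path, sep=_sep_for(meta_path, sep), index=False)


def read_survival(path, sep=None) -> SurvivalData:
    """Read survival data as per-individual death weeks or weekly alive counts.

    Accepted layouts: a ``death_week`` column (one row per animal, optional
    0/1 ``censored`` column), or ``week`` and ``alive`` columns.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.empty:
        raise ValueError(f"{path}: empty survival file")
    cols = set(df.columns)
    if "death_week" in cols:
        weeks = pd.to_numeric(df["death_week"]).to_numpy(float)
        if (weeks < 0).any():
            raise ValueError("negative death week")
        censored = (
            df["censored"].astype(int).to_numpy().astype(bool)
            if "censored" in cols
            else np.zeros(len(weeks), dtype=bool)
        )
        return SurvivalData.from_death_weeks(
            weeks[~censored], censor_weeks=weeks[censored]
        )
    if {"week", "alive"} <= cols:
        weeks = pd.to_numeric(df["week"]).to_numpy(float)
        alive = pd.to_numeric(df["alive"]).to_numpy(float)
        return SurvivalData.from_alive_counts(weeks, alive)
    raise ValueError(
        f"{path}: expected a 'death_week' column or 'week'+'alive' columns; "
        f"found {sorted(cols)}"
    )


def write_survival(data: SurvivalData, path, sep=None) -> None:
    weeks = np.concatenate([data.death_weeks, data.censor_weeks])
    censored = np.concatenate(
        [np.zeros(len(data.death_weeks), int), np.ones(len(data.censor_weeks), int)]
    )
    order = np.argsort(weeks, kind="stable")
    pd.DataFrame({"death_week": weeks[order], "censored": censored[order]}).to_csv(
        path, sep=_sep_for(path, sep), index=False
    )


NETWORK_FORMATS = ("graphml", "edge_list")


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-abundance network; edge attributes r and p_adj kept to 6 s.f."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")
    if format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(net.nodes(data=True))
        for u, v, d in net.edges(data=True):
            attrs = {
                k: float(f"{val:.6g}") if isinstance(val, float) else val
                for k, val in d.items()
            }
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, path)
        return
    with open(path, "w") as fh:
        fh.write("# source target r p_adj\n")
        for u, v, d in net.edges(data=True):
            a, b = sorted((str(u), str(v)))
            fh.write(f"{a} {b} {d.get('r', float('nan')):.6g} {d.get('p_adj', float('nan')):.6g}\n")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")
    if format == "graphml":
        return nx.read_graphml(path)
    net = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, r, p = line.split()
            net.add_edge(u, v, r=float(r), p_adj=float(p))
    return net
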