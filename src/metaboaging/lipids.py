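"""Lipid shorthand parsing, class totals and acylcarnitine chain bins.

Names of the form ``CLASS(C:D)`` (e.g. ``TG(52:2)``) are parsed into a
lipid class, total acyl carbons and double bonds.  Acylcarnitines
(``CAR(n:d)`` or ``<acyl>carnitine Cn``) additionally receive a chain
bin: short (C2-C6), medium (C7-C12) or long (C13-C22).  Anything
unrecognized falls back to ``OTHER`` — parsing never raises.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable
from .trends import TREND_GROUPS

logger = logging.getLogger(__name__)

LIPID_CLASSES = ("TG", "DG", "PC", "PE", "PI", "PS", "PG", "FA", "CER", "ACAR", "OTHER")

_PREFIX_MAP = {
    "TG": "TG",
    "TAG": "TG",
    "DG": "DG",
    "DAG": "DG",
    "PC": "PC",
    "PE": "PE",
    "PI": "PI",
    "PS": "PS",
    "PG": "PG",
    "FA": "FA",
    "CER": "CER",
    "CAR": "ACAR",
    "ACAR": "ACAR",
}

_SHORTHAND = re.compile(r"^\s*([A-Za-z]+)\s*\(\s*(\d+)\s*:\s*(\d+)\s*\)")
_CARNITINE = re.compile(r"carnitine\b.*?\bC(\d+)\b", re.IGNORECASE)


@dataclass(frozen=True)
class LipidAnnotation:
    lipid_class: str
    carbons: int | None = None
    double_bonds: int | None = None
    chain_bin: str | None = None  # acylcarnitines only


def chain_length_bin(carbons: int) -> str | None:
    """Acylcarnitine chain bin: short C2-C6, medium C7-C12, long C13-C22."""
    if 2 <= carbons <= 6:
        return "short"
    if 7 <= carbons <= 12:
        return "medium"
    if 13 <= carbons <= 22:
        return "long"
    return None


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse a lipid shorthand name; unrecognized names map to OTHER."""
    if not isinstance(name, str):
        return LipidAnnotation("OTHER")
    m = _SHORTHAND.match(name)
    if m:
        cls = _PREFIX_MAP.get(m.group(1).upper())
        if cls is not None:
            carbons, dbl = int(m.group(2)), int(m.group(3))
            bin_ = chain_length_bin(carbons) if cls == "ACAR" else None
            return LipidAnnotation(cls, carbons, dbl, bin_)
    m = _CARNITINE.search(name)
    if m:
        carbons = int(m.group(1))
        return LipidAnnotation("ACAR", carbons, None, chain_length_bin(carbons))
    return LipidAnnotation("OTHER")


def annotate(names) -> pd.Series:
    """Vector version of :func:`parse_lipid_name` over an id -> name mapping."""
    if isinstance(names, pd.Series):
        return names.map(parse_lipid_name)
    return pd.Series({k: parse_lipid_name(v) for k, v in dict(names).items()})


def _classes_for(index, annotations) -> pd.Series:
    ann = annotations
    if not isinstance(ann, pd.Series):
        ann = pd.Series(dict(ann))
    cls = ann.map(
        lambda a: a.lipid_class if isinstance(a, LipidAnnotation) else str(a)
    )
    cls = cls.reindex(index)
    missing = cls.isna()
    if missing.any():
        logger.info("%d metabolite(s) lack annotation; counted as OTHER", missing.sum())
        cls = cls.fillna("OTHER")
    return cls


def class_totals(
    table: AbundanceTable,
    trend_calls: pd.DataFrame,
    annotations,
    alpha: float = 0.05,
    statistic: str = "sum",
) -> pd.DataFrame:
    """Per-class, per-group totals of raw peak intensities.

    Only metabolites with ANOVA p < alpha ("significantly altered")
    contribute; classes without qualifying species report zeros.
    ``statistic="mean"`` reports per-group means of the summed class
    signal divided by replicate count instead of plain sums.
    """
    if table.scale != "raw":
        raise ValueError("class totals are computed on raw peak intensities")
    if statistic not in ("sum", "mean"):
        raise ValueError("statistic must be 'sum' or 'mean'")
    cls = _classes_for(table.values.index, annotations)
    sig = trend_calls["anova_p"].reindex(table.values.index) < alpha
    cols = table.group_columns()
    rows = []
    for c in LIPID_CLASSES:
        members = table.values.index[(cls == c) & sig]
        rec = {"lipid_class": c, "n_metabolites_included": len(members)}
        for g, samples in cols.items():
            block = table.values.loc[members, samples].to_numpy(float)
            total = float(block.sum())
            rec[str(g)] = total / len(samples) if statistic == "mean" else total
        rows.append(rec)
    return pd.DataFrame(rows).set_index("lipid_class")


def class_trend_distribution(trend_calls: pd.DataFrame, annotations) -> pd.DataFrame:
    """Contingency of lipid class x trend group; marginals equal class sizes."""
    cls = _classes_for(trend_calls.index, annotations)
    out = pd.DataFrame(
        0, index=pd.Index(LIPID_CLASSES, name="lipid_class"), columns=list(TREND_GROUPS)
    )
    for c, g in zip(cls, trend_calls["trend_group"]):
        out.loc[c, g] += 1
    return out
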