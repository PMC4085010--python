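"""Aggregation layer: resistance ranking, group statistics, and correlations.

Links the kinetics outputs (D50, I_sat, t1, t2) to the structural
descriptors: ranks fragments by D50, classifies them into
sensitive/intermediate/resistant groups, computes group means of any
descriptor over fragment × run cells, native-vs-reduced deltas, and Spearman
rank correlations between resistance and descriptors.

Display convention: values are truncated (not rounded) at presentation —
RMSD to 2 decimals, occupancy and D50 to integers — which is how the
reference tables print their group statistics (e.g. a 1.3266 Å mean printed
as 1.32).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def truncate(x: float, decimals: int = 0) -> float:
    """Truncate toward zero at the given number of decimals."""
    f = 10.0 ** decimals
    return math.trunc(x * f) / f


def rank_by_d50(table: pd.DataFrame, form: Optional[str] = None) -> pd.DataFrame:
    """Fragments in descending D50 order (most resistant first).

    Expects columns ``fragment`` and ``d50_gy`` (optionally ``form`` to
    filter). Ties break lexicographically by fragment name; undefined (NaN)
    D50 sorts last and is flagged in the ``d50_defined`` column.
    """
    df = table.copy()
    if form is not None:
        df = df[df["form"] == form]
    df = df.drop_duplicates(subset="fragment")
    df["d50_defined"] = df["d50_gy"].notna()
    df["_sort"] = df["d50_gy"].fillna(-np.inf)
    df = df.sort_values(["_sort", "fragment"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns="_sort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def classify_resistance(table: pd.DataFrame, form: Optional[str] = None) -> pd.DataFrame:
    """Attach sensitive/intermediate/resistant labels by D50 terciles.

    The cutoffs are the within-form D50 terciles (the groups were named
    narratively in the original comparison, without numeric thresholds).
    """
    ranked = rank_by_d50(table, form=form)
    d50 = ranked["d50_gy"].astype(float)
    lo, hi = np.nanquantile(d50, [1.0 / 3.0, 2.0 / 3.0])
    def label(v):
        if np.isnan(v):
            return "undefined"
        if v >= hi:
            return "resistant"
        if v <= lo:
            return "sensitive"
        return "intermediate"
    ranked["class"] = [label(v) for v in d50]
    return ranked


def group_mean(
    descriptors: pd.DataFrame,
    fragments: Sequence[str],
    runs: Sequence,
    field: str,
    form: Optional[str] = None,
) -> float:
    """Arithmetic mean of ``field`` over the fragment × run cells.

    Every requested cell must be present; rounding happens only at
    presentation (use :func:`truncate`).
    """
    df = descriptors
    if form is not None:
        df = df[df["form"] == form]
    sel = df[df["fragment"].isin(fragments) & df["run"].isin(runs)]
    expected = len(fragments) * len(runs)
    if len(sel) != expected:
        raise ValueError(
            f"expected {expected} cells for {field}, found {len(sel)}"
        )
    return float(sel[field].mean())


def form_delta(
    descriptors: pd.DataFrame, fragment: str, field: str
) -> tuple:
    """(native mean, reduced mean) of ``field`` for one fragment, over runs."""
    out = []
    for form in ("native", "reduced"):
        sel = descriptors[
            (descriptors["fragment"] == fragment) & (descriptors["form"] == form)
        ]
        if sel.empty:
            raise ValueError(f"no {form} rows for {fragment}")
        out.append(float(sel[field].mean()))
    return tuple(out)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired values")
    return float(spearmanr(x, y).statistic)


def build_resistance_table(
    kinetics_summary: pd.DataFrame, form: Optional[str] = None
) -> pd.DataFrame:
    """Ranked + classified resistance table from a kinetics summary frame.

    Expects one row per fragment (× form) with columns ``fragment``,
    ``d50_gy`` and optionally ``form``, ``t1_gy``, ``t2_gy``, ``isat_pct``
    and CV columns; returns it ranked by D50 with class labels.
    """
    return classify_resistance(kinetics_summary, form=form)


def summary_text(ranked: pd.DataFrame) -> str:
    """Plain-text resistance summary, one line per fragment."""
    lines = ["rank  fragment          D50(Gy)  class"]
    for _, r in ranked.iterrows():
        d50 = "undef" if not r.get("d50_defined", True) else f"{truncate(r['d50_gy']):.0f}"
        lines.append(
            f"{int(r['rank']):>4}  {r['fragment']:<16}  {d50:>7}  {r['class']}"
        )
    return "\n".join(lines)
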