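"""Group statistics and summary tables.

Continuous unit features (duration, rate, amplitude, trough/peak, symmetry)
are compared between surface and depth groups with a two-sided Wilcoxon
rank-sum test; the bursting/non-bursting split with a Pearson chi-square on
the 2x2 contingency table, without continuity correction and df = 1.
Summaries report both group means and medians, bursting fractions formatted
as "k/n = p%", p-values to two significant figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_compare_ranksum",
    "group_compare_chisquare",
    "format_fraction",
    "format_pvalue",
    "summary_tables",
]

FEATURE_ROWS = [
    ("Duration", "duration_ms"),
    ("Spike Rate", "spike_rate_hz"),
    ("Amplitude", "amplitude_uv"),
    ("Trough/Peak", "trough_peak_ratio"),
    ("Symmetry", "symmetry"),
]


def group_compare_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when the smaller sample has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections (the convention of the common
    commercial rank-sum implementations). Average ranks for ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    no_ties = np.unique(np.concatenate((a, b))).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def group_compare_chisquare(table) -> float:
    """Upper-tail p of the Pearson chi-square (df = 1, no continuity
    correction) on a 2x2 contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def format_fraction(k: int, n: int) -> str:
    """Format a count as e.g. ``"14/23 = 61%"`` (percentage to 0 d.p.)."""
    return f"{k}/{n} = {round(100.0 * k / n):.0f}%"


def format_pvalue(p: float) -> str:
    """p-value to two significant figures (e.g. ``0.27``, ``5.0e-06``)."""
    if not np.isfinite(p):
        return "nan"
    return f"{p:.2g}" if p >= 1e-3 else f"{p:.1e}"


def summary_tables(features: pd.DataFrame, pairs: pd.DataFrame | None = None,
                   responses: pd.DataFrame | None = None,
                   pair_correlation: tuple | None = None) -> dict:
    """Assemble publication-style summary tables from pipeline outputs.

    Parameters
    ----------
    features : DataFrame
        One row per unit with columns ``unit_id, group, duration_ms,
        spike_rate_hz, amplitude_uv, trough_peak_ratio, symmetry, bursting``.
    pairs : DataFrame, optional
        Output of :func:`surfspike.pair_analysis.pair_table`.
    responses : DataFrame, optional
        One row per unit with ``group, pearson_r, significant``.
    pair_correlation : (r, p), optional
        Distance-synchrony Pearson correlation across pairs.

    Returns
    -------
    dict of DataFrame
        ``unit_table`` (feature rows: group mean/median + rank-sum p;
        bursting row: "k/n = p%" + chi-square p), ``pair_summary`` and
        ``response_summary``. Empty inputs produce empty tables with
        headers.
    """
    required = {"group", "bursting"} | {c for _, c in FEATURE_ROWS}
    missing = sorted(required - set(features.columns)) if len(features) else []
    if missing:
        raise ValueError(f"features table missing columns: {missing}")

    rows = []
    if len(features):
        surf = features[features.group == "surface"]
        dep = features[features.group == "depth"]
        for name, col in FEATURE_ROWS:
            a, b = surf[col].dropna(), dep[col].dropna()
            p = group_compare_ranksum(a, b) if len(a) and len(b) else float("nan")
            rows.append({
                "statistic": name,
                "surface_mean": a.mean(), "surface_median": a.median(),
                "depth_mean": b.mean(), "depth_median": b.median(),
                "p_value": format_pvalue(p), "test": "Rank sum",
            })
        ks, ns = int(surf.bursting.sum()), len(surf)
        kd, nd = int(dep.bursting.sum()), len(dep)
        table = [[ks, ns - ks], [kd, nd - kd]]
        try:
            p = group_compare_chisquare(table)
        except ValueError:
            p = float("nan")
        rows.append({
            "statistic": "Bursts or Not",
            "surface_mean": format_fraction(ks, ns) if ns else "0/0",
            "surface_median": "", "depth_mean": format_fraction(kd, nd) if nd else "0/0",
            "depth_median": "", "p_value": format_pvalue(p), "test": "Chi-square",
        })
    unit_table = pd.DataFrame(rows, columns=["statistic", "surface_mean", "surface_median",
                                             "depth_mean", "depth_median", "p_value", "test"])

    pair_rows = []
    if pairs is not None and len(pairs) and pair_correlation is not None:
        r, p = pair_correlation
        pair_rows.append({"n_pairs": len(pairs), "pearson_r": r,
                          "p_value": format_pvalue(p),
                          "median_spike_distance": pairs.spike_distance.median(),
                          "median_physical_distance_um": pairs.physical_distance.median()})
    pair_summary = pd.DataFrame(pair_rows, columns=["n_pairs", "pearson_r", "p_value",
                                                    "median_spike_distance",
                                                    "median_physical_distance_um"])

    resp_rows = []
    if responses is not None and len(responses):
        for g, sub in responses.groupby("group"):
            sig = sub[sub.significant.astype(bool)]
            resp_rows.append({"group": g, "n_units": len(sub), "n_significant": len(sig),
                              "median_r": sig.pearson_r.median() if len(sig) else float("nan"),
                              "median_effect_size": sig.effect_size.median()
                              if "effect_size" in sig and len(sig) else float("nan")})
    response_summary = pd.DataFrame(resp_rows, columns=["group", "n_units", "n_significant",
                                                        "median_r", "median_effect_size"])
    return {"unit_table": unit_table, "pair_summary": pair_summary,
            "response_summary": response_summary}
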