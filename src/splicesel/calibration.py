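"""Calibration of splicing pathogenicity scores against selection and burden.

Arbitrary per-(position, alt) score tables are made comparable by splitting
changes into 20 brackets of equal cumulative trinucleotide mutation rate,
bracket 20 holding the most pathogenic scores. Each bracket can then be
summarised by MAPS (selection on standing variants), high-pLI depletion, or
the concentration of de novo mutations (cumulative curve and its AUC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .maps import SingletonCalibration, compute_maps
from .regions import CSS_LABELS

SITE_KEY = ["chrom", "pos", "ref", "alt"]


def mes_percent_difference(ref_score: float, alt_score: float) -> float:
    """Percent reduction of a motif score caused by the alternative allele.

    severity = 100 * (ref - alt) / |ref|; the greatest reduction is the most
    pathogenic, and score gains come out negative.
    """
    if ref_score == 0:
        raise ValueError("reference score must be nonzero")
    return 100.0 * (ref_score - alt_score) / abs(ref_score)


def make_brackets(scores: pd.DataFrame, n_brackets: int = 20) -> pd.DataFrame:
    """Assign changes to brackets of equal cumulative mutation rate.

    ``scores`` needs columns chrom, pos, ref, alt, score (severity; larger =
    more pathogenic) and mutability. Changes are sorted by ascending severity
    (ties broken by site key, deterministically) and accumulated greedily:
    bracket b closes once its cumulative mutability reaches b/n of the total,
    the boundary item staying in the lower bracket. Bracket ``n_brackets``
    therefore holds the most pathogenic scores, and per-bracket mutability
    sums agree to within one maximal single-site rate.
    """
    if n_brackets > len(scores):
        raise ValueError(f"n_brackets={n_brackets} exceeds {len(scores)} items")
    df = scores.sort_values(["score"] + SITE_KEY, kind="mergesort").reset_index(drop=True)
    total = float(df["mutability"].sum())
    if total <= 0:
        raise ValueError("total mutability must be > 0")
    cum = df["mutability"].cumsum().to_numpy()
    quota = total / n_brackets
    brackets = np.empty(len(df), dtype=int)
    b = 1
    for i in range(len(df)):
        brackets[i] = b
        if b < n_brackets and cum[i] >= b * quota:
            b += 1
    df["bracket"] = brackets
    return df


def maps_by_bracket(variants: pd.DataFrame, bracketing: pd.DataFrame,
                    model: SingletonCalibration,
                    exclude_css: bool = False) -> tuple[pd.DataFrame, float]:
    """MAPS per score bracket, with the Spearman trend across brackets.

    Variants are matched to the bracketing by (chrom, pos, ref, alt); sites
    the tool does not score are excluded. With ``exclude_css`` the canonical
    dinucleotide positions are removed before bracketing statistics are
    computed, isolating the noncanonical signal.
    """
    v = variants.merge(bracketing[SITE_KEY + ["bracket"]], on=SITE_KEY, how="inner")
    if exclude_css:
        v = v[~v["label"].isin(CSS_LABELS)]
    rows = []
    for b, grp in v.groupby("bracket"):
        r = compute_maps(grp, model, class_name=f"bracket{b:02d}")
        rows.append({"bracket": b, **vars(r)})
    out = pd.DataFrame(rows)
    rho = float(stats.spearmanr(out["bracket"], out["maps"]).statistic)
    return out, rho


def dnm_auc(dnms: pd.DataFrame, bracketing: pd.DataFrame, n_brackets: int = 20,
            method: str = "trapezoid") -> float:
    """Area under the cumulative de novo curve over score brackets.

    Brackets are walked from most to least pathogenic; x advances by 1/n per
    bracket and y is the cumulative fraction of de novo mutations seen so
    far, anchored at (0, 0). ``method`` selects trapezoidal (default) or
    rectangular (right-endpoint) integration. A score concentrating every
    mutation in the top bracket gives 0.975 (trapezoid); a completely
    uninformative one tends to 0.5.
    """
    d = dnms.merge(bracketing[SITE_KEY + ["bracket"]], on=SITE_KEY, how="inner")
    if len(d) == 0:
        raise ValueError("no de novo mutations overlap the bracketing")
    counts = d["bracket"].value_counts()
    total = counts.sum()
    y = np.zeros(n_brackets + 1)
    for i, b in enumerate(range(n_brackets, 0, -1), start=1):
        y[i] = y[i - 1] + counts.get(b, 0) / total
    x = np.arange(n_brackets + 1) / n_brackets
    if method == "trapezoid":
        return float(np.trapezoid(y, x))
    if method == "rectangular":
        return float(np.sum(y[1:]) / n_brackets)
    raise ValueError(f"unknown AUC method {method!r}")


def compare_tools(dnms: pd.DataFrame, scores_by_tool: dict[str, pd.DataFrame],
                  rates, n_brackets: int = 20,
                  exclude_css: bool = False,
                  labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """AUC per tool on the de novo mutations scored by every compared tool.

    Each tool's table (chrom, pos, ref, alt, score) is bracketed on its own
    coverage; the de novo set is restricted to changes covered by all tools
    so the AUCs are directly comparable. ``labels`` (an annotated position
    table) is required when ``exclude_css`` is set.
    """
    bracketings = {}
    common = None
    for tool, sc in scores_by_tool.items():
        sc = sc.copy()
        if "mutability" not in sc.columns:
            sc["mutability"] = rates.mutability(sc["context"], sc["alt"])
        if exclude_css:
            if labels is None:
                raise ValueError("labels required to exclude CSS positions")
            lab = sc.merge(labels[["chrom", "pos", "label"]], on=["chrom", "pos"], how="left")
            sc = sc[~lab["label"].isin(CSS_LABELS).to_numpy()]
        bracketings[tool] = make_brackets(sc, n_brackets)
        keys = set(map(tuple, sc[SITE_KEY].itertuples(index=False)))
        common = keys if common is None else common & keys
    keep = dnms[[tuple(t) in common for t in dnms[SITE_KEY].itertuples(index=False)]]
    rows = []
    for tool, br in bracketings.items():
        rows.append({"tool": tool, "n_dnms": len(keep),
                     "auc": dnm_auc(keep, br, n_brackets)})
    return pd.DataFrame(rows)
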