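"""Mutability-adjusted proportion of singletons (MAPS) and pLI depletion.

MAPS measures purifying selection on a class of standing variants: the
observed fraction of singletons (allele count 1) minus the fraction predicted
from local sequence context alone. The prediction comes from a weighted
least-squares line fitted to synonymous variants — singleton proportion
against trinucleotide mutability — because more mutable contexts harbour
recurrent mutations that look more common than selection alone would make
them. Positive MAPS means an excess of rare variation, i.e. selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def filter_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep PASS variants with FisherStrand FS < 10 (strict)."""
    keep = (variants["FILTER"] == "PASS") & (variants["FS"] < 10)
    return variants[keep].reset_index(drop=True)


@dataclass
class MAPSResult:
    class_name: str
    n_variants: int
    ps_raw: float
    ps_expected: float
    maps: float
    ci95: float  # +/- half-width on ps_raw (normal approximation)


class SingletonCalibration:
    """Weighted least-squares calibration of singleton proportion on mutability.

    Fitted on synonymous variants grouped by collapsed trinucleotide context:
    one point per context at (mutability, singleton proportion), weighted by
    the context's variant count. Predictions are clipped to [0, 1].
    """

    def __init__(self, intercept: float, slope: float):
        self.intercept = intercept
        self.slope = slope

    @classmethod
    def fit(cls, synonymous: pd.DataFrame, rates=None) -> "SingletonCalibration":
        """Fit from a synonymous variant table with columns context, alt, AC.

        ``rates`` may supply mutabilities; if the table already carries a
        ``mutability`` column it is used directly.
        """
        df = synonymous.copy()
        if "mutability" not in df.columns:
            df["mutability"] = rates.mutability(df["context"], df["alt"])
        if rates is not None:
            df["_ctx"] = rates.collapsed_key(df["context"], df["alt"])
        else:
            df["_ctx"] = df["context"] + ">" + df["alt"]
        grp = df.groupby("_ctx").agg(
            mu=("mutability", "first"),
            ps=("AC", lambda a: (a == 1).mean()),
            n=("AC", "size"),
        )
        if len(grp) < 2:
            raise ValueError("need >= 2 distinct contexts to calibrate")
        X = sm.add_constant(grp["mu"].to_numpy())
        fit = sm.WLS(grp["ps"].to_numpy(), X, weights=grp["n"].to_numpy()).fit()
        return cls(intercept=fit.params[0], slope=fit.params[1])

    def predict(self, mutability) -> np.ndarray:
        """Expected singleton proportion at the given mutabilities, in [0, 1]."""
        return np.clip(self.intercept + self.slope * np.asarray(mutability, float), 0, 1)


def compute_maps(variants: pd.DataFrame, model: SingletonCalibration,
                 class_name: str | None = None) -> MAPSResult:
    """MAPS for one variant class.

    maps = observed singleton proportion - mean predicted proportion; the 95%
    CI half-width is the normal approximation on the raw proportion.
    """
    n = len(variants)
    if n == 0:
        raise ValueError("empty variant class")
    ps_raw = float((variants["AC"] == 1).mean())
    ps_exp = float(model.predict(variants["mutability"]).mean())
    ci95 = 1.96 * np.sqrt(ps_raw * (1 - ps_raw) / n)
    name = class_name if class_name is not None else str(
        variants["class"].iloc[0] if "class" in variants else ""
    )
    return MAPSResult(name, n, ps_raw, ps_exp, ps_raw - ps_exp, float(ci95))


def maps_by_class(variants: pd.DataFrame, model: SingletonCalibration,
                  classes=None) -> pd.DataFrame:
    """MAPS for every class in the table (or the given subset)."""
    rows = []
    for cls, grp in variants.groupby("class"):
        if classes is not None and cls not in classes:
            continue
        rows.append(vars(compute_maps(grp, model, class_name=cls)))
    return pd.DataFrame(rows)


def bootstrap_maps_difference(class_a: pd.DataFrame, class_b: pd.DataFrame,
                              model: SingletonCalibration, B: int = 1000,
                              seed: int = 0) -> float:
    """One-sided bootstrap p-value for maps(A) > maps(B).

    Each class is resampled with replacement B times; the p-value is the
    +1-smoothed fraction of resampled differences at or below zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(class_a) == 0 or len(class_b) == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)

    def arrays(df):
        singleton = (df["AC"] == 1).to_numpy(float)
        pred = model.predict(df["mutability"])
        return singleton, pred

    sa, pa = arrays(class_a)
    sb, pb = arrays(class_b)
    ia = rng.integers(0, len(sa), size=(B, len(sa)))
    ib = rng.integers(0, len(sb), size=(B, len(sb)))
    maps_a = sa[ia].mean(axis=1) - pa[ia].mean(axis=1)
    maps_b = sb[ib].mean(axis=1) - pb[ib].mean(axis=1)
    delta = maps_a - maps_b
    return float((1 + np.sum(delta <= 0)) / (B + 1))


def pli_depletion(variants: pd.DataFrame, gene_info: pd.DataFrame,
                  threshold: float = 0.9) -> tuple[float, float]:
    """Proportion of a class's variants lying in high-pLI genes, with Wald CI.

    Constrained (high-pLI) genes should be depleted of deleterious variants in
    healthy carriers, so lower values indicate stronger selection.
    """
    pli = variants["gene"].map(gene_info.set_index("gene")["pLI"])
    if pli.isna().any():
        missing = sorted(variants.loc[pli.isna(), "gene"].unique())
        raise KeyError(f"genes without pLI: {missing[:10]}")
    n = len(variants)
    p = float((pli > threshold).mean())
    ci = 1.96 * np.sqrt(p * (1 - p) / n)
    return p, float(ci)
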