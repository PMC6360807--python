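"""De novo mutation burden against the depth-corrected triplet null model.

The expected number of de novo mutations at a site over a cohort of trios is
twice the trio count times the context-specific mutation rate, damped by an
ascertainment factor for poorly covered exons. Observed burdens are tested
with the exact two-sided Poisson test, corrected across cells by
Benjamini-Hochberg, and summarised as fold enrichments and positive
predictive values PPV = (observed - expected) / observed: the estimated
fraction of the observed mutations that are pathogenic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# ascertainment correction, estimated elsewhere from the observed/expected
# ratio of synonymous de novo mutations at different coverage levels
DEPTH_C0 = 0.119
DEPTH_C1 = 0.204
DEPTH_CUTOFF = 50.0


def depth_factor(d: float) -> float:
    """Ascertainment multiplier for an exon of median coverage ``d``.

    Below 1x the factor is flat at 0.119; between 1x and 50x it rises as
    0.119 + 0.204 ln d (capped at 1); at 50x and above no correction applies.
    """
    d = float(d)
    if d < 0:
        raise ValueError(f"depth must be >= 0, got {d}")
    if d < 1:
        return DEPTH_C0
    if d < DEPTH_CUTOFF:
        return min(1.0, DEPTH_C0 + DEPTH_C1 * np.log(d))
    return 1.0


def expected_dnms(changes: pd.DataFrame, rates, n_trios: int,
                  depth: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """Expected de novo count per (position, alt) over ``n_trios`` trios.

    ``changes`` needs columns context and alt (plus whatever identifiers the
    caller wants to aggregate by later); ``depth`` aligns with its rows (a
    column named ``depth`` is used if present, and no correction is applied
    when absent). expected = 2 * n_trios * rate(context, alt) * depth_factor.
    Aggregation over classes is plain summation.
    """
    out = changes.copy()
    mu = rates.mutability(out["context"], out["alt"])
    if depth is None and "depth" in out.columns:
        depth = out["depth"]
    if depth is not None:
        factors = np.array([depth_factor(d) for d in np.asarray(depth, float)])
    else:
        factors = 1.0
    out["expected"] = 2.0 * n_trios * mu * factors
    return out


def poisson_burden_test(observed: int, expected: float) -> float:
    """Exact two-sided Poisson test of an observed count against its mean.

    The p-value sums the probabilities of all counts no more likely than the
    observed one (the same definition as R's two-sided poisson.test), capped
    at 1.
    """
    if expected <= 0:
        raise ValueError(f"expected must be > 0, got {expected}")
    observed = int(observed)
    p_obs = stats.poisson.pmf(observed, expected)
    # enumerate a support wide enough to hold all non-negligible mass
    hi = int(max(observed, stats.poisson.ppf(1 - 1e-16, expected))) + 10
    k = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(k, expected)
    # relative tolerance guards against ties broken by floating-point noise
    p = pmf[pmf <= p_obs * (1 + 1e-10)].sum()
    return float(min(1.0, p))


def fdr_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compute_ppv(observed: float, expected: float) -> float:
    """Positive predictive value (observed - expected) / observed.

    Clamped at 0 when observed <= expected; NaN (undefined) when observed is 0.
    """
    if expected <= 0:
        raise ValueError(f"expected must be > 0, got {expected}")
    if observed < 0:
        raise ValueError(f"observed must be >= 0, got {observed}")
    if observed == 0:
        return float("nan")
    return max(0.0, (observed - expected) / observed)


def enrichment_table(observed_counts: pd.DataFrame, expected: pd.DataFrame,
                     by: list[str] = ("class", "geneset")) -> pd.DataFrame:
    """Observed vs expected burden per cell, with fold, p, FDR and PPV.

    ``observed_counts`` is a de novo record table (one row per mutation);
    ``expected`` is the per-(position, alt) expectation table. Both are
    aggregated over ``by``; every cell with positive expectation is tested
    and all cells are adjusted together in one family.
    """
    by = list(by)
    exp = expected.groupby(by)["expected"].sum()
    obs = observed_counts.groupby(by).size() if len(observed_counts) else pd.Series(dtype=int)
    cells = exp.index
    rows = []
    for key in cells:
        e = float(exp.loc[key])
        o = int(obs.get(key, 0))
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key_t)) | {
            "observed": o,
            "expected": e,
            "fold": o / e if e > 0 else np.nan,
            "p_raw": poisson_burden_test(o, e),
            "ppv": compute_ppv(o, e),
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy())
    return out


def poisson_exact_ci(observed: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean given a count."""
    alpha = 1 - conf
    lo = 0.0 if observed == 0 else stats.chi2.ppf(alpha / 2, 2 * observed) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * observed + 2) / 2
    return float(lo), float(hi)


def pli_sextile_enrichment(per_exon: pd.DataFrame, gene_info: pd.DataFrame,
                           n_groups: int = 6) -> pd.DataFrame:
    """Observed/expected de novo ratio across pLI sextiles of exons.

    ``per_exon`` carries one row per exon with columns gene, observed and
    expected. Exons are ranked by their gene's pLI (ties broken by gene id,
    then exon order) and split into ``n_groups`` groups of near-equal exon
    count (sizes differing by at most one); each group reports observed,
    expected, ratio and the exact Poisson 95% CI on the ratio.
    """
    df = per_exon.copy()
    df["pLI"] = df["gene"].map(gene_info.set_index("gene")["pLI"])
    if df["pLI"].isna().any():
        missing = sorted(df.loc[df["pLI"].isna(), "gene"].unique())
        raise KeyError(f"genes without pLI: {missing[:10]}")
    df = df.sort_values(["pLI", "gene"], kind="mergesort").reset_index(drop=True)
    # near-equal partition: group sizes differ by <= 1
    bounds = np.linspace(0, len(df), n_groups + 1).round().astype(int)
    rows = []
    for g in range(n_groups):
        part = df.iloc[bounds[g]:bounds[g + 1]]
        o = int(part["observed"].sum())
        e = float(part["expected"].sum())
        lo, hi = poisson_exact_ci(o)
        rows.append({
            "sextile": g + 1,
            "n_exons": len(part),
            "pli_min": float(part["pLI"].min()),
            "pli_max": float(part["pLI"].max()),
            "observed": o,
            "expected": e,
            "ratio": o / e if e > 0 else np.nan,
            "ci_lo": lo / e if e > 0 else np.nan,
            "ci_hi": hi / e if e > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def wilson_ci_cc(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction for a proportion.

    Matches R's one-sample prop.test (correct = TRUE) interval.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    q = 1 - p
    denom = 2 * (n + z ** 2)
    lo = (2 * n * p + z ** 2 - 1 - z * np.sqrt(z ** 2 - 2 - 1 / n + 4 * p * (n * q + 1))) / denom
    hi = (2 * n * p + z ** 2 + 1 + z * np.sqrt(z ** 2 + 2 - 1 / n + 4 * p * (n * q - 1))) / denom
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return float(max(0.0, lo)), float(min(1.0, hi))


def diagnostic_proportion(n_css: int, n_noncss: int) -> dict:
    """Share of splice-disrupting diagnoses at canonical sites, with 95% CI.

    Returns the point estimate (and whole-percent rounding) with the score
    interval with continuity correction, for both the canonical share and its
    noncanonical complement.
    """
    if n_css < 0 or n_noncss < 0:
        raise ValueError("counts must be >= 0")
    n = n_css + n_noncss
    if n == 0:
        raise ValueError("at least one diagnosis required")
    p = n_css / n
    lo, hi = wilson_ci_cc(n_css, n)
    lo2, hi2 = wilson_ci_cc(n_noncss, n)
    return {
        "css_proportion": p,
        "css_percent": round(100 * p),
        "css_ci": (lo, hi),
        "noncss_proportion": 1 - p,
        "noncss_percent": round(100 * (1 - p)),
        "noncss_ci": (lo2, hi2),
    }


def ppv_diagnosis_correlation(ppv: np.ndarray | list, diagnosed_fraction) -> tuple[float, float]:
    """Pearson correlation between per-class PPVs and diagnosed fractions."""
    ppv = np.asarray(ppv, float)
    frac = np.asarray(diagnosed_fraction, float)
    if ppv.size < 3:
        raise ValueError("need >= 3 classes for a correlation")
    r, p = stats.pearsonr(ppv, frac)
    return float(r), float(p)
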