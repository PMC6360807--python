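"""Canonical vs noncanonical splice variants in a clinical-database extract.

A flat TSV export of pathogenic / likely-pathogenic records is matched to the
annotated splice positions, exonic sites with protein-altering consequences
are removed (their pathogenicity is plausibly coding, not splicing), and the
canonical fraction is compared — raw and weighted by submission count as a
proxy for allele count — with the cohort-derived diagnostic split.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from .regions import CSS_LABELS, EXONIC_LABELS

_QUALIFYING = {"pathogenic", "likely pathogenic"}
NONSYNONYMOUS = {
    "missense", "missense_variant", "stop_gained", "stop_lost", "start_lost",
    "nonsynonymous", "frameshift_variant", "inframe_deletion", "inframe_insertion",
}


def significance_qualifies(sig: str) -> bool:
    """True if any token of a (possibly composite) significance string is
    pathogenic or likely pathogenic; conflicting-interpretation records never
    qualify."""
    s = sig.strip().lower().replace("_", " ")
    if "conflicting" in s:
        return False
    tokens = [t.strip() for t in re.split(r"[/;,|]", s)]
    return any(t in _QUALIFYING for t in tokens)


def filter_clinvar(records: pd.DataFrame, positions: pd.DataFrame) -> pd.DataFrame:
    """Retain database records usable for the splice-proportion comparison.

    Kept records fall on an annotated splice position, carry qualifying
    clinical significance, and are not exonic with a protein-altering
    consequence. The splice label is joined onto the output.
    """
    lab = records.merge(
        positions[["chrom", "pos", "label"]], on=["chrom", "pos"], how="inner"
    )
    keep = lab["clinical_significance"].map(significance_qualifies)
    exonic_nonsyn = lab["label"].isin(EXONIC_LABELS) & lab.get(
        "consequence", pd.Series("", index=lab.index)
    ).str.lower().isin(NONSYNONYMOUS)
    return lab[keep & ~exonic_nonsyn].reset_index(drop=True)


def canonical_fraction(records: pd.DataFrame, weighted: bool = False) -> dict:
    """Fraction of retained records at canonical splice-site labels.

    With ``weighted`` the fraction uses submission counts as weights (each
    record counted once per submission), mirroring an allele-count proxy.
    """
    if len(records) == 0:
        raise ValueError("no retained records")
    canonical = records["label"].isin(CSS_LABELS).to_numpy(float)
    if weighted:
        w = records["n_submissions"].to_numpy(float)
        frac = float((canonical * w).sum() / w.sum())
    else:
        frac = float(canonical.mean())
    return {"canonical": frac, "noncanonical": 1 - frac}


def proportion_fisher(n_noncss_diag: int, n_css_diag: int,
                      n_noncss_db: int, n_css_db: int) -> dict:
    """Two-sided Fisher exact test comparing the noncanonical share in the
    cohort diagnoses with that in the database records.

    The 2x2 table is [noncanonical, canonical] x [cohort, database]; it is
    returned alongside the p-value so the construction is explicit.
    """
    table = np.array([[n_noncss_diag, n_noncss_db], [n_css_diag, n_css_db]])
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("both margins must be > 0")
    res = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(res.statistic), "p": float(res.pvalue)}
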