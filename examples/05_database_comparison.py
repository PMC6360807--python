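"""Canonical vs noncanonical splice variants in a clinical-database extract.

Builds a synthetic database extract in which noncanonical splice variants are
underrepresented relative to the unbiased cohort-derived split (27%
noncanonical), then quantifies the discrepancy with Fisher's exact test.
"""

import numpy as np
import pandas as pd

from splicesel import (
    SimConfig, canonical_fraction, filter_clinvar, proportion_fisher,
    simulate_study,
)

study = simulate_study(SimConfig(seed=1))
rng = np.random.default_rng(1)

# synthetic extract: database curators over-report canonical sites
pos = study.positions
css = pos[pos["label"].isin(["acc-2", "acc-1", "don+1", "don+2"])].sample(300, random_state=1)
noncss = pos[~pos["label"].isin(["acc-2", "acc-1", "don+1", "don+2"])].sample(45, random_state=2)
records = pd.concat([css, noncss])[["chrom", "pos"]].copy()
records["ref"], records["alt"] = "A", "G"
records["clinical_significance"] = rng.choice(
    ["Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic", "Benign"],
    size=len(records), p=[0.5, 0.25, 0.1, 0.15])
records["n_submissions"] = rng.geometric(0.5, len(records))
records["consequence"] = ""

kept = filter_clinvar(records, study.positions)
raw = canonical_fraction(kept)
wtd = canonical_fraction(kept, weighted=True)
print(f"retained pathogenic records: {len(kept)}")
print(f"noncanonical fraction: {raw['noncanonical']:.3f} raw, "
      f"{wtd['noncanonical']:.3f} submission-weighted")

n_non = int((~kept["label"].isin(["acc-2", "acc-1", "don+1", "don+2"])).sum())
n_css = len(kept) - n_non
res = proportion_fisher(18, 48, n_non, n_css)
print(f"\n2x2 table [noncanonical, canonical] x [cohort diagnoses, database]:")
print(res["table"])
print(f"Fisher exact P = {res['p']:.3g}")
# A small P says the database's noncanonical share falls short of the 27%
# the unbiased trio burden analysis implies: noncanonical splice mutations
# are missing from curated databases.
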