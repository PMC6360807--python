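"""Calibrating pathogenicity score tables against selection and burden.

Splits each tool's scores into 20 brackets of equal cumulative mutation rate
(bracket 20 = most pathogenic), computes MAPS per bracket with its Spearman
trend, and compares tools by the AUC of the cumulative de novo curve,
restricted to mutations scored by every tool.
"""

import dataclasses

from splicesel import (
    SimConfig, SingletonCalibration, compare_tools, filter_variants,
    make_brackets, maps_by_bracket, mes_percent_difference, simulate_study,
    synthetic_rate_table,
)

rates = synthetic_rate_table()
cfg = SimConfig(seed=1)
study = simulate_study(cfg, rates)

# a motif-score tool reports ref/alt scores; its severity is the percent drop
print(f"motif score 10 -> 5 is a {mes_percent_difference(10, 5):.0f}% reduction "
      f"(most pathogenic end); 8 -> 10 is {mes_percent_difference(8, 10):.0f}%")

v = filter_variants(study.variants)
model = SingletonCalibration.fit(v.query("`class` == 'synonymous'"), rates)

sc = study.scores["cadd"].copy()
sc["mutability"] = rates.mutability(study.expected["context"], study.expected["alt"])
br = make_brackets(sc, 20)
per_bracket, rho = maps_by_bracket(v, br, model)
print(f"\nMAPS rises across cadd-like brackets: Spearman rho = {rho:.2f}")
print(per_bracket[["bracket", "n_variants", "maps"]].iloc[[0, 9, 19]]
      .to_string(index=False))

# inflate the cohort's expected counts so the toy de novo set is big enough
# to compare tools on
exp = study.expected.copy()
exp["expected"] *= 40
from splicesel import generate_dnms
dnms = generate_dnms(exp, cfg.fold_by_class_geneset, cfg)
# as in the burden analyses, compare tools on mutations in dominant DD genes,
# where the pathogenic excess lives
dnms = dnms[dnms["geneset"] == "dominant"]
scores = {}
for tool, df in study.scores.items():
    df = df.merge(study.expected[["chrom", "pos", "alt", "context"]].drop_duplicates(),
                  on=["chrom", "pos", "alt"])
    scores[tool] = df
res = compare_tools(dnms, scores, rates)
print(f"\nAUC per tool on {res['n_dnms'].iloc[0]} shared de novo mutations:")
print(res.sort_values("auc", ascending=False).to_string(index=False))
res_x = compare_tools(dnms, scores, rates, exclude_css=True, labels=study.positions)
print("\nexcluding canonical dinucleotides:")
print(res_x.sort_values("auc", ascending=False).to_string(index=False))
# Informative tools concentrate de novo mutations in their top brackets
# (AUC near 1); the drop after removing CSS positions shows how much of a
# tool's signal came from the easy canonical sites.
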