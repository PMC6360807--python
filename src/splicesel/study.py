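"""End-to-end construction of a synthetic splice-site study.

Convenience layer tying the generators to the analysis stages: build a toy
genome, select exons, annotate near-splice positions, and derive the cohort
variant table, the de novo mutation set and the auxiliary tables, all from
one seeded configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import enrichment, simulate
from .config import SimConfig
from .rates import RateTable, synthetic_rate_table
from .regions import (annotate_positions, select_exons, _exon_position_labels,
                      ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC)
from .simulate import SimGenome


@dataclass
class SimStudy:
    """All artifacts of one simulated study."""

    config: SimConfig
    rates: RateTable
    genome: SimGenome
    exons: pd.DataFrame          # selected exons
    positions: pd.DataFrame      # annotated near-splice positions
    gene_info: pd.DataFrame
    depth: pd.DataFrame          # per-exon per-capture coverage
    variants: pd.DataFrame       # cohort variant table
    expected: pd.DataFrame       # per-(position, alt) null expectations
    dnms: pd.DataFrame
    scores: dict                 # tool -> score table


def _acceptor_side(label: str) -> bool:
    return label in set(ACCEPTOR_INTRONIC) | set(ACCEPTOR_EXONIC)


def attach_exon_depth(positions: pd.DataFrame, exons: pd.DataFrame,
                      depth: pd.DataFrame) -> pd.Series:
    """Per-position coverage for the depth correction.

    Each position inherits the capture-averaged median depth of its exon end
    (acceptor-side labels take the acceptor depth, donor-side the donor
    depth). Positions whose exon carries no depth row get NaN.
    """
    d = depth.groupby(["chrom", "start", "end", "strand"])[
        ["depth_acc", "depth_don"]].mean()
    lookup = {}
    for e in exons.itertuples(index=False):
        key = (e.chrom, e.start, e.end, e.strand)
        if key not in d.index:
            continue
        dacc, ddon = d.loc[key]
        for pos, label in _exon_position_labels(e.start, e.end, e.strand):
            lookup[(e.chrom, pos)] = dacc if _acceptor_side(label) else ddon
    return pd.Series(
        [lookup.get((c, p)) for c, p in zip(positions["chrom"], positions["pos"])],
        index=positions.index, dtype=float, name="depth",
    )


def simulate_study(config: SimConfig, rates: RateTable | None = None) -> SimStudy:
    """Generate a full synthetic study from one configuration."""
    if rates is None:
        rates = synthetic_rate_table()
    genome = simulate.generate_genome(config)
    all_genes = sorted({e.gene_id for e in genome.exons})
    gene_info = simulate.generate_gene_info(all_genes, config)

    # depth is drawn for every exon (decoys included) so the coverage filter
    # operates on the same footing as the annotation filters
    all_exons = pd.DataFrame(
        [{"chrom": e.chrom, "start": e.start, "end": e.end, "strand": e.strand}
         for e in genome.exons]
    ).drop_duplicates(ignore_index=True)
    depth = simulate.generate_depth_table(all_exons, config)

    exons = select_exons(genome.exons, depth)
    positions = annotate_positions(exons, genome.sequences)

    variants = simulate.generate_cohort_variants(positions, rates, config, gene_info)

    changes = simulate.candidate_changes(positions, config)
    changes["depth"] = attach_exon_depth(changes, exons, depth).to_numpy()
    changes["geneset"] = changes["gene"].map(gene_info.set_index("gene")["ddg2p"])
    expected = enrichment.expected_dnms(changes, rates, config.n_trios)
    dnms = simulate.generate_dnms(expected, config.fold_by_class_geneset, config)

    scores = simulate.generate_score_tables(changes, config)
    return SimStudy(config=config, rates=rates, genome=genome, exons=exons,
                    positions=positions, gene_info=gene_info, depth=depth,
                    variants=variants, expected=expected, dnms=dnms, scores=scores)
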