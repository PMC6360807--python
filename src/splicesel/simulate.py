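"""Seeded synthetic genomes, cohorts, de novo mutations and auxiliary tables.

Everything here is a generator for the downstream analyses: a toy genome with
GT..AG introns and a pyrimidine-rich polypyrimidine tract, a cohort variant
table whose singleton structure depends on trinucleotide mutability and on
class-specific selection, de novo mutations drawn from the triplet null model
scaled by configurable fold enrichments, and gene/depth/score side tables.

Each output artifact draws from its own RNG stream derived from the master
seed by a fixed label, so adding one generator never shifts another's stream,
and identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .rates import RateTable, revcomp
from .regions import ExonRecord, EXONIC_LABELS, classify_change

_STREAMS = {
    "genome": 11,
    "consequence": 23,
    "deleteriousness": 29,
    "variants": 37,
    "dnms": 41,
    "genes": 43,
    "depth": 47,
    "scores": 53,
}


def _rng(config: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[label]])


def _rand_seq(rng, n) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _pyrimidine_rich(rng, n, p=0.85) -> str:
    py = rng.random(n) < p
    bases = np.where(
        py,
        np.array(list("CT"))[rng.integers(0, 2, n)],
        np.array(list("AG"))[rng.integers(0, 2, n)],
    )
    return "".join(bases)


def _acceptor_tail(rng) -> str:
    """25 intronic bases ending an intron on the transcript strand.

    Layout (acc-25..acc-1): 8 random bases, the pyrimidine-rich tract
    acc-17..acc-5, a random acc-4, a pyrimidine-biased acc-3, then the
    invariant AG dinucleotide.
    """
    return (
        _rand_seq(rng, 8)
        + _pyrimidine_rich(rng, 13)
        + _rand_seq(rng, 1)
        + _pyrimidine_rich(rng, 1)
        + "AG"
    )


def _donor_head(rng) -> str:
    """10 intronic bases opening an intron: GT, then a consensus-biased run."""
    don3 = "AG"[rng.integers(0, 2)]
    don4 = "A" if rng.random() < 0.7 else _rand_seq(rng, 1)
    don5 = "G" if rng.random() < 0.8 else _rand_seq(rng, 1)
    return "GT" + don3 + don4 + don5 + _rand_seq(rng, 5)


@dataclass
class SimGenome:
    """A simulated genome: contig sequences, GTF lines and the true exon set."""

    sequences: dict
    gtf_lines: list
    exons: list  # ExonRecord, decoys included

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("".join(self.gtf_lines))


def _gtf_attrs(gene, tx, level, tags, gene_type="protein_coding",
               tx_type="protein_coding", gene_status="KNOWN", tx_status="KNOWN"):
    parts = [
        f'gene_id "{gene}"',
        f'transcript_id "{tx}"',
        f'gene_type "{gene_type}"',
        f'gene_status "{gene_status}"',
        f'gene_name "{gene}"',
        f'transcript_type "{tx_type}"',
        f'transcript_status "{tx_status}"',
        f"level {level}",
    ]
    parts += [f'tag "{t}"' for t in tags]
    return "; ".join(parts) + ";"


def generate_genome(config: SimConfig) -> SimGenome:
    """Build the toy genome and GENCODE-dialect gene models.

    Every intron starts GT and ends AG on the transcript strand, and each
    gene is flanked by a virtual acceptor tail upstream and donor head
    downstream so that first and last exons also sit in consensus context.
    Genes alternate between the two strands across two contigs. When
    ``config.include_decoys`` is set, filter-failing decoy genes are added:
    annotation level 3, a 13-bp exon, a NOVEL-status transcript and a
    non-coding gene.
    """
    rng = _rng(config, "genome")
    chrom_seqs = {"chr1": ["N" * 0 + _rand_seq(rng, 50)], "chr2": [_rand_seq(rng, 50)]}
    chrom_len = {c: 50 for c in chrom_seqs}
    gtf = []
    exon_records = []

    def place_gene(gene_id, n_exons, strand, level="2", tags=("CCDS", "appris_principal"),
                   gene_type="protein_coding", tx_type="protein_coding",
                   gene_status="KNOWN", tx_status="KNOWN", exon_len_override=None):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        lens = [
            int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            for _ in range(n_exons)
        ]
        if exon_len_override:
            lens[len(lens) // 2] = exon_len_override
        introns = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_exons - 1)
        ]
        # transcript-strand gene body: virtual acceptor tail, exons/introns,
        # virtual donor head
        parts = [_acceptor_tail(rng)]
        tx_exons = []  # 0-based inclusive within gene body
        cursor = 25
        for i, L in enumerate(lens):
            parts.append(_rand_seq(rng, L))
            tx_exons.append((cursor, cursor + L - 1))
            cursor += L
            if i < n_exons - 1:
                body = introns[i] - 35
                parts.append(_donor_head(rng) + _rand_seq(rng, body) + _acceptor_tail(rng))
                cursor += introns[i]
        parts.append(_donor_head(rng))
        gene_seq = "".join(parts)
        G = len(gene_seq)
        offset = chrom_len[chrom]
        placed = gene_seq if strand == "+" else revcomp(gene_seq)
        chrom_seqs[chrom].append(placed + _rand_seq(rng, 100))
        chrom_len[chrom] += G + 100

        tx_id = gene_id + ".T1"
        genomic = []
        for s, e in tx_exons:
            if strand == "+":
                genomic.append((offset + s + 1, offset + e + 1))
            else:
                genomic.append((offset + G - e, offset + G - s))
        g_start = min(s for s, _ in genomic)
        g_end = max(e for _, e in genomic)
        attrs = _gtf_attrs(gene_id, tx_id, level, tags, gene_type, tx_type,
                           gene_status, tx_status)
        gtf.append(f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t{attrs}\n")
        gtf.append(f"{chrom}\tsim\ttranscript\t{g_start}\t{g_end}\t.\t{strand}\t.\t{attrs}\n")
        for s, e in sorted(genomic):
            gtf.append(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")
            exon_records.append(
                ExonRecord(
                    chrom=chrom, start=s, end=e, strand=strand, gene_id=gene_id,
                    transcript_id=tx_id, level=level, gene_type=gene_type,
                    transcript_type=tx_type, gene_status=gene_status,
                    transcript_status=tx_status, tags=frozenset(tags),
                )
            )

    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        place_gene(f"SIMG{i:04d}", n_exons, "+" if i % 2 == 0 else "-")

    if config.include_decoys:
        place_gene("DECOY_LEVEL3", 3, "+", level="3")
        place_gene("DECOY_SHORTEXON", 1, "-", exon_len_override=13)
        place_gene("DECOY_NOVEL", 3, "+", tx_status="NOVEL")
        place_gene("DECOY_NONCODING", 3, "-", gene_type="lincRNA", tx_type="lincRNA")

    sequences = {c: "".join(parts) + "" for c, parts in chrom_seqs.items()}
    return SimGenome(sequences=sequences, gtf_lines=gtf, exons=exon_records)


def candidate_changes(positions: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """All single-nucleotide changes at the annotated positions, with classes.

    Each position contributes its three alternative alleles. Splice classes
    come from :func:`splicesel.regions.classify_change`; variants at exonic
    labels are instead assigned a coding consequence (synonymous / missense /
    stop_gained) by a seeded draw, emulating an external consequence
    annotator. A latent per-change deleteriousness is attached: the class's
    selection coefficient plus a small seeded jitter, which the score
    generator and the purifying-selection machinery both consume.

    Deterministic for a given config; row order is canonical (chrom, pos, alt).
    """
    if positions.empty:
        raise ValueError("empty position set")
    pos = positions.sort_values(["chrom", "pos"]).reset_index(drop=True)
    alts_by_ref = {r: [b for b in "ACGT" if b != r] for r in "ACGT"}
    rep = pos.loc[pos.index.repeat(3)].reset_index(drop=True)
    rep["ref"] = [c[1] for c in rep["context"]]
    rep["alt"] = [a for r in pos["context"].str[1] for a in alts_by_ref[r]]

    cls = [
        classify_change(l, s, r, a)
        for l, s, r, a in zip(rep["label"], rep["strand"], rep["ref"], rep["alt"])
    ]
    rep["splice_class"] = cls
    crng = _rng(config, "consequence")
    conseq = crng.choice(
        ["synonymous", "missense", "stop_gained"], size=len(rep),
        p=list(config.consequence_probs),
    )
    exonic = rep["label"].isin(EXONIC_LABELS).to_numpy()
    rep["class"] = np.where(exonic, conseq, cls)

    drng = _rng(config, "deleteriousness")
    s = rep["class"].map(
        lambda c: config.selection_by_class.get(c, config.selection_default)
    ).to_numpy(float)
    rep["deleteriousness"] = np.clip(s + drng.normal(0, 0.02, len(rep)), 0, 1)
    return rep


def generate_cohort_variants(
    positions: pd.DataFrame,
    rates: RateTable,
    config: SimConfig,
    gene_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the unaffected-carrier cohort's variant table.

    The probability that a site is polymorphic increases with its context
    mutability; allele counts are drawn geometrically so that the neutral
    singleton proportion is a decreasing affine function of mutability, and
    selection inflates each class's singleton probability toward 1 by its
    deleteriousness. If ``gene_info`` is given, deleterious variants are
    additionally purged from high-pLI genes (``config.purge_strength``).
    A configurable fraction of variants receives FS >= 10 or a non-PASS
    FILTER to exercise the quality filters.
    """
    changes = candidate_changes(positions, config)
    rng = _rng(config, "variants")
    mu = rates.mutability(changes["context"], changes["alt"])
    mu_min, mu_max = mu.min(), mu.max()
    mu_mean = mu.mean()

    p_poly = np.minimum(0.95, config.polymorphic_scale * np.sqrt(mu / mu_mean))
    d = changes["deleteriousness"].to_numpy()
    if gene_info is not None:
        pli = changes["gene"].map(gene_info.set_index("gene")["pLI"]).to_numpy(float)
        high = pli > 0.9
        p_poly = p_poly * np.where(high, 1 - config.purge_strength * np.minimum(d, 1), 1.0)
    polymorphic = rng.random(len(changes)) < p_poly
    v = changes[polymorphic].copy()
    mu_v = mu[polymorphic]
    d_v = d[polymorphic]

    # neutral singleton proportion: affine, decreasing in mutability
    ps0 = 0.65 - 0.30 * (mu_v - mu_min) / (mu_max - mu_min)
    ps = ps0 + np.minimum(d_v, 1.0) * (1 - ps0)
    # AC - 1 geometric: P(AC == 1) equals the target singleton probability
    ac = rng.geometric(np.clip(ps, 1e-9, 1.0))
    v["AC"] = np.minimum(ac, 2 * config.n_parents)

    n = len(v)
    fail = rng.random(n) < config.frac_filter_fail
    fs_fail = fail & (rng.random(n) < 0.5)
    filt_fail = fail & ~fs_fail
    v["FS"] = np.where(fs_fail, rng.uniform(10, 60, n), rng.uniform(0, 9.5, n))
    v["FILTER"] = np.where(filt_fail, "LowQual", "PASS")
    v["mutability"] = mu_v
    cols = ["chrom", "pos", "ref", "alt", "AC", "FILTER", "FS", "gene", "class",
            "label", "strand", "in_polypy", "context", "mutability", "deleteriousness"]
    return v[cols].reset_index(drop=True)


def generate_dnms(expected: pd.DataFrame, fold_by_class_geneset: dict,
                  config: SimConfig) -> pd.DataFrame:
    """Draw de novo mutations from the depth-corrected triplet null model.

    ``expected`` must carry one row per candidate (position, alt) with columns
    chrom, pos, ref, alt, gene, class, geneset and expected (the null expected
    count over the whole cohort). The count at each row is Poisson with mean
    ``expected x fold`` for its (class, gene set) cell; unlisted cells have
    fold 1.
    """
    folds = np.array([
        fold_by_class_geneset.get((c, g), 1.0)
        for c, g in zip(expected["class"], expected["geneset"])
    ])
    if (folds < 0).any():
        raise ValueError("fold enrichments must be >= 0")
    rng = _rng(config, "dnms")
    counts = rng.poisson(expected["expected"].to_numpy() * folds)
    idx = np.repeat(np.arange(len(expected)), counts)
    out = expected.iloc[idx][["chrom", "pos", "ref", "alt", "gene", "class", "geneset"]].copy()
    out.insert(0, "proband", [f"P{p:05d}" for p in rng.integers(0, config.n_trios, len(out))])
    return out.reset_index(drop=True)


def generate_gene_info(genes: list[str], config: SimConfig) -> pd.DataFrame:
    """pLI scores and DDG2P category (dominant / recessive / none) per gene."""
    rng = _rng(config, "genes")
    pli = rng.beta(0.25, 0.25, len(genes))  # U-shaped, like real pLI
    u = rng.random(len(genes))
    cat = np.where(
        u < config.frac_dominant, "dominant",
        np.where(u < config.frac_dominant + config.frac_recessive, "recessive", "none"),
    )
    return pd.DataFrame({"gene": genes, "pLI": pli, "ddg2p": cat})


def generate_depth_table(exons: pd.DataFrame, config: SimConfig,
                         captures=("V3", "V5")) -> pd.DataFrame:
    """Per-exon median coverage at each canonical splice end, per capture set.

    Mostly well-covered (15-100x) with a tail of poorly covered exons below
    15x and below 1x, so both branches of the depth correction are exercised.
    """
    rng = _rng(config, "depth")
    rows = []
    for cap in captures:
        n = len(exons)
        def draw():
            u = rng.random(n)
            return np.where(
                u < 0.05, rng.uniform(0, 1, n),
                np.where(u < 0.15, rng.uniform(1, 15, n), rng.uniform(15, 100, n)),
            )
        df = exons[["chrom", "start", "end", "strand"]].copy()
        df["capture"] = cap
        df["depth_acc"] = draw()
        df["depth_don"] = draw()
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_score_tables(changes: pd.DataFrame, config: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-tool pathogenicity score tables over the candidate changes.

    Each tool's score is a monotone transform of the latent deleteriousness
    plus Gaussian noise of sd ``config.score_noise_sd``; tools cover a
    configurable subset of positions (``config.coverage_by_tool``) to mimic
    differing genomic footprints.
    """
    rng = _rng(config, "scores")
    d = changes["deleteriousness"].to_numpy()
    transforms = {
        "adaboost": lambda x: 1 / (1 + np.exp(-8 * (x - 0.15))),
        "randomforest": lambda x: 1 / (1 + np.exp(-6 * (x - 0.2))),
        "spidex": lambda x: 10 * x,
        "cadd": lambda x: 40 * x,
        "mes": lambda x: 100 * x,
    }
    out = {}
    for tool in config.score_tools:
        f = transforms.get(tool, lambda x: x)
        span = abs(f(1.0) - f(0.0)) or 1.0
        # noise sd is expressed as a fraction of the tool's dynamic range so
        # one config value is comparable across tools
        score = f(d) + rng.normal(0, config.score_noise_sd * span, len(d))
        df = changes[["chrom", "pos", "ref", "alt"]].copy()
        df["score"] = score
        frac = config.coverage_by_tool.get(tool, 1.0)
        if frac < 1.0:
            keep = rng.random(len(df)) < frac
            df = df[keep]
        out[tool] = df.reset_index(drop=True)
    return out
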