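"""Splice-relative annotation of exons and near-splice positions.

Exons are drawn from a GENCODE-dialect GTF and filtered stringently (principal,
protein-coding, well-covered); each surviving exon then contributes a fixed
window of near-splice positions labelled relative to its acceptor and donor:
25 bp of intronic sequence upstream of the acceptor (acc-25..acc-1), the first
11 exonic bases (acc..acc+10), the last 11 exonic bases (don-10..don) and 10 bp
of intronic sequence past the donor (don+1..don+10). The polypyrimidine tract
is the acceptor-proximal intronic stretch acc-3 plus acc-5..acc-17.

Coordinates are 1-based inclusive throughout (GTF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .rates import complement

# Splice-relative label vocabulary: intronic acceptor window, exonic acceptor
# window, exonic donor window, intronic donor window.
ACCEPTOR_INTRONIC = [f"acc-{k}" for k in range(25, 0, -1)]
ACCEPTOR_EXONIC = ["acc"] + [f"acc+{k}" for k in range(1, 11)]
DONOR_EXONIC = [f"don-{k}" for k in range(10, 0, -1)] + ["don"]
DONOR_INTRONIC = [f"don+{k}" for k in range(1, 11)]
LABELS = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC + DONOR_EXONIC + DONOR_INTRONIC

CSS_LABELS = frozenset({"acc-2", "acc-1", "don+1", "don+2"})
POLYPY_LABELS = frozenset({"acc-3"} | {f"acc-{k}" for k in range(5, 18)})
EXONIC_LABELS = frozenset(ACCEPTOR_EXONIC + DONOR_EXONIC)

QUALIFYING_TAGS = frozenset(
    {"CCDS", "appris_principal", "appris_candidate_longest", "appris_candidate", "exp_conf"}
)

# offset of each label from the acceptor-side / donor-side anchor, on the
# transcript strand; positive = downstream of the anchor in transcript order
_ACC_OFFSET = {f"acc-{k}": -k for k in range(1, 26)} | {"acc": 0} | {
    f"acc+{k}": k for k in range(1, 11)
}
_DON_OFFSET = {f"don-{k}": -k for k in range(1, 11)} | {"don": 0} | {
    f"don+{k}": k for k in range(1, 11)
}


@dataclass
class ExonRecord:
    """One stringently filtered exon (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    level: str = "2"
    gene_type: str = "protein_coding"
    transcript_type: str = "protein_coding"
    gene_status: str = "KNOWN"
    transcript_status: str = "KNOWN"
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def parse_gtf_exons(path) -> list[ExonRecord]:
    """Parse exon features from a GENCODE-dialect GTF into ExonRecords.

    Raises a ValueError carrying the 1-based line number on a malformed line.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            try:
                feat = feature_from_line(line.rstrip("\n"))
            except Exception as exc:
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attr = feat.attributes

            def one(key, default=""):
                vals = attr.get(key, [default])
                return vals[0] if vals else default

            records.append(
                ExonRecord(
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    gene_id=one("gene_id"),
                    transcript_id=one("transcript_id"),
                    level=one("level"),
                    gene_type=one("gene_type"),
                    transcript_type=one("transcript_type"),
                    gene_status=one("gene_status"),
                    transcript_status=one("transcript_status"),
                    tags=frozenset(attr.get("tag", [])),
                )
            )
    return records


def select_exons(
    exons: list[ExonRecord],
    depth: pd.DataFrame | None = None,
    min_depth: float = 15.0,
    min_length: int = 14,
) -> pd.DataFrame:
    """Apply the stringent exon filters and deduplicate shared exons.

    Kept exons are protein-coding on both gene and transcript, KNOWN status on
    both, not annotation level 3 (automated), carry at least one qualifying
    principal/CCDS tag, are >= ``min_length`` bp, and — when a depth table is
    supplied — have median coverage >= ``min_depth`` at both the acceptor and
    donor canonical positions in every capture set.

    ``depth`` columns: chrom, start, end, strand, capture, depth_acc, depth_don.
    Exons shared between transcripts are deduplicated by (chrom, start, end,
    strand) with their tags unioned before the tag filter is applied.
    """
    merged: dict[tuple, dict] = {}
    for e in exons:
        key = (e.chrom, e.start, e.end, e.strand)
        if key in merged:
            merged[key]["tags"] = merged[key]["tags"] | e.tags
            merged[key]["transcript_ids"].add(e.transcript_id)
            # a duplicate exon qualifies if any copy's annotations qualify
            merged[key]["ok_meta"] = merged[key]["ok_meta"] or _meta_ok(e)
        else:
            merged[key] = {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "gene_id": e.gene_id,
                "transcript_ids": {e.transcript_id},
                "tags": e.tags,
                "ok_meta": _meta_ok(e),
            }
    rows = []
    for m in merged.values():
        if not m["ok_meta"]:
            continue
        if not (m["tags"] & QUALIFYING_TAGS):
            continue
        if m["end"] - m["start"] + 1 < min_length:
            continue
        rows.append(
            {
                "chrom": m["chrom"],
                "start": m["start"],
                "end": m["end"],
                "strand": m["strand"],
                "gene": m["gene_id"],
                "transcripts": ";".join(sorted(m["transcript_ids"])),
                "tags": ";".join(sorted(m["tags"])),
            }
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene", "transcripts", "tags"]
    )
    if depth is not None and len(out):
        d = depth.copy()
        d["ok"] = (d["depth_acc"] >= min_depth) & (d["depth_don"] >= min_depth)
        # all capture sets must pass at both ends
        ok = d.groupby(["chrom", "start", "end", "strand"])["ok"].all()
        keys = pd.MultiIndex.from_frame(out[["chrom", "start", "end", "strand"]])
        passed = ok.reindex(keys).fillna(False).to_numpy()
        out = out[passed].reset_index(drop=True)
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _meta_ok(e: ExonRecord) -> bool:
    return (
        e.gene_type == "protein_coding"
        and e.transcript_type == "protein_coding"
        and e.gene_status == "KNOWN"
        and e.transcript_status == "KNOWN"
        and str(e.level) != "3"
    )


def _exon_position_labels(start: int, end: int, strand: str):
    """Yield (genomic position, label) for one exon's near-splice window."""
    if strand == "+":
        acc_anchor, don_anchor, sign = start, end, 1
    else:
        acc_anchor, don_anchor, sign = end, start, -1
    for label, off in _ACC_OFFSET.items():
        yield acc_anchor + sign * off, label
    for label, off in _DON_OFFSET.items():
        yield don_anchor + sign * off, label


def annotate_positions(exons: pd.DataFrame, genome: dict | "pyfaidx.Fasta") -> pd.DataFrame:
    """Map every near-splice position of the selected exons to its label.

    Any genomic position receiving two or more distinct labels (within one
    short exon or across exons) is dropped entirely, as is any position falling
    outside its contig; the count of out-of-bounds drops is reported via a
    warning. ``tx_ref`` is the reference base on the transcript strand.

    Returns a DataFrame with columns chrom, pos, label, strand, tx_ref,
    in_polypy, gene, context (reference-strand trinucleotide), unique by
    (chrom, pos).
    """
    rows = []
    for e in exons.itertuples(index=False):
        for pos, label in _exon_position_labels(e.start, e.end, e.strand):
            rows.append((e.chrom, pos, label, e.strand, e.gene))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "label", "strand", "gene"])
    df = df.drop_duplicates()

    n_labels = df.groupby(["chrom", "pos"])["label"].transform("nunique")
    df = df[n_labels == 1]
    # a position reachable from two exons with the same label keeps one row
    df = df.drop_duplicates(subset=["chrom", "pos"]).copy()

    seqs = {c: str(genome[c][:]) for c in df["chrom"].unique()}
    lens = {c: len(s) for c, s in seqs.items()}
    # trinucleotide context needs one flanking base on each side
    in_bounds = np.array(
        [2 <= p <= lens[c] - 1 for c, p in zip(df["chrom"], df["pos"])]
    )
    n_oob = int((~in_bounds).sum())
    if n_oob:
        warnings.warn(f"dropped {n_oob} positions outside contig bounds")
    df = df[in_bounds].copy()

    ref = [seqs[c][p - 1] for c, p in zip(df["chrom"], df["pos"])]
    df["tx_ref"] = [
        b if s == "+" else complement(b) for b, s in zip(ref, df["strand"])
    ]
    df["in_polypy"] = df["label"].isin(POLYPY_LABELS)
    df["context"] = [seqs[c][p - 2 : p + 1] for c, p in zip(df["chrom"], df["pos"])]
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)[
        ["chrom", "pos", "label", "strand", "gene", "tx_ref", "in_polypy", "context"]
    ]


def classify_change(label: str | None, strand: str, ref: str, alt: str) -> str:
    """Class of a single-nucleotide change at an annotated position.

    ``ref``/``alt`` are reference-strand alleles; pyrimidine/purine status is
    assessed on the transcript strand ("adjusting for the strand containing
    the exon"). Returns ``"CSS"`` for the canonical dinucleotides,
    ``"polypy_PyPu"`` / ``"polypy_other"`` inside the polypyrimidine tract,
    the splice-relative label itself for other annotated positions, and
    ``"non-splice"`` when the position carries no label.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    if ref == alt:
        raise ValueError("alt equals ref")
    if not label:
        return "non-splice"
    if label in CSS_LABELS:
        return "CSS"
    if label in POLYPY_LABELS:
        tx_ref = ref if strand == "+" else complement(ref)
        tx_alt = alt if strand == "+" else complement(alt)
        if tx_ref in "CT" and tx_alt in "AG":
            return "polypy_PyPu"
        return "polypy_other"
    return label


def composition_matrix(positions: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Transcript-strand base composition per splice-relative label.

    Returns a column-stochastic 4 x n_labels DataFrame (rows A, C, G, T in the
    vocabulary order of :data:`LABELS`) and the consensus string (argmax base
    per column). Labels with no observations are omitted with a warning.
    """
    counts = (
        positions.groupby(["label", "tx_ref"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list("ACGT"), fill_value=0)
    present = [l for l in LABELS if l in counts.index and counts.loc[l].sum() > 0]
    missing = [l for l in LABELS if l not in present]
    if missing:
        warnings.warn(f"omitting {len(missing)} empty label columns: {missing[:5]}...")
    mat = counts.loc[present].T
    mat = mat / mat.sum(axis=0)
    consensus = "".join(mat[l].idxmax() for l in present)
    return mat, consensus
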