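"""Trinucleotide mutation-rate tables.

The de novo mutation null model and the singleton calibration both key on the
per-generation mutation probability of a single-nucleotide change in its local
trinucleotide context. Rates are stored for all 64 reference-strand contexts
times 3 alternative alleles, but lookups collapse strand-complementary changes
onto a pyrimidine-centred key (the standard triplet-model convention), so the
two strands of one mutational event share one rate.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def collapse_context(context: str, alt: str) -> tuple[str, str]:
    """Map (trinucleotide, alt) onto its pyrimidine-centred representative.

    Contexts whose central base is a purine are reverse-complemented together
    with the alternative allele, so e.g. (``"AGA"``, ``"T"``) and
    (``"TCT"``, ``"A"``) collapse to the same key.
    """
    if context[1] in "CT":
        return context, alt
    return revcomp(context), complement(alt)


class RateTable:
    """Per-site, per-generation mutation probabilities by trinucleotide context.

    Parameters
    ----------
    rates
        Mapping or DataFrame with columns ``context`` (64 reference-strand
        trinucleotides), ``alt`` and ``rate``. Rates must be strictly positive
        and strand-complementary entries must agree after collapsing.
    """

    def __init__(self, rates: pd.DataFrame):
        df = rates[["context", "alt", "rate"]].copy()
        if (df["rate"] <= 0).any():
            raise ValueError("all mutation rates must be > 0")
        keys = [collapse_context(c, a) for c, a in zip(df["context"], df["alt"])]
        df["_key"] = [c + ">" + a for c, a in keys]
        spread = df.groupby("_key")["rate"].agg(["min", "max"])
        bad = spread[~np.isclose(spread["min"], spread["max"], rtol=1e-6, atol=0.0)]
        if len(bad):
            raise ValueError(
                f"strand-complementary contexts disagree for keys: {list(bad.index)}"
            )
        self._by_key = df.groupby("_key")["rate"].first().to_dict()
        self.table = df[["context", "alt", "rate"]].reset_index(drop=True)

    def rate(self, context: str, alt: str) -> float:
        """Rate for one (reference-strand trinucleotide, alt) change."""
        c, a = collapse_context(context.upper(), alt.upper())
        key = c + ">" + a
        if key not in self._by_key:
            raise KeyError(f"no rate for context {context}>{alt}")
        return self._by_key[key]

    def mutability(self, contexts, alts) -> np.ndarray:
        """Vectorised lookup; raises listing any missing contexts."""
        keys = ["{}>{}".format(*collapse_context(c, a)) for c, a in zip(contexts, alts)]
        out = np.array([self._by_key.get(k, np.nan) for k in keys])
        if np.isnan(out).any():
            missing = sorted({k for k, v in zip(keys, out) if np.isnan(v)})
            raise KeyError(f"no rate for contexts: {missing[:10]}")
        return out

    def collapsed_key(self, contexts, alts) -> list[str]:
        return ["{}>{}".format(*collapse_context(c, a)) for c, a in zip(contexts, alts)]

    @classmethod
    def from_tsv(cls, path) -> "RateTable":
        """Read a published-format triplet-rate TSV (columns context, alt, rate)."""
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def synthetic_rate_table(seed: int = 916_001) -> RateTable:
    """Bundled synthetic triplet-rate table.

    Rates for the 96 collapsed (pyrimidine-centred context, alt) classes are
    drawn log-uniformly over [1e-9, 1e-7] and expanded to the full 64x3 table
    with strand-complement symmetry enforced, mimicking the dynamic range of
    published human triplet mutation rates. Deterministic for a given seed, so
    the default table is a fixed artifact of the package.
    """
    rng = np.random.default_rng(seed)
    rows = []
    drawn: dict[str, float] = {}
    for l, c, r in itertools.product(BASES, repeat=3):
        context = l + c + r
        for alt in BASES:
            if alt == c:
                continue
            kc, ka = collapse_context(context, alt)
            key = kc + ">" + ka
            if key not in drawn:
                drawn[key] = 10 ** rng.uniform(-9, -7)
            rows.append({"context": context, "alt": alt, "rate": drawn[key]})
    return RateTable(pd.DataFrame(rows))
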