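"""Simulation configuration for the synthetic splice-site cohort."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


def _default_selection() -> dict[str, float]:
    # singleton-inflation coefficients per variant class, mirroring the
    # qualitative ordering of purifying selection around splice sites:
    # stop-gained ~ CSS > don+5 > missense > PolyPy PyPu > other changes
    return {
        "synonymous": 0.0,
        "missense": 0.10,
        "stop_gained": 0.30,
        "CSS": 0.30,
        "don+5": 0.20,
        "polypy_PyPu": 0.08,
        "polypy_other": 0.02,
    }


def _default_folds() -> dict[tuple[str, str], float]:
    # de novo fold enrichments per (class, gene set); dominant-gene folds
    # follow the burden pattern seen in trio studies of developmental
    # disorders, recessive and non-DD genes sit at the null
    return {
        ("CSS", "dominant"): 20.0,
        ("don+5", "dominant"): 9.29,
        ("polypy_PyPu", "dominant"): 3.46,
        ("polypy_other", "dominant"): 1.2,
        ("missense", "dominant"): 4.8,
        ("stop_gained", "dominant"): 20.0,
    }


@dataclass
class SimConfig:
    """Parameters of the seeded synthetic cohort.

    The cohort sizes default to a trio study of developmental disorders with
    7833 probands and 13,750 unaffected parents; the genome itself is a toy
    (tens of genes) so that every downstream stage runs in seconds.

    Attributes
    ----------
    seed
        Master seed; every output artifact derives its own RNG stream from it.
    n_genes, exons_per_gene, exon_len, intron_len
        Toy genome dimensions. Intron length must be >= 36 bp so that the
        25-bp acceptor and 10-bp donor intronic windows of adjacent exons
        cannot overlap (set ``allow_short_introns`` to construct overlap test
        cases deliberately).
    n_parents, n_trios
        Carrier pool for allele counts, and trio count scaling the expected
        de novo counts.
    selection_by_class
        Class -> singleton-inflation coefficient in [0, 1]; 0 is neutral.
    fold_by_class_geneset
        (class, gene set) -> de novo fold enrichment >= 0; unlisted cells are 1.
    score_noise_sd
        Gaussian noise added to simulated pathogenicity scores.
    frac_dominant, frac_recessive
        Proportions of genes assigned to the dominant / recessive DD sets.
    frac_filter_fail
        Fraction of cohort variants given a failing FILTER or FS >= 10.
    purge_strength
        How strongly deleterious variants are depleted from high-pLI genes.
    """

    seed: int = 0
    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_len: tuple[int, int] = (60, 150)
    intron_len: tuple[int, int] = (60, 150)
    n_parents: int = 13_750
    n_trios: int = 7_833
    selection_by_class: dict = field(default_factory=_default_selection)
    fold_by_class_geneset: dict = field(default_factory=_default_folds)
    score_noise_sd: float = 0.05
    frac_dominant: float = 0.15
    frac_recessive: float = 0.15
    frac_filter_fail: float = 0.06
    purge_strength: float = 0.7
    polymorphic_scale: float = 0.35
    consequence_probs: tuple[float, float, float] = (0.65, 0.28, 0.07)
    selection_default: float = 0.01
    include_decoys: bool = True
    allow_short_introns: bool = False
    score_tools: tuple = ("adaboost", "randomforest", "spidex", "cadd", "mes")
    coverage_by_tool: dict = field(
        default_factory=lambda: {"adaboost": 0.8, "randomforest": 0.8, "mes": 0.9}
    )

    def __post_init__(self):
        if self.exon_len[0] < 14:
            raise ValueError("exon_len minimum must be >= 14 bp")
        if self.intron_len[0] < 36 and not self.allow_short_introns:
            raise ValueError(
                "intron_len minimum must be >= 36 bp so acceptor and donor "
                "intronic windows never overlap (set allow_short_introns to "
                "override for overlap test cases)"
            )
        for rng_pair in (self.exons_per_gene, self.exon_len, self.intron_len):
            if rng_pair[0] > rng_pair[1] or rng_pair[0] < 1:
                raise ValueError(f"invalid range {rng_pair}")
        for name in ("frac_dominant", "frac_recessive", "frac_filter_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_dominant + self.frac_recessive > 1.0:
            raise ValueError("frac_dominant + frac_recessive must be <= 1")
        for c, s in self.selection_by_class.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"selection coefficient for {c} must be in [0, 1]")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")

    def to_file(self, path) -> None:
        """Write as a flat key=value config file."""
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v!r}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        import ast

        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kwargs[k] = ast.literal_eval(v)
        # dict keys serialised as tuples survive literal_eval round trips
        return cls(**kwargs)
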