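"""Synonymous codon usage, rare-codon scoring, and AT content.

Two compositional signals of laterally transferred ("foreign") genes are
computed here: the per-gene frequency of rare codons — sense codons whose
genome-wide share of their synonymous family falls below a threshold
(default 10%, strict inequality) — and the per-gene AT fraction.  Codon
metrics are computed on CDS sequences read in coding orientation; AT content
is computed on the annotated gene span on the reference strand (it is
strand-symmetric, so the choice of strand cannot matter).

Usage fractions are pooled genome-wide: all CDS codon counts are summed
first and synonymous fractions are taken per amino-acid family afterwards,
which is not the same as averaging per-gene fractions.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .models import ForeignscanError, GenomeBundle

log = logging.getLogger("foreignscan.composition")

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)  # 61 sense codons
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa)) for aa in FAMILIES
}

_VALID_BASES = frozenset("ACGT")


def _codons(cds: str):
    """Yield successive in-frame codons of an upper-cased CDS string."""
    cds = cds.upper()
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i:i + 3]


@dataclass
class CodonUsageTable:
    """Pooled genome-wide codon counts and per-family synonymous fractions."""

    counts: dict[str, int]
    fractions: dict[str, float]
    zero_families: frozenset[str] = frozenset()  # amino acids never observed

    def rare_codons(self, threshold: float = 0.10) -> "RareCodonSet":
        """Sense codons strictly below ``threshold`` synonymous usage.

        Codons of unobserved families carry fraction 0 but are flagged, not
        rare: with no observations there is no usage evidence.
        """
        rare = frozenset(
            c
            for c in SENSE_CODONS
            if CODON_TO_AA[c] not in self.zero_families
            and self.fractions[c] < threshold
        )
        return RareCodonSet(codons=rare, threshold=threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": CODON_TO_AA[c],
                "family_size": len(FAMILIES[CODON_TO_AA[c]]),
                "count": self.counts[c],
                "synonymous_fraction": self.fractions[c],
                "family_observed": CODON_TO_AA[c] not in self.zero_families,
            }
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RareCodonSet:
    codons: frozenset[str]
    threshold: float = 0.10

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


def genome_codon_usage(cds_sequences) -> CodonUsageTable:
    """Pool codon counts over all CDSs, then take per-family fractions.

    CDSs whose length is not a multiple of 3 are skipped (logged).  A CDS
    with an internal stop is counted up to the stop, with a warning.  Stop
    codons and codons containing ambiguous bases are excluded from counts.
    """
    counts: Counter[str] = Counter()
    n_seqs = 0
    for idx, cds in enumerate(cds_sequences):
        n_seqs += 1
        if len(cds) % 3 != 0:
            log.warning("CDS #%d length %d not divisible by 3; skipped", idx, len(cds))
            continue
        for j, codon in enumerate(_codons(cds)):
            if codon in STOP_CODONS:
                if j < len(cds) // 3 - 1:
                    warnings.warn(
                        f"CDS #{idx}: internal stop codon at codon {j}; "
                        "counted up to it",
                        stacklevel=2,
                    )
                break
            if set(codon) <= _VALID_BASES:
                counts[codon] += 1
    if n_seqs == 0:
        raise ForeignscanError("genome_codon_usage: empty CDS input")

    fractions: dict[str, float] = {}
    zero_families = set()
    for aa, family in FAMILIES.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            zero_families.add(aa)
            for c in family:
                fractions[c] = 0.0
        else:
            for c in family:
                fractions[c] = counts[c] / total
    return CodonUsageTable(
        counts={c: counts[c] for c in SENSE_CODONS},
        fractions=fractions,
        zero_families=frozenset(zero_families),
    )


def rare_codon_frequency(gene_cds: str, rare: RareCodonSet) -> float:
    """Fraction of a gene's sense codons that are rare.

    Returns NaN (missing, not 0) when the gene contributes no countable
    sense codons.
    """
    n_sense = 0
    n_rare = 0
    for codon in _codons(gene_cds):
        if codon in STOP_CODONS:
            break
        if set(codon) <= _VALID_BASES:
            n_sense += 1
            if codon in rare:
                n_rare += 1
    if n_sense == 0:
        return math.nan
    return n_rare / n_sense


def at_content(seq: str) -> float:
    """(#A + #T) / (#A + #C + #G + #T); ambiguous bases excluded entirely."""
    if not seq:
        raise ForeignscanError("at_content: empty interval")
    seq = seq.upper()
    n_at = seq.count("A") + seq.count("T")
    n_acgt = n_at + seq.count("G") + seq.count("C")
    if n_acgt == 0:
        return math.nan
    return n_at / n_acgt


def gene_at_content(gene, bundle: GenomeBundle) -> float:
    """AT fraction over the annotated gene span on the reference strand."""
    replicon_len = len(bundle.sequences[gene.replicon])
    if not (0 <= gene.start < gene.end <= replicon_len):
        raise ForeignscanError(
            f"gene {gene.gene_id}: interval [{gene.start}, {gene.end}) "
            f"outside replicon {gene.replicon} (length {replicon_len})"
        )
    return at_content(bundle.gene_span(gene))


def per_gene_metrics(
    bundle: GenomeBundle, rare_threshold: float = 0.10
) -> tuple[pd.DataFrame, CodonUsageTable]:
    """Per-gene rare-codon frequency and AT content for a whole bundle.

    Returns a frame indexed like the bundle's gene order with columns
    gene_id, rare_codon_freq, at_content, replicon, category, origin, plus
    the pooled usage table the rare set was derived from.
    """
    usage = genome_codon_usage(bundle.gene_cds(g) for g in bundle.genes)
    rare = usage.rare_codons(rare_threshold)
    rows = [
        {
            "gene_id": g.gene_id,
            "rare_codon_freq": rare_codon_frequency(bundle.gene_cds(g), rare),
            "at_content": gene_at_content(g, bundle),
            "replicon": g.replicon,
            "category": g.category,
            "origin": g.origin,
        }
        for g in bundle.genes
    ]
    return pd.DataFrame(rows), usage


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False)


def read_metrics_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
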