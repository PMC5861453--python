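"""Shared domain types and coordinate conventions.

Every in-memory coordinate in this package is a 0-based, half-open interval
``[start, end)`` on the reference strand.  Conversions to and from the
1-based inclusive conventions of GFF3 and TSS tables happen only at I/O
boundaries.  "5' end" and "3' end" are always strand-aware: for a
plus-strand feature the 5'-most base is ``start``; for a minus-strand
feature it is ``end - 1``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq


class ForeignscanError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(ForeignscanError):
    """Invalid configuration (bad probabilities, impossible layouts, ...)."""


class ParseError(ForeignscanError):
    """Malformed input file; message names the file and line number."""

    def __init__(self, path, lineno: Optional[int], message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")


STRANDS = ("+", "-")


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene; the CDS spans the whole gene interval."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    category: Optional[str] = None
    origin: Optional[str] = None  # "native" | "foreign" where known

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5'-most base (translation start)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeBundle:
    """Replicon sequences plus gene records."""

    sequences: dict[str, str]
    genes: list[Gene]
    replicon_origins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in bundle")

    @property
    def genes_by_id(self) -> dict[str, Gene]:
        return self._by_id

    def gene_span(self, gene: Gene) -> str:
        """Reference-strand sequence over the gene interval."""
        return self.sequences[gene.replicon][gene.start:gene.end]

    def gene_cds(self, gene: Gene) -> str:
        """Coding-strand CDS sequence (reverse-complemented for minus-strand genes)."""
        seq = self.gene_span(gene)
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class TranscriptionUnit:
    """A stranded genomic interval transcribed as one RNA (>= 1 cistron)."""

    tu_id: str
    replicon: str
    start: int
    end: int
    strand: str
    member_gene_ids: list[str] = field(default_factory=list)  # ordered 5' -> 3'

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"TU {self.tu_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"TU {self.tu_id}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class PrimaryTSS:
    """The first transcribed base of a transcription unit (1-based position)."""

    replicon: str
    position: int  # 1-based
    strand: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"TSS position must be >= 1, got {self.position}")
        if self.strand not in STRANDS:
            raise ValueError(f"TSS: bad strand {self.strand!r}")

    @property
    def pos0(self) -> int:
        """0-based coordinate of the TSS base."""
        return self.position - 1


@dataclass
class DESummary:
    """Direction counts from differential-expression classification."""

    n_up: int
    n_down: int
    n_ns: int
    n_total: int

    def __post_init__(self):
        if self.n_up + self.n_down + self.n_ns != self.n_total:
            raise ValueError("direction counts do not sum to n_total")

    @property
    def n_misregulated(self) -> int:
        return self.n_up + self.n_down

    @property
    def misregulated_fraction(self) -> float:
        return self.n_misregulated / self.n_total if self.n_total else float("nan")


@dataclass
class ContingencyResult:
    """Outcome of one contingency test (Fisher exact or rank-sum)."""

    row_labels: tuple
    col_labels: tuple
    counts: tuple  # tuple of tuples of ints
    p_value: float
    method: str  # "fisher_two_sided" | "wilcoxon_rank_sum"
    odds_ratio: Optional[float] = None
    odds_ratio_kind: str = "sample"  # sample (ad/bc), flagged explicitly
    p_adjusted: Optional[float] = None
    adjustment: str = "none"  # "none" | "bonferroni"
    m_tests: Optional[int] = None
    note: str = ""

    def as_record(self) -> dict:
        return {
            "rows": "|".join(map(str, self.row_labels)),
            "cols": "|".join(map(str, self.col_labels)),
            "counts": ";".join(",".join(map(str, row)) for row in self.counts),
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "method": self.method,
            "adjustment": self.adjustment,
            "m_tests": self.m_tests,
            "note": self.note,
        }


# Classes a TU can fall into after refinement against a TSS table.
ADJUSTED = "adjusted"
SHORTENED_INTERNAL = "shortened_internal"
ADDED = "added"
UNCHANGED = "unchanged"


@dataclass
class TuAdjustment:
    """One ledger row of the refinement report.

    ``offset_bp`` is signed in the 5'-ward direction: positive means the 5'
    end moved upstream (TU extended), negative means it moved into the TU.
    Coordinates are 1-based positions of the 5' base for human readability.
    """

    tu_id: str
    replicon: str
    strand: str
    old_five_prime: Optional[int]
    new_five_prime: Optional[int]
    offset_bp: int
    klass: str
    note: str = ""


@dataclass
class AdjustmentReport:
    """Tallies of a TU-map refinement run; counts derive from the ledger."""

    ledger: list[TuAdjustment] = field(default_factory=list)
    n_tss_unassigned: int = 0
    n_refused: int = 0

    def _of(self, klass: str) -> list[TuAdjustment]:
        return [row for row in self.ledger if row.klass == klass]

    @property
    def n_tus_adjusted(self) -> int:
        return len(self._of(ADJUSTED))

    @property
    def n_internal_shortened(self) -> int:
        return len(self._of(SHORTENED_INTERNAL))

    @property
    def n_orphan_added(self) -> int:
        return len(self._of(ADDED))

    @property
    def n_unchanged(self) -> int:
        return len(self._of(UNCHANGED))

    @property
    def n_adjustments_gt100(self) -> int:
        return sum(1 for row in self._of(ADJUSTED) if abs(row.offset_bp) > 100)

    @property
    def median_abs_adjustment_bp(self) -> Optional[float]:
        adj = [abs(row.offset_bp) for row in self._of(ADJUSTED)]
        return statistics.median(adj) if adj else None

    def summary(self) -> dict:
        return {
            "n_tus_adjusted": self.n_tus_adjusted,
            "median_abs_adjustment_bp": self.median_abs_adjustment_bp,
            "n_adjustments_gt100": self.n_adjustments_gt100,
            "n_internal_shortened": self.n_internal_shortened,
            "n_orphan_added": self.n_orphan_added,
            "n_unchanged": self.n_unchanged,
            "n_tss_unassigned": self.n_tss_unassigned,
            "n_refused": self.n_refused,
        }
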