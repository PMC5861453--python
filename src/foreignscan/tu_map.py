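"""Transcription-unit map refinement against a primary-TSS table.

Three refinement moves, mirroring how curated operon maps are reconciled
with TSS mapping data:

* **5'-end adjustment** — a TU with an assigned primary TSS upstream of (or
  inside, but upstream of the first cistron's translation start) its
  annotated 5' end gets its 5' coordinate moved to the TSS; the 3' end,
  strand and replicon never change.
* **internal-TSS shortening** — a TSS falling strictly downstream of the
  first cistron's start splits the TU: the revised TU starts at the
  internal TSS and keeps the downstream cistrons; upstream cistrons are
  discarded with a log entry by default, or retained as a residual TU with
  ``keep_upstream_remainder=True``.
* **orphan-gene TU creation** — a gene with an assigned TSS (via the TSS
  table's gene column) that belongs to no TU becomes a new single-gene TU
  from its TSS to its 3' end.

Also here: strand-aware promoter-window extraction (-50..+10 around each
TSS, 61 nt) for downstream motif discovery.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .models import (
    ADDED,
    ADJUSTED,
    SHORTENED_INTERNAL,
    UNCHANGED,
    AdjustmentReport,
    Gene,
    ParseError,
    PrimaryTSS,
    TranscriptionUnit,
    TuAdjustment,
)

log = logging.getLogger("foreignscan.tu_map")


# ---------------------------------------------------------------------------
# Loaders (I/O dialects -> internal 0-based half-open)
# ---------------------------------------------------------------------------


def load_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_genes(path, replicons=None) -> list[Gene]:
    """Read CDS features from GFF3; attributes gene_id/ID, category, origin."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if replicons is not None and feat.seqid not in replicons:
            raise ParseError(path, None, f"unknown replicon {feat.seqid!r}")
        gid = feat.attributes.get("gene_id", feat.attributes.get("ID", [None]))[0]
        if gid is None:
            raise ParseError(path, None, f"CDS at {feat.seqid}:{feat.start} lacks an id")
        if gid.startswith("cds-"):
            gid = gid[4:]
        genes.append(
            Gene(
                gene_id=gid,
                replicon=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                category=feat.attributes.get("category", [None])[0],
                origin=feat.attributes.get("origin", [None])[0],
            )
        )
    return genes


def load_tu_map(path, replicons=None) -> list[TranscriptionUnit]:
    """BED6 (already 0-based half-open); score column is ignored."""
    tus = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected 6 BED columns, got {len(fields)}")
            rep, start, end, name, _score, strand = fields[:6]
            if replicons is not None and rep not in replicons:
                raise ParseError(path, lineno, f"unknown replicon {rep!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start!r}/{end!r}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            if not 0 <= start_i < end_i:
                raise ParseError(path, lineno, f"bad interval [{start}, {end})")
            tus.append(TranscriptionUnit(name, rep, start_i, end_i, strand))
    return tus


def load_tss_table(path, replicons=None, replicon_lengths=None) -> list[PrimaryTSS]:
    """TSV with header: replicon, position (1-based), strand, gene_id_or_NA."""
    tss = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["replicon", "position", "strand"]:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            rep, pos, strand = fields[:3]
            gene_id = fields[3] if len(fields) > 3 and fields[3] not in ("", "NA") else None
            if replicons is not None and rep not in replicons:
                raise ParseError(path, lineno, f"unknown replicon {rep!r}")
            try:
                pos_i = int(pos)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer position {pos!r}")
            if pos_i < 1:
                raise ParseError(path, lineno, f"position must be >= 1, got {pos_i}")
            if replicon_lengths is not None and pos_i > replicon_lengths.get(rep, pos_i):
                raise ParseError(
                    path, lineno,
                    f"position {pos_i} beyond replicon {rep} "
                    f"(length {replicon_lengths[rep]})",
                )
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            tss.append(PrimaryTSS(rep, pos_i, strand, gene_id))
    return tss


def assign_genes_to_tus(
    tus: list[TranscriptionUnit], genes: list[Gene]
) -> list[TranscriptionUnit]:
    """Return copies of the TUs with member_gene_ids filled (ordered 5'->3').

    A gene is a member of a TU when it lies entirely within the TU interval
    on the same replicon and strand.
    """
    out = []
    for tu in tus:
        members = [
            g
            for g in genes
            if g.replicon == tu.replicon
            and g.strand == tu.strand
            and tu.start <= g.start
            and g.end <= tu.end
        ]
        members.sort(key=lambda g: g.start, reverse=(tu.strand == "-"))
        out.append(
            TranscriptionUnit(
                tu.tu_id, tu.replicon, tu.start, tu.end, tu.strand,
                [g.gene_id for g in members],
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSS -> TU matching
# ---------------------------------------------------------------------------


@dataclass
class TssMatch:
    tss: PrimaryTSS
    tu_id: str
    distance: int  # bp from TSS to annotated TU 5' end (>= 0)
    internal: bool


@dataclass
class MatchResult:
    by_tu: dict = field(default_factory=dict)  # tu_id -> list[TssMatch]
    unassigned: list = field(default_factory=list)


def _upstream_distance(tss: PrimaryTSS, tu: TranscriptionUnit) -> int | None:
    """bp from the TSS to the TU 5' end, positive when the TSS is upstream."""
    if tu.strand == "+":
        return tu.start - tss.pos0
    return tss.pos0 - (tu.end - 1)


def _contains(tss: PrimaryTSS, tu: TranscriptionUnit) -> bool:
    return tu.start <= tss.pos0 < tu.end


def _is_internal(tss: PrimaryTSS, tu: TranscriptionUnit, genes_by_id) -> bool:
    """TSS strictly downstream of the first cistron's translation start."""
    if not tu.member_gene_ids:
        return False
    first = genes_by_id[tu.member_gene_ids[0]]
    if tu.strand == "+":
        return tss.pos0 > first.five_prime
    return tss.pos0 < first.five_prime


def match_tss_to_tu(
    tss_list: list[PrimaryTSS],
    tus: list[TranscriptionUnit],
    max_distance_bp: int = 500,
    genes_by_id: dict | None = None,
) -> MatchResult:
    """Assign each TSS to at most one TU.

    Eligible TUs share replicon and strand and either have their 5' end
    within ``max_distance_bp`` downstream of the TSS or contain the TSS;
    the nearest eligible TU (by |TSS - TU 5'|) wins.  A TSS strictly
    downstream of the first cistron's translation start is flagged internal.
    """
    genes_by_id = genes_by_id or {}
    by_loc: dict[tuple, list[TranscriptionUnit]] = {}
    for tu in tus:
        by_loc.setdefault((tu.replicon, tu.strand), []).append(tu)

    result = MatchResult()
    for tss in tss_list:
        best = None
        best_key = None
        for tu in by_loc.get((tss.replicon, tss.strand), ()):
            d = _upstream_distance(tss, tu)
            if not (0 <= d <= max_distance_bp or _contains(tss, tu)):
                continue
            key = abs(tss.pos0 - tu.five_prime)
            if best_key is None or key < best_key:
                best, best_key = tu, key
        if best is None:
            result.unassigned.append(tss)
            continue
        result.by_tu.setdefault(best.tu_id, []).append(
            TssMatch(
                tss=tss,
                tu_id=best.tu_id,
                distance=int(best_key),
                internal=_is_internal(tss, best, genes_by_id),
            )
        )
    return result


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------


def _pick_primary(matches: list[TssMatch], tu: TranscriptionUnit) -> TssMatch:
    """Nearest TSS to the annotated 5' end; ties go to the more upstream one."""
    def tie_key(m: TssMatch):
        upstreamness = -m.tss.pos0 if tu.strand == "+" else m.tss.pos0
        return (m.distance, -upstreamness)

    return min(matches, key=tie_key)


def _five_prime_to_interval(
    tu: TranscriptionUnit, new5: int
) -> tuple[int, int]:
    """New (start, end) with the 5' base at ``new5`` and the 3' end fixed."""
    if tu.strand == "+":
        return new5, tu.end
    return tu.start, new5 + 1


def refine_tu_map(
    tus: list[TranscriptionUnit],
    tss_list: list[PrimaryTSS],
    genes: list[Gene],
    max_distance_bp: int = 500,
    keep_upstream_remainder: bool = False,
) -> tuple[list[TranscriptionUnit], AdjustmentReport]:
    """Refine a TU map against a primary-TSS table.

    Returns the refined TU list (sorted by replicon, start) and an
    :class:`AdjustmentReport` whose per-TU ledger classes every TU as
    adjusted / shortened_internal / added / unchanged.  A refinement that
    would produce an empty interval is refused, logged, and leaves the TU
    unchanged.
    """
    genes_by_id = {g.gene_id: g for g in genes}
    tus = assign_genes_to_tus(tus, genes)
    matches = match_tss_to_tu(tss_list, tus, max_distance_bp, genes_by_id)

    report = AdjustmentReport(n_tss_unassigned=len(matches.unassigned))
    refined: list[TranscriptionUnit] = []
    covered = {gid for tu in tus for gid in tu.member_gene_ids}

    for tu in tus:
        ms = matches.by_tu.get(tu.tu_id, [])
        primaries = [m for m in ms if not m.internal]
        internals = [m for m in ms if m.internal]
        old5 = tu.five_prime

        new5 = old5
        if primaries:
            new5 = _pick_primary(primaries, tu).tss.pos0

        internal_split = None
        if internals:
            # 5'-most internal TSS keeps the most cistrons in the revised TU
            itss = min(
                internals,
                key=lambda m: m.tss.pos0 if tu.strand == "+" else -m.tss.pos0,
            )
            ipos = itss.tss.pos0
            down = [
                gid
                for gid in tu.member_gene_ids
                if (genes_by_id[gid].five_prime >= ipos) == (tu.strand == "+")
                or genes_by_id[gid].five_prime == ipos
            ]
            if down:
                internal_split = (ipos, down)
            else:
                log.warning(
                    "TU %s: internal TSS at %d leaves no downstream cistron; ignored",
                    tu.tu_id, ipos + 1,
                )

        if internal_split is not None:
            ipos, down = internal_split
            start, end = _five_prime_to_interval(tu, ipos)
            short = TranscriptionUnit(tu.tu_id, tu.replicon, start, end, tu.strand, down)
            refined.append(short)
            upstream = [gid for gid in tu.member_gene_ids if gid not in down]
            if keep_upstream_remainder and upstream:
                last_up = genes_by_id[upstream[-1]]
                if tu.strand == "+":
                    rstart, rend = new5, last_up.end
                else:
                    rstart, rend = last_up.start, new5 + 1
                refined.append(
                    TranscriptionUnit(
                        f"{tu.tu_id}.up", tu.replicon, rstart, rend, tu.strand, upstream
                    )
                )
            elif upstream:
                log.info(
                    "TU %s: %d upstream cistron(s) discarded on internal-TSS "
                    "shortening: %s", tu.tu_id, len(upstream), ",".join(upstream),
                )
            report.ledger.append(
                TuAdjustment(
                    tu.tu_id, tu.replicon, tu.strand, old5 + 1, short.five_prime + 1,
                    0, SHORTENED_INTERNAL,
                    note=f"upstream_cistrons={'kept' if keep_upstream_remainder else 'discarded'}",
                )
            )
            continue

        if new5 != old5:
            start, end = _five_prime_to_interval(tu, new5)
            if start >= end:
                report.n_refused += 1
                log.warning(
                    "TU %s: adjustment to %d would empty the interval; left unchanged",
                    tu.tu_id, new5 + 1,
                )
                refined.append(copy.deepcopy(tu))
                report.ledger.append(
                    TuAdjustment(
                        tu.tu_id, tu.replicon, tu.strand, old5 + 1, old5 + 1, 0,
                        UNCHANGED, note="refused_empty_interval",
                    )
                )
                continue
            # + offset: 5' moved upstream (extension); - : moved into the TU
            offset = (old5 - new5) if tu.strand == "+" else (new5 - old5)
            refined.append(
                TranscriptionUnit(
                    tu.tu_id, tu.replicon, start, end, tu.strand,
                    list(tu.member_gene_ids),
                )
            )
            report.ledger.append(
                TuAdjustment(
                    tu.tu_id, tu.replicon, tu.strand, old5 + 1, new5 + 1,
                    int(offset), ADJUSTED,
                )
            )
        else:
            refined.append(copy.deepcopy(tu))
            report.ledger.append(
                TuAdjustment(tu.tu_id, tu.replicon, tu.strand, old5 + 1, old5 + 1, 0, UNCHANGED)
            )

    # orphan genes: an assigned TSS whose gene is in no TU founds a new TU
    orphan_best: dict[str, PrimaryTSS] = {}
    for tss in matches.unassigned:
        gid = tss.gene_id
        if gid is None or gid in covered or gid not in genes_by_id:
            continue
        gene = genes_by_id[gid]
        if gene.replicon != tss.replicon or gene.strand != tss.strand:
            continue
        prev = orphan_best.get(gid)
        if prev is None or abs(tss.pos0 - gene.five_prime) < abs(prev.pos0 - gene.five_prime):
            orphan_best[gid] = tss
    for gid in sorted(orphan_best):
        gene = genes_by_id[gid]
        tss = orphan_best[gid]
        if gene.strand == "+":
            start, end = tss.pos0, gene.end
        else:
            start, end = gene.start, tss.pos0 + 1
        if start >= end:
            report.n_refused += 1
            log.warning("orphan gene %s: TSS at %d inside/after gene 3' end; skipped",
                        gid, tss.position)
            continue
        new_tu = TranscriptionUnit(f"{gid}.tu", gene.replicon, start, end, gene.strand, [gid])
        refined.append(new_tu)
        report.ledger.append(
            TuAdjustment(
                new_tu.tu_id, gene.replicon, gene.strand, None,
                new_tu.five_prime + 1, 0, ADDED, note=f"orphan_gene={gid}",
            )
        )

    refined.sort(key=lambda t: (t.replicon, t.start))
    s = report.summary()
    log.info(
        "refinement: %d adjusted (median |adj| %s bp, %d > 100 bp), %d internal, "
        "%d added, %d unchanged, %d TSS unassigned",
        s["n_tus_adjusted"], s["median_abs_adjustment_bp"], s["n_adjustments_gt100"],
        s["n_internal_shortened"], s["n_orphan_added"], s["n_unchanged"],
        s["n_tss_unassigned"],
    )
    return refined, report


def write_adjustment_report(report: AdjustmentReport, tsv_path, json_path=None) -> None:
    frame = pd.DataFrame(
        [
            {
                "tu_id": r.tu_id,
                "replicon": r.replicon,
                "strand": r.strand,
                "old_five_prime": r.old_five_prime,
                "new_five_prime": r.new_five_prime,
                "offset_bp": r.offset_bp,
                "class": r.klass,
                "note": r.note,
            }
            for r in report.ledger
        ]
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.summary(), indent=1))


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------


def extract_promoter_windows(
    tss_list: list[PrimaryTSS],
    sequences: dict[str, str],
    upstream: int = 50,
    downstream: int = 10,
) -> tuple[list[tuple[str, str]], int]:
    """(-upstream..+downstream) windows around each TSS, TSS included.

    Each record is ``upstream + downstream + 1`` nt (61 with the defaults).
    Minus-strand windows are reverse-complemented so the TSS-proximal end is
    3'-most.  Windows that would run off a replicon end are dropped and
    counted.  Returns ``([(record_id, sequence), ...], n_dropped)``.
    """
    records: list[tuple[str, str]] = []
    n_dropped = 0
    for tss in tss_list:
        seq = sequences.get(tss.replicon)
        if seq is None or not (0 <= tss.pos0 < len(seq)):
            log.warning("TSS %s:%d off sequence; skipped", tss.replicon, tss.position)
            n_dropped += 1
            continue
        if tss.strand == "+":
            lo, hi = tss.pos0 - upstream, tss.pos0 + downstream + 1
        else:
            lo, hi = tss.pos0 - downstream, tss.pos0 + upstream + 1
        if lo < 0 or hi > len(seq):
            n_dropped += 1
            continue
        window = seq[lo:hi]
        if tss.strand == "-":
            window = str(Seq(window).reverse_complement())
        records.append((f"{tss.replicon}:{tss.position}:{tss.strand}", window))
    if n_dropped:
        log.info("promoter windows: %d TSS dropped at replicon ends/off-sequence", n_dropped)
    return records, n_dropped


def write_promoter_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
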