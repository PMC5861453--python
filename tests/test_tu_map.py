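"""Loaders, TSS-to-TU matching, refinement moves, and promoter windows."""

import pytest

import foreignscan as fs
from foreignscan import tu_map
from foreignscan.models import (
    ADDED,
    ADJUSTED,
    SHORTENED_INTERNAL,
    UNCHANGED,
    Gene,
    ParseError,
    PrimaryTSS,
    TranscriptionUnit,
)

from conftest import small_synth_config


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def test_bed_loader_keeps_half_open_coordinates(tmp_path):
    p = tmp_path / "tus.bed"
    p.write_text("chr1\t99\t199\ttu1\t0\t+\n")
    (tu,) = tu_map.load_tu_map(p)
    assert (tu.start, tu.end, tu.strand, tu.tu_id) == (99, 199, "+", "tu1")


def test_gff_loader_converts_to_zero_based(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=g1;category=J;origin=native\n"
    )
    (gene,) = tu_map.load_genes(p)
    assert (gene.start, gene.end) == (99, 200)
    assert gene.category == "J" and gene.origin == "native"


def test_tss_loader_minus_strand_reference_base(tmp_path):
    p = tmp_path / "tss.tsv"
    p.write_text("replicon\tposition\tstrand\tgene_id\nchr1\t150\t-\tNA\n")
    (tss,) = tu_map.load_tss_table(p)
    assert tss.pos0 == 149
    assert tss.gene_id is None


def test_malformed_line_names_file_and_line(tmp_path):
    p = tmp_path / "tus.bed"
    p.write_text("chr1\t99\t199\ttu1\t0\t+\nchr1\tnotanumber\t5\ttu2\t0\t+\n")
    with pytest.raises(ParseError, match=r"tus\.bed:2"):
        tu_map.load_tu_map(p)


def test_unknown_replicon_rejected(tmp_path):
    p = tmp_path / "tus.bed"
    p.write_text("chrX\t0\t10\ttu1\t0\t+\n")
    with pytest.raises(ParseError, match="unknown replicon"):
        tu_map.load_tu_map(p, replicons={"chr1"})


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _plus_tu(start=100, end=400, members=()):
    return TranscriptionUnit("tu1", "chr", start, end, "+", list(members))


def test_tss_at_tu_five_prime_assigned_offset_zero():
    res = tu_map.match_tss_to_tu([PrimaryTSS("chr", 101, "+")], [_plus_tu()], 500)
    (m,) = res.by_tu["tu1"]
    assert m.distance == 0 and not m.internal


def test_tss_upstream_within_window_assigned():
    res = tu_map.match_tss_to_tu([PrimaryTSS("chr", 71, "+")], [_plus_tu()], 500)
    (m,) = res.by_tu["tu1"]
    assert m.distance == 30


def test_opposite_strand_tss_unassigned():
    res = tu_map.match_tss_to_tu([PrimaryTSS("chr", 101, "-")], [_plus_tu()], 500)
    assert res.by_tu == {} and len(res.unassigned) == 1


def test_tss_beyond_max_distance_unassigned():
    res = tu_map.match_tss_to_tu([PrimaryTSS("chr", 1, "+")], [_plus_tu(600, 900)], 500)
    assert len(res.unassigned) == 1


def test_internal_flag_strictly_downstream_of_first_cistron_start():
    genes = {
        "g1": Gene("g1", "chr", 150, 240, "+"),
        "g2": Gene("g2", "chr", 260, 350, "+"),
    }
    tu = _plus_tu(members=("g1", "g2"))
    at_start = tu_map.match_tss_to_tu([PrimaryTSS("chr", 151, "+")], [tu], 500, genes)
    (m,) = at_start.by_tu["tu1"]
    assert not m.internal  # at the first cistron start, not beyond it
    inside = tu_map.match_tss_to_tu([PrimaryTSS("chr", 261, "+")], [tu], 500, genes)
    (m,) = inside.by_tu["tu1"]
    assert m.internal


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def _three_gene_fixture():
    genes = [
        Gene("g1", "chr", 150, 240, "+"),
        Gene("g2", "chr", 260, 350, "+"),
        Gene("g3", "chr", 370, 460, "+"),
    ]
    tu = TranscriptionUnit("tu1", "chr", 100, 460, "+")
    return genes, tu


def test_coinciding_tss_leaves_map_unchanged():
    genes, tu = _three_gene_fixture()
    refined, report = fs.refine_tu_map([tu], [PrimaryTSS("chr", 101, "+")], genes)
    assert report.n_tus_adjusted == 0
    assert refined[0].start == 100 and refined[0].end == 460


def test_five_prime_adjustment_moves_only_the_five_prime():
    genes, tu = _three_gene_fixture()
    refined, report = fs.refine_tu_map([tu], [PrimaryTSS("chr", 71, "+")], genes)
    assert report.n_tus_adjusted == 1
    assert (refined[0].start, refined[0].end) == (70, 460)
    (row,) = [r for r in report.ledger if r.klass == ADJUSTED]
    assert row.offset_bp == 30  # extension is positive


def test_internal_tss_shortens_to_downstream_cistrons():
    genes, tu = _three_gene_fixture()
    tss = [PrimaryTSS("chr", 101, "+"), PrimaryTSS("chr", 261, "+")]
    refined, report = fs.refine_tu_map([tu], tss, genes)
    assert report.n_internal_shortened == 1
    (short,) = [t for t in refined if t.tu_id == "tu1"]
    assert short.start == 260 and short.end == 460
    assert short.member_gene_ids == ["g2", "g3"]  # g1 discarded by default


def test_keep_upstream_remainder_retains_first_cistron():
    genes, tu = _three_gene_fixture()
    tss = [PrimaryTSS("chr", 101, "+"), PrimaryTSS("chr", 261, "+")]
    refined, _ = fs.refine_tu_map([tu], tss, genes, keep_upstream_remainder=True)
    by_id = {t.tu_id: t for t in refined}
    assert by_id["tu1"].member_gene_ids == ["g2", "g3"]
    assert by_id["tu1.up"].member_gene_ids == ["g1"]
    assert by_id["tu1.up"].start == 100 and by_id["tu1.up"].end == 240
    # gene conservation under the keep policy
    all_members = sorted(g for t in refined for g in t.member_gene_ids)
    assert all_members == ["g1", "g2", "g3"]


def test_orphan_gene_founds_single_gene_tu():
    genes = [Gene("lone", "chr", 1000, 1300, "+")]
    tss = [PrimaryTSS("chr", 961, "+", "lone")]
    refined, report = fs.refine_tu_map([], tss, genes)
    assert report.n_orphan_added == 1
    (tu,) = refined
    assert (tu.start, tu.end, tu.member_gene_ids) == (960, 1300, ["lone"])


def test_orphan_tss_past_gene_three_prime_refused():
    genes = [Gene("lone", "chr", 1000, 1300, "+")]
    tss = [PrimaryTSS("chr", 1400, "+", "lone")]
    refined, report = fs.refine_tu_map([], tss, genes)
    assert refined == [] and report.n_refused == 1


def test_minus_strand_adjustment():
    genes = [Gene("g1", "chr", 200, 350, "-")]
    tu = TranscriptionUnit("tu1", "chr", 200, 400, "-")
    refined, report = fs.refine_tu_map([tu], [PrimaryTSS("chr", 430, "-")], genes)
    assert (refined[0].start, refined[0].end) == (200, 430)
    (row,) = [r for r in report.ledger if r.klass == ADJUSTED]
    assert row.offset_bp == 30


def test_refinement_preserves_three_prime_strand_replicon(small_run):
    tus, tss = small_run["tus"], small_run["tss"]
    genes = small_run["bundle"].genes
    refined, _ = fs.refine_tu_map(tus, tss, genes)
    inputs = {t.tu_id: t for t in tus}
    for t in refined:
        if t.tu_id in inputs:
            before = inputs[t.tu_id]
            assert t.strand == before.strand and t.replicon == before.replicon
            assert t.three_prime == before.three_prime


def test_refinement_idempotent_on_refined_map(small_run):
    tus, tss = small_run["tus"], small_run["tss"]
    genes = small_run["bundle"].genes
    refined, _ = fs.refine_tu_map(tus, tss, genes)
    again, report = fs.refine_tu_map(refined, tss, genes)
    assert report.n_tus_adjusted == 0
    assert report.n_internal_shortened == 0
    assert report.n_orphan_added == 0
    assert {(t.tu_id, t.start, t.end) for t in again} == {
        (t.tu_id, t.start, t.end) for t in refined
    }


def test_recovery_of_injected_offsets(small_run):
    """Refined 5' ends equal ground truth for all non-internal TUs."""
    truth = small_run["truth"]
    refined, _ = fs.refine_tu_map(
        small_run["tus"], small_run["tss"], small_run["bundle"].genes
    )
    by_id = {t.tu_id: t for t in refined}
    internal = set(truth.internal_tss_tus)
    orphan = set(truth.orphan_genes)
    checked = 0
    for tu in truth.true_tus:
        if tu.tu_id in internal:
            continue
        if len(tu.member_gene_ids) == 1 and tu.member_gene_ids[0] in orphan:
            continue
        assert by_id[tu.tu_id].five_prime == tu.five_prime
        checked += 1
    assert checked > 50


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------


def test_promoter_window_plus_strand_boundary():
    seq = "".join("ACGT"[i % 4] for i in range(100))
    records, dropped = fs.extract_promoter_windows(
        [PrimaryTSS("chr", 51, "+")], {"chr": seq}
    )
    assert dropped == 0
    (rid, window) = records[0]
    assert rid == "chr:51:+"
    assert window == seq[0:61]
    assert len(window) == 61


def test_promoter_window_minus_strand_reverse_complement():
    records, dropped = fs.extract_promoter_windows(
        [PrimaryTSS("chr", 50, "-")], {"chr": "A" * 100}
    )
    assert dropped == 0
    (_, window) = records[0]
    assert window == "T" * 61


def test_promoter_window_clipped_at_replicon_end_dropped():
    records, dropped = fs.extract_promoter_windows(
        [PrimaryTSS("chr", 10, "+")], {"chr": "A" * 100}
    )
    assert records == [] and dropped == 1


def test_promoter_window_off_sequence_skipped():
    records, dropped = fs.extract_promoter_windows(
        [PrimaryTSS("chr", 500, "+")], {"chr": "A" * 100}
    )
    assert records == [] and dropped == 1
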