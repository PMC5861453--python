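# Methods

This note documents the models, defaults and numerical choices behind
foreignscan, and what the synthetic tests do and do not demonstrate about
real data.

## Coordinates and conventions

All in-memory intervals are 0-based half-open on the reference strand;
GFF3 (1-based inclusive) and TSS tables (1-based single positions) are
converted at I/O boundaries only. 5′/3′ are strand-aware. BED6 TU maps are
passed through unchanged (BED is already half-open).

## TU-map refinement

**Matching rule.** A TSS is assigned to the nearest same-strand TU whose
annotated 5′ end lies within `max_distance_bp` (default 500) downstream of
the TSS, or that contains the TSS. When several TSSs match one TU, the one
nearest the annotated 5′ end wins; ties go to the more upstream TSS
(minimising perturbation of the existing annotation). The 500 bp default
comfortably covers the long tail of real 5′-end corrections (which extend
past 100 nt) while staying below typical inter-operon spacing.

**Internal TSSs.** A TSS strictly downstream of the first cistron's
translation start (and inside the TU) shortens the TU to start at that
TSS, keeping the downstream cistrons. What curators did with the upstream
cistrons in such revisions is ambiguous, so both behaviours are provided:
the default discards them with a log entry; `keep_upstream_remainder=True`
retains them as a residual TU (id suffix `.up`). Gene conservation across
refinement holds exactly under the keep policy; under the default the
discarded cistrons are enumerated in the log.

**Guards.** Refinement never touches a TU's 3′ coordinate, strand or
replicon. An adjustment that would produce an empty interval is refused
and logged, never clamped. Refinement is idempotent: re-refining a refined
map against the same TSS table yields zero adjustments (the per-TU
nearest-TSS rule keeps the now-coincident TSS as the winner).

**Promoter windows.** Windows span positions −50..+10 around the TSS
inclusive of the TSS base — 61 nt, the bedtools-style interpretation.
Minus-strand windows are reverse-complemented so the TSS-proximal end is
3′-most. Windows that would run off a replicon end are dropped and
counted, not clipped.

## Composition

Codon usage is pooled genome-wide: all CDS codon counts are summed before
per-family fractions are taken (this differs from averaging per-gene
fractions and matches the "genome-wide" definition). Stop codons and
codons containing ambiguous bases are excluded from counts and
denominators; a CDS whose length is not a multiple of 3 is skipped with a
warning, and an internal stop truncates counting at the stop. Start codons
are counted as ordinary sense codons. The rare-codon set uses a **strict**
`< 0.10` threshold, so single-codon families (Met, Trp, fraction 1.0) can
never be rare, and an unobserved family is flagged rather than declared
rare. AT content is computed over the annotated gene span on the reference
strand (strand-symmetric by construction), ambiguous bases excluded from
numerator and denominator; codon metrics use the CDS in coding
orientation.

## Statistics

* **Direction classification**: up iff p_adj < α and log2FC > 0; down iff
  p_adj < α and log2FC < 0; otherwise ns. Missing p_adj ⇒ ns (logged),
  never dropped, so "detected" denominators stay honest. Default α 0.01.
* **Fisher two-sided test**: point-probability definition — the sum of
  hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed that of the observed table. Table
  probabilities are compared as exact integers (`C(r1,a)·C(r2,c1−a)`), so
  ties are decided exactly rather than at floating-point tolerance; the
  p-value is the exact rational rounded once to float. A zero margin
  admits only the observed table: p = 1, with a warning. The odds ratio is
  the sample odds ratio ad/bc, flagged as such.
* **Quartile contrasts**: genes ordered by (metric, gene id) — the stable
  id tie-break makes the partition deterministic — and the lowest/highest
  n//4 genes form Q1/Q4; the 2×2 table is (Q4, Q1) × (direction, rest).
* **Replicon contrasts**: for each non-reference replicon and each
  direction, (direction, not-direction) × (replicon, reference), two
  sided. The alternative construction (increased vs decreased) is
  available as `construction="vs_other"`; note it produces one table per
  replicon, shared by both directions. The reference replicon cannot be
  contrasted with itself. With the published printed counts the vs_rest
  construction reproduces the starred significance pattern exactly.
* **Category enrichment**: per category × per direction tested, Bonferroni
  with m = #categories × #directions; m is always reported, and
  uncategorized genes remain in the complement.
* **Abundance contrast**: TU abundance is the geometric mean of replicate
  TPM columns, assigned to the TU's first cistron; two-sided Wilcoxon
  rank-sum (Mann–Whitney) on log2 abundance of up vs down genes; empty
  groups are an error.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any real sequence content.

**Genome.** Default: a native "chr" (500 kb, 540 genes, including a 15-gene
contiguous prophage-like block of foreign composition, category "X") and a
foreign megaplasmid "pMEG1" (60 kb, 45 genes). TU sizes are 1–4 cistrons
(55/25/12/8%), CDSs are 80–141 codons with start/stop, 5′ UTRs 20–60 bp,
intra-operon gaps 10–30 bp, inter-TU gaps 600–1000 bp (large enough that
TSS-to-TU matching is unambiguous at the default offset magnitudes).
Intergenic background AT is 0.35 (native) / 0.55 (foreign).

**Codon regimes.** The native profile gives the most GC-rich codon of each
family all but 5% per alternative; the foreign profile moves 40% (two-codon
families) or 60% (larger families) of the mass onto the native-rare codons.
With foreign genes ≈ 10% of coding codons, every native-non-preferred codon
stays below the 10% genome-wide threshold (≈ 5–9.5%), so the rare set is
stable, while foreign genes average ≈ 0.45 rare-codon frequency vs ≈ 0.10
for native genes — mirroring the coupling of rare-codon usage and elevated
AT that marks laterally transferred genes in a GC-rich host.

**TU perturbation.** Annotated 5′ ends are shifted by a two-regime draw:
zero with probability 0.15, a > 100 bp offset (uniform 101–330, always an
extension) with probability 0.09, otherwise geometric with mean 5 bp
(extension with probability 0.8; shrinks are capped so the annotated 5′
never enters the first CDS). This reproduces the empirical shape of
curated-map corrections — a small median with a distinct >100 nt tail of
extensions — without fitting any real offset data, whose full distribution
is not published. Six multi-gene TUs receive an additional internal TSS at
their second cistron's start; nine single-gene TUs are withheld from the
map (orphans) but keep their TSS.

**DE truth model.**
`true_lfc = N(0, 1.1) + β_rare·(rareFreq − mean) + β_AT·(AT − mean) +
replicon_effect + category_effect`, with defaults β_rare = −3, β_AT = −5,
replicon effect −0.8 for the foreign megaplasmid and +0.8 for category
"O". Both composition covariates are **centred**: fold changes from a
count model are relative to a library normalisation, so composition enters
as a contrast between compositional extremes; an uncentred term would
shift the whole genome downward and destroy the roughly balanced up/down
split observed in real data. Genes with |true_lfc| ≥ 1 receive p_adj ~
U(0, α); a fraction α of null genes are injected false positives; observed
log2FC adds N(0, 0.1) noise. The baseline SD 1.1 puts the misregulated
fraction near 40%, the regime the analysis targets. TPM tables are
independent log-normal per TU, two replicates, normalised to 10⁶ per
column.

Defaults were fixed by a one-time calibration of the planted-effect
recovery rates and not revisited.

**What the synthetic tests do not show.** The generator plants clean
additive effects with uniform gene lengths, independent TPMs, and exactly
two codon regimes; real transcriptomes have correlated operon structure,
expression-coupled codon bias, overlapping genes and condition-dependent
TSS usage. Passing the recovery tests demonstrates that the
implementation's arithmetic and bookkeeping are correct under the stated
model — not that the biological conclusions transfer to any particular
dataset. Real published per-map counts (e.g. numbers of adjusted TUs in a
specific curated map) depend on those external maps and are out of scope.

## Problem sizes

The default bundle is ~600 genes / ~340 TUs per seed (generation + full
pipeline ≈ 0.3 s), chosen so that multi-seed recovery studies (50–100
seeds) and the exhaustive Fisher sweep (all 2×2 tables with N ≤ 40 against
an exact-Fraction enumeration oracle) run comfortably on one CPU. The
refinement benchmark uses ~200 TUs per seed across 50 seeds.

## Known limitations

* Orphan-TU creation requires the TSS table's gene column; no de novo
  gene–TSS assignment is attempted.
* The abundance contrast drops TUs absent from the TPM table (e.g. newly
  added orphan TUs).
* `vs_other` replicon contrasts cannot distinguish directions within a
  replicon (shared 2×2 table) — an intrinsic property of that
  construction, not a bug.
* The generator's adjusted-p assignment is a labelling device, not a count
  model; only direction/significance labels feed the statistics.
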