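"""Synthetic genome / annotation / TSS / DE bundles with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-replicon genome carrying two synonymous-codon-usage
regimes (native vs. foreign, the compositional signature of laterally
transferred genes), an operon-like transcription-unit map whose annotated
5' ends are perturbed relative to the true primary TSSs, and a
differential-expression table in which compositional foreignness shifts
log2 fold changes downward.  Every stochastic choice is recorded as ground
truth so each downstream stage can be scored exactly.

The DE table is emitted directly from a stated truth model (Gaussian
baseline plus additive composition, replicon, and category effects on the
log2 fold change, with adjusted p-values assigned by thresholding the true
effect); no read-level simulation is attempted, because the analysis scope
starts downstream of DE fitting.

A single named generator (numpy ``default_rng``) is derived from the config
seed per stage; there is no global RNG state, and identical config + seed
reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import composition
from .models import (
    ConfigError,
    Gene,
    GenomeBundle,
    PrimaryTSS,
    TranscriptionUnit,
)

log = logging.getLogger("foreignscan.synthetic")

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(composition.FAMILIES))  # 20 letters
_STOPS = ("TAA", "TAG", "TGA")


def _gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def preferred_codons() -> dict[str, str]:
    """One 'preferred' codon per family: the most GC-rich (ties: alphabetical).

    This mimics a GC-rich host genome whose favoured synonymous codons are
    GC-ending, so that a foreign (AT-shifted) codon regime is simultaneously
    rare-codon-enriched and AT-enriched — the coupling the analysis exploits.
    """
    return {
        aa: max(family, key=lambda c: (_gc(c), c))
        for aa, family in composition.FAMILIES.items()
    }


def default_codon_profiles() -> tuple[dict, dict]:
    """(native, foreign) per-amino-acid synonymous codon probability vectors.

    Native: the preferred codon takes all but 5% per alternative codon, so
    every non-preferred codon sits near 5% genome-wide — below the 10% rare
    threshold.  Foreign: 40% (two-codon families) or 60% (larger families)
    of the mass moves onto the native-rare codons, keeping their pooled
    genome-wide share below 10% as long as foreign genes contribute ~10% of
    codons, while giving foreign genes a far higher rare-codon frequency.
    """
    pref = preferred_codons()
    native: dict[str, dict[str, float]] = {}
    foreign: dict[str, dict[str, float]] = {}
    for aa, family in composition.FAMILIES.items():
        k = len(family)
        p = pref[aa]
        if k == 1:
            native[aa] = {p: 1.0}
            foreign[aa] = {p: 1.0}
            continue
        native[aa] = {c: (1.0 - 0.05 * (k - 1)) if c == p else 0.05 for c in family}
        rare_mass = 0.4 if k == 2 else 0.6
        foreign[aa] = {
            c: (1.0 - rare_mass) if c == p else rare_mass / (k - 1) for c in family
        }
    return native, foreign


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RepliconSpec:
    name: str
    length_bp: int
    gene_count: int
    origin: str  # "native" | "foreign"


@dataclass
class OffsetModel:
    """Two-regime 5'-offset distribution for perturbing annotated TU starts.

    A point mass at zero, a geometric bulk (median ~5 bp), and a separate
    uniform >100 bp atom; large offsets are always extensions, small ones
    are extensions with probability ``p_extension`` (shrinks are capped so
    the annotated 5' never enters the first cistron).
    """

    p_zero: float = 0.15
    geometric_mean_bp: float = 5.0
    p_large: float = 0.09
    p_extension: float = 0.8
    large_min: int = 101
    large_max: int = 330


@dataclass
class DEModel:
    """Truth model for log2 fold changes and significance labels.

    true_lfc = N(0, baseline_lfc_sd) + beta_rare * (rareFreq - mean)
             + beta_at * (AT - mean) + replicon_effect + category_effect.
    Genes with |true_lfc| >= lfc_threshold are significant (padj drawn
    below alpha); a fraction alpha of null genes are injected false
    positives.
    """

    baseline_lfc_sd: float = 1.1
    beta_rare: float = -3.0
    beta_at: float = -5.0
    replicon_effects: dict = field(default_factory=lambda: {"pMEG1": -0.8})
    category_effects: dict = field(default_factory=lambda: {"O": 0.8})
    alpha: float = 0.01
    lfc_threshold: float = 1.0
    lfc_noise_sd: float = 0.1


@dataclass
class ProphageSpec:
    """A contiguous block of foreign-regime genes inside a native replicon."""

    replicon: str = "chr"
    n_genes: int = 15
    category: str = "X"


@dataclass
class SyntheticConfig:
    seed: int = 0
    replicons: list = field(
        default_factory=lambda: [
            RepliconSpec("chr", 500_000, 540, "native"),
            RepliconSpec("pMEG1", 60_000, 45, "foreign"),
        ]
    )
    native_codon_profile: dict = field(default_factory=lambda: default_codon_profiles()[0])
    foreign_codon_profile: dict = field(default_factory=lambda: default_codon_profiles()[1])
    at_native: float = 0.35
    at_foreign: float = 0.55
    tss_offsets: OffsetModel = field(default_factory=OffsetModel)
    n_internal_tss_tus: int = 6
    n_orphan_genes: int = 9
    de: DEModel = field(default_factory=DEModel)
    categories: tuple = ("J", "E", "K", "O", "C", "T", "V")
    prophage: ProphageSpec | None = field(default_factory=ProphageSpec)
    # layout knobs (bp / codons)
    tu_sizes: tuple = ((1, 0.55), (2, 0.25), (3, 0.12), (4, 0.08))
    codon_range: tuple = (78, 139)  # internal sense codons, excl. start/stop
    utr_range: tuple = (20, 60)
    intra_gap_range: tuple = (10, 30)
    inter_gap_range: tuple = (600, 1000)
    margin: int = 500

    def validate(self) -> None:
        if not self.replicons:
            raise ConfigError("at least one replicon required")
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate replicon names")
        for r in self.replicons:
            if r.length_bp <= 0:
                raise ConfigError(f"replicon {r.name}: length_bp must be positive")
            if r.gene_count < 0:
                raise ConfigError(f"replicon {r.name}: gene_count must be >= 0")
            if r.origin not in ("native", "foreign"):
                raise ConfigError(f"replicon {r.name}: origin must be native|foreign")
        for label, profile in (
            ("native", self.native_codon_profile),
            ("foreign", self.foreign_codon_profile),
        ):
            if set(profile) != set(composition.FAMILIES):
                raise ConfigError(f"{label} profile must cover all 20 amino acids")
            for aa, vec in profile.items():
                if set(vec) != set(composition.FAMILIES[aa]):
                    raise ConfigError(f"{label} profile: bad codons for {aa}")
                if any(p < 0 for p in vec.values()):
                    raise ConfigError(f"{label} profile: negative probability for {aa}")
                if abs(sum(vec.values()) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{label} profile: {aa} probabilities sum to "
                        f"{sum(vec.values())!r}, not 1"
                    )
        for label, at in (("at_native", self.at_native), ("at_foreign", self.at_foreign)):
            if not 0.0 <= at <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1]")
        o = self.tss_offsets
        if not (0 <= o.p_zero <= 1 and 0 <= o.p_large <= 1 and o.p_zero + o.p_large <= 1):
            raise ConfigError("offset probabilities must be in [0,1] and sum <= 1")
        if o.geometric_mean_bp < 1:
            raise ConfigError("geometric_mean_bp must be >= 1")
        if not (100 < o.large_min <= o.large_max):
            raise ConfigError("large offsets must exceed 100 bp")
        if not 0 <= o.p_extension <= 1:
            raise ConfigError("p_extension must be in [0, 1]")
        if self.n_internal_tss_tus < 0 or self.n_orphan_genes < 0:
            raise ConfigError("counts must be >= 0")
        if self.de.baseline_lfc_sd <= 0:
            raise ConfigError("baseline_lfc_sd must be positive")
        if not 0 < self.de.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.de.lfc_threshold <= 0:
            raise ConfigError("lfc_threshold must be positive")
        if abs(sum(p for _, p in self.tu_sizes) - 1.0) > 1e-9:
            raise ConfigError("tu_sizes probabilities must sum to 1")
        total_genes = sum(r.gene_count for r in self.replicons)
        if total_genes > 0 and not self.categories:
            raise ConfigError("categories must be non-empty when genes are generated")
        if self.prophage is not None and self.prophage.n_genes > 0:
            rep = {r.name: r for r in self.replicons}.get(self.prophage.replicon)
            if rep is None:
                raise ConfigError(f"prophage replicon {self.prophage.replicon} unknown")
            if self.prophage.n_genes > rep.gene_count:
                raise ConfigError("prophage larger than its replicon's gene count")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["replicons"] = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
                          for r in self.replicons]
        d["categories"] = list(self.categories)
        d["tu_sizes"] = [list(x) for x in self.tu_sizes]
        for key in ("codon_range", "utr_range", "intra_gap_range", "inter_gap_range"):
            d[key] = list(getattr(self, key))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "replicons" in d:
            d["replicons"] = [
                r if isinstance(r, RepliconSpec) else RepliconSpec(**r)
                for r in d["replicons"]
            ]
        if "tss_offsets" in d and isinstance(d["tss_offsets"], dict):
            d["tss_offsets"] = OffsetModel(**d["tss_offsets"])
        if "de" in d and isinstance(d["de"], dict):
            d["de"] = DEModel(**d["de"])
        if "prophage" in d and isinstance(d["prophage"], dict):
            d["prophage"] = ProphageSpec(**d["prophage"])
        if "categories" in d:
            d["categories"] = tuple(d["categories"])
        if "tu_sizes" in d:
            d["tu_sizes"] = tuple(tuple(x) for x in d["tu_sizes"])
        for key in ("codon_range", "utr_range", "intra_gap_range", "inter_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study conditions (calibrated once; see docs/methods.md)."""
    cfg = SyntheticConfig(seed=seed)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator decided, recorded exactly as applied."""

    gene_origin: dict = field(default_factory=dict)
    true_tus: list = field(default_factory=list)  # TranscriptionUnit, incl. orphans
    tu_true_five_prime: dict = field(default_factory=dict)  # tu_id -> 1-based pos
    tu_offsets: dict = field(default_factory=dict)  # tu_id -> signed bp (+ = extension)
    internal_tss_tus: list = field(default_factory=list)
    orphan_genes: list = field(default_factory=list)
    true_log2fc: dict = field(default_factory=dict)
    true_direction: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "gene_origin": self.gene_origin,
            "true_tus": [
                {
                    "tu_id": t.tu_id,
                    "replicon": t.replicon,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "member_gene_ids": t.member_gene_ids,
                }
                for t in self.true_tus
            ],
            "tu_true_five_prime": self.tu_true_five_prime,
            "tu_offsets": self.tu_offsets,
            "internal_tss_tus": self.internal_tss_tus,
            "orphan_genes": self.orphan_genes,
            "true_log2fc": self.true_log2fc,
            "true_direction": self.true_direction,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        truth = cls(
            gene_origin=d["gene_origin"],
            true_tus=[TranscriptionUnit(**t) for t in d["true_tus"]],
            tu_true_five_prime=d["tu_true_five_prime"],
            tu_offsets=d["tu_offsets"],
            internal_tss_tus=d["internal_tss_tus"],
            orphan_genes=d["orphan_genes"],
            true_log2fc=d["true_log2fc"],
            true_direction=d["true_direction"],
        )
        return truth


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    """One named generator per stage, derived from the config seed."""
    return np.random.default_rng([int(config.seed), stage])


# ---------------------------------------------------------------------------
# Stage 1: genome + genes
# ---------------------------------------------------------------------------


@dataclass
class _GeneDraft:
    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    origin: str
    n_codons: int  # internal sense codons (excl. start/stop)
    category: str | None = None


def _draw_tu_sizes(rng, gene_count: int, tu_sizes) -> list[int]:
    sizes = []
    ks = np.array([k for k, _ in tu_sizes])
    ps = np.array([p for _, p in tu_sizes], dtype=float)
    ps = ps / ps.sum()
    remaining = gene_count
    while remaining > 0:
        s = int(rng.choice(ks, p=ps))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def _batch_codons(rng, profile: dict, n_codons_per_gene: list[int]) -> list[str]:
    """Draw internal codon strings for many genes of one origin at once."""
    total = int(sum(n_codons_per_gene))
    if total == 0:
        return ["" for _ in n_codons_per_gene]
    aa_idx = rng.integers(0, len(AMINO_ACIDS), total)
    codon_arr = np.empty(total, dtype="<U3")
    for i, aa in enumerate(AMINO_ACIDS):
        mask = aa_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        family = composition.FAMILIES[aa]
        probs = np.array([profile[aa][c] for c in family])
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        choice = np.searchsorted(cum, rng.random(m), side="right")
        codon_arr[mask] = np.array(family, dtype="<U3")[choice]
    out = []
    pos = 0
    for n in n_codons_per_gene:
        out.append("".join(codon_arr[pos:pos + n]))
        pos += n
    return out


def generate_genome(config: SyntheticConfig) -> tuple[GenomeBundle, GroundTruth]:
    """Lay out operon-like TUs, draw in-frame CDSs, assemble replicon sequences.

    Deterministic for a fixed config + seed.  Raises ``ConfigError`` when the
    requested genes cannot fit into a replicon's length.
    """
    config.validate()
    rng = _rng(config, 0)
    truth = GroundTruth()
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    lo_c, hi_c = config.codon_range

    for rep in config.replicons:
        sizes = _draw_tu_sizes(rng, rep.gene_count, config.tu_sizes)
        prophage_idx: set[int] = set()
        if (
            config.prophage is not None
            and config.prophage.replicon == rep.name
            and config.prophage.n_genes > 0
        ):
            p0 = max(0, rep.gene_count // 2 - config.prophage.n_genes // 2)
            prophage_idx = set(range(p0, p0 + config.prophage.n_genes))

        drafts: list[_GeneDraft] = []
        tus_here: list[tuple[str, int, int, str, list[int]]] = []
        cursor = config.margin
        gidx = 0
        for j, size in enumerate(sizes):
            gap = int(rng.integers(config.inter_gap_range[0], config.inter_gap_range[1] + 1))
            utr = int(rng.integers(config.utr_range[0], config.utr_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_codons = rng.integers(lo_c, hi_c + 1, size)
            intra = rng.integers(
                config.intra_gap_range[0], config.intra_gap_range[1] + 1, max(size - 1, 1)
            )
            tu_id = f"{rep.name}_tu{j:04d}"
            laid_idx: list[int] = []
            if strand == "+":
                tu_start = cursor + gap
                gpos = tu_start + utr
                for k in range(size):
                    length = (int(n_codons[k]) + 2) * 3
                    origin = (
                        "foreign" if (gidx in prophage_idx or rep.origin == "foreign")
                        else "native"
                    )
                    drafts.append(
                        _GeneDraft(
                            f"{rep.name}_g{gidx:04d}", rep.name, gpos, gpos + length,
                            strand, origin, int(n_codons[k]),
                        )
                    )
                    laid_idx.append(len(drafts) - 1)
                    gpos += length + (int(intra[k]) if k < size - 1 else 0)
                    gidx += 1
                tu_end = drafts[-1].end
                cursor = tu_end
            else:
                tu_start = cursor + gap
                gpos = tu_start
                for k in range(size):
                    length = (int(n_codons[k]) + 2) * 3
                    origin = (
                        "foreign" if (gidx in prophage_idx or rep.origin == "foreign")
                        else "native"
                    )
                    drafts.append(
                        _GeneDraft(
                            f"{rep.name}_g{gidx:04d}", rep.name, gpos, gpos + length,
                            strand, origin, int(n_codons[k]),
                        )
                    )
                    laid_idx.append(len(drafts) - 1)
                    gpos += length + (int(intra[k]) if k < size - 1 else 0)
                    gidx += 1
                tu_end = drafts[-1].end + utr
                cursor = tu_end
                laid_idx = laid_idx[::-1]  # 5' -> 3' on minus strand: right to left
            tus_here.append((tu_id, tu_start, tu_end, strand, laid_idx))

        if cursor + config.margin > rep.length_bp:
            raise ConfigError(
                f"replicon {rep.name}: {rep.gene_count} genes need ~{cursor + config.margin} bp "
                f"but length_bp is {rep.length_bp}"
            )

        # categories: prophage block gets its own label; the rest are uniform
        cats = list(config.categories) or [None]
        cat_draw = rng.integers(0, len(cats), len(drafts))
        for i, d in enumerate(drafts):
            if i in prophage_idx and config.prophage is not None:
                d.category = config.prophage.category
            else:
                d.category = cats[int(cat_draw[i])]

        # batched CDS drawing, native genes first then foreign, positional order
        for origin, profile in (
            ("native", config.native_codon_profile),
            ("foreign", config.foreign_codon_profile),
        ):
            group = [d for d in drafts if d.origin == origin]
            if not group:
                continue
            internal = _batch_codons(rng, profile, [d.n_codons for d in group])
            stops = rng.integers(0, 3, len(group))
            for d, mid, s in zip(group, internal, stops):
                d.cds = "ATG" + mid + _STOPS[int(s)]  # type: ignore[attr-defined]

        # background sequence, then paste CDSs (reverse-complement on minus)
        at = config.at_native if rep.origin == "native" else config.at_foreign
        probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
        idx = rng.choice(4, size=rep.length_bp, p=probs)
        arr = np.frombuffer(b"ATGC", dtype=np.uint8)[idx].copy()
        for d in drafts:
            cds = d.cds  # type: ignore[attr-defined]
            if d.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            arr[d.start:d.end] = np.frombuffer(cds.encode(), dtype=np.uint8)
        sequences[rep.name] = arr.tobytes().decode()

        for d in drafts:
            genes.append(
                Gene(d.gene_id, d.replicon, d.start, d.end, d.strand, d.category, d.origin)
            )
            truth.gene_origin[d.gene_id] = d.origin
        for tu_id, tu_start, tu_end, strand, laid_idx in tus_here:
            members = [drafts[i].gene_id for i in laid_idx]
            tu = TranscriptionUnit(tu_id, rep.name, tu_start, tu_end, strand, members)
            truth.true_tus.append(tu)
            truth.tu_true_five_prime[tu_id] = tu.five_prime + 1

        log.info(
            "generated replicon %s: %d genes, %d TUs, %d bp",
            rep.name, len(drafts), len(tus_here), rep.length_bp,
        )

    bundle = GenomeBundle(
        sequences=sequences,
        genes=genes,
        replicon_origins={r.name: r.origin for r in config.replicons},
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Stage 2: perturbed TU map + TSS table
# ---------------------------------------------------------------------------


def generate_tu_and_tss(
    bundle: GenomeBundle, truth: GroundTruth, config: SyntheticConfig
) -> tuple[list[TranscriptionUnit], list[PrimaryTSS]]:
    """Perturb TU 5' ends, inject internal TSSs, and drop orphan genes.

    The emitted TU map is the *annotated* (perturbed) map; the TSS table
    carries the true primary TSS of every TU (orphans included) plus the
    injected internal TSSs.  Offsets are recorded exactly as applied
    (positive = extension beyond the true 5').
    """
    rng = _rng(config, 1)
    o = config.tss_offsets
    genes_by_id = bundle.genes_by_id

    multi = [t for t in truth.true_tus if len(t.member_gene_ids) > 1]
    if config.n_internal_tss_tus > len(multi):
        raise ConfigError(
            f"n_internal_tss_tus={config.n_internal_tss_tus} exceeds the "
            f"{len(multi)} available multi-gene TUs"
        )
    internal_ids: list[str] = []
    if config.n_internal_tss_tus:
        pick = rng.choice(len(multi), size=config.n_internal_tss_tus, replace=False)
        internal_ids = [multi[int(i)].tu_id for i in sorted(pick)]
    mono = [t for t in truth.true_tus if len(t.member_gene_ids) == 1]
    if config.n_orphan_genes > len(mono):
        raise ConfigError(
            f"n_orphan_genes={config.n_orphan_genes} exceeds the "
            f"{len(mono)} available single-gene TUs"
        )
    orphan_tu_ids: set[str] = set()
    if config.n_orphan_genes:
        pick = rng.choice(len(mono), size=config.n_orphan_genes, replace=False)
        orphan_tu_ids = {mono[int(i)].tu_id for i in sorted(pick)}

    perturbed: list[TranscriptionUnit] = []
    tss: list[PrimaryTSS] = []
    geom_p = 1.0 / o.geometric_mean_bp

    for tu in truth.true_tus:
        first = genes_by_id[tu.member_gene_ids[0]]
        # true primary TSS (kept even for orphans)
        tss.append(
            PrimaryTSS(tu.replicon, tu.five_prime + 1, tu.strand, first.gene_id)
        )
        if tu.tu_id in orphan_tu_ids:
            truth.orphan_genes.append(first.gene_id)
            continue

        u = rng.random()
        if u < o.p_zero:
            mag, extend = 0, True
        elif u < o.p_zero + o.p_large:
            mag = int(rng.integers(o.large_min, o.large_max + 1))
            extend = True  # the large-offset regime extends, per the two-regime model
        else:
            mag = int(rng.geometric(geom_p))
            extend = rng.random() < o.p_extension
        utr = (first.start - tu.start) if tu.strand == "+" else (tu.end - first.end)
        if not extend:
            mag = min(mag, max(utr - 1, 0))  # annotated 5' stays out of the first CDS

        if tu.strand == "+":
            new_start = tu.start - mag if extend else tu.start + mag
            if new_start < 0:
                mag, new_start = tu.start, 0
            ptu = TranscriptionUnit(
                tu.tu_id, tu.replicon, new_start, tu.end, tu.strand,
                list(tu.member_gene_ids),
            )
        else:
            length = len(bundle.sequences[tu.replicon])
            new_end = tu.end + mag if extend else tu.end - mag
            if new_end > length:
                mag, new_end = length - tu.end, length
            ptu = TranscriptionUnit(
                tu.tu_id, tu.replicon, tu.start, new_end, tu.strand,
                list(tu.member_gene_ids),
            )
        truth.tu_offsets[tu.tu_id] = mag if extend else -mag
        perturbed.append(ptu)

    for tu_id in internal_ids:
        tu = next(t for t in truth.true_tus if t.tu_id == tu_id)
        cistron = genes_by_id[tu.member_gene_ids[1]]
        tss.append(
            PrimaryTSS(tu.replicon, cistron.five_prime + 1, tu.strand, cistron.gene_id)
        )
        truth.internal_tss_tus.append(tu_id)

    perturbed.sort(key=lambda t: (t.replicon, t.start))
    tss.sort(key=lambda t: (t.replicon, t.position, t.strand))
    log.info(
        "TU map: %d TUs emitted, %d orphan genes withheld, %d internal TSSs injected",
        len(perturbed), len(truth.orphan_genes), len(internal_ids),
    )
    return perturbed, tss


# ---------------------------------------------------------------------------
# Stage 3: differential-expression and abundance tables
# ---------------------------------------------------------------------------


def generate_de_table(
    bundle: GenomeBundle, truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a DE table from the additive truth model, plus a per-TU TPM table.

    Composition covariates are centred: log2 fold changes from a count model
    are relative to a library normalisation, so a composition effect acts as
    a contrast between compositional extremes rather than a genome-wide
    shift.  TPM columns are positive and each sums to 1e6.
    """
    rng = _rng(config, 2)
    de_model = config.de
    metrics, _usage = composition.per_gene_metrics(bundle)
    n = len(metrics)
    if n == 0:
        de = pd.DataFrame(columns=["gene_id", "log2fc", "padj"])
        tpm = pd.DataFrame(columns=["tu_id", "tpm_rep1", "tpm_rep2"])
        return de, tpm

    rare = metrics["rare_codon_freq"].to_numpy(dtype=float)
    at = metrics["at_content"].to_numpy(dtype=float)
    rare_dev = rare - np.nanmean(rare)
    at_dev = at - np.nanmean(at)
    rep_eff = metrics["replicon"].map(
        lambda r: de_model.replicon_effects.get(r, 0.0)
    ).to_numpy(dtype=float)
    cat_eff = metrics["category"].map(
        lambda c: de_model.category_effects.get(c, 0.0)
    ).to_numpy(dtype=float)

    true_lfc = (
        rng.normal(0.0, de_model.baseline_lfc_sd, n)
        + de_model.beta_rare * np.nan_to_num(rare_dev)
        + de_model.beta_at * np.nan_to_num(at_dev)
        + rep_eff
        + cat_eff
    )
    sig = np.abs(true_lfc) >= de_model.lfc_threshold
    padj = np.empty(n)
    padj[sig] = rng.uniform(0.0, de_model.alpha, int(sig.sum()))
    null = ~sig
    fp = rng.random(n) < de_model.alpha
    padj[null & fp] = rng.uniform(0.0, de_model.alpha, int((null & fp).sum()))
    padj[null & ~fp] = rng.uniform(de_model.alpha, 1.0, int((null & ~fp).sum()))
    obs_lfc = true_lfc + rng.normal(0.0, de_model.lfc_noise_sd, n)

    gene_ids = metrics["gene_id"].tolist()
    for gid, lfc, s in zip(gene_ids, true_lfc, sig):
        truth.true_log2fc[gid] = float(lfc)
        truth.true_direction[gid] = ("up" if lfc > 0 else "down") if s else "ns"
    de = pd.DataFrame({"gene_id": gene_ids, "log2fc": obs_lfc, "padj": padj})

    orphans = set(truth.orphan_genes)
    tu_ids = [
        t.tu_id
        for t in truth.true_tus
        if not (len(t.member_gene_ids) == 1 and t.member_gene_ids[0] in orphans)
    ]
    base = rng.lognormal(0.0, 1.2, len(tu_ids))
    reps = {}
    for r in (1, 2):
        w = base * rng.lognormal(0.0, 0.15, len(tu_ids))
        reps[f"tpm_rep{r}"] = w / w.sum() * 1e6
    tpm = pd.DataFrame({"tu_id": tu_ids, **reps})
    return de, tpm


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_genome_fasta(bundle: GenomeBundle, path) -> None:
    with open(path, "w") as fh:
        for name in bundle.sequences:
            fh.write(f">{name}\n")
            seq = bundle.sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_genes_gff3(bundle: GenomeBundle, path) -> None:
    """GFF3 (1-based inclusive); CDS features carry gene id, category, origin."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in bundle.sequences.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in bundle.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.category is not None:
                attrs.append(f"category={g.category}")
            if g.origin is not None:
                attrs.append(f"origin={g.origin}")
            fh.write(
                "\t".join(
                    [
                        g.replicon, "foreignscan", "gene", str(g.start + 1),
                        str(g.end), ".", g.strand, ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )
            cattrs = [f"ID=cds-{g.gene_id}", f"Parent={g.gene_id}",
                      f"gene_id={g.gene_id}"] + attrs[1:]
            fh.write(
                "\t".join(
                    [
                        g.replicon, "foreignscan", "CDS", str(g.start + 1),
                        str(g.end), ".", g.strand, "0", ";".join(cattrs),
                    ]
                )
                + "\n"
            )


def write_tu_bed(tus: list[TranscriptionUnit], path) -> None:
    with open(path, "w") as fh:
        for t in tus:
            fh.write(f"{t.replicon}\t{t.start}\t{t.end}\t{t.tu_id}\t0\t{t.strand}\n")


def write_tss_tsv(tss: list[PrimaryTSS], path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tstrand\tgene_id\n")
        for t in tss:
            fh.write(
                f"{t.replicon}\t{t.position}\t{t.strand}\t"
                f"{t.gene_id if t.gene_id is not None else 'NA'}\n"
            )


def simulate(config: SyntheticConfig, out_dir) -> dict:
    """Run all generator stages and write the full file bundle.

    Returns a dict of output paths.  Identical config + seed produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_genome(config)
    tus, tss = generate_tu_and_tss(bundle, truth, config)
    de, tpm = generate_de_table(bundle, truth, config)

    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.gff3",
        "tus": out / "tus.bed",
        "tss": out / "tss.tsv",
        "de": out / "de.tsv",
        "tpm": out / "tpm.tsv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    write_genome_fasta(bundle, paths["genome"])
    write_genes_gff3(bundle, paths["genes"])
    write_tu_bed(tus, paths["tus"])
    write_tss_tsv(tss, paths["tss"])
    de.to_csv(paths["de"], sep="\t", index=False, float_format="%.6g")
    tpm.to_csv(paths["tpm"], sep="\t", index=False, float_format="%.10g")
    truth.to_json(paths["truth"])
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
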