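"""End-to-end pipeline: simulate -> refine-tu -> composition -> associate.

One reproducible run over a synthetic bundle: the generator writes the
file set, every downstream stage re-reads it from disk (exercising the I/O
dialects), and the run produces a machine-readable report plus a manifest
(config hash, seed, file digests, per-stage row counts) sufficient to
verify byte-identical re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, composition, synthetic, tu_map
from .models import ForeignscanError, GenomeBundle

log = logging.getLogger("foreignscan.pipeline")


@dataclass
class PipelineConfig:
    """Every constant of the analysis surfaced as a named key.

    Defaults follow the analysis conventions: DE significance alpha 0.01,
    rare-codon threshold 0.10 (strict), promoter window -50..+10, TSS-to-TU
    matching distance 500 bp.
    """

    seed: int = 0
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    max_distance_bp: int = 500
    keep_upstream_remainder: bool = False
    promoter_upstream: int = 50
    promoter_downstream: int = 10
    rare_threshold: float = 0.10
    alpha: float = 0.01
    reference_replicon: str | None = None  # default: first native replicon
    construction: str = "vs_rest"

    def __post_init__(self):
        self.synthetic.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = synthetic.SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> tuple[dict, dict]:
    """Execute all stages in dependency order; returns (manifest, report).

    Any stage failure raises with the stage name in the message.  The
    report aggregates the adjustment report, composition summary, DE
    summary and every contingency result; both are also written as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.synthetic.validate()
    manifest: dict = {
        "tool": "foreignscan",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    report: dict = {"seed": config.seed}

    # -- stage 1: simulate --------------------------------------------------
    try:
        paths = synthetic.simulate(config.synthetic, out / "simulated")
    except Exception as exc:
        raise ForeignscanError(f"stage simulate failed: {exc}") from exc
    manifest["inputs"] = {k: _sha256(v) for k, v in paths.items()}
    log.info("stage simulate: wrote %d files (seed %d)", len(paths), config.seed)

    # -- stage 2: refine-tu -------------------------------------------------
    try:
        sequences = tu_map.load_genome_fasta(paths["genome"])
        genes = tu_map.load_genes(paths["genes"], replicons=set(sequences))
        tus = tu_map.load_tu_map(paths["tus"], replicons=set(sequences))
        tss = tu_map.load_tss_table(
            paths["tss"], replicons=set(sequences),
            replicon_lengths={k: len(v) for k, v in sequences.items()},
        )
        refined, adj_report = tu_map.refine_tu_map(
            tus, tss, genes,
            max_distance_bp=config.max_distance_bp,
            keep_upstream_remainder=config.keep_upstream_remainder,
        )
        synthetic.write_tu_bed(refined, out / "refined_tus.bed")
        tu_map.write_adjustment_report(
            adj_report, out / "adjustments.tsv", out / "adjustments.json"
        )
        windows, n_dropped = tu_map.extract_promoter_windows(
            tss, sequences, config.promoter_upstream, config.promoter_downstream
        )
        tu_map.write_promoter_fasta(windows, out / "promoters.fa")
    except ForeignscanError:
        raise
    except Exception as exc:
        raise ForeignscanError(f"stage refine-tu failed: {exc}") from exc
    manifest["stages"]["refine_tu"] = {
        "n_tus_in": len(tus), "n_tus_out": len(refined),
        "n_tss": len(tss), "n_promoter_windows": len(windows),
        "n_windows_dropped": n_dropped,
    }
    report["adjustment"] = adj_report.summary()
    log.info("stage refine-tu: %d TUs in, %d out, %d TSS", len(tus), len(refined), len(tss))

    # -- stage 3: composition ----------------------------------------------
    try:
        bundle = GenomeBundle(sequences=sequences, genes=genes)
        metrics, usage = composition.per_gene_metrics(bundle, config.rare_threshold)
        composition.write_metrics_tsv(metrics, out / "metrics.tsv")
        usage.to_frame().to_csv(out / "codon_usage.tsv", sep="\t", index=False)
    except ForeignscanError:
        raise
    except Exception as exc:
        raise ForeignscanError(f"stage composition failed: {exc}") from exc
    rare = usage.rare_codons(config.rare_threshold)
    manifest["stages"]["composition"] = {"n_genes": len(metrics)}
    report["composition"] = {
        "n_rare_codons": len(rare.codons),
        "rare_threshold": config.rare_threshold,
        "mean_rare_codon_freq": float(metrics["rare_codon_freq"].mean()),
        "mean_at_content": float(metrics["at_content"].mean()),
    }
    log.info("stage composition: %d genes, %d rare codons", len(metrics), len(rare.codons))

    # -- stage 4: associate -------------------------------------------------
    try:
        de = pd.read_csv(paths["de"], sep="\t")
        tpm = pd.read_csv(paths["tpm"], sep="\t")
        labeled, summary = association.classify_de(de, config.alpha)
        labeled = labeled.merge(
            metrics[["gene_id", "rare_codon_freq", "at_content", "replicon", "category"]],
            on="gene_id", how="left",
        )

        reference = config.reference_replicon
        if reference is None:
            native = [r.name for r in config.synthetic.replicons if r.origin == "native"]
            reference = native[0] if native else config.synthetic.replicons[0].name

        q_rare = association.quartile_contrast(
            labeled.set_index("gene_id")["rare_codon_freq"], labeled,
            direction="down", metric_name="rare_codon_freq",
        )
        q_at = association.quartile_contrast(
            labeled.set_index("gene_id")["at_content"], labeled,
            direction="down", metric_name="at_content",
        )
        repl = association.replicon_contrasts(labeled, reference, config.construction)
        cats = association.category_enrichment(labeled)

        region = None
        prophage = config.synthetic.prophage
        if prophage is not None and prophage.n_genes > 0:
            region_genes = [
                g.gene_id for g in genes if g.category == prophage.category
            ]
            if region_genes:
                region = association.region_summary(labeled, region_genes)

        abundance = association.abundance_contrast(tpm, refined, labeled)

        tidy = association.results_to_frame([q_rare, q_at] + cats + [abundance])
        tidy.to_csv(out / "association_results.tsv", sep="\t", index=False)
        repl.to_csv(out / "replicon_contrasts.tsv", sep="\t", index=False)
    except ForeignscanError:
        raise
    except Exception as exc:
        raise ForeignscanError(f"stage associate failed: {exc}") from exc

    report["de_summary"] = {
        "alpha": config.alpha,
        "n_up": summary.n_up,
        "n_down": summary.n_down,
        "n_ns": summary.n_ns,
        "n_total": summary.n_total,
        "misregulated_fraction": summary.misregulated_fraction,
    }
    report["contrasts"] = {
        "quartile_rare_codon": q_rare.as_record(),
        "quartile_at_content": q_at.as_record(),
        "replicon": repl.to_dict(orient="records"),
        "categories": [r.as_record() for r in cats],
        "abundance": abundance.as_record(),
    }
    if region is not None:
        report["contrasts"]["prophage_region"] = region
    manifest["stages"]["associate"] = {
        "n_genes": summary.n_total,
        "n_tests": 2 + len(cats) + len(repl) + 1,
        "reference_replicon": reference,
    }
    log.info(
        "stage associate: %d/%d genes misregulated; quartile p (rare) = %.3g",
        summary.n_misregulated, summary.n_total, q_rare.p_value,
    )

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*"))
        if p.is_file() and p.suffix in (".tsv", ".bed", ".fa", ".json")
        and p.name not in ("report.json", "manifest.json")
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest, report
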