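"""Differential-expression direction classification and contingency analyses.

The questions answered here are those a compositional-foreignness study
asks of a DE table: is the direction of regulation (up / down at
p_adj < alpha) associated with rare-codon frequency or AT content
(first-vs-fourth quartile contrasts), with the replicon a gene resides on
(each secondary replicon against the main chromosome), or with functional
category (per-category Fisher tests with Bonferroni correction)?  Plus
plain count summaries for gene regions (e.g. a prophage block) and a
rank-sum contrast of transcript abundance between up- and downregulated
first cistrons.

The two-sided Fisher exact p-value uses the point-probability definition
(the sum of hypergeometric probabilities of all tables, with the observed
margins, that are no more probable than the observed table), evaluated in
exact integer arithmetic so that ties between table probabilities are
decided exactly.  The reported odds ratio is the sample odds ratio ad/bc,
flagged as such.
"""

from __future__ import annotations

import logging
import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .models import ContingencyResult, DESummary, ForeignscanError

log = logging.getLogger("foreignscan.association")

DIRECTIONS = ("up", "down", "ns")


# ---------------------------------------------------------------------------
# DE direction classification
# ---------------------------------------------------------------------------


def classify_de(de: pd.DataFrame, alpha: float = 0.01) -> tuple[pd.DataFrame, DESummary]:
    """Label each gene up / down / ns at significance level ``alpha``.

    up: padj < alpha and log2fc > 0; down: padj < alpha and log2fc < 0;
    everything else (including missing padj, which is logged) is ns.
    Returns the labeled frame (copy, with a ``direction`` column) and the
    summary counts.
    """
    if not {"gene_id", "log2fc", "padj"} <= set(de.columns):
        raise ForeignscanError("DE table needs columns gene_id, log2fc, padj")
    out = de.copy()
    padj = out["padj"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    n_missing = int(np.isnan(padj).sum())
    if n_missing:
        log.info("classify_de: %d genes with missing padj treated as ns", n_missing)
    sig = ~np.isnan(padj) & (padj < alpha)
    direction = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    out["direction"] = direction
    summary = DESummary(
        n_up=int((direction == "up").sum()),
        n_down=int((direction == "down").sum()),
        n_ns=int((direction == "ns").sum()),
        n_total=len(out),
    )
    return out, summary


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, point-probability definition)
# ---------------------------------------------------------------------------


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_two_sided(
    table,
    row_labels=("row1", "row2"),
    col_labels=("col1", "col2"),
    note: str = "",
) -> ContingencyResult:
    """Exact two-sided Fisher test on a 2x2 table of non-negative ints.

    p = sum of P(table') over tables with the observed margins whose
    hypergeometric probability is <= that of the observed table, with
    probability comparisons done on exact integer weights.  A table with a
    zero margin admits only itself, so p = 1 (warned).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise ForeignscanError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2

    if min(r1, r2, c1, c2) == 0:
        warnings.warn("fisher_two_sided: zero margin, p = 1", stacklevel=2)
        p = 1.0
    else:
        amin, amax = max(0, c1 - r2), min(c1, r1)
        weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(amin, amax + 1)]
        w_obs = weights[a - amin]
        p = float(Fraction(sum(w for w in weights if w <= w_obs), math.comb(n, c1)))

    return ContingencyResult(
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
        counts=((a, b), (c, d)),
        p_value=p,
        method="fisher_two_sided",
        odds_ratio=_sample_odds_ratio(a, b, c, d),
        odds_ratio_kind="sample",
        note=note,
    )


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def apply_bonferroni(results: list[ContingencyResult]) -> list[ContingencyResult]:
    m = len(results)
    for r in results:
        r.p_adjusted = bonferroni(r.p_value, m)
        r.adjustment = "bonferroni"
        r.m_tests = m
    return results


# ---------------------------------------------------------------------------
# Replicon contrasts (Table-1-style)
# ---------------------------------------------------------------------------


def replicon_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-replicon (detected, increased, decreased) counts from labeled DE."""
    if "replicon" not in labeled.columns:
        raise ForeignscanError("labeled DE table needs a 'replicon' column")
    rows = []
    for rep, grp in labeled.groupby("replicon", sort=True):
        rows.append(
            {
                "replicon": rep,
                "detected": len(grp),
                "increased": int((grp["direction"] == "up").sum()),
                "decreased": int((grp["direction"] == "down").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("replicon")


def replicon_contrasts_from_counts(
    counts: pd.DataFrame,
    reference: str,
    construction: str = "vs_rest",
) -> pd.DataFrame:
    """Fisher contrasts of each replicon against a reference replicon.

    ``counts`` is indexed by replicon with columns detected / increased /
    decreased.  For each non-reference replicon and each direction the 2x2
    table is, under ``vs_rest`` (the default): (direction, not-direction) x
    (replicon, reference); under ``vs_other``: (increased, decreased) x
    (replicon, reference) — note the latter yields the same table, hence
    the same p, for both directions of one replicon.
    """
    if construction not in ("vs_rest", "vs_other"):
        raise ForeignscanError(f"unknown construction {construction!r}")
    if reference not in counts.index:
        raise ForeignscanError(f"reference replicon {reference!r} not in counts")
    ref = counts.loc[reference]
    rows = []
    for rep, row in counts.iterrows():
        if rep == reference:
            continue
        for direction, col, other_col in (
            ("increased", "increased", "decreased"),
            ("decreased", "decreased", "increased"),
        ):
            if construction == "vs_rest":
                tab = (
                    (int(row[col]), int(row["detected"] - row[col])),
                    (int(ref[col]), int(ref["detected"] - ref[col])),
                )
            else:
                tab = (
                    (int(row[col]), int(row[other_col])),
                    (int(ref[col]), int(ref[other_col])),
                )
            res = fisher_two_sided(
                tab,
                row_labels=(rep, reference),
                col_labels=(direction, "rest" if construction == "vs_rest" else other_col),
                note=construction,
            )
            rows.append(
                {
                    "replicon": rep,
                    "direction": direction,
                    "detected": int(row["detected"]),
                    "increased": int(row["increased"]),
                    "decreased": int(row["decreased"]),
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                    "construction": construction,
                }
            )
    return pd.DataFrame(rows)


def replicon_contrasts(
    labeled: pd.DataFrame,
    reference: str,
    construction: str = "vs_rest",
) -> pd.DataFrame:
    """Table-1-style layout plus per-direction Fisher p against the reference."""
    counts = replicon_counts(labeled)
    if reference not in counts.index:
        raise ForeignscanError(f"reference replicon {reference!r} has no genes")
    return replicon_contrasts_from_counts(counts, reference, construction)


# ---------------------------------------------------------------------------
# Quartile contrasts
# ---------------------------------------------------------------------------


def quartile_contrast(
    metric: pd.Series,
    labeled: pd.DataFrame,
    direction: str = "down",
    metric_name: str = "metric",
) -> ContingencyResult:
    """Fisher contrast of DE direction between metric quartiles Q4 and Q1.

    Genes are ordered by (metric, gene_id) — the stable gene-id tie-break
    makes the partition deterministic — and the lowest and highest n//4
    genes form Q1 and Q4.  The 2x2 table is (Q4, Q1) x (direction, rest);
    an odds ratio > 1 means the high-metric quartile is enriched for the
    direction.
    """
    if direction not in ("up", "down"):
        raise ForeignscanError("direction must be 'up' or 'down'")
    df = labeled.set_index("gene_id")[["direction"]].join(metric.rename("metric"), how="inner")
    df = df.dropna(subset=["metric"])
    n = len(df)
    if n < 4:
        raise ForeignscanError(f"quartile_contrast: need >= 4 genes with metric, got {n}")
    # pre-sort by gene id, then stable-sort by metric: ties break on gene id
    df = df.loc[df.index.sort_values()].sort_values(["metric"], kind="mergesort")
    q = n // 4
    q1 = df.iloc[:q]
    q4 = df.iloc[-q:]
    tab = (
        (int((q4["direction"] == direction).sum()), int((q4["direction"] != direction).sum())),
        (int((q1["direction"] == direction).sum()), int((q1["direction"] != direction).sum())),
    )
    return fisher_two_sided(
        tab,
        row_labels=(f"{metric_name}_Q4", f"{metric_name}_Q1"),
        col_labels=(direction, "rest"),
        note=f"n={n},quartile_size={q}",
    )


# ---------------------------------------------------------------------------
# Category enrichment
# ---------------------------------------------------------------------------


def category_enrichment(
    labeled: pd.DataFrame,
    directions: tuple = ("up", "down"),
) -> list[ContingencyResult]:
    """Per-category, per-direction Fisher tests with Bonferroni correction.

    Uncategorized genes stay in the out-of-category complement; m (always
    reported) is #categories x #directions tested.
    """
    if "category" not in labeled.columns:
        raise ForeignscanError("labeled DE table needs a 'category' column")
    cats = sorted(c for c in labeled["category"].dropna().unique())
    results: list[ContingencyResult] = []
    dir_arr = labeled["direction"]
    for cat in cats:
        in_cat = labeled["category"] == cat
        for d in directions:
            is_d = dir_arr == d
            tab = (
                (int((in_cat & is_d).sum()), int((in_cat & ~is_d).sum())),
                (int((~in_cat & is_d).sum()), int((~in_cat & ~is_d).sum())),
            )
            results.append(
                fisher_two_sided(
                    tab,
                    row_labels=(cat, f"not_{cat}"),
                    col_labels=(d, f"not_{d}"),
                    note="enriched" if _sample_odds_ratio(*tab[0], *tab[1]) > 1 else "depleted",
                )
            )
    return apply_bonferroni(results)


# ---------------------------------------------------------------------------
# Region summaries and abundance contrast
# ---------------------------------------------------------------------------


def region_summary(labeled: pd.DataFrame, gene_ids) -> dict:
    """Plain direction counts for a gene region (no test)."""
    gene_ids = list(gene_ids)
    sub = labeled.set_index("gene_id")
    missing = [g for g in gene_ids if g not in sub.index]
    if missing:
        raise ForeignscanError(
            f"region_summary: {len(missing)} region gene(s) absent from DE table "
            f"(first: {missing[0]})"
        )
    sub = sub.loc[gene_ids]
    return {
        "n_genes": len(sub),
        "n_up": int((sub["direction"] == "up").sum()),
        "n_down": int((sub["direction"] == "down").sum()),
        "n_ns": int((sub["direction"] == "ns").sum()),
    }


def abundance_contrast(
    tpm: pd.DataFrame,
    tus,
    labeled: pd.DataFrame,
) -> ContingencyResult:
    """Rank-sum contrast of transcript abundance between up and down TUs.

    Abundance per TU is the geometric mean of its replicate TPM columns;
    each TU inherits the DE direction of its first cistron.  The two-sided
    Wilcoxon rank-sum (Mann-Whitney) test compares log-abundances of up vs
    down TUs.
    """
    rep_cols = [c for c in tpm.columns if c != "tu_id"]
    if not rep_cols:
        raise ForeignscanError("TPM table has no replicate columns")
    vals = tpm[rep_cols].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ForeignscanError("TPM values must be positive for included TUs")
    abundance = pd.Series(np.exp(np.log(vals).mean(axis=1)), index=tpm["tu_id"])

    first_cistron = {tu.tu_id: tu.member_gene_ids[0] for tu in tus if tu.member_gene_ids}
    direction = labeled.set_index("gene_id")["direction"]
    groups: dict[str, list[float]] = {"up": [], "down": []}
    for tu_id, ab in abundance.items():
        gid = first_cistron.get(tu_id)
        if gid is None or gid not in direction.index:
            continue
        d = direction[gid]
        if d in groups:
            groups[d].append(math.log2(ab))
    n_up, n_down = len(groups["up"]), len(groups["down"])
    if n_up == 0 or n_down == 0:
        raise ForeignscanError(
            f"abundance_contrast: empty group (n_up={n_up}, n_down={n_down})"
        )
    stat = stats.mannwhitneyu(groups["up"], groups["down"], alternative="two-sided")
    return ContingencyResult(
        row_labels=("up", "down"),
        col_labels=("n_tus",),
        counts=((n_up,), (n_down,)),
        p_value=float(stat.pvalue),
        method="wilcoxon_rank_sum",
        note="log2 geometric-mean TPM of first cistrons",
    )


def results_to_frame(results: list[ContingencyResult]) -> pd.DataFrame:
    """One tidy row per test: labels, counts, OR, p, p_adj, method, m."""
    return pd.DataFrame([r.as_record() for r in results])
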