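"""Direction classification and the contingency analyses.

The Fisher implementation is checked against two independent routes: an
exact-Fraction enumeration oracle (factorial formula, all tables with the
observed margins) and scipy's implementation.
"""

import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import foreignscan as fs
from foreignscan import association as assoc
from foreignscan.models import ForeignscanError, TranscriptionUnit

from conftest import small_synth_config


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided point-probability p by exact enumeration (independent route)."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    f = math.factorial

    def prob(x):
        y = c1 - x
        return Fraction(f(r1) * f(r2) * f(c1) * f(c2),
                        f(n) * f(x) * f(r1 - x) * f(y) * f(r2 - y))

    amin, amax = max(0, c1 - r2), min(c1, r1)
    p_obs = prob(a)
    return float(sum(p for p in (prob(x) for x in range(amin, amax + 1)) if p <= p_obs))


# ---------------------------------------------------------------------------
# classify_de
# ---------------------------------------------------------------------------


def test_classification_rule_instances():
    de = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "log2fc": [1.2, -2.0, -0.5, 0.8],
            "padj": [0.005, 0.5, 0.001, np.nan],
        }
    )
    labeled, summary = assoc.classify_de(de, alpha=0.01)
    assert list(labeled["direction"]) == ["up", "ns", "down", "ns"]
    assert (summary.n_up, summary.n_down, summary.n_ns) == (1, 1, 2)
    assert summary.n_up + summary.n_down + summary.n_ns == summary.n_total


def test_classification_partition_is_exhaustive(small_run):
    labeled, summary = assoc.classify_de(small_run["de"], 0.01)
    assert len(labeled) == summary.n_total
    assert set(labeled["direction"]) <= {"up", "down", "ns"}


def test_alpha_boundary_is_strict():
    de = pd.DataFrame({"gene_id": ["a"], "log2fc": [2.0], "padj": [0.01]})
    labeled, _ = assoc.classify_de(de, alpha=0.01)
    assert labeled["direction"].iloc[0] == "ns"


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def test_fisher_symmetric_table_gives_p_one():
    assert assoc.fisher_two_sided(((5, 5), (5, 5))).p_value == 1.0


def test_fisher_phv1_decreased_vs_main_below_point_001():
    res = assoc.fisher_two_sided(((35, 40), (534, 2406)))
    assert res.p_value < 0.001


@pytest.mark.parametrize(
    "table",
    [
        ((2, 3), (4, 1)),
        ((1, 9), (11, 3)),
        ((0, 5), (7, 2)),
        ((10, 10), (2, 18)),
        ((3, 0), (0, 3)),
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    (a, b), (c, d) = table
    assert assoc.fisher_two_sided(table).p_value == pytest.approx(
        fisher_enumeration_oracle(a, b, c, d), abs=1e-14
    )


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        mine = assoc.fisher_two_sided(((a, b), (c, d))).p_value
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, abs=1e-12)


def test_fisher_zero_margin_warns_p_one():
    with pytest.warns(UserWarning, match="zero margin"):
        res = assoc.fisher_two_sided(((0, 0), (3, 4)))
    assert res.p_value == 1.0


def test_fisher_rejects_non_integers():
    with pytest.raises(ForeignscanError):
        assoc.fisher_two_sided(((1.5, 2), (3, 4)))


def test_sample_odds_ratio_flagged():
    res = assoc.fisher_two_sided(((2, 4), (1, 8)))
    assert res.odds_ratio == pytest.approx((2 * 8) / (4 * 1))
    assert res.odds_ratio_kind == "sample"


def test_bonferroni_arithmetic():
    assert assoc.bonferroni(0.01, 20) == pytest.approx(0.2)
    assert assoc.bonferroni(0.2, 20) == 1.0


# ---------------------------------------------------------------------------
# replicon contrasts
# ---------------------------------------------------------------------------


def _printed_counts():
    return pd.DataFrame(
        {
            "replicon": ["main", "pHV1", "pHV3", "pHV4"],
            "detected": [2940, 75, 372, 606],
            "increased": [617, 1, 81, 82],
            "decreased": [534, 35, 27, 142],
        }
    ).set_index("replicon")


def test_replicon_reference_against_itself_disallowed():
    counts = _printed_counts()
    res = assoc.replicon_contrasts_from_counts(counts, "main")
    assert "main" not in set(res["replicon"])
    with pytest.raises(ForeignscanError):
        assoc.replicon_contrasts_from_counts(counts.loc[["main"]], "pHV1")


def test_vs_other_construction_shares_p_between_directions():
    res = assoc.replicon_contrasts_from_counts(_printed_counts(), "main", "vs_other")
    for rep, grp in res.groupby("replicon"):
        ps = grp["p_value"].to_numpy()
        assert ps[0] == pytest.approx(ps[1], rel=1e-12)


def test_replicon_contrasts_from_genes(small_run):
    labeled, _ = assoc.classify_de(small_run["de"], 0.01)
    metrics, _ = fs.per_gene_metrics(small_run["bundle"])
    labeled = labeled.merge(metrics, on="gene_id", how="left")
    res = assoc.replicon_contrasts(labeled, "chr")
    assert set(res["replicon"]) == {"pMEG1"}
    assert set(res["direction"]) == {"increased", "decreased"}


# ---------------------------------------------------------------------------
# quartile contrast
# ---------------------------------------------------------------------------


def test_quartile_contrast_hand_fixture():
    labeled = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(8)],
            "direction": ["ns", "ns", "up", "ns", "ns", "ns", "down", "down"],
        }
    )
    metric = pd.Series(
        [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
        index=[f"g{i}" for i in range(8)], name="m",
    )
    res = assoc.quartile_contrast(metric, labeled, "down")
    # Q1 = {g0, g1}: 0 down; Q4 = {g6, g7}: 2 down
    assert res.counts == ((2, 0), (0, 2))
    assert res.p_value == pytest.approx(fisher_enumeration_oracle(2, 0, 0, 2))


def test_quartile_contrast_needs_four_genes():
    labeled = pd.DataFrame({"gene_id": ["a", "b"], "direction": ["up", "down"]})
    metric = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ForeignscanError, match=">= 4"):
        assoc.quartile_contrast(metric, labeled)


def test_quartile_tie_break_is_deterministic():
    labeled = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(8)], "direction": ["ns"] * 8}
    )
    metric = pd.Series([0.5] * 8, index=[f"g{i}" for i in range(8)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # all-ns labels: zero margin
        r1 = assoc.quartile_contrast(metric, labeled, "down")
        r2 = assoc.quartile_contrast(metric.iloc[::-1], labeled.iloc[::-1], "down")
    assert r1.counts == r2.counts


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------


def test_single_category_covering_all_genes_gives_p_one():
    labeled = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "direction": ["up", "down", "ns"],
            "category": ["J", "J", "J"],
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # zero-margin tables
        results = assoc.category_enrichment(labeled)
    assert all(r.p_value == 1.0 for r in results)
    assert all(r.m_tests == 2 for r in results)  # 1 category x 2 directions


def test_planted_category_downshift_detected():
    """A strong planted down-shift in one category survives Bonferroni."""
    detected = 0
    n_seeds = 100
    for s in range(n_seeds):
        cfg = fs.default_config(seed=3000 + s)
        cfg.de.category_effects = {"O": -1.2}
        bundle, truth = fs.generate_genome(cfg)
        de, _ = fs.generate_de_table(bundle, truth, cfg)
        metrics, _ = fs.per_gene_metrics(bundle)
        labeled, _ = assoc.classify_de(de, 0.01)
        labeled = labeled.merge(metrics, on="gene_id", how="left")
        res = assoc.category_enrichment(labeled)
        hit = next(
            r for r in res if r.row_labels[0] == "O" and r.col_labels[0] == "down"
        )
        detected += hit.p_adjusted < 0.05
    assert detected >= 90


# ---------------------------------------------------------------------------
# region summary
# ---------------------------------------------------------------------------


def test_region_summary_counts(small_run):
    labeled, summary = assoc.classify_de(small_run["de"], 0.01)
    assert assoc.region_summary(labeled, []) == {
        "n_genes": 0, "n_up": 0, "n_down": 0, "n_ns": 0,
    }
    whole = assoc.region_summary(labeled, labeled["gene_id"])
    assert (whole["n_up"], whole["n_down"], whole["n_ns"]) == (
        summary.n_up, summary.n_down, summary.n_ns,
    )
    with pytest.raises(ForeignscanError, match="absent"):
        assoc.region_summary(labeled, ["not-a-gene"])


def test_prophage_region_skews_down():
    cfg = fs.default_config(seed=17)
    bundle, truth = fs.generate_genome(cfg)
    de, _ = fs.generate_de_table(bundle, truth, cfg)
    labeled, _ = assoc.classify_de(de, 0.01)
    region = [g.gene_id for g in bundle.genes if g.category == cfg.prophage.category]
    counts = assoc.region_summary(labeled, region)
    assert counts["n_genes"] == cfg.prophage.n_genes
    assert counts["n_down"] >= counts["n_up"]


# ---------------------------------------------------------------------------
# abundance contrast
# ---------------------------------------------------------------------------


def _abundance_setup(rng, n_per_group, shift_log2=0.0):
    n = 2 * n_per_group
    tus = [
        TranscriptionUnit(f"tu{i}", "chr", 10 * i + 1, 10 * i + 5, "+", [f"g{i}"])
        for i in range(n)
    ]
    direction = ["up"] * n_per_group + ["down"] * n_per_group
    labeled = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                            "direction": direction})
    base = rng.lognormal(3.0, 1.0, n)
    base[n_per_group:] *= 2.0 ** shift_log2
    tpm = pd.DataFrame(
        {
            "tu_id": [f"tu{i}" for i in range(n)],
            "tpm_rep1": base * rng.lognormal(0, 0.1, n),
            "tpm_rep2": base * rng.lognormal(0, 0.1, n),
        }
    )
    return tpm, tus, labeled


def test_abundance_contrast_null_type_one_error_controlled():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(4000 + s)
        tpm, tus, labeled = _abundance_setup(rng, 100)
        res = assoc.abundance_contrast(tpm, tus, labeled)
        hits += res.p_value < 0.01
    assert hits <= 5


def test_abundance_contrast_detects_one_log2_shift():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(5000 + s)
        tpm, tus, labeled = _abundance_setup(rng, 200, shift_log2=1.0)
        res = assoc.abundance_contrast(tpm, tus, labeled)
        hits += res.p_value < 0.001
    assert hits >= 95


def test_abundance_contrast_empty_group_errors():
    rng = np.random.default_rng(0)
    tpm, tus, labeled = _abundance_setup(rng, 10)
    labeled["direction"] = "up"
    with pytest.raises(ForeignscanError, match="empty group"):
        assoc.abundance_contrast(tpm, tus, labeled)


# ---------------------------------------------------------------------------
# permutation null: super-uniform p-values
# ---------------------------------------------------------------------------


def test_quartile_p_super_uniform_under_label_permutation(small_run):
    metrics, _ = fs.per_gene_metrics(small_run["bundle"])
    labeled, _ = assoc.classify_de(small_run["de"], 0.01)
    labeled = labeled.merge(metrics, on="gene_id", how="left")
    metric = labeled.set_index("gene_id")["rare_codon_freq"]
    rng = np.random.default_rng(1)
    ps = []
    perm = labeled.copy()
    for _ in range(1000):
        perm["direction"] = rng.permutation(labeled["direction"].to_numpy())
        ps.append(assoc.quartile_contrast(metric, perm, "down").p_value)
    ps = np.sort(ps)
    ecdf = np.arange(1, len(ps) + 1) / len(ps)
    d_plus = float(np.max(ecdf - ps))
    # one-sided KS bound at ~alpha 1e-3 for n=1000, plus slack for discreteness
    assert d_plus <= 1.95 / math.sqrt(1000)
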