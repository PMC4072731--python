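"""Differential allelic expression: pooling, filters, chi-square test,
cross-trial consistency and cis/trans classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import REFERENCE_DAE_ROWS
from poolex import dae
from poolex.formats import AlleleCountRecord, LibraryInfo

META = {
    "h1": LibraryInfo("t", "high", 1),
    "h2": LibraryInfo("t", "high", 2),
    "h3": LibraryInfo("t", "high", 3),
    "l1": LibraryInfo("t", "low", 1),
}


def _record(depths, region="Syn", gene_id="g1"):
    return AlleleCountRecord("chr1", 100, gene_id, region, "A", "G", depths)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def test_pool_replicates_sums_elementwise():
    rec = _record({"h1": (10, 20), "h2": (30, 40), "h3": (5, 5), "l1": (1, 1)})
    pooled = dae.pool_replicates(rec, META)
    assert pooled.pooled["high"] == (45, 65)
    assert pooled.pooled["low"] == (1, 1)


def test_pooled_frequency_differs_from_mean_of_frequencies():
    # unbalanced depths: frequency of pooled counts != mean of per-replicate
    # frequencies, which is why counts are pooled before testing
    rec = _record({"h1": (90, 10), "h2": (1, 9), "h3": (0, 0), "l1": (1, 1)})
    pooled = dae.pool_replicates(rec, META)
    freq_pooled = pooled.freq_b("high")
    freq_mean = np.mean([10 / 100, 9 / 10])
    assert freq_pooled == pytest.approx(19 / 110)
    assert abs(freq_pooled - freq_mean) > 0.3


def test_pool_single_replicate_is_identity():
    rec = _record({"h1": (7, 13), "l1": (2, 3)})
    pooled = dae.pool_replicates(rec, {"h1": META["h1"], "l1": META["l1"]})
    assert pooled.pooled["high"] == (7, 13)


def test_pool_missing_treatment_errors():
    rec = _record({"h1": (7, 13)})
    with pytest.raises(ValueError, match="low"):
        dae.pool_replicates(rec, META)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _pooled(high, low):
    return dae.PooledSnp("chr1", 1, "g", "Syn", "A", "G", {"high": high, "low": low})


@pytest.mark.parametrize(
    "high,low,expected,reason_part",
    [
        ((40, 5), (30, 10), False, "depth"),
        ((1000, 19), (990, 15), False, "support"),
        ((830, 917), (941, 290), True, ""),  # reference pooled entry
        ((5000, 25), (4950, 24), False, "vaf"),
        ((30, 20), (10, 5), True, ""),  # boundary: depth 50, support 20
    ],
)
def test_snp_filters(high, low, expected, reason_part):
    ok, reason = dae.snp_filters(_pooled(high, low))
    assert ok is expected
    if reason_part:
        assert reason_part in reason


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


def test_chi_square_identical_frequencies():
    stat, p = dae.chi_square_dae((50, 50), (50, 50))
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi_square_zero_marginal_degenerate():
    stat, p = dae.chi_square_dae((0, 0), (10, 20))
    assert (stat, p) == (0.0, 1.0)


@pytest.mark.parametrize("gene_id", list(REFERENCE_DAE_ROWS))
def test_chi_square_reference_rows_significant(gene_id):
    row = REFERENCE_DAE_ROWS[gene_id]
    for trial in ("trial1", "trial2"):
        stat, p = dae.chi_square_dae(row[f"{trial}_high"], row[f"{trial}_low"])
        assert p <= 1e-4


def test_chi_square_matches_contingency_oracle():
    rng = np.random.default_rng(8)
    for _ in range(100):
        table = rng.integers(5, 500, size=(2, 2))
        stat, p = dae.chi_square_dae(tuple(table[0]), tuple(table[1]))
        res = stats.chi2_contingency(table, correction=False)
        if (res.expected_freq >= 5).all():
            assert stat == pytest.approx(res.statistic, abs=1e-10)
            assert p == pytest.approx(res.pvalue, abs=1e-10)


def test_chi_square_fisher_fallback_on_sparse_table():
    stat, p = dae.chi_square_dae((2, 8), (9, 1))
    _, fisher_p = stats.fisher_exact([[2, 8], [9, 1]])
    assert p == pytest.approx(fisher_p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(1, 2000)] * 4))
def test_chi_square_allele_relabel_invariance(cells):
    a, b, c, d = cells
    stat1, p1 = dae.chi_square_dae((a, b), (c, d))
    stat2, p2 = dae.chi_square_dae((b, a), (d, c))
    assert stat1 == pytest.approx(stat2, rel=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_chi_square_p_monotone_in_depth():
    ps = []
    for k in (1, 2, 5, 10, 30):
        _, p = dae.chi_square_dae((70 * k, 30 * k), (60 * k, 40 * k))
        ps.append(p)
    assert all(p2 < p1 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# Calling and cross-trial consistency
# ---------------------------------------------------------------------------


def _trial_frame(rows):
    cols = [
        "chrom", "pos", "gene_id", "region", "ref", "alt",
        "high_ref", "high_alt", "freq_high", "low_ref", "low_alt", "freq_low",
        "delta_freq", "chi2", "p_value", "filter_pass", "filter_reason",
    ]
    return pd.DataFrame(rows, columns=cols)


def _row(pos, gene, p, f_high, f_low, ref="A", alt="G"):
    return (
        "chr1", pos, gene, "Syn", ref, alt,
        100, int(100 * f_high / (1 - f_high)), f_high,
        100, int(100 * f_low / (1 - f_low)), f_low,
        f_low - f_high, 10.0, p, True, "",
    )


def test_call_dae_inclusive_threshold_boundary():
    df = _trial_frame([_row(1, "g1", 1e-4, 0.2, 0.5), _row(2, "g2", 1.1e-4, 0.2, 0.5)])
    called = dae.call_dae(df, p_threshold=1e-4)
    assert called.significant.tolist() == [True, False]


def test_cross_trial_same_direction_and_exclusions():
    t1 = _trial_frame([
        _row(1, "g1", 1e-9, 0.52, 0.24),   # decrease in low, both trials
        _row(2, "g2", 1e-9, 0.30, 0.60),   # increase vs decrease -> excluded
        _row(3, "g3", 1e-9, 0.40, 0.40),   # delta zero in trial 1
        _row(4, "g4", 0.5, 0.40, 0.45),    # not significant in trial 1
    ])
    t2 = _trial_frame([
        _row(1, "g1", 1e-9, 0.46, 0.13),
        _row(2, "g2", 1e-9, 0.60, 0.30),
        _row(3, "g3", 1e-9, 0.30, 0.60),
        _row(4, "g4", 1e-9, 0.20, 0.60),
    ])
    merged = dae.cross_trial_consistency(t1, t2)
    by_pos = merged.set_index("pos")
    assert by_pos.loc[1, "shared"] and by_pos.loc[1, "same_direction"]
    assert by_pos.loc[2, "shared"] and not by_pos.loc[2, "same_direction"]
    assert not by_pos.loc[3, "same_direction"]
    assert not by_pos.loc[4, "shared"]


def test_cross_trial_reorients_swapped_alleles():
    t1 = _trial_frame([_row(1, "g1", 1e-9, 0.20, 0.60)])
    t2 = _trial_frame([_row(1, "g1", 1e-9, 0.80, 0.40, ref="G", alt="A")])
    merged = dae.cross_trial_consistency(t1, t2)
    assert len(merged) == 1
    assert merged.same_direction.iloc[0]
    assert merged.freq_high_trial2.iloc[0] == pytest.approx(0.20)


def test_classify_regulatory_rules():
    t1 = _trial_frame([
        _row(1, "gDE", 1e-9, 0.2, 0.6),
        _row(2, "gOther", 1e-9, 0.2, 0.6),
        _row(3, "", 1e-9, 0.2, 0.6),       # intergenic: never cis
        _row(4, "gDE", 0.9, 0.4, 0.4),     # not DAE
    ])
    merged = dae.cross_trial_consistency(t1, t1.copy())
    out = dae.classify_regulatory(merged, {"gDE"})
    by_pos = out.set_index("pos")
    assert by_pos.loc[1, "regulatory_class"] == "cis_candidate"
    assert by_pos.loc[2, "regulatory_class"] == "dae_only"
    assert by_pos.loc[3, "regulatory_class"] == "dae_only"
    assert by_pos.loc[4, "regulatory_class"] == "none"


def test_region_distribution_counts_and_normalisation():
    df = pd.DataFrame({"region": ["Syn", "Syn", "NonSyn", "UTR3"]})
    out = dae.region_distribution({"all": df})
    syn = out[(out.set == "all") & (out.region == "Syn")]
    assert syn["fraction"].iloc[0] == pytest.approx(0.5)
    assert out.groupby("set")["fraction"].sum().iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_region_distribution_recovers_planted_mix(small_dataset):
    truth = small_dataset.truth.snps
    out = dae.region_distribution({"truth": truth})
    for region in ("Syn", "NonSyn"):
        frac = out.loc[out.region == region, "fraction"].iloc[0]
        expected = (truth.region == region).mean()
        assert frac == pytest.approx(expected)
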