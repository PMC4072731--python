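"""Differential-expression stage: CPM arithmetic, filtering, TMM,
the exact NB test and BH adjustment, against independent oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from poolex import dge, syndata
from poolex.formats import CountMatrix, LibraryInfo


def _matrix(counts, treatments=None):
    counts = np.asarray(counts)
    n_lib = counts.shape[1]
    if treatments is None:
        treatments = ["high"] * (n_lib // 2) + ["low"] * (n_lib - n_lib // 2)
    libs = [f"L{i}" for i in range(n_lib)]
    meta = {
        lib: LibraryInfo("t", tr, i + 1) for i, (lib, tr) in enumerate(zip(libs, treatments))
    }
    return CountMatrix([f"g{i}" for i in range(counts.shape[0])], libs, counts, meta)


# ---------------------------------------------------------------------------
# CPM and filter
# ---------------------------------------------------------------------------


def test_cpm_definition_and_inverse():
    counts = np.array([[50], [50_000_000 - 50]])
    cm = _matrix(counts, ["high"])
    cpm = dge.compute_cpm(cm)
    assert cpm[0, 0] == pytest.approx(1.0)
    # algebraic inverse: cpm * lib_size / 1e6 reproduces the raw counts
    back = cpm * cm.library_sizes / 1e6
    assert np.allclose(back, counts)


def test_cpm_zero_library_rejected():
    cm = _matrix(np.array([[0, 5], [0, 5]]))
    with pytest.raises(ValueError, match="zero total"):
        dge.compute_cpm(cm)


def test_filter_boundary_pass_at_exactly_min():
    # gene0 at exactly 1 CPM in exactly 3 of 6 libraries -> pass
    filler = 1_000_000
    row = [1, 1, 1, 0, 0, 0]
    counts = np.array([row, [filler - c for c in row]])
    mask = dge.filter_low_expression(_matrix(counts), min_cpm=1.0, min_libraries=3)
    assert mask[0]


def test_filter_boundary_fail_just_below():
    # 0.99 CPM in all 6 libraries -> fail
    total = 1_000_000
    row = [0] * 6
    counts = np.array([[99] * 6, [total * 100 - 99] * 6])  # 99 / 1e8 * 1e6 = 0.99
    mask = dge.filter_low_expression(_matrix(counts), min_cpm=1.0, min_libraries=3)
    assert not mask[0]


def test_filter_pass_fraction_monotone_in_depth():
    fracs = []
    for lib_size in (500, 5_000):
        cfg = syndata.SimConfig(
            n_genes=1000, genes_per_chrom=500, mean_lib_size=lib_size,
            frac_snp_genes=0.0, frac_selected=0.0, seed=2,
        )
        truth = syndata.plan_truth(cfg, syndata.generate_annotation(cfg)[0])
        cm = syndata.simulate_counts(cfg, truth)["trial1"]
        fracs.append(dge.filter_low_expression(cm).mean())
    assert fracs[0] < fracs[1]


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def test_tmm_identical_libraries_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.poisson(100, size=500)
    cm = _matrix(np.column_stack([col, col]))
    assert np.allclose(dge.tmm_factors(cm), [1.0, 1.0])


def test_tmm_pure_depth_change_absorbed_by_library_size():
    rng = np.random.default_rng(1)
    col = rng.poisson(200, size=500) + 1
    cm = _matrix(np.column_stack([col, 2 * col]))
    assert np.allclose(dge.tmm_factors(cm), [1.0, 1.0], atol=1e-9)


def test_tmm_spiked_library_compensated():
    rng = np.random.default_rng(2)
    base = rng.poisson(200, size=2000) + 1
    cols = [rng.poisson(base) + 1 for _ in range(4)]
    spiked = cols[3].copy()
    spiked[: len(spiked) // 20] *= 8  # 5% of genes 8-fold up in one library
    cols[3] = spiked
    cm = _matrix(np.column_stack(cols))
    f = dge.tmm_factors(cm)
    # spiked library is scaled down relative to the unspiked ones, which
    # stay mutually consistent (geometric-mean-1 rescaling shifts all)
    assert f[3] / np.exp(np.mean(np.log(f[:3]))) < 0.85
    assert np.ptp(np.log2(f[:3])) < 0.05


# ---------------------------------------------------------------------------
# Exact NB test
# ---------------------------------------------------------------------------


def test_exact_symmetric_split_gives_p1():
    for phi in (0.0, 0.05, 0.4):
        assert dge.exact_nb_pvalue(40, 40, 3, 3, phi) == pytest.approx(1.0)


def test_exact_binomial_limit_matches_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n1, n2 = rng.integers(2, 4, size=2)
        z1, z2 = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        if z1 + z2 == 0:
            continue
        z = z1 + z2
        pmf = stats.binom.pmf(np.arange(z + 1), z, n1 / (n1 + n2))
        oracle = pmf[pmf <= pmf[z1] * (1 + 1e-12)].sum()
        got = dge.exact_nb_pvalue(z1, z2, int(n1), int(n2), dispersion=0.0)
        assert got == pytest.approx(min(1.0, oracle), abs=1e-9)


def test_exact_all_zero_gene_degenerate():
    counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 1000)])
    cm = _matrix(counts)
    res = dge.exact_nb_test(cm, dispersion=0.1)
    assert res.p_value[0] == 1.0 and res.log2fc[0] == 0.0


def test_exact_detects_large_shift():
    counts = np.array([[1000, 1100, 950, 240, 260, 250], [5000] * 6])
    cm = _matrix(counts)
    res = dge.exact_nb_test(cm, dispersion=0.05)
    assert res.p_value[0] < 1e-6
    assert res.log2fc[0] < -1.5  # down in low-trait samples


def test_common_dispersion_recovered_from_null():
    cfg = syndata.SimConfig(
        n_genes=1500, genes_per_chrom=750, frac_de=0.0, frac_snp_genes=0.0,
        frac_selected=0.0, nb_dispersion=0.1, seed=9,
    )
    truth = syndata.plan_truth(cfg, syndata.generate_annotation(cfg)[0])
    cm = syndata.simulate_counts(cfg, truth)["trial1"]
    factors = dge.tmm_factors(cm)
    phi = dge.estimate_common_dispersion(cm, factors)
    assert 0.07 < phi < 0.14
    # simpler fallback agrees to first order
    phi_mom = dge.dispersion_mom(cm, factors)
    assert 0.05 < phi_mom < 0.2


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Textbook step-up computed gene by gene (independent of the
    vectorised implementation)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        adj[i] = best
    return adj


def test_bh_single_p_unchanged():
    assert dge.bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_stepped_example():
    assert dge.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_rejects_nan():
    with pytest.raises(ValueError, match="NaN"):
        dge.bh_fdr([0.1, np.nan])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_bruteforce_oracle_and_is_monotone(p):
    got = dge.bh_fdr(p)
    assert got == pytest.approx(_bh_oracle(p))
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(got[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Cross-trial consistency
# ---------------------------------------------------------------------------


def _dge_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value", "fdr", "filter_pass"])


def test_consistent_de_threshold_and_direction():
    t1 = _dge_frame([
        ("gA", -2.4, 1e-11, 7e-10, True),   # matches a known strongly down gene
        ("gB", 1.0, 0.01, 0.04, True),
        ("gC", -1.0, 0.02, 0.06, True),
        ("gD", 2.0, 1e-5, 1e-4, True),
    ])
    t2 = _dge_frame([
        ("gA", -2.0, 1e-7, 4e-6, True),
        ("gB", -1.2, 0.001, 0.004, True),
        ("gC", -1.1, 0.001, 0.004, True),
        ("gD", 1.5, 1e-5, 1e-4, False),     # filtered out in trial 2
    ])
    cs = dge.consistent_de(t1, t2, alpha=0.05)
    assert cs.both_significant == frozenset({"gA", "gB"})
    assert cs.same_direction == frozenset({"gA"})       # gB flips sign
    assert cs.opposite_direction == frozenset({"gB"})
    assert cs.down_in_low == frozenset({"gA"}) and not cs.up_in_low
    assert "gC" not in cs.both_significant  # fdr 0.06 in one trial
    assert "gD" not in cs.both_significant  # excluded by filter


def test_consistent_de_recovers_planted_direction():
    cfg = syndata.SimConfig(
        n_genes=600, genes_per_chrom=300, frac_snp_genes=0.0, frac_selected=0.0,
        mean_lib_size=300_000, seed=21,
    )
    ds = syndata.generate_dataset(cfg)
    res = {t: dge.run_dge_trial(ds.counts[t]) for t in ds.counts}
    cs = dge.consistent_de(res["trial1"], res["trial2"])
    planted = ds.truth.genes[ds.truth.genes.de_direction != "none"]
    recovered = set(planted.gene_id) & cs.same_direction
    assert len(recovered) / len(planted) >= 0.8
    # opposite-direction calls are rare when effects share a sign
    assert len(cs.opposite_direction) <= 0.01 * max(1, len(cs.both_significant))
    down = set(planted.loc[planted.de_direction == "down", "gene_id"])
    assert down & cs.same_direction <= cs.down_in_low
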