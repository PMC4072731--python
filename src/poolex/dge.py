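"""Differential gene expression between low- and high-trait bulks.

Per trial: CPM-based low-expression filtering, TMM normalisation factors,
a common negative-binomial dispersion estimated by conditional maximum
likelihood, and an exact conditional test on the two treatment group sums
(the classic exact NB test for two-group designs with replicates). The
cross-trial step intersects the per-trial significant sets and splits
them by fold-change direction.

Sign convention: log2 fold change is low-trait relative to high-trait, so
a negative value means down-regulated in the low-trait samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .formats import CountMatrix

log = logging.getLogger(__name__)

#: Prior count added per library-size-normalised count when computing
#: fold changes, to keep them finite for zero groups.
PRIOR_COUNT = 0.125


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def compute_cpm(matrix: CountMatrix) -> np.ndarray:
    """Counts per million: counts / library size * 1e6 (library size =
    column sum)."""
    sizes = matrix.library_sizes.astype(float)
    if (sizes == 0).any():
        bad = matrix.library_ids[int(np.flatnonzero(sizes == 0)[0])]
        raise ValueError(f"library {bad} has zero total counts")
    return matrix.counts / sizes * 1e6


def filter_low_expression(
    matrix: CountMatrix, min_cpm: float = 1.0, min_libraries: int = 3
) -> np.ndarray:
    """Expression filter: keep genes with CPM >= min_cpm in at least
    min_libraries libraries (boundaries inclusive)."""
    cpm = compute_cpm(matrix)
    return (cpm >= min_cpm).sum(axis=1) >= min_libraries


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


def tmm_factors(
    matrix: CountMatrix,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, scaled to geometric mean 1.

    Reference library: the one whose 75th-percentile count fraction is
    closest to the mean across libraries. Per library, M (log2 ratio) and
    A (mean log2 abundance) are computed over genes nonzero in both
    libraries, the extreme 30% of M and 5% of A are trimmed, and the
    factor is the inverse-asymptotic-variance-weighted mean of M.
    """
    counts = matrix.counts.astype(float)
    sizes = counts.sum(axis=0)
    frac75 = np.array([np.quantile(counts[:, j] / sizes[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(frac75 - frac75.mean())))
    yr, nr = counts[:, ref], sizes[ref]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y, n = counts[:, j], sizes[j]
        pos = (y > 0) & (yr > 0)
        if not pos.any():
            log.warning(
                "TMM: library %s shares no expressed genes with the reference; factor 1",
                matrix.library_ids[j],
            )
            continue
        p, pr = y[pos] / n, yr[pos] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        # Asymptotic variance of M (delta method on two binomial proportions);
        # floored so a gene carrying a whole library cannot get infinite weight.
        v = (n - y[pos]) / (n * y[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        v = np.maximum(v, 1e-12)
        k = len(m)
        lo_m, hi_m = int(np.floor(k * logratio_trim)), k - int(np.floor(k * logratio_trim))
        lo_a, hi_a = int(np.floor(k * abundance_trim)), k - int(np.floor(k * abundance_trim))
        rank_m = np.argsort(np.argsort(m, kind="mergesort"), kind="mergesort")
        rank_a = np.argsort(np.argsort(a, kind="mergesort"), kind="mergesort")
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if not keep.any():
            keep = np.ones_like(keep)
        w = 1.0 / v[keep]
        factors[j] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def _pseudo_counts(matrix: CountMatrix, factors: np.ndarray) -> tuple[np.ndarray, float]:
    """Counts scaled to the geometric mean of the effective (TMM-adjusted)
    library sizes, so replicates become exchangeable for the conditional
    test."""
    eff = matrix.library_sizes.astype(float) * factors
    geo = float(np.exp(np.mean(np.log(eff))))
    return matrix.counts * (geo / eff), geo


def _conditional_ll(phi: float, pseudo: np.ndarray, group_cols: list[list[int]]) -> float:
    r = 1.0 / phi
    total = 0.0
    for cols in group_cols:
        y = pseudo[:, cols]
        n = len(cols)
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r).sum(axis=1) - n * gammaln(r) + gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    matrix: CountMatrix, factors: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Common NB dispersion maximising the conditional log-likelihood given
    the per-group sums, on counts scaled to a common library size."""
    pseudo, _ = _pseudo_counts(matrix, factors)
    if mask is not None:
        pseudo = pseudo[mask]
    group_cols = [matrix.libraries_for("high"), matrix.libraries_for("low")]
    res = minimize_scalar(
        lambda lg: -_conditional_ll(10.0**lg, pseudo, group_cols),
        bounds=(-6.0, 1.0),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0 ** res.x)


def dispersion_mom(matrix: CountMatrix, factors: np.ndarray) -> float:
    """Simpler fallback: per-gene method-of-moments dispersion within
    groups, median across genes (floored at 0)."""
    pseudo, _ = _pseudo_counts(matrix, factors)
    phis = []
    for cols in (matrix.libraries_for("high"), matrix.libraries_for("low")):
        y = pseudo[:, cols]
        mu = y.mean(axis=1)
        var = y.var(axis=1, ddof=1)
        ok = mu > 0
        phis.append((var[ok] - mu[ok]) / mu[ok] ** 2)
    allphi = np.concatenate(phis)
    return float(max(0.0, np.median(allphi)))


# ---------------------------------------------------------------------------
# Exact NB test
# ---------------------------------------------------------------------------


def exact_nb_pvalue(z1: int, z2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact p-value for the split of the total z1+z2 between two
    groups of NB replicates with common dispersion.

    Conditional on the total, the group-1 sum follows a negative
    hypergeometric law with parameters n1/dispersion and n2/dispersion;
    the p-value is the sum of all conditional probabilities not exceeding
    the probability of the observed split. In the dispersion -> 0 limit
    the law is Binomial(z, n1/(n1+n2)).
    """
    z1, z2 = int(z1), int(z2)
    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if dispersion < 1e-8:
        p1 = n1 / (n1 + n2)
        lp = (
            gammaln(z + 1)
            - gammaln(k + 1)
            - gammaln(z - k + 1)
            + k * np.log(p1)
            + (z - k) * np.log(1.0 - p1)
        )
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        lp = (
            gammaln(k + r1)
            - gammaln(k + 1)
            + gammaln(z - k + r2)
            - gammaln(z - k + 1)
        )
        lp -= lp.max()
        lp -= logsumexp(lp)
    obs = lp[z1]
    return float(min(1.0, np.exp(logsumexp(lp[lp <= obs + 1e-10]))))


def exact_nb_test(
    matrix: CountMatrix,
    factors: np.ndarray | None = None,
    dispersion: float | None = None,
    mask: np.ndarray | None = None,
    prior_count: float = PRIOR_COUNT,
) -> pd.DataFrame:
    """Per-gene exact NB test of low vs high treatment for one trial.

    Returns a DataFrame with gene_id, log2fc (low relative to high),
    p_value and mean_cpm; the estimated common dispersion is stored in
    ``df.attrs['dispersion']``. Genes outside ``mask`` get p = NaN.
    """
    if factors is None:
        factors = tmm_factors(matrix)
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, factors, mask)
    pseudo, _ = _pseudo_counts(matrix, factors)
    hi_cols = matrix.libraries_for("high")
    lo_cols = matrix.libraries_for("low")
    if not hi_cols or not lo_cols:
        raise ValueError("both 'high' and 'low' treatment libraries are required")
    z_hi = np.rint(pseudo[:, hi_cols].sum(axis=1)).astype(np.int64)
    z_lo = np.rint(pseudo[:, lo_cols].sum(axis=1)).astype(np.int64)
    m_hi = pseudo[:, hi_cols].mean(axis=1)
    m_lo = pseudo[:, lo_cols].mean(axis=1)
    log2fc = np.log2((m_lo + prior_count) / (m_hi + prior_count))
    cpm = compute_cpm(matrix).mean(axis=1)
    n_genes = matrix.counts.shape[0]
    pvals = np.full(n_genes, np.nan)
    idx = np.arange(n_genes) if mask is None else np.flatnonzero(mask)
    for g in idx:
        if z_hi[g] + z_lo[g] == 0:
            pvals[g] = 1.0
            log2fc[g] = 0.0
        else:
            pvals[g] = exact_nb_pvalue(
                z_lo[g], z_hi[g], len(lo_cols), len(hi_cols), dispersion
            )
    df = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "mean_cpm": cpm,
        }
    )
    df.attrs["dispersion"] = dispersion
    return df


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Per-trial driver and cross-trial consistency
# ---------------------------------------------------------------------------


def run_dge_trial(
    matrix: CountMatrix,
    min_cpm: float = 1.0,
    min_libraries: int = 3,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Filter, normalise and test one trial; FDR is computed across the
    filter-passing genes only (filtered genes get NaN p/fdr)."""
    mask = filter_low_expression(matrix, min_cpm, min_libraries)
    factors = tmm_factors(matrix)
    df = exact_nb_test(matrix, factors, dispersion=dispersion, mask=mask)
    df["filter_pass"] = mask
    fdr = np.full(len(df), np.nan)
    fdr[mask] = bh_fdr(df.loc[mask, "p_value"].to_numpy())
    df["fdr"] = fdr
    return df


@dataclass
class ConsistentDeSet:
    """Cross-trial DE comparison: genes significant in both trials, split
    by whether the fold changes agree in sign, with the same-direction set
    partitioned into up/down in the low-trait samples."""

    both_significant: frozenset
    same_direction: frozenset
    opposite_direction: frozenset
    up_in_low: frozenset
    down_in_low: frozenset
    table: pd.DataFrame

    def __post_init__(self):
        assert self.same_direction | self.opposite_direction == self.both_significant
        assert not (self.same_direction & self.opposite_direction)
        assert not (self.up_in_low & self.down_in_low)
        assert self.up_in_low | self.down_in_low == self.same_direction


def consistent_de(
    result_trial1: pd.DataFrame,
    result_trial2: pd.DataFrame,
    alpha: float = 0.05,
    trial_names: tuple[str, str] = ("trial1", "trial2"),
) -> ConsistentDeSet:
    """Intersect per-trial DE calls (fdr < alpha in both); genes filtered
    out of either trial are excluded from the comparison."""
    t1, t2 = trial_names
    merged = result_trial1.merge(
        result_trial2, on="gene_id", suffixes=(f"_{t1}", f"_{t2}")
    )
    merged = merged[merged[f"filter_pass_{t1}"] & merged[f"filter_pass_{t2}"]]
    sig = merged[(merged[f"fdr_{t1}"] < alpha) & (merged[f"fdr_{t2}"] < alpha)].copy()
    s1 = np.sign(sig[f"log2fc_{t1}"])
    s2 = np.sign(sig[f"log2fc_{t2}"])
    same = sig[(s1 == s2) & (s1 != 0)]
    opposite = sig[~sig.gene_id.isin(same.gene_id)]
    up = same[same[f"log2fc_{t1}"] > 0]
    down = same[same[f"log2fc_{t1}"] < 0]
    cols = ["gene_id"] + [
        f"{c}_{t}" for t in (t1, t2) for c in ("log2fc", "fdr")
    ]
    return ConsistentDeSet(
        both_significant=frozenset(sig.gene_id),
        same_direction=frozenset(same.gene_id),
        opposite_direction=frozenset(opposite.gene_id),
        up_in_low=frozenset(up.gene_id),
        down_in_low=frozenset(down.gene_id),
        table=same[cols].reset_index(drop=True),
    )
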