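"""Differential allelic expression from pooled bulk allele depths.

Replicate bulks within a treatment are pooled by summing read depths
(pooling counts, not averaging frequencies), SNPs are filtered with
VarScan-style count thresholds, and the allele-frequency difference
between the low- and high-trait treatments is tested with a Pearson
chi-square on the pooled 2x2 table. Cross-trial consistency (significant
in both trials, frequency shift in the same direction) defines the
robust DAE set; DAE SNPs whose host gene is itself in the cross-trial
consistent DE set are classified as cis-regulatory candidates, the rest
(including intergenic SNPs) as DAE-only / putatively trans.

Direction convention: delta_freq is the allele-B (alt) frequency in the
low-trait treatment minus the high-trait treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import REGION_CLASSES, AlleleCountRecord, LibraryInfo

log = logging.getLogger(__name__)


@dataclass
class PooledSnp:
    """One SNP's depths pooled to a single (ref, alt) pair per treatment."""

    chrom: str
    pos: int
    gene_id: str
    region: str
    ref: str
    alt: str
    pooled: dict[str, tuple[int, int]]  # treatment -> (ref, alt)

    def freq_b(self, treatment: str) -> float:
        r, a = self.pooled[treatment]
        total = r + a
        return a / total if total else float("nan")


def pool_replicates(
    record: AlleleCountRecord, library_meta: dict[str, LibraryInfo]
) -> PooledSnp:
    """Element-wise sum of ref/alt depths across replicate bulks within
    each treatment (one trial's record)."""
    pooled = {"high": [0, 0], "low": [0, 0]}
    seen = {"high": 0, "low": 0}
    for bulk, (r, a) in record.depths.items():
        treatment = library_meta[bulk].treatment
        pooled[treatment][0] += r
        pooled[treatment][1] += a
        seen[treatment] += 1
    missing = [t for t, n in seen.items() if n == 0]
    if missing:
        raise ValueError(f"SNP {record.chrom}:{record.pos}: no bulks for treatment {missing}")
    return PooledSnp(
        chrom=record.chrom,
        pos=record.pos,
        gene_id=record.gene_id,
        region=record.region,
        ref=record.ref,
        alt=record.alt,
        pooled={t: (v[0], v[1]) for t, v in pooled.items()},
    )


def snp_filters(
    pooled: PooledSnp,
    min_depth: int = 50,
    min_support: int = 20,
    min_vaf: float = 0.01,
) -> tuple[bool, str]:
    """VarScan-style count filters on the pooled treatment samples.

    A SNP passes if, in at least one pooled treatment: total depth >=
    min_depth, minor-allele supporting reads >= min_support and minor
    allele frequency >= min_vaf. The failing reason of the best sample is
    reported otherwise.
    """
    reasons = []
    for treatment in ("high", "low"):
        r, a = pooled.pooled[treatment]
        total = r + a
        minor = min(r, a)
        if total < min_depth:
            reasons.append(f"{treatment}: depth {total} < {min_depth}")
            continue
        if minor < min_support:
            reasons.append(f"{treatment}: support {minor} < {min_support}")
            continue
        if minor / total < min_vaf:
            reasons.append(f"{treatment}: vaf {minor / total:.4f} < {min_vaf}")
            continue
        return True, ""
    return False, "; ".join(reasons)


def chi_square_dae(
    high: tuple[int, int], low: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the pooled
    2x2 allele-count table.

    Degenerate tables (a zero marginal) return (0, 1). If any expected
    cell is below 5 the p-value falls back to a two-sided Fisher exact
    test (logged); the statistic reported is still Pearson's.
    """
    a, b = high
    c, d = low
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = np.outer(row, col) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    if (expected < 5).any():
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        log.debug("chi_square_dae: expected cell < 5, Fisher fallback p=%.3g", p)
        return stat, float(p)
    return stat, float(stats.chi2.sf(stat, df=1))


def run_dae_trial(
    records: list[AlleleCountRecord],
    library_meta: dict[str, LibraryInfo],
    min_depth: int = 50,
    min_support: int = 20,
    min_vaf: float = 0.01,
) -> pd.DataFrame:
    """Pool, filter and chi-square test every SNP of one trial."""
    rows = []
    for rec in records:
        ps = pool_replicates(rec, library_meta)
        ok, reason = snp_filters(ps, min_depth, min_support, min_vaf)
        stat, p = (np.nan, np.nan)
        if ok:
            stat, p = chi_square_dae(ps.pooled["high"], ps.pooled["low"])
        rows.append(
            {
                "chrom": ps.chrom,
                "pos": ps.pos,
                "gene_id": ps.gene_id,
                "region": ps.region,
                "ref": ps.ref,
                "alt": ps.alt,
                "high_ref": ps.pooled["high"][0],
                "high_alt": ps.pooled["high"][1],
                "freq_high": ps.freq_b("high"),
                "low_ref": ps.pooled["low"][0],
                "low_alt": ps.pooled["low"][1],
                "freq_low": ps.freq_b("low"),
                "delta_freq": ps.freq_b("low") - ps.freq_b("high"),
                "chi2": stat,
                "p_value": p,
                "filter_pass": ok,
                "filter_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def call_dae(results: pd.DataFrame, p_threshold: float = 1e-4) -> pd.DataFrame:
    """Flag significant SNPs: p <= p_threshold (inclusive boundary)."""
    out = results.copy()
    out["significant"] = out.filter_pass & (out.p_value <= p_threshold)
    return out


def cross_trial_consistency(
    trial1: pd.DataFrame,
    trial2: pd.DataFrame,
    p_threshold: float = 1e-4,
    trial_names: tuple[str, str] = ("trial1", "trial2"),
) -> pd.DataFrame:
    """Match SNPs across trials on (chrom, pos, ref, alt) and flag the
    shared (significant in both) and same-direction sets.

    A SNP whose alleles are recorded swapped in the second trial is
    re-oriented (counts and frequency flipped) before comparison.
    """
    t1, t2 = trial_names
    a = call_dae(trial1, p_threshold)
    b = call_dae(trial2, p_threshold).copy()

    key1 = set(zip(a.chrom, a.pos, a.ref, a.alt))
    flips = []
    for i, r in b.iterrows():
        if (r.chrom, r.pos, r.ref, r.alt) not in key1 and (
            (r.chrom, r.pos, r.alt, r.ref) in key1
        ):
            flips.append(i)
    if flips:
        log.warning("cross_trial_consistency: re-orienting %d allele-swapped SNPs", len(flips))
        for i in flips:
            r = b.loc[i]
            b.loc[i, ["ref", "alt"]] = [r.alt, r.ref]
            b.loc[i, ["high_ref", "high_alt"]] = [r.high_alt, r.high_ref]
            b.loc[i, ["low_ref", "low_alt"]] = [r.low_alt, r.low_ref]
            b.loc[i, "freq_high"] = 1.0 - r.freq_high
            b.loc[i, "freq_low"] = 1.0 - r.freq_low
            b.loc[i, "delta_freq"] = -r.delta_freq

    keep = [
        "chrom", "pos", "ref", "alt", "gene_id", "region",
        "high_ref", "high_alt", "freq_high", "low_ref", "low_alt", "freq_low",
        "delta_freq", "chi2", "p_value", "filter_pass", "significant",
    ]
    merged = a[keep].merge(
        b[keep].drop(columns=["gene_id", "region"]),
        on=["chrom", "pos", "ref", "alt"],
        suffixes=(f"_{t1}", f"_{t2}"),
    )
    merged["shared"] = merged[f"significant_{t1}"] & merged[f"significant_{t2}"]
    s1 = np.sign(merged[f"delta_freq_{t1}"])
    s2 = np.sign(merged[f"delta_freq_{t2}"])
    merged["same_direction"] = merged.shared & (s1 == s2) & (s1 != 0)
    return merged


def classify_regulatory(
    merged: pd.DataFrame, consistent_de_genes: set[str] | frozenset
) -> pd.DataFrame:
    """Assign regulatory classes to the cross-trial DAE set.

    cis_candidate: shared + same-direction DAE and the host gene is in
    the cross-trial consistent DE set; dae_only: shared + same-direction
    DAE elsewhere (putatively trans, including intergenic SNPs, which are
    never cis candidates); none: everything else.
    """
    out = merged.copy()
    robust = out.shared & out.same_direction
    in_de = out.gene_id.isin(set(consistent_de_genes)) & (out.gene_id != "")
    out["regulatory_class"] = np.where(
        robust & in_de, "cis_candidate", np.where(robust, "dae_only", "none")
    )
    return out


def region_distribution(snp_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tally region classes per SNP set; fractions sum to 1 per set."""
    rows = []
    for name, df in snp_sets.items():
        counts = df.region.value_counts()
        total = int(counts.sum())
        for region in REGION_CLASSES:
            c = int(counts.get(region, 0))
            rows.append(
                {
                    "set": name,
                    "region": region,
                    "count": c,
                    "fraction": c / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
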