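"""Variant effect classification and Ka/Ks positive-selection scoring.

Variants are classified against gene models (strand- and frame-aware for
coding positions). Synonymous/nonsynonymous site lengths per gene follow
the Nei-Gojobori (1986) equal-rate counting method: each codon position
contributes the fraction of its three possible point mutations that are
synonymous to the synonymous site total Ls, the remainder to the
nonsynonymous total Ln, so Ln + Ls equals the CDS length in nucleotides.

Per gene, with NS nonsynonymous and SS synonymous substitutions observed,

    Ka = (NS + 1) / Ln,   Ks = (SS + 1) / Ls,   Ka/Ks = Ka / Ks

The +1 pseudocount keeps the ratio defined for genes with no observed
substitutions (a zero-SNP gene scores Ls/Ln, well below 1). Genes with
Ka/Ks strictly greater than the threshold (default 1.5) in a trial are
flagged as candidates for positive selection.

Because substitutions here are within-population polymorphisms from
pooled RNA reads rather than fixed between-species differences, the
statistic is really a pN/pS-style polymorphism ratio; the Ka/Ks name is
kept as the field's conventional label for this screen.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .formats import AlleleCountRecord, GeneModel, LibraryInfo, complement

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

# Standard codon table with explicit '*' for stops.
_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    try:
        return CODON_TO_AA[codon]
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid codon {codon!r}") from exc


@dataclass(frozen=True)
class SiteCounts:
    """Nei-Gojobori site counts for one CDS, in units of 'sites'."""

    gene_id: str
    ln: float  # nonsynonymous sites
    ls: float  # synonymous sites
    method: str = "NG86"


@dataclass(frozen=True)
class KaKsResult:
    gene_id: str
    ns: int
    ss: int
    ln: float
    ls: float
    ka: float
    ks: float
    ratio: float
    selected: bool


class GeneIndex:
    """Position -> gene lookup over non-overlapping gene models."""

    def __init__(self, models: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom in {m.chrom for m in models}:
            ms = sorted((m for m in models if m.chrom == chrom), key=lambda m: m.span[0])
            self._by_chrom[chrom] = ([m.span[0] for m in ms], ms)

    def find(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ms = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and ms[i].span[0] <= pos <= ms[i].span[1]:
            return ms[i]
        return None


def classify_variant(
    chrom: str, pos: int, ref: str, alt: str, model: GeneModel | None
) -> tuple[str, dict]:
    """Classify one biallelic variant against a gene model.

    Returns (region, detail); region is one of Syn/NonSyn/UTR5/UTR3/
    Intron/Intergenic. For coding positions the alleles are placed in the
    codon in the correct frame (reverse-complemented on '-' strand genes)
    and the variant is Syn iff the encoded amino acid is unchanged;
    stop-gain/loss changes are NonSyn. A ref allele inconsistent with the
    CDS sequence at that position is an error.
    """
    if model is None:
        return "Intergenic", {}
    structural = model.region_of(pos)
    if structural is None:
        return "Intergenic", {}
    if structural != "CDS":
        return structural, {"gene_id": model.gene_id}
    if not model.cds_seq:
        raise ValueError(f"gene {model.gene_id}: no CDS sequence available for classification")
    idx = model.cds_index_of(pos)
    assert idx is not None
    ref_t, alt_t = (ref, alt) if model.strand == "+" else (complement(ref), complement(alt))
    if model.cds_seq[idx] != ref_t:
        raise ValueError(
            f"variant {chrom}:{pos}: ref allele {ref!r} inconsistent with CDS base "
            f"{model.cds_seq[idx]!r} of gene {model.gene_id} (transcription strand)"
        )
    codon_i, off = divmod(idx, 3)
    codon = model.cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:off] + alt_t + codon[off + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    detail = {
        "gene_id": model.gene_id,
        "codon": codon,
        "alt_codon": alt_codon,
        "aa_ref": aa_ref,
        "aa_alt": aa_alt,
        "codon_position": off + 1,
    }
    return ("Syn" if aa_ref == aa_alt else "NonSyn"), detail


def count_sites(cds_seq: str, gene_id: str = "") -> SiteCounts:
    """Nei-Gojobori synonymous/nonsynonymous site counts for a CDS.

    Per codon position, the synonymous fraction is the share of the three
    possible point mutations that leave the amino acid unchanged (a stop
    codon mutating to another stop counts as synonymous; creating or
    destroying a stop is nonsynonymous). Ln + Ls equals the CDS length.
    """
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    if any(b not in "ACGT" for b in seq):
        bad = next(b for b in seq if b not in "ACGT")
        raise ValueError(f"ambiguous base {bad!r} in CDS")
    ls = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = translate_codon(codon)
        for off in range(3):
            syn = 0
            for b in _BASES:
                if b == codon[off]:
                    continue
                if translate_codon(codon[:off] + b + codon[off + 1 :]) == aa:
                    syn += 1
            ls += syn / 3.0
    return SiteCounts(gene_id=gene_id, ln=len(seq) - ls, ls=ls)


def variant_filters(
    ref_total: int,
    alt_total: int,
    min_count: int = 4,
    min_cov: int = 20,
    max_cov: int = 2000,
) -> tuple[bool, str]:
    """Count/coverage filters on depths pooled across all bulks of a trial:
    minor-allele count >= min_count and min_cov <= total coverage <= max_cov."""
    total = ref_total + alt_total
    if min(ref_total, alt_total) < min_count:
        return False, f"minor allele count {min(ref_total, alt_total)} < {min_count}"
    if total < min_cov:
        return False, f"coverage {total} < {min_cov}"
    if total > max_cov:
        return False, f"coverage {total} > {max_cov}"
    return True, ""


def kaks_ratio(ns: int, ss: int, sites: SiteCounts, threshold: float = 1.5) -> KaKsResult:
    """Pseudocounted, length-normalised Ka/Ks with strict '>' flagging."""
    ka = (ns + 1) / sites.ln
    ks = (ss + 1) / sites.ls
    ratio = ka / ks
    return KaKsResult(
        gene_id=sites.gene_id,
        ns=int(ns),
        ss=int(ss),
        ln=sites.ln,
        ls=sites.ls,
        ka=ka,
        ks=ks,
        ratio=ratio,
        selected=bool(ratio > threshold),
    )


def run_kaks_trial(
    models: list[GeneModel],
    records: list[AlleleCountRecord],
    min_count: int = 4,
    min_cov: int = 20,
    max_cov: int = 2000,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-gene Ka/Ks for one trial.

    Depths are pooled across every bulk of the trial, the count/coverage
    filters applied, passing variants classified against the annotation
    (the stored region label is recomputed; discrepancies are logged and
    the recomputed class wins), and NS/SS tallied per gene.
    """
    index = GeneIndex(models)
    ns: dict[str, int] = {}
    ss: dict[str, int] = {}
    for rec in records:
        ref_total = sum(r for r, _ in rec.depths.values())
        alt_total = sum(a for _, a in rec.depths.values())
        ok, _reason = variant_filters(ref_total, alt_total, min_count, min_cov, max_cov)
        if not ok:
            continue
        model = index.find(rec.chrom, rec.pos)
        region, detail = classify_variant(rec.chrom, rec.pos, rec.ref, rec.alt, model)
        if rec.region and rec.region != "Unassigned" and region != rec.region:
            log.warning(
                "SNP %s:%d: stored region %s != recomputed %s; using recomputed",
                rec.chrom, rec.pos, rec.region, region,
            )
        if region == "NonSyn":
            ns[detail["gene_id"]] = ns.get(detail["gene_id"], 0) + 1
        elif region == "Syn":
            ss[detail["gene_id"]] = ss.get(detail["gene_id"], 0) + 1
    rows = []
    for m in models:
        if not m.cds_seq:
            continue
        sites = count_sites(m.cds_seq, gene_id=m.gene_id)
        res = kaks_ratio(ns.get(m.gene_id, 0), ss.get(m.gene_id, 0), sites, threshold)
        rows.append(
            {
                "gene_id": m.gene_id,
                "ns": res.ns,
                "ss": res.ss,
                "ln": res.ln,
                "ls": res.ls,
                "ka": res.ka,
                "ks": res.ks,
                "ratio": res.ratio,
                "selected": res.selected,
            }
        )
    return pd.DataFrame(rows)


def selection_intersections(
    kaks_by_trial: dict[str, pd.DataFrame],
    consistent_de,
    dae_merged: pd.DataFrame | None = None,
) -> dict:
    """Cross-trial positive-selection gene sets and their intersections
    with the consistent DE set and with cross-trial DAE SNPs."""
    trials = list(kaks_by_trial)
    sel_sets = [set(df.loc[df.selected, "gene_id"]) for df in kaks_by_trial.values()]
    selected_both = sorted(set.intersection(*sel_sets)) if sel_sets else []

    de_table = None
    de_genes: set[str] = set()
    if consistent_de is not None:
        de_genes = set(consistent_de.same_direction)
        rows = []
        for g in selected_both:
            if g not in de_genes:
                continue
            row = {"gene_id": g}
            for t in trials:
                df = kaks_by_trial[t]
                row[f"kaks_{t}"] = float(df.loc[df.gene_id == g, "ratio"].iloc[0])
            de_row = consistent_de.table.loc[consistent_de.table.gene_id == g]
            for t in trials:
                row[f"log2fc_{t}"] = float(de_row[f"log2fc_{t}"].iloc[0])
                row[f"fdr_{t}"] = float(de_row[f"fdr_{t}"].iloc[0])
            rows.append(row)
        cols = ["gene_id"] + [f"{c}_{t}" for t in trials for c in ("kaks", "log2fc", "fdr")]
        de_table = pd.DataFrame(rows, columns=cols) if not rows else pd.DataFrame(rows)

    dae_table = None
    if dae_merged is not None and len(dae_merged):
        hits = dae_merged[
            dae_merged.same_direction
            & dae_merged.shared
            & dae_merged.gene_id.isin(selected_both)
        ]
        dae_table = hits.reset_index(drop=True)

    return {
        "selected_by_trial": {t: sorted(s) for t, s in zip(trials, sel_sets)},
        "selected_both": selected_both,
        "selected_and_de": de_table,
        "selected_with_dae": dae_table,
    }
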