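"""Synthetic two-trial pooled-extremes RNA-seq datasets with ground truth.

Emulates the study design the downstream statistics assume: two field
trials, each sequenced as 3 replicate bulk libraries per phenotype extreme
("high" / "low" treatment), with

* negative-binomially distributed gene read counts and planted fold
  changes applied to the low-trait treatment, same sign in both trials;
* per-bulk biallelic SNP allele depths (binomial draws at the planted
  allele-B frequency, Poisson depths with log-normal heterogeneity
  across SNPs), with planted frequency shifts for DAE SNPs;
* coding variants planted per gene to hit target nonsynonymous /
  synonymous substitution ratios for the Ka/Ks stage.

Every planted effect is recorded in a machine-readable :class:`TruthTable`
so recovery can be measured without any external data. Identical config
and seed yield byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kaks as _kaks
from .formats import (
    AlleleCountRecord,
    CountMatrix,
    GeneModel,
    LibraryInfo,
    complement,
    write_cds_fasta,
    write_gtf,
)

_BASES = ("A", "C", "G", "T")
_STOPS = ("TAA", "TAG", "TGA")
_SENSE = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)

# Region mix for planted genic SNPs, loosely following the observed
# transcriptome-wide distribution (synonymous sites dominate).
_REGION_MIX = (("Syn", 0.45), ("NonSyn", 0.20), ("UTR3", 0.20), ("Intron", 0.10), ("UTR5", 0.05))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale version of a two-trial pooled-extremes
    experiment: 2 trials x 2 treatments x 3 replicate bulks, ~500 expected
    reads per gene per library, NB dispersion 0.1 (typical biological
    replicate variability), planted |log2FC| of 2 for DE genes, per-bulk
    SNP depth ~250 (so ~750 pooled per treatment and ~1500 pooled across
    a trial's six bulks), and an allele-frequency shift of 0.25 for DAE
    SNPs.
    """

    n_genes: int = 2000
    genes_per_chrom: int = 200
    cds_codons_range: tuple[int, int] = (60, 300)
    n_trials: int = 2
    n_reps: int = 3
    mean_lib_size: float = 1_000_000.0
    nb_dispersion: float = 0.1
    frac_de: float = 0.10
    log2fc_magnitude: float = 2.0
    frac_snp_genes: float = 0.25
    snp_depth_mean: float = 250.0
    snp_depth_log_sigma: float = 0.25
    frac_dae: float = 0.25
    dae_shift: float = 0.25
    frac_cis: float = 0.5
    frac_selected: float = 0.05
    selected_ns: int = 10
    selected_ss: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_de", "frac_snp_genes", "frac_dae", "frac_cis", "frac_selected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1 or self.genes_per_chrom < 1:
            raise ValueError("n_genes and genes_per_chrom must be positive")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 < self.dae_shift <= 0.5:
            raise ValueError(f"dae_shift must be in (0, 0.5], got {self.dae_shift}")
        if self.cds_codons_range[0] < 3:
            raise ValueError("cds_codons_range minimum must be at least 3 codons")
        if self.cds_codons_range[0] > self.cds_codons_range[1]:
            raise ValueError("cds_codons_range must be (min, max) with min <= max")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_lib_size <= 0 or self.snp_depth_mean <= 0:
            raise ValueError("mean_lib_size and snp_depth_mean must be positive")

    @property
    def trial_names(self) -> list[str]:
        return [f"trial{t + 1}" for t in range(self.n_trials)]

    def library_ids(self, trial: str) -> list[str]:
        return [
            f"{trial}_{treatment}{r + 1}"
            for treatment in ("high", "low")
            for r in range(self.n_reps)
        ]

    def library_meta(self) -> dict[str, LibraryInfo]:
        meta = {}
        for trial in self.trial_names:
            for treatment in ("high", "low"):
                for r in range(self.n_reps):
                    meta[f"{trial}_{treatment}{r + 1}"] = LibraryInfo(trial, treatment, r + 1)
        return meta


@dataclass
class TruthTable:
    """Machine-readable record of every planted effect.

    ``genes``: gene_id, de_direction ('up'/'down'/'none', direction in the
    low-trait treatment), planted_log2fc, selected, planted_ns, planted_ss.
    ``snps``: coordinates, alleles, region_class, dae flag, shift_direction
    ('up'/'down'/''), regulatory_class ('cis'/'trans'/'none'), and the
    planted allele-B frequencies per treatment.
    """

    genes: pd.DataFrame
    snps: pd.DataFrame


@dataclass
class SynDataset:
    config: SimConfig
    models: list[GeneModel]
    gtf_text: str
    fasta_text: str
    truth: TruthTable
    counts: dict[str, CountMatrix]
    alleles: dict[str, list[AlleleCountRecord]]
    library_meta: dict[str, LibraryInfo]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    middle = rng.choice(len(_SENSE), size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_SENSE[i] for i in middle) + stop


def _split_lengths(rng: np.random.Generator, total: int, pieces: int, minimum: int) -> list[int]:
    free = total - pieces * minimum
    extra = rng.multinomial(free, [1.0 / pieces] * pieces)
    return [minimum + int(e) for e in extra]


def generate_annotation(config: SimConfig) -> tuple[list[GeneModel], str, str]:
    """Generate gene models plus their GTF and CDS-FASTA serialisations.

    Every gene has a 5'UTR, a multi-exon CDS (whole codons, ATG...stop,
    hence at least one intron), and a 3'UTR; strands are mixed and genes
    are separated by intergenic gaps.
    """
    config.validate()
    rng = _rng(config, 0)
    models: list[GeneModel] = []
    seqs: dict[str, str] = {}
    cursor = 0
    current_chrom = None
    cmin, cmax = config.cds_codons_range
    for i in range(config.n_genes):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        if chrom != current_chrom:
            current_chrom = chrom
            cursor = 1000
        gid = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(cmin, cmax + 1))
        cds_seq = _random_cds(rng, n_codons)
        cds_len = 3 * n_codons
        utr5_len = int(rng.integers(100, 301))
        utr3_len = int(rng.integers(100, 301))
        n_cds_exons = 2 if cds_len < 180 else int(rng.integers(2, 5))
        min_piece = max(3, min(30, cds_len // (2 * n_cds_exons)))
        piece_lens = _split_lengths(rng, cds_len, n_cds_exons, min_piece)
        intron_lens = [int(rng.integers(80, 501)) for _ in range(n_cds_exons - 1)]

        # Feature layout in transcription order: UTR5, CDS pieces with
        # introns between, UTR3.
        tx_feats: list[tuple[str, int]] = [("utr5", utr5_len)]
        for j, pl in enumerate(piece_lens):
            if j > 0:
                tx_feats.append(("intron", intron_lens[j - 1]))
            tx_feats.append(("cds", pl))
        tx_feats.append(("utr3", utr3_len))
        genomic_feats = tx_feats if strand == "+" else tx_feats[::-1]

        pos = cursor
        cds_ivs, utr5_ivs, utr3_ivs, exon_ivs = [], [], [], []
        exon_start = None
        for kind, length in genomic_feats:
            iv = (pos, pos + length - 1)
            if kind == "intron":
                if exon_start is not None:
                    exon_ivs.append((exon_start, pos - 1))
                    exon_start = None
            else:
                if exon_start is None:
                    exon_start = pos
                {"cds": cds_ivs, "utr5": utr5_ivs, "utr3": utr3_ivs}[kind].append(iv)
            pos += length
        if exon_start is not None:
            exon_ivs.append((exon_start, pos - 1))

        model = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exon_ivs,
            cds=cds_ivs,
            utr5=utr5_ivs,
            utr3=utr3_ivs,
            cds_seq=cds_seq,
        )
        models.append(model)
        seqs[gid] = cds_seq
        cursor = pos + int(rng.integers(500, 2001))
    return models, write_gtf(models), write_cds_fasta(seqs)


# ---------------------------------------------------------------------------
# Coding-variant planting
# ---------------------------------------------------------------------------


def _codon_variant(
    rng: np.random.Generator,
    model: GeneModel,
    want_syn: bool,
    used: set[int],
    max_tries: int = 500,
) -> tuple[int, str, str] | None:
    """Pick a CDS position and alt allele whose effect matches want_syn.

    Returns (genomic_pos, ref_genomic, alt_genomic) or None. The start and
    stop codons are avoided so planted variants stay interior.
    """
    seq = model.cds_seq
    positions = model.cds_genomic_positions()
    L = len(seq)
    for _ in range(max_tries):
        idx = int(rng.integers(3, L - 3))
        if idx in used:
            continue
        codon_i, off = divmod(idx, 3)
        codon = seq[3 * codon_i : 3 * codon_i + 3]
        ref_t = seq[idx]
        alts = [b for b in _BASES if b != ref_t]
        rng.shuffle(alts)
        for alt_t in alts:
            alt_codon = codon[:off] + alt_t + codon[off + 1 :]
            syn = _kaks.translate_codon(codon) == _kaks.translate_codon(alt_codon)
            if syn == want_syn:
                used.add(idx)
                gpos = positions[idx]
                if model.strand == "-":
                    return gpos, complement(ref_t), complement(alt_t)
                return gpos, ref_t, alt_t
    return None


def plant_coding_variants(
    config: SimConfig,
    models: list[GeneModel],
    selected_ids: list[str],
    rng: np.random.Generator,
) -> list[dict]:
    """Plant coding variants in positive-selection genes.

    Each selected gene receives ``config.selected_ns`` nonsynonymous and
    ``config.selected_ss`` synonymous variants, chosen so that the
    pseudocounted, length-normalised Ka/Ks exceeds the 1.5 flagging
    threshold. Raises if a gene is too short to host the request.
    """
    by_id = {m.gene_id: m for m in models}
    variants: list[dict] = []
    for gid in selected_ids:
        model = by_id[gid]
        n_req = config.selected_ns + config.selected_ss
        if n_req > model.cds_length // 3 - 2:
            raise ValueError(
                f"gene {gid}: CDS too short ({model.cds_length} nt) to host {n_req} variants"
            )
        used: set[int] = set()
        for want_syn, n in ((False, config.selected_ns), (True, config.selected_ss)):
            for _ in range(n):
                hit = _codon_variant(rng, model, want_syn, used)
                if hit is None:
                    raise ValueError(f"gene {gid}: could not place a planted coding variant")
                gpos, ref, alt = hit
                variants.append(
                    {
                        "chrom": model.chrom,
                        "pos": gpos,
                        "gene_id": gid,
                        "region": "Syn" if want_syn else "NonSyn",
                        "ref": ref,
                        "alt": alt,
                    }
                )
        sites = _kaks.count_sites(model.cds_seq)
        res = _kaks.kaks_ratio(config.selected_ns, config.selected_ss, sites)
        if not res.selected:
            raise ValueError(
                f"gene {gid}: planted NS/SS ({config.selected_ns}/{config.selected_ss}) "
                f"gives Ka/Ks {res.ratio:.2f} <= 1.5; increase selected_ns"
            )
    return variants


# ---------------------------------------------------------------------------
# Truth planning
# ---------------------------------------------------------------------------


def _intergenic_gaps(models: list[GeneModel]) -> list[tuple[str, int, int]]:
    gaps = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, ms in by_chrom.items():
        ms = sorted(ms, key=lambda m: m.span[0])
        prev_end = 0
        for m in ms:
            lo, hi = m.span
            if lo - prev_end > 60:
                gaps.append((chrom, prev_end + 30, lo - 30))
            prev_end = hi
        gaps.append((chrom, prev_end + 30, prev_end + 500))
    return gaps


def _place_genic_snp(
    rng: np.random.Generator, model: GeneModel, region: str
) -> tuple[int, str, str]:
    if region in ("Syn", "NonSyn"):
        hit = _codon_variant(rng, model, region == "Syn", set())
        if hit is None:  # tiny CDS with no site of the wanted class
            raise ValueError(f"gene {model.gene_id}: no {region} site available")
        return hit
    if region == "UTR5":
        ivs = model.utr5
    elif region == "UTR3":
        ivs = model.utr3
    elif region == "Intron":
        ivs = _introns_of(model)
    else:
        raise ValueError(f"unexpected genic region {region}")
    a, b = ivs[rng.integers(len(ivs))]
    pos = int(rng.integers(a, b + 1))
    ref = _BASES[rng.integers(4)]
    alt = rng.choice([x for x in _BASES if x != ref])
    return pos, ref, str(alt)


def _introns_of(model: GeneModel) -> list[tuple[int, int]]:
    introns = []
    for (a1, b1), (a2, b2) in zip(model.exons, model.exons[1:]):
        if a2 > b1 + 1:
            introns.append((b1 + 1, a2 - 1))
    return introns


def plan_truth(config: SimConfig, models: list[GeneModel]) -> TruthTable:
    """Assign planted DE genes, DAE SNPs (cis in DE genes, trans
    elsewhere), region classes and positive-selection genes, and verify
    every planted label against the emitted coordinates."""
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genes
    gene_ids = [m.gene_id for m in models]

    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_dir = rng.choice([1, -1], size=n_de)
    de_direction = {gene_ids[i]: ("up" if s > 0 else "down") for i, s in zip(de_idx, de_dir)}
    de_lfc = {
        gene_ids[i]: float(s * config.log2fc_magnitude) for i, s in zip(de_idx, de_dir)
    }
    de_set = set(de_direction)

    # SNP-carrying genes: one DAE-test SNP per gene. Cis SNPs must land in
    # DE genes, trans SNPs in non-DE genes.
    n_snp_genes = round(config.frac_snp_genes * n)
    n_intergenic = max(2, round(0.04 * n_snp_genes))
    n_snps = n_snp_genes + n_intergenic
    n_dae = round(config.frac_dae * n_snps)
    n_dae_intergenic = min(n_intergenic, round(config.frac_dae * n_intergenic))
    n_cis = min(round(config.frac_cis * (n_dae - n_dae_intergenic)), len(de_set))
    n_trans_genic = n_dae - n_dae_intergenic - n_cis

    de_list = sorted(de_set)
    non_de_list = sorted(set(gene_ids) - de_set)
    cis_genes = list(rng.choice(de_list, size=n_cis, replace=False))
    pool = [g for g in non_de_list]
    rng.shuffle(pool)
    trans_genes = pool[:n_trans_genic]
    remaining = sorted(set(gene_ids) - set(cis_genes) - set(trans_genes))
    rng.shuffle(remaining)
    null_genes = remaining[: n_snp_genes - n_cis - n_trans_genic]

    # Positive-selection genes: disjoint from DAE-test genes so the
    # planted NS/SS budget is not perturbed.
    snp_gene_set = set(cis_genes) | set(trans_genes) | set(null_genes)
    sel_pool = sorted(set(gene_ids) - snp_gene_set)
    rng.shuffle(sel_pool)
    n_sel = round(config.frac_selected * n)
    selected_ids = sorted(sel_pool[:n_sel])

    by_id = {m.gene_id: m for m in models}
    region_names = [r for r, _ in _REGION_MIX]
    region_probs = [p for _, p in _REGION_MIX]

    snp_rows: list[dict] = []

    def add_genic(gid: str, reg_class: str, dae: bool) -> None:
        model = by_id[gid]
        region = str(rng.choice(region_names, p=region_probs))
        pos, ref, alt = _place_genic_snp(rng, model, region)
        snp_rows.append(
            _snp_row(rng, config, model.chrom, pos, gid, region, ref, alt, dae, reg_class)
        )

    for gid in cis_genes:
        add_genic(gid, "cis", dae=True)
    for gid in trans_genes:
        add_genic(gid, "trans", dae=True)
    for gid in null_genes:
        add_genic(gid, "none", dae=False)

    gaps = _intergenic_gaps(models)
    used_pos: set[tuple[str, int]] = {(r["chrom"], r["pos"]) for r in snp_rows}
    for k in range(n_intergenic):
        while True:
            chrom, a, b = gaps[rng.integers(len(gaps))]
            pos = int(rng.integers(a, b + 1))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        ref = _BASES[rng.integers(4)]
        alt = str(rng.choice([x for x in _BASES if x != ref]))
        dae = k < n_dae_intergenic
        snp_rows.append(
            _snp_row(rng, config, chrom, pos, "", "Intergenic", ref, alt, dae,
                     "trans" if dae else "none")
        )

    # Ka/Ks variants (non-DAE, constant frequency across treatments).
    for v in plant_coding_variants(config, models, selected_ids, rng):
        if (v["chrom"], v["pos"]) in used_pos:
            continue
        used_pos.add((v["chrom"], v["pos"]))
        snp_rows.append(
            _snp_row(rng, config, v["chrom"], v["pos"], v["gene_id"], v["region"],
                     v["ref"], v["alt"], dae=False, reg_class="none")
        )

    snps = pd.DataFrame(snp_rows).sort_values(["chrom", "pos"], kind="mergesort")
    snps = snps.reset_index(drop=True)

    # Per-gene planted NS/SS tallies over every coding variant.
    ns_count = snps[snps.region == "NonSyn"].groupby("gene_id").size()
    ss_count = snps[snps.region == "Syn"].groupby("gene_id").size()
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "de_direction": [de_direction.get(g, "none") for g in gene_ids],
            "planted_log2fc": [de_lfc.get(g, 0.0) for g in gene_ids],
            "selected": [g in set(selected_ids) for g in gene_ids],
            "planted_ns": [int(ns_count.get(g, 0)) for g in gene_ids],
            "planted_ss": [int(ss_count.get(g, 0)) for g in gene_ids],
        }
    )

    truth = TruthTable(genes=genes, snps=snps)
    _verify_truth(truth, models)
    return truth


def _snp_row(
    rng: np.random.Generator,
    config: SimConfig,
    chrom: str,
    pos: int,
    gene_id: str,
    region: str,
    ref: str,
    alt: str,
    dae: bool,
    reg_class: str,
) -> dict:
    d = config.dae_shift
    if dae:
        f0 = float(rng.uniform(0.05 + d / 2, 0.95 - d / 2))
        s = 1 if rng.random() < 0.5 else -1
        f_high = f0 - s * d / 2
        f_low = f0 + s * d / 2
        shift_direction = "up" if s > 0 else "down"
    else:
        f0 = float(rng.uniform(0.10, 0.90))
        f_high = f_low = f0
        shift_direction = ""
    return {
        "chrom": chrom,
        "pos": pos,
        "gene_id": gene_id,
        "region": region,
        "ref": ref,
        "alt": alt,
        "dae": dae,
        "shift_direction": shift_direction,
        "regulatory_class": reg_class,
        "f_high": f_high,
        "f_low": f_low,
    }


def _verify_truth(truth: TruthTable, models: list[GeneModel]) -> None:
    """Truth invariants: cis SNPs sit inside DE genes; every region label
    agrees with coordinate reclassification by the kaks module."""
    de_genes = set(truth.genes.loc[truth.genes.de_direction != "none", "gene_id"])
    index = _kaks.GeneIndex(models)
    for r in truth.snps.itertuples():
        if r.regulatory_class == "cis" and r.gene_id not in de_genes:
            raise AssertionError(f"cis SNP {r.chrom}:{r.pos} not in a DE gene")
        model = index.find(r.chrom, r.pos)
        region, _ = _kaks.classify_variant(r.chrom, r.pos, r.ref, r.alt, model)
        if region != r.region:
            raise AssertionError(
                f"SNP {r.chrom}:{r.pos}: planted region {r.region} != reclassified {region}"
            )


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def simulate_counts(config: SimConfig, truth: TruthTable) -> dict[str, CountMatrix]:
    """Draw negative-binomial gene counts per trial.

    For DE genes the low-treatment mean equals the high-treatment mean
    times 2**planted_log2fc (same sign in both trials); library sizes vary
    +/-20% around ``mean_lib_size``.
    """
    config.validate()
    meta = config.library_meta()
    gene_ids = list(truth.genes.gene_id)
    lfc = truth.genes.planted_log2fc.to_numpy(float)
    out: dict[str, CountMatrix] = {}
    for t, trial in enumerate(config.trial_names):
        rng = _rng(config, 100 + t)
        # Relative expression levels, redrawn per trial.
        w = rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))
        w /= w.sum()
        libs = config.library_ids(trial)
        counts = np.zeros((len(gene_ids), len(libs)), dtype=np.int64)
        for j, lib in enumerate(libs):
            lib_size = config.mean_lib_size * rng.uniform(0.8, 1.2)
            mu = w * lib_size
            if meta[lib].treatment == "low":
                mu = mu * np.exp2(lfc)
            if config.nb_dispersion == 0:
                counts[:, j] = rng.poisson(mu)
            else:
                r = 1.0 / config.nb_dispersion
                counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        out[trial] = CountMatrix(
            gene_ids=gene_ids,
            library_ids=libs,
            counts=counts,
            library_meta={lib: meta[lib] for lib in libs},
        )
    return out


# ---------------------------------------------------------------------------
# Allele-depth simulation
# ---------------------------------------------------------------------------


def simulate_allele_counts(
    config: SimConfig, truth: TruthTable, models: list[GeneModel] | None = None
) -> dict[str, list[AlleleCountRecord]]:
    """Draw per-bulk allele depths per trial.

    Depth per bulk is Poisson around ``snp_depth_mean`` scaled by a
    per-SNP log-normal factor (depths in real pooled data span orders of
    magnitude); the alt-allele count is binomial at the planted allele-B
    frequency of the bulk's treatment, identical in both trials.
    """
    config.validate()
    out: dict[str, list[AlleleCountRecord]] = {}
    for t, trial in enumerate(config.trial_names):
        rng = _rng(config, 200 + t)
        records: list[AlleleCountRecord] = []
        for r in truth.snps.itertuples():
            m = float(rng.lognormal(0.0, config.snp_depth_log_sigma))
            depths: dict[str, tuple[int, int]] = {}
            for treatment, f in (("high", r.f_high), ("low", r.f_low)):
                for rep in range(config.n_reps):
                    depth = int(rng.poisson(config.snp_depth_mean * m))
                    alt = int(rng.binomial(depth, f)) if depth > 0 else 0
                    depths[f"{trial}_{treatment}{rep + 1}"] = (depth - alt, alt)
            records.append(
                AlleleCountRecord(
                    chrom=r.chrom,
                    pos=int(r.pos),
                    gene_id=r.gene_id,
                    region=r.region,
                    ref=r.ref,
                    alt=r.alt,
                    depths=depths,
                )
            )
        out[trial] = records
    return out


# ---------------------------------------------------------------------------
# Category map with a planted enrichment
# ---------------------------------------------------------------------------


def plant_category_map(
    truth: TruthTable,
    seed: int,
    n_categories: int = 25,
    enrichment: float = 5.0,
) -> tuple[pd.DataFrame, str]:
    """Assign genes to functional categories, over-representing category
    CAT001 among down-in-low DE genes by ``enrichment``-fold.

    Returns (annotation map with columns gene_id/category_id/category_name,
    planted category id).
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 77])
    genes = truth.genes
    planted = "CAT001"
    base_p = 0.04
    rows = []
    down = set(genes.loc[genes.de_direction == "down", "gene_id"])
    for g in genes.gene_id:
        p1 = min(1.0, base_p * enrichment) if g in down else base_p
        if rng.random() < p1:
            rows.append({"gene_id": g, "category_id": planted, "category_name": "planted_process"})
        for c in range(2, n_categories + 1):
            if rng.random() < base_p:
                rows.append(
                    {
                        "gene_id": g,
                        "category_id": f"CAT{c:03d}",
                        "category_name": f"background_process_{c}",
                    }
                )
    return pd.DataFrame(rows), planted


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig) -> SynDataset:
    """Generate the complete synthetic dataset for one config+seed."""
    models, gtf_text, fasta_text = generate_annotation(config)
    truth = plan_truth(config, models)
    counts = simulate_counts(config, truth)
    alleles = simulate_allele_counts(config, truth, models)
    return SynDataset(
        config=config,
        models=models,
        gtf_text=gtf_text,
        fasta_text=fasta_text,
        truth=truth,
        counts=counts,
        alleles=alleles,
        library_meta=config.library_meta(),
    )


def write_dataset(ds: SynDataset, outdir) -> None:
    """Write every artifact of a synthetic dataset as plain text."""
    from pathlib import Path

    from . import formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "annotation.gtf").write_text(ds.gtf_text, encoding="utf-8")
    (outdir / "cds.fasta").write_text(ds.fasta_text, encoding="utf-8")
    formats.write_library_meta(ds.library_meta, outdir / "library_meta.tsv")
    for trial, cm in ds.counts.items():
        formats.write_counts(cm, outdir / f"counts_{trial}.tsv")
    for trial, recs in ds.alleles.items():
        formats.write_allele_table(recs, outdir / f"alleles_{trial}.tsv")
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    ds.truth.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
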