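"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate convention is 1-based inclusive everywhere: GTF intervals are
stored as parsed, VCF positions are emitted unchanged. All tables are
plain UTF-8 TSV with a deterministic column order, so that a fixed
simulation seed yields byte-identical artifacts.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Region classes a SNP can be assigned to, in canonical output order.
REGION_CLASSES = ("Syn", "NonSyn", "UTR5", "UTR3", "Intron", "Intergenic", "Unassigned")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class LibraryInfo:
    """Metadata for one sequenced bulk: which trial, which phenotype
    extreme (treatment) and which biological replicate it is."""

    trial: str
    treatment: str  # "high" or "low"
    replicate: int

    def __post_init__(self):
        if self.treatment not in ("high", "low"):
            raise ValueError(f"treatment must be 'high' or 'low', got {self.treatment!r}")


def _check_intervals(ivs: list[Interval], label: str, gene_id: str) -> list[Interval]:
    ivs = sorted((int(a), int(b)) for a, b in ivs)
    prev_end = 0
    for a, b in ivs:
        if a < 1 or b < a:
            raise ValueError(f"gene {gene_id}: bad {label} interval ({a}, {b})")
        if a <= prev_end:
            raise ValueError(f"gene {gene_id}: overlapping {label} intervals")
        prev_end = b
    return ivs


@dataclass
class GeneModel:
    """One gene's structure: strand, exon/CDS/UTR intervals (1-based
    inclusive, sorted by genomic start) and the CDS nucleotide sequence
    in transcription order (reverse-complemented for '-' strand genes).

    This is the coordinate authority for variant classification.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    cds_seq: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.exons = _check_intervals(self.exons, "exon", self.gene_id)
        self.cds = _check_intervals(self.cds, "CDS", self.gene_id)
        self.utr5 = _check_intervals(self.utr5, "UTR5", self.gene_id)
        self.utr3 = _check_intervals(self.utr3, "UTR3", self.gene_id)
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.cds_seq and len(self.cds_seq) != self.cds_length:
            raise ValueError(
                f"gene {self.gene_id}: cds_seq length {len(self.cds_seq)} != "
                f"summed CDS interval length {self.cds_length}"
            )
        self._pos_to_cds_index: dict[int, int] | None = None

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_genomic_positions(self) -> list[int]:
        """Genomic coordinates of CDS nucleotides in transcription order,
        so position i corresponds to cds_seq[i]."""
        pos: list[int] = []
        for a, b in self.cds:
            pos.extend(range(a, b + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_index_of(self, pos: int) -> int | None:
        """Index into cds_seq of genomic position pos, or None if non-coding."""
        if self._pos_to_cds_index is None:
            self._pos_to_cds_index = {p: i for i, p in enumerate(self.cds_genomic_positions())}
        return self._pos_to_cds_index.get(pos)

    def region_of(self, pos: int) -> str | None:
        """Structural region of a position: 'CDS', 'UTR5', 'UTR3',
        'Intron', or None if outside the gene span."""
        lo, hi = self.span
        if pos < lo or pos > hi:
            return None
        for label, ivs in (("CDS", self.cds), ("UTR5", self.utr5), ("UTR3", self.utr3)):
            for a, b in ivs:
                if a <= pos <= b:
                    return label
        return "Intron"


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_FEATURES = {
    "gene": None,
    "exon": "exons",
    "CDS": "cds",
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
}

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def write_gtf(models: list[GeneModel], source: str = "poolex") -> str:
    """Serialise gene models to 9-column GTF text (1-based inclusive)."""
    out = io.StringIO()
    for m in models:
        attrs = f'gene_id "{m.gene_id}";'
        lo, hi = m.span
        rows = [("gene", lo, hi)]
        rows += [("exon", a, b) for a, b in m.exons]
        rows += [("CDS", a, b) for a, b in m.cds]
        rows += [("five_prime_utr", a, b) for a, b in m.utr5]
        rows += [("three_prime_utr", a, b) for a, b in m.utr3]
        for feat, a, b in rows:
            out.write(
                f"{m.chrom}\t{source}\t{feat}\t{a}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
            )
    return out.getvalue()


def parse_gtf(text: str) -> list[GeneModel]:
    """Parse GTF text into gene models (without CDS sequences).

    Unknown feature types are ignored with a warning; malformed lines and
    genes whose CDS length is not a multiple of 3 raise ValueError.
    """
    per_gene: dict[str, dict] = {}
    warned: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GTF line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _source, feat, start, end, _score, strand, _frame, attrs = cols
        if feat not in _GTF_FEATURES:
            if feat not in warned:
                log.warning("GTF: ignoring unknown feature type %r", feat)
                warned.add(feat)
            continue
        m = _GENE_ID_RE.search(attrs)
        if m is None:
            raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
        gid = m.group(1)
        try:
            a, b = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"GTF line {lineno}: non-integer coordinates") from exc
        g = per_gene.setdefault(
            gid, {"chrom": chrom, "strand": strand, "exons": [], "cds": [], "utr5": [], "utr3": []}
        )
        slot = _GTF_FEATURES[feat]
        if slot is not None:
            g[slot].append((a, b))
    models = []
    for gid, g in per_gene.items():
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                exons=g["exons"],
                cds=g["cds"],
                utr5=g["utr5"],
                utr3=g["utr3"],
            )
        )
    return models


def read_gtf(path) -> list[GeneModel]:
    with open(path, encoding="utf-8") as fh:
        return parse_gtf(fh.read())


# ---------------------------------------------------------------------------
# FASTA (CDS sequences)
# ---------------------------------------------------------------------------


def write_cds_fasta(seqs: dict[str, str], path=None) -> str:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def attach_cds_sequences(models: list[GeneModel], seqs: dict[str, str]) -> list[GeneModel]:
    """Attach CDS sequences (transcription order) to parsed models,
    validating the length contract."""
    for m in models:
        if m.gene_id in seqs:
            seq = seqs[m.gene_id]
            if len(seq) != m.cds_length:
                raise ValueError(
                    f"gene {m.gene_id}: FASTA CDS length {len(seq)} != annotation {m.cds_length}"
                )
            m.cds_seq = seq
    return models


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x libraries integer read counts with per-library metadata."""

    gene_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray
    library_meta: dict[str, LibraryInfo]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ValueError("count matrix dimensions do not match id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, l = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]}, library {self.library_ids[l]}"
            )
        missing = [l for l in self.library_ids if l not in self.library_meta]
        if missing:
            raise ValueError(f"libraries missing metadata: {missing}")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def libraries_for(self, treatment: str) -> list[int]:
        return [
            i
            for i, lib in enumerate(self.library_ids)
            if self.library_meta[lib].treatment == treatment
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.library_ids)


def write_counts(matrix: CountMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts(path, library_meta: dict[str, LibraryInfo]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        bad = ~(np.mod(vals, 1) == 0) | ~np.isfinite(vals.astype(float))
        if bad.any():
            g, l = np.argwhere(bad)[0]
            raise ValueError(
                f"non-integer count at row {df.index[g]!r}, column {df.columns[l]!r}"
            )
        vals = vals.astype(np.int64)
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        library_ids=list(df.columns.astype(str)),
        counts=vals,
        library_meta=library_meta,
    )


def write_library_meta(meta: dict[str, LibraryInfo], path) -> None:
    rows = [
        {"library_id": lib, "trial": m.trial, "treatment": m.treatment, "replicate": m.replicate}
        for lib, m in meta.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_meta(path) -> dict[str, LibraryInfo]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.library_id): LibraryInfo(str(r.trial), str(r.treatment), int(r.replicate))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Allele count tables
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountRecord:
    """Per-bulk ref/alt read depths for one biallelic SNP.

    ``gene_id`` may be empty for intergenic SNPs. ``region`` is the stored
    region class; it is always recomputable from the annotation and the
    recomputation is authoritative on conflict.
    """

    chrom: str
    pos: int
    gene_id: str
    region: str
    ref: str
    alt: str
    depths: dict[str, tuple[int, int]]

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"SNP {self.chrom}:{self.pos}: ref equals alt")
        if self.region not in REGION_CLASSES:
            raise ValueError(f"SNP {self.chrom}:{self.pos}: unknown region {self.region!r}")
        for bulk, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"SNP {self.chrom}:{self.pos}: negative depth in bulk {bulk}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def write_allele_table(records: list[AlleleCountRecord], path) -> None:
    if not records:
        pd.DataFrame(columns=["chrom", "pos", "gene_id", "region", "ref", "alt"]).to_csv(
            path, sep="\t", index=False
        )
        return
    bulks = list(records[0].depths)
    rows = []
    for rec in records:
        if list(rec.depths) != bulks:
            raise ValueError("all records must share the same bulk ordering")
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "gene_id": rec.gene_id,
            "region": rec.region,
            "ref": rec.ref,
            "alt": rec.alt,
        }
        for b in bulks:
            row[f"{b}_ref"], row[f"{b}_alt"] = rec.depths[b]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_table(path) -> list[AlleleCountRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"gene_id": str, "chrom": str})
    fixed = ["chrom", "pos", "gene_id", "region", "ref", "alt"]
    bulk_cols = [c for c in df.columns if c not in fixed]
    bulks = []
    for c in bulk_cols:
        if c.endswith("_ref"):
            b = c[: -len("_ref")]
            if f"{b}_alt" not in df.columns:
                raise ValueError(f"allele table: missing column {b}_alt")
            bulks.append(b)
    records = []
    seen: set[tuple[str, int]] = set()
    for r in df.itertuples(index=False):
        d = r._asdict()
        key = (str(d["chrom"]), int(d["pos"]))
        if key in seen:
            raise ValueError(f"duplicate SNP at {key[0]}:{key[1]}")
        seen.add(key)
        depths = {b: (int(d[f"{b}_ref"]), int(d[f"{b}_alt"])) for b in bulks}
        records.append(
            AlleleCountRecord(
                chrom=key[0],
                pos=key[1],
                gene_id=str(d["gene_id"]),
                region=str(d["region"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                depths=depths,
            )
        )
    return records


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------


def export_vcf(records: list[AlleleCountRecord], path) -> None:
    """Write a minimal VCF v4.2 with one sample column per bulk and an AD
    FORMAT field carrying ref,alt read depths."""
    bulks = list(records[0].depths) if records else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Host gene id">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(bulks) + "\n")
        for rec in records:
            info = f"REGION={rec.region}"
            if rec.gene_id:
                info = f"GENE={rec.gene_id};" + info
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                "PASS",
                info,
                "AD",
            ] + [f"{rec.depths[b][0]},{rec.depths[b][1]}" for b in bulks]
            fh.write("\t".join(fields) + "\n")
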