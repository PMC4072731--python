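"""End-to-end pipeline driver: simulate (or load) -> DGE -> DAE -> Ka/Ks
-> enrichment, with a structured, auditable run report.

All randomness flows from the single seed in the run configuration, so
two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dae as _dae
from . import dge as _dge
from . import enrich as _enrich
from . import formats, kaks as _kaks
from . import syndata

log = logging.getLogger(__name__)

_THRESHOLD_FIELDS = {
    "dge_fdr": 0.05,
    "dae_p": 1e-4,
    "kaks_threshold": 1.5,
    "min_cpm": 1.0,
    "min_cpm_libraries": 3,
    "dae_min_depth": 50,
    "dae_min_support": 20,
    "dae_min_vaf": 0.01,
    "kaks_min_count": 4,
    "kaks_min_cov": 20,
    "kaks_max_cov": 2000,
}


@dataclass
class RunConfig:
    """Full-run configuration: either a simulation block or input paths,
    plus every analysis threshold (defaults follow the standard pooled
    RNA-seq settings)."""

    outdir: str
    seed: int = 0
    sim: syndata.SimConfig | None = None
    inputs: dict | None = None
    dge_fdr: float = 0.05
    dae_p: float = 1e-4
    kaks_threshold: float = 1.5
    min_cpm: float = 1.0
    min_cpm_libraries: int = 3
    dae_min_depth: int = 50
    dae_min_support: int = 20
    dae_min_vaf: float = 0.01
    kaks_min_count: int = 4
    kaks_min_cov: int = 20
    kaks_max_cov: int = 2000
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of 'sim' or 'inputs' must be given")
        for name in ("dge_fdr", "dae_p", "kaks_threshold", "min_cpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sim is not None:
            self.sim.validate()
        if self.inputs is not None:
            required = {"gtf", "cds_fasta", "library_meta", "counts", "alleles"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing keys: {sorted(missing)}")
            for key in ("gtf", "cds_fasta", "library_meta"):
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input file not found: {self.inputs[key]}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "cds_codons_range" in sim_raw:
                sim_raw["cds_codons_range"] = tuple(sim_raw["cds_codons_range"])
            sim_known = {f.name for f in dataclasses.fields(syndata.SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            raw["sim"] = syndata.SimConfig(**sim_raw)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    report: dict
    dge_by_trial: dict[str, pd.DataFrame]
    consistent: _dge.ConsistentDeSet
    dae_by_trial: dict[str, pd.DataFrame]
    dae_classified: pd.DataFrame
    kaks_by_trial: dict[str, pd.DataFrame]
    intersections: dict
    enrichment: _enrich.EnrichmentReport | None
    truth: syndata.TruthTable | None = None


def _load_inputs(config: RunConfig):
    paths = config.inputs
    models = formats.read_gtf(paths["gtf"])
    formats.attach_cds_sequences(models, formats.read_cds_fasta(paths["cds_fasta"]))
    meta = formats.read_library_meta(paths["library_meta"])
    counts = {
        trial: formats.read_counts(p, meta) for trial, p in sorted(paths["counts"].items())
    }
    alleles = {trial: formats.read_allele_table(p) for trial, p in sorted(paths["alleles"].items())}
    annotation = None
    if paths.get("categories"):
        annotation = pd.read_csv(paths["categories"], sep="\t")
    return models, meta, counts, alleles, annotation, None


def run_all(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline; every stage failure aborts with the
    stage name in the exception message."""
    config.validate()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        ds = syndata.generate_dataset(sim)
        models, meta, counts, alleles = ds.models, ds.library_meta, ds.counts, ds.alleles
        annotation, _planted = syndata.plant_category_map(ds.truth, seed=config.seed)
        truth = ds.truth
        if write:
            syndata.write_dataset(ds, outdir / "synthetic")
            annotation.to_csv(outdir / "synthetic" / "categories.tsv", sep="\t", index=False)
    else:
        models, meta, counts, alleles, annotation, truth = _load_inputs(config)

    trials = sorted(counts)
    report: dict = {"seed": config.seed, "trials": trials, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    # --- DGE per trial -----------------------------------------------------
    st = stage("dge")
    dge_by_trial = {}
    for trial in trials:
        try:
            res = _dge.run_dge_trial(
                counts[trial], config.min_cpm, config.min_cpm_libraries
            )
        except Exception as exc:
            raise RuntimeError(f"stage dge failed for {trial}: {exc}") from exc
        dge_by_trial[trial] = res
        st[trial] = {
            "genes_total": int(len(res)),
            "genes_filtered_in": int(res.filter_pass.sum()),
            "de_genes": int((res.fdr < config.dge_fdr).sum()),
            "dispersion": float(res.attrs["dispersion"]),
        }

    # --- cross-trial DE ----------------------------------------------------
    st = stage("consistent_de")
    consistent = _dge.consistent_de(
        dge_by_trial[trials[0]], dge_by_trial[trials[1]], config.dge_fdr,
        trial_names=(trials[0], trials[1]),
    )
    st.update(
        both_significant=len(consistent.both_significant),
        same_direction=len(consistent.same_direction),
        opposite_direction=len(consistent.opposite_direction),
        up_in_low=len(consistent.up_in_low),
        down_in_low=len(consistent.down_in_low),
    )

    # --- DAE ---------------------------------------------------------------
    st = stage("dae")
    dae_by_trial = {}
    for trial in trials:
        res = _dae.run_dae_trial(
            alleles[trial], meta, config.dae_min_depth, config.dae_min_support,
            config.dae_min_vaf,
        )
        dae_by_trial[trial] = _dae.call_dae(res, config.dae_p)
        st[trial] = {
            "snps_total": int(len(res)),
            "snps_filtered_in": int(res.filter_pass.sum()),
            "dae_significant": int(dae_by_trial[trial].significant.sum()),
        }
    merged = _dae.cross_trial_consistency(
        dae_by_trial[trials[0]], dae_by_trial[trials[1]], config.dae_p,
        trial_names=(trials[0], trials[1]),
    )
    classified = _dae.classify_regulatory(merged, consistent.same_direction)
    n_cis = int((classified.regulatory_class == "cis_candidate").sum())
    st["shared"] = int(merged.shared.sum())
    st["same_direction"] = int(merged.same_direction.sum())
    st["cis_candidates"] = n_cis
    st["cis_genes"] = int(
        classified.loc[classified.regulatory_class == "cis_candidate", "gene_id"].nunique()
    )

    # --- Ka/Ks -------------------------------------------------------------
    st = stage("kaks")
    kaks_by_trial = {}
    for trial in trials:
        kaks_by_trial[trial] = _kaks.run_kaks_trial(
            models, alleles[trial], config.kaks_min_count, config.kaks_min_cov,
            config.kaks_max_cov, config.kaks_threshold,
        )
        st[trial] = {"selected": int(kaks_by_trial[trial].selected.sum())}
    inter = _kaks.selection_intersections(kaks_by_trial, consistent, classified)
    st["selected_both"] = len(inter["selected_both"])
    st["selected_and_de"] = 0 if inter["selected_and_de"] is None else len(inter["selected_and_de"])

    # --- Enrichment --------------------------------------------------------
    enrichment = None
    if annotation is not None and len(annotation):
        st = stage("enrich")
        de_universe = set()
        for trial in trials:
            de_universe |= set(dge_by_trial[trial].loc[dge_by_trial[trial].filter_pass, "gene_id"])
        gene_universe = {m.gene_id for m in models}
        enrichment = _enrich.run_enrichment_suites(
            consistent, classified, inter["selected_by_trial"], annotation,
            de_universe, gene_universe,
        )
        for name, df in enrichment.suites.items():
            st[name] = {
                "categories_tested": int(len(df)),
                "enriched_fdr05": int((df.fdr < 0.05).sum()) if len(df) else 0,
            }

    # --- set-algebra invariants -------------------------------------------
    robust_keys = set(
        map(tuple, classified.loc[classified.same_direction, ["chrom", "pos"]].to_numpy())
    )
    cis_keys = set(
        map(
            tuple,
            classified.loc[
                classified.regulatory_class == "cis_candidate", ["chrom", "pos"]
            ].to_numpy(),
        )
    )
    sel_and_de = (
        set() if inter["selected_and_de"] is None else set(inter["selected_and_de"].gene_id)
    )
    report["invariants"] = {
        "cis_subset_of_shared_dae": cis_keys <= robust_keys,
        "selected_and_de_subset_of_selected_both": sel_and_de <= set(inter["selected_both"]),
        "same_plus_opposite_equals_both": (
            len(consistent.same_direction) + len(consistent.opposite_direction)
            == len(consistent.both_significant)
        ),
        "updown_partition_disjoint": not (consistent.up_in_low & consistent.down_in_low),
    }

    result = RunResult(
        report=report,
        dge_by_trial=dge_by_trial,
        consistent=consistent,
        dae_by_trial=dae_by_trial,
        dae_classified=classified,
        kaks_by_trial=kaks_by_trial,
        intersections=inter,
        enrichment=enrichment,
        truth=truth,
    )
    if write:
        _write_outputs(result, outdir, trials)
    return result


def _write_outputs(result: RunResult, outdir: Path, trials: list[str]) -> None:
    float_fmt = "%.6g"
    for trial in trials:
        result.dge_by_trial[trial].to_csv(
            outdir / f"dge_{trial}.tsv", sep="\t", index=False, float_format=float_fmt
        )
        result.dae_by_trial[trial].to_csv(
            outdir / f"dae_{trial}.tsv", sep="\t", index=False, float_format=float_fmt
        )
        result.kaks_by_trial[trial].to_csv(
            outdir / f"kaks_{trial}.tsv", sep="\t", index=False, float_format=float_fmt
        )
    result.consistent.table.to_csv(
        outdir / "consistent_de.tsv", sep="\t", index=False, float_format=float_fmt
    )
    result.dae_classified.to_csv(
        outdir / "dae_cross_trial.tsv", sep="\t", index=False, float_format=float_fmt
    )
    if result.intersections["selected_and_de"] is not None:
        result.intersections["selected_and_de"].to_csv(
            outdir / "selected_and_de.tsv", sep="\t", index=False, float_format=float_fmt
        )
    if result.intersections["selected_with_dae"] is not None:
        result.intersections["selected_with_dae"].to_csv(
            outdir / "selected_with_dae.tsv", sep="\t", index=False, float_format=float_fmt
        )
    if result.enrichment is not None:
        for name, df in result.enrichment.suites.items():
            df.to_csv(
                outdir / f"enrich_{name}.tsv", sep="\t", index=False, float_format=float_fmt
            )
    cis = result.dae_classified[result.dae_classified.regulatory_class == "cis_candidate"]
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote outputs to %s (%d cis candidates)", outdir, len(cis))
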