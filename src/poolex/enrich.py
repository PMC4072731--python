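"""Category (GO-style) over-representation tests for result gene sets.

One-sided Fisher exact tests (equivalently hypergeometric upper tails) on
the 2x2 table of in-query vs not, in-category vs not, with
Benjamini-Hochberg adjustment across the categories tested. The universe
is the set of genes eligible for the upstream analysis that produced the
query set (e.g. expression-filtered genes for DE suites).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .dge import bh_fdr


def fisher_enrichment(
    query: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category over-representation of ``query`` within ``universe``.

    ``annotation`` has columns gene_id, category_id, category_name; only
    annotations of universe genes count. Categories with no query member
    are reported with p = 1. Returns category_id, category_name,
    universe_total, changed, p_value, fdr sorted by category_id.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query set must be a subset of the universe")
    ann = annotation[annotation.gene_id.isin(universe)]
    m = len(universe)
    n_query = len(query)
    rows = []
    for cat_id, grp in ann.groupby("category_id", sort=True):
        members = set(grp.gene_id)
        k_total = len(members)
        k_changed = len(members & query)
        if k_changed == 0:
            p = 1.0
        else:
            # Upper tail of Hypergeometric(m, k_total, n_query) at k_changed.
            p = float(stats.hypergeom.sf(k_changed - 1, m, k_total, n_query))
        rows.append(
            {
                "category_id": cat_id,
                "category_name": grp.category_name.iloc[0],
                "universe_total": k_total,
                "changed": k_changed,
                "p_value": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df.p_value.to_numpy())
    else:
        df = pd.DataFrame(
            columns=["category_id", "category_name", "universe_total", "changed", "p_value", "fdr"]
        )
    return df


@dataclass
class EnrichmentReport:
    suites: dict[str, pd.DataFrame]


def run_enrichment_suites(
    consistent_de,
    dae_classified: pd.DataFrame,
    selected_by_trial: dict[str, list[str]],
    annotation: pd.DataFrame,
    de_universe: set[str],
    gene_universe: set[str],
) -> EnrichmentReport:
    """Standard suites: DE-up, DE-down, DGE∩DAE genes, DAE-only genes,
    and positive-selection genes per trial.

    DE suites use the expression-filtered universe; DAE and selection
    suites use the full annotated gene universe. Empty query sets yield
    empty tables without error.
    """
    suites: dict[str, pd.DataFrame] = {}

    def run(name: str, query: set[str], universe: set[str]) -> None:
        query = {g for g in query if g} & universe
        if not query:
            suites[name] = pd.DataFrame(
                columns=["category_id", "category_name", "universe_total", "changed",
                         "p_value", "fdr"]
            )
            return
        suites[name] = fisher_enrichment(query, universe, annotation)

    run("de_up", set(consistent_de.up_in_low), de_universe)
    run("de_down", set(consistent_de.down_in_low), de_universe)

    robust = dae_classified[dae_classified.regulatory_class != "none"]
    cis_genes = set(robust.loc[robust.regulatory_class == "cis_candidate", "gene_id"])
    dae_only_genes = set(robust.loc[robust.regulatory_class == "dae_only", "gene_id"])
    run("dge_and_dae", cis_genes, gene_universe)
    run("dae_only", dae_only_genes, gene_universe)

    for trial, genes in selected_by_trial.items():
        run(f"selected_{trial}", set(genes), gene_universe)
    return EnrichmentReport(suites=suites)
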