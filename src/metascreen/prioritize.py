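"""Frequency ranking, top-N selection, OncoPrint-style export, and hit calls.

Genes are ranked by how many qualifying samples (recurrent tumors, blood,
and organ metastases by default — the compartments where a disseminating
knockout clone can appear) contain them; ties break by the summed reads of
their threshold-passing guides in those samples, then alphabetically, so the
ordering is a reproducible total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import COMPARTMENTS, LibraryDesign, SampleSheet
from .enrichment import GeneSetReport, PresenceMatrix
from .cohort import CandidateCatalog, HomologMap, map_homologs

DEFAULT_COMPARTMENTS = frozenset({"recurrent", "blood", "metastasis"})


def rank_by_frequency(
    presence: PresenceMatrix,
    counts: pd.DataFrame,
    lib: LibraryDesign,
    sheet: SampleSheet,
    compartments: frozenset | set = DEFAULT_COMPARTMENTS,
) -> pd.DataFrame:
    """Rank genes by qualifying-sample appearance count.

    Returns a DataFrame with columns ``gene, frequency, total_reads, rank``
    sorted by frequency desc, then total_reads desc, then symbol asc, with
    consecutive 1-based ranks.
    """
    if not compartments:
        raise ValueError("compartment selection must not be empty")
    unknown = set(compartments) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartment(s): {sorted(unknown)}")
    qualifying = [
        s
        for c in COMPARTMENTS
        if c in compartments
        for s in sheet.samples_in(c)
        if s in presence.sample_ids
    ]
    freq = presence.frame[qualifying].sum(axis=1).astype(int)
    # reads of threshold-passing guides in qualifying samples, per gene
    sub = counts[[s for s in qualifying if s in counts.columns]]
    passing = sub.where(sub >= presence.tau, 0)
    gene_of = lib.gene_of().loc[sub.index]
    reads = passing.groupby(gene_of.to_numpy()).sum().sum(axis=1).astype(int)
    reads = reads.reindex(freq.index, fill_value=0)

    table = pd.DataFrame(
        {"gene": freq.index, "frequency": freq.to_numpy(), "total_reads": reads.to_numpy()}
    )
    table = table.sort_values(
        ["frequency", "total_reads", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = table.index + 1
    return table


def top_n(rank_table: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    """First min(n, len) rows of a rank table, order preserved."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rank_table.head(n).reset_index(drop=True)


def oncoprint_matrix(
    top_genes: list[str],
    presence: PresenceMatrix,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Binary gene x sample matrix for OncoPrint-style display.

    Rows follow the given (rank) order; columns are grouped by compartment
    (in canonical order), then organ, then sample id.
    """
    missing = [g for g in top_genes if g not in presence.genes]
    if missing:
        raise ValueError(f"genes not in presence matrix: {missing[:3]}")
    order = sheet.frame.assign(
        _c=pd.Categorical(sheet.frame["compartment"], categories=COMPARTMENTS)
    ).sort_values(["_c", "organ", "sample_id"])
    cols = [s for s in order["sample_id"] if s in presence.sample_ids]
    return presence.frame.loc[top_genes, cols].astype(int)


@dataclass(frozen=True)
class HitReport:
    """Top-ranked genes annotated with organ ubiquity and pan-organ status."""

    table: pd.DataFrame = field(repr=False)  # gene, rank, frequency, total_reads,
    #                                          k, pan_organ[, in_catalog]
    k_observed: int
    unique_pan_organ: bool  # exactly one gene carries k == k_observed

    def to_dict(self) -> dict:
        return {
            "k_observed": self.k_observed,
            "unique_pan_organ": self.unique_pan_organ,
            "hits": self.table.to_dict(orient="records"),
        }


def call_hits(
    rank_table: pd.DataFrame,
    report: GeneSetReport,
    catalog: CandidateCatalog | None = None,
    hm: HomologMap | None = None,
) -> HitReport:
    """Annotate ranked genes with ubiquity k and the pan-organ flag.

    When a human candidate catalog is supplied, each gene is additionally
    flagged for catalog membership after homolog mapping. Also reports
    whether exactly one gene in the whole report is pan-organ.
    """
    table = rank_table.copy()
    table["k"] = [report.ubiquity.get(g, 0) for g in table["gene"]]
    table["pan_organ"] = [g in report.pan_organ for g in table["gene"]]
    if catalog is not None:
        flags = []
        for g in table["gene"]:
            mapped, _ = map_homologs([g], hm)
            flags.append(bool(mapped & catalog.candidates))
        table["in_catalog"] = flags
    return HitReport(
        table=table,
        k_observed=report.k_observed,
        unique_pan_organ=len(report.pan_organ) == 1,
    )
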