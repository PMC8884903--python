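"""Read-count thresholding and gene-set derivation.

The screen's enrichment filter is a hard cut: a guide is *enriched* in a
sample when its read count reaches tau (default 10 reads), and a gene is
*present* when at least ``min_sgrnas`` of its guides are enriched. All
downstream biology — per-compartment gene sets, the cross-compartment shared
set, per-organ ubiquity — is plain set algebra over these presence calls.
No depth normalisation or statistical enrichment model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import LibraryDesign, SampleSheet


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean gene x sample presence calls plus the thresholds that made them."""

    frame: pd.DataFrame = field(repr=False)  # bool, genes x samples
    tau: int
    min_sgrnas: int

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    def genes_in(self, sample_ids: list[str]) -> frozenset:
        """Union of genes present in at least one of the given samples."""
        if not sample_ids:
            return frozenset()
        mask = self.frame[sample_ids].any(axis=1)
        return frozenset(self.frame.index[mask])


@dataclass(frozen=True)
class GeneSetReport:
    """Compartment/organ gene sets derived from one presence matrix.

    ``shared_all`` intersects the post-implantation compartment sets (the
    preimplant pool is the reference the screen is read against, so it is
    excluded unless ``preimplant_in_shared`` was set). ``ubiquity`` maps each
    gene to k, the number of distinct metastatic organs where it is present;
    genes at k = ``k_observed`` form ``pan_organ``.
    """

    compartment_sets: dict[str, frozenset]
    all_samples_union: frozenset
    shared_all: frozenset
    organ_sets: dict[str, frozenset]
    ubiquity: dict[str, int]
    pan_organ: frozenset
    k_observed: int
    tau: int
    min_sgrnas: int
    preimplant_in_shared: bool = False

    def to_dict(self) -> dict:
        """JSON-ready form: sets as sorted symbol arrays."""
        return {
            "tau": self.tau,
            "min_sgrnas": self.min_sgrnas,
            "k_observed": self.k_observed,
            "preimplant_in_shared": self.preimplant_in_shared,
            "compartment_sets": {
                c: sorted(s) for c, s in self.compartment_sets.items()
            },
            "all_samples_union": sorted(self.all_samples_union),
            "shared_all": sorted(self.shared_all),
            "organ_sets": {o: sorted(s) for o, s in self.organ_sets.items()},
            "ubiquity": {g: int(k) for g, k in sorted(self.ubiquity.items())},
            "pan_organ": sorted(self.pan_organ),
        }


def call_presence(
    counts: pd.DataFrame,
    lib: LibraryDesign,
    tau: int = 10,
    min_sgrnas: int = 1,
) -> PresenceMatrix:
    """Threshold guide counts into gene-level presence calls.

    presence(g, s) is true iff at least ``min_sgrnas`` guides of gene g have
    count >= tau in sample s. Exact thresholding, nothing else.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if min_sgrnas < 1:
        raise ValueError("min_sgrnas must be >= 1")
    stray = counts.index.difference(lib.sgrna_ids)
    if len(stray):
        raise ValueError(f"count rows not in library: {list(stray[:3])}")
    gene_of = lib.gene_of().loc[counts.index]
    enriched = counts >= tau
    present = enriched.groupby(gene_of.to_numpy()).sum() >= min_sgrnas
    present.index.name = "gene"
    return PresenceMatrix(frame=present, tau=tau, min_sgrnas=min_sgrnas)


def compartment_sets(
    presence: PresenceMatrix,
    sheet: SampleSheet,
    preimplant_in_shared: bool = False,
) -> GeneSetReport:
    """Per-compartment gene unions and the cross-compartment shared set.

    A gene belongs to a compartment's set when present in at least one of
    that compartment's samples; ``shared_all`` is the intersection over the
    compartments present in the sheet (preimplant excluded by default).
    The organ fields are left empty; see :func:`organ_ubiquity` and
    :func:`gene_set_report`.
    """
    stray = presence.sample_ids.difference(sheet.sample_ids)
    if len(stray):
        raise ValueError(f"presence samples missing from sheet: {list(stray[:3])}")
    comps = sheet.compartments_present()
    sets = {
        c: presence.genes_in(
            [s for s in sheet.samples_in(c) if s in presence.sample_ids]
        )
        for c in comps
    }
    union = presence.genes_in(list(presence.sample_ids))
    shared_comps = [
        c for c in comps if preimplant_in_shared or c != "preimplant"
    ]
    if shared_comps:
        shared = frozenset.intersection(*(sets[c] for c in shared_comps))
    else:
        shared = frozenset()
    return GeneSetReport(
        compartment_sets=sets,
        all_samples_union=union,
        shared_all=shared,
        organ_sets={},
        ubiquity={},
        pan_organ=frozenset(),
        k_observed=0,
        tau=presence.tau,
        min_sgrnas=presence.min_sgrnas,
        preimplant_in_shared=preimplant_in_shared,
    )


def organ_ubiquity(presence: PresenceMatrix, sheet: SampleSheet) -> GeneSetReport:
    """Per-organ gene sets, per-gene organ count k, and the pan-organ set.

    Organ sets pool metastasis samples across mice; k(g) counts the distinct
    organs containing g; pan_organ holds genes seen in every observed organ
    (the k = K pattern of a ubiquitous metastasis suppressor).
    """
    organs = sheet.organs_present()
    if not organs:
        raise ValueError("sample sheet contains no metastasis samples")
    stray = presence.sample_ids.difference(sheet.sample_ids)
    if len(stray):
        raise ValueError(f"presence samples missing from sheet: {list(stray[:3])}")
    organ_sets = {
        o: presence.genes_in(
            [s for s in sheet.samples_in("metastasis", o) if s in presence.sample_ids]
        )
        for o in organs
    }
    k_observed = len(organs)
    ubiquity = {
        g: sum(g in organ_sets[o] for o in organs) for g in presence.genes
    }
    pan = frozenset(g for g, k in ubiquity.items() if k == k_observed)
    return GeneSetReport(
        compartment_sets={},
        all_samples_union=frozenset(),
        shared_all=frozenset(),
        organ_sets=organ_sets,
        ubiquity=ubiquity,
        pan_organ=pan,
        k_observed=k_observed,
        tau=presence.tau,
        min_sgrnas=presence.min_sgrnas,
    )


def gene_set_report(
    presence: PresenceMatrix,
    sheet: SampleSheet,
    preimplant_in_shared: bool = False,
) -> GeneSetReport:
    """Full report: compartment part merged with the organ part (if any mets)."""
    comp = compartment_sets(presence, sheet, preimplant_in_shared)
    if sheet.organs_present():
        org = organ_ubiquity(presence, sheet)
    else:
        org = None
    return GeneSetReport(
        compartment_sets=comp.compartment_sets,
        all_samples_union=comp.all_samples_union,
        shared_all=comp.shared_all,
        organ_sets=org.organ_sets if org else {},
        ubiquity=org.ubiquity if org else {},
        pan_organ=org.pan_organ if org else frozenset(),
        k_observed=org.k_observed if org else 0,
        tau=presence.tau,
        min_sgrnas=presence.min_sgrnas,
        preimplant_in_shared=preimplant_in_shared,
    )


def write_presence(presence: PresenceMatrix, path) -> None:
    """Presence matrix as 0/1 TSV (genes x samples)."""
    presence.frame.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_presence(path, tau: int = 10, min_sgrnas: int = 1) -> PresenceMatrix:
    """Read a 0/1 presence TSV; tau/min_sgrnas are provenance, not recomputed."""
    frame = pd.read_csv(path, sep="\t", index_col="gene").astype(bool)
    return PresenceMatrix(frame=frame, tau=tau, min_sgrnas=min_sgrnas)
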