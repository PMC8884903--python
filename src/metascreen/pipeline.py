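"""End-to-end pipeline: (simulate | load) -> filter -> intersect -> catalog -> rank -> hits.

Every run writes each intermediate artifact plus a manifest recording the
parameters, seed, and SHA-256 checksums of inputs and outputs, so an
identical config + seed provably reproduces identical files. A failing stage
aborts with the stage name and drops a STALE marker next to whatever partial
outputs exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import (
    CandidateCatalog,
    HomologMap,
    candidate_catalog,
    map_homologs,
    read_cohort,
    read_homolog_map,
)
from .enrichment import (
    GeneSetReport,
    call_presence,
    gene_set_report,
    write_presence,
)
from .io import read_counts, read_library, read_sample_sheet
from .prioritize import (
    DEFAULT_COMPARTMENTS,
    HitReport,
    call_hits,
    oncoprint_matrix,
    rank_by_frequency,
    top_n,
)
from .simulate import (
    CohortSimConfig,
    ScreenSimConfig,
    simulate_cohort,
    simulate_screen,
    write_cohort_sim,
    write_screen,
)

log = logging.getLogger("metascreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: inputs (files or simulator configs) and knobs."""

    outdir: str
    seed: int = 0
    # screen inputs: either the three file paths, or simulate_screen knobs
    library: str | None = None
    sample_sheet: str | None = None
    counts: str | None = None
    simulate_screen: dict | None = None
    # cohort inputs: either the three file paths, or simulate_cohort knobs
    expression: str | None = None
    groups: str | None = None
    survival: str | None = None
    simulate_cohort: dict | None = None
    homolog_map: str | None = None
    # analysis knobs
    tau: int = 10
    min_sgrnas: int = 1
    alpha: float = 0.05
    n_top: int = 50
    compartments: tuple[str, ...] = tuple(sorted(DEFAULT_COMPARTMENTS))
    preimplant_in_shared: bool = False

    def __post_init__(self) -> None:
        has_files = all(x is not None for x in (self.library, self.sample_sheet, self.counts))
        if not has_files and self.simulate_screen is None:
            raise ValueError(
                "config must provide library/sample_sheet/counts paths "
                "or a simulate_screen block"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "compartments" in data:
            data = {**data, "compartments": tuple(data["compartments"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    report: GeneSetReport
    hits: HitReport
    catalog: CandidateCatalog | None
    summary: dict
    manifest: dict
    outdir: Path = field(repr=False)


def _check_inputs(cfg: PipelineConfig) -> list[Path]:
    """Fail before any stage runs if a referenced input file is missing."""
    paths = [
        cfg.library, cfg.sample_sheet, cfg.counts,
        cfg.expression, cfg.groups, cfg.survival, cfg.homolog_map,
    ]
    existing: list[Path] = []
    for p in paths:
        if p is None:
            continue
        path = Path(p)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        existing.append(path)
    return existing


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages, write every artifact, and return the in-memory results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stale = outdir / "STALE"
    inputs = _check_inputs(cfg)
    outputs: dict[str, Path] = {}
    stage = "setup"
    t0 = time.monotonic()
    try:
        if cfg.simulate_screen is not None:
            stage = "simulate-screen"
            log.info("stage %s", stage)
            sim_cfg = ScreenSimConfig.from_dict(
                {**cfg.simulate_screen, "seed": cfg.seed}
            )
            lib, sheet, counts, truth = simulate_screen(sim_cfg)
            for name, p in write_screen(lib, sheet, counts, truth, outdir / "sim").items():
                outputs[f"sim/{p.name}"] = p
        else:
            stage = "load-screen"
            log.info("stage %s", stage)
            lib = read_library(cfg.library)
            sheet = read_sample_sheet(cfg.sample_sheet)
            counts = read_counts(cfg.counts, lib=lib, sheet=sheet)

        stage = "filter"
        log.info("stage %s", stage)
        presence = call_presence(counts, lib, tau=cfg.tau, min_sgrnas=cfg.min_sgrnas)
        write_presence(presence, outdir / "presence.tsv")
        outputs["presence.tsv"] = outdir / "presence.tsv"

        stage = "intersect"
        log.info("stage %s", stage)
        report = gene_set_report(presence, sheet, cfg.preimplant_in_shared)
        (outdir / "gene_sets.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        outputs["gene_sets.json"] = outdir / "gene_sets.json"

        catalog = None
        hm = HomologMap()
        if cfg.homolog_map is not None:
            hm = read_homolog_map(cfg.homolog_map)
        if cfg.simulate_cohort is not None:
            stage = "simulate-cohort"
            log.info("stage %s", stage)
            ccfg = CohortSimConfig.from_dict({**cfg.simulate_cohort, "seed": cfg.seed})
            cohort, ctruth = simulate_cohort(ccfg)
            for name, p in write_cohort_sim(cohort, ctruth, outdir / "sim").items():
                outputs[f"sim/{p.name}"] = p
        elif cfg.expression is not None:
            stage = "load-cohort"
            log.info("stage %s", stage)
            cohort = read_cohort(cfg.expression, cfg.groups, cfg.survival)
        else:
            cohort = None
        if cohort is not None:
            stage = "catalog"
            log.info("stage %s", stage)
            catalog = candidate_catalog(cohort, alpha=cfg.alpha)
            (outdir / "catalog.json").write_text(
                json.dumps(catalog.to_dict(), indent=2, sort_keys=True)
            )
            outputs["catalog.json"] = outdir / "catalog.json"

        stage = "rank"
        log.info("stage %s", stage)
        rank = rank_by_frequency(
            presence, counts, lib, sheet, compartments=frozenset(cfg.compartments)
        )
        rank.to_csv(outdir / "rank.tsv", sep="\t", index=False)
        outputs["rank.tsv"] = outdir / "rank.tsv"
        top = top_n(rank, cfg.n_top)
        onco = oncoprint_matrix(list(top["gene"]), presence, sheet)
        onco.to_csv(outdir / "oncoprint.tsv", sep="\t", index_label="gene")
        outputs["oncoprint.tsv"] = outdir / "oncoprint.tsv"

        stage = "hits"
        log.info("stage %s", stage)
        hits = call_hits(top, report, catalog=catalog, hm=hm)
        (outdir / "hits.json").write_text(
            json.dumps(hits.to_dict(), indent=2, sort_keys=True)
        )
        outputs["hits.json"] = outdir / "hits.json"

        stage = "report"
        log.info("stage %s", stage)
        summary = write_report(hits, catalog, report, hm=hm, path=outdir / "summary.json")
        outputs["summary.json"] = outdir / "summary.json"
        outputs["summary.txt"] = outdir / "summary.txt"

        stage = "manifest"
        manifest = {
            "tool": "metascreen",
            "version": __version__,
            "seed": cfg.seed,
            "parameters": {
                "tau": cfg.tau,
                "min_sgrnas": cfg.min_sgrnas,
                "alpha": cfg.alpha,
                "n_top": cfg.n_top,
                "compartments": sorted(cfg.compartments),
                "preimplant_in_shared": cfg.preimplant_in_shared,
            },
            "inputs": {str(p): sha256_of(p) for p in inputs},
            "outputs": {name: sha256_of(p) for name, p in sorted(outputs.items())},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        if stale.exists():
            stale.unlink()
        log.info("pipeline done in %.1fs", time.monotonic() - t0)
        return PipelineResult(
            report=report,
            hits=hits,
            catalog=catalog,
            summary=summary,
            manifest=manifest,
            outdir=outdir,
        )
    except PipelineError:
        raise
    except Exception as exc:
        stale.write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc


def write_report(
    hits: HitReport,
    catalog: CandidateCatalog | None,
    report: GeneSetReport,
    hm: HomologMap | None = None,
    path: str | Path | None = None,
) -> dict:
    """Human-readable ledger of set sizes at each stage of the analysis.

    Mirrors the screen's funnel: preimplant pool -> all-sample union ->
    metastasis set -> shared-across-compartments set, then the cohort funnel
    (low expression / poor survival / candidates) and the homolog
    intersections of screen sets with the candidate catalog.
    """
    comp_sizes = {c: len(s) for c, s in report.compartment_sets.items()}
    summary: dict = {
        "thresholds": {"tau": report.tau, "min_sgrnas": report.min_sgrnas},
        "compartment_set_sizes": comp_sizes,
        "all_samples_union": len(report.all_samples_union),
        "shared_all": len(report.shared_all),
        "organ_set_sizes": {o: len(s) for o, s in report.organ_sets.items()},
        "pan_organ": sorted(report.pan_organ),
        "unique_pan_organ": hits.unique_pan_organ,
        "top_genes": list(hits.table["gene"].head(10)),
    }
    if catalog is not None:
        summary["catalog_sizes"] = catalog.sizes
        met = report.compartment_sets.get("metastasis", frozenset())
        union_hits = sorted(
            map_homologs(report.all_samples_union, hm)[0] & catalog.candidates
        )
        met_hits = sorted(map_homologs(met, hm)[0] & catalog.candidates)
        summary["screen_union_x_catalog"] = {
            "size": len(union_hits),
            "genes": union_hits,
        }
        summary["metastasis_x_catalog"] = {"size": len(met_hits), "genes": met_hits}
    if path is not None:
        path = Path(path)
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        lines = ["metascreen summary", "=================="]
        lines.append(f"thresholds: tau={report.tau}, min_sgrnas={report.min_sgrnas}")
        for c, n in comp_sizes.items():
            lines.append(f"genes identified in {c}: {n}")
        lines.append(f"union across all samples: {summary['all_samples_union']}")
        lines.append(f"shared across compartments: {summary['shared_all']}")
        for o, n in summary["organ_set_sizes"].items():
            lines.append(f"genes in {o} metastases: {n}")
        lines.append(
            f"pan-organ genes (k={report.k_observed}): {len(report.pan_organ)}"
            f" {summary['pan_organ']}"
        )
        if catalog is not None:
            cs = catalog.sizes
            lines.append(
                "cohort catalog: "
                f"{cs['low_expr']} low-expression, {cs['poor_surv']} poor-survival, "
                f"{cs['candidates']} candidates"
            )
            lines.append(
                f"screen union x catalog: {summary['screen_union_x_catalog']['size']}"
            )
            lines.append(
                f"metastasis set x catalog: {summary['metastasis_x_catalog']['size']}"
            )
        lines.append(f"top ranked genes: {', '.join(summary['top_genes'])}")
        path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return summary
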