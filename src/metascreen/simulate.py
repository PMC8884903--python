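"""Stochastic generators for a pooled in vivo knockout screen and a patient cohort.

The screen generator emulates the dominant noise sources of an in vivo
pooled screen: a lognormally skewed founder library with random guide
dropout after transduction/selection, a multinomial implantation bottleneck
per mouse, neutral expansion of the primary tumor, a Poisson metastatic
seeding bottleneck per organ whose rate is multiplied by the planted
suppressor effect h >= 1, lognormal clonal expansion within each lesion, and
Dirichlet-multinomial (overdispersed) sequencing of every sample. Knockouts
of planted suppressor genes seed organs at elevated rates — pan-organ
suppressors in every organ, organ-specific ones in a single organ — which is
exactly the signal the enrichment/ubiquity pipeline is meant to recover.

The cohort generator plants genes that are both down-shifted in tumors and
hazard-increasing when lowly expressed, via a latent "suppressor-low" tumor
subtype: in that fraction of tumor subjects the planted genes are shifted
down by delta/subtype_frac (so the overall tumor shift averages -delta) and
the hazard is multiplied by HR for the low median-split arm of the mean of
the planted genes' expression. The subtype is what makes a *single* gene's
median split informative about survival, mirroring how real suppressor
programs are co-lost in aggressive tumors.

Every output file round-trips through the :mod:`metascreen.io` readers, and
a fixed seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortData
from .io import (
    ORGANS,
    LibraryDesign,
    SampleSheet,
    write_counts,
    write_library,
    write_sample_sheet,
)

_BASES = np.array(list("ACGT"))


def _config_from_dict(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Knobs of the pooled-screen generator.

    Defaults are the desk-scale study conditions: a 1000-gene, 6-guides-per-
    gene library, 8 mice, the 5 organs, 10 pan-organ plus 10 single-organ
    planted suppressors with a 100-fold seeding advantage over the 1e-6
    per-cell baseline seeding probability, and 1e6 reads per sample.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 6
    n_mice: int = 8
    organs: tuple[str, ...] = ORGANS
    cells_implanted: int = 100_000
    #: clone sizes at harvest: the implanted composition neutrally expanded
    #: to this many tumor cells; together with baseline_seed_prob it sets the
    #: metastatic bottleneck to O(10) seeded clones per organ.
    tumor_cells: float = 1e7
    moi: float = 0.1  # protocol echo (low-MOI transduction)
    selection_days: int = 7  # protocol echo (puromycin selection)
    sgrna_dropout_prob: float = 0.05
    baseline_seed_prob: float = 1e-6  # per tumor cell, per organ
    n_pan_planted: int = 10
    n_single_planted: int = 10
    effect_size: float = 100.0  # seeding-rate multiplier h for planted genes
    reads_per_sample: int = 1_000_000
    overdispersion: float = 1000.0  # total Dirichlet concentration
    founder_sigma: float = 1.0  # lognormal spread of library abundances
    clone_sigma: float = 1.0  # lognormal clonal-expansion spread in lesions
    blood_primary_frac: float = 0.9
    spacer_length: int = 20
    week: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise ValueError("config implies an empty library")
        if self.reads_per_sample < 1:
            raise ValueError("config implies zero reads per sample")
        if min(self.cells_implanted, self.tumor_cells, self.n_mice) < 1:
            raise ValueError("cells_implanted, tumor_cells, n_mice must be >= 1")
        for name in ("baseline_seed_prob", "moi", "sgrna_dropout_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.sgrna_dropout_prob < 1):
            raise ValueError("sgrna_dropout_prob must lie in [0, 1)")
        if self.effect_size < 1:
            raise ValueError("effect_size (h) must be >= 1")
        if self.n_pan_planted + self.n_single_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not self.organs:
            raise ValueError("at least one organ required")

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenSimConfig":
        if "organs" in data:
            data = {**data, "organs": tuple(data["organs"])}
        return _config_from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenSimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class SimTruth:
    """Planted suppressors with their organ profiles, plus the config echo."""

    planted_pan: tuple[str, ...]
    planted_single: dict[str, str]  # gene -> its single target organ
    effect_size: float
    config: dict

    @property
    def planted(self) -> frozenset:
        return frozenset(self.planted_pan) | frozenset(self.planted_single)

    def to_dict(self) -> dict:
        return {
            "planted_pan": list(self.planted_pan),
            "planted_single": dict(sorted(self.planted_single.items())),
            "effect_size": self.effect_size,
            "config": self.config,
        }


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    spacers: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in spacers:
                spacers.add(s)
                out.append(s)
    return out


def _dirichlet_multinomial(
    rng: np.random.Generator, reads: int, props: np.ndarray, concentration: float
) -> np.ndarray:
    """Overdispersed sequencing draw; zero-probability categories stay zero."""
    counts = np.zeros(len(props), dtype=np.int64)
    support = props > 0
    if not support.any():
        return counts
    alpha = concentration * props[support] / props[support].sum()
    w = rng.gamma(alpha)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):  # pathological underflow guard
        p = props[support] / props[support].sum()
    else:
        p = w / total
    counts[support] = rng.multinomial(reads, p)
    return counts


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[LibraryDesign, SampleSheet, pd.DataFrame, SimTruth]:
    """Run the full generative screen and return pipeline-ready objects.

    Emits one preimplant sample and, per mouse, one primary, one recurrent,
    one blood, and one metastasis sample per organ (all-zero when no clone
    seeded that organ). Column sums of samples with material equal
    ``reads_per_sample`` exactly.
    """
    master = np.random.SeedSequence(cfg.seed)
    s_lib, s_founder, s_mice, s_seq = master.spawn(4)
    rng_lib = np.random.default_rng(s_lib)

    # --- library and planted truth -------------------------------------
    genes = [f"Mg{i:04d}" for i in range(cfg.n_genes)]
    n_sg = cfg.n_genes * cfg.sgrnas_per_gene
    spacers = _random_spacers(rng_lib, n_sg, cfg.spacer_length)
    lib_frame = pd.DataFrame(
        {
            "sgrna_id": [
                f"{g}_sg{j}" for g in genes for j in range(cfg.sgrnas_per_gene)
            ],
            "spacer": spacers,
            "gene": np.repeat(genes, cfg.sgrnas_per_gene),
        }
    )
    lib = LibraryDesign(lib_frame)

    n_planted = cfg.n_pan_planted + cfg.n_single_planted
    planted = rng_lib.choice(cfg.n_genes, size=n_planted, replace=False)
    planted_pan = [genes[i] for i in planted[: cfg.n_pan_planted]]
    planted_single = {
        genes[i]: cfg.organs[j % len(cfg.organs)]
        for j, i in enumerate(planted[cfg.n_pan_planted :])
    }
    # per-sgRNA seeding multiplier h, one column per organ
    h = np.ones((n_sg, len(cfg.organs)))
    gene_index = {g: i for i, g in enumerate(genes)}
    sg_gene = np.repeat(np.arange(cfg.n_genes), cfg.sgrnas_per_gene)
    for g in planted_pan:
        h[sg_gene == gene_index[g], :] = cfg.effect_size
    for g, organ in planted_single.items():
        h[sg_gene == gene_index[g], cfg.organs.index(organ)] = cfg.effect_size

    # --- founder pool ----------------------------------------------------
    rng_f = np.random.default_rng(s_founder)
    founder = rng_f.lognormal(0.0, cfg.founder_sigma, size=n_sg)
    kept = rng_f.random(n_sg) >= cfg.sgrna_dropout_prob
    founder *= kept
    if founder.sum() <= 0:
        raise ValueError("every sgRNA was dropped; lower sgrna_dropout_prob")
    founder_props = founder / founder.sum()

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []

    def add_sample(sample_id, compartment, organ, subject, week, composition, rng_s):
        columns[sample_id] = _dirichlet_multinomial(
            rng_s, cfg.reads_per_sample, composition, cfg.overdispersion
        )
        sheet_rows.append(
            {
                "sample_id": sample_id,
                "compartment": compartment,
                "organ": organ,
                "subject_id": subject,
                "week": week,
            }
        )

    rng_seq = np.random.default_rng(s_seq)
    add_sample("preimplant", "preimplant", "", "library", 0, founder_props, rng_seq)

    mouse_seeds = s_mice.spawn(cfg.n_mice)
    for m in range(cfg.n_mice):
        rng_m = np.random.default_rng(mouse_seeds[m])
        mouse = f"m{m + 1:02d}"

        # implantation bottleneck, then neutral expansion
        implant = rng_m.multinomial(cfg.cells_implanted, founder_props)
        if implant.sum() == 0:
            raise ValueError("implantation bottleneck produced no cells")
        primary_props = implant / implant.sum()
        add_sample(
            f"{mouse}_primary", "primary", "", mouse, cfg.week, primary_props, rng_seq
        )

        # recurrent tumor: a second bottleneck of the primary
        recurrent = rng_m.multinomial(cfg.cells_implanted, primary_props)
        recurrent_props = recurrent / recurrent.sum()
        add_sample(
            f"{mouse}_recurrent",
            "recurrent",
            "",
            mouse,
            cfg.week,
            recurrent_props,
            rng_seq,
        )

        # dissemination: Poisson seeding per organ, lognormal clonal expansion
        cells_at_harvest = primary_props * cfg.tumor_cells
        pooled_lesions = np.zeros(n_sg)
        lesions: dict[str, np.ndarray] = {}
        for j, organ in enumerate(cfg.organs):
            lam = cells_at_harvest * cfg.baseline_seed_prob * h[:, j]
            seeded = rng_m.poisson(lam)
            weights = np.zeros(n_sg)
            for idx in np.nonzero(seeded)[0]:
                weights[idx] = rng_m.lognormal(
                    0.0, cfg.clone_sigma, size=seeded[idx]
                ).sum()
            lesions[organ] = weights
            pooled_lesions += weights

        # blood: mostly primary, plus circulating disseminating clones
        if pooled_lesions.sum() > 0:
            blood = (
                cfg.blood_primary_frac * primary_props
                + (1 - cfg.blood_primary_frac) * pooled_lesions / pooled_lesions.sum()
            )
        else:
            blood = primary_props
        add_sample(f"{mouse}_blood", "blood", "", mouse, cfg.week, blood, rng_seq)

        for organ in cfg.organs:
            w = lesions[organ]
            comp = w / w.sum() if w.sum() > 0 else w
            add_sample(
                f"{mouse}_met_{organ}",
                "metastasis",
                organ,
                mouse,
                cfg.week,
                comp,
                rng_seq,
            )

    counts = pd.DataFrame(columns, index=lib.sgrna_ids).astype(np.int64)
    counts.index.name = "sgrna_id"
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SimTruth(
        planted_pan=tuple(planted_pan),
        planted_single=planted_single,
        effect_size=cfg.effect_size,
        config=dataclasses.asdict(cfg) | {"organs": list(cfg.organs)},
    )
    return lib, sheet, counts, truth


def synthesize_fastq_reads(
    lib: LibraryDesign,
    counts_column: pd.Series,
    rng: np.random.Generator,
    offset: int = 0,
    read_length: int = 50,
) -> list[str]:
    """Reads carrying each guide's spacer at ``offset`` inside random flanks."""
    L = lib.spacer_length
    if offset + L > read_length:
        raise ValueError("offset + spacer length exceeds read length")
    spacer_of = lib.frame.set_index("sgrna_id")["spacer"]
    reads: list[str] = []
    for sgrna_id, n in counts_column.items():
        spacer = spacer_of[sgrna_id]
        for _ in range(int(n)):
            flanks = rng.integers(0, 4, size=read_length - L)
            left = "".join(_BASES[flanks[:offset]])
            right = "".join(_BASES[flanks[offset:]])
            reads.append(left + spacer + right)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_screen(
    lib: LibraryDesign,
    sheet: SampleSheet,
    counts: pd.DataFrame,
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write library.csv, samples.tsv, counts.tsv and truth.json to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": outdir / "library.csv",
        "samples": outdir / "samples.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.json",
    }
    write_library(lib, paths["library"])
    write_sample_sheet(sheet, paths["samples"])
    write_counts(counts, paths["counts"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# patient cohort


@dataclass(frozen=True)
class CohortSimConfig:
    """Knobs of the cohort generator.

    Defaults are the study conditions for catalog recovery: 500 genes with
    50 planted suppressors, 200 tumor and 100 normal subjects, a 1.5 SD mean
    tumor down-shift of planted genes, hazard ratio 3 for the low arm, and
    30% uniform censoring.
    """

    n_genes: int = 500
    n_planted: int = 50
    n_tumor: int = 200
    n_normal: int = 100
    delta: float = 1.5  # mean tumor down-shift of planted genes, SD units
    baseline_hazard: float = 0.1
    hazard_ratio: float = 3.0
    censoring: float = 0.3
    #: fraction of tumor subjects in the latent suppressor-low subtype that
    #: carries the expression shift and the elevated hazard
    subtype_frac: float = 0.5
    #: "mean": hazard from the median split of the planted genes' mean
    #: expression; "per_gene": each planted gene contributes its own
    #: multiplicative HR^z term
    hazard_mode: str = "mean"
    #: explicit gene symbols (e.g. human homologs of a screen library);
    #: default Hg#### names are generated when None
    gene_names: tuple[str, ...] | None = None
    #: explicit planted genes (subset of the gene universe); drawn at random
    #: when None
    planted_genes: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.hazard_ratio < 1:
            raise ValueError("hazard_ratio must be >= 1")
        if not (0 <= self.censoring < 1):
            raise ValueError("censoring must lie in [0, 1)")
        if not (0 < self.subtype_frac <= 1):
            raise ValueError("subtype_frac must lie in (0, 1]")
        if self.hazard_mode not in ("mean", "per_gene"):
            raise ValueError("hazard_mode must be 'mean' or 'per_gene'")
        if self.n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if min(self.n_tumor, self.n_normal) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.gene_names is not None:
            if len(set(self.gene_names)) != self.n_genes:
                raise ValueError("gene_names must be n_genes unique symbols")
        if self.planted_genes is not None:
            if self.gene_names is None:
                raise ValueError("planted_genes requires gene_names")
            if len(set(self.planted_genes)) != self.n_planted:
                raise ValueError("planted_genes must be n_planted unique symbols")
            if not set(self.planted_genes) <= set(self.gene_names):
                raise ValueError("planted_genes must be a subset of gene_names")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSimConfig":
        for key in ("gene_names", "planted_genes"):
            if data.get(key) is not None:
                data = {**data, key: tuple(data[key])}
        return _config_from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class CohortTruth:
    planted: tuple[str, ...]
    subtype: dict[str, int] = field(repr=False)  # tumor subject -> 0/1
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted": list(self.planted),
            "subtype": dict(sorted(self.subtype.items())),
            "config": self.config,
        }


def _calibrate_censoring_bound(times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring with E[censored] = target."""
    lo, hi = float(times.min()) * 1e-6, float(times.max()) * 1e6
    for _ in range(200):
        c = np.sqrt(lo * hi)
        frac = np.minimum(times / c, 1.0).mean()  # P(C < t | C ~ U(0,c))
        if frac > target:
            lo = c
        else:
            hi = c
    return c


def simulate_cohort(cfg: CohortSimConfig) -> tuple[CohortData, CohortTruth]:
    """Generate the expression + survival cohort with planted suppressors."""
    master = np.random.SeedSequence(cfg.seed)
    s_expr, s_surv = master.spawn(2)
    rng_e = np.random.default_rng(s_expr)

    if cfg.gene_names is not None:
        genes = list(cfg.gene_names)
    else:
        genes = [f"Hg{i:04d}" for i in range(cfg.n_genes)]
    tumors = [f"T{i:04d}" for i in range(cfg.n_tumor)]
    normals = [f"N{i:04d}" for i in range(cfg.n_normal)]
    if cfg.planted_genes is not None:
        index_of = {g: i for i, g in enumerate(genes)}
        planted_idx = np.array(sorted(index_of[g] for g in cfg.planted_genes))
    else:
        planted_idx = rng_e.choice(cfg.n_genes, size=cfg.n_planted, replace=False)
    planted = [genes[i] for i in sorted(planted_idx)]

    expr = rng_e.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_tumor + cfg.n_normal))
    subtype = (rng_e.random(cfg.n_tumor) < cfg.subtype_frac).astype(int)
    # shift concentrated in the subtype so the mean tumor shift equals -delta
    shift = cfg.delta / cfg.subtype_frac
    for i in planted_idx:
        expr[i, : cfg.n_tumor] -= shift * subtype

    expression = pd.DataFrame(expr, index=genes, columns=tumors + normals)
    expression.index.name = "gene"
    group = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
        index=tumors + normals,
        name="group",
    )

    rng_s = np.random.default_rng(s_surv)
    log_hr = np.log(cfg.hazard_ratio)
    if cfg.hazard_mode == "mean":
        mean_planted = expr[np.ix_(planted_idx, np.arange(cfg.n_tumor))].mean(axis=0)
        z = (mean_planted <= np.median(mean_planted)).astype(float)
        log_hazard = np.log(cfg.baseline_hazard) + z * log_hr
    else:  # per_gene: every planted gene contributes its own term
        sub = expr[np.ix_(planted_idx, np.arange(cfg.n_tumor))]
        zg = sub <= np.median(sub, axis=1, keepdims=True)
        log_hazard = np.log(cfg.baseline_hazard) + zg.sum(axis=0) * log_hr
    times = rng_s.exponential(1.0 / np.exp(log_hazard))
    if cfg.censoring > 0:
        bound = _calibrate_censoring_bound(times, cfg.censoring)
        censor = rng_s.uniform(0.0, bound, size=cfg.n_tumor)
        observed = np.minimum(times, censor)
        event = (times <= censor).astype(int)
    else:
        observed, event = times, np.ones(cfg.n_tumor, dtype=int)

    survival = pd.DataFrame(
        {"subject_id": tumors, "time": observed, "event": event}
    )
    cohort = CohortData(expression=expression, group=group, survival=survival)
    truth = CohortTruth(
        planted=tuple(planted),
        subtype={t: int(s) for t, s in zip(tumors, subtype)},
        config=dataclasses.asdict(cfg),
    )
    return cohort, truth


def write_cohort_sim(
    cohort: CohortData, truth: CohortTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write expression.tsv, groups.tsv, survival.tsv and cohort_truth.json."""
    from .cohort import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "cohort_truth.json",
    }
    write_cohort(cohort, paths["expression"], paths["groups"], paths["survival"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return paths
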