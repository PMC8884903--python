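# Methods

## Scope and data model

The pipeline analyses a pooled in vivo CRISPR knockout screen at the
resolution its library defines: a `LibraryDesign` maps each sgRNA (unique id,
fixed-length ACGT spacer, default L = 20 nt) to a gene symbol; a
`SampleSheet` assigns each sequenced sample to one of five compartments —
preimplant (the infected cell pool before implantation), primary tumor,
recurrent tumor, blood, metastasis — with an organ label (lung, liver,
spleen, brain, kidney) required exactly for metastasis samples; a
`CountMatrix` holds nonnegative integer reads per (sgRNA, sample). All three
round-trip losslessly through pinned TSV/CSV dialects so that byte-identity
is a meaningful determinism check.

## FASTQ quantification

Reads are assigned by the L-mer at a fixed, configurable offset (default 0).
A read counts toward exactly one guide: an exact spacer match, or — when
`max_mismatch = 1` — the unique guide at Hamming distance 1. Reads matching
zero or several guides at the best tier, and reads shorter than
`offset + L`, are tallied as unassigned, so assigned + unassigned always
equals the FASTQ record count. The fixed-offset policy is a deliberate
stand-in for whatever read structure a given protocol produces: it is
deterministic, tie-safe, and exactly matched by the simulator's synthetic
reads. Genome alignment, UMIs, paired-end merging and base-quality filtering
are out of scope.

## Enrichment filter and gene sets

Presence is a hard threshold: gene G is present in sample s when at least
`min_sgrnas` (m, default 1) of its guides have count ≥ τ (default 10 reads).
The filter is applied at guide level and reported at gene level; m is
exposed for stringency studies but the default mirrors the convention that a
gene is "identified" as soon as any of its guides is enriched. No depth
normalization, control-guide scaling, or count modelling (e.g.
negative-binomial screen tests) is applied — the screen's biology
(bottlenecks that zero out most guides) makes presence/absence the robust
signal, and raising τ or m is monotone by construction: it can only remove
calls and shrink every derived set.

Compartment sets are unions over the compartment's samples; the
shared-across-compartments set intersects the post-implantation compartments
only. The preimplant pool is the reference the screen is read against, so it
is excluded from the intersection by default (`preimplant_in_shared` flips
this). Organ sets pool metastasis samples across mice (per-mouse concordance
is not required); ubiquity k(G) counts distinct organs containing G, and
pan-organ means k equals the number of organs actually observed in the
sheet, not a hard-coded 5.

## Frequency ranking and hits

The ranking key is the number of qualifying samples (default compartments:
recurrent, blood, metastasis — the compartments a disseminating clone can
reach) in which a gene is present. "Appearance frequency" could also be read
as a read sum; both are computed, with sample count as the primary key and
the summed reads of threshold-passing guides as the tie-break, followed by
an alphabetical tie-break so the output is a reproducible total order.
`call_hits` annotates the top-N table with k, the pan-organ flag, and
(optionally) membership in the cohort catalog after homolog mapping, and
reports whether the pan-organ flag is unique — the pattern of a single
ubiquitous suppressor dominating every organ.

## Cohort statistics

- **Two-sample t**: pooled-variance Student form by default (`pooled=False`
  gives Welch with Satterthwaite df). Degenerate inputs are handled
  explicitly: both variances zero with equal means gives t = 0, p = 1.
- **Log-rank**: at each distinct event time the observed group-A events are
  compared with the hypergeometric expectation given the pooled risk set;
  the statistic (ΣO − ΣE)²/ΣV is referred to χ² with 1 df, with the standard
  tie correction and the n = 1 risk-set term contributing zero variance. The
  returned direction flag states which group carries the excess of observed
  events; it is what lets the catalog require that *low* expression be the
  harmful arm. The implementation is vectorized over event times
  (rank-ordered risk sets via sorted search) and is cross-checked in the
  test suite against an explicit event-table oracle and against lifelines.
- **Median split**: values strictly above the median are "high"; ties and
  the median itself go "low", so the low arm never loses members to
  rounding. An all-constant vector cannot be split and is an error.
- **2^−ΔΔCt**: plain arithmetic on four cycle thresholds; no error model.

The candidate catalog takes a gene when (i) tumor mean < normal mean with
two-tailed t p < α, and (ii) log-rank p < α with the excess of events in the
low median-split arm (tumor subjects only; healthy donors carry no survival
records). Candidates are the exact intersection of the two sets. Selection
uses raw p-values at α = 0.05 twice, deliberately uncorrected — the two
hurdles jointly control the false-positive rate near α²/4 under the null —
and Benjamini–Hochberg q-values are available as annotation only. Genes with
zero variance everywhere are skipped and listed rather than silently
dropped. Homolog mapping defaults to uppercasing mouse symbols; a
user-supplied two-column table overrides the rule per symbol, conflicting
rows are an error, and unmapped symbols are reported, never dropped.

## Screen simulator

The generator is a chain of the bottlenecks that dominate real in vivo
screens; each stage draws from its own seed spawned from the master seed so
stages can be regenerated independently, and a fixed seed reproduces every
output file byte for byte.

1. **Founder pool** — per-guide abundance ~ lognormal(0, σ), σ = 1, then
   Bernoulli guide dropout (default 5%) standing in for low-MOI transduction
   plus a week of selection (`moi` and `selection_days` are recorded as
   protocol echoes; the dropout probability is the explicit knob).
2. **Implantation bottleneck** — per mouse, multinomial draw of
   `cells_implanted` (default 1e5) cells over founder proportions.
3. **Primary and recurrent tumors** — the primary is a neutral expansion
   (implant proportions carried forward); the recurrent tumor is a second
   multinomial bottleneck of the primary.
4. **Dissemination** — for each mouse, organ and guide, seeded clones ~
   Poisson(cells_g · p0 · h(gene, organ)), where cells_g is the clone's size
   at harvest (implant proportion × `tumor_cells`, default 1e7),
   p0 = 1e-6 per cell per organ, and h ≥ 1 is the planted seeding advantage
   (default 100; h = 1 for all non-planted genes). Lesion composition is the
   seeded clones weighted by lognormal clonal-expansion factors (σ = 1).
   With the defaults the metastatic bottleneck admits O(10) clones per
   organ: planted genes seed each relevant organ at ≈ 1 clone per mouse
   while a non-planted gene's chance of appearing in all five organs is
   vanishingly small — the regime the ubiquity analysis is designed for.
5. **Blood** — 90% primary composition plus 10% pooled disseminating
   clones.
6. **Sequencing** — per sample, counts ~ Dirichlet-multinomial with total
   concentration 1000 over the sample's composition and `reads_per_sample`
   (default 1e6) reads, giving the overdispersion bulk RNA/amplicon
   sequencing shows. Column sums equal the configured depth exactly; a
   mouse×organ with zero seeded clones is still emitted as an all-zero
   column (no material, no reads), so downstream ubiquity sees k = 0 rather
   than a missing sample.

Ground truth (planted pan-organ genes, single-organ genes with their target
organ, and the full config echo) is written alongside the data.

Defaults are desk-scale study conditions: 1000 genes × 6 guides, 8 mice,
5 organs, 10 pan-organ + 10 single-organ planted suppressors. At this scale
a full simulate-and-analyse cycle takes well under a second, so recovery
statistics are computed over 20 replicate seeds.

## Cohort simulator

Expression is Normal(0, 1) per gene and subject on the log scale. Planted
suppressor genes are down-shifted in tumors through a latent "suppressor-low"
subtype: a fraction (default 1/2) of tumor subjects carries a shift of
−Δ/subtype_frac on every planted gene, so the mean tumor shift is −Δ
(default 1.5 SD). Survival times are Exponential(λ · HR^z), λ = 0.1,
HR = 3, with z = 1 for the low median-split arm of the planted genes' mean
expression; uniform censoring is calibrated by bisection to the configured
fraction (default 30%). A per-gene variant (each planted gene contributing
its own multiplicative HR^z term) is available behind `hazard_mode`.

The subtype construction is the package's key modelling choice: if every
tumor were shifted equally, a single gene's median split would be almost
uncorrelated with the hazard arm and no per-gene survival test could
recover the planted genes; co-loss of a suppressor program in an aggressive
subtype is also the biologically realistic way low expression and poor
outcome co-occur. With the subtype, an individual planted gene's split
agrees with the hazard arm ≈ 93% of the time and per-gene log-rank power is
essentially 1 at the default cohort size. The cohort's gene universe and
planted set can be pinned explicitly (`gene_names`, `planted_genes`) to link
the cohort to a screen's homologs, as `analysis/01_simulate_data.py` does.

## What the simulators do and do not emulate

They reproduce the *structure* of the study — skewed founder libraries,
sequential clonal bottlenecks, organ-specific seeding advantages,
overdispersed counts, expression down-shift coupled to survival — and
therefore validate the set algebra, the ranking, the statistics and the
recovery behaviour of the pipeline. They do not model tumor spatial
structure, immune dynamics, guide-specific cutting efficiency, off-target
effects, sequencing error in the spacer itself, batch effects, or real
homolog divergence (the uppercase rule is exact in simulation). Passing
recovery tests therefore shows the pipeline's logic is sound under realistic
noise, not that any particular biological screen will reach the same recall.

## Numerical and design choices

- Thresholds τ ≥ 1, m ≥ 1 are validated; τ = 10 is the screen's read-count
  cut and the default top-N is 50.
- Ranking ties are broken deterministically (reads, then symbol); permuting
  sample order cannot change the table.
- The log-rank variance term is skipped when the risk set has a single
  subject (its hypergeometric variance is zero).
- Censoring calibration bisects on the realized event times, so the
  *expected* censored fraction equals the target; the realized fraction
  varies binomially around it.
- Dirichlet-multinomial sampling draws per-category gamma variates on the
  support only; zero-probability categories stay exactly zero, and a
  pathological all-underflow draw falls back to the composition itself.
- Pipeline manifests contain parameters, seed and SHA-256 checksums of all
  inputs and outputs, and no timestamps or absolute output paths, so rerun
  manifests are byte-comparable.

## Known limitations

- The presence filter has no depth normalization: samples sequenced to very
  different depths should be compared only at matched depth (the simulator
  holds depth fixed per sample).
- The catalog's two raw p < 0.05 hurdles are a screening heuristic, not an
  error-controlled discovery procedure; the BH annotation is provided for
  readers who want one.
- Hamming-1 assignment is exact but quadratic in memory for very large
  libraries (one dictionary entry per 1-neighbor); at GeCKO scale
  (~130k × 60 variants) this is still comfortably in memory, but
  `max_mismatch=0` is the conservative default.
- The log-rank direction flag compares observed vs expected events; with
  heavy censoring imbalance between arms it should be read together with
  the Kaplan-Meier curves, which the package does not plot.
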