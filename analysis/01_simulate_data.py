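#!/usr/bin/env python
"""Generate the study's synthetic inputs: one pooled in vivo screen and one
expression+survival patient cohort, both at the default desk-scale
conditions, written under results/analysis/data/.

The screen plants 10 pan-organ and 10 single-organ metastasis suppressors
(100-fold seeding advantage) in a 1000-gene, 6-guides-per-gene library
screened through 8 mice and 5 organs; the cohort plants 50 suppressor genes
(mean tumor down-shift 1.5 SD, hazard ratio 3 for the low-expression arm)
among 500 genes in 200 tumor / 100 normal subjects.
"""

import json
from pathlib import Path

from metascreen.simulate import (
    CohortSimConfig,
    ScreenSimConfig,
    simulate_cohort,
    simulate_screen,
    write_cohort_sim,
    write_screen,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis" / "data"


def main() -> None:
    screen_cfg = ScreenSimConfig(seed=SEED)
    lib, sheet, counts, truth = simulate_screen(screen_cfg)
    paths = write_screen(lib, sheet, counts, truth, OUT / "screen")
    print(f"screen: {len(lib)} sgRNAs, {len(lib.genes)} genes, "
          f"{counts.shape[1]} samples -> {paths['counts'].parent}")
    print(f"  planted pan-organ: {', '.join(truth.planted_pan)}")
    print(f"  planted single-organ: "
          f"{', '.join(f'{g}({o})' for g, o in truth.planted_single.items())}")

    # the cohort's gene universe is the human homolog set of the screen
    # library (uppercase rule); the screen's planted suppressors are planted
    # in the cohort too, padded with extra cohort-only suppressors to 50
    human_genes = tuple(sorted(g.upper() for g in lib.genes))
    screen_planted_human = tuple(sorted(g.upper() for g in truth.planted))
    extras = tuple(
        g for g in human_genes if g not in screen_planted_human
    )[: 50 - len(screen_planted_human)]
    cohort_cfg = CohortSimConfig(
        n_genes=len(human_genes),
        n_planted=50,
        gene_names=human_genes,
        planted_genes=screen_planted_human + extras,
        seed=SEED,
    )
    cohort, ctruth = simulate_cohort(cohort_cfg)
    cpaths = write_cohort_sim(cohort, ctruth, OUT / "cohort")
    n_events = int(cohort.survival["event"].sum())
    print(f"cohort: {cohort.expression.shape[0]} genes, "
          f"{len(cohort.tumor_subjects)} tumor / {len(cohort.normal_subjects)} "
          f"normal subjects, {n_events} deaths -> {cpaths['expression'].parent}")

    (OUT / "seed.json").write_text(json.dumps({"seed": SEED}))


if __name__ == "__main__":
    main()
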