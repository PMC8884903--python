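"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-cell loops, exhaustive scans,
explicit event tables — and shares no code with the package, so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def brute_presence(counts: pd.DataFrame, gene_of: dict, tau: int, m: int) -> dict:
    """presence[(gene, sample)] by direct per-cell evaluation."""
    genes = sorted(set(gene_of.values()))
    out = {}
    for g in genes:
        guides = [sg for sg, gg in gene_of.items() if gg == g and sg in counts.index]
        for s in counts.columns:
            passing = sum(1 for sg in guides if counts.at[sg, s] >= tau)
            out[(g, s)] = passing >= m
    return out


def brute_compartment_sets(presence: dict, sample_comp: dict) -> dict:
    """compartment -> set of genes present in >=1 of its samples."""
    sets: dict = {}
    for (g, s), present in presence.items():
        if present:
            sets.setdefault(sample_comp[s], set()).add(g)
    return sets


def brute_organ_k(presence: dict, sample_organ: dict) -> dict:
    """gene -> number of distinct organs with the gene present."""
    per_gene_organs: dict = {}
    for (g, s), present in presence.items():
        organ = sample_organ.get(s)
        if present and organ:
            per_gene_organs.setdefault(g, set()).add(organ)
    genes = {g for (g, _s) in presence}
    return {g: len(per_gene_organs.get(g, set())) for g in genes}


def brute_assign(read: str, spacers: dict, offset: int, max_mismatch: int):
    """Assign one read by exhaustive scan over the whole library.

    Returns the sgRNA id, or None when zero or >=2 guides qualify at the
    best tier (exact first, then Hamming distance exactly 1).
    """
    lengths = {len(sp) for sp in spacers.values()}
    (L,) = lengths
    if len(read) < offset + L:
        return None
    kmer = read[offset : offset + L]
    exact = [sg for sg, sp in spacers.items() if sp == kmer]
    if len(exact) == 1:
        return exact[0]
    if len(exact) >= 2:
        return None
    if max_mismatch == 1:
        near = [
            sg
            for sg, sp in spacers.items()
            if sum(a != b for a, b in zip(sp, kmer)) == 1
        ]
        if len(near) == 1:
            return near[0]
    return None


def pooled_t_formula(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classic pooled-variance Student t, written out longhand."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def permutation_t_p(x, y, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for the pooled t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    px, py = perm[:, :n], perm[:, n:]

    def tstat(a, b):
        na, nb = a.shape[1], b.shape[1]
        sp2 = (
            (na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)
        ) / (na + nb - 2)
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))

    t0 = tstat(x[None, :], y[None, :])[0]
    return float(np.mean(np.abs(tstat(px, py)) >= abs(t0) - 1e-12))


def event_table_logrank(ta, ea, tb, eb) -> tuple[float, float, float, float]:
    """(O_A, E_A, V, statistic) from an explicit per-event-time table."""
    times = np.concatenate([np.asarray(ta, float), np.asarray(tb, float)])
    events = np.concatenate([np.asarray(ea, int), np.asarray(eb, int)])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        n, n_a = risk.sum(), (risk & in_a).sum()
        dying = (times == t) & (events == 1)
        d, d_a = dying.sum(), (dying & in_a).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (O - E) ** 2 / V if V > 0 else 0.0
    return float(O), float(E), float(V), float(stat)


def sort_based_median_split(values) -> list[str]:
    """Median split via explicit sorting: values above the middle are high."""
    values = list(map(float, values))
    s = sorted(values)
    n = len(s)
    med = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
    return ["high" if v > med else "low" for v in values]


def random_screen_instance(rng: np.random.Generator, n_genes=8, sg_per=3,
                           n_samples=6, max_count=25):
    """A small random count matrix + sheet for set-algebra oracle checks."""
    from metascreen.io import LibraryDesign, SampleSheet, ORGANS

    genes = [f"G{i}" for i in range(n_genes)]
    sgrnas = [f"G{i}_s{j}" for i in range(n_genes) for j in range(sg_per)]
    bases = np.array(list("ACGT"))
    spacers = set()
    while len(spacers) < len(sgrnas):
        spacers.add("".join(bases[rng.integers(0, 4, 12)]))
    lib = LibraryDesign(
        pd.DataFrame(
            {"sgrna_id": sgrnas, "spacer": sorted(spacers),
             "gene": np.repeat(genes, sg_per)}
        )
    )
    comps = ["preimplant", "primary", "recurrent", "blood", "metastasis"]
    rows = []
    for k in range(n_samples):
        comp = comps[int(rng.integers(0, 5))] if k >= 5 else comps[k]
        organ = ORGANS[int(rng.integers(0, 5))] if comp == "metastasis" else ""
        rows.append(
            {"sample_id": f"s{k}", "compartment": comp, "organ": organ,
             "subject_id": f"m{k % 3}", "week": 8}
        )
    sheet = SampleSheet(pd.DataFrame(rows))
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(len(sgrnas), n_samples)),
        index=pd.Index(sgrnas, name="sgrna_id"),
        columns=[f"s{k}" for k in range(n_samples)],
    )
    return lib, sheet, counts
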