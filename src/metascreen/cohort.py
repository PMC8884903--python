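"""Patient-cohort statistics and the candidate-suppressor catalog.

A candidate metastasis suppressor must clear two independent hurdles in the
human cohort: (i) significantly *lower* expression in tumors than in normal
tissue (two-tailed Student's t, raw p < alpha), and (ii) significantly
*worse* survival in the low-expression arm of a per-gene median split
(log-rank, raw p < alpha, with the excess of observed events in the low
arm). The catalog is the exact intersection of the two gene sets. No
multiple-testing correction is used for selection — the cut is raw p < 0.05
twice — though Benjamini-Hochberg q-values can be annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# primitives


def two_sample_t(
    x: np.ndarray, y: np.ndarray, pooled: bool = True
) -> tuple[float, float]:
    """Two-sample t test, two-tailed.

    ``pooled=True`` is the classic Student form (pooled variance, df =
    nx+ny-2); ``pooled=False`` is Welch's unequal-variance form with
    Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return sign * np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), float(p)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    #: which group carries the excess of observed over expected events:
    #: "A", "B", or "none" when O == E exactly.
    direction: str
    observed_a: float
    expected_a: float


def log_rank(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time, the observed number of group-A events is
    compared with its hypergeometric expectation given the pooled risk set;
    the statistic (sum O - sum E)^2 / sum V is referred to chi-square with
    1 df. Ties are handled by the standard hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if (ta <= 0).any() or (tb <= 0).any():
        raise ValueError("survival times must be positive")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])

    # per distinct event time t: risk-set sizes by rank order, event counts
    # by unique-with-counts; equivalent to the explicit event-table loop
    event_times, d = np.unique(times[events == 1], return_counts=True)
    n = len(times) - np.searchsorted(np.sort(times), event_times, side="left")
    n_a = len(ta) - np.searchsorted(np.sort(ta), event_times, side="left")
    ua, ca = np.unique(ta[ea == 1], return_counts=True)
    d_a = np.zeros(len(event_times))
    d_a[np.searchsorted(event_times, ua)] = ca

    o_a = float(d_a.sum())
    e_a = float((d * n_a / n).sum())
    frac = n_a / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d * frac * (1 - frac) * (n - d) / (n - 1)
    v = float(terms[n > 1].sum())
    if v == 0.0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (o_a - e_a) ** 2 / v
        p = float(stats.chi2.sf(statistic, df=1))
    if o_a > e_a:
        direction = "A"
    elif o_a < e_a:
        direction = "B"
    else:
        direction = "none"
    return LogRankResult(float(statistic), p, direction, float(o_a), float(e_a))


def median_split(values: np.ndarray) -> np.ndarray:
    """Label values above the median "high", the rest (ties included) "low"."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to split")
    if np.all(values == values[0]):
        raise ValueError("all values identical: no median split possible")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref) in the case condition minus the same
    difference in the control condition; the fold change is 2**(-ddCt).
    A ddCt of 2 therefore reports 25% relative expression.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH q-values (annotation only; never used for selection here)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# cohort containers


@dataclass(frozen=True)
class CohortData:
    """Expression (log scale, gene x subject), tumor/normal labels, survival."""

    expression: pd.DataFrame = field(repr=False)
    group: pd.Series = field(repr=False)  # subject -> "tumor" | "normal"
    survival: pd.DataFrame = field(repr=False)  # subject_id, time, event

    def __post_init__(self) -> None:
        bad = set(self.group.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        missing = self.expression.columns.difference(self.group.index)
        if len(missing):
            raise ValueError(f"subjects without group label: {list(missing[:3])}")
        tumors = set(self.group.index[self.group == "tumor"])
        normals = set(self.group.index[self.group == "normal"])
        if not tumors or not normals:
            raise ValueError("both tumor and normal groups must be non-empty")
        stray = set(self.survival["subject_id"]) - tumors
        if stray:
            raise ValueError(
                f"survival records for non-tumor subjects: {sorted(stray)[:3]}"
            )
        if (self.survival["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(self.survival["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @property
    def tumor_subjects(self) -> pd.Index:
        return self.group.index[self.group == "tumor"]

    @property
    def normal_subjects(self) -> pd.Index:
        return self.group.index[self.group == "normal"]


def read_cohort(
    expression_path: str | Path,
    groups_path: str | Path,
    survival_path: str | Path,
) -> CohortData:
    expr = pd.read_csv(expression_path, sep="\t", index_col="gene")
    groups = pd.read_csv(groups_path, sep="\t", index_col="subject_id")["group"]
    surv = pd.read_csv(survival_path, sep="\t")
    return CohortData(expression=expr, group=groups, survival=surv)


def write_cohort(
    cohort: CohortData,
    expression_path: str | Path,
    groups_path: str | Path,
    survival_path: str | Path,
) -> None:
    cohort.expression.to_csv(expression_path, sep="\t", index_label="gene")
    cohort.group.rename("group").to_csv(
        groups_path, sep="\t", index_label="subject_id"
    )
    cohort.survival.to_csv(survival_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate catalog


@dataclass(frozen=True)
class CandidateCatalog:
    """Low-expression genes, poor-survival genes, and their intersection."""

    low_expr: dict[str, float]  # gene -> t-test p (tumor mean < normal mean)
    poor_surv: dict[str, float]  # gene -> log-rank p (low arm worse)
    candidates: frozenset
    alpha: float
    skipped: tuple[str, ...]  # degenerate genes (no variance / no split)
    expr_p: pd.Series = field(repr=False, default=None)
    surv_p: pd.Series = field(repr=False, default=None)

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "low_expr": len(self.low_expr),
            "poor_surv": len(self.poor_surv),
            "candidates": len(self.candidates),
        }

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "sizes": self.sizes,
            "low_expr": {g: float(p) for g, p in sorted(self.low_expr.items())},
            "poor_surv": {g: float(p) for g, p in sorted(self.poor_surv.items())},
            "candidates": sorted(self.candidates),
            "skipped": list(self.skipped),
        }


def candidate_catalog(
    cohort: CohortData,
    alpha: float = 0.05,
    pooled_t: bool = True,
) -> CandidateCatalog:
    """Build the candidate-suppressor catalog from a cohort.

    Per gene: (i) *low expression* when the tumor mean is below the normal
    mean and the two-tailed t-test p < alpha; (ii) *poor survival* when the
    log-rank p across the tumor-side median split is < alpha and the low arm
    carries the excess of observed events. Candidates are the exact
    intersection. Genes with zero variance everywhere are skipped and listed.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    tumor = cohort.expression[cohort.tumor_subjects]
    normal = cohort.expression[cohort.normal_subjects]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 subjects per group")

    surv = cohort.survival.set_index("subject_id")
    surv_subjects = [s for s in cohort.tumor_subjects if s in surv.index]
    tumor_surv = tumor[surv_subjects]
    t_time = surv.loc[surv_subjects, "time"].to_numpy(float)
    t_event = surv.loc[surv_subjects, "event"].to_numpy(int)

    low_expr: dict[str, float] = {}
    poor_surv: dict[str, float] = {}
    skipped: list[str] = []
    expr_p = pd.Series(np.nan, index=cohort.expression.index, name="expr_p")
    surv_p = pd.Series(np.nan, index=cohort.expression.index, name="surv_p")

    # expression arm, vectorised across genes
    tv = tumor.to_numpy(float)
    nv = normal.to_numpy(float)
    degenerate = (tv.var(axis=1, ddof=1) == 0) & (nv.var(axis=1, ddof=1) == 0)
    tstat, tp = stats.ttest_ind(tv, nv, axis=1, equal_var=pooled_t)
    lower = tv.mean(axis=1) < nv.mean(axis=1)

    for i, gene in enumerate(cohort.expression.index):
        if degenerate[i]:
            skipped.append(gene)
            continue
        expr_p[gene] = tp[i]
        if lower[i] and tp[i] < alpha:
            low_expr[gene] = float(tp[i])
        vals = tumor_surv.iloc[i].to_numpy(float)
        if np.all(vals == vals[0]):
            # no split possible; survival arm undefined for this gene
            continue
        labels = median_split(vals)
        low = labels == "low"
        if t_event[low].sum() + t_event[~low].sum() == 0:
            continue
        res = log_rank(t_time[low], t_event[low], t_time[~low], t_event[~low])
        surv_p[gene] = res.p_value
        if res.p_value < alpha and res.direction == "A":
            poor_surv[gene] = res.p_value

    candidates = frozenset(low_expr) & frozenset(poor_surv)
    return CandidateCatalog(
        low_expr=low_expr,
        poor_surv=poor_surv,
        candidates=candidates,
        alpha=alpha,
        skipped=tuple(skipped),
        expr_p=expr_p,
        surv_p=surv_p,
    )


# ---------------------------------------------------------------------------
# homolog mapping and screen-vs-catalog intersection


@dataclass(frozen=True)
class HomologMap:
    """Mouse -> human symbol map; default rule uppercases (Atp11b -> ATP11B)."""

    table: Mapping[str, str] = field(default_factory=dict)
    use_default_rule: bool = True

    def lookup(self, mouse_symbol: str) -> str | None:
        if mouse_symbol in self.table:
            return self.table[mouse_symbol]
        if self.use_default_rule:
            return mouse_symbol.upper()
        return None


def read_homolog_map(path: str | Path, use_default_rule: bool = True) -> HomologMap:
    """Two-column TSV (mouse_symbol, human_symbol); conflicting rows are an error."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = ["mouse_symbol", "human_symbol"]
    table: dict[str, str] = {}
    for mouse, human in zip(frame["mouse_symbol"], frame["human_symbol"]):
        if mouse in table and table[mouse] != human:
            raise ValueError(
                f"conflicting homolog rows for {mouse!r}: "
                f"{table[mouse]!r} vs {human!r}"
            )
        table[mouse] = human
    return HomologMap(table=table, use_default_rule=use_default_rule)


def map_homologs(
    genes: Iterable[str], hm: HomologMap | None = None
) -> tuple[frozenset, list[str]]:
    """Map mouse symbols to human; unmapped symbols are reported, not dropped."""
    hm = hm or HomologMap()
    mapped, unmapped = set(), []
    for g in sorted(set(genes)):
        human = hm.lookup(g)
        if human is None:
            unmapped.append(g)
        else:
            mapped.add(human)
    return frozenset(mapped), unmapped


def screen_vs_catalog(
    screen_genes: Iterable[str],
    catalog: CandidateCatalog,
    hm: HomologMap | None = None,
) -> frozenset:
    """Human homologs of screen hits that are also catalog candidates."""
    mapped, _unmapped = map_homologs(screen_genes, hm)
    return mapped & catalog.candidates
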