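"""Median-split 2x2 condition assignment and covariate-balanced selection.

Image pairs are labelled low/high on contrast-energy change and low/high on
subjective-importance change by median split (ties to low), giving four
condition cells. A seeded randomized swap search selects a fixed-size set
with exactly equal cell counts whose balancing covariates show no group
difference (one-way ANOVA and Kruskal-Wallis, all p > alpha). Subsets for
presentation reuse pairs a fixed number of times but never repeat a source
image within a subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateReportError,
    DegenerateSplitError,
    InfeasibleDesignError,
    InfeasibleSubsetsError,
    InvalidParameterError,
)

CONDITIONS = ("lowCE-lowSI", "highCE-lowSI", "lowCE-highSI", "highCE-highSI")

BALANCE_COVARIATES = (
    "size_px",
    "eccentricity_deg",
    "mean_contrast",
    "max_contrast",
    "min_contrast",
    "luminance_change",
    "sf_change",
)

__all__ = [
    "CONDITIONS",
    "BALANCE_COVARIATES",
    "PairScore",
    "DesignAssignment",
    "BalanceReport",
    "median_split",
    "assign_conditions",
    "select_balanced_set",
    "build_subsets",
    "balance_report",
]


@dataclass
class PairScore:
    """Scores and covariates for one manipulation (one image pair)."""

    pair_id: str
    source_image_id: str
    ce_change: float
    si_change: float
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class BalanceReport:
    """Per-covariate ANOVA/Kruskal-Wallis group-difference statistics."""

    stats: dict[str, dict[str, float]]  # covariate -> {F, p_anova, H, p_kruskal}
    alpha: float
    df_between: int
    df_within: int

    @property
    def passed(self) -> bool:
        return all(
            s["p_anova"] > self.alpha and s["p_kruskal"] > self.alpha
            for s in self.stats.values()
        )

    @property
    def min_p(self) -> float:
        return min(
            min(s["p_anova"], s["p_kruskal"]) for s in self.stats.values()
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "passed": self.passed,
            "covariates": self.stats,
        }


@dataclass
class DesignAssignment:
    """Condition labels, selection flags and subset membership.

    ``subsets`` maps 1-based subset ids to lists of pair ids. A pair may
    appear in several subsets (subsets are presentation sets, not a
    partition), but a source image never repeats within one subset.
    """

    condition: dict[str, str]
    selected: list[str]
    source: dict[str, str]
    subsets: dict[int, list[str]] = field(default_factory=dict)
    balance: BalanceReport | None = None

    def cell_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for pid in self.selected:
            counts[self.condition[pid]] += 1
        return counts

    def subset_cell_counts(self, subset_id: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pid in self.subsets[subset_id]:
            counts[self.condition[pid]] = counts.get(self.condition[pid], 0) + 1
        return counts


def median_split(values) -> np.ndarray:
    """Label each value 'low' (<= 50th percentile) or 'high' (above).

    Ties at the median go to 'low'. All-identical input is a degenerate
    split and raises.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidParameterError("median split needs at least 2 values")
    if np.all(v == v[0]):
        raise DegenerateSplitError("all values identical; median split degenerate")
    med = np.percentile(v, 50)
    return np.where(v <= med, "low", "high")


def assign_conditions(scores: list[PairScore]) -> DesignAssignment:
    """Cross the CE and SI median splits into the four condition cells."""
    ce_labels = median_split([s.ce_change for s in scores])
    si_labels = median_split([s.si_change for s in scores])
    condition = {
        s.pair_id: f"{ce}CE-{si}SI"
        for s, ce, si in zip(scores, ce_labels, si_labels)
    }
    return DesignAssignment(
        condition=condition,
        selected=[s.pair_id for s in scores],
        source={s.pair_id: s.source_image_id for s in scores},
    )


def _group_values(assignment, scores_by_id, covariate):
    groups = []
    for cond in CONDITIONS:
        vals = [
            scores_by_id[pid].covariates[covariate]
            for pid in assignment.selected
            if assignment.condition[pid] == cond
        ]
        groups.append(np.asarray(vals, dtype=float))
    return groups


def balance_report(
    assignment: DesignAssignment,
    scores: list[PairScore],
    alpha: float = 0.05,
    covariates=BALANCE_COVARIATES,
) -> BalanceReport:
    """ANOVA F and Kruskal-Wallis H per covariate across the 4 cells."""
    scores_by_id = {s.pair_id: s for s in scores}
    counts = assignment.cell_counts()
    if any(counts[c] < 2 for c in CONDITIONS):
        raise DegenerateReportError(f"cells too small for a balance report: {counts}")
    n = sum(counts.values())
    out = {}
    for cov in covariates:
        groups = _group_values(assignment, scores_by_id, cov)
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            out[cov] = {"F": 0.0, "p_anova": 1.0, "H": 0.0, "p_kruskal": 1.0}
            continue
        f, p_f = stats.f_oneway(*groups)
        h, p_h = stats.kruskal(*groups)
        out[cov] = {
            "F": float(f),
            "p_anova": float(p_f),
            "H": float(h),
            "p_kruskal": float(p_h),
        }
    return BalanceReport(
        stats=out, alpha=alpha, df_between=len(CONDITIONS) - 1, df_within=n - len(CONDITIONS)
    )


def _attempt_report(selected_scores, alpha, covariates):
    """Assignment + report for a candidate selection; None if counts wrong."""
    assignment = assign_conditions(selected_scores)
    n_per_cell = len(selected_scores) // len(CONDITIONS)
    counts = assignment.cell_counts()
    if any(counts[c] != n_per_cell for c in CONDITIONS):
        return assignment, None
    report = balance_report(assignment, selected_scores, alpha, covariates)
    return assignment, report


def select_balanced_set(
    pool: list[PairScore],
    n_total: int = 108,
    n_per_cell: int | None = None,
    alpha: float = 0.05,
    ecc_min_deg: float = 1.6,
    seed: int = 0,
    max_iter: int = 10_000,
    covariates=BALANCE_COVARIATES,
) -> DesignAssignment:
    """Seeded randomized search for an equal-cell, covariate-balanced set.

    Pairs whose change-region centroid lies within ``ecc_min_deg`` of the
    image centre are dropped first. The condition labels of a candidate set
    are recomputed from its own median splits at every step, so the search
    swaps members until the selected set both splits into exactly
    ``n_per_cell`` pairs per cell and passes the balance report at ``alpha``.
    """
    if n_per_cell is None:
        n_per_cell = n_total // len(CONDITIONS)
    if n_per_cell * len(CONDITIONS) != n_total:
        raise InvalidParameterError("n_total must be divisible by 4")
    rng = np.random.default_rng(seed)

    eligible = [
        s for s in pool if s.covariates.get("eccentricity_deg", np.inf) >= ecc_min_deg
    ]
    if len(eligible) < n_total:
        raise InfeasibleDesignError(
            f"only {len(eligible)} pairs beyond {ecc_min_deg} deg; need {n_total}"
        )

    # Initial guess: equal draw from the four pool-median cells.
    pool_assign = assign_conditions(eligible)
    by_cell = {c: [] for c in CONDITIONS}
    for s in eligible:
        by_cell[pool_assign.condition[s.pair_id]].append(s)
    selected: list[PairScore] = []
    for cond in CONDITIONS:
        cell = by_cell[cond]
        take = min(n_per_cell, len(cell))
        idx = rng.choice(len(cell), size=take, replace=False)
        selected.extend(cell[i] for i in idx)
    chosen_ids = {s.pair_id for s in selected}
    deficit = n_total - len(selected)
    if deficit:
        rest = [s for s in eligible if s.pair_id not in chosen_ids]
        idx = rng.choice(len(rest), size=deficit, replace=False)
        selected.extend(rest[i] for i in idx)
        chosen_ids = {s.pair_id for s in selected}

    best_report = None
    for _ in range(max_iter):
        assignment, report = _attempt_report(selected, alpha, covariates)
        if report is not None:
            if best_report is None or report.min_p > best_report.min_p:
                best_report = report
            if report.passed:
                assignment.balance = report
                return assignment

        unselected = [s for s in eligible if s.pair_id not in chosen_ids]
        if not unselected:
            break
        if report is None:
            # Cell counts off: move a pair out of an over-full cell and pull
            # in an unselected pair predicted to land in an under-full cell.
            counts = assignment.cell_counts()
            over = [c for c in CONDITIONS if counts[c] > n_per_cell]
            under = [c for c in CONDITIONS if counts[c] < n_per_cell]
            ce_med = np.percentile([s.ce_change for s in selected], 50)
            si_med = np.percentile([s.si_change for s in selected], 50)

            def predicted(s):
                ce = "low" if s.ce_change <= ce_med else "high"
                si = "low" if s.si_change <= si_med else "high"
                return f"{ce}CE-{si}SI"

            target = under[rng.integers(len(under))]
            cand_in = [s for s in unselected if predicted(s) == target]
            drop_cond = over[rng.integers(len(over))]
            cand_out = [
                s for s in selected if assignment.condition[s.pair_id] == drop_cond
            ]
            if not cand_in:
                cand_in = unselected
        else:
            # Counts fine but balance failing: random within-cell swap,
            # accepted only if the worst balance p-value improves.
            cond = CONDITIONS[rng.integers(len(CONDITIONS))]
            cand_out = [
                s for s in selected if assignment.condition[s.pair_id] == cond
            ]
            ce_med = np.percentile([s.ce_change for s in selected], 50)
            si_med = np.percentile([s.si_change for s in selected], 50)

            def predicted(s, ce_med=ce_med, si_med=si_med):
                ce = "low" if s.ce_change <= ce_med else "high"
                si = "low" if s.si_change <= si_med else "high"
                return f"{ce}CE-{si}SI"

            cand_in = [s for s in unselected if predicted(s) == cond] or unselected

        s_out = cand_out[rng.integers(len(cand_out))]
        s_in = cand_in[rng.integers(len(cand_in))]
        trial = [s for s in selected if s.pair_id != s_out.pair_id] + [s_in]
        if report is None:
            selected = trial
        else:
            _, trial_report = _attempt_report(trial, alpha, covariates)
            if trial_report is not None and trial_report.min_p > report.min_p:
                selected = trial
        chosen_ids = {s.pair_id for s in selected}

    raise InfeasibleDesignError(
        f"no balanced selection found within {max_iter} iterations",
        best_report=best_report,
    )


def build_subsets(
    assignment: DesignAssignment,
    n_subsets: int = 6,
    per_subset: int = 36,
    seed: int = 0,
    max_restarts: int = 500,
) -> DesignAssignment:
    """Distribute selected pairs into presentation subsets.

    Each subset holds ``per_subset`` pairs with equal counts per condition,
    and no source image appears twice within a subset. Every selected pair
    is used exactly ``n_subsets * per_subset / n_selected`` times (which must
    be a positive integer), so subsets may overlap when that ratio exceeds 1
    — e.g. 108 pairs into 6 subsets of 36 uses each pair twice.
    """
    n_sel = len(assignment.selected)
    slots = n_subsets * per_subset
    if slots % n_sel != 0:
        raise InfeasibleSubsetsError(
            f"{slots} subset slots not divisible by {n_sel} selected pairs"
        )
    uses_per_pair = slots // n_sel
    if uses_per_pair > n_subsets:
        raise InfeasibleSubsetsError("pair reuse exceeds number of subsets")
    conds = sorted({assignment.condition[p] for p in assignment.selected})
    if per_subset % len(conds) != 0:
        raise InfeasibleSubsetsError(
            f"per_subset={per_subset} not divisible by {len(conds)} conditions"
        )
    quota = per_subset // len(conds)
    rng = np.random.default_rng(seed)

    # Sources with many pairs are the binding constraint; place them first.
    pairs = list(assignment.selected)
    source_mult = {
        src: sum(1 for p in pairs if assignment.source[p] == src)
        for src in {assignment.source[p] for p in pairs}
    }

    for _ in range(max_restarts):
        order = list(rng.permutation(pairs))
        order.sort(key=lambda p: -source_mult[assignment.source[p]])
        capacity = {
            sid: {c: quota for c in conds} for sid in range(1, n_subsets + 1)
        }
        used_sources = {sid: set() for sid in range(1, n_subsets + 1)}
        subsets = {sid: [] for sid in range(1, n_subsets + 1)}
        ok = True
        for pid in order:
            cond = assignment.condition[pid]
            src = assignment.source[pid]
            feasible = [
                sid
                for sid in capacity
                if capacity[sid][cond] > 0 and src not in used_sources[sid]
            ]
            if len(feasible) < uses_per_pair:
                ok = False
                break
            # Prefer subsets with most remaining room to avoid dead ends.
            weights = np.array([capacity[sid][cond] for sid in feasible], dtype=float)
            weights += rng.random(len(feasible))  # random tie-break
            chosen = [feasible[i] for i in np.argsort(-weights)[:uses_per_pair]]
            for sid in chosen:
                capacity[sid][cond] -= 1
                used_sources[sid].add(src)
                subsets[sid].append(pid)
        if ok:
            return DesignAssignment(
                condition=dict(assignment.condition),
                selected=list(assignment.selected),
                source=dict(assignment.source),
                subsets=subsets,
                balance=assignment.balance,
            )
    raise InfeasibleSubsetsError(
        f"no valid subset layout found within {max_restarts} restarts"
    )
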