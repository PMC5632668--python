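"""Race-model inequality test for the redundant (high/high) condition.

The race bound at time t is the sum of the empirical CDFs of the two
single-property conditions, P(RT1 < t) + P(RT2 < t) — an upper bound on the
redundant-condition CDF under any race of separate channels (the bound is
left uncapped; values above 1 are never the binding part of the test).
Observed redundant RTs are compared against the bound in the quantile
domain (RT at fixed probability) at the deciles 0.1 .. 0.9, with a
subject-level bootstrap for confidence intervals and one-sided p-values and
Bonferroni correction across the 9 quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MissingConditionError
from .rt_analysis import TrialTable

COND_SINGLE_CE = "highCE-lowSI"
COND_SINGLE_SI = "lowCE-highSI"
COND_REDUNDANT = "highCE-highSI"

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))

__all__ = [
    "EmpiricalCdf",
    "RaceTestResult",
    "empirical_cdf",
    "race_bound",
    "race_test",
    "violation_summary",
]


class EmpiricalCdf:
    """Right-continuous step CDF with linear-interpolation quantiles."""

    def __init__(self, rts):
        x = np.asarray(rts, dtype=float)
        if x.size == 0:
            raise InvalidParameterError("empty sample")
        self.sorted = np.sort(x)
        self.n = x.size

    def cdf(self, t):
        """F(t) = (# rts <= t) / n."""
        return np.searchsorted(self.sorted, np.asarray(t, dtype=float), side="right") / self.n

    def quantile(self, q):
        """Linear interpolation between order statistics (numpy default)."""
        return np.quantile(self.sorted, q)


def empirical_cdf(rts) -> EmpiricalCdf:
    return EmpiricalCdf(rts)


class RaceBound:
    """B(t) = F1(t) + F2(t), with quantile inversion on the pooled grid."""

    def __init__(self, cdf1: EmpiricalCdf, cdf2: EmpiricalCdf):
        self.cdf1 = cdf1
        self.cdf2 = cdf2
        self._grid = np.union1d(cdf1.sorted, cdf2.sorted)
        self._values = cdf1.cdf(self._grid) + cdf2.cdf(self._grid)

    def value(self, t):
        return self.cdf1.cdf(t) + self.cdf2.cdf(t)

    def quantile(self, q):
        """RT at which the bound reaches probability q (interpolated)."""
        return np.interp(q, self._values, self._grid)


def race_bound(cdf1: EmpiricalCdf, cdf2: EmpiricalCdf) -> RaceBound:
    return RaceBound(cdf1, cdf2)


@dataclass
class RaceTestResult:
    """Quantile-wise comparison of the redundant condition with the bound."""

    quantiles: np.ndarray
    observed_rt: np.ndarray      # redundant-condition RT at each quantile
    bound_rt: np.ndarray         # RT at which the race bound reaches q
    violation: np.ndarray        # bound_rt - observed_rt; > 0 means faster
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray         # one-sided, from the subject bootstrap
    significant: np.ndarray      # Bonferroni-corrected, positive only
    alpha: float
    corrected_alpha: float
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "corrected_alpha": self.corrected_alpha,
            "n_boot": self.n_boot,
            "quantiles": self.quantiles.tolist(),
            "observed_rt": self.observed_rt.tolist(),
            "bound_rt": self.bound_rt.tolist(),
            "violation": self.violation.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "p_values": self.p_values.tolist(),
            "significant": self.significant.tolist(),
            "max_significant_violation_s": violation_summary(self),
        }


def _condition_arrays(table: TrialTable):
    """Hit RTs per subject for the three race-test conditions."""
    hits = table.hits()
    subjects = np.sort(hits["subject_id"].unique())
    if subjects.size < 2:
        raise MissingConditionError("race test needs at least 2 subjects")
    per_subject = {}
    for cond in (COND_SINGLE_CE, COND_SINGLE_SI, COND_REDUNDANT):
        sub = hits[hits["condition"] == cond]
        if sub.empty:
            raise MissingConditionError(f"no hit trials in condition {cond}")
        grouped = {
            sid: grp["rt_s"].to_numpy(dtype=float)
            for sid, grp in sub.groupby("subject_id")
        }
        per_subject[cond] = [grouped.get(sid, np.empty(0)) for sid in subjects]
    return subjects, per_subject


def _violations(rt1, rt2, rt12, quantiles):
    bound = RaceBound(EmpiricalCdf(rt1), EmpiricalCdf(rt2))
    observed = np.quantile(np.sort(rt12), quantiles)
    bound_rt = bound.quantile(quantiles)
    return observed, bound_rt, bound_rt - observed


def race_test(
    table: TrialTable,
    quantiles=DEFAULT_QUANTILES,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> RaceTestResult:
    """Quantile-domain race-model inequality test with subject bootstrap.

    Per quantile q the observed redundant-condition RT is compared with the
    RT at which the race bound reaches q. Bootstrap replicates resample
    subjects with replacement, pool their hit trials per condition and
    recompute the violation; the one-sided p-value is the fraction of
    replicates with violation <= 0. Significance requires
    p < alpha / n_quantiles and a positive observed violation.
    """
    quantiles = np.asarray(quantiles, dtype=float)
    if quantiles.size == 0 or np.any((quantiles <= 0) | (quantiles >= 1)):
        raise InvalidParameterError("quantiles must lie strictly in (0, 1)")
    subjects, per_subject = _condition_arrays(table)
    n_subj = subjects.size

    pooled = {c: np.concatenate(a) for c, a in per_subject.items()}
    observed, bound_rt, viol = _violations(
        pooled[COND_SINGLE_CE], pooled[COND_SINGLE_SI], pooled[COND_REDUNDANT], quantiles
    )

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, quantiles.size))
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        samples = {}
        ok = True
        for cond in (COND_SINGLE_CE, COND_SINGLE_SI, COND_REDUNDANT):
            arrs = [per_subject[cond][i] for i in idx]
            s = np.concatenate(arrs) if arrs else np.empty(0)
            if s.size == 0:
                ok = False
                break
            samples[cond] = s
        if not ok:
            boot[b] = np.nan
            continue
        _, _, boot[b] = _violations(
            samples[COND_SINGLE_CE], samples[COND_SINGLE_SI],
            samples[COND_REDUNDANT], quantiles,
        )
    valid = boot[~np.isnan(boot).any(axis=1)]
    if valid.shape[0] == 0:
        raise MissingConditionError("all bootstrap replicates had an empty condition")
    ci_low = np.percentile(valid, 2.5, axis=0)
    ci_high = np.percentile(valid, 97.5, axis=0)
    p_values = (valid <= 0).mean(axis=0)
    corrected = alpha / quantiles.size
    significant = (p_values < corrected) & (viol > 0)
    return RaceTestResult(
        quantiles=quantiles,
        observed_rt=observed,
        bound_rt=bound_rt,
        violation=viol,
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=p_values,
        significant=significant,
        alpha=alpha,
        corrected_alpha=corrected,
        n_boot=int(valid.shape[0]),
    )


def violation_summary(result: RaceTestResult) -> float:
    """Maximum violation (s) over corrected-significant quantiles; 0 if none."""
    if not result.significant.any():
        return 0.0
    return float(result.violation[result.significant].max())
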