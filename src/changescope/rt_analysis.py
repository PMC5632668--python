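"""Trial classification, exclusion, and inverse-Gaussian RT modelling.

Reaction-time distributions in change-detection tasks are strongly
right-skewed, so the condition effects are estimated with a generalized
linear model using an inverse-Gaussian response family. Two regressor
codings are supported: ``split`` (binary low/high per condition axis) and
``ranked`` (within-experiment ranks of the underlying change scores).
Per-condition RT distributions can additionally be summarised by explicit
inverse-Gaussian (shifted-Wald) maximum-likelihood fits with a CDF R^2
quality measure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import (
    DimensionError,
    FitError,
    InvalidParameterError,
    MissingConditionError,
    NoDataError,
    UnbalancedDesignError,
)
from .image_metrics import ChangeRegion, ImageGeometry

logger = logging.getLogger(__name__)

MAX_TRIAL_S = 240.0
OUTCOMES = ("hit", "false_alarm", "miss")

TRIAL_COLUMNS = [
    "subject_id",
    "pair_id",
    "condition",
    "rt_s",
    "responded",
    "click_x",
    "click_y",
    "outcome",
    "ce_change",
    "si_change",
]

__all__ = [
    "MAX_TRIAL_S",
    "TrialTable",
    "GlmResult",
    "IgFit",
    "classify_trial",
    "exclusion_filter",
    "proportions_anova",
    "ks_nonnormality",
    "fit_rt_glm",
    "fit_ig_cdf",
    "fit_ig_by_condition",
]


@dataclass
class TrialTable:
    """Per-trial records backed by a pandas DataFrame.

    Required columns: subject_id, pair_id, condition, rt_s, responded,
    outcome. Optional: click_x, click_y, ce_change, si_change (the last two
    are needed for ranked-coding GLMs).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"subject_id", "pair_id", "condition", "rt_s", "responded", "outcome"}
        missing = required - set(self.data.columns)
        if missing:
            raise DimensionError(f"trial table missing columns: {sorted(missing)}")
        bad_rt = self.data["rt_s"] > MAX_TRIAL_S
        if bad_rt.any():
            raise InvalidParameterError(
                f"{int(bad_rt.sum())} trials exceed the {MAX_TRIAL_S:.0f} s maximum"
            )
        unresponded = ~self.data["responded"].astype(bool)
        if (self.data.loc[unresponded, "outcome"] != "miss").any():
            raise InvalidParameterError("non-responded trials must be misses")

    def __len__(self):
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def hits(self) -> pd.DataFrame:
        return self.data[self.data["outcome"] == "hit"]

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def classify_trial(
    responded: bool,
    click_px: tuple[float, float] | None,
    region: ChangeRegion,
    geom: ImageGeometry,
    radius_deg: float = 0.75,
) -> str:
    """Classify one trial as hit / false_alarm / miss.

    A response counts as a hit when the click falls within ``radius_deg``
    (converted to pixels) of any changed pixel; responses elsewhere are
    false alarms; no response is a miss. Clicks outside the image bounds are
    false alarms (with a warning).
    """
    if not responded:
        return "miss"
    if click_px is None:
        raise InvalidParameterError("responded trial without click coordinates")
    x, y = click_px
    if not (0 <= x < geom.width_px and 0 <= y < geom.height_px):
        logger.warning("click (%s, %s) outside image bounds; counting as false alarm", x, y)
        return "false_alarm"
    rows, cols = np.nonzero(region.mask)
    d_px = np.sqrt((cols - x) ** 2 + (rows - y) ** 2).min()
    return "hit" if d_px * geom.deg_per_px <= radius_deg else "false_alarm"


def exclusion_filter(table: TrialTable) -> tuple[TrialTable, dict]:
    """Retain hit trials only; summarise what was excluded.

    Idempotent: filtering an already-filtered table is the identity.
    """
    df = table.data
    kept = df[df["outcome"] == "hit"].copy()
    if kept.empty:
        raise NoDataError("no hit trials remain after exclusion")
    summary = {
        "n_input": int(len(df)),
        "n_retained": int(len(kept)),
        "n_excluded": int(len(df) - len(kept)),
        "by_outcome": df["outcome"].value_counts().to_dict(),
        "retained_by_condition": kept["condition"].value_counts().to_dict(),
    }
    return TrialTable(kept, dict(table.metadata)), summary


def proportions_anova(table: TrialTable, convention: str = "cells") -> dict:
    """One-way ANOVA on per-subject outcome proportions across conditions.

    For each subject x condition cell the proportions of false alarms and of
    misses are computed; each outcome is then tested for condition
    differences. ``convention="cells"`` treats the subject x condition
    proportions as independent observations — a one-way ANOVA across
    conditions with df = (k-1, n*k-k), i.e. (3, 236) for 60 subjects and 4
    conditions. ``convention="rm"`` is the classical repeated-measures
    ANOVA with df = (k-1, (k-1)(n-1)).
    """
    if convention not in ("cells", "rm"):
        raise InvalidParameterError(f"unknown convention {convention!r}")
    df = table.data
    if df["subject_id"].nunique() < 2:
        raise InvalidParameterError("need at least 2 subjects")
    conds = sorted(df["condition"].unique())
    counts = df.groupby(["subject_id", "condition"]).size().unstack(fill_value=0)
    if (counts[conds] == 0).any().any() or counts.shape[1] != len(conds):
        raise UnbalancedDesignError("some subject has no trials in some condition")

    out = {}
    for outcome in ("false_alarm", "miss"):
        flag = (df["outcome"] == outcome).astype(float)
        prop = (
            df.assign(flag=flag)
            .groupby(["subject_id", "condition"])["flag"]
            .mean()
            .unstack()
        )[conds]
        mat = prop.to_numpy()  # subjects x conditions
        n, k = mat.shape
        grand = mat.mean()
        ss_cond = n * ((mat.mean(axis=0) - grand) ** 2).sum()
        if convention == "cells":
            ss_within = ((mat - mat.mean(axis=0)) ** 2).sum()
            df1, df2 = k - 1, n * k - k
            ms_err = ss_within / df2 if df2 else np.nan
        else:
            ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
            ss_tot = ((mat - grand) ** 2).sum()
            ss_err = ss_tot - ss_cond - ss_subj
            df1, df2 = k - 1, (k - 1) * (n - 1)
            ms_err = ss_err / df2 if df2 else np.nan
        ms_cond = ss_cond / df1
        if ms_err == 0:
            f_stat, p = 0.0 if ms_cond == 0 else np.inf, 1.0 if ms_cond == 0 else 0.0
        else:
            f_stat = ms_cond / ms_err
            p = float(stats.f.sf(f_stat, df1, df2))
        out[outcome] = {"F": float(f_stat), "p": p, "df1": df1, "df2": df2}
    return out


def ks_nonnormality(rts) -> tuple[float, float]:
    """One-sample KS test of the pooled RTs against a plug-in normal."""
    x = np.asarray(rts, dtype=float)
    if x.size < 10:
        raise InvalidParameterError("need at least 10 RTs")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidParameterError("zero-variance RTs; KS test degenerate")
    d, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(d), float(p)


@dataclass
class GlmResult:
    """Inverse-Gaussian GLM fit summary."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    df_resid: int
    coding: str
    link: str
    family: str = "inverse_gaussian"
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "link": self.link,
            "coding": self.coding,
            "df_resid": self.df_resid,
            "converged": self.converged,
            "terms": {
                name: {
                    "coef": self.coefficients[name],
                    "se": self.std_errors[name],
                    "t": self.t_values[name],
                    "p": self.p_values[name],
                }
                for name in self.coefficients
            },
        }


_LINKS = {
    "log": sm.families.links.Log,
    "identity": sm.families.links.Identity,
    "canonical": sm.families.links.InverseSquared,
    "inverse_squared": sm.families.links.InverseSquared,
}


def fit_rt_glm(table: TrialTable, coding: str = "split", link: str = "log") -> GlmResult:
    """GLM of RT on CE level, SI level and their interaction.

    Response family is inverse Gaussian; the link is selectable (default
    ``log`` for numerical stability; ``canonical`` is 1/mu^2). ``split``
    coding uses 0/1 low/high indicators from the condition label; ``ranked``
    uses average ranks of the per-trial ce_change / si_change values scaled
    to (0, 1]. Trials are canonically sorted before fitting so that row
    order of the input never affects the result.
    """
    if coding not in ("split", "ranked"):
        raise InvalidParameterError(f"unknown coding {coding!r}")
    if link not in _LINKS:
        raise InvalidParameterError(f"unknown link {link!r}; options: {sorted(_LINKS)}")
    df = table.data.sort_values(
        ["condition", "rt_s", "subject_id", "pair_id"], kind="mergesort"
    ).reset_index(drop=True)
    if df.empty:
        raise NoDataError("empty trial table")
    rt = df["rt_s"].to_numpy(dtype=float)
    if np.any(rt <= 0):
        raise InvalidParameterError("RTs must be positive for an IG response")

    if coding == "split":
        ce = df["condition"].str.startswith("high").astype(float).to_numpy()
        si = df["condition"].str.endswith("highSI").astype(float).to_numpy()
    else:
        if "ce_change" not in df or "si_change" not in df:
            raise InvalidParameterError(
                "ranked coding requires ce_change and si_change columns"
            )
        n = len(df)
        ce = stats.rankdata(df["ce_change"].to_numpy(), method="average") / n
        si = stats.rankdata(df["si_change"].to_numpy(), method="average") / n
    if np.all(ce == ce[0]) or np.all(si == si[0]):
        raise InvalidParameterError("both factors must vary to fit the GLM")

    X = np.column_stack([np.ones_like(rt), ce, si, ce * si])
    names = ["intercept", "ce", "si", "ce_x_si"]
    family = sm.families.InverseGaussian(link=_LINKS[link]())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(rt, X, family=family).fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise FitError(f"GLM failed: {exc}") from exc
    if not res.converged:
        raise FitError("GLM did not converge", diagnostics={"iterations": res.fit_history})
    df_resid = int(len(rt) - X.shape[1])
    tvals = res.params / res.bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    return GlmResult(
        coefficients=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, res.bse))),
        t_values=dict(zip(names, map(float, tvals))),
        p_values=dict(zip(names, map(float, pvals))),
        df_resid=df_resid,
        coding=coding,
        link=link,
    )


@dataclass
class IgFit:
    """Inverse-Gaussian (optionally shifted) fit for one RT sample."""

    mean: float
    shape: float
    shift: float
    r_squared: float
    n: int

    def cdf(self, t):
        return stats.invgauss.cdf(
            np.asarray(t, dtype=float) - self.shift,
            self.mean / self.shape,
            scale=self.shape,
        )


def _ig_loglik(x, mu, lam):
    return np.sum(stats.invgauss.logpdf(x, mu / lam, scale=lam))


def fit_ig_cdf(rts, shifted: bool = False) -> IgFit:
    """Maximum-likelihood inverse-Gaussian fit with CDF-based R^2.

    Without shift the MLE is closed form (mu = sample mean,
    lambda = n / sum(1/x - 1/mu)). With ``shifted=True`` the onset shift is
    profiled numerically, bounded below the sample minimum. R^2 compares
    the fitted CDF against the empirical CDF (Hazen plotting positions) at
    the sorted sample.
    """
    x = np.sort(np.asarray(rts, dtype=float))
    n = x.size
    if n < 20:
        raise InvalidParameterError("need at least 20 RTs for a distribution fit")
    if x[0] <= 0:
        raise InvalidParameterError("RTs must be positive")
    if x[0] == x[-1]:
        raise FitError("constant RTs; inverse-Gaussian fit degenerate")

    def mle(shift):
        y = x - shift
        mu = y.mean()
        denom = np.sum(1.0 / y - 1.0 / mu)
        if denom <= 0:
            raise FitError("shape MLE undefined for this sample")
        lam = n / denom
        return mu, lam

    if not shifted:
        shift = 0.0
        mu, lam = mle(shift)
    else:
        hi = x[0] * (1 - 1e-6)

        def neg_profile(s):
            try:
                mu_s, lam_s = mle(s)
            except FitError:
                return np.inf
            return -_ig_loglik(x - s, mu_s, lam_s)

        res = optimize.minimize_scalar(neg_profile, bounds=(0.0, hi), method="bounded")
        if not res.success or not math.isfinite(res.fun):
            raise FitError("shifted IG fit did not converge")
        shift = float(res.x)
        mu, lam = mle(shift)

    emp = (np.arange(1, n + 1) - 0.5) / n
    fitted = stats.invgauss.cdf(x - shift, mu / lam, scale=lam)
    ss_res = float(np.sum((fitted - emp) ** 2))
    ss_tot = float(np.sum((emp - emp.mean()) ** 2))
    return IgFit(
        mean=float(mu), shape=float(lam), shift=shift,
        r_squared=1.0 - ss_res / ss_tot, n=int(n),
    )


def fit_ig_by_condition(table: TrialTable, shifted: bool = False) -> dict[str, IgFit]:
    """Per-condition inverse-Gaussian fits of the hit RTs."""
    fits = {}
    for cond, grp in table.hits().groupby("condition"):
        rts = grp["rt_s"].to_numpy()
        if rts.size < 20:
            raise MissingConditionError(f"condition {cond} has too few hits to fit")
        fits[cond] = fit_ig_cdf(rts, shifted=shifted)
    return fits
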