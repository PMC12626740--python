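"""Paired cohort statistics: t-tests, Bonferroni control, effect size, power.

Per-patient complication probabilities under several plans are compared
with two-sided paired t-tests; the two planned original-vs-replan
comparisons form the Bonferroni family (per-test alpha = family alpha / 2),
while the 3D-vs-IMRT contrast is reported outside that family.
All probabilities are stored as fractions internally and rendered as
percent only at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PLANS",
    "ENDPOINTS",
    "PairedTResult",
    "DeltaSummary",
    "CohortNTCP",
    "ComparisonTable",
    "paired_t",
    "bonferroni",
    "delta_summary",
    "paired_power",
    "standardized_effect",
    "compare_cohort",
]

PLANS = ("original", "replan_3d", "replan_imrt")
ENDPOINTS = ("xerostomia", "dry_eye")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_two_sided: float


@dataclass(frozen=True)
class DeltaSummary:
    mean_delta: float
    sd_delta: float


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test of x against y.

    t = mean(d) / (sd(d) / sqrt(n)) with d = x - y, df = n - 1, and sd the
    sample standard deviation (n - 1 denominator).  Zero-variance
    differences are an error, not a p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "differences have zero variance (all pairs shift identically); "
            "the paired t statistic is undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTResult(t=t, df=df, p_two_sided=p)


def bonferroni(alpha_family: float, k: int) -> float:
    """Per-comparison significance level controlling the familywise rate."""
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be at least 1")
    return alpha_family / k


def delta_summary(x, y) -> DeltaSummary:
    """Mean and sample SD of the per-pair differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs for a sample SD")
    d = x - y
    return DeltaSummary(mean_delta=float(d.mean()), sd_delta=float(d.std(ddof=1)))


def paired_power(n: int, effect_size: float, alpha: float) -> float:
    """Power of the two-sided paired t-test via the noncentral t distribution.

    df = n - 1, noncentrality = effect_size * sqrt(n); the rejection region
    is |T| > t_{1 - alpha/2, df}.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    nc = effect_size * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def standardized_effect(delta: float, sd: float) -> float:
    """Standardized effect size delta / sd (Cohen's d for paired designs)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return delta / sd


class CohortNTCP:
    """Per-patient, per-plan, per-endpoint complication probabilities.

    Backed by a long-format table with columns ``patient_id``, ``plan``,
    ``endpoint``, ``ntcp`` (fractions in [0, 1]).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"patient_id", "plan", "endpoint", "ntcp"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        table = table.loc[:, ["patient_id", "plan", "endpoint", "ntcp"]].copy()
        table["ntcp"] = table["ntcp"].astype(float)
        if ((table["ntcp"] < 0) | (table["ntcp"] > 1)).any():
            raise ValueError("ntcp values must lie in [0, 1] (fractions)")
        unknown = set(table["plan"]) - set(PLANS)
        if unknown:
            raise ValueError(f"unknown plan labels: {sorted(unknown)}")
        if table.duplicated(["patient_id", "plan", "endpoint"]).any():
            raise ValueError("duplicate (patient, plan, endpoint) rows")
        self.table = table

    @property
    def patient_ids(self) -> list:
        return sorted(self.table["patient_id"].unique())

    @property
    def endpoints(self) -> list:
        return sorted(self.table["endpoint"].unique())

    def pivot(self, endpoint: str) -> pd.DataFrame:
        """Patients x plans matrix for one endpoint; errors if incomplete."""
        sub = self.table[self.table["endpoint"] == endpoint]
        if sub.empty:
            raise ValueError(f"no rows for endpoint {endpoint!r}")
        wide = sub.pivot(index="patient_id", columns="plan", values="ntcp")
        missing = [p for p in PLANS if p not in wide.columns]
        if missing or wide.isna().any().any():
            raise ValueError(
                f"endpoint {endpoint!r} is not completely paired across plans "
                f"{PLANS} (missing: {missing or 'some patient rows'})"
            )
        return wide.loc[:, list(PLANS)].sort_index()


@dataclass(frozen=True)
class ComparisonTable:
    """Cohort summary: one row per endpoint x plan, plus the 3D-vs-IMRT contrast.

    ``summary`` columns: endpoint, plan, n, mean_pct, sd_pct, and for the
    re-plans delta_mean_pct, delta_sd_pct, t, p_two_sided, significant
    (at the Bonferroni-adjusted per-test alpha).  ``replan_contrast`` holds
    the IMRT-vs-3D comparison per endpoint, reported outside the family.
    """

    summary: pd.DataFrame
    replan_contrast: pd.DataFrame
    alpha_family: float
    alpha_per_test: float


def compare_cohort(c: CohortNTCP, alpha_family: float = 0.05) -> ComparisonTable:
    """Paired original-vs-replan comparisons per endpoint, Bonferroni-controlled.

    The family consists of the two original-vs-replan tests per endpoint;
    each is judged at ``alpha_family / 2``.  The 3D-vs-IMRT contrast is
    additionally reported but not part of the family.
    """
    alpha = bonferroni(alpha_family, 2)
    rows = []
    contrast_rows = []
    for endpoint in c.endpoints:
        wide = c.pivot(endpoint)
        n = len(wide)
        for plan in PLANS:
            vals = wide[plan].to_numpy()
            row = {
                "endpoint": endpoint,
                "plan": plan,
                "n": n,
                "mean_pct": 100.0 * vals.mean(),
                "sd_pct": 100.0 * vals.std(ddof=1),
                "delta_mean_pct": np.nan,
                "delta_sd_pct": np.nan,
                "t": np.nan,
                "p_two_sided": np.nan,
                "significant": pd.NA,
            }
            if plan != "original":
                ds = delta_summary(vals, wide["original"].to_numpy())
                row.update(
                    delta_mean_pct=100.0 * ds.mean_delta,
                    delta_sd_pct=100.0 * ds.sd_delta,
                )
                if ds.sd_delta == 0.0:
                    # degenerate pairing (e.g., re-plan identical to the
                    # original): no test statistic, never significant
                    row.update(significant=False)
                else:
                    tt = paired_t(vals, wide["original"].to_numpy())
                    row.update(
                        t=tt.t,
                        p_two_sided=tt.p_two_sided,
                        significant=bool(tt.p_two_sided < alpha),
                    )
            rows.append(row)

        imrt = wide["replan_imrt"].to_numpy()
        three_d = wide["replan_3d"].to_numpy()
        ds = delta_summary(imrt, three_d)
        contrast = {
            "endpoint": endpoint,
            "comparison": "replan_imrt_vs_replan_3d",
            "n": n,
            "delta_mean_pct": 100.0 * ds.mean_delta,
            "delta_sd_pct": 100.0 * ds.sd_delta,
            "t": np.nan,
            "p_two_sided": np.nan,
        }
        if ds.sd_delta > 0.0:
            tt = paired_t(imrt, three_d)
            contrast.update(t=tt.t, p_two_sided=tt.p_two_sided)
        contrast_rows.append(contrast)

    return ComparisonTable(
        summary=pd.DataFrame(rows),
        replan_contrast=pd.DataFrame(contrast_rows),
        alpha_family=alpha_family,
        alpha_per_test=alpha,
    )
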