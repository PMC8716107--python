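"""Two-group comparisons and distribution fits.

Every comparison reports mean ± SEM per group and a two-tailed Mann-Whitney U
test; U is reported as min(U_x, U_y) and the two-tailed p doubles the smaller
one-tail mass (capped at 1).  The exact null distribution of U is used when
both samples are small and tie-free; otherwise the normal approximation with
tie and continuity corrections applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AxonRecord, PARTNER_CLASSES, ValidationError, VTYPES

EXACT_MAX_N = 8  # exact U distribution when min(n_x, n_y) <= this and no ties


@dataclass
class GroupComparison:
    metric: str
    group_names: tuple[str, str]
    x: np.ndarray
    y: np.ndarray
    mean_x: float
    sem_x: float
    mean_y: float
    sem_y: float
    U: float
    p_two_tailed: float
    method: str  # 'exact' or 'normal_approx'

    @property
    def n(self) -> tuple[int, int]:
        return (len(self.x), len(self.y))

    def summary(self) -> dict:
        return {
            "metric": self.metric,
            "group_x": self.group_names[0],
            "group_y": self.group_names[1],
            "n_x": len(self.x),
            "n_y": len(self.y),
            "mean_x": self.mean_x,
            "sem_x": self.sem_x,
            "mean_y": self.mean_y,
            "sem_y": self.sem_y,
            "U": self.U,
            "p_two_tailed": self.p_two_tailed,
            "method": self.method,
        }


def mean_sem(values) -> tuple[float, float, int]:
    """Sample mean, SEM (sd with n-1 denominator / sqrt(n)) and n.

    SEM is NaN (flagged undefined) for n < 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else float("nan")
    return mean, sem, int(v.size)


def mann_whitney_two_tailed(x, y) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U test; returns (min(U_x, U_y), p, method).

    Exact enumeration of the U null distribution when min(n_x, n_y) <= 8 and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = (min(x.size, y.size) <= EXACT_MAX_N) and not has_ties
    method = "exact" if use_exact else "normal_approx"
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    return u_min, float(res.pvalue), method


def compare_groups(metric: str, x, y, group_names=("saline", "cocaine")) -> GroupComparison:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_x, sem_x, _ = mean_sem(x)
    mean_y, sem_y, _ = mean_sem(y)
    u, p, method = mann_whitney_two_tailed(x, y)
    return GroupComparison(
        metric=metric, group_names=tuple(group_names), x=x, y=y,
        mean_x=mean_x, sem_x=sem_x, mean_y=mean_y, sem_y=sem_y,
        U=u, p_two_tailed=p, method=method,
    )


@dataclass
class LogNormalFit:
    """Maximum-likelihood log-normal fit (mu, sigma on the log scale)."""

    mu: float
    sigma: float
    n: int
    log_likelihood: float
    qq: np.ndarray  # (n, 2) array of (fitted quantile, sorted datum)

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2))


def fit_lognormal(values) -> LogNormalFit:
    """MLE log-normal fit: mu = mean of logs, sigma = population sd of logs."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValidationError("log-normal fit requires strictly positive values")
    if v.size < 2:
        raise ValidationError("log-normal fit requires n >= 2")
    logs = np.log(v)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    loglik = float(np.sum(stats.lognorm.logpdf(v, s=sigma, scale=np.exp(mu)))) \
        if sigma > 0 else float("inf")
    order = np.sort(v)
    probs = (np.arange(1, v.size + 1) - 0.5) / v.size
    fitted_q = np.exp(mu + sigma * stats.norm.ppf(probs))
    return LogNormalFit(
        mu=mu, sigma=sigma, n=int(v.size), log_likelihood=loglik,
        qq=np.column_stack([fitted_q, order]),
    )


def proportion_table(labels) -> pd.DataFrame:
    """Counts and fractions of contact-point partner classes."""
    labels = list(labels)
    if not labels:
        raise ValidationError("no labels to tabulate")
    for lab in labels:
        if lab not in PARTNER_CLASSES:
            raise ValidationError(f"unknown partner class {lab!r}")
    rows = []
    for cls in PARTNER_CLASSES:
        count = labels.count(cls)
        rows.append({"partner_class": cls, "count": count, "fraction": count / len(labels)})
    return pd.DataFrame(rows)


def mito_cooccurrence(varicosities) -> pd.DataFrame:
    """Fraction of varicosities with a mitochondrion within ~1 µm, per type.

    Strata with no classified varicosities report NaN (undefined flag).
    Includes an 'all' row over every classified varicosity.
    """
    by_type: dict[str, list[bool]] = {t: [] for t in VTYPES}
    for v in varicosities:
        if v.vtype in by_type:
            by_type[v.vtype].append(bool(v.mito_within_1um))
    rows = []
    pooled: list[bool] = []
    for t in VTYPES:
        flags = by_type[t]
        pooled.extend(flags)
        rows.append(
            {
                "vtype": t,
                "n": len(flags),
                "fraction_with_mito": float(np.mean(flags)) if flags else float("nan"),
            }
        )
    rows.append(
        {
            "vtype": "all",
            "n": len(pooled),
            "fraction_with_mito": float(np.mean(pooled)) if pooled else float("nan"),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study-level metric extraction
# ---------------------------------------------------------------------------

def metric_values(axons: list[AxonRecord], metric: str) -> np.ndarray:
    """Per-axon or per-structure values for a named study metric.

    Per-axon metrics: branch/contact/swelling/mito densities (/µm of cable).
    Per-structure: 'mito_length_um' (one value per mitochondrion) and
    'mito_length_per_dendrite_diameter' for dendrite compartments (mito length
    in nm over dendrite diameter in nm).
    """
    from . import morphometry  # local import to avoid a cycle at import time

    if metric in (
        "branch_density_per_um",
        "contact_density_per_um",
        "swelling_density_per_um",
        "mito_density_per_um",
    ):
        return np.array([morphometry.measure_axon(a)[metric] for a in axons])
    if metric == "mito_length_um":
        return np.array(
            [
                morphometry.mito_length(a.skeleton, chain)
                for a in axons
                for chain in a.mito_segments
            ]
        )
    raise ValidationError(f"unknown metric {metric!r}")
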