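"""Null model for varicosity-type organization along axons.

Under the null, each axon's varicosity types are drawn iid from the pooled
population frequencies f, holding the per-axon varicosity counts fixed at the
observed ones.  The test statistic per (type T, threshold k) is the dataset
exceedance count C(T, k): how many axons carry more than k type-T
varicosities.  Two routes to the null distribution of C are provided:

* Monte Carlo — M simulated datasets (default 100,000), p = Pr(C_sim >= C_obs);
* exact — per axon a, q_a = P(Binomial(n_a, f_T) > k); C is then
  Poisson-binomial(q_1..q_A), whose mass function is computed by dynamic
  programming.  The exact route is the analytic oracle for the simulation and
  never relies on stochastic agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError, VTYPES
from .varicosity import ExceedanceTable, TypeFrequencies


def _as_freq_vector(f) -> np.ndarray:
    if isinstance(f, TypeFrequencies):
        f = f.f
    f = np.asarray(f, dtype=float)
    if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError(f"invalid type frequency vector {f}")
    return f


@dataclass
class NullConfig:
    """Settings of the Monte Carlo null (trial count, frequencies, tail)."""

    trials: int = 100_000
    f: np.ndarray | TypeFrequencies | None = None  # None: estimate from data
    min_varicosities: int = 3
    tail: str = "geq"  # 'geq': Pr(C_sim >= C_obs); 'gt': Pr(C_sim > C_obs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValidationError("trial count must be >= 1")
        if self.tail not in ("geq", "gt"):
            raise ValidationError(f"unknown tail convention {self.tail!r}")


# ---------------------------------------------------------------------------
# Monte Carlo route
# ---------------------------------------------------------------------------

def simulate_null_counts(
    axon_sizes: list[int] | np.ndarray,
    f,
    k_max: int,
    trials: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-trial exceedance counts under the iid null.

    For each trial, every axon a receives ``n_a`` iid type draws from ``f``
    (equivalently a Multinomial(n_a, f) count vector) and C(T, k) is tallied
    exactly as for the observed data.  Returns an int32 array of shape
    ``(trials, 4, k_max)``; reproducible from ``seed``.
    """
    sizes = np.asarray(axon_sizes, dtype=int)
    if sizes.size == 0:
        raise ValidationError("no axons to simulate")
    if (sizes < 1).any():
        raise ValidationError("axon varicosity counts must be >= 1")
    fv = _as_freq_vector(f)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    out = np.zeros((trials, 4, k_max), dtype=np.int32)
    # group identical sizes so each multinomial call covers several axons
    for size, reps in zip(*np.unique(sizes, return_counts=True)):
        for _ in range(reps):
            counts = rng.multinomial(int(size), fv, size=trials)  # (trials, 4)
            out += counts[:, :, None] > ks[None, None, :]
    return out


# ---------------------------------------------------------------------------
# Exact route (Poisson-binomial dynamic programming)
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(q: np.ndarray) -> np.ndarray:
    """Mass function of a sum of independent Bernoulli(q_a) variables.

    Standard DP: fold each axon's success probability into the running pmf.
    Returns an array of length ``len(q) + 1``.
    """
    q = np.asarray(q, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValidationError("Bernoulli probabilities must lie in [0, 1]")
    pmf = np.zeros(len(q) + 1)
    pmf[0] = 1.0
    for j, qa in enumerate(q):
        pmf[1 : j + 2] = pmf[1 : j + 2] * (1 - qa) + pmf[: j + 1] * qa
        pmf[0] *= 1 - qa
    return pmf


@dataclass
class ExactNull:
    """Exact null distribution of C(T, k) for one (type, threshold) cell."""

    q: np.ndarray    # per-axon exceedance probabilities
    pmf: np.ndarray  # Poisson-binomial mass function of C

    @property
    def mean(self) -> float:
        return float(self.q.sum())

    def tail_geq(self, c: int) -> float:
        """P(C >= c)."""
        if c <= 0:
            return 1.0
        return float(np.clip(self.pmf[min(c, len(self.pmf)) :].sum(), 0.0, 1.0))

    def tail_gt(self, c: int) -> float:
        return self.tail_geq(c + 1)

    def tail(self, c: int, convention: str = "geq") -> float:
        return self.tail_geq(c) if convention == "geq" else self.tail_gt(c)


def exact_null(axon_sizes: list[int] | np.ndarray, f, type_index: int, k: int) -> ExactNull:
    """Exact distribution of C(T, k) under the iid null.

    ``type_index`` selects T in 0..3 (types I..IV); ``k`` is the strict
    exceedance threshold (count_T > k).
    """
    if k < 0:
        raise ValidationError("threshold k must be >= 0")
    sizes = np.asarray(axon_sizes, dtype=int)
    if sizes.size == 0:
        raise ValidationError("no axons in exact null")
    fv = _as_freq_vector(f)
    f_t = fv[type_index]
    q = stats.binom.sf(k, sizes, f_t)  # P(count > k) per axon
    return ExactNull(q=q, pmf=poisson_binomial_pmf(q))


# ---------------------------------------------------------------------------
# p-value table
# ---------------------------------------------------------------------------

@dataclass
class NullModelResult:
    """Per-(type, k) observed counts, null summaries and p-values."""

    table: pd.DataFrame
    trials: int
    seed: int
    tail: str
    f: np.ndarray
    axon_sizes: list[int]
    null_histograms: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def p_mc(self, vtype: str, k: int) -> float:
        row = self.table[(self.table.vtype == vtype) & (self.table.k == k)]
        return float(row.p_mc.iloc[0])

    def p_exact(self, vtype: str, k: int) -> float:
        row = self.table[(self.table.vtype == vtype) & (self.table.k == k)]
        return float(row.p_exact.iloc[0])


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pvalue_table(
    observed: ExceedanceTable,
    config: NullConfig,
    f=None,
) -> NullModelResult:
    """Monte Carlo and exact p-values for every (type, k) cell of ``observed``.

    ``f`` defaults to ``config.f``; one of the two must be given (the caller
    usually supplies the pooled frequencies of the full dataset).  The Monte
    Carlo p is ``#{trials with C_sim tail-comparing C_obs} / trials``; a raw 0
    is kept in the machine output and rendered ``< 1/M`` in the display column.
    """
    fv = _as_freq_vector(f if f is not None else config.f)
    sizes = np.asarray(observed.axon_sizes, dtype=int)
    if (observed.counts > len(sizes)).any():
        raise ValidationError("observed exceedance count exceeds number of axons")
    sims = simulate_null_counts(
        sizes, fv, observed.k_max, trials=config.trials, seed=config.seed
    )
    rows = []
    hists: dict[tuple[str, int], np.ndarray] = {}
    for t in range(4):
        for k in range(1, observed.k_max + 1):
            c_obs = int(observed.counts[t, k - 1])
            null_sample = sims[:, t, k - 1]
            if config.tail == "geq":
                p_mc = float(np.mean(null_sample >= c_obs))
            else:
                p_mc = float(np.mean(null_sample > c_obs))
            exact = exact_null(sizes, fv, t, k)
            p_ex = exact.tail(c_obs, config.tail)
            hists[(VTYPES[t], k)] = np.bincount(null_sample, minlength=len(sizes) + 1)
            rows.append(
                {
                    "vtype": VTYPES[t],
                    "k": k,
                    "c_obs": c_obs,
                    "null_mean": float(null_sample.mean()),
                    "null_q05": float(np.quantile(null_sample, 0.05)),
                    "null_q95": float(np.quantile(null_sample, 0.95)),
                    "null_mean_exact": exact.mean,
                    "p_mc": p_mc,
                    "p_mc_display": f"< {1.0 / config.trials:g}" if p_mc == 0 else f"{p_mc:g}",
                    "p_exact": p_ex,
                    "stars": _stars(p_mc),
                }
            )
    return NullModelResult(
        table=pd.DataFrame(rows),
        trials=config.trials,
        seed=config.seed,
        tail=config.tail,
        f=fv,
        axon_sizes=list(map(int, sizes)),
        null_histograms=hists,
    )


def achievable_size(exact: ExactNull, alpha: float = 0.05, convention: str = "geq") -> float:
    """Exact attainable rejection probability at level ``alpha``.

    The p-value is a discrete function of C, so the test's true size is the
    null probability of the rejection region {C : p(C) <= alpha}, at most
    ``alpha`` but typically below it.
    """
    n = len(exact.pmf) - 1
    for c in range(n + 1):
        if exact.tail(c, convention) <= alpha:
            # rejection region is {C >= c}; its null mass is the true size
            return exact.tail_geq(c)
    return 0.0
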