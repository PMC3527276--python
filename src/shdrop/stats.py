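"""Exact per-shRNA differential-depletion inference.

For each shRNA and genotype, the T0-vs-T10 comparison is a 2x2 table of the
shRNA's reads against all other assigned reads.  With both margins fixed the
cell count A follows Fisher's noncentral hypergeometric law with odds
parameter psi:

    P_psi(A = x)  proportional to  C(n1, x) * C(n2, m1 - x) * psi**x

where n1, n2 are the T0/T10 totals and m1 the shRNA's total.  This module
computes the two-sided Fisher exact p-value (point-probability rule, with the
R convention's 1e-7 relative tolerance on the observed point probability),
the conditional-MLE odds ratio (the psi solving E_psi[A] = a_obs, found by
monotone root-finding on the log-odds scale), the exact tail-inversion
confidence interval, a pseudocount-stabilised fold depletion, and
Benjamini-Hochberg adjustment applied per genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .model import CountMatrix, Genotype, PipelineConfig, SampleId, Timepoint

# Relative slack when comparing point probabilities in the two-sided rule;
# matches R's fisher.test, which the original analysis used.
_REL_TOL = 1e-7

# Convergence target on the log-odds scale for psi root-finding.
_LOG_PSI_XTOL = 1e-12
_LOG_PSI_MAX = 700.0


@dataclass(frozen=True)
class Contingency2x2:
    """T0-vs-T10 table for one shRNA: (a, b) at T0, (c, d) at T10.

    a, c are the shRNA's reads; b, d all other assigned reads at the same
    timepoint, so a + b and c + d are the sample totals.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table {self.cells()}")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n_t0(self) -> int:
        return self.a + self.b

    @property
    def n_t10(self) -> int:
        return self.c + self.d


@dataclass
class DepletionStat:
    """Full differential-depletion result for one shRNA in one genotype."""

    shrna_id: str
    genotype: Genotype
    p_two_sided: float
    p_adj: float
    or_cmle: float
    ci_low: float
    ci_high: float
    fold_depletion: float
    log2_fold: float


def build_table(matrix: CountMatrix, shrna_id: str, genotype: Genotype) -> Contingency2x2:
    """Build the shRNA-vs-rest 2x2 table for one genotype."""
    if shrna_id not in matrix.shrna_ids:
        raise KeyError(f"shRNA {shrna_id!r} not in count matrix")
    t0 = matrix.sample(SampleId(genotype, Timepoint.T0))
    t10 = matrix.sample(SampleId(genotype, Timepoint.T10))
    n_t0, n_t10 = int(t0.sum()), int(t10.sum())
    if n_t0 <= 0 or n_t10 <= 0:
        raise ValueError(f"zero sample total for {genotype.value}")
    a, c = int(t0[shrna_id]), int(t10[shrna_id])
    return Contingency2x2(a, n_t0 - a, c, n_t10 - c)


def _support(table: Contingency2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support of A and log kernel log[C(n1,x) C(n2,m1-x)] over it."""
    n1, n2 = table.n_t0, table.n_t10
    m1 = table.a + table.c
    xlo = max(0, m1 - n2)
    xhi = min(n1, m1)
    x = np.arange(xlo, xhi + 1)
    logk = (
        gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
        + gammaln(n2 + 1) - gammaln(m1 - x + 1) - gammaln(n2 - (m1 - x) + 1)
    )
    return x, logk


def fisher_two_sided(table: Contingency2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums hypergeometric probabilities over every table (with the observed
    margins) whose probability does not exceed the observed one, within a
    1e-7 relative tolerance.
    """
    x, logk = _support(table)
    logz = logsumexp(logk)
    logp = logk - logz
    logp_obs = logp[table.a - x[0]]
    keep = logp <= logp_obs + math.log1p(_REL_TOL)
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def _log_weights(logk: np.ndarray, x: np.ndarray, log_psi: float) -> np.ndarray:
    w = logk + x * log_psi
    return w - w.max()


def _expectation(logk: np.ndarray, x: np.ndarray, log_psi: float) -> float:
    w = np.exp(_log_weights(logk, x, log_psi))
    return float((x * w).sum() / w.sum())


def _bracket(f, lo: float, hi: float) -> tuple[float, float] | None:
    """Expand [lo, hi] geometrically until f changes sign; None if it never does."""
    flo, fhi = f(lo), f(hi)
    while flo * fhi > 0:
        if flo > 0:  # f decreasing targets or both positive: move left
            lo = 2 * lo if lo < 0 else -1.0
            if lo < -_LOG_PSI_MAX:
                return None
            flo = f(lo)
        else:
            hi = 2 * hi if hi > 0 else 1.0
            if hi > _LOG_PSI_MAX:
                return None
            fhi = f(hi)
    return lo, hi


def cmle_odds_ratio(table: Contingency2x2) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves E_psi[A] = a_obs, which maximises the noncentral hypergeometric
    conditional likelihood.  Returns 0.0 / +inf at the lower / upper boundary
    of the support (the likelihood is maximised in the limit) and 1.0 when
    the support is a single point (psi unidentifiable).
    """
    x, logk = _support(table)
    if len(x) == 1:
        return 1.0
    if table.a == x[0]:
        return 0.0
    if table.a == x[-1]:
        return math.inf

    def f(log_psi: float) -> float:
        return _expectation(logk, x, log_psi) - table.a

    br = _bracket(f, -1.0, 1.0)
    if br is None:  # numerically at a boundary
        return 0.0 if f(0.0) > 0 else math.inf
    root = brentq(f, br[0], br[1], xtol=_LOG_PSI_XTOL, rtol=8.9e-16)
    return float(math.exp(root))


def _log_tail(logk: np.ndarray, x: np.ndarray, log_psi: float, upper: bool, a: int) -> float:
    """log P_psi(A >= a) if upper else log P_psi(A <= a)."""
    w = _log_weights(logk, x, log_psi)
    sel = x >= a if upper else x <= a
    return float(logsumexp(w[sel]) - logsumexp(w))


def exact_ci(table: Contingency2x2, ci_level: float) -> tuple[float, float]:
    """Exact tail-inversion confidence interval for the odds ratio.

    With alpha = 1 - ci_level, the upper endpoint solves
    P_psi(A <= a_obs) = alpha/2 and the lower endpoint solves
    P_psi(A >= a_obs) = alpha/2, both under the noncentral hypergeometric
    law; boundary observations give 0 or +inf.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    x, logk = _support(table)
    a = table.a
    log_half_alpha = math.log((1.0 - ci_level) / 2.0)
    if len(x) == 1:
        return 0.0, math.inf

    if a == x[-1]:
        hi = math.inf
    else:
        def g(log_psi: float) -> float:
            # decreasing in psi; negate so the root-finder sees an increasing f
            return log_half_alpha - _log_tail(logk, x, log_psi, upper=False, a=a)

        br = _bracket(g, -1.0, 1.0)
        hi = math.inf if br is None else float(
            math.exp(brentq(g, br[0], br[1], xtol=_LOG_PSI_XTOL, rtol=8.9e-16))
        )

    if a == x[0]:
        lo = 0.0
    else:
        def h(log_psi: float) -> float:
            return _log_tail(logk, x, log_psi, upper=True, a=a) - log_half_alpha

        br = _bracket(h, -1.0, 1.0)
        lo = 0.0 if br is None else float(
            math.exp(brentq(h, br[0], br[1], xtol=_LOG_PSI_XTOL, rtol=8.9e-16))
        )
    return lo, hi


def fold_depletion(table: Contingency2x2, pseudocount: float) -> float:
    """Frequency-ratio fold depletion, T0 over T10; > 1 means loss at T10.

    A Haldane-style pseudocount stabilises zero T10 counts (true dropouts);
    with pseudocount 0 and c = 0 the value is +inf by convention.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num = (table.a + pseudocount) / table.n_t0
    den = (table.c + pseudocount) / table.n_t10
    if den == 0:
        return math.inf
    return num / den


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def stats_for_genotype(
    matrix: CountMatrix, genotype: Genotype, config: PipelineConfig
) -> pd.DataFrame:
    """Per-shRNA depletion statistics for one genotype, BH-adjusted.

    Returns a DataFrame indexed by shrna_id with columns gene_id, a, c,
    fold_depletion, log2_fold, odds_ratio, ci_low, ci_high, p, p_adj.
    """
    config.validate()
    t0 = matrix.sample(SampleId(genotype, Timepoint.T0)).to_numpy()
    t10 = matrix.sample(SampleId(genotype, Timepoint.T10)).to_numpy()
    n_t0, n_t10 = int(t0.sum()), int(t10.sum())
    if n_t0 <= 0 or n_t10 <= 0:
        raise ValueError(f"zero sample total for {genotype.value}")
    rows = []
    for a, c in zip(t0, t10):
        table = Contingency2x2(int(a), n_t0 - int(a), int(c), n_t10 - int(c))
        fold = fold_depletion(table, config.pseudocount)
        ci_lo, ci_hi = exact_ci(table, config.ci_level)
        rows.append(
            (
                int(a),
                int(c),
                fold,
                math.log2(fold) if fold > 0 else -math.inf,
                cmle_odds_ratio(table),
                ci_lo,
                ci_hi,
                fisher_two_sided(table),
            )
        )
    df = pd.DataFrame(
        rows,
        index=matrix.shrna_ids,
        columns=["a", "c", "fold_depletion", "log2_fold", "odds_ratio", "ci_low", "ci_high", "p"],
    )
    df.insert(0, "gene_id", matrix.gene_ids)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df.index.name = "shrna_id"
    return df


def run_stats(matrix: CountMatrix, config: PipelineConfig) -> dict[Genotype, pd.DataFrame]:
    """Full statistics for both genotypes; BH families are per genotype."""
    return {g: stats_for_genotype(matrix, g, config) for g in Genotype}


def stat_from_row(shrna_id: str, genotype: Genotype, row: pd.Series) -> DepletionStat:
    return DepletionStat(
        shrna_id=shrna_id,
        genotype=genotype,
        p_two_sided=float(row["p"]),
        p_adj=float(row["p_adj"]),
        or_cmle=float(row["odds_ratio"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        fold_depletion=float(row["fold_depletion"]),
        log2_fold=float(row["log2_fold"]),
    )


def write_stats_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-genotype stats TSV; unbounded values as the literal Inf."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "Inf" if v == math.inf else ("-Inf" if v == -math.inf else f"{v:.10g}")
            )
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_stats_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="shrna_id")
    return df
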