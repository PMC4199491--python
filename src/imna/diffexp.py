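"""Pairwise differential expression, cell-type gene signatures, and overlap tests.

Three statistical kernels used throughout validation:

* a two-sample Student t-test per probe (pooled variance by default, Welch
  optionally) with Benjamini-Hochberg FDR control;
* the four-parameter cell-type signature rule: p <= 0.001, FDR <= 0.05,
  |log2 fold change| >= 1, and within-cell-type standard deviation <= 0.5;
* a one-sided (enrichment) Fisher/hypergeometric overlap test computed in log
  space, so tail probabilities around 1e-190 survive without underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import t as t_dist

from .expression import ExpressionMatrix, LOG2_CENTERED, ScaleError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (q-values), input order preserved.

    q_(i) = min_{j >= i} n * p_(j) / j over the sorted order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Two-sample t-test
# ---------------------------------------------------------------------------


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test over rows. Returns (t, two-sided p).

    Zero-variance rows: p = 0 when the means differ, p = 1 when equal (with
    t = +/-inf or 0 accordingly), so noiseless synthetic fixtures do not
    produce NaNs.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = va / na + vb / nb
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
            df = np.full(a.shape[0], na + nb - 2, dtype=float)
        tstat = diff / np.sqrt(se2)
        p = 2.0 * t_dist.sf(np.abs(tstat), df)
    degenerate = se2 == 0
    if np.any(degenerate):
        eq = degenerate & (diff == 0)
        ne = degenerate & (diff != 0)
        tstat[eq], p[eq] = 0.0, 1.0
        tstat[ne], p[ne] = np.sign(diff[ne]) * np.inf, 0.0
        logger.debug("t-test: %d zero-variance probes handled degenerately",
                     int(degenerate.sum()))
    return tstat, p


@dataclass
class DEResult:
    """Per-probe differential expression between two array groups."""

    table: pd.DataFrame  # columns: gene_symbol, log2_fold_change, t_statistic, p_value, q_value, passes
    group_a: list[str]
    group_b: list[str]
    fc_cut: float
    alpha: float

    def passing(self, direction: str | None = None) -> set[str]:
        """Probe ids that pass; ``direction`` 'up'/'down' restricts by FC sign."""
        t = self.table[self.table["passes"]]
        if direction == "up":
            t = t[t["log2_fold_change"] > 0]
        elif direction == "down":
            t = t[t["log2_fold_change"] < 0]
        elif direction is not None:
            raise ValueError(f"unknown direction {direction!r}")
        return set(t.index)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")


def pairwise_de(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    fc_cut: float = 1.0,
    alpha: float = 0.05,
    welch: bool = False,
) -> DEResult:
    """Probe-wise Student t-test of group A vs group B with BH correction.

    log2 fold change is mean(A) - mean(B).  A probe passes iff q < ``alpha``
    and |log2FC| >= ``fc_cut``.
    """
    if matrix.scale != LOG2_CENTERED:
        raise ScaleError("pairwise_de expects a log2-centered matrix")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 arrays")
    a = matrix.values[group_a].to_numpy()
    b = matrix.values[group_b].to_numpy()
    tstat, p = _two_sample_t(a, b, welch=welch)
    q = benjamini_hochberg(p)
    fc = a.mean(axis=1) - b.mean(axis=1)
    passes = (q < alpha) & (np.abs(fc) >= fc_cut)
    table = pd.DataFrame(
        {
            "gene_symbol": matrix.gene_symbols.loc[matrix.values.index].to_numpy(),
            "log2_fold_change": fc,
            "t_statistic": tstat,
            "p_value": p,
            "q_value": q,
            "passes": passes,
        },
        index=matrix.values.index,
    )
    return DEResult(table=table, group_a=group_a, group_b=group_b,
                    fc_cut=fc_cut, alpha=alpha)


# ---------------------------------------------------------------------------
# Cell-type signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureParams:
    p_cut: float = 0.001
    fdr_cut: float = 0.05
    fc_cut: float = 1.0
    sd_cut: float = 0.5


@dataclass
class SignatureResult:
    """Positive/negative gene signature of one cell population vs the rest."""

    population: str
    positive: set[str]
    negative: set[str]
    params: SignatureParams
    table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative signatures must be disjoint")


def cell_signature(
    matrix: ExpressionMatrix,
    population: str,
    params: SignatureParams = SignatureParams(),
    welch: bool = False,
) -> SignatureResult:
    """One-vs-rest signature of ``population`` under the four-parameter rule.

    Per probe: t-test of the population's arrays against all other arrays;
    log2FC = in-population mean - out mean; the within-population SD is taken
    over the population's arrays only.  BH is computed over all probes of this
    one test (one family per population).
    """
    if matrix.scale != LOG2_CENTERED:
        raise ScaleError("cell_signature expects a log2-centered matrix")
    inside = matrix.arrays_of(population)
    outside = [a for a in matrix.array_ids if a not in inside]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("need >= 2 arrays inside and outside the population")
    a = matrix.values[inside].to_numpy()
    b = matrix.values[outside].to_numpy()
    tstat, p = _two_sample_t(a, b, welch=welch)
    q = benjamini_hochberg(p)
    fc = a.mean(axis=1) - b.mean(axis=1)
    sd = a.std(axis=1, ddof=1)
    base = (p <= params.p_cut) & (q <= params.fdr_cut) & (sd <= params.sd_cut)
    pos = base & (fc >= params.fc_cut)
    neg = base & (fc <= -params.fc_cut)
    table = pd.DataFrame(
        {
            "gene_symbol": matrix.gene_symbols.loc[matrix.values.index].to_numpy(),
            "log2_fold_change": fc,
            "t_statistic": tstat,
            "p_value": p,
            "q_value": q,
            "in_population_sd": sd,
            "direction": np.where(pos, "positive", np.where(neg, "negative", "none")),
        },
        index=matrix.values.index,
    )
    return SignatureResult(
        population=population,
        positive=set(matrix.values.index[pos]),
        negative=set(matrix.values.index[neg]),
        params=params,
        table=table,
    )


# ---------------------------------------------------------------------------
# One-sided overlap (Fisher / hypergeometric)
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """2x2 overlap table with a one-sided (enrichment) hypergeometric p.

    a = |query & reference|, a+b = |query|, a+c = |reference|,
    a+b+c+d = |universe|.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_one_sided: float
    log10_p: float

    @property
    def overlap_fraction(self) -> float:
        """Fraction of the query covered by the reference."""
        return self.a / (self.a + self.b) if self.a + self.b else 0.0

    def to_dict(self) -> dict:
        return {
            "table": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "odds_ratio": self.odds_ratio,
            "p_one_sided": self.p_one_sided,
            "log10_p": self.log10_p,
            "overlap_fraction": self.overlap_fraction,
        }


def log_hypergeom_tail(a: int, n_query: int, n_ref: int, n_universe: int) -> float:
    """Natural log of P(X >= a) for X ~ Hypergeom(N=universe, K=ref, n=query).

    Summed in log space via log-gamma so that tails near 1e-190 are exact to
    floating precision rather than underflowing to 0.
    """
    if a <= 0:
        return 0.0
    kmax = min(n_query, n_ref)
    if a > kmax:
        return -math.inf
    ks = np.arange(a, kmax + 1)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = (
        logC(n_ref, ks)
        + logC(n_universe - n_ref, n_query - ks)
        - logC(n_universe, n_query)
    )
    return float(logsumexp(terms))


def overlap_fisher(query, reference, universe) -> OverlapResult:
    """One-sided enrichment test of |query & reference| against the universe."""
    query, reference, universe = set(query), set(reference), set(universe)
    if not query <= universe:
        raise ValueError("query set must be contained in the universe")
    if not reference <= universe:
        raise ValueError("reference set must be contained in the universe")
    a = len(query & reference)
    b = len(query) - a
    c = len(reference) - a
    d = len(universe) - a - b - c
    return overlap_fisher_counts(a, b, c, d)


def overlap_fisher_counts(a: int, b: int, c: int, d: int) -> OverlapResult:
    """Same test from the raw 2x2 counts."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    logp = log_hypergeom_tail(a, a + b, a + c, n)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p = math.exp(logp)
    return OverlapResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=odds,
        p_one_sided=min(p, 1.0),
        log10_p=logp / math.log(10.0),
    )
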