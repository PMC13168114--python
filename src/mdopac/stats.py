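"""Cohort statistics implemented from first principles.

The statistical layer reproduces the study-style analysis of posture
categories against covariates:

* Fisher's exact test for 2x2 tables and its Freeman-Halton extension to
  r x c tables, both by full enumeration of the fiber of tables with the
  observed margins. Two-sided p-values use probability-mass ordering (the
  convention of mainstream statistical packages): the sum of the
  probabilities of all tables no more probable than the observed one,
  with a (1 + 1e-7) tolerance factor guarding floating-point ties.
* The Mann-Whitney U test with midranks, tie-corrected normal
  approximation (no continuity correction), and an exact small-sample
  mode by complete enumeration of group assignments.
* Binary logistic regression fitted by iteratively reweighted least
  squares (IRLS), reporting Exp(B) odds ratios with Wald 95% intervals
  using z = 1.959964. With a single categorical predictor the model is
  saturated, so each Exp(B) equals the cross-product ratio of the
  corresponding level-vs-reference 2x2 collapse — a closed form used as
  an internal cross-check. (A multinomial model over two outcome
  categories reduces exactly to this binary model.)

Printed odds ratios in source tables of this kind frequently truncate
rather than round decimals; :func:`format_report` supports both
conventions, with p-values always rounded half-up.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr
from scipy.stats import rankdata

from .geometry import ComponentID
from .scoring import CATEGORIES

_TIE_FACTOR = 1.0 + 1e-7
Z_WALD = 1.959964  # 97.5% normal quantile at the precision SPSS uses


class CapacityError(ValueError):
    """Table too large for exact enumeration (no silent approximation)."""


class SeparationError(ValueError):
    """A zero cell makes the logistic MLE infinite (quasi-separation)."""


# ---------------------------------------------------------------------------
# contingency tables

@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # shape (r, c), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("grand total must be positive")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match counts shape")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, percents: bool = True) -> pd.DataFrame:
        """Render in the 'n (%)' style, percentages within rows."""
        if not percents:
            return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        out = {}
        row_tot = self.row_margins
        for j, col in enumerate(self.col_labels):
            out[col] = [
                f"{self.counts[i, j]} ({100.0 * self.counts[i, j] / row_tot[i]:.1f})"
                if row_tot[i]
                else f"{self.counts[i, j]} (-)"
                for i in range(len(self.row_labels))
            ]
        return pd.DataFrame(out, index=self.row_labels)


def crosstab(
    scorecards: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: ComponentID | str,
    group: str,
) -> ContingencyTable:
    """Cross-tabulate a component (or overall) category against a covariate.

    Rows are covariate levels (in order of first appearance, with the
    enumerated orderings used for gender/level), columns are the observed
    posture categories in acceptable < compromised < harmful order.
    """
    if len(scorecards) == 0:
        raise ValueError("empty cohort")
    col = f"{outcome.value}_category" if isinstance(outcome, ComponentID) else str(outcome)
    merged = scorecards.merge(covariates, on="subject_id", validate="one_to_one")
    if col not in merged.columns:
        raise ValueError(f"outcome column {col!r} not found")
    if group not in merged.columns:
        raise ValueError(f"group column {group!r} not found")
    observed_cats = [c for c in CATEGORIES if (merged[col] == c).any()]
    bad = set(merged[col]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown outcome categories {sorted(bad)}")
    from .topology import GENDERS, LEVELS

    order = {"gender": list(GENDERS), "level": list(LEVELS)}.get(group)
    if order is None:
        order = list(dict.fromkeys(merged[group]))
    levels = [g for g in order if (merged[group] == g).any()]
    counts = np.array(
        [
            [int(((merged[group] == g) & (merged[col] == c)).sum()) for c in observed_cats]
            for g in levels
        ]
    )
    return ContingencyTable(
        row_labels=[str(g) for g in levels], col_labels=observed_cats, counts=counts
    )


# ---------------------------------------------------------------------------
# exact tests

@dataclass
class ExactTestResult:
    p_value: float
    method: Literal["fisher_2x2", "freeman_halton"]
    tables_enumerated: int
    statistic_prob: float  # probability of the observed table


def _log_table_prob(counts: np.ndarray, row_m: np.ndarray, col_m: np.ndarray, n: int) -> float:
    # multivariate hypergeometric: (prod r_i! prod c_j!)/(N! prod n_ij!)
    return float(
        gammaln(row_m + 1).sum()
        + gammaln(col_m + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> ExactTestResult:
    """Two-sided Fisher exact test on a 2x2 table by enumeration.

    Enumerates every table sharing the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table. A zero margin admits only one table; p = 1.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(
        ["r0", "r1"], ["c0", "c1"], np.asarray(table)
    )
    if t.counts.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 needs a 2x2 table, got {t.counts.shape}")
    row_m, col_m, n = t.row_margins, t.col_margins, t.total
    if (row_m == 0).any() or (col_m == 0).any():
        import logging

        logging.getLogger(__name__).warning("zero margin: exact test degenerate, p = 1")
        return ExactTestResult(1.0, "fisher_2x2", 1, 1.0)
    a_lo = max(0, int(row_m[0] - col_m[1]))
    a_hi = min(int(row_m[0]), int(col_m[0]))
    obs_lp = _log_table_prob(t.counts, row_m, col_m, n)
    threshold = math.exp(obs_lp) * _TIE_FACTOR
    p = 0.0
    count = 0
    for a in range(a_lo, a_hi + 1):
        cell = np.array(
            [[a, row_m[0] - a], [col_m[0] - a, row_m[1] - col_m[0] + a]], dtype=np.int64
        )
        prob = math.exp(_log_table_prob(cell, row_m, col_m, n))
        count += 1
        if prob <= threshold:
            p += prob
    return ExactTestResult(min(p, 1.0), "fisher_2x2", count, math.exp(obs_lp))


def count_tables_with_margins(row_m: Sequence[int], col_m: Sequence[int]) -> int:
    """Number of non-negative integer tables with the given margins.

    Dynamic program over rows: the state is the vector of remaining
    column margins. Used as an independent check on the recursive
    enumeration.
    """
    from collections import Counter

    states: Counter[tuple[int, ...]] = Counter({tuple(int(c) for c in col_m): 1})
    for r in row_m[:-1]:
        new: Counter[tuple[int, ...]] = Counter()
        for state, mult in states.items():
            for comp in _compositions(int(r), state):
                new[tuple(s - c for s, c in zip(state, comp))] += mult
        states = new
    # last row is forced iff remaining margins sum to it
    return sum(m for s, m in states.items() if sum(s) == int(row_m[-1]))


def _compositions(total: int, caps: Sequence[int]):
    """All ways to write ``total`` as a sum over cells bounded by ``caps``."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    lo = max(0, total - sum(caps[1:]))
    hi = min(total, caps[0])
    for first in range(lo, hi + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


def freeman_halton(
    table: ContingencyTable | Sequence[Sequence[int]],
    max_total: int = 200,
    max_tables: int = 5_000_000,
) -> ExactTestResult:
    """Freeman-Halton exact test on an r x c table by full enumeration.

    Recursively enumerates all tables with the observed margins, sums the
    multivariate-hypergeometric probabilities of those no more probable
    than the observed table, and verifies that the enumerated
    probabilities sum to 1 (normalization over the fiber). Tables beyond
    the capacity limits raise :class:`CapacityError` rather than silently
    approximating.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(
        [f"r{i}" for i in range(len(table))],
        [f"c{j}" for j in range(len(table[0]))],
        np.asarray(table),
    )
    row_m, col_m, n = t.row_margins, t.col_margins, t.total
    if n > max_total:
        raise CapacityError(f"grand total {n} exceeds enumeration capacity {max_total}")
    if max(t.counts.shape) > 8:
        raise CapacityError(f"table shape {t.counts.shape} exceeds enumeration capacity")
    keep_rows = row_m > 0
    keep_cols = col_m > 0
    counts = t.counts[np.ix_(keep_rows, keep_cols)]
    row_m, col_m = counts.sum(axis=1), counts.sum(axis=0)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        import logging

        logging.getLogger(__name__).warning("degenerate margins: exact test p = 1")
        return ExactTestResult(1.0, "freeman_halton", 1, 1.0)

    n_expected = count_tables_with_margins(list(row_m), list(col_m))
    if n_expected > max_tables:
        raise CapacityError(f"{n_expected} tables with these margins exceed capacity")

    obs_lp = _log_table_prob(counts, row_m, col_m, n)
    threshold = math.exp(obs_lp) * _TIE_FACTOR
    base = (
        float(gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(n + 1))
    )

    p = 0.0
    total_prob = 0.0
    count = 0
    rows = [int(r) for r in row_m]

    def recurse(i: int, remaining: tuple[int, ...], log_fact_sum: float) -> None:
        nonlocal p, total_prob, count
        if i == len(rows) - 1:
            # last row forced by the remaining column margins
            lf = log_fact_sum + float(gammaln(np.array(remaining) + 1).sum())
            prob = math.exp(base - lf)
            count += 1
            total_prob += prob
            if prob <= threshold:
                p += prob
            return
        for comp in _compositions(rows[i], remaining):
            recurse(
                i + 1,
                tuple(s - c for s, c in zip(remaining, comp)),
                log_fact_sum + float(gammaln(np.array(comp) + 1).sum()),
            )

    recurse(0, tuple(int(c) for c in col_m), 0.0)
    if count != n_expected:
        raise RuntimeError(
            f"enumeration count {count} != closed-form fiber size {n_expected}"
        )
    if abs(total_prob - 1.0) > 1e-9:
        raise RuntimeError(f"fiber probabilities sum to {total_prob}, not 1")
    return ExactTestResult(min(p, 1.0), "freeman_halton", count, math.exp(obs_lp))


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass
class RankTestResult:
    U: float
    U1: float
    U2: float
    mean_rank: tuple[float, float]
    p_value: float
    tie_correction_applied: bool
    mode: str


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
    mode: Literal["asymptotic", "exact"] = "asymptotic",
    exact_limit: int = 12,
) -> RankTestResult:
    """Mann-Whitney U with midranks for ties.

    Asymptotic mode uses the tie-corrected normal approximation without
    continuity correction. Exact mode (total n <= ``exact_limit``)
    enumerates every assignment of the pooled observations to the two
    groups and counts assignments at least as extreme (|U - n1 n2 / 2|)
    as observed. The reported U is min(U1, U2); U1 + U2 = n1 * n2.
    """
    if alternative != "two-sided":
        raise NotImplementedError("only the two-sided alternative is provided")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    mean_rank = (r1 / n1, float(ranks[n1:].sum()) / n2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    nn = n1 + n2
    mu = n1 * n2 / 2.0

    if mode == "exact":
        if nn > exact_limit:
            raise CapacityError(f"exact mode limited to n1+n2 <= {exact_limit}")
        obs_dev = abs(u1 - mu)
        extreme = 0
        total = 0
        idx = range(nn)
        for subset in itertools.combinations(idx, n1):
            rsum = float(ranks[list(subset)].sum())
            u = rsum - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
        return RankTestResult(min(u1, u2), u1, u2, mean_rank, p, has_ties, "exact")

    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (nn * (nn - 1))) if nn > 1 else 0.0
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return RankTestResult(mu, u1, u2, mean_rank, 1.0, has_ties, "asymptotic")
    z = (u1 - mu) / math.sqrt(var)
    p = float(2.0 * ndtr(-abs(z)))
    return RankTestResult(min(u1, u2), u1, u2, mean_rank, min(p, 1.0), has_ties, "asymptotic")


# ---------------------------------------------------------------------------
# logistic regression (IRLS)

@dataclass
class OddsResult:
    term: str
    beta: float
    se: float
    exp_b: float
    ci_low: float
    ci_high: float
    p_value: float


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fit logistic regression by IRLS; returns (beta, covariance)."""
    n, k = X.shape
    beta = np.zeros(k)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        w = p * (1.0 - p)
        z = eta + (y - p) / w
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        eta = X @ beta
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if abs(dev - dev_old) < tol:
            break
        dev_old = dev
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = p * (1.0 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def logistic_or(
    outcome: Sequence[int],
    predictor: Sequence[str],
    reference_level: str,
) -> list[OddsResult]:
    """Odds ratios of a binary outcome for a categorical predictor.

    ``outcome`` is coded 1 for the index category (acceptable) and 0 for
    the reference category (compromised); ``predictor`` is dummy-coded
    against ``reference_level``. A zero cell in the level-by-outcome
    cross-table makes the MLE infinite and raises
    :class:`SeparationError` — no silent penalization.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    pred = pd.Series(list(predictor), dtype="object")
    levels = list(dict.fromkeys(pred))
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not observed")
    contrast_levels = [lv for lv in levels if lv != reference_level]
    # separation check: every level must have both outcomes
    for lv in levels:
        mask = pred.values == lv
        ones = int(y[mask].sum())
        if ones == 0 or ones == mask.sum():
            raise SeparationError(
                f"level {lv!r} has a zero cell (quasi-separation); odds ratio undefined"
            )
    X = np.column_stack(
        [np.ones(len(y))] + [(pred.values == lv).astype(float) for lv in contrast_levels]
    )
    beta, cov = _irls_logistic(X, y)
    se = np.sqrt(np.diag(cov))
    results = []
    for j, lv in enumerate(contrast_levels, start=1):
        b, s = float(beta[j]), float(se[j])
        z = b / s
        results.append(
            OddsResult(
                term=str(lv),
                beta=b,
                se=s,
                exp_b=math.exp(b),
                ci_low=math.exp(b - Z_WALD * s),
                ci_high=math.exp(b + Z_WALD * s),
                p_value=float(2.0 * ndtr(-abs(z))),
            )
        )
    return results


# ---------------------------------------------------------------------------
# reporting

def _truncate(x: float, decimals: int) -> str:
    q = 10**decimals
    v = math.floor(abs(x) * q + 1e-12) / q
    v = math.copysign(v, x) if x < 0 else v
    return f"{v:.{decimals}f}"


def _round_half_up(x: float, decimals: int) -> str:
    return str(Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def format_value(x: float, round_mode: str = "round", decimals: int = 2) -> str:
    if round_mode == "truncate":
        return _truncate(x, decimals)
    if round_mode == "round":
        return _round_half_up(x, decimals)
    raise ValueError(f"round_mode must be round/truncate, got {round_mode!r}")


def format_report(
    results: Sequence[OddsResult],
    round_mode: str = "round",
    decimals: int = 2,
) -> list[dict[str, str]]:
    """Render odds-ratio rows; estimates/CIs follow ``round_mode``,
    p-values always round half-up."""
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.term,
                "exp_b": format_value(r.exp_b, round_mode, decimals),
                "ci_low": format_value(r.ci_low, round_mode, decimals),
                "ci_high": format_value(r.ci_high, round_mode, decimals),
                "p": _round_half_up(r.p_value, decimals),
            }
        )
    return rows
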