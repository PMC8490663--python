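"""Statistical harness for cohort comparisons of voxel-based eloquence.

Exact contingency tests (Fisher 2×2 and its Freeman–Halton r×c
generalization), Cohen's kappa for agreement between clinician-presumed and
voxel-based eloquence, univariable logistic regression with Wald intervals,
the group-comparison dispatch battery, and the multiplicity-adjusted
significance rule (α = 0.002, inclusive).

Two-sided exact p-values use the point-probability criterion: the sum of
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's, with a 1 + 1e-7 relative tie tolerance.
This is the convention that reproduces published three-decimal p-values and
degrades gracefully under floating-point ties.

Wald intervals are reported on the log-odds (coefficient) scale. For a
binary predictor the maximum-likelihood fit has the closed form

    coef = ln(ad / bc),   SE = sqrt(1/a + 1/b + 1/c + 1/d)

with the 2×2 cell convention: a = events with the predictor, b = events
without, c = non-events with, d = non-events without ("event" = response 1).
The iterative fit agrees with this closed form to numerical precision; any
zero cell triggers the Haldane–Anscombe +0.5 correction with a mandatory
flag, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from ._errors import CapacityError, UndefinedStatisticError
from .atlas import AnalysisConfig

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "WaldLogisticResult",
    "GroupComparison",
    "fisher_exact_2x2",
    "freeman_halton_exact",
    "cohens_kappa",
    "logistic_wald_univariable",
    "logistic_wald_from_cells",
    "compare_groups",
    "significant",
    "binarize_kps",
]

#: z quantile used for 95% Wald intervals (the reporting convention the
#: published intervals follow).
WALD_Z = 1.96

_TIE_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c table of non-negative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table."""
    c = _as_counts(table)
    if c.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got {c.shape}")
    return float(sps.fisher_exact(c, alternative="two-sided").pvalue)


def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - float(gammaln(table + 1).sum())


def freeman_halton_exact(
    table,
    max_tables: int = 10_000_000,
    monte_carlo: bool = False,
    n_samples: int = 200_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher–Freeman–Halton exact p-value for an r×c table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed one. When the
    enumeration would exceed ``max_tables`` candidate tables, a seeded
    Monte-Carlo estimate over the conditional null is used instead if
    ``monte_carlo`` is set; otherwise a capacity error is raised.
    """
    obs = _as_counts(table)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("empty table")
    # drop all-zero margins: they carry no probability mass
    obs = obs[rows > 0][:, cols > 0]
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    log_const = float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    log_p_obs = _log_table_prob(obs, log_const)
    cutoff = log_p_obs + math.log(_TIE_TOL)

    # loose bound on the number of candidate tables: the free cells are the
    # first (r-1)×(c-1) block, each bounded by its row total
    bound = 1.0
    for r in rows[:-1]:
        bound *= float(min(r, cols.max()) + 1) ** (len(cols) - 1)
        if bound > max_tables:
            break
    if bound > max_tables:
        if not monte_carlo:
            raise CapacityError(
                f"enumeration bound {bound:.3g} exceeds {max_tables}; "
                "pass monte_carlo=True for a seeded estimate"
            )
        rng = np.random.default_rng(seed)
        dist = sps.random_table(rows, cols)
        samples = dist.rvs(n_samples, random_state=rng)
        log_ps = log_const - gammaln(samples + 1).sum(axis=(1, 2))
        return float(np.mean(log_ps <= cutoff))

    r, c = obs.shape
    total_p = 0.0
    current = np.zeros((r, c), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray) -> None:
        nonlocal total_p
        if i == r - 1:
            current[i] = remaining_cols
            if _log_table_prob(current, log_const) <= cutoff:
                total_p += math.exp(_log_table_prob(current, log_const))
            return
        row_total = int(rows[i])

        def fill_cell(j: int, row_left: int, cols_left: np.ndarray) -> None:
            if j == c - 1:
                if row_left <= cols_left[j]:
                    current[i, j] = row_left
                    new_cols = cols_left.copy()
                    new_cols[j] -= row_left
                    fill_row(i + 1, new_cols)
                return
            hi = min(row_left, int(cols_left[j]))
            for v in range(hi + 1):
                current[i, j] = v
                new_cols = cols_left.copy()
                new_cols[j] -= v
                fill_cell(j + 1, row_left - v, new_cols)

        fill_cell(0, row_total, remaining_cols)

    fill_row(0, cols.astype(np.int64))
    return min(total_p, 1.0)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def cohens_kappa(table) -> KappaResult:
    """Cohen's kappa from a square rater-A × rater-B agreement table.

    kappa = (po − pe) / (1 − pe) with po the diagonal fraction and pe the
    chance agreement from the margins.
    """
    c = _as_counts(table).astype(float)
    if c.shape[0] != c.shape[1]:
        raise ValueError("agreement table must be square")
    n = c.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    po = float(np.trace(c) / n)
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum() / n**2)
    if pe >= 1.0 - 1e-15:
        raise UndefinedStatisticError(
            "kappa is undefined: expected agreement is 1 (degenerate margins)"
        )
    return KappaResult(
        kappa=(po - pe) / (1 - pe),
        observed_agreement=po,
        expected_agreement=pe,
    )


@dataclass(frozen=True)
class WaldLogisticResult:
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.coefficient)


def logistic_wald_from_cells(
    a: float, b: float, c: float, d: float, z: float = WALD_Z
) -> WaldLogisticResult:
    """Closed-form univariable logistic fit for a binary predictor.

    Cells: a = response 1 with predictor 1, b = response 1 with predictor 0,
    c = response 0 with predictor 1, d = response 0 with predictor 0. The
    coefficient is ln(ad/bc); any zero cell gets the Haldane–Anscombe +0.5
    correction and a flag; complete separation is additionally flagged.
    """
    flags: list[str] = []
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if (b == 0 and c == 0) or (a == 0 and d == 0):
        flags.append("complete_separation")
    if np.any(cells == 0):
        flags.append("haldane_anscombe")
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    coef = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    zstat = coef / se
    p = 2 * sps.norm.sf(abs(zstat))
    return WaldLogisticResult(
        coefficient=coef,
        se=se,
        ci_low=coef - z * se,
        ci_high=coef + z * se,
        p=float(p),
        flags=tuple(flags),
    )


def logistic_wald_univariable(
    response: Sequence[int],
    predictor: Sequence[float],
    z: float = WALD_Z,
) -> WaldLogisticResult:
    """Univariable logistic regression with a 95% Wald interval.

    Binary predictors take the exact closed-form ML solution (see
    :func:`logistic_wald_from_cells`); numeric predictors are fitted by
    maximum likelihood. Complete separation yields a flagged result, never a
    silent number.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("response and predictor must be equal-length vectors")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both response outcomes must be present")
    uniq = np.unique(x)
    if uniq.size < 2:
        return WaldLogisticResult(
            coefficient=float("nan"), se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p=float("nan"),
            flags=("constant_predictor",),
        )
    if uniq.size == 2:
        lo, hi = uniq
        xb = (x == hi).astype(int)
        a = int(np.sum((y == 1) & (xb == 1)))
        b = int(np.sum((y == 1) & (xb == 0)))
        c = int(np.sum((y == 0) & (xb == 1)))
        d = int(np.sum((y == 0) & (xb == 0)))
        return logistic_wald_from_cells(a, b, c, d, z=z)
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    try:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises in statsmodels
        return WaldLogisticResult(
            coefficient=float("nan"), se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p=float("nan"),
            flags=("complete_separation", f"fit_failed: {exc}"),
        )
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    flags = []
    if not fit.mle_retvals.get("converged", True) or abs(coef) > 20:
        flags.append("separation_suspected")
    return WaldLogisticResult(
        coefficient=coef,
        se=se,
        ci_low=coef - z * se,
        ci_high=coef + z * se,
        p=2 * float(sps.norm.sf(abs(coef / se))),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p: float


_KINDS = ("continuous_normal", "continuous_nonnormal", "categorical")


def compare_groups(
    values: Sequence,
    groups: Sequence,
    variable_kind: str,
    fh_seed: int | None = None,
) -> GroupComparison:
    """Dispatch the appropriate two- or k-group test.

    Two groups: unpaired t-test / Mann–Whitney U / Fisher exact; three or
    more: one-way ANOVA / Kruskal–Wallis / Freeman–Halton exact. The variable
    kind is declared by the caller — normality is never auto-tested.
    """
    if variable_kind not in _KINDS:
        raise ValueError(f"variable_kind must be one of {_KINDS}")
    values = np.asarray(values)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    split = [values[groups == g] for g in labels]
    if variable_kind == "continuous_normal":
        arrays = [np.asarray(s, dtype=float) for s in split]
        if labels.size == 2:
            res = sps.ttest_ind(*arrays)
            return GroupComparison("t-test", float(res.statistic), float(res.pvalue))
        res = sps.f_oneway(*arrays)
        return GroupComparison("ANOVA", float(res.statistic), float(res.pvalue))
    if variable_kind == "continuous_nonnormal":
        arrays = [np.asarray(s, dtype=float) for s in split]
        if labels.size == 2:
            res = sps.mannwhitneyu(*arrays, alternative="two-sided")
            return GroupComparison(
                "Mann-Whitney U", float(res.statistic), float(res.pvalue)
            )
        res = sps.kruskal(*arrays)
        return GroupComparison(
            "Kruskal-Wallis", float(res.statistic), float(res.pvalue)
        )
    cats = np.unique(values)
    counts = np.array(
        [[int(np.sum((groups == g) & (values == c))) for c in cats] for g in labels]
    )
    if counts.shape == (2, 2):
        return GroupComparison("Fisher exact", float("nan"), fisher_exact_2x2(counts))
    p = freeman_halton_exact(counts, monte_carlo=True, seed=fh_seed)
    return GroupComparison("Freeman-Halton exact", float("nan"), p)


def significant(p: float, config: AnalysisConfig | None = None) -> bool:
    """Inclusive significance rule: true iff p ≤ α (default 0.002)."""
    config = config or AnalysisConfig()
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    return p <= config.alpha


def binarize_kps(kps: int, config: AnalysisConfig | None = None) -> bool:
    """True when the Karnofsky score marks impaired performance (< cutoff)."""
    config = config or AnalysisConfig()
    if kps not in range(0, 101, 10):
        raise ValueError(f"KPS must be one of 0, 10, ..., 100, got {kps}")
    return kps < config.kps_cutoff
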