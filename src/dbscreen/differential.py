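"""Two-group differential tests with adaptive FDR, and rank-based
multi-group comparisons.

The differential-expression (DEP) stage runs a per-protein two-sample
t-test on log2 %beta-actin values, controls the false discovery rate with
the Benjamini-Krieger-Yekutieli adaptive two-stage linear step-up
procedure, and calls DEPs with a q-value cutoff plus a fold-change cutoff
(defaults q < 0.01, fold change >= 2 in either direction).

Group comparisons of single proteins (several patient groups against the
two healthy cohorts) use the Kruskal-Wallis rank test followed by Dunn's
multiple-comparisons post-hoc with tie-corrected variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .matrix import NormalizedMatrix, ValidationError


@dataclass
class DepConfig:
    """Cutoffs for differential-expression calls."""

    q_cutoff: float = 0.01
    fold_cutoff: float = 2.0
    alpha_bky: float = 0.05
    test_variant: str = "student"  # or "welch"
    fold_change_basis: str = "linear_means"  # or "log2_means"

    def __post_init__(self) -> None:
        if self.q_cutoff <= 0 or self.fold_cutoff <= 0:
            raise ValidationError("cutoffs must be positive")
        if self.test_variant not in ("student", "welch"):
            raise ValidationError("test_variant must be 'student' or 'welch'")
        if self.fold_change_basis not in ("linear_means", "log2_means"):
            raise ValidationError(
                "fold_change_basis must be 'linear_means' or 'log2_means'"
            )


# ---------------------------------------------------------------------------
# multiple t-tests
# ---------------------------------------------------------------------------


def multi_t_test(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    variant: str = "student",
) -> pd.DataFrame:
    """Per-protein two-sided two-sample t-test on log2-scale values.

    Returns a DataFrame indexed by protein with columns ``t``, ``p_value``,
    ``log2_fold_change`` (mean A - mean B on the log2 scale) and
    ``fold_change_linear`` (ratio of arithmetic means of the linear values,
    A over B).  Proteins where both groups are constant and equal get
    t = 0, p = 1 by convention.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("t-tests require a complete matrix; impute first")
    with warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # degenerate variance in both groups: equal means -> p=1; unequal -> p=0
    degenerate = np.isnan(t)
    equal = degenerate & np.isclose(mean_a, mean_b)
    t[equal], p[equal] = 0.0, 1.0
    unequal = degenerate & ~np.isclose(mean_a, mean_b)
    t[unequal] = np.sign(mean_a[unequal] - mean_b[unequal]) * np.inf
    p[unequal] = 0.0
    lin_a = np.exp2(a).mean(axis=1)
    lin_b = np.exp2(b).mean(axis=1)
    return pd.DataFrame(
        {
            "t": t,
            "p_value": p,
            "log2_fold_change": mean_a - mean_b,
            "fold_change_linear": lin_a / lin_b,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# Benjamini-Krieger-Yekutieli adaptive two-stage FDR
# ---------------------------------------------------------------------------


def _bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Linear step-up rejection set at level alpha (boolean array)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = sorted_p <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Standard step-up adjusted p-values (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bky_two_stage_fdr(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, int]:
    """Adaptive two-stage linear step-up FDR control.

    Stage 1 runs the linear step-up at alpha' = alpha/(1+alpha) and uses its
    rejection count r1 to estimate the number of true nulls m0 = m - r1.
    If r1 = 0 nothing is discovered; if r1 = m everything is.  Otherwise
    stage 2 reruns the step-up at level alpha' * m / m0.

    Returns
    -------
    reject : bool array of per-hypothesis discovery flags
    q : adjusted q-values on the adaptive scale (discovery <=> q <= alpha)
    m0 : estimated number of true null hypotheses
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, bool), np.zeros(0), 0
    alpha_prime = alpha / (1.0 + alpha)
    stage1 = _bh_stepup(p, alpha_prime)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        q = np.minimum(_bh_adjust(p) * (1.0 + alpha), 1.0)
        return stage1, q, m - r1
    m0 = m - r1
    reject = _bh_stepup(p, alpha_prime * m / m0)
    # adaptive q-values: BH-adjusted p scaled by the null fraction estimate
    q = np.minimum(_bh_adjust(p) * (m0 / m) * (1.0 + alpha), 1.0)
    return reject, q, m0


# ---------------------------------------------------------------------------
# DEP calls
# ---------------------------------------------------------------------------


def call_deps(test_results: pd.DataFrame, config: DepConfig | None = None) -> pd.DataFrame:
    """Apply BKY FDR and the q/fold-change cutoffs to t-test results.

    Adds ``q_value``, ``significant`` (BKY discovery at alpha_bky),
    ``fold_change``, ``is_dep`` and ``direction`` columns.  A DEP needs
    q < q_cutoff AND a linear fold change >= fold_cutoff in either
    direction; direction follows the sign of the log2 fold change.
    """
    config = config or DepConfig()
    out = test_results.copy()
    reject, q, _ = bky_two_stage_fdr(out["p_value"].to_numpy(), config.alpha_bky)
    out["q_value"] = q
    out["significant"] = reject
    if config.fold_change_basis == "linear_means":
        fc = out["fold_change_linear"].to_numpy(dtype=float)
    else:
        fc = np.exp2(out["log2_fold_change"].to_numpy(dtype=float))
    out["fold_change"] = fc
    magnitude = np.maximum(fc, 1.0 / fc)
    out["is_dep"] = (out["q_value"] < config.q_cutoff) & (magnitude >= config.fold_cutoff)
    direction = np.where(out["log2_fold_change"] > 0, "up", "down")
    out["direction"] = np.where(out["is_dep"], direction, "none")
    return out


class TwoGroupDifferential(BaseEstimator):
    """Estimator wrapper for the DEP stage.

    ``fit(values, group_a, group_b)`` runs the t-tests, the BKY procedure
    and the DEP calls on a complete log2 matrix; results land in
    ``results_`` (the DEP table) and ``n_deps_``.
    """

    def __init__(
        self,
        q_cutoff: float = 0.01,
        fold_cutoff: float = 2.0,
        alpha_bky: float = 0.05,
        test_variant: str = "student",
        fold_change_basis: str = "linear_means",
    ):
        self.q_cutoff = q_cutoff
        self.fold_cutoff = fold_cutoff
        self.alpha_bky = alpha_bky
        self.test_variant = test_variant
        self.fold_change_basis = fold_change_basis

    def _config(self) -> DepConfig:
        return DepConfig(
            self.q_cutoff,
            self.fold_cutoff,
            self.alpha_bky,
            self.test_variant,
            self.fold_change_basis,
        )

    def fit(self, values: pd.DataFrame | NormalizedMatrix, group_a: list[str], group_b: list[str]):
        if isinstance(values, NormalizedMatrix):
            if values.transform_state != "log2":
                raise ValidationError("DEP stage expects a log2 matrix")
            values = values.values
        tests = multi_t_test(values, group_a, group_b, self.test_variant)
        self.results_ = call_deps(tests, self._config())
        self.n_deps_ = int(self.results_["is_dep"].sum())
        return self


def dep_table(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    config: DepConfig | None = None,
) -> pd.DataFrame:
    """One-call DEP analysis: t-tests, BKY FDR, cutoff calls."""
    config = config or DepConfig()
    est = TwoGroupDifferential(
        config.q_cutoff,
        config.fold_cutoff,
        config.alpha_bky,
        config.test_variant,
        config.fold_change_basis,
    )
    return est.fit(values, group_a, group_b).results_


# ---------------------------------------------------------------------------
# rank-based multi-group comparison
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with the chi-square p (k-1 df).

    All-identical input returns H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's multiple-comparisons test after Kruskal-Wallis.

    For each pair (i, j), z = (Rbar_i - Rbar_j) / sqrt(S2 * (1/n_i + 1/n_j))
    with S2 = N(N+1)/12 - T/(12(N-1)) and tie term T = sum(t^3 - t).  The
    two-sided normal p is multiplied by the number of compared pairs and
    capped at 1 (the conventional Dunn family-wise adjustment).
    """
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    s2 = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        s2 -= _tie_term(pooled) / (12.0 * (n_total - 1))
    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        denom = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_value": min(p_raw, 1.0),
                "p_adjusted": min(p_raw * len(pairs), 1.0),
            }
        )
    return pd.DataFrame(rows)
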