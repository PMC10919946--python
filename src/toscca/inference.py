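"""Permutation-based significance testing of sparse canonical correlations.

The null hypothesis for component k is that, after removing the first
k-1 components, the two datasets are unrelated.  The null distribution
is approximated by shuffling the sample rows of X2 (X1 fixed), which
breaks any cross-dataset association while preserving each dataset's
internal correlation structure, and refitting a single component on the
shuffled data.  Crucially every permuted refit uses the *same* exact
nonzero counts (p_alpha, q_beta) as the observed analysis — with a
penalty-parameter method the realized sparsity drifts across
permutations and the null draws stop being comparable.  The default test
statistic is the out-of-sample canonical correlation, whose in-sample
counterpart is systematically inflated by sparse selection under noise.

Multiplicity across the K tested components is handled either by a
Bonferroni correction of the raw permutation p-values or by the
max-statistic rule, which compares every observed statistic against the
upper quantile of the null draws of the component with the largest
observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import core
from .metrics import _fold_indices

__all__ = ["PermutationReport", "permutation_test", "adjust_multiplicity"]

STATISTIC_KINDS = ("oos", "insample")
MTC_METHODS = ("bonferroni", "max_stat")


@dataclass(frozen=True)
class PermutationReport:
    """Observed statistic, null draws and p-values for one component."""

    component: int
    observed: float
    null_draws: np.ndarray
    p_raw: float
    p_bonferroni: float
    significant_max_stat: bool
    b: int
    statistic_kind: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "observed": self.observed,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "significant_max_stat": bool(self.significant_max_stat),
            "b": self.b,
            "statistic_kind": self.statistic_kind,
            "seed": self.seed,
        }


def _single_fit_statistic(
    x1: np.ndarray,
    x2: np.ndarray,
    sparsity: "core.SparsityLevel",
    init: np.ndarray,
    statistic_kind: str,
    fold_sets: list[np.ndarray] | None,
    tol: float,
    max_iter: int,
) -> float:
    """Deterministic statistic for one (possibly permuted) dataset pair.

    The init vector and fold partition are fixed by the caller, so the
    statistic is the same function of (x1, x2) for the observed data and
    for every permutation — the exchangeability the test relies on.
    """
    full = core._nipals(x1, x2, sparsity.p_alpha, sparsity.q_beta, init, tol, max_iter)
    assert np.count_nonzero(full.alpha) <= sparsity.p_alpha
    assert np.count_nonzero(full.beta) <= sparsity.q_beta
    if statistic_kind == "insample":
        return full.rho_insample
    if full.degenerate:
        return 0.0
    vals = []
    n = x1.shape[0]
    for test_idx in fold_sets:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        comp = core._nipals(
            x1[mask], x2[mask], sparsity.p_alpha, sparsity.q_beta, init, tol, max_iter
        )
        if comp.degenerate:
            continue
        sign = np.sign(comp.alpha @ full.alpha) * np.sign(comp.beta @ full.beta)
        if sign == 0.0:
            sign = 1.0
        u = x1[test_idx] @ comp.alpha
        v = x2[test_idx] @ comp.beta
        vals.append(sign * core._pearson(u, v))
    return float(np.mean(vals)) if vals else 0.0


def permutation_test(
    pair: "core.StandardizedPair",
    sparsity: "core.SparsityLevel",
    k_components: int = 1,
    b: int = 100,
    statistic_kind: str = "oos",
    seed: int = 0,
    folds: int = 5,
    alpha: float = 0.05,
    init_mode: str = "uniform_random",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[PermutationReport]:
    """Permutation test of the first ``k_components`` canonical correlations.

    The observed model is fitted once; component k's statistic is then
    computed on the matrices deflated by the observed components 1..k-1.
    Each of the ``b`` permutations shuffles the rows of the (deflated) X2,
    refits a single component at the identical sparsity, and records the
    same statistic.  Raw p-values use the (1 + exceedances)/(b + 1)
    convention, so the smallest attainable p-value is 1/(b+1); both the
    Bonferroni-corrected p-value and the max-statistic significance flag
    are filled in.

    A degenerate permuted fit contributes its (zero) statistic rather
    than failing, keeping the null sample size at ``b``.
    """
    if b < 19:
        raise ValueError(f"b must be at least 19, got {b}")
    if statistic_kind not in STATISTIC_KINDS:
        raise ValueError(f"statistic_kind must be one of {STATISTIC_KINDS}")

    ss = np.random.SeedSequence(seed)
    fit_seed, stat_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    observed_fit = core.fit_toscca(
        pair, sparsity, k=k_components, init_mode=init_mode, seed=fit_seed,
        tol=tol, max_iter=max_iter,
    )
    k_eff = observed_fit.k
    if k_eff == 0:
        return []
    rng = np.random.default_rng(stat_seed)

    reports: list[PermutationReport] = []
    for kidx in range(k_eff):
        x1_k, x2_k = observed_fit.deflation_trail[kidx]
        init = core.make_init(init_mode, x1_k, rng)
        fold_sets = (
            _fold_indices(pair.n, folds, int(rng.integers(2**31)))
            if statistic_kind == "oos"
            else None
        )
        # the permuted refits run at exactly the observed sparsity
        assert observed_fit.sparsity == sparsity

        observed = _single_fit_statistic(
            x1_k, x2_k, sparsity, init, statistic_kind, fold_sets, tol, max_iter
        )
        null = np.empty(b)
        for j in range(b):
            perm = rng.permutation(pair.n)
            null[j] = _single_fit_statistic(
                x1_k, x2_k[perm], sparsity, init, statistic_kind, fold_sets, tol, max_iter
            )
        p_raw = (1.0 + np.count_nonzero(null >= observed)) / (b + 1.0)
        reports.append(
            PermutationReport(
                component=kidx + 1,
                observed=observed,
                null_draws=null,
                p_raw=p_raw,
                p_bonferroni=min(1.0, k_eff * p_raw),
                significant_max_stat=False,
                b=b,
                statistic_kind=statistic_kind,
                seed=seed,
            )
        )
    return adjust_multiplicity(reports, method="max_stat", alpha=alpha)


def adjust_multiplicity(
    reports: list[PermutationReport],
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> list[PermutationReport]:
    """Fill multiplicity-adjusted fields across a family of reports.

    ``bonferroni`` sets p_bonferroni = min(1, K * p_raw).  ``max_stat``
    flags component k significant iff its observed statistic exceeds the
    (1 - alpha) quantile of the null draws of the component with the
    largest observed statistic.
    """
    if not reports:
        raise ValueError("reports must be non-empty")
    if method not in MTC_METHODS:
        raise ValueError(f"method must be one of {MTC_METHODS}")
    bs = {r.b for r in reports}
    kinds = {r.statistic_kind for r in reports}
    if len(bs) > 1:
        raise ValueError("reports have inconsistent permutation counts")
    if len(kinds) > 1:
        raise ValueError("reports have inconsistent statistic kinds")
    k = len(reports)
    if method == "bonferroni":
        return [replace(r, p_bonferroni=min(1.0, k * r.p_raw)) for r in reports]
    ref = max(reports, key=lambda r: r.observed)
    threshold = float(np.quantile(ref.null_draws, 1.0 - alpha))
    return [replace(r, significant_max_stat=bool(r.observed > threshold)) for r in reports]
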