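"""Canonical correlation, explained variance, and out-of-sample evaluation.

Two quantities summarize a fitted sparse CCA.  The cumulative percentage
of explained variance (CPEV) for dataset X after k components is

    CPEV_k = tr(G_k' G_k) / tr(X' X),

where G_k stacks the first k latent variables.  Because sparsity breaks
the orthogonality that deflation would otherwise guarantee, later latent
variables can repeat information already captured; the adjusted CPEV
discounts component k by the factor prod_{i<k} (1 - |cor(g_i, g_k)|), so
a component perfectly correlated with an earlier one contributes nothing.

The in-sample canonical correlation of a sparse fit is optimistic — it
grows as more noise variables are admitted — so model assessment here
relies on the out-of-sample canonical correlation: weights are fitted on
training folds and correlated on held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .core import SparsityLevel, StandardizedPair

__all__ = [
    "ExplainedVariance",
    "OosCorrelation",
    "canonical_correlation",
    "cpev",
    "cpev_adjusted",
    "out_of_sample_cc",
]


@dataclass(frozen=True)
class ExplainedVariance:
    """CPEV curve, its adjusted counterpart, and the |correlation| matrix
    between latent variables used in the adjustment."""

    cpev: np.ndarray
    cpev_adj: np.ndarray
    cross_component_cor: np.ndarray

    def __post_init__(self) -> None:
        if self.cpev.shape != self.cpev_adj.shape:
            raise ValueError("cpev and cpev_adj must have the same length")
        k = self.cpev.shape[0]
        if self.cross_component_cor.shape != (k, k):
            raise ValueError("cross_component_cor must be K x K")


@dataclass(frozen=True)
class OosCorrelation:
    """Per-fold out-of-sample canonical correlations and their mean.

    Folds whose training fit was degenerate are recorded as NaN and
    excluded from the mean.
    """

    fold_correlations: np.ndarray
    mean_oos: float
    folds: int
    fold_assignment_seed: int


def canonical_correlation(alpha: np.ndarray, beta: np.ndarray, pair: "StandardizedPair") -> float:
    """Canonical correlation of the latent pair (X1 alpha, X2 beta).

    Computed as  a'X1'X2 b / sqrt(a'X1'X1 a) sqrt(b'X2'X2 b), which on
    column-centered data equals the Pearson correlation of the latent
    variables.
    """
    u = pair.x1 @ np.asarray(alpha, dtype=float)
    v = pair.x2 @ np.asarray(beta, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-norm latent variable")
    return float(u @ v / (nu * nv))


def cpev(latents: np.ndarray, x_original: np.ndarray, unit_norm_latents: bool = False) -> np.ndarray:
    """Cumulative explained-variance fractions tr(G_k'G_k)/tr(X'X).

    ``latents`` is n x K; entry k of the result uses the first k columns.
    By default the latent variables are used as given (the un-normalized
    convention ``gamma_k = X alpha_k`` with unit-norm weights);
    ``unit_norm_latents=True`` rescales each column to unit norm first,
    reproducing the literal formula in which the numerator counts one per
    component.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if latents.shape[0] != x_original.shape[0]:
        raise ValueError("latents and x_original must share their row count")
    if unit_norm_latents:
        norms = np.linalg.norm(latents, axis=0)
        safe = np.where(norms == 0.0, 1.0, norms)
        latents = latents / safe
    denom = float(np.sum(x_original ** 2))
    if denom == 0.0:
        raise ValueError("x_original has zero Frobenius norm")
    return np.cumsum(np.sum(latents ** 2, axis=0)) / denom


def cpev_adjusted(cpev_values: np.ndarray, latents: np.ndarray) -> ExplainedVariance:
    """Discount CPEV for information repeated across correlated latents.

    adjusted[k] = cpev[k] * prod_{i<k} (1 - |cor(g_i, g_k)|); the empty
    product leaves the first component unadjusted.  A zero-variance latent
    is treated as uncorrelated with everything.
    """
    cpev_values = np.asarray(cpev_values, dtype=float)
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    k = cpev_values.shape[0]
    if latents.shape[1] != k:
        raise ValueError("latents must have one column per cpev entry")
    if k < 1:
        raise ValueError("need at least one component")
    centered = latents - latents.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    safe = np.where(norms == 0.0, 1.0, norms)
    corr = np.abs((centered / safe).T @ (centered / safe))
    corr[norms == 0.0, :] = 0.0
    corr[:, norms == 0.0] = 0.0
    np.fill_diagonal(corr, 1.0)
    adj = cpev_values.copy()
    for j in range(1, k):
        adj[j] = cpev_values[j] * np.prod(1.0 - corr[:j, j])
    return ExplainedVariance(cpev=cpev_values, cpev_adj=adj, cross_component_cor=corr)


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def _standardize_with(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (x - mu) / sd


def out_of_sample_cc(
    pair: "StandardizedPair",
    sparsity: "SparsityLevel",
    k_component: int = 1,
    folds: int = 5,
    seed: int = 0,
    init_mode: str = "uniform_random",
    tol: float = 1e-6,
    max_iter: int = 500,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    scheme: str = "kfold",
    holdout_fraction: float = 0.3,
) -> OosCorrelation:
    """Cross-validated canonical correlation of component ``k_component``.

    For each fold the training rows are re-standardized and a fresh
    ``k_component``-deep fit (with deflation) is run; the resulting
    weights are frozen and applied to the held-out rows (standardized
    with the training statistics), and the Pearson correlation of the two
    test latent variables is recorded.  Fold weights are sign-aligned to
    ``reference`` weights (the full-data fit when not supplied) so the
    fold correlations average meaningfully.  ``scheme="holdout"`` uses a
    single seeded train/test split of the given fraction instead of
    K-fold rotation.
    """
    from . import core

    n = pair.n
    if scheme not in ("kfold", "holdout"):
        raise ValueError("scheme must be 'kfold' or 'holdout'")
    if scheme == "holdout":
        n_test = int(round(n * holdout_fraction))
        if n_test < 2 or n - n_test < 3:
            raise ValueError(
                f"holdout fraction {holdout_fraction} leaves too few samples (n={n})"
            )
    else:
        if folds < 2:
            raise ValueError("folds must be at least 2")
        if n // folds < 2:
            raise ValueError(
                f"folds={folds} leaves fewer than 2 test samples per fold (n={n})"
            )
        if n - int(np.ceil(n / folds)) < 3:
            raise ValueError("each training fold must retain at least 3 samples")

    if reference is None:
        full = core.fit_toscca(
            pair, sparsity, k=k_component, init_mode=init_mode, seed=seed,
            tol=tol, max_iter=max_iter,
        )
        if full.k < k_component:
            raise ValueError(f"full-data fit is degenerate before component {k_component}")
        ref_alpha = full.components[k_component - 1].alpha
        ref_beta = full.components[k_component - 1].beta
    else:
        ref_alpha, ref_beta = reference

    rng = np.random.default_rng(seed)
    if scheme == "holdout":
        perm = np.random.default_rng(seed).permutation(n)
        fold_sets = [np.sort(perm[: int(round(n * holdout_fraction))])]
        folds = 1
    else:
        fold_sets = _fold_indices(n, folds, seed)
    vals = np.full(folds, np.nan)
    for f, test_idx in enumerate(fold_sets):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        x1_tr, x2_tr = pair.x1[mask], pair.x2[mask]
        mu1, sd1 = x1_tr.mean(axis=0), x1_tr.std(axis=0, ddof=1)
        mu2, sd2 = x2_tr.mean(axis=0), x2_tr.std(axis=0, ddof=1)
        sd1 = np.where(sd1 == 0.0, 1.0, sd1)
        sd2 = np.where(sd2 == 0.0, 1.0, sd2)
        x1c = _standardize_with(x1_tr, mu1, sd1)
        x2c = _standardize_with(x2_tr, mu2, sd2)
        comp = None
        for _ in range(k_component):
            init = core.make_init(init_mode, x1c, rng)
            comp = core._nipals(
                x1c, x2c, sparsity.p_alpha, sparsity.q_beta, init, tol, max_iter
            )
            if comp.degenerate:
                break
            x1c = core.deflate(x1c, comp.gamma)
            x2c = core.deflate(x2c, comp.zeta)
        if comp is None or comp.degenerate:
            continue  # fold recorded as missing
        sign = np.sign(comp.alpha @ ref_alpha) * np.sign(comp.beta @ ref_beta)
        if sign == 0.0:
            sign = 1.0
        u = _standardize_with(pair.x1[test_idx], mu1, sd1) @ comp.alpha
        v = _standardize_with(pair.x2[test_idx], mu2, sd2) @ comp.beta
        vals[f] = sign * core._pearson(u, v)

    valid = vals[~np.isnan(vals)]
    mean = float(valid.mean()) if valid.size else float("nan")
    return OosCorrelation(
        fold_correlations=vals, mean_oos=mean, folds=folds, fold_assignment_seed=seed
    )
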