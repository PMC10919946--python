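"""Soft-thresholded NIPALS for sparse canonical correlation analysis.

Canonical correlation analysis (CCA) seeks weight vectors ``alpha`` (length
p) and ``beta`` (length q) such that the latent variables ``gamma = X1 @
alpha`` and ``zeta = X2 @ beta`` are maximally correlated across the shared
n samples.  In high dimensions (p, q >> n) the unconstrained solution is
degenerate and uninterpretable, so this module estimates *sparse* canonical
weights by an alternating least-squares (NIPALS) loop in which each weight
update is soft-thresholded to an exact, user-chosen number of nonzero
entries.  Fixing the nonzero count — rather than a lasso-style penalty
parameter — gives direct control over how many variables are selected,
keeps the selection comparable across permutations (see
:mod:`toscca.inference`), and lets several sparsity levels be explored in a
single run (:func:`fit_sparsity_path`).

Multiple components are obtained by deflating both matrices with the
sample-space projector of their own latent variables and re-running the
loop on the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StandardizedPair",
    "SparsityLevel",
    "CanonicalComponent",
    "FitResult",
    "ThresholdTieWarning",
    "DegenerateComponentWarning",
    "standardize",
    "soft_threshold_support",
    "nipals_component",
    "deflate",
    "fit_toscca",
    "fit_sparsity_path",
]

INIT_MODES = ("uniform_random", "uniform_constant", "decomposition")


class ThresholdTieWarning(UserWarning):
    """Entries tied in magnitude at the threshold boundary shrank to zero,
    so the returned vector is sparser than requested."""


class DegenerateComponentWarning(UserWarning):
    """A thresholded weight vector became identically zero; no further
    components can be estimated."""


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Sample Pearson correlation; 0.0 for a zero-variance argument."""
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(uc @ vc / (nu * nv))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizedPair:
    """Two column-standardized data matrices sharing their sample rows.

    ``x1`` is n x p and ``x2`` is n x q, with identical row order.  Every
    column has mean 0 and unit sample standard deviation (divisor n-1);
    construction validates this so downstream code may assume it.
    """

    x1: np.ndarray
    x2: np.ndarray
    sample_ids: tuple[str, ...]
    feature_names_1: tuple[str, ...]
    feature_names_2: tuple[str, ...]

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_names_1", tuple(self.feature_names_1))
        object.__setattr__(self, "feature_names_2", tuple(self.feature_names_2))
        if x1.ndim != 2 or x2.ndim != 2:
            raise ValueError("x1 and x2 must be 2-d arrays")
        if x1.shape[0] != x2.shape[0]:
            raise ValueError(
                f"row count mismatch: x1 has {x1.shape[0]} rows, x2 has {x2.shape[0]}"
            )
        n = x1.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_names_1) != x1.shape[1]:
            raise ValueError("feature_names_1 length does not match x1 columns")
        if len(self.feature_names_2) != x2.shape[1]:
            raise ValueError("feature_names_2 length does not match x2 columns")
        for name, x in (("x1", x1), ("x2", x2)):
            means = x.mean(axis=0)
            if np.max(np.abs(means)) >= 1e-10:
                raise ValueError(f"{name} columns are not centered (|mean| >= 1e-10)")
            sds = x.std(axis=0, ddof=1)
            if np.max(np.abs(sds - 1.0)) >= 1e-10:
                raise ValueError(f"{name} columns are not unit-scale (|sd - 1| >= 1e-10)")

    @property
    def n(self) -> int:
        return self.x1.shape[0]

    @property
    def p(self) -> int:
        return self.x1.shape[1]

    @property
    def q(self) -> int:
        return self.x2.shape[1]


@dataclass(frozen=True)
class SparsityLevel:
    """Exact nonzero counts requested for the two canonical weight vectors."""

    p_alpha: int
    q_beta: int

    def __post_init__(self) -> None:
        for name, v in (("p_alpha", self.p_alpha), ("q_beta", self.q_beta)):
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        object.__setattr__(self, "p_alpha", int(self.p_alpha))
        object.__setattr__(self, "q_beta", int(self.q_beta))

    def validate_for(self, p: int, q: int) -> None:
        if self.p_alpha > p:
            raise ValueError(f"p_alpha={self.p_alpha} exceeds feature count p={p}")
        if self.q_beta > q:
            raise ValueError(f"q_beta={self.q_beta} exceeds feature count q={q}")


@dataclass
class CanonicalComponent:
    """One fitted pair of sparse canonical vectors with diagnostics.

    ``alpha``/``beta`` are unit-norm weight vectors with at most the
    requested number of nonzeros; ``gamma``/``zeta`` are the unit-norm
    latent variables computed on the matrices the component was fitted on
    (i.e. the deflated matrices for components beyond the first).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    zeta: np.ndarray
    rho_insample: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    rho_oos: float | None = None
    rho_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "rho_insample": self.rho_insample,
            "rho_oos": self.rho_oos,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "nnz_alpha": int(np.count_nonzero(self.alpha)),
            "nnz_beta": int(np.count_nonzero(self.beta)),
        }


@dataclass
class FitResult:
    """Ordered sequence of canonical components plus explained-variance
    summaries and the deflation trail (the matrices each component was
    fitted on, used by the permutation test)."""

    components: list[CanonicalComponent]
    sparsity: SparsityLevel
    cpev_1: np.ndarray
    cpev_2: np.ndarray
    cpev_adj_1: np.ndarray
    cpev_adj_2: np.ndarray
    seed: int
    deflation_trail: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    def weight_matrix_1(self) -> np.ndarray:
        """p x K matrix of alpha vectors."""
        return np.column_stack([c.alpha for c in self.components])

    def weight_matrix_2(self) -> np.ndarray:
        """q x K matrix of beta vectors."""
        return np.column_stack([c.beta for c in self.components])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sparsity": {"p_alpha": self.sparsity.p_alpha, "q_beta": self.sparsity.q_beta},
            "components": [c.to_dict() for c in self.components],
            "cpev_1": [float(v) for v in self.cpev_1],
            "cpev_2": [float(v) for v in self.cpev_2],
            "cpev_adj_1": [float(v) for v in self.cpev_adj_1],
            "cpev_adj_2": [float(v) for v in self.cpev_adj_2],
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def standardize(
    raw_x1: np.ndarray,
    raw_x2: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    feature_names_1: Sequence[str] | None = None,
    feature_names_2: Sequence[str] | None = None,
) -> StandardizedPair:
    """Center each column to mean 0 and scale to unit sample standard
    deviation (divisor n-1).

    Raises ``ValueError`` on mismatched row counts, missing values, or a
    constant column (named in the error message).
    """
    x1 = np.asarray(raw_x1, dtype=float)
    x2 = np.asarray(raw_x2, dtype=float)
    if x1.ndim != 2 or x2.ndim != 2:
        raise ValueError("input matrices must be 2-d")
    if x1.shape[0] != x2.shape[0]:
        raise ValueError(
            f"row count mismatch: x1 has {x1.shape[0]} rows, x2 has {x2.shape[0]}"
        )
    n = x1.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if feature_names_1 is None:
        feature_names_1 = [f"X1_{j + 1}" for j in range(x1.shape[1])]
    if feature_names_2 is None:
        feature_names_2 = [f"X2_{j + 1}" for j in range(x2.shape[1])]

    out = []
    for x, names, label in ((x1, feature_names_1, "x1"), (x2, feature_names_2, "x2")):
        if np.isnan(x).any():
            raise ValueError(f"{label} contains missing values")
        sds = x.std(axis=0, ddof=1)
        constant = np.flatnonzero(sds == 0.0)
        if constant.size:
            bad = ", ".join(str(names[j]) for j in constant[:5])
            raise ValueError(f"constant column(s) in {label}: {bad}")
        out.append((x - x.mean(axis=0)) / sds)

    return StandardizedPair(out[0], out[1], sample_ids, feature_names_1, feature_names_2)


def soft_threshold_support(v: np.ndarray, keep: int) -> np.ndarray:
    """Rank-based soft-thresholding to at most ``keep`` nonzero entries.

    Let lambda be the (keep+1)-th largest magnitude of ``v`` (0 when
    ``keep`` equals the length, or when fewer than keep+1 entries are
    nonzero).  The top ``keep`` entries by magnitude are shrunk toward
    zero by lambda, signs preserved; everything else is zeroed.  Ties at
    the boundary are admitted in ascending index order; a survivor whose
    magnitude equals lambda shrinks to exactly zero, making the result
    sparser than requested (a :class:`ThresholdTieWarning` is emitted).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("v must be 1-d")
    m = v.size
    if not 1 <= keep <= m:
        raise ValueError(f"keep must be in [1, {m}], got {keep}")
    if keep == m:
        return v.copy()
    a = np.abs(v)
    part = np.argpartition(-a, (keep - 1, keep))
    lam = a[part[keep]]
    if lam > 0.0 and a[part[keep - 1]] == lam:
        # magnitude tie spanning the boundary: resolve by a stable sort so
        # tied entries are admitted in ascending index order (the admitted
        # ones still shrink to exactly zero)
        order = np.argsort(-a, kind="stable")
        top = order[:keep]
        warnings.warn(
            f"magnitude tie at the threshold boundary (lambda={lam:g}): "
            "result is sparser than requested",
            ThresholdTieWarning,
            stacklevel=2,
        )
    else:
        top = part[:keep]
    w = np.zeros(m)
    w[top] = np.sign(v[top]) * (a[top] - lam)
    return w


def _unit(v: np.ndarray) -> tuple[np.ndarray, float]:
    nrm = float(np.linalg.norm(v))
    if nrm == 0.0:
        return v, 0.0
    return v / nrm, nrm


def _apply_sign_convention(comp: CanonicalComponent) -> CanonicalComponent:
    """Flip the whole component so the largest-|alpha| entry is positive."""
    if comp.alpha.any():
        j = int(np.argmax(np.abs(comp.alpha)))
        if comp.alpha[j] < 0:
            comp.alpha = -comp.alpha
            comp.beta = -comp.beta
            comp.gamma = -comp.gamma
            comp.zeta = -comp.zeta
    return comp


def _nipals(
    x1: np.ndarray,
    x2: np.ndarray,
    p_alpha: int,
    q_beta: int,
    init: np.ndarray,
    tol: float,
    max_iter: int,
) -> CanonicalComponent:
    """Single-component alternating loop on raw (possibly deflated) matrices."""
    alpha, nrm = _unit(np.asarray(init, dtype=float))
    if nrm == 0.0:
        raise ValueError("init must have at least one nonzero entry")
    if tol <= 0:
        raise ValueError("tol must be positive")
    from math import sqrt

    n = x1.shape[0]
    p, q = x1.shape[1], x2.shape[1]
    beta = np.zeros(q)
    gamma = np.zeros(n)
    zeta = np.zeros(n)
    rho_prev = 0.0
    rho = 0.0
    rho_path: list[float] = []
    converged = False
    degenerate = False
    t = 0
    for t in range(1, max_iter + 1):
        gamma = x1 @ alpha
        nrm = sqrt(gamma @ gamma)
        if nrm == 0.0:
            degenerate = True
            break
        gamma /= nrm
        beta = soft_threshold_support(gamma @ x2, q_beta)
        if not beta.any():
            degenerate = True
            break
        zeta = x2 @ beta
        zeta /= sqrt(zeta @ zeta)
        alpha_new = soft_threshold_support(zeta @ x1, p_alpha)
        if not alpha_new.any():
            degenerate = True
            break
        alpha = alpha_new
        gamma = x1 @ alpha
        gamma /= sqrt(gamma @ gamma)
        # Pearson correlation of two unit-norm vectors via raw moments
        sg = gamma.sum()
        sz = zeta.sum()
        var_g = 1.0 - sg * sg / n
        var_z = 1.0 - sz * sz / n
        if var_g <= 0.0 or var_z <= 0.0:
            rho = 0.0
        else:
            rho = float((gamma @ zeta - sg * sz / n) / sqrt(var_g * var_z))
        rho_path.append(rho)
        if abs(rho - rho_prev) <= tol:
            converged = True
            break
        rho_prev = rho

    if not degenerate:
        alpha, _ = _unit(alpha)
        beta, _ = _unit(beta)
    comp = CanonicalComponent(
        alpha=alpha if not degenerate else np.zeros(p),
        beta=beta if not degenerate else np.zeros(q),
        gamma=gamma,
        zeta=zeta,
        rho_insample=rho if not degenerate else 0.0,
        n_iter=t,
        converged=converged,
        degenerate=degenerate,
        rho_path=np.asarray(rho_path),
    )
    return _apply_sign_convention(comp)


def nipals_component(
    pair: StandardizedPair,
    sparsity: SparsityLevel,
    init: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CanonicalComponent:
    """Estimate one pair of sparse canonical vectors by the alternating
    soft-thresholded loop.

    Starting from ``init`` (for alpha), the loop repeats: form the latent
    variable ``gamma = X1 alpha`` (unit norm), regress ``X2`` on it under
    the orthogonal-design simplification (``beta_tilde = X2' gamma``),
    soft-threshold to ``q_beta`` nonzeros, and symmetrically update
    ``alpha``; it stops when the in-sample canonical correlation changes
    by at most ``tol`` between iterations, or after ``max_iter``
    iterations (returned with ``converged=False``, never an exception).
    An all-zero thresholded vector marks the component degenerate —
    there is no signal at the requested sparsity.
    """
    sparsity.validate_for(pair.p, pair.q)
    init = np.asarray(init, dtype=float)
    if init.shape != (pair.p,):
        raise ValueError(f"init must have length p={pair.p}")
    return _nipals(pair.x1, pair.x2, sparsity.p_alpha, sparsity.q_beta, init, tol, max_iter)


def deflate(x: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Project the latent variable out of the sample space of ``x``.

    Returns ``(I_n - g g' / g'g) x``; every column of the result is
    orthogonal to ``latent``.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(latent, dtype=float).ravel()
    if g.shape[0] != x.shape[0]:
        raise ValueError(
            f"latent length {g.shape[0]} does not match row count {x.shape[0]}"
        )
    gg = float(g @ g)
    if gg == 0.0:
        raise ValueError("latent vector is zero")
    return x - np.outer(g, (g @ x) / gg)


def make_init(mode: str, x1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Initial alpha vector: seeded uniform draws, constant weights, or the
    leading right singular vector of ``x1``."""
    p = x1.shape[1]
    if mode == "uniform_random":
        return rng.uniform(-1.0, 1.0, size=p)
    if mode == "uniform_constant":
        return np.full(p, 1.0 / np.sqrt(p))
    if mode == "decomposition":
        _, _, vt = np.linalg.svd(x1, full_matrices=False)
        return vt[0]
    raise ValueError(f"unknown init mode {mode!r}; choose from {INIT_MODES}")


def fit_toscca(
    pair: StandardizedPair,
    sparsity: SparsityLevel,
    k: int = 1,
    init_mode: str = "uniform_random",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    folds: int | None = None,
) -> FitResult:
    """Fit ``k`` sparse canonical components with sequential deflation.

    Component 1 is estimated on the standardized matrices; each subsequent
    component is estimated after deflating X1 by its own latent variable
    ``gamma`` and X2 by ``zeta``.  Cumulative explained variance (CPEV) and
    its adjusted counterpart are computed against the original matrices.
    When ``folds`` is given, a per-component out-of-sample canonical
    correlation is attached via seeded cross-validation.

    A degenerate component (all weights thresholded to zero) truncates the
    sequence with a :class:`DegenerateComponentWarning` rather than
    failing.
    """
    from . import metrics  # runtime import; metrics needs no core symbols at import

    sparsity.validate_for(pair.p, pair.q)
    if k < 1 or k > min(pair.p, pair.q):
        raise ValueError(f"k must be in [1, {min(pair.p, pair.q)}], got {k}")
    rng = np.random.default_rng(seed)
    x1c, x2c = pair.x1, pair.x2
    components: list[CanonicalComponent] = []
    trail: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(k):
        init = make_init(init_mode, x1c, rng)
        comp = _nipals(x1c, x2c, sparsity.p_alpha, sparsity.q_beta, init, tol, max_iter)
        if comp.degenerate:
            warnings.warn(
                f"component {len(components) + 1} is degenerate at "
                f"(p_alpha={sparsity.p_alpha}, q_beta={sparsity.q_beta}); "
                "truncating the sequence",
                DegenerateComponentWarning,
                stacklevel=2,
            )
            break
        components.append(comp)
        trail.append((x1c, x2c))
        x1c = deflate(x1c, comp.gamma)
        x2c = deflate(x2c, comp.zeta)

    if components:
        lat1 = pair.x1 @ np.column_stack([c.alpha for c in components])
        lat2 = pair.x2 @ np.column_stack([c.beta for c in components])
        cpev_1 = metrics.cpev(lat1, pair.x1)
        cpev_2 = metrics.cpev(lat2, pair.x2)
        # the adjustment discounts repeated information between the fitted
        # latent variables; deflation makes those near-orthogonal here, so
        # for this estimator the correction is typically tiny, whereas
        # externally produced components (no deflation) are penalized
        fitted_g = np.column_stack([c.gamma for c in components])
        fitted_z = np.column_stack([c.zeta for c in components])
        cpev_adj_1 = metrics.cpev_adjusted(cpev_1, fitted_g).cpev_adj
        cpev_adj_2 = metrics.cpev_adjusted(cpev_2, fitted_z).cpev_adj
    else:
        cpev_1 = cpev_2 = cpev_adj_1 = cpev_adj_2 = np.empty(0)

    result = FitResult(
        components=components,
        sparsity=sparsity,
        cpev_1=cpev_1,
        cpev_2=cpev_2,
        cpev_adj_1=cpev_adj_1,
        cpev_adj_2=cpev_adj_2,
        seed=seed,
        deflation_trail=trail,
    )
    if folds is not None and components:
        for idx, comp in enumerate(components):
            oos = metrics.out_of_sample_cc(
                pair,
                sparsity,
                k_component=idx + 1,
                folds=folds,
                seed=seed,
                init_mode=init_mode,
                tol=tol,
                max_iter=max_iter,
                reference=(comp.alpha, comp.beta),
            )
            comp.rho_oos = oos.mean_oos
    return result


def fit_sparsity_path(
    pair: StandardizedPair,
    levels: Sequence[SparsityLevel],
    k: int = 1,
    init_mode: str = "decomposition",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[FitResult]:
    """Fit the same decomposition at several sparsity levels sharing one
    initialization per component.

    All levels start from identical init vectors, so the resulting
    per-level fits are exactly what :func:`fit_toscca` would return with
    the same seed and init mode — the path exists to browse supports
    across sparsity levels (smaller supports are nested in larger ones
    when a signal is present) without re-specifying the run.  The
    default initialization is the leading singular vector of the (per
    level, per component deflated) first block: the alternating loop has
    multiple attractors, and a common data-driven start keeps every
    sparsity level in the basin of the same underlying component, which
    is what makes supports comparable — and nested — across the path.
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    for level in levels:
        level.validate_for(pair.p, pair.q)
    return [
        fit_toscca(
            pair, level, k=k, init_mode=init_mode, seed=seed, tol=tol, max_iter=max_iter
        )
        for level in levels
    ]
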