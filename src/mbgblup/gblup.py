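"""GBLUP mixed-model engine.

Builds incidence structures for the record model

    y = X b + Z1 g + W w + Z1 Q q + Z2 s + e

(fixed effects including breed-proportion covariates Qq; additive genetic
values g with covariance G * sigma_g^2 from a genomic relationship matrix;
i.i.d. maternal effects w per dam; i.i.d. sire-by-flock effects s;
residual e), solves Henderson's mixed model equations for the genomic
breeding values, and estimates variance components for the reduced
additive-plus-residual model by EM-REML.

Breed effects are fitted as fixed covariates (one column per breed minus a
reference breed). Variance components for the full model are supplied by
the caller — typically the simulation truth — while the reduced model can
estimate them from data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import GRMatrix

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FitResult",
    "VarianceComponents",
    "build_design_matrices",
    "solve_mme",
    "em_reml",
]


@dataclass
class ModelSpec:
    """What goes into the mixed model.

    ``fixed_factors`` are categorical record columns (reference level =
    first observed level, absorbed in the intercept); ``covariates`` are
    continuous columns, centred. ``breed_covariates`` selects the Q
    columns to fit (the reference breed's column should be omitted by the
    caller; constant columns are dropped automatically). ``variance_components``
    maps ``additive``, ``maternal``, ``sire_flock`` and ``residual`` to
    variances; terms absent from the map are not fitted.
    """

    response: str = "y"
    fixed_factors: Sequence[str] = ("birth_type", "rear_type", "sex", "cg")
    covariates: Sequence[str] = ("age",)
    breed_covariates: Sequence[str] = ()
    maternal: bool = True
    sire_flock: bool = True
    variance_components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.variance_components.items():
            if v < 0:
                raise ValueError(f"variance component {k} must be >= 0")


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Z1: np.ndarray  # records x animals-in-G
    W: np.ndarray | None
    Z2: np.ndarray | None
    x_names: list[str]
    g_ids: list
    w_ids: list
    s_ids: list
    dropped: list[str] = field(default_factory=list)


@dataclass
class FitResult:
    fixed_solutions: pd.Series
    gbv: pd.Series
    maternal_solutions: pd.Series | None
    sire_flock_solutions: pd.Series | None
    pev: pd.Series | None
    variance_components: dict
    meta: dict = field(default_factory=dict)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(values))
    cols, names = [], []
    for lev in levels[1:]:  # first level is the reference
        cols.append((values == lev).to_numpy(float))
        names.append(f"{prefix}[{lev}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def build_design_matrices(
    records: pd.DataFrame,
    spec: ModelSpec,
    Q: pd.DataFrame | None = None,
    g_ids: Sequence | None = None,
) -> DesignMatrices:
    """Incidence structures for the full mixed model.

    ``g_ids`` lists the animals carried in the genomic relationship
    matrix; it may include animals without records (e.g. validation
    sires), whose breeding values are then predicted through their genomic
    relationships alone. Fixed-effect columns that are constant or
    linearly dependent are dropped with a warning recorded in ``dropped``.
    """
    rec = records.reset_index(drop=True)
    n = len(rec)
    y = rec[spec.response].to_numpy(float)

    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for f in spec.fixed_factors:
        if f not in rec.columns:
            raise KeyError(f"unknown fixed factor {f!r}")
        b, nm = _dummies(rec[f].astype(str), f)
        blocks.append(b)
        names += nm
    for c in spec.covariates:
        if c not in rec.columns:
            raise KeyError(f"unknown covariate {c!r}")
        v = rec[c].to_numpy(float)
        blocks.append((v - v.mean())[:, None])
        names.append(c)
    if Q is not None and len(spec.breed_covariates) > 0:
        qsub = Q.loc[rec["id"], list(spec.breed_covariates)].to_numpy(float)
        blocks.append(qsub)
        names += [f"breed[{b}]" for b in spec.breed_covariates]
    X = np.column_stack([b for b in blocks if b.size > 0])

    dropped: list[str] = []
    # prune constant and collinear columns (keep a full-column-rank X)
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.ptp(X[:, j]) == 0 or np.linalg.matrix_rank(cand) <= len(keep):
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"dropped aliased fixed-effect columns: {dropped}")
    X = X[:, keep]
    names = [names[j] for j in keep]

    if g_ids is None:
        g_ids = list(pd.unique(rec["id"]))
    g_ids = list(g_ids)
    g_index = {a: i for i, a in enumerate(g_ids)}
    missing = [a for a in rec["id"] if a not in g_index]
    if missing:
        raise KeyError(f"records for animals absent from G: {missing[:5]}")
    Z1 = np.zeros((n, len(g_ids)))
    Z1[np.arange(n), [g_index[a] for a in rec["id"]]] = 1.0

    W = w_ids = None
    if spec.maternal:
        w_ids = list(pd.unique(rec["dam"]))
        w_index = {d: i for i, d in enumerate(w_ids)}
        W = np.zeros((n, len(w_ids)))
        W[np.arange(n), [w_index[d] for d in rec["dam"]]] = 1.0
    Z2 = s_ids = None
    if spec.sire_flock:
        key = rec["sire"].astype(str) + ":" + rec["flock"].astype(str)
        s_ids = list(pd.unique(key))
        s_index = {k: i for i, k in enumerate(s_ids)}
        Z2 = np.zeros((n, len(s_ids)))
        Z2[np.arange(n), [s_index[k] for k in key]] = 1.0

    return DesignMatrices(
        y=y, X=X, Z1=Z1, W=W, Z2=Z2, x_names=names, g_ids=g_ids,
        w_ids=w_ids or [], s_ids=s_ids or [], dropped=dropped,
    )


def _inverse_with_stabilization(G: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert a GRM, adding 0.01 to the diagonal only when the plain
    Cholesky factorization fails or the matrix is numerically singular."""
    stabilized = False
    A = np.asarray(G, float)
    try:
        c = np.linalg.cholesky(A)
        # reject factorizations that succeeded despite near-singularity
        if np.diag(c).min() < 1e-8 * np.diag(c).max():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        A = A + 0.01 * np.eye(A.shape[0])
        stabilized = True
        c = np.linalg.cholesky(A)
    identity = np.eye(A.shape[0])
    cinv = np.linalg.solve(c, identity)
    return cinv.T @ cinv, stabilized


def solve_mme(
    design: DesignMatrices,
    G: GRMatrix | np.ndarray,
    varcomp: dict,
    compute_pev: bool = True,
) -> FitResult:
    """Solve Henderson's mixed model equations.

    ``varcomp`` must contain ``additive`` and ``residual`` variances, plus
    ``maternal`` / ``sire_flock`` when the design carries those terms.
    Prediction error variances of the breeding values come from the
    additive diagonal block of the inverse coefficient matrix times the
    residual variance. Solutions equal generalized least squares on the
    equivalent model.
    """
    Gv = G.values if isinstance(G, GRMatrix) else np.asarray(G, float)
    if Gv.shape[0] != len(design.g_ids):
        raise ValueError("G dimension does not match design g_ids")
    se2 = float(varcomp["residual"])
    sg2 = float(varcomp["additive"])
    if se2 <= 0 or sg2 <= 0:
        raise ValueError("additive and residual variances must be positive")
    Ginv, stabilized = _inverse_with_stabilization(Gv)

    blocks = [design.X, design.Z1]
    sizes = [design.X.shape[1], design.Z1.shape[1]]
    lambdas = [None, se2 / sg2]
    if design.W is not None:
        blocks.append(design.W)
        sizes.append(design.W.shape[1])
        lambdas.append(se2 / float(varcomp["maternal"]))
    if design.Z2 is not None:
        blocks.append(design.Z2)
        sizes.append(design.Z2.shape[1])
        lambdas.append(se2 / float(varcomp["sire_flock"]))

    T = np.hstack(blocks)
    C = T.T @ T
    rhs = T.T @ design.y
    off = np.cumsum([0] + sizes)
    # add the random-effect penalties on the diagonal blocks
    gs, ge = off[1], off[2]
    C[gs:ge, gs:ge] += lambdas[1] * Ginv
    for k in range(2, len(blocks)):
        s, e = off[k], off[k + 1]
        C[s:e, s:e] += lambdas[k] * np.eye(e - s)

    try:
        sol = np.linalg.solve(C, rhs)
        Cinv = np.linalg.inv(C) if compute_pev else None
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(C)
        raise np.linalg.LinAlgError(
            f"singular mixed-model coefficient matrix (cond={cond:.3e})"
        ) from err

    fixed = pd.Series(sol[: off[1]], index=design.x_names)
    gbv = pd.Series(sol[gs:ge], index=design.g_ids)
    k = 2
    maternal = sire_flock = None
    if design.W is not None:
        maternal = pd.Series(sol[off[k] : off[k + 1]], index=design.w_ids)
        k += 1
    if design.Z2 is not None:
        sire_flock = pd.Series(sol[off[k] : off[k + 1]], index=design.s_ids)
    pev = None
    if compute_pev:
        pev = pd.Series(np.diag(Cinv)[gs:ge] * se2, index=design.g_ids)
        pev = pev.clip(lower=0.0)
    return FitResult(
        fixed_solutions=fixed,
        gbv=gbv,
        maternal_solutions=maternal,
        sire_flock_solutions=sire_flock,
        pev=pev,
        variance_components=dict(varcomp),
        meta={"stabilized": stabilized, "n_records": len(design.y)},
    )


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    G: GRMatrix | np.ndarray,
    init: tuple[float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """EM-REML for the reduced animal model ``y = X b + g + e`` with
    ``g ~ N(0, G sigma_g^2)`` and one record per animal.

    Works in the eigenbasis of G, so each EM step costs O(n p^2). The EM
    updates guarantee a non-decreasing restricted log-likelihood, which is
    recorded per iteration. Components are floored at a small positive
    value; hitting the floor is reported through the convergence flag
    rather than as an error.
    """
    Gv = G.values if isinstance(G, GRMatrix) else np.asarray(G, float)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more records than fixed effects")
    d, U = np.linalg.eigh(Gv)
    d = np.clip(d, 1e-10, None)
    yt = U.T @ y
    Xt = U.T @ X

    vy = y.var()
    sg2, se2 = init if init is not None else (0.5 * vy, 0.5 * vy)
    floor = 1e-8 * vy
    trace: list[float] = []

    def reml_pieces(sg2, se2):
        v = sg2 * d + se2
        vinv_y = yt / v
        Xv = Xt / v[:, None]
        B = Xt.T @ Xv
        Binv = np.linalg.inv(B)
        beta = Binv @ (Xv.T @ yt)
        Py = vinv_y - Xv @ beta  # U' P U yt
        ll = -0.5 * (
            np.log(v).sum()
            + np.linalg.slogdet(B)[1]
            + float(yt @ Py)
        )
        trPG = float((d / v).sum() - np.einsum("ij,ji->", Binv, Xv.T @ (d[:, None] * Xv)))
        trP = float((1 / v).sum() - np.einsum("ij,ji->", Binv, Xv.T @ Xv))
        return ll, Py, trPG, trP

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, Py, trPG, trP = reml_pieces(sg2, se2)
        trace.append(ll)
        if ll < ll_old - 1e-6:  # EM guarantees this cannot happen
            warnings.warn("REML likelihood decreased; stopping")
            break
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
        yPGPy = float(Py @ (d * Py))
        yPPy = float(Py @ Py)
        sg2 = max(sg2 + (sg2**2 / n) * (yPGPy - trPG), floor)
        se2 = max(se2 + (se2**2 / n) * (yPPy - trP), floor)
    else:
        warnings.warn(f"EM-REML did not converge in {max_iter} iterations")

    ll_final, *_ = reml_pieces(sg2, se2)
    return VarianceComponents(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        loglik=float(ll_final),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )
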