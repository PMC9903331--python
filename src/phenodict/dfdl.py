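"""Discriminative feature-oriented dictionary learning (DFDL).

Two dictionaries are learned, one per class, each trained so that its
atoms reconstruct patches of its own class well while reconstructing
patches of the other class poorly.  For a class with training matrix
``Y`` (``N`` columns) and out-class matrix ``Ybar``, the objective is

    min_D  (1/N) * min_{||s||_0 <= L} ||Y - D S||_F^2
         - (rho/N) * min_{||sbar||_0 <= L} ||Ybar - D Sbar||_F^2

with unit-norm atoms.  ``rho`` trades reconstruction quality of the own
class against poor reconstruction of the other class.  The inner minima
are approximated by orthogonal matching pursuit (OMP); the outer problem
is solved by alternating sparse coding with an atom-wise
block-coordinate dictionary update on the quadratic surrogate

    E = (1/N) (Y S^T - rho * Ybar Sbar^T),
    F = (1/N) (S S^T - rho * Sbar Sbar^T),

where atom j is updated to the stationary point of the surrogate in
d_j whenever its curvature F_jj exceeds a small threshold (the
discriminative term can make F indefinite), then renormalized.

``normalize_by_own_N=True`` divides the out-class term by its own column
count instead of N (the other convention in the discriminative
dictionary-learning literature); the default keeps both terms over N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patches import PatchMatrix

_UNIT_NORM_TOL = 1e-8


@dataclass(frozen=True)
class DFDLConfig:
    """Training configuration for one pair of class dictionaries."""

    k_atoms_per_class: int = 50
    L: int = 5
    rho: float = 0.1
    max_iters: int = 30
    rel_tol: float = 1e-4
    seed: int = 0
    normalize_by_own_N: bool = False
    curvature_tol: float = 1e-8
    coder: str = "omp"  # "omp" (default) or "lasso"
    lasso_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.k_atoms_per_class < 1:
            raise ValueError("k_atoms_per_class must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.L > self.k_atoms_per_class:
            raise ValueError("L must not exceed the per-class atom count")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.coder not in ("omp", "lasso"):
            raise ValueError("coder must be 'omp' or 'lasso'")


@dataclass
class ClassDictionary:
    """d x k matrix of unit-norm atoms for one class."""

    atoms: np.ndarray
    class_label: int
    config: DFDLConfig | None = None
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        _check_unit_norm(self.atoms)

    @property
    def d(self) -> int:
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        return self.atoms.shape[1]


@dataclass
class CombinedDictionary:
    """Concatenation [D1 | D2]; columns 0..k-1 are class 1, k..2k-1 class 2."""

    atoms: np.ndarray
    k_per_class: int
    class_labels: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.shape[1] != 2 * self.k_per_class:
            raise ValueError("combined dictionary must have 2k columns")

    @classmethod
    def from_pair(cls, d1: ClassDictionary, d2: ClassDictionary) -> "CombinedDictionary":
        if d1.k != d2.k:
            raise ValueError("class dictionaries have different atom counts")
        return cls(np.hstack([d1.atoms, d2.atoms]), d1.k, (d1.class_label, d2.class_label))

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def half(self, class_label: int) -> np.ndarray:
        i = self.class_labels.index(class_label)
        k = self.k_per_class
        return self.atoms[:, i * k : (i + 1) * k]

    def half_slice(self, class_label: int) -> slice:
        i = self.class_labels.index(class_label)
        k = self.k_per_class
        return slice(i * k, (i + 1) * k)

    def atom_class(self, j: int) -> int:
        return self.class_labels[0] if j < self.k_per_class else self.class_labels[1]


def _check_unit_norm(D: np.ndarray) -> None:
    norms = np.linalg.norm(D, axis=0)
    if not np.allclose(norms, 1.0, atol=_UNIT_NORM_TOL):
        raise ValueError("dictionary columns must have unit l2 norm")


def omp_batch(
    Y: np.ndarray, D: np.ndarray, L: int, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal matching pursuit for every column of ``Y`` against ``D``.

    Greedy atom selection by maximal absolute residual correlation with a
    full least-squares refit on the selected support each iteration,
    stopping at ``L`` atoms or when the residual norm drops below ``tol``.
    Implemented in the Gram domain, vectorized over columns.

    Returns ``(codes, residual_norms)`` with ``codes`` of shape (k, N).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    D = np.asarray(D, dtype=float)
    if Y.shape[0] != D.shape[0]:
        raise ValueError("signal and dictionary dimensions do not match")
    _check_unit_norm(D)
    k = D.shape[1]
    N = Y.shape[1]
    codes = np.zeros((k, N))
    norms2 = np.einsum("ij,ij->j", Y, Y)
    resid2 = norms2.copy()
    if L == 0 or N == 0:
        return codes, np.sqrt(np.clip(resid2, 0.0, None))
    L = min(L, k)
    G = D.T @ D
    alpha0 = D.T @ Y
    corr = alpha0.copy()
    support = np.full((L, N), -1, dtype=int)
    active = resid2 > tol**2
    for t in range(L):
        cols = np.flatnonzero(active)
        if cols.size == 0:
            break
        sel = np.abs(corr[:, cols]).argmax(axis=0)
        support[t, cols] = sel
        S = support[: t + 1, cols].T  # (Na, t+1)
        Gs = G[S[:, :, None], S[:, None, :]]
        a_s = alpha0[S, cols[:, None]]  # (Na, t+1)
        try:
            x = np.linalg.solve(Gs, a_s[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # Collinear support atoms: minimum-norm least-squares refit.
            x = np.einsum("nij,nj->ni", np.linalg.pinv(Gs), a_s)
        # Write the refit coefficients for the active columns.
        codes[:, cols] = 0.0
        codes[S.ravel(), np.repeat(cols, t + 1)] = x.ravel()
        # Residual correlations and squared norms in the Gram domain.
        corr[:, cols] = alpha0[:, cols] - np.einsum("knt,nt->kn", G[:, S], x)
        corr[S.ravel(), np.repeat(cols, t + 1)] = 0.0
        resid2[cols] = norms2[cols] - np.einsum("nt,nt->n", a_s, x)
        active[cols] = resid2[cols] > tol**2
    return codes, np.sqrt(np.clip(resid2, 0.0, None))


def omp_code(
    y: np.ndarray, D: np.ndarray, L: int, tol: float = 1e-10
) -> tuple[np.ndarray, float]:
    """OMP for a single signal; returns ``(code, residual_norm)``."""
    codes, resid = omp_batch(np.asarray(y, dtype=float).reshape(-1, 1), D, L, tol)
    return codes[:, 0], float(resid[0])


def lasso_batch(Y: np.ndarray, D: np.ndarray, alpha: float) -> np.ndarray:
    """l1 (LASSO) sparse coding behind the same contract as :func:`omp_batch`.

    Provided as an alternative coder; codes are not hard-limited to L
    nonzeros, sparsity is governed by ``alpha``.
    """
    from sklearn.decomposition import sparse_encode

    codes = sparse_encode(
        np.asarray(Y, dtype=float).T, D.T, algorithm="lasso_lars", alpha=alpha
    )
    return codes.T


def _code(Y: np.ndarray, D: np.ndarray, cfg: DFDLConfig) -> np.ndarray:
    if cfg.coder == "lasso":
        return lasso_batch(Y, D, cfg.lasso_alpha)
    codes, _ = omp_batch(Y, D, cfg.L)
    return codes


def objective_value(
    D: np.ndarray,
    Y: np.ndarray,
    Ybar: np.ndarray,
    L: int,
    rho: float,
    normalize_by_own_N: bool = False,
) -> float:
    """Evaluate the DFDL objective at ``D`` (inner minima via OMP)."""
    if Y.shape[0] != D.shape[0] or Ybar.shape[0] != D.shape[0]:
        raise ValueError("dimension mismatch between dictionary and data")
    if Y.shape[1] < 1 or Ybar.shape[1] < 1:
        raise ValueError("both patch matrices must be non-empty")
    _, r_in = omp_batch(Y, D, L)
    _, r_out = omp_batch(Ybar, D, L)
    N = Y.shape[1]
    Nbar = Ybar.shape[1] if normalize_by_own_N else N
    return float(np.sum(r_in**2) / N - rho * np.sum(r_out**2) / Nbar)


def _init_dictionary(Y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    N = Y.shape[1]
    if N < k:
        raise ValueError(f"need at least k={k} in-class patches, got {N}")
    idx = rng.choice(N, size=k, replace=False)
    D = Y[:, idx].astype(float).copy()
    norms = np.linalg.norm(D, axis=0)
    zero = norms < 1e-12
    if zero.any():
        # All-zero training columns cannot seed an atom; use random directions.
        D[:, zero] = rng.standard_normal((D.shape[0], int(zero.sum())))
        norms = np.linalg.norm(D, axis=0)
    return D / norms


def train_dfdl(
    Y: PatchMatrix | np.ndarray,
    Ybar: PatchMatrix | np.ndarray,
    cfg: DFDLConfig,
    class_label: int = 1,
) -> ClassDictionary:
    """Learn one class dictionary by alternating OMP coding and atom updates.

    Initialization draws ``k`` distinct in-class patch columns (by
    ``cfg.seed``); atoms whose surrogate curvature is below
    ``cfg.curvature_tol`` are left unchanged for that iteration; atoms
    never selected by any code are re-seeded from the worst-reconstructed
    in-class patch.  Deterministic given (inputs, cfg).
    """
    Ymat = Y.columns if isinstance(Y, PatchMatrix) else np.asarray(Y, dtype=float)
    Bmat = Ybar.columns if isinstance(Ybar, PatchMatrix) else np.asarray(Ybar, dtype=float)
    if Ymat.shape[1] == 0 or Bmat.shape[1] == 0:
        raise ValueError("both patch matrices must be non-empty")
    if Ymat.shape[0] != Bmat.shape[0]:
        raise ValueError("patch dimension d differs between classes")
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_atoms_per_class
    D = _init_dictionary(Ymat, k, rng)
    N = Ymat.shape[1]
    Nbar = Bmat.shape[1] if cfg.normalize_by_own_N else N
    history: list[float] = []
    prev = None
    for _ in range(cfg.max_iters):
        S = _code(Ymat, D, cfg)
        Sbar = _code(Bmat, D, cfg)
        r_in = Ymat - D @ S
        r_out = Bmat - D @ Sbar
        obj = float(np.sum(r_in**2) / N - cfg.rho * np.sum(r_out**2) / Nbar)
        history.append(obj)
        # Atom-wise block-coordinate update of the quadratic surrogate.
        E = Ymat @ S.T / N - cfg.rho * (Bmat @ Sbar.T) / Nbar
        F = S @ S.T / N - cfg.rho * (Sbar @ Sbar.T) / Nbar
        for j in range(k):
            fjj = F[j, j]
            if fjj <= cfg.curvature_tol:
                continue
            d_new = (E[:, j] - D @ F[:, j] + D[:, j] * fjj) / fjj
            norm = np.linalg.norm(d_new)
            if norm < 1e-12:
                continue
            D[:, j] = d_new / norm
        # Re-seed atoms never used by the in-class codes.
        used = np.abs(S).sum(axis=1) > 0
        if not used.all():
            errs = np.einsum("ij,ij->j", r_in, r_in)
            order = np.argsort(errs)[::-1]
            for rank, j in enumerate(np.flatnonzero(~used)):
                col = Ymat[:, order[rank % len(order)]]
                norm = np.linalg.norm(col)
                if norm < 1e-12:
                    col = rng.standard_normal(Ymat.shape[0])
                    norm = np.linalg.norm(col)
                D[:, j] = col / norm
        if prev is not None and abs(obj - prev) <= cfg.rel_tol * max(abs(prev), 1e-12):
            break
        prev = obj
    return ClassDictionary(D, class_label, cfg, history)


def train_pair(
    Y1: PatchMatrix | np.ndarray,
    Y2: PatchMatrix | np.ndarray,
    cfg: DFDLConfig,
) -> tuple[ClassDictionary, ClassDictionary, CombinedDictionary]:
    """Train both class dictionaries and their concatenation [D1 | D2]."""
    d1 = train_dfdl(Y1, Y2, cfg, class_label=1)
    d2 = train_dfdl(Y2, Y1, cfg, class_label=2)
    return d1, d2, CombinedDictionary.from_pair(d1, d2)
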