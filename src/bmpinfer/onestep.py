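"""Deterministic steady-state solver for the BMP "onestep" mass-action model.

A type-A (type I) receptor, a type-B (type II) receptor and a homodimeric
ligand bind in a single reaction to a signalling trimer::

    A_i + B_k + L_j  <-->  T_ijk        (equilibrium constant K_ijk)

At equilibrium ``T_ijk = K_ijk * a_i * b_k * l_j`` where ``a, b, l`` are the
free concentrations, subject to conservation of each total
(``A0_i = a_i + sum_jk T_ijk`` and analogously for B and L).  The downstream
readout is a weighted sum of complex concentrations,
``signal = sum_ijk eps_ijk * T_ijk``, with one signalling efficiency
``eps_ijk`` per complex; together with ``K_ijk`` this gives two free
parameters per complex (60 at the full pathway scale of 3 type-A receptors,
2 type-B receptors and 5 ligands).

Concentrations carry one common arbitrary unit; K is in that unit^-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import SolverError, ValidationError

__all__ = [
    "ModelShape",
    "ModelParameters",
    "CellContext",
    "EquilibriumState",
    "PAPER_SHAPE",
    "solve_equilibrium",
    "readout_signal",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ModelShape:
    """Counts of receptor and ligand species.

    Index convention throughout: ``i`` runs over type-A receptors, ``j`` over
    ligands, ``k`` over type-B receptors; K and eps arrays are shaped
    ``(nA, nL, nB)``.
    """

    nA: int
    nB: int
    nL: int

    def __post_init__(self):
        for name in ("nA", "nB", "nL"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def n_complexes(self) -> int:
        return self.nA * self.nB * self.nL

    @property
    def n_parameters(self) -> int:
        """Free parameters: one equilibrium constant and one efficiency per complex."""
        return 2 * self.n_complexes

    @property
    def array_shape(self) -> tuple[int, int, int]:
        return (self.nA, self.nL, self.nB)


#: Full pathway scale: 3 type-A receptors, 2 type-B receptors, 5 ligands.
PAPER_SHAPE = ModelShape(nA=3, nB=2, nL=5)


@dataclass
class ModelParameters:
    """Equilibrium constants K and signalling efficiencies eps, shape (nA, nL, nB)."""

    K: np.ndarray
    eps: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.K.shape != self.eps.shape or self.K.ndim != 3:
            raise ValidationError(
                f"K and eps must share a 3-d shape (nA, nL, nB); "
                f"got {self.K.shape} and {self.eps.shape}"
            )
        if not (np.all(np.isfinite(self.K)) and np.all(np.isfinite(self.eps))):
            raise ValidationError("K and eps must be finite")
        if np.any(self.K < 0) or np.any(self.eps < 0):
            raise ValidationError("K and eps must be non-negative")

    @property
    def shape(self) -> ModelShape:
        nA, nL, nB = self.K.shape
        return ModelShape(nA=nA, nB=nB, nL=nL)

    def to_flat(self) -> np.ndarray:
        """Flatten to theta = [K.ravel(), eps.ravel()] (length 2*nA*nL*nB)."""
        return np.concatenate([self.K.ravel(), self.eps.ravel()])

    @classmethod
    def from_flat(cls, theta: np.ndarray, shape: ModelShape) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float).ravel()
        m = shape.n_complexes
        if theta.size != 2 * m:
            raise ValidationError(
                f"theta has length {theta.size}, expected {2 * m} for shape {shape}"
            )
        return cls(
            K=theta[:m].reshape(shape.array_shape),
            eps=theta[m:].reshape(shape.array_shape),
        )


@dataclass
class CellContext:
    """Total concentrations for one experiment: A0 (nA,), B0 (nB,), L0 (nL,)."""

    A0: np.ndarray
    B0: np.ndarray
    L0: np.ndarray

    def __post_init__(self):
        self.A0 = np.atleast_1d(np.asarray(self.A0, dtype=float))
        self.B0 = np.atleast_1d(np.asarray(self.B0, dtype=float))
        self.L0 = np.atleast_1d(np.asarray(self.L0, dtype=float))
        for name, v in (("A0", self.A0), ("B0", self.B0), ("L0", self.L0)):
            if v.ndim != 1:
                raise ValidationError(f"{name} must be 1-d")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValidationError(f"{name} must be finite and non-negative")

    @property
    def shape(self) -> ModelShape:
        return ModelShape(nA=self.A0.size, nB=self.B0.size, nL=self.L0.size)

    def features(self) -> np.ndarray:
        """Concatenated totals (A0, B0, L0) as conditioning features."""
        return np.concatenate([self.A0, self.B0, self.L0])


@dataclass
class EquilibriumState:
    """Solved free concentrations, complex concentrations and scalar readout."""

    freeA: np.ndarray
    freeB: np.ndarray
    freeL: np.ndarray
    T: np.ndarray
    signal: float
    residual: float = 0.0
    iterations: int = 0


def _complexes(K, a, b, l):
    # T_ijk = K_ijk * a_i * l_j * b_k with array layout (i, j, k)
    return K * a[:, None, None] * l[None, :, None] * b[None, None, :]


def _residuals(K, a, b, l, A0, B0, L0):
    T = _complexes(K, a, b, l)
    rA = A0 - a - T.sum(axis=(1, 2))
    rL = L0 - l - T.sum(axis=(0, 2))
    rB = B0 - b - T.sum(axis=(0, 1))
    return rA, rB, rL, T


def _max_rel_residual(rA, rB, rL, A0, B0, L0):
    num = np.concatenate([np.abs(rA), np.abs(rB), np.abs(rL)])
    den = np.concatenate([A0, B0, L0]) + 1.0
    return float(np.max(num / den))


def solve_equilibrium(
    params: ModelParameters,
    context: CellContext,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve the competitive trimer-formation equilibrium for one context.

    Uses a damped fixed-point iteration on the free concentrations,

        a_i <- A0_i / (1 + sum_jk K_ijk l_j b_k)   (and cyclically for l, b),

    damped geometrically (i.e. linearly in log space, which keeps every
    iterate strictly positive), with an adaptive damping factor.  If the
    iteration stalls, falls back to a least-squares root solve on the
    conservation residuals in log free concentration.

    Raises
    ------
    ValidationError
        on shape mismatch, negative inputs or non-positive ``tol``.
    SolverError
        if neither stage reaches the requested tolerance; carries the
        final residual.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    if params.K.shape != (context.A0.size, context.L0.size, context.B0.size):
        raise ValidationError(
            f"parameter shape {params.K.shape} does not match context "
            f"(nA={context.A0.size}, nL={context.L0.size}, nB={context.B0.size})"
        )

    K = params.K
    A0, B0, L0 = context.A0, context.B0, context.L0

    # Trivial cases: no ligand, or no binding at all.
    if np.all(L0 == 0) or np.all(K == 0):
        T = np.zeros_like(K)
        state = EquilibriumState(A0.copy(), B0.copy(), L0.copy(), T, 0.0)
        state.signal = readout_signal(state, params)
        return state

    a, b, l = A0.copy(), B0.copy(), L0.copy()
    omega = 0.7
    best = np.inf
    res = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        a_new = A0 / (1.0 + np.einsum("ijk,j,k->i", K, l, b))
        l_new = L0 / (1.0 + np.einsum("ijk,i,k->j", K, a_new, b))
        b_new = B0 / (1.0 + np.einsum("ijk,i,j->k", K, a_new, l_new))
        # geometric damping preserves positivity and exact zeros
        a = a ** (1.0 - omega) * a_new**omega
        l = l ** (1.0 - omega) * l_new**omega
        b = b ** (1.0 - omega) * b_new**omega
        if it % 8 == 0 or it == max_iter:
            rA, rB, rL, _ = _residuals(K, a, b, l, A0, B0, L0)
            res = _max_rel_residual(rA, rB, rL, A0, B0, L0)
            if res < tol:
                break
            if res > best * 0.999:
                omega = max(omega * 0.5, 0.05)  # oscillating: damp harder
            best = min(best, res)

    if res >= tol:
        a, b, l, res = _root_fallback(K, A0, B0, L0, a, b, l, tol)
    if res >= tol:
        raise SolverError(
            f"equilibrium solver did not reach tol={tol:g} "
            f"(residual {res:.3e} after {it} iterations)",
            residual=res,
        )

    rA, rB, rL, T = _residuals(K, a, b, l, A0, B0, L0)
    state = EquilibriumState(a, b, l, T, 0.0, residual=res, iterations=it)
    state.signal = readout_signal(state, params)
    return state


def _root_fallback(K, A0, B0, L0, a, b, l, tol):
    """Least-squares solve on conservation residuals in log free concentration."""
    pos = [A0 > 0, B0 > 0, L0 > 0]
    x0 = np.log(
        np.concatenate([np.maximum(a[pos[0]], 1e-300),
                        np.maximum(b[pos[1]], 1e-300),
                        np.maximum(l[pos[2]], 1e-300)])
    )
    nA_p, nB_p = int(pos[0].sum()), int(pos[1].sum())

    def unpack(x):
        aa = np.zeros_like(A0)
        bb = np.zeros_like(B0)
        ll = np.zeros_like(L0)
        aa[pos[0]] = np.exp(x[:nA_p])
        bb[pos[1]] = np.exp(x[nA_p:nA_p + nB_p])
        ll[pos[2]] = np.exp(x[nA_p + nB_p:])
        return aa, bb, ll

    def fun(x):
        aa, bb, ll = unpack(x)
        rA, rB, rL, _ = _residuals(K, aa, bb, ll, A0, B0, L0)
        return np.concatenate([rA[pos[0]] / (A0[pos[0]] + 1.0),
                               rB[pos[1]] / (B0[pos[1]] + 1.0),
                               rL[pos[2]] / (L0[pos[2]] + 1.0)])

    sol = optimize.least_squares(fun, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a, b, l = unpack(sol.x)
    rA, rB, rL, _ = _residuals(K, a, b, l, A0, B0, L0)
    return a, b, l, _max_rel_residual(rA, rB, rL, A0, B0, L0)


def readout_signal(state: EquilibriumState, params: ModelParameters) -> float:
    """Downstream scalar readout: efficiency-weighted sum of complex levels."""
    if state.T.shape != params.eps.shape:
        raise ValidationError(
            f"state complexes {state.T.shape} do not match eps {params.eps.shape}"
        )
    return float(np.sum(params.eps * state.T))


def simulate_dataset(
    params: ModelParameters,
    contexts: list[CellContext],
    tol: float = 1e-10,
) -> np.ndarray:
    """Noiseless readouts for a list of contexts (one scalar per experiment)."""
    if len(contexts) < 1:
        raise ValidationError("need at least one context")
    out = np.empty(len(contexts))
    for n, ctx in enumerate(contexts):
        try:
            out[n] = solve_equilibrium(params, ctx, tol=tol).signal
        except SolverError as err:
            err.context_index = n
            raise
    return out


def trimer_oracle_111(K: float, A0: float, B0: float, L0: float) -> float:
    """Bisection oracle for the 1x1x1 system: root of T = K (A0-T)(B0-T)(L0-T).

    Independent of the general solver; used for cross-checks.
    """
    if K == 0 or A0 == 0 or B0 == 0 or L0 == 0:
        return 0.0
    hi = min(A0, B0, L0)

    def f(T):
        return K * (A0 - T) * (B0 - T) * (L0 - T) - T

    lo_b, hi_b = 0.0, hi
    for _ in range(200):
        mid = 0.5 * (lo_b + hi_b)
        if f(mid) > 0:
            lo_b = mid
        else:
            hi_b = mid
    return 0.5 * (lo_b + hi_b)
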