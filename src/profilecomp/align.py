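"""Elastic geometric compensation of 1-D intensity profiles.

Every column y_j of the profile matrix Y is modelled as a distorted,
non-uniformly sampled observation of one latent population template

    f(x) = sum_k c_k * sinc(x/Delta - k),      Delta = 1/(L-1),  x in [0, 1],

through an unknown monotone warp g_j.  The template coefficients c and the
per-profile sample locations X = {x_{i,j}} are estimated jointly by
alternating minimisation of the energy

    E(X, c, Y) = E_Y(X, c, Y) + alpha * c' psi_L c + beta * Tr[X' psi_N X]

where E_Y is the (outlier-weighted) data-fidelity term under an AWGN or
Poisson noise model, psi are first-difference quadratic penalties (smoothness
of f; tension between consecutive locations), and binary per-profile outlier
indicators omega_j exclude profiles far from the current template from the
fit while their locations keep being updated (so they can be re-admitted).

Internuclear templates are symmetric by construction (the interface looks the
same from either cell), imposed through c = P c_tilde with the fold-over
matrix P; radial templates are unconstrained.

The coefficient step solves the regularised weighted normal equations
exactly; the location step is a damped fixed-point update of the stationarity
condition, followed by re-pinning the endpoints to 0/1 and a monotonicity
projection (running maximum).  The step fraction is halved (backtracking)
whenever the energy would increase, which keeps the energy trace
non-increasing whenever the objective itself is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .profiles import ProfileMatrix

__all__ = [
    "AlignmentParams",
    "AlignmentState",
    "IdealProfile",
    "sinc_basis",
    "sinc_basis_deriv",
    "symmetry_matrix",
    "difference_penalty",
    "weights",
    "coefficient_update",
    "outlier_update",
    "omega_matrix",
    "location_update",
    "total_energy",
    "compensate",
    "compensated_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Tunable parameters of the compensation solver.

    alpha : weight of the template-smoothness penalty (a.u.^2 per squared
        coefficient difference).
    beta : weight of the location tension penalty; larger values stiffen the
        warps.
    L : number of sinc basis functions (even; node spacing 1/(L-1)).
    noise_model : "awgn" or "poisson" data-fidelity weighting.
    symmetric : fold the template about x = 0.5 (internuclear profiles).
    outlier_factor : multiplier of the robust (MAD-based) spread in the
        column-rejection threshold.
    epsilon : guard constant in the Poisson weights and log terms.
    seed : reserved; the solver itself is deterministic.
    """

    alpha: float = 0.3
    beta: float = 10.0
    L: int = 20
    noise_model: str = "poisson"
    symmetric: bool = True
    outlier_factor: float = 3.0
    epsilon: float = 1e-6
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.L < 4 or self.L % 2:
            raise ValueError("L must be even and >= 4")
        if self.noise_model not in ("awgn", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def for_kind(cls, kind: str, **kw) -> "AlignmentParams":
        """Defaults per profile kind: IN profiles are symmetric, RD are not."""
        kw.setdefault("symmetric", kind.upper() == "IN")
        return cls(**kw)


@dataclass
class AlignmentState:
    X: np.ndarray  # (N, M) locations in [0, 1], columns non-decreasing
    c: np.ndarray  # (L,) template coefficients
    omega: np.ndarray  # (M,) binary outlier indicators, >= one set
    energy_trace: np.ndarray
    iterations: int
    c_tilde: np.ndarray | None = None
    damping_events: int = 0
    omega_changes: list = field(default_factory=list)  # iterations where omega flipped
    X_history: list = field(default_factory=list, repr=False)


@dataclass
class IdealProfile:
    """The estimated continuous template f(x, c) on [0, 1]."""

    c: np.ndarray
    L: int
    symmetric: bool

    @property
    def delta(self) -> float:
        return 1.0 / (self.L - 1)

    def evaluate(self, x) -> np.ndarray:
        return sinc_basis(np.atleast_1d(np.asarray(x, dtype=float)).ravel(), self.L).T @ self.c

    __call__ = evaluate

    def derivative(self, x) -> np.ndarray:
        return (
            sinc_basis_deriv(np.atleast_1d(np.asarray(x, dtype=float)).ravel(), self.L).T
            @ self.c
        )


def sinc_basis(x_points: np.ndarray, L: int) -> np.ndarray:
    """Matrix of normalised-sinc interpolators, entry (k, p) = sinc(x_p/Delta - k).

    At the nodes x = k*Delta the basis reduces to unit vectors, so
    f(k*Delta) = c_k exactly.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    x = np.asarray(x_points, dtype=float).ravel()
    delta = 1.0 / (L - 1)
    k = np.arange(L)[:, None]
    return np.sinc(x[None, :] / delta - k)


def sinc_basis_deriv(x_points: np.ndarray, L: int) -> np.ndarray:
    """Analytic derivative of the sinc basis w.r.t. x.

    d/dt sinc(t) = (cos(pi t) - sinc(t)) / t, with the removable singularity
    at t = 0 evaluated as 0; the chain rule contributes a 1/Delta factor.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    x = np.asarray(x_points, dtype=float).ravel()
    delta = 1.0 / (L - 1)
    t = x[None, :] / delta - np.arange(L)[:, None]
    out = np.zeros_like(t)
    nz = np.abs(t) > 1e-12
    tn = t[nz]
    out[nz] = (np.cos(np.pi * tn) - np.sinc(tn)) / tn
    return out / delta


def symmetry_matrix(L: int) -> np.ndarray:
    """Fold-over matrix P (L x L/2) such that c = P c_tilde is mirror symmetric."""
    if L % 2:
        raise ValueError("L must be even")
    half = L // 2
    P = np.zeros((L, half))
    for k in range(L):
        P[k, k if k < half else L - 1 - k] = 1.0
    return P


def difference_penalty(size: int) -> np.ndarray:
    """First-difference quadratic penalty psi = D'D.

    c' psi c = sum_k (c_k - c_{k-1})^2; symmetric PSD with the constants as
    null space.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    D = np.diff(np.eye(size), axis=0)
    return D.T @ D


def _f_values(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    L = len(c)
    return (sinc_basis(np.ravel(X), L).T @ c).reshape(np.shape(X))


def weights(
    X: np.ndarray,
    c: np.ndarray | None,
    omega: np.ndarray,
    noise_model: str,
    epsilon: float = 1e-6,
) -> np.ndarray:
    """Diagonal weights sigma_{i,j} = omega_j * gamma_{i,j}.

    gamma is 1 under AWGN and 1/(2 f(x_{i,j}) + epsilon) under the Poisson
    model (the local curvature of the negative log-likelihood); a missing
    template (first iteration) falls back to unit gamma.
    """
    X = np.asarray(X, dtype=float)
    if noise_model == "poisson" and c is not None:
        f = np.maximum(_f_values(X, c), 0.0)
        gamma = 1.0 / (2.0 * f + epsilon)
    else:
        gamma = np.ones_like(X)
    return gamma * np.asarray(omega, dtype=float)[None, :]


def coefficient_update(
    X: np.ndarray,
    Y: np.ndarray,
    sigma: np.ndarray,
    alpha: float,
    P: np.ndarray | None = None,
    L: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Exact solve of the regularised weighted normal equations for c.

    Unconstrained: c = (Phi Sigma Phi' + alpha psi_L)^-1 Phi Sigma y.
    Symmetric: the same system folded through P with the half-length penalty
    2 alpha psi_{L/2} (for a mirror-symmetric c the full penalty c' psi_L c
    equals exactly 2 c_tilde' psi_{L/2} c_tilde, so this factor makes the
    folded solve the exact minimiser of the total energy); the returned
    c = P c_tilde is mirror symmetric by construction.
    """
    if P is not None:
        L = P.shape[0]
    if L is None:
        raise ValueError("need either P or L")
    Phi = sinc_basis(np.ravel(X), L)
    return _solve_coefficients(Phi, np.ravel(sigma), np.ravel(Y), alpha, P, L)


def _solve_coefficients(Phi, w, y, alpha, P, L):
    if not np.any(w > 0):
        raise ValueError("no valid profiles: all columns are outliers")
    Phi_w = Phi * w[None, :]
    A = Phi_w @ Phi.T
    b = Phi_w @ y
    if P is None:
        return np.linalg.solve(A + alpha * difference_penalty(L), b), None
    half = L // 2
    A_half = P.T @ A @ P + 2.0 * alpha * difference_penalty(half)
    c_tilde = np.linalg.solve(A_half, P.T @ b)
    return P @ c_tilde, c_tilde


def outlier_update(
    Y: np.ndarray, X: np.ndarray, c: np.ndarray, outlier_factor: float = 3.0
) -> np.ndarray:
    """Binary column indicators from the distance to the current template.

    d_j = ||f(x_j) - y_j||^2; columns with d_j above the robust threshold

        tau = median(d) + outlier_factor * (1.4826 * MAD(d) + median(d))

    are flagged (omega_j = 0).  Flooring the spread estimate by the median
    keeps the rule scale-free: squared distances of well-aligned columns
    concentrate near zero (MAD alone would then flag ordinary population
    heterogeneity), while genuine garbage sits orders of magnitude above the
    median.  The rule is re-evaluated every iteration, so previously rejected
    columns re-enter as soon as they fall below the threshold, and the
    median-based form guarantees at least one valid column.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] == 1:
        return np.ones(1)
    d = ((_f_values(X, c) - Y) ** 2).sum(axis=0)
    return _omega_from_distances(d, outlier_factor)


def _omega_from_distances(d: np.ndarray, outlier_factor: float) -> np.ndarray:
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    tau = med + outlier_factor * (1.4826 * mad + med) + 1e-12 * (1.0 + med)
    return (d <= tau).astype(float)


def omega_matrix(N: int) -> np.ndarray:
    """Neighbour-sum operator of the fixed-point location update.

    Tridiagonal of ones with the two off-diagonal boundary entries doubled,
    so (Omega x)_i = x_{i-1} + x_i + x_{i+1} in the interior.
    """
    Om = (
        np.eye(N)
        + np.diag(np.ones(N - 1), 1)
        + np.diag(np.ones(N - 1), -1)
    )
    Om[0, 1] = 2.0
    Om[N - 1, N - 2] = 2.0
    return Om


def location_update(
    X: np.ndarray,
    c: np.ndarray,
    Y: np.ndarray,
    beta: float,
    gamma: np.ndarray,
    damping: float = 1.0,
) -> np.ndarray:
    """One damped fixed-point step on the sample locations.

    x_j <- (1/3) (Omega x_j - z_j / beta) with
    z_{i,j} = gamma_{i,j} [f(x_{i,j}) - y_{i,j}] f'(x_{i,j}), blended with the
    current locations by ``damping``; afterwards the endpoints are re-pinned
    to 0 and 1 and each column is projected onto the monotone non-decreasing
    cone (running maximum, clipped to [0, 1]).

    ``gamma`` carries the noise-model weights without the outlier indicators:
    rejected columns keep feeling the pull of the template, so they can
    realign and be re-admitted in later iterations.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    L = len(c)
    xflat = np.ravel(X)
    F = (sinc_basis(xflat, L).T @ c).reshape(X.shape)
    Fd = (sinc_basis_deriv(xflat, L).T @ c).reshape(X.shape)
    z = np.asarray(gamma, dtype=float) * (F - np.asarray(Y, dtype=float)) * Fd
    X_fp = (omega_matrix(N) @ X - z / beta) / 3.0
    # trust region: the raw fixed-point displacement can blow up where the
    # Poisson weight 1/(2f+eps) diverges (f near 0); cap each entry's move at
    # one grid spacing so backtracking operates on a sane candidate
    step = np.clip(X_fp - X, -1.0 / (N - 1), 1.0 / (N - 1))
    Xn = X + np.asarray(damping) * step  # damping may be per-column (M,)
    Xn = np.clip(Xn, 0.0, 1.0)
    Xn[0, :] = 0.0
    Xn = np.maximum.accumulate(Xn, axis=0)
    Xn[-1, :] = 1.0
    return Xn


def _column_energies(
    X: np.ndarray, c: np.ndarray, Y: np.ndarray, params: AlignmentParams
) -> np.ndarray:
    """Per-column data + tension energy with unit column weights.

    This is the column-separable part of the objective used by the
    location-step line search; the template penalty is constant there.
    """
    F = _f_values(X, c)
    if params.noise_model == "awgn":
        e_data = ((F - Y) ** 2).sum(axis=0)
    else:
        Fc = np.maximum(F, params.epsilon)
        e_data = (Fc - Y * np.log(Fc)).sum(axis=0)
    return e_data + params.beta * (np.diff(X, axis=0) ** 2).sum(axis=0)


def total_energy(
    X: np.ndarray,
    c: np.ndarray,
    Y: np.ndarray,
    params: AlignmentParams,
    omega: np.ndarray,
) -> float:
    """Three-term energy: data fidelity + template smoothness + location tension.

    AWGN fidelity is the outlier-weighted sum of squares; Poisson fidelity is
    the (shifted) negative log-likelihood sum omega_j [f - y log f], with f
    clipped below at epsilon inside the log.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    om = np.asarray(omega, dtype=float)[None, :]
    F = _f_values(X, c)
    if params.noise_model == "awgn":
        e_data = float(np.sum(om * (F - Y) ** 2))
    else:
        if (Y < 0).any():
            raise ValueError("Poisson fidelity requires non-negative intensities")
        Fc = np.maximum(F, params.epsilon)
        e_data = float(np.sum(om * (Fc - Y * np.log(Fc))))
    psi_L = difference_penalty(len(c))
    e_c = params.alpha * float(c @ psi_L @ c)
    e_x = params.beta * float(np.sum(np.diff(X, axis=0) ** 2))
    return e_data + e_c + e_x


def compensate(
    matrix: ProfileMatrix | np.ndarray,
    params: AlignmentParams | None = None,
    keep_history: bool = False,
) -> tuple[AlignmentState, IdealProfile]:
    """Alternating estimation of the template and the compensated locations.

    Locations start uniform (x_{i,j} = i/(N-1)); each iteration runs
    weights -> coefficient update -> outlier update -> damped location update
    and stops when the relative energy change drops below ``tol`` or after
    ``max_iter`` iterations.  A location step that would raise the energy is
    backtracked (step fraction halved, logged); the backtracking state
    persists across iterations so a divergent step size decays.
    """
    if isinstance(matrix, ProfileMatrix):
        Y = matrix.Y
        if params is None:
            params = AlignmentParams.for_kind(matrix.kind)
    else:
        Y = np.asarray(matrix, dtype=float)
        if params is None:
            params = AlignmentParams()
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 1:
        raise ValueError("Y must be N x M with N >= 2, M >= 1")
    N, M = Y.shape
    if params.noise_model == "poisson" and (Y < 0).any():
        raise ValueError("Poisson fidelity requires non-negative intensities")
    X = np.tile(np.linspace(0.0, 1.0, N)[:, None], (1, M))
    omega = np.ones(M)
    P = symmetry_matrix(params.L) if params.symmetric else None
    L = params.L
    psi_L = difference_penalty(L)
    y_flat = np.ravel(Y)
    grid_cap = 1.0 / (N - 1)
    Om = omega_matrix(N)
    poisson = params.noise_model == "poisson"

    def data_cols(F, Ycols):
        if not poisson:
            return ((F - Ycols) ** 2).sum(axis=0)
        Fc = np.maximum(F, params.epsilon)
        return (Fc - Ycols * np.log(Fc)).sum(axis=0)

    def tension_cols(Xc):
        return (np.diff(Xc, axis=0) ** 2).sum(axis=0)

    def project(Xc):
        Xc = np.clip(Xc, 0.0, 1.0)
        Xc[0, :] = 0.0
        Xc = np.maximum.accumulate(Xc, axis=0)
        Xc[-1, :] = 1.0
        return Xc

    c: np.ndarray | None = None
    c_tilde = None
    trace: list[float] = []
    merit_trace: list[float] = []
    lam = np.ones(M)
    damping_events = 0
    omega_changes: list[int] = []
    history: list[np.ndarray] = []
    it = 0
    for it in range(1, params.max_iter + 1):
        Phi = sinc_basis(np.ravel(X), L)  # reused by every sub-step at this X
        if poisson and c is not None:
            F_prev = (Phi.T @ c).reshape(N, M)
            gamma0 = 1.0 / (2.0 * np.maximum(F_prev, 0.0) + params.epsilon)
        else:
            gamma0 = np.ones((N, M))
        c, c_tilde = _solve_coefficients(
            Phi, np.ravel(gamma0 * omega[None, :]), y_flat, params.alpha, P, L
        )
        F = (Phi.T @ c).reshape(N, M)
        if M > 1:
            d = ((F - Y) ** 2).sum(axis=0)
            new_omega = _omega_from_distances(d, params.outlier_factor)
            if not np.array_equal(new_omega, omega):
                # re-fit immediately so freshly rejected columns (e.g. the
                # all-ones first pass) never leak into the template that
                # drives this iteration's location step
                omega = new_omega
                omega_changes.append(it)
                c, c_tilde = _solve_coefficients(
                    Phi, np.ravel(gamma0 * omega[None, :]), y_flat, params.alpha, P, L
                )
                F = (Phi.T @ c).reshape(N, M)
        gamma = 1.0 / (2.0 * np.maximum(F, 0.0) + params.epsilon) if poisson else np.ones((N, M))
        Fd = (sinc_basis_deriv(np.ravel(X), L).T @ c).reshape(N, M)
        z = gamma * (F - Y) * Fd
        X_fp = (Om @ X - z / params.beta) / 3.0
        # trust region: the Poisson weight diverges where f is near 0, so cap
        # each entry's fixed-point displacement at one grid spacing
        step = np.clip(X_fp - X, -grid_cap, grid_cap)
        # per-column backtracking line search: the location problem is
        # column-separable given c, and the merit weights every column so
        # rejected columns stay free to realign (the omega-weighted energy
        # would veto their motion as pure tension increase) without letting
        # any one column's misfit steer the step size of the others
        e_before = data_cols(F, Y) + params.beta * tension_cols(X)
        e_after = e_before.copy()
        lam_try = np.minimum(1.0, lam * 1.5)
        pending = np.ones(M, dtype=bool)
        X_new = X.copy()
        for _ in range(15):
            cols = np.flatnonzero(pending)
            X_cand = project(X[:, cols] + lam_try[cols][None, :] * step[:, cols])
            F_cand = (sinc_basis(np.ravel(X_cand), L).T @ c).reshape(N, len(cols))
            e_cand = data_cols(F_cand, Y[:, cols]) + params.beta * tension_cols(X_cand)
            good = e_cand <= e_before[cols] + 1e-12 * (1.0 + np.abs(e_before[cols]))
            gcols = cols[good]
            X_new[:, gcols] = X_cand[:, good]
            e_after[gcols] = e_cand[good]
            pending[gcols] = False
            if not pending.any():
                break
            lam_try[pending] *= 0.5
            damping_events += int(pending.sum())
        if pending.any():
            logger.warning(
                "location step rejected for %d column(s) at iteration %d "
                "(energy would increase)",
                int(pending.sum()),
                it,
            )
        X = X_new
        lam = lam_try
        psi_c_term = params.alpha * float(c @ psi_L @ c)
        dat = e_after - params.beta * tension_cols(X)
        trace.append(
            float((omega * dat).sum()) + psi_c_term
            + params.beta * float(tension_cols(X).sum())
        )
        merit_trace.append(float(e_after.sum()) + psi_c_term)
        if keep_history:
            history.append(X.copy())
        if len(merit_trace) >= 2:
            prev = merit_trace[-2]
            if abs(merit_trace[-1] - prev) < params.tol * abs(prev) + 1e-15:
                break
    if damping_events:
        logger.info("location step damped %d time(s)", damping_events)
    state = AlignmentState(
        X=X,
        c=c,
        omega=omega,
        energy_trace=np.array(trace),
        iterations=it,
        c_tilde=c_tilde,
        damping_events=damping_events,
        omega_changes=omega_changes,
        X_history=history,
    )
    return state, IdealProfile(c=c, L=params.L, symmetric=params.symmetric)


def compensated_map(
    state: AlignmentState, matrix: ProfileMatrix | np.ndarray
) -> np.ndarray:
    """Resample every profile at its compensated locations onto the uniform grid.

    Column j of the result is the monotone (piecewise-linear) interpolation of
    the pairs (x*_{i,j}, y_{i,j}) evaluated at i/(N-1).  Outlier columns are
    retained (they are flagged in ``state.omega``).
    """
    Y = matrix.Y if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, dtype=float)
    X = state.X
    if np.any(np.diff(X, axis=0) < -1e-12):
        raise ValueError("non-monotone compensated locations")
    N, M = Y.shape
    grid = np.linspace(0.0, 1.0, N)
    out = np.empty_like(Y)
    for j in range(M):
        out[:, j] = np.interp(grid, X[:, j], Y[:, j])
    return out
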