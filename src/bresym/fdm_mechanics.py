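"""Explicit finite-difference solver for damped neo-Hookean dynamics.

The solver works directly on the image-space grid (no meshing): displacement
components live at every voxel/node, spatial derivatives are central
differences, and time integration is the conditionally stable explicit
scheme

    U^{n+1} = ((2 rho + h_t r) U^n - rho U^{n-1} + h_t^2 rho K^n)
              / (rho + h_t r)

with speed-proportional damping ``r`` and the acceleration-equivalent nodal
force ``K = (div_0 N) / rho_0 + f``. All solver quantities are SI (metres,
seconds, Pa, kg/m^3); the mm world of the image containers is converted at
the module boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "SimulationGrid",
    "DisplacementState",
    "KinematicsField",
    "SolverParams",
    "SpatialDerivatives",
    "StencilError",
    "ElementInversionError",
    "DivergenceError",
    "spatial_derivatives",
    "deformation_gradient",
    "neo_hookean_stress",
    "divergence_of_stress",
    "assemble_nodal_force",
    "explicit_step",
    "critical_time_step",
    "lame_lambda_from_mu",
    "boundary_mask",
]


class StencilError(ValueError):
    """Grid too small for the finite-difference stencils."""


class ElementInversionError(RuntimeError):
    """J <= 0 somewhere: the local mapping folded over.

    Usually means the time step or a constraint correction is too large.
    """

    def __init__(self, worst_index: tuple[int, ...], worst_j: float):
        self.worst_index = worst_index
        self.worst_j = worst_j
        super().__init__(
            f"element inversion: J = {worst_j:.4g} at node {worst_index}; "
            "reduce the time step or the correction speed"
        )


class DivergenceError(RuntimeError):
    """Non-finite values appeared in the state."""


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform axis-aligned node grid. ``spacing`` in metres."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.shape):
            raise StencilError(f"grid extent must be >= 3 per axis, got {self.shape}")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return tuple(1e3 * h for h in self.spacing)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class SolverParams:
    """Explicit-integration controls.

    damping:
        speed-proportional coefficient r (kg m^-3 s^-1); scalar or per-node
        field. ``None`` lets callers pick a near-critical default.
    safety:
        fraction of the critical CFL step actually used, in (0, 1).
    """

    damping: float | np.ndarray | None = None
    safety: float = 0.5
    max_steps: int = 20000

    def __post_init__(self) -> None:
        if not 0 < self.safety < 1:
            raise ValueError("safety factor must lie in (0, 1)")
        if self.damping is not None and np.any(np.asarray(self.damping) < 0):
            raise ValueError("damping must be >= 0")


@dataclass
class DisplacementState:
    """U at the current and previous time level, metres."""

    u: np.ndarray  # (3, nx, ny, nz)
    u_prev: np.ndarray
    h_t: float
    step: int = 0

    @classmethod
    def zeros(cls, grid: SimulationGrid, h_t: float) -> "DisplacementState":
        z = np.zeros((3, *grid.shape))
        return cls(u=z, u_prev=z.copy(), h_t=h_t)

    @property
    def speed(self) -> np.ndarray:
        """Nodal speed magnitude |U^n - U^{n-1}| / h_t (m/s)."""
        return np.sqrt(((self.u - self.u_prev) ** 2).sum(axis=0)) / self.h_t

    @property
    def max_speed(self) -> float:
        return float(self.speed.max())


@dataclass
class KinematicsField:
    """Deformation gradient F (and derived C, J) per node."""

    F: np.ndarray  # (3, 3, nx, ny, nz)
    J: np.ndarray  # (nx, ny, nz)

    @cached_property
    def C(self) -> np.ndarray:
        """Right Cauchy deformation tensor F^T F."""
        return np.einsum("ki...,kj...->ij...", self.F, self.F)


# ---------------------------------------------------------------------------
# stencils
# ---------------------------------------------------------------------------


@dataclass
class SpatialDerivatives:
    """first[c, a]  = d u_c / d X_a   (central, one-sided at the edges)
    second[c, a, b] = d^2 u_c / d X_a d X_b  (central / 4-point mixed;
    the one-voxel boundary layer is filled with zeros and is unused because
    boundary nodes are Dirichlet)."""

    first: np.ndarray  # (3, 3, nx, ny, nz)
    second: np.ndarray  # (3, 3, 3, nx, ny, nz)


def _check_grid(u: np.ndarray, grid: SimulationGrid) -> None:
    if u.shape != (3, *grid.shape):
        raise ValueError(f"field shape {u.shape} does not match grid {grid.shape}")
    if any(n < 3 for n in grid.shape):
        raise StencilError("grid extent must be >= 3 per axis")


def _first_derivatives(u: np.ndarray, spacing) -> np.ndarray:
    out = np.empty((3, 3, *u.shape[1:]))
    for c in range(3):
        grads = np.gradient(u[c], *spacing, edge_order=1)
        for a in range(3):
            out[c, a] = grads[a]
    return out


def _second_pure(a: np.ndarray, axis: int, h: float) -> np.ndarray:
    out = np.zeros_like(a)
    sl_c = [slice(None)] * 3
    sl_p = [slice(None)] * 3
    sl_m = [slice(None)] * 3
    sl_c[axis] = slice(1, -1)
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(None, -2)
    out[tuple(sl_c)] = (a[tuple(sl_p)] - 2 * a[tuple(sl_c)] + a[tuple(sl_m)]) / h**2
    return out


def _second_mixed(a: np.ndarray, ax1: int, ax2: int, h1: float, h2: float) -> np.ndarray:
    """4-point mixed stencil:
    (u_{+,+} + u_{-,-} - u_{-,+} - u_{+,-}) / (4 h1 h2)."""
    out = np.zeros_like(a)

    def sl(s1, s2):
        s = [slice(1, -1)] * 3
        s[ax1] = s1
        s[ax2] = s2
        return tuple(s)

    pp = sl(slice(2, None), slice(2, None))
    mm = sl(slice(None, -2), slice(None, -2))
    mp = sl(slice(None, -2), slice(2, None))
    pm = sl(slice(2, None), slice(None, -2))
    interior = sl(slice(1, -1), slice(1, -1))
    out[interior] = (a[pp] + a[mm] - a[mp] - a[pm]) / (4 * h1 * h2)
    return out


def spatial_derivatives(u: np.ndarray, grid: SimulationGrid) -> SpatialDerivatives:
    """All first and second partials of each displacement component."""
    _check_grid(u, grid)
    h = grid.spacing
    first = _first_derivatives(u, h)
    second = np.zeros((3, 3, 3, *grid.shape))
    for c in range(3):
        for a in range(3):
            second[c, a, a] = _second_pure(u[c], a, h[a])
            for b in range(a + 1, 3):
                m = _second_mixed(u[c], a, b, h[a], h[b])
                second[c, a, b] = m
                second[c, b, a] = m
    return SpatialDerivatives(first=first, second=second)


# ---------------------------------------------------------------------------
# kinematics and constitutive law
# ---------------------------------------------------------------------------


def _det3(F: np.ndarray) -> np.ndarray:
    return (
        F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
        - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
        + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
    )


def _inv3(F: np.ndarray, det: np.ndarray) -> np.ndarray:
    inv = np.empty_like(F)
    inv[0, 0] = F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]
    inv[0, 1] = F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]
    inv[0, 2] = F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]
    inv[1, 0] = F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]
    inv[1, 1] = F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]
    inv[1, 2] = F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]
    inv[2, 0] = F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]
    inv[2, 1] = F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]
    inv[2, 2] = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
    return inv / det


def deformation_gradient(u: np.ndarray, grid: SimulationGrid) -> KinematicsField:
    """F = I + du/dX from central first differences; J = det F."""
    _check_grid(u, grid)
    F = _first_derivatives(u, grid.spacing)
    for a in range(3):
        F[a, a] += 1.0
    return KinematicsField(F=F, J=_det3(F))


def _check_positive_j(J: np.ndarray) -> None:
    if J.min() <= 0:
        worst = np.unravel_index(int(np.argmin(J)), J.shape)
        raise ElementInversionError(tuple(int(i) for i in worst), float(J.min()))


def neo_hookean_stress(
    kin: KinematicsField,
    mu_field: np.ndarray | float,
    lambda_field: np.ndarray | float,
) -> np.ndarray:
    """Nominal stress N = (mu (I - C^-1) + lambda ln J C^-1) F^T per node.

    Evaluated as the transpose of the first Piola-Kirchhoff stress
    P = mu (F - F^-T) + lambda ln J F^-T, which is algebraically identical
    and needs one 3x3 inverse instead of two.
    """
    F, J = kin.F, kin.J
    _check_positive_j(J)
    Finv = _inv3(F, J)
    FinvT = np.swapaxes(Finv, 0, 1)
    mu = np.asarray(mu_field)
    lam = np.asarray(lambda_field)
    logJ = np.log(J)
    P = mu * (F - FinvT) + (lam * logJ) * FinvT
    return np.swapaxes(P, 0, 1)  # N = P^T


def linear_elastic_stress(
    grad_u: np.ndarray,
    mu_field: np.ndarray | float,
    lambda_field: np.ndarray | float,
) -> np.ndarray:
    """Small-strain (Hookean) stress sigma = mu (G + G^T) + lambda tr(G) I
    with G = du/dX. Used for the background medium: it has no inversion
    singularity, so heavily compressed 'air' stays numerically regular."""
    mu = np.asarray(mu_field)
    lam = np.asarray(lambda_field)
    sym = grad_u + np.swapaxes(grad_u, 0, 1)
    trace = grad_u[0, 0] + grad_u[1, 1] + grad_u[2, 2]
    N = mu * sym
    for a in range(3):
        N[a, a] += lam * trace
    return N


def divergence_of_stress(N: np.ndarray, grid: SimulationGrid) -> np.ndarray:
    """(div_0 N)_i = sum_j dN_{ji} / dX_j, central differences per component."""
    div = np.zeros((3, *grid.shape))
    for i in range(3):
        for j in range(3):
            div[i] += np.gradient(N[j, i], grid.spacing[j], axis=j, edge_order=1)
    return div


def assemble_nodal_force(
    u: np.ndarray,
    grid: SimulationGrid,
    mu_field: np.ndarray | float,
    lambda_field: np.ndarray | float,
    rho_field: np.ndarray | float,
    body_force: np.ndarray | float = 0.0,
    hyperelastic_mask: np.ndarray | None = None,
) -> np.ndarray:
    """K = (div_0 N) / rho_0 + f  (m/s^2 per node).

    With a ``hyperelastic_mask``, the neo-Hookean law applies only inside the
    mask (tissue/chest) and the background medium outside carries the
    inversion-free linear-elastic stress; the J > 0 requirement is then only
    enforced where the hyperelastic law is evaluated.
    """
    kin = deformation_gradient(u, grid)
    if hyperelastic_mask is None:
        N = neo_hookean_stress(kin, mu_field, lambda_field)
    else:
        grad_u = kin.F.copy()
        for a in range(3):
            grad_u[a, a] -= 1.0
        N = linear_elastic_stress(grad_u, mu_field, lambda_field)
        mask = np.asarray(hyperelastic_mask, dtype=bool)
        if mask.any():
            J_sub = kin.J[mask]
            if J_sub.min() <= 0:
                worst_flat = np.argwhere(mask)[int(np.argmin(J_sub))]
                raise ElementInversionError(
                    tuple(int(i) for i in worst_flat), float(J_sub.min())
                )
            kin_sub = KinematicsField(F=kin.F[:, :, mask], J=J_sub)

            def sub(field):
                arr = np.asarray(field)
                return arr[mask] if arr.ndim == 3 else arr

            N[:, :, mask] = neo_hookean_stress(
                kin_sub, sub(mu_field), sub(lambda_field)
            )
    K = divergence_of_stress(N, grid) / np.asarray(rho_field)
    K = K + np.asarray(body_force)
    return K


def explicit_step(
    state: DisplacementState,
    K: np.ndarray,
    rho_field: np.ndarray | float,
    damping: np.ndarray | float,
    dirichlet: np.ndarray | None = None,
) -> DisplacementState:
    """Advance one explicit step (the scheme above), in place of the oldest
    level; Dirichlet nodes are forced to zero displacement."""
    rho = np.asarray(rho_field)
    r = np.asarray(damping)
    h_t = state.h_t
    num = (2 * rho + h_t * r) * state.u - rho * state.u_prev + h_t**2 * rho * K
    u_next = num / (rho + h_t * r)
    if dirichlet is not None:
        u_next[:, dirichlet] = 0.0
    if not np.isfinite(u_next).all():
        raise DivergenceError(
            "non-finite displacement: reduce the time step or increase damping"
        )
    return DisplacementState(u=u_next, u_prev=state.u, h_t=h_t, step=state.step + 1)


def critical_time_step(
    mu_field: np.ndarray | float,
    lambda_field: np.ndarray | float,
    rho_field: np.ndarray | float,
    grid: SimulationGrid,
    safety: float = 0.5,
) -> float:
    """CFL-type bound: h_t = safety * min(h) / c_d, with the dilatational wave
    speed c_d = sqrt((lambda + 2 mu) / rho) taken at the stiffest/lightest
    node: c_d = sqrt(max(lambda + 2 mu) / min(rho)). The density minimum and
    stiffness maximum are combined because, at a material interface, the
    stress of the stiff side accelerates nodes of the light side."""
    mu = np.asarray(mu_field, dtype=float)
    lam = np.asarray(lambda_field, dtype=float)
    rho = np.asarray(rho_field, dtype=float)
    stiff = lam + 2 * mu
    if np.all(stiff == 0):
        raise ValueError("all-zero stiffness: dilatational wave speed undefined")
    c_max = float(np.sqrt(stiff.max() / rho.min()))
    return safety * min(grid.spacing) / c_max


def lame_lambda_from_mu(mu: np.ndarray | float, poisson: float = 0.49):
    """First Lame parameter from the shear modulus at fixed Poisson ratio."""
    if not -1 < poisson < 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5)")
    return 2.0 * np.asarray(mu) * poisson / (1.0 - 2.0 * poisson)


def boundary_mask(shape: tuple[int, int, int], width: int = 1) -> np.ndarray:
    """Boolean mask of the outermost ``width`` node layers (Dirichlet)."""
    mask = np.zeros(shape, dtype=bool)
    w = width
    mask[:w, :, :] = mask[-w:, :, :] = True
    mask[:, :w, :] = mask[:, -w:, :] = True
    mask[:, :, :w] = mask[:, :, -w:] = True
    return mask
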