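"""Analytic 2-D model potential-energy surfaces and differential operators.

These surfaces stand in for an electronic-structure engine in the
reaction-path pipeline: two dimensions is the smallest space in which a
first-order saddle point — the 2-D analogue of a transition state with one
imaginary vibrational frequency — exists, so the whole NEB / climbing-image
/ saddle-verification machinery can be exercised and validated at desk
scale.

Two surfaces are registered:

``sn2``
    A double-well quartic along the reaction coordinate x with a harmonic
    transverse channel, V = V0·(x²−1)² + asym·x + ½·k·(y−c·x)².  With
    asym = 0 and c = 0 it is exactly symmetric: minima at (±1, 0) with
    V = 0 and a saddle at the origin with V = V0, so the barrier is V0 in
    closed form — a controllable stand-in for a symmetric SN2 profile.

``muller_brown``
    The standard Müller–Brown benchmark surface (sum of four anisotropic
    Gaussian-exponential wells), with its literature constants fixed as
    module constants.  Its three minima and two saddles are located here
    by a dense-grid + Newton oracle, never hard-coded.

Energies are in dimensionless model units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelPES",
    "SN2Surrogate",
    "MullerBrown",
    "StationaryPointInfo",
    "numerical_gradient",
    "numerical_hessian",
    "find_stationary_points",
    "get_pes",
    "PES_REGISTRY",
]


class ModelPES:
    """Interface: scalar energy and analytic 2-vector gradient on R²."""

    name: str = "pes"

    def energy(self, p) -> float:
        raise NotImplementedError

    def gradient(self, p) -> np.ndarray:
        raise NotImplementedError


@dataclass
class SN2Surrogate(ModelPES):
    """Double-well quartic with a transverse harmonic channel.

    V(x, y) = V0·(x²−1)² + asym·x + ½·k·(y − c·x)²

    Parameters: V0 > 0 the symmetric barrier height, asym a linear tilt
    (makes forward and reverse barriers differ), k > 0 the transverse
    stiffness, c a coupling that shears the valley floor off the x-axis.
    For small |asym| the two minima sit near x = ±1.
    """

    V0: float = 15.4
    asym: float = 0.0
    k: float = 1.0
    c: float = 0.0
    name: str = "sn2"

    def __post_init__(self) -> None:
        if self.V0 <= 0 or self.k <= 0:
            raise ValueError(f"require V0 > 0 and k > 0, got V0={self.V0}, k={self.k}")

    def energy(self, p) -> float:
        x, y = float(p[0]), float(p[1])
        t = y - self.c * x
        return self.V0 * (x * x - 1.0) ** 2 + self.asym * x + 0.5 * self.k * t * t

    def gradient(self, p) -> np.ndarray:
        x, y = float(p[0]), float(p[1])
        t = y - self.c * x
        gx = 4.0 * self.V0 * x * (x * x - 1.0) + self.asym - self.k * self.c * t
        gy = self.k * t
        return np.array([gx, gy])


# Literature-standard Müller-Brown constants.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


@dataclass
class MullerBrown(ModelPES):
    """The Müller–Brown surface, the standard 2-D path-method benchmark.

    V(x, y) = Σᵢ Aᵢ exp(aᵢ(x−xᵢ⁰)² + bᵢ(x−xᵢ⁰)(y−yᵢ⁰) + cᵢ(y−yᵢ⁰)²)

    with the four-term constant set fixed above.  Three minima, two
    first-order saddles, all inside the box x ∈ [−1.7, 1.3], y ∈ [−0.4, 2.1].
    """

    name: str = "muller_brown"

    def _terms(self, x: float, y: float) -> np.ndarray:
        dx = x - _MB_x0
        dy = y - _MB_y0
        return _MB_A * np.exp(_MB_a * dx * dx + _MB_b * dx * dy + _MB_c * dy * dy)

    def energy(self, p) -> float:
        return float(np.sum(self._terms(float(p[0]), float(p[1]))))

    def gradient(self, p) -> np.ndarray:
        x, y = float(p[0]), float(p[1])
        dx = x - _MB_x0
        dy = y - _MB_y0
        terms = self._terms(x, y)
        gx = np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy))
        gy = np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy))
        return np.array([gx, gy])


PES_REGISTRY = {"sn2": SN2Surrogate, "muller_brown": MullerBrown}


def get_pes(name: str, **params) -> ModelPES:
    """Instantiate a registered surface by name with parameter overrides."""
    try:
        cls = PES_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown PES {name!r}; registered: {sorted(PES_REGISTRY)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------------
# Numerical differential operators

# Default steps balance truncation against round-off for double precision.
GRADIENT_STEP = 1e-5
HESSIAN_STEP = 1e-4


def numerical_gradient(pes: ModelPES, point, h: float = GRADIENT_STEP) -> np.ndarray:
    """Central-difference gradient, O(h²) accurate."""
    if h <= 0:
        raise ValueError(f"step must be positive, got {h}")
    p = np.asarray(point, dtype=float)
    g = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        g[i] = (pes.energy(p + e) - pes.energy(p - e)) / (2.0 * h)
    return g


def numerical_hessian(
    pes: ModelPES, point, h: float = HESSIAN_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric central-difference Hessian and its eigenvalues (ascending).

    The off-diagonal element uses the four-point cross stencil; the matrix
    is symmetric by construction, so eigenvalues are real.
    """
    if h <= 0:
        raise ValueError(f"step must be positive, got {h}")
    p = np.asarray(point, dtype=float)
    e0 = pes.energy(p)
    H = np.empty((2, 2))
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h
        H[i, i] = (pes.energy(p + ei) - 2.0 * e0 + pes.energy(p - ei)) / (h * h)
    ex = np.array([h, 0.0])
    ey = np.array([0.0, h])
    H[0, 1] = H[1, 0] = (
        pes.energy(p + ex + ey)
        - pes.energy(p + ex - ey)
        - pes.energy(p - ex + ey)
        + pes.energy(p - ex - ey)
    ) / (4.0 * h * h)
    eigvals = np.linalg.eigvalsh(H)
    return H, eigvals


# ---------------------------------------------------------------------------
# Dense-grid + Newton stationary-point oracle


@dataclass
class StationaryPointInfo:
    location: np.ndarray
    energy: float
    eigenvalues: np.ndarray
    kind: str  # "minimum", "saddle", "maximum"


def _newton_polish(pes: ModelPES, p0: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 50) -> np.ndarray | None:
    """Newton iteration on the gradient; None if it wanders or stalls."""
    p = p0.copy()
    for _ in range(max_iter):
        g = pes.gradient(p)
        if np.linalg.norm(g) < tol:
            return p
        H, _ = numerical_hessian(pes, p)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return None
        if np.linalg.norm(step) > 0.5:  # diverging from the basin
            return None
        p = p + step
    return None


def find_stationary_points(
    pes: ModelPES,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    n_grid: int = 400,
    grad_tol: float = 1e-8,
) -> list[StationaryPointInfo]:
    """Locate all stationary points in a box by brute force.

    Scans an n_grid × n_grid lattice for local minima of the gradient
    norm, polishes each candidate by Newton iteration, deduplicates, and
    classifies by Hessian eigenvalues.  Deliberately exhaustive and
    independent of any path-optimization machinery — this is the oracle
    the NEB results are validated against.
    """
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    xs = np.linspace(x_lo, x_hi, n_grid)
    ys = np.linspace(y_lo, y_hi, n_grid)
    gnorm = np.empty((n_grid, n_grid))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            gnorm[i, j] = np.linalg.norm(pes.gradient((x, y)))
    found: list[StationaryPointInfo] = []
    interior = gnorm[1:-1, 1:-1]
    is_local_min = np.ones_like(interior, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neighbor = gnorm[1 + di : n_grid - 1 + di, 1 + dj : n_grid - 1 + dj]
            is_local_min &= interior <= neighbor
    for i, j in zip(*np.nonzero(is_local_min)):
        p0 = np.array([xs[i + 1], ys[j + 1]])
        p = _newton_polish(pes, p0, tol=grad_tol)
        if p is None:
            continue
        if not (x_lo - 0.1 <= p[0] <= x_hi + 0.1 and y_lo - 0.1 <= p[1] <= y_hi + 0.1):
            continue
        if any(np.linalg.norm(p - f.location) < 1e-4 for f in found):
            continue
        _, eigvals = numerical_hessian(pes, p)
        n_neg = int(np.sum(eigvals < 0))
        kind = {0: "minimum", 1: "saddle", 2: "maximum"}[n_neg]
        found.append(
            StationaryPointInfo(
                location=p, energy=pes.energy(p), eigenvalues=eigvals, kind=kind
            )
        )
    found.sort(key=lambda s: s.energy)
    return found
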