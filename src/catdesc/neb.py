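"""Nudged-elastic-band path optimization with climbing-image refinement.

The pipeline mirrors how transition states are located along enzyme
reaction paths: interpolate a chain of images between the reactant and
product minima, relax it with the NEB force projection (true force
perpendicular to the path tangent, spring force along it), switch the
highest image to climbing mode so it converges onto the saddle exactly,
verify the saddle by its gradient norm and Hessian spectrum (exactly one
negative eigenvalue — the 2-D analogue of one imaginary vibrational
frequency), and finally relocate the path endpoints by displacing along
the unstable mode and quenching downhill to the two connected minima.

Implementation choices: the improved (energy-weighted) tangent estimate,
which avoids the kinked paths of the original bisection tangent, and a
FIRE-type quenched-velocity minimizer with a capped step.  Plain
steepest descent is available for debugging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pes_models import ModelPES, numerical_hessian

__all__ = [
    "NEBConfig",
    "NEBPath",
    "SaddleReport",
    "NEBError",
    "interpolate_path",
    "neb_optimize",
    "locate_ts",
    "verify_saddle",
    "relocate_endpoints",
    "barrier_from_path",
]


class NEBError(ValueError):
    """Invalid path or configuration for NEB operations."""


@dataclass
class NEBConfig:
    """Band and optimizer settings.

    n_images counts both fixed endpoints.  Convergence requires the
    maximum per-image NEB force norm below max_force_tol; the climbing
    image additionally converges its full (unprojected) gradient.
    Climbing activates only once the plain band has reached
    climb_activation_factor × max_force_tol, so the climber never runs on
    an unequilibrated band.  The FIRE parameters are the standard set;
    max_step caps any single image displacement.  seed feeds any
    randomized restart and is recorded for reproducibility (the default
    optimizer is fully deterministic).
    """

    n_images: int = 12
    spring_k: float = 1.0
    max_force_tol: float = 1e-3
    max_iter: int = 5000
    climbing: bool = True
    climb_activation_factor: float = 10.0
    dt_init: float = 0.02
    dt_max: float = 0.2
    max_step: float = 0.05
    minimizer: str = "fire"  # or "sd" (plain steepest descent)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 4:
            raise NEBError(f"n_images must be >= 4, got {self.n_images}")
        if self.max_force_tol <= 0 or self.spring_k <= 0:
            raise NEBError("tolerances and spring constant must be positive")
        if self.minimizer not in ("fire", "sd"):
            raise NEBError(f"minimizer must be 'fire' or 'sd', got {self.minimizer!r}")


@dataclass
class NEBPath:
    """A discretized path: images (n, 2), per-image energies, and state."""

    images: np.ndarray
    energies: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    iterations: int = 0
    max_force_history: list[float] = field(default_factory=list)
    climbing_index: int | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 2 or self.images.shape[1] != 2:
            raise NEBError(f"images must be (n, 2), got {self.images.shape}")

    @property
    def n_images(self) -> int:
        return len(self.images)


def interpolate_path(start, end, n_images: int) -> NEBPath:
    """Linear interpolation between two endpoints, evenly spaced."""
    if n_images < 4:
        raise NEBError(f"n_images must be >= 4, got {n_images}")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.allclose(start, end):
        raise NEBError("start and end must differ")
    frac = np.linspace(0.0, 1.0, n_images)[:, None]
    images = (1.0 - frac) * start[None, :] + frac * end[None, :]
    images[0] = start  # endpoints bit-exact
    images[-1] = end
    return NEBPath(images=images)


def _tangents(images: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Improved (energy-weighted) tangent estimate, normalized, per interior image."""
    n = len(images)
    tau = np.zeros_like(images)
    for i in range(1, n - 1):
        d_fwd = images[i + 1] - images[i]
        d_back = images[i] - images[i - 1]
        e_prev, e_i, e_next = energies[i - 1], energies[i], energies[i + 1]
        if e_next > e_i > e_prev:
            t = d_fwd
        elif e_next < e_i < e_prev:
            t = d_back
        else:
            d_max = max(abs(e_next - e_i), abs(e_prev - e_i))
            d_min = min(abs(e_next - e_i), abs(e_prev - e_i))
            if e_next > e_prev:
                t = d_fwd * d_max + d_back * d_min
            else:
                t = d_fwd * d_min + d_back * d_max
        norm = np.linalg.norm(t)
        tau[i] = t / norm if norm > 0 else t
    return tau


def _neb_forces(
    pes: ModelPES,
    images: np.ndarray,
    spring_k: float,
    climb_index: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Projected NEB forces on all images (endpoints zero) and energies."""
    n = len(images)
    energies = np.array([pes.energy(p) for p in images])
    grads = np.array([pes.gradient(p) for p in images])
    tau = _tangents(images, energies)
    forces = np.zeros_like(images)
    for i in range(1, n - 1):
        t = tau[i]
        g = grads[i]
        if i == climb_index:
            # Climbing image: invert the parallel component, no springs.
            forces[i] = -g + 2.0 * np.dot(g, t) * t
            continue
        f_perp = -(g - np.dot(g, t) * t)
        ell_fwd = np.linalg.norm(images[i + 1] - images[i])
        ell_back = np.linalg.norm(images[i] - images[i - 1])
        f_spring = spring_k * (ell_fwd - ell_back) * t
        forces[i] = f_perp + f_spring
    return forces, energies


def neb_optimize(pes: ModelPES, path: NEBPath, config: NEBConfig) -> NEBPath:
    """Relax a band until the maximum NEB force norm drops below tolerance.

    Returns a new NEBPath; endpoints are never moved.  Non-convergence
    within max_iter is reported through converged=False, not an exception.
    With climbing enabled, the returned path's climbing_index marks the
    image that converged onto the saddle (its full gradient norm is below
    tolerance on success).
    """
    images = path.images.copy()
    n = len(images)
    if n < 4:
        raise NEBError(f"need >= 4 images, got {n}")
    start, end = images[0].copy(), images[-1].copy()

    velocity = np.zeros_like(images)
    dt = config.dt_init
    alpha = 0.1
    n_uphill = 0
    # Standard FIRE constants.
    f_inc, f_dec, alpha_start, f_alpha, n_min = 1.1, 0.5, 0.1, 0.99, 5

    climb_index: int | None = None
    history: list[float] = []
    converged = False
    iteration = 0
    energies = np.array([pes.energy(p) for p in images])

    for iteration in range(1, config.max_iter + 1):
        forces, energies = _neb_forces(pes, images, config.spring_k, climb_index)
        max_force = float(np.max(np.linalg.norm(forces[1:-1], axis=1)))
        history.append(max_force)

        if config.climbing and climb_index is None:
            if max_force < config.climb_activation_factor * config.max_force_tol:
                interior = np.argmax(energies[1:-1]) + 1
                climb_index = int(interior)
                continue  # recompute forces with the climber active

        if max_force < config.max_force_tol:
            if not config.climbing or climb_index is not None:
                converged = True
                break

        if config.minimizer == "sd":
            step = dt * forces
        else:
            power = float(np.sum(forces * velocity))
            if power > 0.0:
                fnorm = np.linalg.norm(forces)
                vnorm = np.linalg.norm(velocity)
                if fnorm > 0:
                    velocity = (1.0 - alpha) * velocity + alpha * vnorm * forces / fnorm
                n_uphill += 1
                if n_uphill > n_min:
                    dt = min(dt * f_inc, config.dt_max)
                    alpha *= f_alpha
            else:
                velocity[:] = 0.0
                dt *= f_dec
                alpha = alpha_start
                n_uphill = 0
            velocity += dt * forces
            step = dt * velocity

        lengths = np.linalg.norm(step, axis=1)
        too_big = lengths > config.max_step
        if np.any(too_big):
            step[too_big] *= (config.max_step / lengths[too_big])[:, None]
        step[0] = 0.0
        step[-1] = 0.0
        images += step

    images[0] = start
    images[-1] = end
    energies = np.array([pes.energy(p) for p in images])
    return NEBPath(
        images=images,
        energies=energies,
        converged=converged,
        iterations=iteration,
        max_force_history=history,
        climbing_index=climb_index,
    )


def locate_ts(path: NEBPath) -> int:
    """Index (0-based) of the interior energy maximum along the path.

    A maximum sitting on an endpoint means the band found no interior
    barrier and raises.  Exact ties break toward the lowest index with a
    warning.
    """
    if path.n_images < 3:
        raise NEBError(f"need >= 3 images to locate a TS, got {path.n_images}")
    if len(path.energies) != path.n_images:
        raise NEBError("path has no per-image energies; optimize it first")
    e = path.energies
    i_max = int(np.argmax(e))
    if i_max in (0, path.n_images - 1):
        raise NEBError(
            "no interior barrier: the energy maximum sits on an endpoint"
        )
    if np.sum(e == e[i_max]) > 1:
        warnings.warn(
            "multiple images share the maximum energy; using the lowest index",
            stacklevel=2,
        )
    return i_max


@dataclass
class SaddleReport:
    """Saddle verdict at a point: gradient norm plus Hessian spectrum."""

    location: np.ndarray
    energy: float
    eigenvalues: np.ndarray
    gradient_norm: float
    is_saddle: bool


def verify_saddle(pes: ModelPES, point, tol: float = 1e-3) -> SaddleReport:
    """Check the first-order-saddle criterion at a point.

    is_saddle is True iff the gradient norm is below tol and the Hessian
    has exactly one negative eigenvalue — the configuration-space analogue
    of a transition state with a single imaginary frequency.  The report
    always carries the evidence; no exception for a failed verdict.
    """
    p = np.asarray(point, dtype=float)
    g = pes.gradient(p)
    _, eigvals = numerical_hessian(pes, p)
    gnorm = float(np.linalg.norm(g))
    n_neg = int(np.sum(eigvals < 0))
    return SaddleReport(
        location=p,
        energy=pes.energy(p),
        eigenvalues=eigvals,
        gradient_norm=gnorm,
        is_saddle=(gnorm < tol and n_neg == 1),
    )


def relocate_endpoints(
    pes: ModelPES,
    saddle,
    displacement: float = 0.1,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Displace off a saddle along its unstable mode and quench to the minima.

    The two returned points are the minima the saddle connects, in the
    order (negative-mode direction, positive-mode direction); flipping the
    displacement sign swaps them.  Each quenched point has gradient norm
    below tol, otherwise the quench is reported as failed.
    """
    p = np.asarray(saddle, dtype=float)
    _, eigvals = numerical_hessian(pes, p)
    if eigvals[0] >= 0:
        raise NEBError(
            f"point {p} has no negative Hessian eigenvalue; not a saddle"
        )
    H, _ = numerical_hessian(pes, p)
    w, V = np.linalg.eigh(H)
    mode = V[:, 0]  # eigenvector of the most negative eigenvalue

    def _quench(p0: np.ndarray, max_disp: float = 0.01) -> np.ndarray:
        # Capped-step steepest descent follows the gradient-flow line into
        # the *adjacent* basin (a quasi-Newton minimizer can hop over a
        # shallow intermediate minimum), then Newton polish to tolerance.
        q = p0.copy()
        dt = 2e-3
        for _ in range(100_000):
            g = pes.gradient(q)
            gnorm = np.linalg.norm(g)
            _, eigs = numerical_hessian(pes, q)
            if gnorm < 1.0 and eigs[0] > 0:  # safely inside a basin
                break
            step = dt * gnorm
            q = q - (min(step, max_disp) / max(gnorm, 1e-300)) * g
        for _ in range(50):
            g = pes.gradient(q)
            if np.linalg.norm(g) < tol:
                return q
            Hq, _ = numerical_hessian(pes, q)
            try:
                q = q + np.linalg.solve(Hq, -g)
            except np.linalg.LinAlgError:
                break
        g = np.linalg.norm(pes.gradient(q))
        if g >= tol:
            raise NEBError(
                f"quench from {p0} did not converge: gradient norm {g:.2e} >= {tol}"
            )
        return q

    lo = _quench(p - displacement * mode)
    hi = _quench(p + displacement * mode)
    return lo, hi


def barrier_from_path(path: NEBPath, reference: str = "start") -> float:
    """Barrier height E(TS image) − E(reference endpoint).

    For an asymmetric profile the forward and reverse barriers differ by
    exactly the endpoint energy gap.
    """
    if reference not in ("start", "end"):
        raise ValueError(f"reference must be 'start' or 'end', got {reference!r}")
    i_ts = locate_ts(path)
    e_ref = path.energies[0] if reference == "start" else path.energies[-1]
    return float(path.energies[i_ts] - e_ref)
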