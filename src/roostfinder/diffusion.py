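"""Forward model: diffusive dispersal from a roost and detector-level detection.

Bats are modelled as diffusing agents released at the roost ``z`` at sunset,
so the position density at time ``t`` is the 2-D Gaussian heat kernel

    phi(x, y; z, t) = 1/(4 pi D t) * exp(-((x-z_x)^2 + (y-z_y)^2) / (4 D t)).

A detector at ``X_i`` hears a bat anywhere inside a disk ``Omega_i`` of radius
``r`` (~15 m for greater horseshoe bats), so the instantaneous detection
probability is the integral of ``phi`` over the disk,

    P_i(z, t) = int_{Omega_i} phi dA,

and the expected number of passes per bat over the post-sunset window [0, T]
is ``E_i(z) = int_0^T P_i(z, t) dt`` (the colony size cancels once detector
values are normalised into proportions ``F_i = E_i / sum_j E_j``).

Because the kernel is nearly constant across a 15 m disk except very close to
the roost, the disk integral admits the cheap algebraic approximation

    P_i ~= r^2/(4 D t) * exp(-d_i^2 / (4 D t)),     d_i = |X_i - z|,

(the kernel value at the detector centre times the disk area), clamped to
[0, 1] since it diverges as t -> 0 at d = 0.  The time integral has no
elementary antiderivative, so Simpson's rule is used in both exact and
approximate modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the dispersal and detection model.

    Attributes
    ----------
    D : float
        Diffusion coefficient, m^2/s.  Default 80, fitted from radio-tracking
        mean-squared-displacement curves for greater horseshoe bats.
    T : float
        Integration horizon in seconds.  Default 5400 s = the 90 min
        post-sunset window in which movement is diffusive.
    detector_radius : float
        Radius of the circular detection footprint, m.  Default 15.
    time_steps : int
        Simpson nodes for the time integral (odd, >= 3).  Default 501.
    radial_nodes, angular_nodes : int
        Gauss-Legendre x uniform-angle tensor rule for the exact disk
        integral.  Defaults 16 x 32.
    """

    D: float = 80.0
    T: float = 5400.0
    detector_radius: float = 15.0
    time_steps: int = 501
    radial_nodes: int = 16
    angular_nodes: int = 32

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be positive")
        if self.T <= 0:
            raise ValueError("horizon T must be positive")
        if self.detector_radius <= 0:
            raise ValueError("detector_radius must be positive")
        if self.time_steps < 3 or self.time_steps % 2 == 0:
            raise ValueError("time_steps must be an odd integer >= 3 (Simpson)")


CandidateRoost = tuple[float, float]


def density(x, y, roost: CandidateRoost, t, params: DiffusionParams):
    """Dispersal density phi(x, y; z, t) in m^-2.  Vectorised over x, y, t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("density requires t > 0 (delta initial condition at t = 0)")
    zx, zy = roost
    d2 = (np.asarray(x, float) - zx) ** 2 + (np.asarray(y, float) - zy) ** 2
    return np.exp(-d2 / (4.0 * params.D * t)) / (4.0 * math.pi * params.D * t)


def prob_beyond_radius(R: float, params: DiffusionParams, t: float | None = None) -> float:
    """Probability a diffusing agent is farther than ``R`` from the roost at
    time ``t`` (default: the horizon T): the Gaussian tail exp(-R^2/(4 D t))."""
    if R < 0:
        raise ValueError("R must be non-negative")
    t = params.T if t is None else t
    if t <= 0:
        raise ValueError("t must be positive")
    return float(np.exp(-(R * R) / (4.0 * params.D * t)))


def disk_quadrature(params: DiffusionParams) -> tuple[np.ndarray, np.ndarray]:
    """Tensor quadrature for the detection disk: Gauss-Legendre nodes in
    radius (with the polar Jacobian folded into the weights) crossed with
    uniformly spaced angles.

    Returns (offsets, weights): ``offsets`` is (K, 2) of displacements from
    the disk centre, and ``sum(weights * f(centre + offsets))`` approximates
    the integral of f over the disk (weights sum to pi r^2).
    """
    r = params.detector_radius
    nodes, gl_w = np.polynomial.legendre.leggauss(params.radial_nodes)
    radii = 0.5 * r * (nodes + 1.0)
    rad_w = 0.5 * r * gl_w * radii  # includes Jacobian r'
    theta = 2.0 * math.pi * np.arange(params.angular_nodes) / params.angular_nodes
    ang_w = 2.0 * math.pi / params.angular_nodes
    offsets = np.stack(
        [
            np.outer(radii, np.cos(theta)).ravel(),
            np.outer(radii, np.sin(theta)).ravel(),
        ],
        axis=1,
    )
    weights = np.repeat(rad_w, params.angular_nodes) * ang_w
    return offsets, weights


def detection_prob_exact(
    detector_pos, roost: CandidateRoost, t, params: DiffusionParams
):
    """P_i(z, t): integral of the dispersal density over the detector disk,
    by polar quadrature.  Vectorised over t; result in [0, 1].

    At d = 0 this matches the centred-disk closed form
    1 - exp(-r^2 / (4 D t)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("detection probability requires t > 0")
    offsets, weights = disk_quadrature(params)
    pos = np.asarray(detector_pos, dtype=float)
    pts = pos[None, :] + offsets  # (K, 2)
    d2 = (pts[:, 0] - roost[0]) ** 2 + (pts[:, 1] - roost[1]) ** 2
    four_dt = 4.0 * params.D * t
    # shape (K,) x t-shape -> broadcast over a new leading axis
    vals = np.exp(-d2.reshape((-1,) + (1,) * t.ndim) / four_dt) / (math.pi * four_dt)
    out = np.tensordot(weights, vals, axes=(0, 0))
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


def detection_prob_centred_closed_form(t, params: DiffusionParams):
    """Closed form 1 - exp(-r^2/(4 D t)) for a disk centred on the roost."""
    t = np.asarray(t, dtype=float)
    r = params.detector_radius
    return 1.0 - np.exp(-(r * r) / (4.0 * params.D * t))


def detection_prob_approx(
    detector_pos, roost: CandidateRoost, t, params: DiffusionParams
):
    """Algebraic approximation P~_i = r^2/(4 D t) * exp(-d^2/(4 D t)),
    clamped to [0, 1].  Vectorised over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("detection probability requires t > 0")
    pos = np.asarray(detector_pos, dtype=float)
    d2 = (pos[0] - roost[0]) ** 2 + (pos[1] - roost[1]) ** 2
    four_dt = 4.0 * params.D * t
    raw = (params.detector_radius**2 / four_dt) * np.exp(-d2 / four_dt)
    out = np.clip(raw, 0.0, 1.0)
    return out if out.ndim else float(out)


def _simpson_weights(n: int, h: float) -> np.ndarray:
    """Composite Simpson weights for n (odd) uniformly spaced nodes."""
    if n < 3 or n % 2 == 0:
        raise ValueError("Simpson's rule needs an odd number of nodes >= 3")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def _time_nodes(params: DiffusionParams, time_steps: int | None):
    n = params.time_steps if time_steps is None else int(time_steps)
    if n < 3 or n % 2 == 0:
        raise ValueError("time_steps must be an odd integer >= 3 (Simpson)")
    t = np.linspace(0.0, params.T, n)
    w = _simpson_weights(n, t[1] - t[0])
    return t, w


def expected_calls(
    detector_pos,
    roost: CandidateRoost,
    params: DiffusionParams,
    mode: str = "approx",
    time_steps: int | None = None,
) -> float:
    """Expected passes per bat, E_i(z) = int_0^T P_i(z, t) dt, by Simpson's
    rule on a uniform time grid.

    The integrand at t = 0 is taken as its analytic limit: 0 for a detector
    away from the roost, and the clamped value 1 when the detector centre
    coincides with the roost.
    """
    E = expected_calls_matrix(
        np.asarray(roost, float)[None, :],
        np.asarray(detector_pos, float)[None, :],
        params,
        mode=mode,
        time_steps=time_steps,
    )
    return float(E[0, 0])


def expected_calls_matrix(
    roosts: np.ndarray,
    detector_positions: np.ndarray,
    params: DiffusionParams,
    mode: str = "approx",
    time_steps: int | None = None,
    cell_chunk: int = 20000,
) -> np.ndarray:
    """E_i(z) for every candidate roost x detector pair.

    Parameters
    ----------
    roosts : (M, 2) candidate roost positions (e.g. grid cell centres).
    detector_positions : (N, 2).
    mode : "approx" (algebraic kernel, the fast default) or "exact"
        (disk quadrature at every time node).

    Returns
    -------
    (M, N) array of expected passes per bat over [0, T].
    """
    if mode not in ("approx", "exact"):
        raise ValueError(f"mode must be 'approx' or 'exact', got {mode!r}")
    roosts = np.atleast_2d(np.asarray(roosts, dtype=float))
    X = np.atleast_2d(np.asarray(detector_positions, dtype=float))
    t, w = _time_nodes(params, time_steps)
    M, N = roosts.shape[0], X.shape[0]
    E = np.empty((M, N))
    r2 = params.detector_radius**2
    if mode == "exact":
        offsets, qw = disk_quadrature(params)
        cell_chunk = min(cell_chunk, max(1, 400 * 20000 // (N * len(qw))))
        qpts = X[:, None, :] + offsets[None, :, :]  # (N, K, 2)
    for lo in range(0, M, cell_chunk):
        Z = roosts[lo : lo + cell_chunk]  # (m, 2)
        d2 = ((Z[:, None, :] - X[None, :, :]) ** 2).sum(-1)  # (m, N)
        acc = np.zeros_like(d2)
        if mode == "approx":
            for tk, wk in zip(t[1:], w[1:]):
                four_dt = 4.0 * params.D * tk
                acc += wk * np.minimum(1.0, (r2 / four_dt) * np.exp(-d2 / four_dt))
        else:
            dq2 = ((Z[:, None, None, :] - qpts[None, :, :, :]) ** 2).sum(-1)  # (m,N,K)
            for tk, wk in zip(t[1:], w[1:]):
                four_dt = 4.0 * params.D * tk
                P = np.einsum(
                    "k,mnk->mn", qw, np.exp(-dq2 / four_dt)
                ) / (math.pi * four_dt)
                acc += wk * np.minimum(P, 1.0)
        # t = 0 node: analytic limit, non-zero only at d = 0 (clamped to 1)
        acc += w[0] * (d2 == 0.0)
        E[lo : lo + cell_chunk] = acc
    return E


def expected_proportions(
    detector_positions,
    roost: CandidateRoost,
    params: DiffusionParams,
    mode: str = "approx",
    time_steps: int | None = None,
) -> np.ndarray:
    """F~_i(z) = E_i / sum_j E_j: the model-expected share of calls at each
    detector for a roost at ``z``.  Independent of colony size by
    construction; sums to 1.
    """
    positions = np.atleast_2d(np.asarray(detector_positions, dtype=float))
    E = expected_calls_matrix(
        np.asarray(roost, float)[None, :], positions, params, mode, time_steps
    )[0]
    total = E.sum()
    if total <= 0:
        raise ValueError(
            "all expected call counts are zero: every detector is beyond the "
            "numerical support of the dispersal kernel; increase T or move "
            "candidate roosts closer to the array"
        )
    return E / total
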