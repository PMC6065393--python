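"""Within-cycle growth dynamics of a producer / non-producer pair in one well.

The system is a two-strain budding-yeast public-goods community growing on
sucrose.  Producers secrete invertase, whose products (glucose/fructose) act
as a public good that both strains consume; producers additionally keep a
small private share of the hydrolysis products.  Both strains grow
logistically toward a common carrying capacity ``K``, with the growth rate of
each strain modulated by a Monod (Michaelis–Menten) factor in the amount of
available public good, taken proportional to the producer density ``Np``:

.. math::

    \\frac{dN_{np}}{dt} &= r \\, N_{np} \\Big(1 - \\frac{N_p+N_{np}}{K}\\Big)
        \\frac{N_p}{N_p + k_M} \\\\
    \\frac{dN_p}{dt} &= r (1-c) \\, N_p \\Big(1 - \\frac{N_p+N_{np}}{K}\\Big)
        \\frac{N_p + \\varepsilon}{N_p + \\varepsilon + k_M}

``c`` is the metabolic cost of producing the good (paid only by producers),
``k_M`` the producer density at which non-producer growth is half-maximal,
and ``eps`` (ε) the private benefit: the extra public good a producer
captures before diffusion, expressed in equivalent producer cells/µL.
Because ε sits in both numerator and denominator of the producer Monod
factor, a vanishingly rare producer still grows at rate
``r(1-c)·ε/(ε+k_M)`` while non-producers cannot grow at all — the source of
negative frequency-dependent selection.  The shared logistic factor creates
density-dependent selection, and the Monod factor an Allee effect: below a
critical producer density the population cannot outgrow the daily dilution
and collapses.

Densities are in cells/µL, rates in h⁻¹, time in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "NodeState",
    "DEFAULT_PARAMS",
    "IntegrationError",
    "growth_derivatives",
    "grow",
    "grow_many",
]

#: default integration tolerances (relative; absolute in cells/µL)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to complete a growth period."""


@dataclass(frozen=True)
class ModelParams:
    """Constants of the two-strain growth model plus the growth duration.

    Parameters
    ----------
    r : float
        Maximum per-capita growth rate (h⁻¹).
    c : float
        Cost of public-good production, as a fraction of ``r`` (0 ≤ c < 1).
    K : float
        Common carrying capacity (cells/µL).
    eps : float
        Producer private benefit ε, in equivalent producer cells/µL.
    k_m : float
        Half-saturation producer density k_M (cells/µL).
    t_grow : float
        Effective growth duration per daily cycle (h); the lag phase is
        implicit (a 23 h incubation with a 1 h lag gives ``t_grow = 22``).
    """

    r: float = 0.5
    c: float = 0.07
    K: float = 90_000.0
    eps: float = 14.0
    k_m: float = 26.0
    t_grow: float = 22.0

    def __post_init__(self) -> None:
        vals = (self.r, self.c, self.K, self.eps, self.k_m, self.t_grow)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model parameter in {self!r}")
        if self.r <= 0:
            raise ValueError("growth rate r must be positive")
        if not 0 <= self.c < 1:
            raise ValueError("cost c must satisfy 0 <= c < 1")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.eps < 0:
            raise ValueError("private benefit eps must be non-negative")
        if self.k_m <= 0:
            raise ValueError("half-saturation k_m must be positive")
        if self.t_grow <= 0:
            raise ValueError("growth duration t_grow must be positive")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        from dataclasses import replace as _replace

        return _replace(self, **changes)


#: the fitted parameter set used throughout the study conditions
DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class NodeState:
    """Producer and non-producer densities of one subpopulation (cells/µL)."""

    producers: float
    nonproducers: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.producers) and math.isfinite(self.nonproducers)):
            raise ValueError("densities must be finite")
        if self.producers < 0 or self.nonproducers < 0:
            raise ValueError("densities must be non-negative")

    @property
    def total(self) -> float:
        return self.producers + self.nonproducers

    @property
    def fraction(self) -> float:
        """Producer fraction; NaN for an empty well."""
        t = self.total
        return self.producers / t if t > 0 else float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([self.producers, self.nonproducers], dtype=float)


def _rhs(params: ModelParams):
    """Vectorised right-hand side over a flat (n·2,) state vector."""
    r, c, K, eps, k_m = params.r, params.c, params.K, params.eps, params.k_m

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = y.reshape(-1, 2)
        n_p, n_np = y[:, 0], y[:, 1]
        crowd = 1.0 - (n_p + n_np) / K
        d_p = r * (1.0 - c) * n_p * crowd * (n_p + eps) / (n_p + eps + k_m)
        d_np = r * n_np * crowd * n_p / (n_p + k_m)
        return np.column_stack([d_p, d_np]).ravel()

    return rhs


def growth_derivatives(state: NodeState, params: ModelParams) -> tuple[float, float]:
    """Instantaneous growth rates ``(dNp/dt, dNnp/dt)`` in cells/µL/h.

    Both derivatives vanish when the respective strain is absent and when the
    total density reaches the carrying capacity.
    """
    y = state.as_array()[None, :]
    d = _rhs(params)(0.0, y.ravel())
    return float(d[0]), float(d[1])


def grow_many(
    densities: np.ndarray,
    params: ModelParams,
    duration: float | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Integrate the growth ODE for every node simultaneously.

    Parameters
    ----------
    densities : ndarray of shape (n_nodes, 2)
        Columns are producer and non-producer densities (cells/µL).
    params : ModelParams
    duration : float, optional
        Growth period in hours; defaults to ``params.t_grow``.
    rtol, atol : float
        Tolerances passed to the adaptive Runge–Kutta integrator.
        Densities below ``atol`` after integration are clipped to 0.

    Returns
    -------
    ndarray of shape (n_nodes, 2)
        Post-growth densities.  A strain that starts at exactly 0 stays at
        exactly 0 (the subspace is absorbing and enforced exactly).

    Raises
    ------
    IntegrationError
        If the adaptive solver fails (e.g. step-size underflow); the solver
        diagnostic message is included rather than silently clamping.
    """
    dens = np.asarray(densities, dtype=float)
    if dens.ndim != 2 or dens.shape[1] != 2:
        raise ValueError(f"densities must have shape (n, 2), got {dens.shape}")
    if not np.isfinite(dens).all():
        raise ValueError("densities must be finite")
    if (dens < 0).any():
        raise ValueError("densities must be non-negative")
    if duration is None:
        duration = params.t_grow
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0 or not dens.any():
        return dens.copy()

    sol = solve_ivp(
        _rhs(params),
        (0.0, float(duration)),
        dens.ravel(),
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"growth integration failed after {sol.t[-1]:.3g} h "
            f"of {duration:g} h: {sol.message}"
        )
    out = sol.y[:, -1].reshape(dens.shape)
    np.maximum(out, 0.0, out=out)  # round-off guard
    out[dens == 0.0] = 0.0  # absent strains remain absent exactly
    out[out < atol] = 0.0
    return out


def grow(
    state: NodeState,
    params: ModelParams,
    duration: float | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> NodeState:
    """Integrate one well over a growth period; see :func:`grow_many`."""
    out = grow_many(state.as_array()[None, :], params, duration, rtol=rtol, atol=atol)
    return NodeState(producers=float(out[0, 0]), nonproducers=float(out[0, 1]))
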