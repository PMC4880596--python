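"""Homeostatic growth curves and synaptic-element bookkeeping.

Neurons express *synaptic elements* — axonal boutons (senders) and dendritic
spines (receivers). Each element type on a neuron grows or retracts according
to a calcium-dependent rule dz/dt = g(Ca):

linear
    ``g(Ca) = nu * (1 - Ca/eps)`` — positive below the setpoint ``eps``,
    negative above it.
gaussian
    ``g(Ca) = nu * (2 * exp(-((Ca - xi)/zeta)^2) - 1)`` with
    ``xi = (eta + eps)/2`` and ``zeta = (eps - eta)/(2*sqrt(ln 2))``.
    The curve crosses zero at both ``eta`` (minimum calcium needed to form
    elements) and ``eps`` (the homeostatic setpoint), peaks at ``nu`` at the
    midpoint ``xi``, and saturates at ``-nu`` far above the setpoint.

``z`` is a continuous variable; the number of usable elements is
``floor(max(z, 0))``. Crossing an integer boundary upward creates a vacant
element; dropping below the number of currently connected elements forces
synapse deletion. ``z`` may go negative (an element deficit that must be
regrown before any element reappears); the vacant count clamps at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .calcium import CalciumParams

__all__ = [
    "GrowthCurveSpec",
    "ElementPool",
    "growth_rate",
    "integrate_elements",
    "prune_vacant",
    "available",
    "ElementArray",
]

_SQRT_LN2 = math.sqrt(math.log(2.0))


@dataclass(frozen=True)
class GrowthCurveSpec:
    """A homeostatic growth rule for one element type.

    Parameters
    ----------
    kind : {"linear", "gaussian"}
    nu : float
        Peak growth rate, elements/ms. Must be positive.
    eps : float
        Target (setpoint) calcium concentration.
    eta : float
        Minimum calcium needed to form elements (gaussian only); must be
        strictly below ``eps``.
    continuous : bool
        Whether reported element counts are the raw float ``z`` (True) or the
        truncated integer count (False). Internal state is always continuous.
    """

    kind: Literal["linear", "gaussian"]
    nu: float
    eps: float
    eta: float = 0.0
    continuous: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"unknown growth curve kind {self.kind!r}")
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not self.eps > 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.kind == "gaussian" and not self.eta < self.eps:
            raise ValueError(f"gaussian curve requires eta < eps, got eta={self.eta}, eps={self.eps}")

    # xi and zeta are always derived, never stored.
    @property
    def xi(self) -> float:
        """Calcium level of the gaussian peak: midpoint of (eta, eps)."""
        return 0.5 * (self.eta + self.eps)

    @property
    def zeta(self) -> float:
        """Gaussian width; the sqrt(ln 2) factor places the zeros at eta and eps."""
        return (self.eps - self.eta) / (2.0 * _SQRT_LN2)


def growth_rate(curve: GrowthCurveSpec, ca):
    """Element growth rate dz/dt (elements/ms) at calcium level ``ca``.

    Accepts scalars or arrays. The gaussian output is bounded in [-nu, nu].
    """
    ca = np.asarray(ca, dtype=float)
    if curve.kind == "linear":
        out = curve.nu * (1.0 - ca / curve.eps)
    else:
        out = curve.nu * (2.0 * np.exp(-(((ca - curve.xi) / curve.zeta) ** 2)) - 1.0)
    return out if out.ndim else float(out)


def available(z: float) -> int:
    """Usable (integer) element count for a continuous ``z``: floor of the non-negative clamp."""
    return int(math.floor(max(z, 0.0)))


@dataclass(frozen=True)
class ElementPool:
    """State of one element type on one neuron."""

    element_type: str
    z: float = 0.0
    connected: int = 0

    def __post_init__(self) -> None:
        if self.connected < 0:
            raise ValueError("connected count cannot be negative")

    @property
    def vacant(self) -> int:
        return max(0, available(self.z) - self.connected)


def _delta_z_linear(nu: float, eps: float, ca_start, dt: float, tau: float):
    # Exact integral of nu*(1 - Ca(t)/eps) with Ca(t) = ca_start * exp(-t/tau)
    # over [0, dt] (no spike mid-interval; spikes roll into the next interval's
    # start value).
    return nu * dt - (nu / eps) * ca_start * tau * (1.0 - np.exp(-dt / tau))


def integrate_elements(
    pool: ElementPool,
    curve: GrowthCurveSpec,
    ca_start: float,
    dt: float,
    cal: CalciumParams,
) -> tuple[ElementPool, int, int]:
    """Advance ``z`` over one structural interval and report count changes.

    The linear curve is integrated exactly under the no-spike calcium decay
    over the interval; the gaussian curve takes a single forward-Euler step at
    the interval-start calcium.

    Returns
    -------
    (pool', n_new_vacant, n_deleted)
        ``n_new_vacant`` — integer elements gained (floor crossings upward on
        the non-negative clamp); ``n_deleted`` — connected elements that must
        be released because the usable count fell below ``connected``.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if curve.kind == "linear":
        dz = float(_delta_z_linear(curve.nu, curve.eps, ca_start, dt, cal.tau))
    else:
        dz = growth_rate(curve, ca_start) * dt
    z_new = pool.z + dz
    n_new_vacant = max(0, available(z_new) - available(pool.z))
    n_deleted = max(0, pool.connected - available(z_new))
    return replace(pool, z=z_new), n_new_vacant, n_deleted


def prune_vacant(pool: ElementPool, fraction: float) -> ElementPool:
    """Retract ``fraction`` of the vacant elements (continuous reduction of z).

    Models the decay of unused contact sites; connected elements are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return replace(pool, z=pool.z - fraction * pool.vacant)


class ElementArray:
    """Vectorized pools of one element type over its owner neurons.

    Owners may span populations with different growth parameters, so curve
    parameters are stored per owner. Semantics match the scalar operations
    :func:`integrate_elements` and :func:`prune_vacant` element-wise.
    """

    def __init__(self, element_type: str, owner_ids: np.ndarray, curves: list[GrowthCurveSpec]) -> None:
        n = len(owner_ids)
        if len(curves) != n:
            raise ValueError("one curve per owner required")
        self.element_type = element_type
        self.owner_ids = np.asarray(owner_ids, dtype=np.int64)
        # owner_ids must be sorted and unique for searchsorted-based lookup
        if n and np.any(np.diff(self.owner_ids) <= 0):
            raise ValueError("owner_ids must be strictly increasing")
        self.z = np.zeros(n)
        self.connected = np.zeros(n, dtype=np.int64)
        self.nu = np.array([c.nu for c in curves])
        self.eps = np.array([c.eps for c in curves])
        self.xi = np.array([c.xi if c.kind == "gaussian" else np.nan for c in curves])
        self.zeta = np.array([c.zeta if c.kind == "gaussian" else np.nan for c in curves])
        self.is_gaussian = np.array([c.kind == "gaussian" for c in curves])

    def __len__(self) -> int:
        return len(self.owner_ids)

    @property
    def avail(self) -> np.ndarray:
        return np.floor(np.clip(self.z, 0.0, None)).astype(np.int64)

    @property
    def vacant(self) -> np.ndarray:
        return np.maximum(0, self.avail - self.connected)

    def index_of(self, neuron_ids: np.ndarray) -> np.ndarray:
        """Positions of global neuron ids within this array's owners."""
        idx = np.searchsorted(self.owner_ids, neuron_ids)
        if np.any(idx >= len(self.owner_ids)) or np.any(self.owner_ids[idx] != neuron_ids):
            raise KeyError(f"neuron(s) do not own element type {self.element_type!r}")
        return idx

    def integrate(self, ca_start: np.ndarray, dt: float, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One structural-interval growth step for all owners.

        ``ca_start`` and ``tau`` are aligned to owners. Returns
        ``(n_new_vacant, n_deleted)`` integer arrays.
        """
        lin = _delta_z_linear(self.nu, self.eps, ca_start, dt, tau)
        gau = self.nu * (2.0 * np.exp(-(((ca_start - self.xi) / self.zeta) ** 2)) - 1.0) * dt
        dz = np.where(self.is_gaussian, gau, lin)
        avail_before = self.avail
        self.z = self.z + dz
        avail_after = self.avail
        n_new_vacant = np.maximum(0, avail_after - avail_before)
        n_deleted = np.maximum(0, self.connected - avail_after)
        return n_new_vacant, n_deleted

    def prune(self, fraction: float) -> None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        self.z = self.z - fraction * self.vacant
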