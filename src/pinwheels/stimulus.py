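"""Drifting-grating stimuli and closed-form pulse-pair kinematics.

A drifting grating with space frequency ``K = 1/L`` (cycles/mm) and speed
``V`` (mm/s) crosses two global points ``P1`` and ``P2`` that relay pulses
to two closely situated local cells ``p1`` and ``p2``.  The closed-form
quantities are

    delta_S = |P1 - p1| - |P2 - p2|            (path difference, mm)
    delta_T = delta_S / nu                     (conduction lag, s)
    delta_t = m L / (V sin(theta))             (same-line crossing interval)
    lambda  = delta_T - delta_t                (arrival lag, s)
    omega   = nu / |delta_S|                   (synchronous-pair rate, 1/s)

with ``m = |P1 - P2| * K`` and ``theta`` the angle between the grating
lines and the segment P1P2.  ``lambda = 0`` defines synchrony, realised
only on a manifold of {K, V, sin(theta)} triplets; at synchrony
``omega = K' V sin(theta)`` with ``K' = K/m``.

The spatiotemporal orientation (STO) ``phi`` is the acute angle between
P1P2 and the radial direction of the target map: radial pairs (phi = 0)
have ``delta_S = mL``; circumferential pairs (phi = pi/2) have
``delta_S = 0`` and an unbounded synchronous rate.

An event-based oracle (`generate_pulse_trains`) realises these kinematics
literally -- crossings at rate KV, same-line crossings separated by the
traversal interval, conduction delays ``|P - p| / nu`` -- and a greedy
coincidence detector closes the loop.  Note one deliberate fidelity choice:
the traversal interval is implemented exactly as the closed form above
(line traversal at velocity ``V sin(theta)`` along the segment), not as an
independent plane-wavefront derivation.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import LocalMapSpec, LocalPosition, SingularityError

__all__ = [
    "Grating",
    "PairGeometry",
    "PulseTrain",
    "pair_geometry",
    "radial_wiring_pair",
    "crossing_interval",
    "lag",
    "synchrony_rate",
    "triplet_manifold",
    "generate_pulse_trains",
    "coincidence_count",
]


@dataclass(frozen=True)
class Grating:
    """A drifting grating stimulus acting directly on the cortical sheet."""

    K: float  # space frequency, cycles/mm (K = 1/L)
    V: float  # drift speed, mm/s
    orientation: float  # line orientation, rad, pi-periodic
    phase: float = 0.0
    profile: str = "sine"  # "sine" | "square"

    def __post_init__(self) -> None:
        if self.K <= 0 or self.V <= 0:
            raise ValueError("grating requires K > 0 and V > 0")
        if self.profile not in ("sine", "square"):
            raise ValueError(f"unknown grating profile {self.profile!r}")
        object.__setattr__(self, "orientation", self.orientation % math.pi)

    @property
    def L(self) -> float:
        return 1.0 / self.K

    def harmonics(self, n_max: int = 5) -> list[tuple["Grating", float]]:
        """Odd-harmonic decomposition of a square profile (1, 1/3, 1/5 ...).

        A sine grating is its own single harmonic.
        """
        if self.profile == "sine":
            return [(self, 1.0)]
        out = []
        for h in range(1, n_max + 1, 2):
            out.append((replace(self, K=self.K * h, profile="sine"), 1.0 / h))
        return out


@dataclass(frozen=True)
class PairGeometry:
    """Relay geometry of a (P1, P2) -> (p1, p2) pulse-pair pathway."""

    P1: complex
    P2: complex
    p1: LocalPosition
    p2: LocalPosition
    delta_S: float  # signed path difference, mm
    delta_T: float  # delta_S / nu, s
    separation: float  # |P1 - P2|, mm
    psi: float  # azimuth of P2 - P1, rad
    phi_STO: float  # acute angle to the radial direction, [0, pi/2]
    nu: float

    def m(self, K: float) -> float:
        """|P1 - P2| in units of the grating spacing L = 1/K."""
        return self.separation * K


def _acute(a: float) -> float:
    """Fold an angle difference to the acute range [0, pi/2]."""
    a = abs((a + math.pi / 2) % math.pi - math.pi / 2)
    return a


def pair_geometry(
    P1: complex,
    P2: complex,
    p1: LocalPosition | complex,
    p2: LocalPosition | complex,
    spec: LocalMapSpec,
    nu: float,
) -> PairGeometry:
    """Closed-form kinematic geometry of a relayed pair.

    ``phi_STO`` is measured between the line P1P2 and the radial direction
    from the map centre through the midpoint of P1P2.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    lp1 = p1 if isinstance(p1, LocalPosition) else LocalPosition(p1, +1, spec.map_id)
    lp2 = p2 if isinstance(p2, LocalPosition) else LocalPosition(p2, +1, spec.map_id)
    z1, z2 = complex(lp1.value), complex(lp2.value)
    dS = abs(P1 - z1) - abs(P2 - z2)
    mid = 0.5 * (P1 + P2)
    if mid == spec.p0:
        raise SingularityError("STO undefined: pair midpoint at the map singularity")
    radial = cmath.phase(mid - spec.p0)
    psi = cmath.phase(P2 - P1)
    return PairGeometry(
        P1=P1,
        P2=P2,
        p1=lp1,
        p2=lp2,
        delta_S=dS,
        delta_T=dS / nu,
        separation=abs(P1 - P2),
        psi=psi,
        phi_STO=_acute(psi - radial),
        nu=nu,
    )


def radial_wiring_pair(
    R: float, separation: float, phi: float, spec: LocalMapSpec, nu: float
) -> PairGeometry:
    """The idealised radial-wiring pair used for the STO bounds.

    Both local cells sit at the cluster centre; the source segment of
    length ``separation`` has its midpoint at distance ``R`` from the
    singularity and makes angle ``phi`` with the radial direction.  Then
    ``delta_S(0) = separation`` and ``delta_S(pi/2) = 0`` exactly, with
    delta_S monotone decreasing in phi.
    """
    if R <= separation / 2:
        raise ValueError("midpoint must lie beyond the half-separation")
    mid = spec.p0 + R
    half = 0.5 * separation * cmath.exp(1j * phi)
    return pair_geometry(mid + half, mid - half, spec.p0, spec.p0, spec, nu)


def sin_theta(pair: PairGeometry, grating: Grating) -> float:
    """|sin| of the angle between the grating lines and the segment P1P2.

    Values below 1e-12 (lines numerically parallel to the segment) snap to
    zero so the infinite-interval sentinel triggers reliably.
    """
    s = abs(math.sin(grating.orientation - pair.psi))
    return 0.0 if s < 1e-12 else s


def crossing_interval(pair: PairGeometry, grating: Grating) -> float:
    """Same-line crossing interval delta_t = m L / (V sin(theta)), seconds.

    Returns ``inf`` when the grating lines are parallel to the segment.
    """
    s = sin_theta(pair, grating)
    if s == 0.0:
        return math.inf
    return pair.separation / (grating.V * s)


def lag(pair: PairGeometry, grating: Grating) -> float:
    """Arrival-time separation lambda = delta_S/nu - m L/(V sin theta)."""
    return pair.delta_T - crossing_interval(pair, grating)


def synchrony_rate(pair: PairGeometry, nu: float | None = None) -> float:
    """Rate of synchronous pair generation omega = nu / |delta_S|, 1/s.

    Unbounded (returns ``inf``) for circumferential pairs with
    ``delta_S = 0``.
    """
    v = nu if nu is not None else pair.nu
    if pair.delta_S == 0.0:
        return math.inf
    return v / abs(pair.delta_S)


def triplet_manifold(
    pair: PairGeometry,
    K_grid: np.ndarray,
    V_grid: np.ndarray,
    theta_grid: np.ndarray,
    tol: float,
    orientation_reference: float | None = None,
) -> pd.DataFrame:
    """Grid triplets {K, V, theta} whose lag falls within ``tol`` of zero.

    ``theta`` is measured between grating lines and the segment; the
    returned frame carries (K, V, theta, lambda) rows and doubles as the
    polar-diagram table (theta vs V at fixed K).
    """
    K_grid = np.asarray(K_grid, dtype=float)
    V_grid = np.asarray(V_grid, dtype=float)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if K_grid.size == 0 or V_grid.size == 0 or theta_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    s = np.abs(np.sin(theta_grid))[None, :]
    with np.errstate(divide="ignore"):
        dt = pair.separation / (V_grid[:, None] * s)  # (V, theta)
    lam = pair.delta_T - dt
    rows = []
    for iK, K in enumerate(K_grid):
        mask = np.abs(lam) <= tol
        iv, it = np.nonzero(mask)
        for v_i, t_i in zip(iv, it):
            rows.append((float(K), float(V_grid[v_i]), float(theta_grid[t_i]), float(lam[v_i, t_i])))
    return pd.DataFrame(rows, columns=["K", "V", "theta", "lambda"])


@dataclass(frozen=True)
class PulseTrain:
    """Sorted pulse arrival times at one cell."""

    cell_id: int
    times: np.ndarray

    @property
    def n(self) -> int:
        return int(self.times.size)


def generate_pulse_trains(
    pair: PairGeometry,
    grating: Grating,
    duration: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    ids: tuple[int, int] = (0, 1),
) -> tuple[PulseTrain, PulseTrain]:
    """Event-based oracle for pulse arrivals at the two local cells.

    One pulse is generated each time a grating line crosses P1 or P2, at
    rate ``K V``; the same line crosses P2 a traversal interval after P1;
    each pulse reaches its local cell after the conduction delay
    ``|P - p| / nu``.  With zero jitter, the two arrival trains are offset
    by exactly ``-lambda``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt_line = crossing_interval(pair, grating)
    if not math.isfinite(dt_line):
        raise ValueError("grating lines parallel to the pair segment: no traversal")
    rate = grating.K * grating.V
    t0 = (grating.phase % (2 * math.pi)) / (2 * math.pi) / rate
    n_events = int(math.floor((duration - t0) * rate)) + 1 if t0 <= duration else 0
    crossings = t0 + np.arange(n_events) / rate
    d1 = abs(pair.P1 - complex(pair.p1.value)) / pair.nu
    d2 = abs(pair.P2 - complex(pair.p2.value)) / pair.nu
    a1 = crossings + d1
    a2 = crossings + dt_line + d2
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        a1 = a1 + rng.normal(0, jitter_sd, a1.size)
        a2 = a2 + rng.normal(0, jitter_sd, a2.size)
    return (
        PulseTrain(ids[0], np.sort(a1)),
        PulseTrain(ids[1], np.sort(a2)),
    )


class CoincidenceResult(NamedTuple):
    count: int
    rate: float  # per second of observation


def coincidence_count(
    t1: np.ndarray | PulseTrain,
    t2: np.ndarray | PulseTrain,
    epsilon: float,
    duration: float | None = None,
) -> CoincidenceResult:
    """Greedy one-to-one matching of events within ``epsilon`` seconds.

    Each event is used at most once; the sweep advances whichever train is
    behind, matching fronts when they fall within the window.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a = t1.times if isinstance(t1, PulseTrain) else np.asarray(t1, dtype=float)
    b = t2.times if isinstance(t2, PulseTrain) else np.asarray(t2, dtype=float)
    i = j = count = 0
    while i < a.size and j < b.size:
        d = a[i] - b[j]
        if abs(d) <= epsilon:
            count += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    if duration is None:
        hi = max(a[-1] if a.size else 0.0, b[-1] if b.size else 0.0)
        lo = min(a[0] if a.size else 0.0, b[0] if b.size else 0.0)
        duration = max(hi - lo, epsilon)
    return CoincidenceResult(count=count, rate=count / duration)
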