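"""Complex-plane projections between the global cortical sheet and local maps.

The cortical sheet is modelled as a bounded region of the complex plane
(units: mm).  Each local map is a Moebius-strip-like projection of the
surrounding sheet onto a small cluster of local cells: a point ``P`` on the
sheet maps to

    p = p' * w_c**n / |w|**(n-1) + p0,      w = P - p0,

where ``p0`` is the map centre (the OP singularity), ``p'`` is a complex
scale-rotation factor, ``n`` is an even integer, and ``w_c`` is ``w`` for a
map of chirality +1 and ``conj(w)`` for chirality -1 (a true mirror image).
The projection multiplies azimuths by ``chirality * n`` while scaling radii
linearly by ``|p'|``, so the global azimuths ``alpha`` and ``alpha + pi``
land on the same apparent 2-D local position -- the two coincident "limbs"
of the Moebius representation.  Orientation preference (OP) about the
singularity follows from the radial like-to-like wiring: the local cell fed
from azimuth ``alpha`` carries OP ``alpha mod pi``, which winds through a
total of pi per circuit of the singularity in the local (cortical) plane --
the familiar half-pinwheel -- with winding sign set by chirality.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlobalPosition",
    "LocalPosition",
    "LocalMapSpec",
    "MapTiling",
    "forward_map",
    "inverse_map",
    "op_from_azimuth",
    "op_winding",
    "tile_maps",
    "delta_s_general",
]

#: A position on the global cortical sheet, mm, as a complex number.
GlobalPosition = complex

_TWO_PI = 2.0 * math.pi


class MapConfigurationError(ValueError):
    """Raised for invalid local-map parameters (odd n, zero p', ...)."""


class SingularityError(ValueError):
    """Raised where a quantity is undefined at a map singularity."""


@dataclass(frozen=True)
class LocalPosition:
    """A position within one local map.

    Parameters
    ----------
    value : complex
        Position in mm, in sheet coordinates (local clusters live
        physically on the sheet, close to their map centre).
    limb : int
        +1 for the 0..pi limb, -1 for the pi..2pi limb.  The two limbs are
        coincident when viewed in two dimensions but are distinct branches
        of the Moebius-like projection.
    map_id : str
        Identifier of the host map.
    """

    value: complex
    limb: int
    map_id: str

    def __post_init__(self) -> None:
        if self.limb not in (+1, -1):
            raise ValueError(f"limb must be +1 or -1, got {self.limb}")


@dataclass(frozen=True)
class LocalMapSpec:
    """Geometry of one local map (one pinwheel).

    ``p0`` is the singularity, ``p_prime`` the complex scale-rotation of
    the projection, ``chirality`` the mirror handedness and ``n`` the even
    projection order (n=2 is a single Moebius strip).
    """

    map_id: str
    p0: complex
    p_prime: complex = -0.25
    chirality: int = +1
    n: int = 2

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise MapConfigurationError(f"n must be an even integer >= 2, got {self.n}")
        if self.p_prime == 0:
            raise MapConfigurationError("p_prime must be nonzero")
        if self.chirality not in (+1, -1):
            raise MapConfigurationError(f"chirality must be +1 or -1, got {self.chirality}")

    @property
    def k(self) -> complex:
        """Convenience accessor: p' = -1/k."""
        return -1.0 / self.p_prime


def _limb_of_azimuth(azimuth: float) -> int:
    """Half-open limb partition: azimuth in [0, pi) -> +1, [pi, 2pi) -> -1."""
    a = azimuth % _TWO_PI
    if a >= _TWO_PI:  # guard the rounding case (-eps % 2pi == 2pi)
        a = 0.0
    return +1 if a < math.pi else -1


def forward_map(P: GlobalPosition, spec: LocalMapSpec) -> LocalPosition:
    """Project a global position into a local map.

    Satisfies ``|p - p0| = |p'| * |P - p0|`` and
    ``arg(p - p0) = chirality * n * arg(P - p0) + arg(p')  (mod 2 pi)``.
    ``P = p0`` is a fixed point (returned on limb +1 by convention).
    """
    w = complex(P) - spec.p0
    if w == 0:
        return LocalPosition(spec.p0, +1, spec.map_id)
    limb = _limb_of_azimuth(cmath.phase(w))
    wc = w if spec.chirality > 0 else w.conjugate()
    p = spec.p_prime * wc ** spec.n / abs(w) ** (spec.n - 1) + spec.p0
    return LocalPosition(p, limb, spec.map_id)


def inverse_map(p: LocalPosition, spec: LocalMapSpec, branch: int = 0) -> GlobalPosition:
    """Return the global position that projects to ``p`` on its stated limb.

    For ``n = 2`` the two n-th roots fall one per limb and the limb tag
    selects the unique preimage.  For higher even ``n`` each limb holds
    ``n/2`` preimages; ``branch`` (0-based, by increasing azimuth) selects
    among them.
    """
    if p.limb not in (+1, -1):
        raise ValueError("local position must carry a limb tag")
    d = (complex(p.value) - spec.p0) / spec.p_prime
    if d == 0:
        return spec.p0
    # |p - p0| = |p'| |w|  =>  |w| = |d|;  arg(w_c) = (arg(d) + 2 pi k)/n
    r = abs(d)
    base = cmath.phase(d)
    candidates = []
    for kk in range(spec.n):
        a_c = (base + _TWO_PI * kk) / spec.n
        a = a_c if spec.chirality > 0 else -a_c
        if _limb_of_azimuth(a) == p.limb:
            candidates.append(a % _TWO_PI)
    candidates.sort()
    if not candidates:  # pragma: no cover - cannot happen for even n
        raise ValueError("no preimage on the requested limb")
    if branch >= len(candidates):
        raise ValueError(f"branch {branch} out of range ({len(candidates)} preimages on limb)")
    a = candidates[branch]
    return spec.p0 + r * cmath.exp(1j * a)


def op_from_azimuth(P: GlobalPosition, spec: LocalMapSpec) -> float:
    """OP (radians in [0, pi)) carried by the radial like-to-like line through P.

    The line through azimuths ``alpha`` and ``alpha + pi`` is a single
    orientation, so OP is pi-periodic and identical on the two limbs.
    Undefined at the singularity.
    """
    w = complex(P) - spec.p0
    if w == 0:
        raise SingularityError("OP undefined at the map singularity")
    return cmath.phase(w) % math.pi


def op_winding(spec: LocalMapSpec, n_samples: int = 360, radius: float = 1.0) -> float:
    """Total OP winding over one circuit of the singularity in the local plane.

    Samples local positions on a circle about ``p0``, pulls each back
    through the inverse map (limb +1, principal branch) and accumulates the
    wrapped OP increments.  Equals ``chirality * pi`` for ``n = 2``.
    """
    betas = np.linspace(0.0, _TWO_PI, n_samples, endpoint=False)
    ops = np.empty(n_samples)
    for i, b in enumerate(betas):
        p = LocalPosition(spec.p0 + radius * cmath.exp(1j * b), +1, spec.map_id)
        ops[i] = op_from_azimuth(inverse_map(p, spec), spec)
    return float(wrapped_op_winding(ops))


def wrapped_op_winding(ops: np.ndarray) -> float:
    """Winding of a closed loop of pi-periodic orientation samples.

    Differences are wrapped into [-pi/2, pi/2) before summing, the standard
    plaquette rule for orientation fields.
    """
    d = np.diff(np.concatenate([ops, ops[:1]]))
    d = (d + math.pi / 2) % math.pi - math.pi / 2
    return float(d.sum())


@dataclass
class MapTiling:
    """A set of local maps tiling the sheet, with neighbour bookkeeping."""

    maps: list[LocalMapSpec]
    neighbor_pairs: set[tuple[str, str]] = field(default_factory=set)
    seed: int = 0
    map_radius: float = 0.0

    def __getitem__(self, map_id: str) -> LocalMapSpec:
        for m in self.maps:
            if m.map_id == map_id:
                return m
        raise KeyError(map_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "map_radius": self.map_radius,
                "maps": [
                    {
                        "map_id": m.map_id,
                        "p0": [m.p0.real, m.p0.imag],
                        "p_prime": [m.p_prime.real, m.p_prime.imag],
                        "chirality": m.chirality,
                        "n": m.n,
                    }
                    for m in self.maps
                ],
                "neighbor_pairs": sorted(self.neighbor_pairs),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MapTiling":
        obj = json.loads(text)
        maps = [
            LocalMapSpec(
                map_id=m["map_id"],
                p0=complex(*m["p0"]),
                p_prime=complex(*m["p_prime"]),
                chirality=m["chirality"],
                n=m["n"],
            )
            for m in obj["maps"]
        ]
        return cls(
            maps=maps,
            neighbor_pairs={tuple(p) for p in obj["neighbor_pairs"]},
            seed=obj["seed"],
            map_radius=obj["map_radius"],
        )

    def neighbor_table(self) -> pd.DataFrame:
        rows = sorted(self.neighbor_pairs)
        return pd.DataFrame(rows, columns=["map_a", "map_b"])


def tile_maps(
    width: float,
    height: float,
    spacing: float,
    seed: int = 0,
    jitter: float = 0.0,
    p_prime: complex = -0.25,
    n: int = 2,
    map_radius: float | None = None,
) -> MapTiling:
    """Tile the sheet with local maps on a jittered lattice.

    Chirality alternates in a checkerboard (mirror-image neighbours) and
    neighbour pairs are the 4-neighbourhood of the lattice.  Deterministic
    for a fixed seed.
    """
    nx = int(round(width / spacing))
    ny = int(round(height / spacing))
    if nx < 1 or ny < 1:
        feasible = f"spacing <= {min(width, height):g} fits >= 1 map per axis"
        raise ValueError(f"map spacing {spacing} too large for {width}x{height} sheet; {feasible}")
    if jitter > 0.25 * spacing:
        raise ValueError("jitter must be <= spacing/4 to preserve minimum centre separation")
    rng = np.random.default_rng(seed)
    maps: list[LocalMapSpec] = []
    pairs: set[tuple[str, str]] = set()
    ids = {}
    for j in range(ny):
        for i in range(nx):
            cx = (i + 0.5) * spacing
            cy = (j + 0.5) * spacing
            if jitter > 0:
                cx += rng.uniform(-jitter, jitter)
                cy += rng.uniform(-jitter, jitter)
            mid = f"m{i}_{j}"
            ids[(i, j)] = mid
            maps.append(
                LocalMapSpec(
                    map_id=mid,
                    p0=complex(cx, cy),
                    p_prime=p_prime,
                    chirality=+1 if (i + j) % 2 == 0 else -1,
                    n=n,
                )
            )
    for (i, j), mid in ids.items():
        for di, dj in ((1, 0), (0, 1)):
            other = ids.get((i + di, j + dj))
            if other is not None:
                pairs.add(tuple(sorted((mid, other))))
    radius = map_radius if map_radius is not None else 0.45 * spacing
    return MapTiling(maps=maps, neighbor_pairs=pairs, seed=seed, map_radius=radius)


def delta_s_general(
    p1: LocalPosition,
    map1: LocalMapSpec,
    p2: LocalPosition,
    map2: LocalMapSpec,
) -> float:
    """General-case path-length difference between two relayed inputs.

    The two local cells may sit in different limbs of one map or in
    different maps.  Each local position is pulled back through its map's
    inverse projection and the signed difference of the global path
    lengths ``|P(i) - p(i)|`` is returned.  Reduces to the simple
    same-limb, same-map expression ``|P1 - p1| - |P2 - p2|``.
    """
    if complex(p1.value) == map1.p0 or complex(p2.value) == map2.p0:
        raise SingularityError("path difference undefined at a map singularity")
    P1 = inverse_map(p1, map1)
    P2 = inverse_map(p2, map2)
    return abs(P1 - complex(p1.value)) - abs(P2 - complex(p2.value))
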