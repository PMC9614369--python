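"""Antenatal connectome scaffold and population synchrony diagnostics.

The antenatal scaffold consists of a patch-cell system sampled along radial
like-to-like half-lines of each local map, local excitatory cells receiving
reciprocal relay from those patch cells (their antenatal OP is the line
orientation), sparse inhibitory partners, and initially *unidirectional*
local-to-local links along each radial line.  Postnatal learning
supplements these with bidirectional and circumferential connections.

The free-energy diagnostic is

    F = A - C

where ``A`` is the population sum of pulse autocorrelations and ``C`` the
(partner-averaged) sum of pulse cross-correlations, estimated here as
zero-lag Pearson correlation of binned counts.  A surrogate common-source
point process stands in for full neural dynamics: it produces trains whose
pairwise synchrony is tunable by bidirectional connection strength, which
is all the diagnostic needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import LocalMapSpec, LocalPosition, MapTiling, forward_map, op_from_azimuth
from .stimulus import PairGeometry, pair_geometry

__all__ = [
    "Cell",
    "Edge",
    "Connectome",
    "ScaffoldConfig",
    "FreeEnergyTrace",
    "FreeEnergyResult",
    "build_antenatal_connectome",
    "mapped_pairs",
    "surrogate_pulse_exchange",
    "correlated_pair_trains",
    "free_energy",
    "symmetry_index",
]


@dataclass
class Cell:
    cell_id: int
    kind: str  # "patch" | "local_exc" | "local_inh"
    position: complex  # physical position on the sheet, mm
    map_id: str | None = None
    limb: int | None = None
    source: complex | None = None  # global source point P (local cells)
    op: float | None = None  # antenatal OP, rad in [0, pi)
    azimuth_index: int | None = None
    ring_index: int | None = None

    @property
    def local_value(self) -> LocalPosition | None:
        if self.map_id is None or self.limb is None:
            return None
        return LocalPosition(self.position, self.limb, self.map_id)


@dataclass
class Edge:
    pre: int
    post: int
    rho: float = 1.0
    gain: float = 1.0
    efficacy: float = 1.0
    delay: float = 0.0  # seconds, = |pre - post| / nu
    directed: bool = True  # True while no reciprocal edge exists
    kind: str = "antenatal"  # "patch" | "relay" | "local" | "learned" | "bridge"
    epoch_created: int = -1

    @property
    def strength(self) -> float:
        return self.rho * self.gain * self.efficacy


@dataclass
class Connectome:
    """Cells plus directed edges; reciprocal edges model bidirectional links."""

    cells: list[Cell]
    edges: dict[tuple[int, int], Edge] = field(default_factory=dict)
    nu: float = 300.0  # axonal conduction speed, mm/s
    seed: int = 0

    def cell(self, cell_id: int) -> Cell:
        return self.cells[cell_id]

    def has_edge(self, pre: int, post: int) -> bool:
        return (pre, post) in self.edges

    def edge(self, pre: int, post: int) -> Edge:
        return self.edges[(pre, post)]

    def add_edge(self, edge: Edge) -> Edge:
        if edge.pre == edge.post:
            raise ValueError("self-edges are not allowed")
        if not (0 <= edge.pre < len(self.cells) and 0 <= edge.post < len(self.cells)):
            raise ValueError("edge endpoint does not exist")
        self.edges[(edge.pre, edge.post)] = edge
        rev = self.edges.get((edge.post, edge.pre))
        if rev is not None:
            edge.directed = False
            rev.directed = False
        return edge

    def connect(self, pre: int, post: int, *, kind: str, gain: float = 1.0, epoch: int = -1) -> Edge:
        d = abs(self.cells[pre].position - self.cells[post].position) / self.nu
        return self.add_edge(Edge(pre, post, gain=gain, delay=d, kind=kind, epoch_created=epoch))

    def local_excitatory(self) -> list[Cell]:
        return [c for c in self.cells if c.kind == "local_exc"]

    def unordered_pairs(self) -> dict[tuple[int, int], tuple[float, float]]:
        """Connected unordered pairs -> (strength i->j, strength j->i)."""
        out: dict[tuple[int, int], tuple[float, float]] = {}
        for (i, j), e in self.edges.items():
            a, b = (i, j) if i < j else (j, i)
            fwd = out.get((a, b), (0.0, 0.0))
            if (i, j) == (a, b):
                out[(a, b)] = (e.strength, fwd[1])
            else:
                out[(a, b)] = (fwd[0], e.strength)
        return out

    def bidirectional_fraction(self) -> float:
        pairs = self.unordered_pairs()
        if not pairs:
            return 0.0
        n_bi = sum(1 for s_ij, s_ji in pairs.values() if s_ij > 0 and s_ji > 0)
        return n_bi / len(pairs)

    def copy(self) -> "Connectome":
        import copy as _copy

        return _copy.deepcopy(self)

    # ------------------------------------------------------------------ io
    def cells_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "kind": [c.kind for c in self.cells],
                "x_mm": [c.position.real for c in self.cells],
                "y_mm": [c.position.imag for c in self.cells],
                "map_id": [c.map_id or "" for c in self.cells],
                "limb": [c.limb if c.limb is not None else 0 for c in self.cells],
                "op_rad": [c.op if c.op is not None else np.nan for c in self.cells],
            }
        )

    def edges_df(self) -> pd.DataFrame:
        keys = sorted(self.edges)
        es = [self.edges[k] for k in keys]
        return pd.DataFrame(
            {
                "pre": [e.pre for e in es],
                "post": [e.post for e in es],
                "rho": [e.rho for e in es],
                "gain": [e.gain for e in es],
                "efficacy": [e.efficacy for e in es],
                "delay_s": [e.delay for e in es],
                "directed": [e.directed for e in es],
                "kind": [e.kind for e in es],
                "epoch_created": [e.epoch_created for e in es],
            }
        )

    def cells_df_full(self) -> pd.DataFrame:
        df = self.cells_df()
        df["source_x"] = [c.source.real if c.source is not None else np.nan for c in self.cells]
        df["source_y"] = [c.source.imag if c.source is not None else np.nan for c in self.cells]
        df["azimuth_index"] = [c.azimuth_index if c.azimuth_index is not None else -1 for c in self.cells]
        df["ring_index"] = [c.ring_index if c.ring_index is not None else -1 for c in self.cells]
        return df

    @classmethod
    def from_frames(cls, cells: pd.DataFrame, edges: pd.DataFrame, nu: float, seed: int = 0) -> "Connectome":
        conn = cls(cells=[], nu=nu, seed=seed)
        for row in cells.itertuples(index=False):
            src = complex(row.source_x, row.source_y) if not math.isnan(row.source_x) else None
            conn.cells.append(
                Cell(
                    cell_id=int(row.cell_id),
                    kind=row.kind,
                    position=complex(row.x_mm, row.y_mm),
                    map_id=row.map_id if isinstance(row.map_id, str) and row.map_id else None,
                    limb=int(row.limb) if row.limb else None,
                    source=src,
                    op=None if math.isnan(row.op_rad) else float(row.op_rad),
                    azimuth_index=None if row.azimuth_index < 0 else int(row.azimuth_index),
                    ring_index=None if row.ring_index < 0 else int(row.ring_index),
                )
            )
        for row in edges.itertuples(index=False):
            conn.add_edge(
                Edge(
                    pre=int(row.pre),
                    post=int(row.post),
                    rho=float(row.rho),
                    gain=float(row.gain),
                    efficacy=float(row.efficacy),
                    delay=float(row.delay_s),
                    kind=row.kind,
                    epoch_created=int(row.epoch_created),
                )
            )
        return conn

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for c in self.cells:
            g.add_node(
                c.cell_id,
                kind=c.kind,
                x_mm=c.position.real,
                y_mm=c.position.imag,
                map_id=c.map_id or "",
                limb=c.limb if c.limb is not None else 0,
            )
        for (i, j) in sorted(self.edges):
            e = self.edges[(i, j)]
            g.add_edge(
                i,
                j,
                rho=e.rho,
                gain=e.gain,
                efficacy=e.efficacy,
                delay_s=e.delay,
                kind=e.kind,
                epoch_created=e.epoch_created,
            )
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class ScaffoldConfig:
    """Geometry and density of the antenatal scaffold.

    ``n_azimuths`` counts radial *half-lines* per map (evenly spaced over
    2 pi; orientations mod pi number half as many).  ``bend`` rotates the
    sample azimuth by ``chirality * bend * (r/R)**2`` so the like-to-like
    arcs curve circumferentially toward the map periphery.  ``nu`` is the
    axonal conduction speed in mm/s (default 300 mm/s = 0.3 mm/ms, the
    order of magnitude of unmyelinated horizontal fibres).
    """

    n_azimuths: int = 8
    n_rings: int = 3
    bend: float = 0.35
    nu: float = 300.0
    n_inhibitory: int = 4
    inhibitory_spread: float = 0.25  # fraction of local cluster radius

    def __post_init__(self) -> None:
        if self.n_azimuths < 2 or self.n_rings < 1:
            raise ValueError("scaffold requires >= 2 azimuths and >= 1 ring (density too low)")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


def ring_radii(tiling: MapTiling, config: ScaffoldConfig) -> np.ndarray:
    R = tiling.map_radius
    return R * (np.arange(config.n_rings) + 1.0) / config.n_rings


def source_point(spec: LocalMapSpec, tiling: MapTiling, config: ScaffoldConfig, a: int, j: int) -> complex:
    """Global source point of half-line ``a`` at ring ``j`` (with bend)."""
    r = ring_radii(tiling, config)[j]
    alpha = 2.0 * math.pi * a / config.n_azimuths
    gamma = spec.chirality * config.bend * (r / tiling.map_radius) ** 2
    return spec.p0 + r * complex(math.cos(alpha + gamma), math.sin(alpha + gamma))


def build_antenatal_connectome(tiling: MapTiling, config: ScaffoldConfig, seed: int = 0) -> Connectome:
    """Construct the antenatal connectome for a tiling.

    Per map and half-line: patch cells at each ring radius (patch-to-patch
    edges along the line give the annular connection-length spectrum),
    one local excitatory cell per patch cell via the forward projection
    (reciprocal relay edges), and unidirectional outward local-to-local
    links along the line.  Deterministic for fixed (tiling, config, seed).
    """
    conn = Connectome(cells=[], nu=config.nu, seed=seed)
    rng = np.random.default_rng(seed)
    radii = ring_radii(tiling, config)
    for spec in tiling.maps:
        patch_ids: dict[tuple[int, int], int] = {}
        local_ids: dict[tuple[int, int], int] = {}
        for a in range(config.n_azimuths):
            for j in range(config.n_rings):
                P = source_point(spec, tiling, config, a, j)
                cid = len(conn.cells)
                conn.cells.append(Cell(cid, "patch", P, map_id=spec.map_id, azimuth_index=a, ring_index=j))
                patch_ids[(a, j)] = cid
                lp = forward_map(P, spec)
                lid = len(conn.cells)
                conn.cells.append(
                    Cell(
                        lid,
                        "local_exc",
                        lp.value,
                        map_id=spec.map_id,
                        limb=lp.limb,
                        source=P,
                        op=op_from_azimuth(P, spec),
                        azimuth_index=a,
                        ring_index=j,
                    )
                )
                local_ids[(a, j)] = lid
        # patch-to-patch along each half-line: all ring pairs, reciprocal
        for a in range(config.n_azimuths):
            for j in range(config.n_rings):
                for k in range(j + 1, config.n_rings):
                    conn.connect(patch_ids[(a, j)], patch_ids[(a, k)], kind="patch")
                    conn.connect(patch_ids[(a, k)], patch_ids[(a, j)], kind="patch")
        # reciprocal patch <-> local relay
        for key, pid in patch_ids.items():
            lid = local_ids[key]
            conn.connect(pid, lid, kind="relay")
            conn.connect(lid, pid, kind="relay")
        # antenatal local-to-local: unidirectional, outward along the line
        for a in range(config.n_azimuths):
            for j in range(config.n_rings - 1):
                conn.connect(local_ids[(a, j)], local_ids[(a, j + 1)], kind="local")
        # inhibitory partners: labels for the competition rule, no edges
        cluster_r = abs(spec.p_prime) * radii[-1] * config.inhibitory_spread
        for _ in range(config.n_inhibitory):
            z = spec.p0 + cluster_r * complex(*rng.uniform(-1, 1, 2))
            conn.cells.append(Cell(len(conn.cells), "local_inh", z, map_id=spec.map_id))
    return conn


@dataclass(frozen=True)
class PairRecord:
    """A candidate local-cell pair with its relay geometry."""

    cell1: int  # P1 side (ordered so delta_S >= 0)
    cell2: int
    kind: str  # "radial" | "circumferential"
    geometry: PairGeometry


def mapped_pairs(conn: Connectome, tiling: MapTiling, config: ScaffoldConfig) -> list[PairRecord]:
    """Enumerate same-map candidate pairs for synchrony-driven learning.

    Radial pairs link consecutive rings on one half-line; circumferential
    pairs link adjacent half-lines on one ring within one limb.  Pairs are
    ordered so the signed path difference is >= 0 (P1 is the longer path).
    """
    by_key: dict[tuple[str, int, int], Cell] = {}
    for c in conn.cells:
        if c.kind == "local_exc":
            by_key[(c.map_id, c.azimuth_index, c.ring_index)] = c
    out: list[PairRecord] = []
    for spec in tiling.maps:
        for a in range(config.n_azimuths):
            for j in range(config.n_rings - 1):
                c1 = by_key[(spec.map_id, a, j)]
                c2 = by_key[(spec.map_id, a, j + 1)]
                out.append(_ordered_pair(c1, c2, "radial", spec, conn.nu))
        for j in range(config.n_rings):
            for a in range(config.n_azimuths):
                a2 = (a + 1) % config.n_azimuths
                c1 = by_key[(spec.map_id, a, j)]
                c2 = by_key[(spec.map_id, a2, j)]
                if c1.limb != c2.limb:
                    continue  # cross-limb association is postnatal bridging
                out.append(_ordered_pair(c1, c2, "circumferential", spec, conn.nu))
    return out


def _ordered_pair(c1: Cell, c2: Cell, kind: str, spec: LocalMapSpec, nu: float) -> PairRecord:
    g = pair_geometry(c1.source, c2.source, c1.local_value, c2.local_value, spec, nu)
    if g.delta_S < 0:
        g = pair_geometry(c2.source, c1.source, c2.local_value, c1.local_value, spec, nu)
        return PairRecord(c2.cell_id, c1.cell_id, kind, g)
    return PairRecord(c1.cell_id, c2.cell_id, kind, g)


# --------------------------------------------------------------------------
# surrogate pulse exchange and the free-energy diagnostic


def correlated_pair_trains(
    rate: float, q: float, duration: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two Poisson trains sharing a common-source fraction ``q`` of events.

    Each train has marginal rate ``rate``; the zero-lag binned correlation
    approaches ``q`` for bins shorter than the mean interval.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = np.sort(rng.uniform(0, duration, rng.poisson(rate * q * duration)))
    t1 = np.sort(np.concatenate([shared, rng.uniform(0, duration, rng.poisson(rate * (1 - q) * duration))]))
    t2 = np.sort(np.concatenate([shared, rng.uniform(0, duration, rng.poisson(rate * (1 - q) * duration))]))
    return t1, t2


def surrogate_pulse_exchange(
    conn: Connectome,
    duration: float,
    seed: int = 0,
    rate: float = 20.0,
    strength_scale: float = 10.0,
    cells: Iterable[int] | None = None,
    kinds: tuple[str, ...] = ("local", "learned", "bridge"),
) -> dict[int, np.ndarray]:
    """Seeded common-source surrogate pulse trains for the local population.

    Each selected cell fires as a homogeneous point process of rate
    ``rate``; every bidirectionally linked pair shares a common source
    whose fraction is the pair's bidirectional strength
    ``min(s_ij, s_ji) / strength_scale`` (clipped so each cell's shared
    budget stays below 1).  Pairwise zero-lag correlation thus grows with
    bidirectional connection strength, which is the only property the
    free-energy diagnostic relies on.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ids = list(cells) if cells is not None else [c.cell_id for c in conn.local_excitatory()]
    idset = set(ids)
    rng = np.random.default_rng(seed)
    q: dict[tuple[int, int], float] = {}
    for (i, j), (s_ij, s_ji) in conn.unordered_pairs().items():
        if i not in idset or j not in idset:
            continue
        e = conn.edges.get((i, j)) or conn.edges.get((j, i))
        if e is not None and e.kind not in kinds:
            continue
        s = min(s_ij, s_ji)
        if s > 0:
            q[(i, j)] = min(s / strength_scale, 1.0)
    budget = {i: 0.0 for i in ids}
    for (i, j), qq in q.items():
        budget[i] += qq
        budget[j] += qq
    scale = {i: min(1.0, 0.95 / b) if b > 0 else 1.0 for i, b in budget.items()}
    trains: dict[int, list[np.ndarray]] = {i: [] for i in ids}
    shared_total = {i: 0.0 for i in ids}
    for (i, j) in sorted(q):
        qq = q[(i, j)] * math.sqrt(scale[i] * scale[j])
        n = rng.poisson(rate * qq * duration)
        t = rng.uniform(0, duration, n)
        trains[i].append(t)
        trains[j].append(t)
        shared_total[i] += qq
        shared_total[j] += qq
    out: dict[int, np.ndarray] = {}
    for i in ids:
        own = max(0.0, 1.0 - shared_total[i])
        t = rng.uniform(0, duration, rng.poisson(rate * own * duration))
        trains[i].append(t)
        out[i] = np.sort(np.concatenate(trains[i]))
    return out


class FreeEnergyResult(NamedTuple):
    A: float
    C_cross: float
    F: float
    empty_cells: tuple[int, ...]


def free_energy(
    trains: dict[int, np.ndarray] | list[np.ndarray],
    bin_width: float = 0.01,
    duration: float | None = None,
) -> FreeEnergyResult:
    """F = A - C from binned zero-lag Pearson correlations.

    ``A`` sums the (unit) autocorrelations of non-degenerate trains; ``C``
    sums cross-correlations averaged over partners, ``C = sum_{i!=j}
    corr(x_i, x_j) / (N - 1)``, so that A and C share the same scale:
    perfectly synchronous populations give F = 0 and independent ones give
    F ~= N.  Empty (or constant) trains contribute autocorrelation 0 and
    are reported in ``empty_cells``.
    """
    if isinstance(trains, dict):
        ids = sorted(trains)
        series = [np.asarray(trains[i], dtype=float) for i in ids]
    else:
        ids = list(range(len(trains)))
        series = [np.asarray(t, dtype=float) for t in trains]
    n = len(series)
    if n < 2:
        raise ValueError("free energy requires >= 2 trains")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    T = duration
    if T is None:
        T = max((t[-1] for t in series if t.size), default=bin_width)
    n_bins = max(2, int(math.ceil(T / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    X = np.stack([np.histogram(t, bins=edges)[0].astype(float) for t in series])
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = np.zeros_like(X)
    Xc[ok] = (X[ok] - mu[ok]) / sd[ok][:, None]
    corr = Xc @ Xc.T / n_bins
    A = float(ok.sum())
    C = float((corr.sum() - np.trace(corr)) / (n - 1))
    empty = tuple(ids[i] for i in range(n) if not ok[i])
    return FreeEnergyResult(A=A, C_cross=C, F=A - C, empty_cells=empty)


@dataclass
class FreeEnergyTrace:
    """Per-epoch record of the learning diagnostics."""

    epochs: list[tuple[int, float, float, float, float]] = field(default_factory=list)

    def append(self, epoch: int, A: float, C_cross: float, bidirectional_fraction: float) -> None:
        self.epochs.append((epoch, A, C_cross, A - C_cross, bidirectional_fraction))

    @property
    def F(self) -> np.ndarray:
        return np.array([row[3] for row in self.epochs])

    @property
    def bidirectional_fraction(self) -> np.ndarray:
        return np.array([row[4] for row in self.epochs])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs, columns=["epoch", "A", "C_cross", "F", "bidirectional_fraction"])


def symmetry_index(conn: Connectome, floor: float = 1e-30) -> float:
    """Mean directional asymmetry of connection products rho*g*eps.

    0 for a fully symmetric connectome, 1 when every connection is strictly
    one-way.
    """
    pairs = conn.unordered_pairs()
    if not pairs:
        return 0.0
    vals = [abs(a - b) / (a + b + floor) for a, b in pairs.values()]
    return float(np.mean(vals))
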