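"""Postnatal synapse selection driven by pulse-pair arrival lags.

Each epoch, every mapped local-cell pair is classified per ensemble
grating by its arrival lag ``lambda``: synchronous pairs (|lambda| within
tolerance) strengthen *bidirectional* gains, creating the reverse edge
where absent; lead/lag pairs strengthen the directed lead-to-lag edge.
Pairs that remain synchronous for several consecutive epochs acquire an
established spatiotemporal orientation (STO), the acute angle of their
source segment to the radial direction.  The free-energy diagnostic
``F = A - C`` is appended to a trace every epoch, computed on surrogate
pulse trains whose pairwise synchrony follows the bidirectional gains, so
F falls as bidirectional connectivity consolidates.

Provisional STO at unestablished positions is interpolated from the
established cells with inverse-quadratic distance weights,

    phi_int = arg( sum_i u(phi_i) / (1 + C_range * r_i**2) ) / 2,

where ``u(phi) = exp(2 i phi)`` places the [0, pi/2] STO range on the
upper unit semicircle (radial and circumferential extremes antipodal), so
the argument of any positive combination stays in [0, pi] and halving it
returns a value in [0, pi/2].  Single-source and constant fields are exact
fixed points of the interpolation.

Crossed inhibition between the radially linked and circumferentially
linked groups is resolved per pinwheel core by a seeded winner-take-all
weighted by accumulated gains, assigning the whole core to high or low
space-frequency preference (HSFP / LSFP).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LocalMapSpec, MapTiling, delta_s_general
from .scaffold import (
    Connectome,
    FreeEnergyTrace,
    PairRecord,
    ScaffoldConfig,
    free_energy,
    mapped_pairs,
    surrogate_pulse_exchange,
    symmetry_index,
)
from .stimulus import Grating, crossing_interval, lag

__all__ = [
    "LearningConfig",
    "STOField",
    "TrainResult",
    "classify_pair",
    "train",
    "interpolate_sto",
    "resolve_sfp_domains",
    "bridge_long_range",
]


@dataclass(frozen=True)
class LearningConfig:
    """Parameters of postnatal synapse selection.

    ``lambda_tolerance`` is relative: a pair counts as synchronous when
    ``|lambda| <= lambda_tolerance * delta_t`` for some ensemble grating
    (dimensionless, scale-free).  Gains are soft-capped at ``g_max``.
    """

    lambda_tolerance: float = 0.05
    eta_bi: float = 0.3
    eta_uni: float = 0.15
    epsilon_rate: float = 0.1  # fast efficacy rate (reserved; efficacy stays 1)
    epochs: int = 10
    C_range: float = 1.0
    singularity_radius: float = 0.02  # mm, in local (cortical) coordinates
    establish_epochs: int = 3
    g_max: float = 10.0
    wta_sigma: float = 1.0
    hsfp_prior: float = 0.5
    V_ref: float = 3000.0  # mm/s, reference drift speed for SFP readout
    surrogate_rate: float = 20.0
    surrogate_duration: float = 20.0
    surrogate_bin: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_tolerance <= 0:
            raise ValueError("lambda_tolerance must be positive")
        for name in ("eta_bi", "eta_uni", "epsilon_rate", "g_max", "V_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def classify_pair(lam: float, tol: float) -> str:
    """Classify an arrival lag: bidirectional, directed_lead or directed_lag.

    ``directed_lead`` means lambda > tol (the p2 pulse arrives first),
    ``directed_lag`` the mirror case.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if abs(lam) <= tol:
        return "bidirectional"
    return "directed_lead" if lam > 0 else "directed_lag"


@dataclass
class STOEntry:
    phi: float | None
    established: bool
    position: complex
    map_id: str


@dataclass
class EstablishedPair:
    cell1: int
    cell2: int
    phi: float
    delta_S: float
    separation: float
    kind: str  # "radial" | "circumferential"
    geometry: "object" = None  # the full PairGeometry of the pair


@dataclass
class STOField:
    """Per-cell STO values over the local excitatory population."""

    entries: dict[int, STOEntry] = field(default_factory=dict)
    pairs: list[EstablishedPair] = field(default_factory=list)

    def established_cells(self) -> list[int]:
        return [i for i, e in self.entries.items() if e.established]

    def established_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ids = self.established_cells()
        pos = np.array([self.entries[i].position for i in ids], dtype=complex)
        phi = np.array([self.entries[i].phi for i in ids], dtype=float)
        return pos, phi

    def to_dataframe(self) -> pd.DataFrame:
        ids = sorted(self.entries)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "x_mm": [self.entries[i].position.real for i in ids],
                "y_mm": [self.entries[i].position.imag for i in ids],
                "map_id": [self.entries[i].map_id for i in ids],
                "sto_rad": [self.entries[i].phi if self.entries[i].phi is not None else np.nan for i in ids],
                "established": [self.entries[i].established for i in ids],
            }
        )


@dataclass
class TrainResult:
    connectome: Connectome
    sto_field: STOField
    trace: FreeEnergyTrace
    symmetry: list[float] = field(default_factory=list)
    pairs: list[PairRecord] = field(default_factory=list)

    def __iter__(self):
        return iter((self.connectome, self.sto_field, self.trace))


def established_pairs_df(field_: STOField) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell1": [p.cell1 for p in field_.pairs],
            "cell2": [p.cell2 for p in field_.pairs],
            "kind": [p.kind for p in field_.pairs],
            "phi_sto": [p.phi for p in field_.pairs],
            "delta_s_mm": [p.delta_S for p in field_.pairs],
            "separation_mm": [p.separation for p in field_.pairs],
        }
    )


def sto_field_from_frames(pairs_df: pd.DataFrame, conn: Connectome, tiling: MapTiling) -> STOField:
    """Rebuild an STO field (with pair geometry) from its serialized pairs."""
    from .stimulus import pair_geometry

    field_ = STOField()
    for c in conn.local_excitatory():
        field_.entries[c.cell_id] = STOEntry(None, False, c.position, c.map_id)
    specs = {m.map_id: m for m in tiling.maps}
    for row in pairs_df.itertuples(index=False):
        c1, c2 = conn.cell(int(row.cell1)), conn.cell(int(row.cell2))
        g = pair_geometry(c1.source, c2.source, c1.local_value, c2.local_value, specs[c1.map_id], conn.nu)
        field_.pairs.append(
            EstablishedPair(
                cell1=c1.cell_id,
                cell2=c2.cell_id,
                phi=g.phi_STO,
                delta_S=g.delta_S,
                separation=g.separation,
                kind=row.kind,
                geometry=g,
            )
        )
    _assign_cell_sto(conn, field_)
    return field_


def _soft_increment(g: float, eta: float, g_max: float) -> float:
    return g + eta * max(0.0, 1.0 - g / g_max)


def train(
    conn: Connectome,
    tiling: MapTiling,
    ensemble: list[Grating],
    cfg: LearningConfig,
    scaffold_config: ScaffoldConfig,
) -> TrainResult:
    """Run synchrony-driven synapse selection over the grating ensemble.

    The input connectome is not modified; a trained copy is returned
    together with the STO field and the free-energy trace.  Fully
    deterministic for a fixed (connectome, ensemble, cfg) triple.
    """
    conn = conn.copy()
    field_ = STOField()
    for c in conn.local_excitatory():
        field_.entries[c.cell_id] = STOEntry(None, False, c.position, c.map_id)
    trace = FreeEnergyTrace()
    result = TrainResult(conn, field_, trace)
    if cfg.epochs == 0:
        return result
    if not ensemble:
        raise ValueError("grating ensemble must be non-empty")

    pairs = mapped_pairs(conn, tiling, scaffold_config)
    result.pairs = pairs
    if not pairs:
        raise ValueError("no mapped pairs: empty local maps")
    # classification is purely geometric, hence constant across epochs
    plans = []
    for rec in pairs:
        classes = []
        for g in ensemble:
            dt = crossing_interval(rec.geometry, g)
            if not math.isfinite(dt):
                continue
            classes.append(classify_pair(lag(rec.geometry, g), cfg.lambda_tolerance * dt))
        plans.append((rec, classes))

    consec = {id(rec): 0 for rec, _ in plans}
    established: dict[tuple[int, int], PairRecord] = {}
    for epoch in range(1, cfg.epochs + 1):
        for rec, classes in plans:
            any_bi = "bidirectional" in classes
            if any_bi:
                _update_bidirectional(conn, rec, cfg, epoch)
            elif classes:
                # never synchronous under the ensemble: reinforce the
                # majority lead->lag direction (directed_lead = p2 first)
                n_lead = sum(1 for cl in classes if cl == "directed_lead")
                if n_lead * 2 >= len(classes):
                    _update_directed(conn, rec.cell2, rec.cell1, cfg, epoch)
                else:
                    _update_directed(conn, rec.cell1, rec.cell2, cfg, epoch)
            if any_bi:
                consec[id(rec)] += 1
                if consec[id(rec)] >= cfg.establish_epochs:
                    established[(rec.cell1, rec.cell2)] = rec
            else:
                consec[id(rec)] = 0
        trains = surrogate_pulse_exchange(
            conn,
            duration=cfg.surrogate_duration,
            seed=_epoch_seed(cfg.seed, epoch),
            rate=cfg.surrogate_rate,
            strength_scale=cfg.g_max,
        )
        fe = free_energy(trains, bin_width=cfg.surrogate_bin, duration=cfg.surrogate_duration)
        trace.append(epoch, fe.A, fe.C_cross, _local_bidirectional_fraction(conn))
        result.symmetry.append(symmetry_index(conn))

    for (i, j), rec in sorted(established.items()):
        ep = EstablishedPair(
            cell1=i,
            cell2=j,
            phi=rec.geometry.phi_STO,
            delta_S=rec.geometry.delta_S,
            separation=rec.geometry.separation,
            kind=rec.kind,
            geometry=rec.geometry,
        )
        field_.pairs.append(ep)
    _assign_cell_sto(conn, field_)
    return result


def _epoch_seed(seed: int, epoch: int) -> int:
    return int((seed * 100003 + epoch * 7919) % (2**31 - 1))


def _update_bidirectional(conn: Connectome, rec: PairRecord, cfg: LearningConfig, epoch: int) -> None:
    for pre, post in ((rec.cell1, rec.cell2), (rec.cell2, rec.cell1)):
        if not conn.has_edge(pre, post):
            conn.connect(pre, post, kind="learned", gain=0.0, epoch=epoch)
        e = conn.edge(pre, post)
        e.gain = _soft_increment(e.gain, cfg.eta_bi, cfg.g_max)


def _update_directed(conn: Connectome, lead: int, lagc: int, cfg: LearningConfig, epoch: int) -> None:
    if not conn.has_edge(lead, lagc):
        conn.connect(lead, lagc, kind="learned", gain=0.0, epoch=epoch)
    e = conn.edge(lead, lagc)
    e.gain = _soft_increment(e.gain, cfg.eta_uni, cfg.g_max)


def _local_bidirectional_fraction(conn: Connectome) -> float:
    """Fraction of connected local-cell pairs with reciprocal gain."""
    local = {c.cell_id for c in conn.local_excitatory()}
    n = n_bi = 0
    for (i, j), (s_ij, s_ji) in conn.unordered_pairs().items():
        if i in local and j in local:
            n += 1
            if min(s_ij, s_ji) > 0:
                n_bi += 1
    return n_bi / n if n else 0.0


def _pair_bidirectional_gain(conn: Connectome, i: int, j: int) -> float:
    if conn.has_edge(i, j) and conn.has_edge(j, i):
        return min(conn.edge(i, j).gain, conn.edge(j, i).gain)
    return 0.0


def _assign_cell_sto(conn: Connectome, field_: STOField) -> None:
    best: dict[int, tuple[float, float]] = {}  # cell -> (gain, phi)
    for ep in field_.pairs:
        g = _pair_bidirectional_gain(conn, ep.cell1, ep.cell2)
        for cid in (ep.cell1, ep.cell2):
            if g > best.get(cid, (-1.0, 0.0))[0]:
                best[cid] = (g, ep.phi)
    for cid, (_, phi) in best.items():
        e = field_.entries[cid]
        e.phi = phi
        e.established = True


# --------------------------------------------------------------------------
# STO interpolation (provisional STO at unestablished positions)


def interpolate_sto(
    field_: STOField,
    query_positions: np.ndarray,
    C_range: float,
) -> np.ndarray:
    """Weighted circular interpolation of STO at query positions.

    Established STO angles phi_i in [0, pi/2] are encoded as unit vectors
    exp(2 i phi_i), combined with weights 1 / (1 + C_range * r_i**2) and
    decoded as arg/2, which lands back in [0, pi/2].
    """
    pos, phi = field_.established_arrays()
    if pos.size == 0:
        raise ValueError("no established STO cells to interpolate from")
    q = np.asarray(query_positions, dtype=complex).ravel()
    u = np.exp(2j * phi)  # (n_est,)
    r2 = np.abs(q[:, None] - pos[None, :]) ** 2
    w = 1.0 / (1.0 + C_range * r2)
    s = w @ u
    ang = np.angle(s)  # numerically may dip slightly below 0
    ang = np.clip(ang, 0.0, math.pi)
    return ang / 2.0


# --------------------------------------------------------------------------
# crossed-inhibition resolution of SFP domains


def resolve_sfp_domains(
    tiling: MapTiling,
    field_: STOField,
    conn: Connectome,
    cfg: LearningConfig,
) -> pd.DataFrame:
    """Assign per-cell SFP values and HSFP/LSFP classes.

    Continuous SFP follows the cell's synchronous-pair geometry,
    ``SFP = nu / (|delta_S| * V_ref)`` (cycles/mm), averaged with gain
    weights over the cell's established pairs in each STO group
    (radial phi < pi/4 vs circumferential phi >= pi/4).  Within
    ``singularity_radius`` of each map centre the two groups compete:
    a seeded winner-take-all weighted by accumulated gains assigns the
    whole pinwheel core to HSFP (circumferential wins, small |delta_S|)
    or LSFP (radial wins).  Outside the core a cell follows its
    circumferential group when it has one (the synergic periphery) and
    its radial group otherwise.
    """
    if not field_.pairs:
        raise ValueError("untrained connectome: no established pairs")
    rng = np.random.default_rng(cfg.seed)
    nu = conn.nu
    # per-cell group statistics
    stats: dict[int, dict[str, list[tuple[float, float]]]] = {}
    for ep in field_.pairs:
        g = _pair_bidirectional_gain(conn, ep.cell1, ep.cell2)
        if g <= 0:
            continue
        grp = "circ" if ep.phi >= math.pi / 4 else "rad"
        for cid in (ep.cell1, ep.cell2):
            stats.setdefault(cid, {"rad": [], "circ": []})[grp].append((g, abs(ep.delta_S)))

    def group_value(cid: int, grp: str) -> tuple[float, float]:
        """(total gain, gain-weighted mean |delta_S|) of a cell's group."""
        lst = stats.get(cid, {}).get(grp, [])
        if not lst:
            return 0.0, math.nan
        gs = np.array([g for g, _ in lst])
        ds = np.array([d for _, d in lst])
        return float(gs.sum()), float((gs * ds).sum() / gs.sum())

    cells = conn.local_excitatory()
    by_map: dict[str, list] = {}
    for c in cells:
        by_map.setdefault(c.map_id, []).append(c)
    rows = []
    # draw per-map winner noise in sorted map order for determinism
    for spec in tiling.maps:
        mc = by_map.get(spec.map_id, [])
        core = [c for c in mc if abs(c.position - spec.p0) < cfg.singularity_radius]
        # intensive comparison: mean gain per established pair, so the
        # conflict is decided by synchrony strength, not group size
        n_rad = sum(len(stats.get(c.cell_id, {}).get("rad", [])) for c in core)
        n_circ = sum(len(stats.get(c.cell_id, {}).get("circ", [])) for c in core)
        G_rad = sum(group_value(c.cell_id, "rad")[0] for c in core) / max(n_rad, 1)
        G_circ = sum(group_value(c.cell_id, "circ")[0] for c in core) / max(n_circ, 1)
        z = rng.normal(0.0, 1.0, 2)
        prior = math.log(cfg.hsfp_prior / (1.0 - cfg.hsfp_prior)) if 0 < cfg.hsfp_prior < 1 else 0.0
        w_circ = math.log(G_circ + 1e-12) + cfg.wta_sigma * z[0] + prior
        w_rad = math.log(G_rad + 1e-12) + cfg.wta_sigma * z[1]
        core_class = "HSFP" if w_circ > w_rad else "LSFP"
        core_grp = "circ" if core_class == "HSFP" else "rad"
        # map-level fallback |delta_S| for winner group
        ds_all = [
            group_value(c.cell_id, core_grp)[1]
            for c in core
            if not math.isnan(group_value(c.cell_id, core_grp)[1])
        ]
        ds_fallback = float(np.mean(ds_all)) if ds_all else math.nan
        for c in mc:
            in_core = abs(c.position - spec.p0) < cfg.singularity_radius
            if in_core:
                grp, klass = core_grp, core_class
            else:
                g_c, _ = group_value(c.cell_id, "circ")
                grp = "circ" if g_c > 0 else "rad"
                klass = "HSFP" if grp == "circ" else "LSFP"
            _, ds = group_value(c.cell_id, grp)
            if math.isnan(ds) and in_core:
                ds = ds_fallback
            sfp = nu / (ds * cfg.V_ref) if ds and not math.isnan(ds) and ds > 0 else math.nan
            tfp = nu / ds if ds and not math.isnan(ds) and ds > 0 else math.nan
            entry = field_.entries[c.cell_id]
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "x_mm": c.position.real,
                    "y_mm": c.position.imag,
                    "map_id": c.map_id,
                    "limb": c.limb,
                    "ring_index": c.ring_index,
                    "zone": "core" if in_core else "outer",
                    "op_rad": c.op,
                    "sto_rad": entry.phi if entry.phi is not None else np.nan,
                    "delta_s_mm": ds,
                    "sfp_cyc_per_mm": sfp,
                    "sfp_class": klass,
                    "tfp_hz": tfp,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# long-range bridging across limbs and maps


def bridge_long_range(
    tiling: MapTiling,
    conn: Connectome,
    ensemble: list[Grating],
    threshold: float,
    max_separation: float | None = None,
    epoch: int = 0,
) -> tuple[Connectome, list[tuple[int, int, float]]]:
    """Create postnatal bridge edges between limbs and maps.

    Candidate pairs are local excitatory cells differing in limb or map.
    The general-case path difference is computed through the inverse maps
    and a bridge forms when some ensemble grating brings the arrival lag
    within ``threshold * delta_t`` (relative tolerance; threshold 0 admits
    nothing).  Returns a new connectome plus (cell1, cell2, lambda) rows
    for the bridges created.
    """
    conn = conn.copy()
    cells = conn.local_excitatory()
    specs = {m.map_id: m for m in tiling.maps}
    created: list[tuple[int, int, float]] = []
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    for i, c1 in enumerate(cells):
        for c2 in cells[i + 1 :]:
            if c1.map_id == c2.map_id and c1.limb == c2.limb:
                continue
            if max_separation is not None and abs(c1.position - c2.position) > max_separation:
                continue
            s1, s2 = specs[c1.map_id], specs[c2.map_id]
            dS = delta_s_general(c1.local_value, s1, c2.local_value, s2)
            a, b = (c1, c2) if dS >= 0 else (c2, c1)
            dS = abs(dS)
            # global source points via the cells' own wiring
            P1, P2 = a.source, b.source
            sep = abs(P1 - P2)
            if sep == 0:
                continue
            psi = cmath.phase(P2 - P1)
            best = None
            for g in ensemble:
                s = abs(math.sin(g.orientation - psi))
                if s == 0:
                    continue
                dt = sep / (g.V * s)
                lam = dS / conn.nu - dt
                if abs(lam) <= threshold * dt:
                    best = lam if best is None or abs(lam) < abs(best) else best
            if best is not None:
                conn.connect(a.cell_id, b.cell_id, kind="bridge", gain=1.0, epoch=epoch)
                conn.connect(b.cell_id, a.cell_id, kind="bridge", gain=1.0, epoch=epoch)
                created.append((a.cell_id, b.cell_id, best))
    return conn, created
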