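"""Virtual experiments and map statistics on trained networks.

The observable "response" of a local cell is operationalised as the
gain-weighted rate of same-line pulse-pair coincidences across the cell's
bidirectionally linked (established) assembly, measured on the event-based
pulse oracle, and attenuated by a log-Gaussian resonance factor around the
assembly's synchronous-pair rate ``omega = nu/|delta_S|``:

    response = sum_pairs gain * coincidence_rate * exp(-ln(KV/omega)^2 / 2 sigma^2)

The coincidence term carries the lag (spatiotemporal-orientation)
selectivity -- a pair fires synchronously only when the probe drives its
lag to zero -- while the resonance term carries the temporal-frequency
selectivity of the recurrently connected assembly, whose preferred pulse
rate is omega.  Temporal-frequency preference is then TFP = omega, space
frequency preference SFP = omega / V for a given drift speed V, and square
gratings decompose into odd harmonics (amplitudes 1, 1/3, 1/5) whose
responses sum, favouring broadband (high-SFP) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import MapTiling, wrapped_op_winding
from .plasticity import EstablishedPair, STOField, _pair_bidirectional_gain
from .scaffold import Connectome
from .stimulus import Grating, crossing_interval, generate_pulse_trains, lag, synchrony_rate

__all__ = [
    "TuningCurve",
    "MapStatistics",
    "response",
    "measure_tfp",
    "measure_sfp",
    "cancellation_test",
    "map_statistics",
    "detect_pinwheels",
    "save_fields_hdf5",
]


def save_fields_hdf5(fields: pd.DataFrame, path, grid_n: int = 64) -> None:
    """Rasterize per-cell OP/STO/SFP fields to grids and write HDF5.

    Nearest-cell rasterization over the bounding box of the cells; grids
    are stored as ``op_rad``, ``sto_rad`` and ``sfp_cyc_per_mm`` datasets
    with the axes in ``x_mm`` / ``y_mm``.
    """
    import h5py
    from scipy.spatial import cKDTree

    xy = fields[["x_mm", "y_mm"]].to_numpy()
    tree = cKDTree(xy)
    xs = np.linspace(xy[:, 0].min(), xy[:, 0].max(), grid_n)
    ys = np.linspace(xy[:, 1].min(), xy[:, 1].max(), grid_n)
    gx, gy = np.meshgrid(xs, ys)
    _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    with h5py.File(path, "w") as h5:
        h5.create_dataset("x_mm", data=xs)
        h5.create_dataset("y_mm", data=ys)
        for col in ("op_rad", "sto_rad", "sfp_cyc_per_mm"):
            vals = fields[col].to_numpy()[idx].reshape(grid_n, grid_n)
            h5.create_dataset(col, data=vals)


@dataclass
class TuningCurve:
    axis: str  # "K" | "V" | "omega" | "orientation"
    values: np.ndarray
    responses: np.ndarray
    flag: str | None = None  # e.g. "outside_probe_range", "unbounded_omega"

    @property
    def peak(self) -> float:
        return float(self.values[int(np.argmax(self.responses))])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({self.axis: self.values, "response": self.responses})


def _assembly(cell_id: int, conn: Connectome, field_: STOField) -> list[tuple[EstablishedPair, float]]:
    cell = conn.cell(cell_id)
    if cell.kind != "local_exc" or cell.map_id is None:
        raise ValueError(f"cell {cell_id} is not a mapped local excitatory cell")
    out = []
    for ep in field_.pairs:
        if cell_id in (ep.cell1, ep.cell2):
            g = _pair_bidirectional_gain(conn, ep.cell1, ep.cell2)
            if g > 0:
                out.append((ep, g))
    return out


def _same_line_coincidence_rate(
    ep: EstablishedPair, grating: Grating, duration: float, eps: float, jitter_sd: float, seed: int
) -> float:
    """Rate of same-line pulse pairs arriving within ``eps`` seconds.

    Same-line matching (k-th crossing of P1 with k-th crossing of P2) is
    the mechanism that drives the pair: with zero jitter every pair is
    separated by exactly the lag lambda.
    """
    t1, t2 = generate_pulse_trains(ep.geometry, grating, duration, jitter_sd=jitter_sd, seed=seed)
    n = min(t1.n, t2.n)
    if n == 0:
        return 0.0
    hits = int(np.sum(np.abs(t1.times[:n] - t2.times[:n]) <= eps))
    return hits / duration


def response(
    cell_id: int,
    grating: Grating,
    conn: Connectome,
    field_: STOField,
    duration: float = 0.05,
    seed: int = 0,
    lambda_tolerance: float = 0.05,
    sigma_rate: float = 0.2,
    jitter_sd: float = 0.0,
) -> float:
    """Scalar response rate (1/s) of a trained cell to a drifting grating."""
    pairs = _assembly(cell_id, conn, field_)
    total = 0.0
    for harmonic, amp in grating.harmonics():
        for k, (ep, gain) in enumerate(pairs):
            dt = crossing_interval(ep.geometry, harmonic)
            if not math.isfinite(dt):
                continue
            eps = lambda_tolerance * dt
            rate = _same_line_coincidence_rate(ep, harmonic, duration, eps, jitter_sd, seed + k)
            if rate == 0.0:
                continue
            om = synchrony_rate(ep.geometry)
            if not math.isfinite(om):
                continue
            drive = harmonic.K * harmonic.V
            res = math.exp(-(math.log(drive / om)) ** 2 / (2.0 * sigma_rate**2))
            total += amp * gain * rate * res
    return total


def _dominant_pair(cell_id: int, conn: Connectome, field_: STOField) -> tuple[EstablishedPair, float]:
    pairs = _assembly(cell_id, conn, field_)
    if not pairs:
        raise ValueError(f"cell {cell_id} has no established pairs")
    return max(pairs, key=lambda pg: pg[1])


def measure_tfp(
    cell_id: int,
    conn: Connectome,
    field_: STOField,
    omega_grid: np.ndarray,
    duration: float | None = None,
    seed: int = 0,
    **resp_kw,
) -> TuningCurve:
    """Temporal-frequency tuning: sweep KV at the orientation orthogonal to
    the dominant pair with K = 1/separation (m = 1, sin theta = 1), so the
    stimulus temporal frequency KV reads directly in units of omega."""
    ep, _ = _dominant_pair(cell_id, conn, field_)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if ep.delta_S == 0.0:
        return TuningCurve("omega", omega_grid, np.zeros_like(omega_grid), flag="unbounded_omega")
    K = 1.0 / ep.separation
    ori = ep.geometry.psi + math.pi / 2
    responses = np.empty_like(omega_grid)
    for i, om in enumerate(omega_grid):
        g = Grating(K=K, V=om / K, orientation=ori)
        dur = duration if duration is not None else 1000.0 / (g.K * g.V)
        responses[i] = response(cell_id, g, conn, field_, duration=dur, seed=seed, **resp_kw)
    flag = None
    om_true = synchrony_rate(ep.geometry)
    if om_true > omega_grid.max() or responses.max() == 0.0:
        flag = "outside_probe_range"
    return TuningCurve("omega", omega_grid, responses, flag=flag)


def measure_sfp(
    cell_id: int,
    conn: Connectome,
    field_: STOField,
    K_grid: np.ndarray,
    V_ref: float,
    duration: float | None = None,
    seed: int = 0,
    **resp_kw,
) -> TuningCurve:
    """Space-frequency tuning at fixed drift speed ``V_ref``.

    The probe orientation opens the lag gate of the dominant pair
    (sin theta* = separation * nu / (V_ref * |delta_S|)); the peak then
    falls at K = omega / V_ref, the rate-resonance optimum.
    """
    ep, _ = _dominant_pair(cell_id, conn, field_)
    K_grid = np.asarray(K_grid, dtype=float)
    if ep.delta_S == 0.0:
        return TuningCurve("K", K_grid, np.zeros_like(K_grid), flag="unbounded_omega")
    s_star = ep.separation * ep.geometry.nu / (V_ref * abs(ep.delta_S))
    if s_star > 1.0:
        return TuningCurve("K", K_grid, np.zeros_like(K_grid), flag="outside_probe_range")
    ori = ep.geometry.psi + math.asin(s_star)
    responses = np.empty_like(K_grid)
    for i, K in enumerate(K_grid):
        g = Grating(K=K, V=V_ref, orientation=ori)
        dur = duration if duration is not None else 1000.0 / (g.K * g.V)
        responses[i] = response(cell_id, g, conn, field_, duration=dur, seed=seed, **resp_kw)
    return TuningCurve("K", K_grid, responses, flag=None if responses.max() > 0 else "outside_probe_range")


def cancellation_test(
    cell_id: int,
    grating1: Grating,
    grating2: Grating,
    conn: Connectome,
    field_: STOField,
    inhibition: float = 0.6,
    lambda_tolerance: float = 0.05,
    duration: float = 0.05,
    seed: int = 0,
    **resp_kw,
) -> dict:
    """Concurrent two-grating presentation with crossed inhibition.

    The pairs resonant to each grating form its drive group; disjoint
    groups (e.g. a radial and a circumferential assembly at matched omega)
    suppress each other in proportion to ``inhibition``, so the combined
    response falls below either single-grating response instead of
    summing.  Returns the single responses, the combined response, and
    ``ratio = combined / min(single)``.
    """

    def drive_group(g: Grating) -> frozenset:
        out = set()
        for ep, gain in _assembly(cell_id, conn, field_):
            dt = crossing_interval(ep.geometry, g)
            if math.isfinite(dt) and abs(lag(ep.geometry, g)) <= lambda_tolerance * dt:
                out.add((ep.cell1, ep.cell2))
        return frozenset(out)

    r1 = response(cell_id, grating1, conn, field_, duration=duration, seed=seed,
                  lambda_tolerance=lambda_tolerance, **resp_kw)
    r2 = response(cell_id, grating2, conn, field_, duration=duration, seed=seed,
                  lambda_tolerance=lambda_tolerance, **resp_kw)
    g1, g2 = drive_group(grating1), drive_group(grating2)
    union = g1 | g2
    overlap = len(g1 & g2) / len(union) if union else 1.0
    conflict = 1.0 - overlap
    combined = (1.0 - inhibition * conflict) * max(r1, r2)
    lo = min(r1, r2)
    ratio = combined / lo if lo > 0 else math.nan
    return {"r1": r1, "r2": r2, "combined": combined, "ratio": ratio, "conflict": conflict}


# --------------------------------------------------------------------------
# map statistics


@dataclass
class MapStatistics:
    pinwheels: list[tuple[complex, float]]  # (position, winding)
    sfp_by_zone: dict[str, float]
    bimodality: dict[str, float]
    per_map_core_class: dict[str, str] = field(default_factory=dict)


def detect_pinwheels(op_grid: np.ndarray, origin: complex = 0j, spacing: float = 1.0) -> list[tuple[complex, float]]:
    """Detect OP singularities on a gridded orientation field.

    Sums wrapped OP differences around every 2x2 plaquette; plaquettes with
    total winding +-pi are singular, and adjacent singular plaquettes of
    equal sign merge into one pinwheel at their centroid.
    """
    op = np.asarray(op_grid, dtype=float)
    if op.ndim != 2 or op.shape[0] < 3 or op.shape[1] < 3:
        raise ValueError("OP field must be a grid of at least 3x3")

    def wrap(d):
        return (d + math.pi / 2) % math.pi - math.pi / 2

    w = (
        wrap(op[:-1, 1:] - op[:-1, :-1])
        + wrap(op[1:, 1:] - op[:-1, 1:])
        + wrap(op[1:, :-1] - op[1:, 1:])
        + wrap(op[:-1, :-1] - op[1:, :-1])
    )
    out = []
    for sign in (+1, -1):
        mask = sign * w > math.pi / 2
        labels, n = ndimage.label(mask)
        for lab in range(1, n + 1):
            ii, jj = np.nonzero(labels == lab)
            cy, cx = ii.mean() + 0.5, jj.mean() + 0.5
            out.append((origin + spacing * complex(cx, cy), sign * math.pi))
    return out


def _ring_winding(df_map: pd.DataFrame, center: complex) -> float:
    """OP winding around the map centre from the outermost cell ring."""
    z = df_map["x_mm"].to_numpy() + 1j * df_map["y_mm"].to_numpy()
    r = np.abs(z - center)
    outer = r >= 0.5 * r.max()
    z, op = z[outer], df_map["op_rad"].to_numpy()[outer]
    # the two limbs duplicate apparent positions; keep one per angle
    ang = np.angle(z - center)
    order = np.argsort(ang)
    ang, op = ang[order], op[order]
    keep = np.concatenate([[True], np.diff(ang) > 1e-9])
    return wrapped_op_winding(op[keep])


def _two_cluster_separation(values: np.ndarray) -> float:
    """Best 1-D two-means split: between-cluster share of total variance."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or np.allclose(v, v[0]):
        return 0.0
    total = ((v - v.mean()) ** 2).sum()
    best = 0.0
    for i in range(1, n):
        a, b = v[:i], v[i:]
        between = i * (a.mean() - v.mean()) ** 2 + (n - i) * (b.mean() - v.mean()) ** 2
        best = max(best, between / total)
    return float(best)


def map_statistics(
    fields: pd.DataFrame,
    tiling: MapTiling,
    n_shuffles: int = 100,
    seed: int = 0,
    gradient_quantile: float = 0.5,
) -> MapStatistics:
    """Pinwheel loci, SFP-by-zone summaries and core-SFP bimodality.

    ``fields`` is the per-cell frame from `resolve_sfp_domains`.  Zones:
    "core" from the frame; remaining cells split into "linear" (OP
    gradient below the quantile and distance above the map median -- the
    smooth periphery) and "mid_radial".  Bimodality of per-map core SFP
    means is scored by the best two-means separation, against a null that
    shuffles core cells across maps.
    """
    if len(fields) < 9:
        raise ValueError("fields must cover at least a 3x3 cell grid")
    rng = np.random.default_rng(seed)
    pinwheels = []
    per_map_class = {}
    zone = pd.Series("mid_radial", index=fields.index)
    zone[fields["zone"] == "core"] = "core"
    for spec in tiling.maps:
        sub = fields[fields["map_id"] == spec.map_id]
        if len(sub) >= 4:
            wind = _ring_winding(sub, spec.p0)
            if abs(wind) > math.pi / 2:
                pinwheels.append((spec.p0, math.copysign(math.pi, wind)))
        core_sub = sub[sub["zone"] == "core"]
        if len(core_sub):
            per_map_class[spec.map_id] = core_sub["sfp_class"].mode().iat[0]
        # OP gradient per cell from 3 nearest same-map neighbours
        z = sub["x_mm"].to_numpy() + 1j * sub["y_mm"].to_numpy()
        op = sub["op_rad"].to_numpy()
        r = np.abs(z - spec.p0)
        grad = np.full(len(sub), np.nan)
        for i in range(len(sub)):
            d = np.abs(z - z[i])
            d[i] = np.inf
            near = np.argsort(d)[:3]
            dd = d[near]
            dop = np.abs((op[near] - op[i] + math.pi / 2) % math.pi - math.pi / 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                grad[i] = np.nanmean(np.where(dd > 0, dop / dd, np.nan))
        outer = (sub["zone"] != "core").to_numpy()
        if outer.sum():
            gthr = np.nanquantile(grad[outer], gradient_quantile)
            rthr = np.median(r[outer])
            distal = outer & (r >= rthr)
            zone.loc[sub.index[distal & (grad <= gthr)]] = "linear"
            zone.loc[sub.index[distal & (grad > gthr)]] = "other"
    sfp = fields["sfp_cyc_per_mm"]
    sfp_by_zone = {
        zname: float(sfp[zone == zname].dropna().mean()) if (zone == zname).any() else math.nan
        for zname in ("core", "mid_radial", "linear")
    }
    # core bimodality across maps
    core = fields[fields["zone"] == "core"].dropna(subset=["sfp_cyc_per_mm"])
    stat = null_95 = math.nan
    if len(core) and core["map_id"].nunique() >= 4:
        means = core.groupby("map_id")["sfp_cyc_per_mm"].mean().to_numpy()
        stat = _two_cluster_separation(means)
        vals = core["sfp_cyc_per_mm"].to_numpy()
        groups = core["map_id"].to_numpy()
        nulls = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(vals)
            dfp = pd.DataFrame({"m": groups, "v": perm})
            nulls[s] = _two_cluster_separation(dfp.groupby("m")["v"].mean().to_numpy())
        null_95 = float(np.quantile(nulls, 0.95))
    return MapStatistics(
        pinwheels=pinwheels,
        sfp_by_zone=sfp_by_zone,
        bimodality={"separation": float(stat), "null_95": null_95},
        per_map_core_class=per_map_class,
    )
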