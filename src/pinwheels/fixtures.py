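"""Deterministic small-scale study scenarios.

Each fixture realises the study conditions at desk scale: a tiling, its
antenatal connectome, and a grating ensemble *designed from the scaffold
geometry* to resonate with its radial pairs (at every ring) and with the
circumferential pairs of the innermost ring (creating the radial/
circumferential conflict at each pinwheel core) and of the outermost ring
(the synergic periphery).  Mid-ring circumferential pairs are deliberately
left off-resonance -- the ensemble builder prunes any grating that would
synchronise them -- so mid-radius cells remain dominated by the radial,
low-SFP geometry, as the competition account requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import (
    GratingSettings,
    LearningSettings,
    RunConfig,
    ScaffoldSettings,
    SheetSettings,
    config_to_objects,
)
from .geometry import MapTiling
from .plasticity import LearningConfig
from .scaffold import Connectome, ScaffoldConfig, build_antenatal_connectome, mapped_pairs, ring_radii
from .stimulus import Grating, crossing_interval, lag

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES", "resonant_ensemble"]

FIXTURE_NAMES = ("one_map_minimal", "two_map_mirror", "ensemble_20maps")


@dataclass
class Fixture:
    name: str
    config: RunConfig
    tiling: MapTiling
    scaffold_config: ScaffoldConfig
    learning: LearningConfig
    connectome: Connectome
    ensemble: list[Grating]


def resonant_ensemble(
    conn: Connectome,
    tiling: MapTiling,
    scfg: ScaffoldConfig,
    lambda_tolerance: float = 0.05,
    circ_rings: tuple[int, ...] | None = None,
) -> list[Grating]:
    """Gratings tuned to the scaffold's pair classes.

    For each radial pair (every ring) and each circumferential pair on the
    selected rings (default: innermost and outermost), one grating is
    oriented orthogonally to the pair segment (sin theta = 1) with drift
    speed set by the zero-lag condition V = separation * nu / delta_S.
    Near-duplicates are merged and any grating that would also
    synchronise a mid-ring circumferential pair is pruned.
    """
    if circ_rings is None:
        circ_rings = (0, scfg.n_rings - 1)
    pairs = mapped_pairs(conn, tiling, scfg)
    K0 = scfg.n_rings / tiling.map_radius  # m = separation * K0 ~ 1 for radial pairs
    candidates: dict[tuple[float, float], Grating] = {}
    for rec in pairs:
        ring = conn.cell(rec.cell1).ring_index
        if rec.kind == "circumferential" and ring not in circ_rings:
            continue
        g = rec.geometry
        if g.delta_S <= 0:
            continue
        ori = (g.psi + math.pi / 2) % math.pi
        V = g.separation * conn.nu / g.delta_S
        key = (round(ori, 4), round(math.log(V), 4))
        if key not in candidates:
            candidates[key] = Grating(K=K0, V=V, orientation=ori)
    mid_circ = [
        r
        for r in pairs
        if r.kind == "circumferential" and conn.cell(r.cell1).ring_index not in circ_rings
    ]
    out = []
    for key in sorted(candidates):
        g = candidates[key]
        bad = False
        for rec in mid_circ:
            dt = crossing_interval(rec.geometry, g)
            if math.isfinite(dt) and abs(lag(rec.geometry, g)) <= lambda_tolerance * dt:
                bad = True
                break
        if not bad:
            out.append(g)
    return out


def _base_learning(tiling: MapTiling, scfg: ScaffoldConfig, p_prime_mag: float, **overrides) -> LearningSettings:
    radii = ring_radii(tiling, scfg)
    core_r = p_prime_mag * (radii[0] + radii[1]) / 2.0 if len(radii) > 1 else p_prime_mag * radii[0] * 1.5
    defaults = dict(singularity_radius=core_r, V_ref=10.0 * scfg.nu)
    defaults.update(overrides)
    return LearningSettings(**defaults)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a named fixture deterministically from a seed."""
    if name == "one_map_minimal":
        sheet = SheetSettings(width=1.0, height=1.0, map_spacing=1.0)
        scaffold = ScaffoldSettings(n_azimuths=8, n_rings=3)
        surrogate = dict(surrogate_duration=10.0)
    elif name == "two_map_mirror":
        sheet = SheetSettings(width=2.0, height=1.0, map_spacing=1.0, map_radius=0.6)
        scaffold = ScaffoldSettings(n_azimuths=8, n_rings=3)
        surrogate = dict(surrogate_duration=10.0)
    elif name == "ensemble_20maps":
        sheet = SheetSettings(width=5.0, height=4.0, map_spacing=1.0, jitter=0.05)
        scaffold = ScaffoldSettings(n_azimuths=8, n_rings=3)
        surrogate = dict(surrogate_duration=20.0)
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    cfg = RunConfig(sheet=sheet, scaffold=scaffold, seed=seed)
    tiling, scfg, _, _ = config_to_objects(cfg)
    conn = build_antenatal_connectome(tiling, scfg, seed=seed)
    ensemble = resonant_ensemble(conn, tiling, scfg)
    learning = _base_learning(tiling, scfg, abs(complex(*sheet.p_prime)), **surrogate)
    cfg = RunConfig(
        sheet=sheet,
        scaffold=scaffold,
        learning=learning,
        gratings=[
            GratingSettings(K=g.K, V=g.V, orientation=g.orientation, phase=g.phase, profile=g.profile)
            for g in ensemble
        ],
        seed=seed,
    )
    _, _, lcfg, ensemble = config_to_objects(cfg)
    return Fixture(
        name=name,
        config=cfg,
        tiling=tiling,
        scaffold_config=scfg,
        learning=lcfg,
        connectome=conn,
        ensemble=ensemble,
    )
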