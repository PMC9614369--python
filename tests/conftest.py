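"""Shared fixtures: trained networks are expensive enough to share per session."""

from __future__ import annotations

import pytest

import pinwheels as pw


@pytest.fixture(scope="session")
def one_map_trained():
    fx = pw.make_fixture("one_map_minimal", seed=1)
    result = pw.train(fx.connectome, fx.tiling, fx.ensemble, fx.learning, fx.scaffold_config)
    fields = pw.resolve_sfp_domains(fx.tiling, result.sto_field, result.connectome, fx.learning)
    return fx, result, fields


@pytest.fixture(scope="session")
def two_map_trained():
    fx = pw.make_fixture("two_map_mirror", seed=1)
    result = pw.train(fx.connectome, fx.tiling, fx.ensemble, fx.learning, fx.scaffold_config)
    return fx, result


@pytest.fixture(scope="session")
def ensemble_runs():
    """ensemble_20maps trained for three seeds, with fields and statistics."""
    out = []
    for seed in (1, 2, 3):
        fx = pw.make_fixture("ensemble_20maps", seed=seed)
        result = pw.train(fx.connectome, fx.tiling, fx.ensemble, fx.learning, fx.scaffold_config)
        fields = pw.resolve_sfp_domains(fx.tiling, result.sto_field, result.connectome, fx.learning)
        stats = pw.map_statistics(fields, fx.tiling, seed=seed)
        out.append((fx, result, fields, stats))
    return out
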