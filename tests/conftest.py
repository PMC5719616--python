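"""Shared fixtures: small generated meshes and the solved default pipeline.

Session-scoped fixtures cache the expensive builds (the synthetic limb and
one solved stance position) so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from stancelimb.io import PipelineConfig
from stancelimb.rigid_statics import solve_position
from stancelimb.synthetic_anatomy import (
    BoneSpec,
    PatchSpec,
    build_limb,
    gen_attachment_patches,
    gen_bone_mesh,
    gen_gait_table,
)
from stancelimb.validation import build_position_model, run_position


@pytest.fixture(scope="session")
def small_tube():
    """A small hollow-tube bone mesh with one end-cap patch."""
    mesh = gen_bone_mesh(BoneSpec("tube", 60.0, 12.0, 8.0, 6.0))
    gen_attachment_patches(mesh, [PatchSpec("cap", (0.0, 60.0, 0.0), 12.2, normal=(0, 1, 0))])
    return mesh


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def gait_table(default_config):
    return gen_gait_table(default_config.gait, seed=0)


@pytest.fixture(scope="session")
def limb_pos4(default_config, gait_table):
    pos = gait_table[3]
    return build_limb(default_config.limb, flexion_deg=pos.knee_flexion, seed=0)


@pytest.fixture(scope="session")
def solved_pos4(default_config, gait_table, limb_pos4):
    """Model, recruitment solution, report and FE result for position 4."""
    pos = gait_table[3]
    model = build_position_model(limb_pos4, pos, default_config)
    recruitment = solve_position(model.linkage, pos, limb_pos4.muscles)
    report, result = run_position(model, pos, recruitment, default_config)
    return {
        "position": pos,
        "model": model,
        "recruitment": recruitment,
        "report": report,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
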