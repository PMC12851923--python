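"""Shared fixtures: all test data is generated at test time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from poselens.datamodel import ComplexRecord
from poselens.fixtures import (
    FixtureSpec,
    MethodProfile,
    embed_ligand,
    make_fixture_dataset,
    make_helix,
    make_mock_method_runs,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_record() -> ComplexRecord:
    """One ethanol-bound helix target."""
    return make_toy_complex(FixtureSpec(seed=7, n_residues=12, ligand_templates=("CCO",)))


@pytest.fixture(scope="session")
def multi_record() -> ComplexRecord:
    """A three-ligand target (primary + two fragments)."""
    return make_toy_complex(
        FixtureSpec(
            seed=11,
            n_residues=16,
            ligand_templates=("CC(=O)Nc1ccccc1", "CCO", "c1ccccc1"),
            target_id="multi1",
        )
    )


@pytest.fixture(scope="session")
def benzene_pose():
    return embed_ligand("c1ccccc1", seed=3, ligand_id="BNZ", role="primary")


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture(scope="session")
def bench_env(tmp_path_factory) -> dict:
    """A small on-disk benchmark: 4 toy targets, 3 mock methods, 2 runs."""
    root = tmp_path_factory.mktemp("bench")
    manifest, records = make_fixture_dataset(root, n_targets=4, seed=7)
    profiles = [
        MethodProfile("exact", 0.0),
        MethodProfile("noisy", 1.5),
        MethodProfile("bad", 25.0),
    ]
    predictions = make_mock_method_runs(
        records, profiles, n_runs=2, seed=7, out_dir=root / "predictions"
    )
    return {
        "root": root,
        "manifest": manifest,
        "records": records,
        "profiles": profiles,
        "predictions": predictions,
        "methods": [p.name for p in profiles],
        "n_runs": 2,
    }


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation for invariance tests."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
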