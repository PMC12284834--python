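"""Shared fixtures: ideal silk-parameter bundles and small hand-built models.

All structural fixtures are generated programmatically from the Crick
builder; nothing is read from data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from coilspect.crick_synth import CrickParams, build_bundle
from coilspect.geometry import fit_coiled_coil
from coilspect.structure_io import (
    AtomRecord,
    ChainModel,
    ResidueRecord,
    StructureModel,
)


@pytest.fixture(scope="session")
def silk_params() -> CrickParams:
    """Antiparallel 4-helix bundle at the silk dimensions (r0 5.8 Å,
    pitch 153 Å, 168 residues/chain, U/D/U/D)."""
    return CrickParams.silk_tetramer()


@pytest.fixture(scope="session")
def silk_bundle(silk_params):
    return build_bundle(silk_params)


@pytest.fixture(scope="session")
def silk_fit(silk_bundle):
    model, _ = silk_bundle
    return fit_coiled_coil(model)


def make_residue(seq_id: int, res_name: str, **atoms) -> ResidueRecord:
    """Residue from atom_name=(x, y, z) keyword arguments."""
    elements = {"N": "N", "O": "O"}
    rec = ResidueRecord(seq_id=seq_id, res_name=res_name)
    for name, pos in atoms.items():
        elem = elements.get(name[0], "C")
        rec.add_atom(AtomRecord(name, elem, np.asarray(pos, dtype=float)))
    return rec


def make_model(chains: dict[str, list[ResidueRecord]]) -> StructureModel:
    return StructureModel(
        chains=[ChainModel(chain_id=cid, residues=res)
                for cid, res in chains.items()]
    )


def rotate_translate(model: StructureModel, rotation: np.ndarray,
                     translation: np.ndarray) -> StructureModel:
    """Rigidly transformed copy of a model."""
    from coilspect.crick_synth import perturb

    out = perturb(model, 0.0, 0)  # deep copy
    for chain in out:
        for res in chain:
            for atom in res.atoms.values():
                atom.position[:] = rotation @ atom.position + translation
    return out


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
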