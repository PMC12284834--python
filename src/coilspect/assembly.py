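"""Stepwise hetero-oligomer assembly stoichiometry and SEC prediction.

The honeybee silk tetramer assembles sequentially: F2 and F4 first form a
stable dimeric coiled coil, F3 binds the dimer to give a trimer, and F1
completes the F1·F2·F3·F4 heterotetramer.  In the strong-binding
(infinite-affinity) limit each step runs to completion, so the species
distribution for any input amounts follows from mass balance alone:

    dimer0  = min(F2, F4)
    trimer0 = min(dimer0, F3)
    tetramer = min(trimer0, F1)

with residual trimer/dimer and free monomers by conservation.  The result
is independent of the order in which proteins are added, matching the
observation that addition order does not change the complexes formed.

``predict_sec`` renders a species mix as a sum of Gaussian elution peaks.
The default calibration uses the measured elution volumes on an analytical
Superdex200 10/300 column: tetramer 8.71, F2·F4 dimer 9.75, F1 10.12,
F2 10.34, F3 11.22, F4 11.31 mL.  No measured volume exists for the
trimer, so a trimer-containing mix needs a user calibration entry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesMix",
    "SecProfile",
    "assemble",
    "order_invariance_check",
    "predict_sec",
    "DEFAULT_SEC_CALIBRATION",
    "SPECIES_SIZE",
]

MONOMERS = ("F1", "F2", "F3", "F4")

#: Subunit count per species (used for size weighting of SEC peak areas).
SPECIES_SIZE = {
    "F1": 1, "F2": 1, "F3": 1, "F4": 1,
    "F2F4": 2, "F2F3F4": 3, "F1F2F3F4": 4,
}

#: Elution-volume centers (mL) on an analytical Superdex200 10/300 column.
DEFAULT_SEC_CALIBRATION = {
    "F1F2F3F4": (8.71, 0.12),
    "F2F4": (9.75, 0.12),
    "F1": (10.12, 0.12),
    "F2": (10.34, 0.12),
    "F3": (11.22, 0.12),
    "F4": (11.31, 0.12),
}


@dataclass
class SpeciesMix:
    """Molar amounts of free monomers and complexes, plus the inputs."""

    inputs: dict[str, float]
    free: dict[str, float]
    dimer: float
    trimer: float
    tetramer: float

    def amount(self, species: str) -> float:
        if species in MONOMERS:
            return self.free[species]
        return {"F2F4": self.dimer, "F2F3F4": self.trimer,
                "F1F2F3F4": self.tetramer}[species]

    def nonzero_species(self, tol: float = 1e-12) -> list[str]:
        return [s for s in SPECIES_SIZE if self.amount(s) > tol]

    def mass_balance_residual(self) -> dict[str, float]:
        """Per-protein conservation residual (exactly zero for a valid mix)."""
        used = {
            "F1": self.tetramer,
            "F2": self.dimer + self.trimer + self.tetramer,
            "F3": self.trimer + self.tetramer,
            "F4": self.dimer + self.trimer + self.tetramer,
        }
        return {
            m: self.inputs[m] - self.free[m] - used[m] for m in MONOMERS
        }

    def to_dict(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "free": dict(self.free),
            "F2F4": self.dimer,
            "F2F3F4": self.trimer,
            "F1F2F3F4": self.tetramer,
        }


@dataclass
class SecProfile:
    """A simulated SEC trace: elution grid (mL), signal, and a peak table."""

    volume: np.ndarray
    signal: np.ndarray
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)


def assemble(f1: float, f2: float, f3: float, f4: float,
             dissociation_constants: dict[str, float] | None = None
             ) -> SpeciesMix:
    """Species distribution in the strong-binding sequential limit.

    ``dissociation_constants`` is an extension hook for a per-step
    equilibrium model; it is not yet parameterized and must be None.
    """
    if dissociation_constants is not None:
        raise NotImplementedError(
            "equilibrium (finite-Kd) assembly is a stub; only the "
            "strong-binding limit is implemented"
        )
    amounts = {"F1": f1, "F2": f2, "F3": f3, "F4": f4}
    if any(v < 0 for v in amounts.values()):
        raise ValueError("input amounts must be >= 0")
    dimer0 = min(f2, f4)
    trimer0 = min(dimer0, f3)
    tetramer = min(trimer0, f1)
    trimer = trimer0 - tetramer
    dimer = dimer0 - trimer0
    free = {
        "F1": f1 - tetramer,
        "F2": f2 - dimer0,
        "F3": f3 - trimer0,
        "F4": f4 - dimer0,
    }
    return SpeciesMix(
        inputs=amounts, free=free, dimer=dimer, trimer=trimer,
        tetramer=tetramer,
    )


def order_invariance_check(
    inputs: dict[str, float],
    addition_order: tuple[str, ...] | None = None,
) -> SpeciesMix:
    """Assemble under a stated addition order and assert order invariance.

    The proteins are introduced one at a time in ``addition_order`` (a
    permutation of F1–F4), re-equilibrating the pool after each addition;
    in the strong-binding limit the final mix is identical for all 24
    orders, and this function asserts that before returning it.
    """
    if addition_order is None:
        addition_order = MONOMERS
    if sorted(addition_order) != sorted(MONOMERS):
        raise ValueError("addition_order must be a permutation of F1–F4")
    pool = {m: 0.0 for m in MONOMERS}
    mix = assemble(0.0, 0.0, 0.0, 0.0)
    for protein in addition_order:
        pool[protein] += inputs.get(protein, 0.0)
        mix = assemble(pool["F1"], pool["F2"], pool["F3"], pool["F4"])
    reference = assemble(*(inputs.get(m, 0.0) for m in MONOMERS))
    for order in itertools.permutations(MONOMERS):
        pool = {m: 0.0 for m in MONOMERS}
        trial = assemble(0.0, 0.0, 0.0, 0.0)
        for protein in order:
            pool[protein] += inputs.get(protein, 0.0)
            trial = assemble(pool["F1"], pool["F2"], pool["F3"], pool["F4"])
        if not np.allclose(
            [trial.dimer, trial.trimer, trial.tetramer]
            + [trial.free[m] for m in MONOMERS],
            [reference.dimer, reference.trimer, reference.tetramer]
            + [reference.free[m] for m in MONOMERS],
        ):
            raise AssertionError(f"assembly depends on addition order {order}")
    return mix


def predict_sec(
    mix: SpeciesMix,
    calibration: dict[str, tuple[float, float]] | None = None,
    size_weighting: bool = True,
    volume_grid: np.ndarray | None = None,
) -> SecProfile:
    """Render a species mix as a sum of Gaussian SEC peaks.

    Peak area is amount × subunit count when ``size_weighting`` (signal
    scales with the mass of protein eluting), else amount alone.
    ``calibration`` maps species → (center mL, width mL) and must cover
    every nonzero species.
    """
    cal = dict(DEFAULT_SEC_CALIBRATION)
    if calibration:
        cal.update(calibration)
    if volume_grid is None:
        volume_grid = np.arange(6.0, 13.0, 0.01)
    v = np.asarray(volume_grid, dtype=float)
    signal = np.zeros_like(v)
    rows = []
    for species in mix.nonzero_species():
        if species not in cal:
            raise ValueError(
                f"no SEC calibration for nonzero species {species}"
            )
        center, width = cal[species]
        area = mix.amount(species) * (
            SPECIES_SIZE[species] if size_weighting else 1.0
        )
        signal += (
            area / (width * np.sqrt(2 * np.pi))
            * np.exp(-((v - center) ** 2) / (2 * width**2))
        )
        rows.append({"species": species, "center_mL": center, "area": area})
    peaks = pd.DataFrame(rows, columns=["species", "center_mL", "area"])
    if not peaks.empty:
        peaks = peaks.sort_values("center_mL", ignore_index=True)
    return SecProfile(volume=v, signal=signal, peaks=peaks)
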