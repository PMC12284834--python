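"""Synthetic coiled-coil generator with known ground truth.

Builds ideal 2–4-helix bundles from Crick parameters (superhelical radius,
pitch, handedness, per-chain azimuth/phase/stagger), threads heptad
registers and sequences onto them, perturbs coordinates with seeded noise,
and simulates the downstream observables used elsewhere in the package:
lysine-pair crosslink tables, two-state thermal melt curves, and additive
α-helical CD spectra.

The Crick parameterization used for a chain running "up" (N→C along +z):

    alpha  = atan(2π r0 / pitch)                 (superhelix crossing angle)
    w0     = ±2π rise·cos(alpha) / pitch          (supercoil step per residue;
                                                   negative for a left-handed
                                                   supercoil)
    w1     = 2π / res_per_turn                    (minor-helix step per residue)
    θ_i    = w0·i + phase0,   φ_i = w1·i + phase1
    x_i    = r0 cosθ + r1 (cosθ cosφ − cosα sinθ sinφ)
    y_i    = r0 sinθ + r1 (sinθ cosφ + cosα cosθ sinφ)
    z_i    = rise·cosα·i − r1 sinα sinφ + stagger

"Down" chains are built as up chains and rigidly rotated 180° about the
x-axis, which preserves both α-helix chirality and supercoil handedness,
then shifted so they span the same axial range before stagger is applied.

A CB pseudo-atom is placed 1.53 Å from each CA along the outward radial
direction from the local minor-helix axis.  For charged residues a single
charged-group pseudo-atom (NZ, NH1, OD1 or OE1) is placed further along the
same direction so that crosslink mapping and salt-bridge detection have
physical anchors to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    AtomRecord,
    ChainModel,
    ONE_TO_THREE,
    ResidueRecord,
    StructureModel,
)

__all__ = [
    "CrickParams",
    "GroundTruth",
    "MeltSimSpec",
    "build_bundle",
    "perturb",
    "sample_crosslinks",
    "simulate_melt",
    "simulate_cd",
    "silk_like_sequence",
    "canonical_phase1",
    "HEPTAD",
]

HEPTAD = "abcdefg"

#: Crick phase (deg) at which an *a*-position residue points so that the
#: a/d pair straddles the inward direction: the a/d mean azimuth faces the
#: superhelical axis.  Derived from w1 = 2π/3.5: d sits at a − 51.43°, so
#: the optimum has the a-residue minor-helix phase at 180° + 51.43°/2.
_PHI_A_DEG = 180.0 + (360.0 / 3.5 - 360.0 / 7.0) / 2.0  # 205.714°

# Radial distance (Å) from CA to the single charged-group pseudo-atom.
_CHARGED_ATOMS = {
    "LYS": ("NZ", "N", 5.0),
    "ARG": ("NH1", "N", 5.5),
    "ASP": ("OD1", "O", 2.5),
    "GLU": ("OE1", "O", 3.2),
}


@dataclass
class CrickParams:
    """Generative parameters of an ideal coiled-coil bundle.

    Angles are in degrees, lengths in Å.  ``pitch`` is positive; handedness
    is carried separately.  Defaults follow the canonical heptad coiled
    coil: r1 = 2.26 Å, rise = 1.51 Å, 3.5 residues/turn, left-handed.
    """

    n_chains: int
    orientations: tuple[str, ...]
    r0: float
    pitch: float
    n_res: int
    handedness: str = "left"
    r1: float = 2.26
    rise: float = 1.51
    res_per_turn: float = 3.5
    phase0: tuple[float, ...] | None = None
    phase1: tuple[float, ...] | None = None
    stagger: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.n_chains <= 4:
            raise ValueError("n_chains must be 2–4")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.n_res < 8:
            raise ValueError("n_res must be >= 8")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        self.orientations = tuple(self.orientations)
        if len(self.orientations) != self.n_chains:
            raise ValueError("orientations length must equal n_chains")
        if any(o not in ("U", "D") for o in self.orientations):
            raise ValueError("orientations must be 'U' or 'D'")
        if self.phase0 is None:
            self.phase0 = tuple(
                360.0 * k / self.n_chains for k in range(self.n_chains)
            )
        self.phase0 = tuple(float(p) for p in self.phase0)
        if len(self.phase0) != self.n_chains:
            raise ValueError("phase0 length must equal n_chains")
        if self.phase1 is not None:
            self.phase1 = tuple(float(p) for p in self.phase1)
            if len(self.phase1) != self.n_chains:
                raise ValueError("phase1 length must equal n_chains")
        if self.stagger is None:
            self.stagger = (0.0,) * self.n_chains
        self.stagger = tuple(float(s) for s in self.stagger)
        if len(self.stagger) != self.n_chains:
            raise ValueError("stagger length must equal n_chains")

    @property
    def alpha(self) -> float:
        """Superhelix crossing angle (radians)."""
        return np.arctan(2.0 * np.pi * self.r0 / self.pitch)

    @property
    def omega0(self) -> float:
        """Signed supercoil rotation per residue (radians)."""
        sign = -1.0 if self.handedness == "left" else 1.0
        return sign * 2.0 * np.pi * self.rise * np.cos(self.alpha) / self.pitch

    @property
    def omega1(self) -> float:
        """Minor-helix rotation per residue (radians)."""
        return 2.0 * np.pi / self.res_per_turn

    @property
    def axial_rise(self) -> float:
        """Rise per residue along the superhelical axis (Å)."""
        return self.rise * np.cos(self.alpha)

    @classmethod
    def silk_tetramer(cls, n_res: int = 168, **kw) -> "CrickParams":
        """Antiparallel 4-helix bundle at the honeybee-silk dimensions
        (superhelical radius 5.8 Å, pitch 153 Å), U/D/U/D."""
        kw.setdefault("orientations", ("U", "D", "U", "D"))
        return cls(n_chains=4, r0=5.8, pitch=153.0, n_res=n_res, **kw)


@dataclass
class GroundTruth:
    """Generative parameters plus the threaded register and sequence."""

    params: CrickParams
    register: tuple[str, ...]
    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        for reg, seq in zip(self.register, self.sequence):
            if len(reg) != self.params.n_res or len(seq) != self.params.n_res:
                raise ValueError("register/sequence length must equal n_res")


@dataclass
class MeltSimSpec:
    """Two-state thermal melt simulation parameters.

    ``folded_baseline`` and ``unfolded_baseline`` are (intercept, slope)
    pairs of mean-residue-ellipticity versus temperature (°C).  Defaults
    mimic a well-folded helical complex monitored at 222 nm.
    """

    tm: float
    width: float = 2.0
    folded_baseline: tuple[float, float] = (-28000.0, 40.0)
    unfolded_baseline: tuple[float, float] = (-6000.0, 10.0)
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(30.0, 81.0, 1.0)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")

    @property
    def amplitude(self) -> float:
        """|folded − unfolded| baseline separation at the midpoint."""
        bf = self.folded_baseline[0] + self.folded_baseline[1] * self.tm
        bu = self.unfolded_baseline[0] + self.unfolded_baseline[1] * self.tm
        return abs(bf - bu)


def canonical_phase1(first_register: str) -> float:
    """Minor-helix phase (deg) of residue 1 placing the threaded register's
    a/d positions toward the superhelical core."""
    k = HEPTAD.index(first_register)
    # 'a' occurs at residue index (7 - k) % 7; walk phase back from there.
    j = (7 - k) % 7
    return (_PHI_A_DEG - j * (360.0 / 3.5)) % 360.0


def _per_chain(value, n_chains: int, default) -> list:
    if value is None:
        value = default
    if isinstance(value, str):
        return [value] * n_chains
    value = list(value)
    if len(value) != n_chains:
        raise ValueError("need one entry per chain")
    return value


def _thread(pattern: str, n_res: int) -> str:
    reps = -(-n_res // len(pattern))
    return (pattern * reps)[:n_res]


def silk_like_sequence(n_res: int, register: str, seed: int = 0) -> str:
    """A silk-flavoured random sequence for a given register string:
    alanine-rich at a/d/e/g, charged and polar residues at b/c/f."""
    rng = np.random.default_rng(seed)
    core = list("AAAAAASV")          # a, d, e, g: small and apolar
    outer = list("KKEEQNSLTD")       # b, c, f: charged / polar
    out = []
    for reg in register:
        pool = core if reg in "adeg" else outer
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _crick_chain(params: CrickParams, chain_idx: int,
                 phase0_deg: float, phase1_deg: float) -> dict[str, np.ndarray]:
    """CA positions and outward radial unit vectors of an up chain."""
    i = np.arange(params.n_res, dtype=float)
    th = params.omega0 * i + np.deg2rad(phase0_deg)
    ph = params.omega1 * i + np.deg2rad(phase1_deg)
    ca, sa = np.cos(params.alpha), np.sin(params.alpha)
    r0, r1 = params.r0, params.r1
    axis = np.stack([r0 * np.cos(th), r0 * np.sin(th),
                     params.axial_rise * i], axis=1)
    offset = np.stack(
        [
            r1 * (np.cos(th) * np.cos(ph) - ca * np.sin(th) * np.sin(ph)),
            r1 * (np.sin(th) * np.cos(ph) + ca * np.cos(th) * np.sin(ph)),
            -r1 * sa * np.sin(ph),
        ],
        axis=1,
    )
    pos = axis + offset
    if r1 > 0:
        radial = offset / np.linalg.norm(offset, axis=1, keepdims=True)
    else:
        radial = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
    return {"ca": pos, "radial": radial}


def build_bundle(
    params: CrickParams,
    register: str | Sequence[str] | None = None,
    sequence: str | Sequence[str] | None = None,
    chain_ids: Sequence[str] | None = None,
    place_charged_atoms: bool = True,
    sequence_seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """Build an ideal bundle and return it with its ground truth.

    ``register`` defaults to the repeating heptad ``abcdefg``; ``sequence``
    defaults to a seeded silk-like sequence matched to the register.  Unless
    ``params.phase1`` is given explicitly, each chain's minor-helix phase is
    chosen so that the threaded a/d positions face the superhelical core.
    """
    registers = [
        _thread(r, params.n_res) if len(r) < params.n_res else r[: params.n_res]
        for r in _per_chain(register, params.n_chains, HEPTAD)
    ]
    if sequence is None:
        sequences = [
            silk_like_sequence(params.n_res, registers[c], seed=sequence_seed + c)
            for c in range(params.n_chains)
        ]
    else:
        sequences = [
            _thread(s, params.n_res)
            for s in _per_chain(sequence, params.n_chains, None)
        ]
    if chain_ids is None:
        chain_ids = [chr(ord("A") + c) for c in range(params.n_chains)]
    chain_ids = list(chain_ids)
    if len(chain_ids) != params.n_chains:
        raise ValueError("chain_ids length must equal n_chains")

    if params.phase1 is None:
        phase1 = tuple(canonical_phase1(r[0]) for r in registers)
        params = replace(params, phase1=phase1)

    length_z = params.axial_rise * (params.n_res - 1)
    chains: list[ChainModel] = []
    # Build azimuths are chosen so that phase0 is each chain's azimuth
    # offset in the common supercoil field theta(z) = (w0/axial_rise)·z +
    # phase0: a staggered chain is screwed along the superhelix, and a
    # flipped (D) chain lands at the azimuth its phase0 prescribes.
    w0_deg = np.degrees(params.omega0)
    for c in range(params.n_chains):
        up = params.orientations[c] == "U"
        if up:
            ph0 = params.phase0[c] + w0_deg * params.stagger[c] / params.axial_rise
        else:
            ph0 = -(
                params.phase0[c]
                + w0_deg * (params.n_res - 1
                            + params.stagger[c] / params.axial_rise)
            )
        geom = _crick_chain(params, c, ph0, params.phase1[c])
        ca, radial = geom["ca"], geom["radial"]
        if not up:
            flip = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
            ca = ca @ flip.T
            radial = radial @ flip.T
            ca[:, 2] += length_z
        ca[:, 2] += params.stagger[c]
        residues = []
        for i in range(params.n_res):
            aa = sequences[c][i]
            res_name = ONE_TO_THREE.get(aa, "ALA")
            rec = ResidueRecord(seq_id=i + 1, res_name=res_name)
            rec.add_atom(AtomRecord("CA", "C", ca[i]))
            if params.r1 > 0:
                rec.add_atom(AtomRecord("CB", "C", ca[i] + 1.53 * radial[i]))
                if place_charged_atoms and res_name in _CHARGED_ATOMS:
                    name, elem, dist = _CHARGED_ATOMS[res_name]
                    rec.add_atom(AtomRecord(name, elem, ca[i] + dist * radial[i]))
            residues.append(rec)
        chains.append(ChainModel(chain_id=chain_ids[c], residues=residues))

    model = StructureModel(chains=chains, title="coilspect synthetic bundle")
    truth = GroundTruth(
        params=params, register=tuple(registers), sequence=tuple(sequences)
    )
    return model, truth


def perturb(model: StructureModel, noise_sd: float, seed: int) -> StructureModel:
    """Displace every atom by isotropic Gaussian noise (per-axis sd in Å)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    chains = []
    for chain in model:
        residues = []
        for res in chain:
            rec = ResidueRecord(seq_id=res.seq_id, res_name=res.res_name)
            for atom in res.atoms.values():
                shift = rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else 0.0
                rec.add_atom(
                    AtomRecord(atom.atom_name, atom.element,
                               atom.position + shift)
                )
            residues.append(rec)
        chains.append(ChainModel(chain_id=chain.chain_id, residues=residues))
    return StructureModel(chains=chains, title=model.title)


def sample_crosslinks(
    model: StructureModel,
    n_links: int,
    max_dist: float = 30.0,
    decoy_fraction: float = 0.0,
    seed: int = 0,
    lysine_only: bool = True,
) -> pd.DataFrame:
    """Sample a crosslink table from linkable residue pairs of a structure.

    Linkable residues are lysines plus each chain's first residue (the
    N-terminus); set ``lysine_only=False`` to treat every residue as
    linkable.  A fraction ``1 − decoy_fraction`` of links is drawn (without
    replacement) from pairs within ``max_dist``, the rest from violating
    pairs.  The returned table records the ground-truth distance and
    satisfiability of each link.
    """
    from .xlms import anchor_position  # local import: xlms owns the atom rule

    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    sites: list[tuple[str, int, np.ndarray]] = []
    for chain in model:
        for idx, res in enumerate(chain):
            if lysine_only and res.res_name != "LYS" and idx != 0:
                continue
            sites.append(
                (chain.chain_id, res.seq_id,
                 anchor_position(chain, res))
            )
    if len(sites) < 2:
        raise ValueError("no eligible residue pairs to link")
    pairs, dists = [], []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            pairs.append((sites[i], sites[j]))
            dists.append(float(np.linalg.norm(sites[i][2] - sites[j][2])))
    dists = np.asarray(dists)
    good = np.flatnonzero(dists <= max_dist)
    bad = np.flatnonzero(dists > max_dist)
    n_decoy = int(round(n_links * decoy_fraction))
    n_true = n_links - n_decoy
    if n_true > len(good) or n_decoy > len(bad):
        raise ValueError(
            f"not enough eligible pairs ({len(good)} satisfying, "
            f"{len(bad)} violating) for the requested table"
        )
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            rng.choice(good, size=n_true, replace=False) if n_true else [],
            rng.choice(bad, size=n_decoy, replace=False) if n_decoy else [],
        ]
    ).astype(int)
    rows = []
    for k in chosen:
        (ca_, ra, _), (cb_, rb, _) = pairs[k]
        rows.append(
            {
                "chain_a": ca_, "res_a": ra, "chain_b": cb_, "res_b": rb,
                "count": 1, "distance": dists[k],
                "satisfiable": bool(dists[k] <= max_dist),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chain_a", "res_a", "chain_b", "res_b", "count",
                 "distance", "satisfiable"],
    )


def simulate_melt(spec: MeltSimSpec) -> pd.DataFrame:
    """Simulate a two-state melt: logistic folded fraction between linear
    baselines plus Gaussian noise.  Returns columns temperature_C,
    ellipticity."""
    t = spec.t_grid
    f = 1.0 / (1.0 + np.exp((t - spec.tm) / spec.width))
    bf = spec.folded_baseline[0] + spec.folded_baseline[1] * t
    bu = spec.unfolded_baseline[0] + spec.unfolded_baseline[1] * t
    y = f * bf + (1.0 - f) * bu
    if spec.noise_sd > 0:
        y = y + np.random.default_rng(spec.seed).normal(0, spec.noise_sd, t.shape)
    return pd.DataFrame({"temperature_C": t, "ellipticity": y})


def simulate_cd(
    kind: str = "single_helix",
    ratio_222_209: float | None = None,
    wavelengths: np.ndarray | None = None,
    amplitude: float = 10000.0,
):
    """Phenomenological α-helical CD spectrum with a prescribed 222/209 ratio.

    The spectrum is a sum of two negative Gaussian bands at 209 and 222 nm
    and a positive band at 192 nm; the 222-band depth is solved so the
    ellipticity ratio at exactly 222/209 nm equals ``ratio_222_209``
    (default 0.8 for ``single_helix``, 0.95 for ``coiled_coil``).  Band
    shapes are a stand-in: only ratios and additivity are meaningful.
    """
    from .cd_thermo import CdSpectrum

    if kind not in ("single_helix", "coiled_coil"):
        raise ValueError("kind must be 'single_helix' or 'coiled_coil'")
    if ratio_222_209 is None:
        ratio_222_209 = 0.8 if kind == "single_helix" else 0.95
    if ratio_222_209 <= 0:
        raise ValueError("ratio_222_209 must be positive")
    if wavelengths is None:
        wavelengths = np.arange(190.0, 260.5, 0.5)
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() > 190.0 or wl.max() < 260.0:
        raise ValueError("wavelength grid must cover 190–260 nm")

    def band(center, sigma):
        return np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))

    s_neg = 6.5
    a209 = amplitude
    a_pos = 1.5 * amplitude
    g = float(np.exp(-(13.0**2) / (2.0 * s_neg**2)))  # 209<->222 overlap
    p209 = a_pos * float(np.exp(-((209.0 - 192.0) ** 2) / (2.0 * 5.5**2)))
    p222 = a_pos * float(np.exp(-((222.0 - 192.0) ** 2) / (2.0 * 5.5**2)))
    r = ratio_222_209
    a222 = (r * (p209 - a209) - p222 + a209 * g) / (r * g - 1.0)
    y = (
        a_pos * band(192.0, 5.5)
        - a209 * band(209.0, s_neg)
        - a222 * band(222.0, s_neg)
    )
    return CdSpectrum(wavelengths=wl, ellipticity=y, label=kind)
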