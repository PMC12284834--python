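"""Knobs-into-holes core packing and interhelical salt bridges.

KIH detection follows a side-chain-center simplification of the SOCKET
criterion: a residue is a knob when at least four side-chain centers of a
single other chain lie within a cutoff (default 7 Å) of its own side-chain
center; the four nearest form the hole.  Side-chain centers are the mean of
non-backbone heavy atoms (so a lone CB pseudo-atom counts).

Salt bridges pair basic (Lys NZ; Arg NH1/NH2/NE) against acidic
(Asp OD1/OD2; Glu OE1/OE2) charged heavy atoms at a minimum distance of
4.0 Å by default.  Histidine is not treated as basic.  Each interaction is
classified by the heptad registers of its participants, basic residue
first (e.g. ``c-c``, ``g-c``, ``b-b``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CoiledCoilFit
from .structure_io import ChainModel, ResidueRecord, StructureModel

__all__ = [
    "KihContact",
    "SaltBridge",
    "LayerReport",
    "detect_kih",
    "detect_salt_bridges",
    "layer_summary",
    "side_chain_center",
]

BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class KihContact:
    """One knob packed into a four-residue hole on another chain."""

    knob: tuple[str, int]
    hole: list[tuple[str, int]]
    center_distances: list[float]
    knob_register: str
    axial: float  # knob position along the bundle axis (Å)


@dataclass
class SaltBridge:
    basic: tuple[str, int, str]
    acidic: tuple[str, int, str]
    min_distance: float
    position_class: str

    @property
    def is_intermolecular(self) -> bool:
        return self.basic[0] != self.acidic[0]


@dataclass
class LayerReport:
    """Axial layering of KIH contacts: (register, n_contacts, z) per layer
    and whether a/d layer types strictly alternate."""

    layers: list[tuple[str, int, float]]
    alternating: bool


def side_chain_center(res: ResidueRecord) -> np.ndarray | None:
    """Mean position of non-backbone heavy atoms; None if there are none."""
    pos = [
        a.position for a in res.atoms.values()
        if a.atom_name not in BACKBONE and a.element != "H"
    ]
    if not pos:
        return None
    return np.mean(pos, axis=0)


def _centers(chain: ChainModel) -> tuple[list[int], np.ndarray]:
    ids, pts = [], []
    for res in chain:
        c = side_chain_center(res)
        if c is not None:
            ids.append(res.seq_id)
            pts.append(c)
    return ids, (np.stack(pts) if pts else np.empty((0, 3)))


def detect_kih(
    model: StructureModel,
    fit: CoiledCoilFit | None = None,
    center_cutoff: float = 7.0,
) -> list[KihContact]:
    """Detect knobs-into-holes contacts between all chain pairs.

    Contacts are sorted along the bundle axis (the fitted axis when ``fit``
    is given, else the z-axis).  Knob registers come from ``fit`` when
    available, '?' otherwise.
    """
    per_chain = {c.chain_id: _centers(c) for c in model}
    if all(len(ids) == 0 for ids, _ in per_chain.values()):
        raise ValueError("no side-chain information in any chain")
    if fit is not None:
        origin, direction = fit.axis_origin, fit.axis_direction
    else:
        origin, direction = np.zeros(3), np.array([0.0, 0.0, 1.0])
    contacts: list[KihContact] = []
    for chain in model:
        ids_a, pts_a = per_chain[chain.chain_id]
        for other in model:
            if other.chain_id == chain.chain_id:
                continue
            ids_b, pts_b = per_chain[other.chain_id]
            if len(ids_b) < 4:
                continue
            d = np.linalg.norm(
                pts_a[:, None, :] - pts_b[None, :, :], axis=2
            )
            for i, sid in enumerate(ids_a):
                within = np.flatnonzero(d[i] <= center_cutoff)
                if len(within) < 4:
                    continue
                nearest = within[np.argsort(d[i, within])[:4]]
                reg = fit.register_of(chain.chain_id, sid) if fit else "?"
                contacts.append(
                    KihContact(
                        knob=(chain.chain_id, sid),
                        hole=[(other.chain_id, ids_b[j]) for j in nearest],
                        center_distances=[float(d[i, j]) for j in nearest],
                        knob_register=reg,
                        axial=float((pts_a[i] - origin) @ direction),
                    )
                )
    contacts.sort(key=lambda c: c.axial)
    return contacts


def detect_salt_bridges(
    model: StructureModel,
    fit: CoiledCoilFit | None = None,
    cutoff: float = 4.0,
    scope: str = "both",
) -> list[SaltBridge]:
    """All basic/acidic residue pairs whose minimal charged-heavy-atom
    distance is within ``cutoff``; ``scope`` restricts to 'inter', 'intra'
    or 'both'."""
    if scope not in ("inter", "intra", "both"):
        raise ValueError("scope must be 'inter', 'intra' or 'both'")
    if fit is None:
        warnings.warn(
            "no geometry fit supplied; position classes reported as '?-?'",
            stacklevel=2,
        )
    basics, acidics = [], []
    for chain in model:
        for res in chain:
            for table, out in ((BASIC_ATOMS, basics), (ACIDIC_ATOMS, acidics)):
                names = table.get(res.res_name)
                if not names:
                    continue
                pts = [res.atoms[n].position for n in names if n in res.atoms]
                if pts:
                    out.append((chain.chain_id, res.seq_id, res.res_name,
                                np.stack(pts)))
    bridges: list[SaltBridge] = []
    for cb, sb, nb, pb in basics:
        for ca_, sa, na, pa in acidics:
            inter = cb != ca_
            if scope == "inter" and not inter:
                continue
            if scope == "intra" and inter:
                continue
            dmin = float(
                np.min(np.linalg.norm(pb[:, None, :] - pa[None, :, :], axis=2))
            )
            if dmin > cutoff:
                continue
            if fit is not None:
                cls = (f"{fit.register_of(cb, sb)}-"
                       f"{fit.register_of(ca_, sa)}")
            else:
                cls = "?-?"
            bridges.append(
                SaltBridge(
                    basic=(cb, sb, nb),
                    acidic=(ca_, sa, na),
                    min_distance=dmin,
                    position_class=cls,
                )
            )
    bridges.sort(key=lambda b: (b.basic[0], b.basic[1], b.acidic[0], b.acidic[1]))
    return bridges


def layer_summary(contacts: list[KihContact], gap: float = 2.5,
                  core_only: bool = True) -> LayerReport:
    """Group KIH contacts into axial layers and report their register types.

    With ``core_only`` (default) only core knobs (registers a and d) enter
    the report — the alternating-layer structure of a coiled-coil core is a
    property of the a/d knobs, while flanking e/g knobs interleave axially.
    Contacts are sorted by axial coordinate; a new layer starts whenever
    the axial gap to the previous contact exceeds ``gap`` Å.  Each layer's
    register is the majority knob register of its contacts; ``alternating``
    is true when no two consecutive layers share a register type.
    """
    if not contacts:
        raise ValueError("no contacts to summarize")
    if core_only:
        core = [c for c in contacts if c.knob_register in ("a", "d")]
        contacts = core or contacts
    ordered = sorted(contacts, key=lambda c: c.axial)
    layers: list[list[KihContact]] = [[ordered[0]]]
    for c in ordered[1:]:
        if c.axial - layers[-1][-1].axial > gap:
            layers.append([])
        layers[-1].append(c)
    summary = []
    for group in layers:
        regs = [c.knob_register for c in group]
        majority = max(set(regs), key=regs.count)
        z_mid = float(np.mean([c.axial for c in group]))
        summary.append((majority, len(group), z_mid))
    alternating = all(
        a[0] != b[0] for a, b in zip(summary, summary[1:])
    )
    return LayerReport(layers=summary, alternating=alternating)
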