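"""Coiled-coil geometry fitting from atomic coordinates.

The pipeline is: sliding-window local helix axes per chain → total-least-
squares superhelical axis over all axis points → radius and pitch from the
azimuth-versus-axial-coordinate regression → chain orientations (U/D),
clockwise arrangement, axial stagger, rod extent → per-residue Crick phase
and heptad register.

Local axis points are centroids of seven consecutive CA atoms.  For an
ideal helix at 3.5 residues/turn the minor-helix contribution cancels
exactly, leaving the point on the helix axis; on a supercoil the window
additionally chord-averages the superhelical circle, shrinking the apparent
radius by the analytic factor sin(7·w0/2) / (7·sin(w0/2)) where w0 is the
supercoil rotation per residue.  ``fit_radius_pitch`` measures w0 from its
own azimuth regression and divides this bias out, so the recovered radius
is unbiased on ideal bundles.

Conventions (fixed and documented so results are reproducible):

* The superhelical axis direction is signed so that the first chain runs
  N→C positive.
* "Clockwise" is judged looking from the positive axis end toward the
  origin (the standard view down the axis): clockwise = decreasing
  mathematical azimuth in a right-handed frame.
* A left-handed supercoil has azimuth decreasing with the axial coordinate;
  slopes below 2π/2000 Å⁻¹ (pitch > 2000 Å) are reported as no supercoil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import ChainModel, StructureModel

__all__ = [
    "AxisPoint",
    "CoiledCoilFit",
    "local_axis",
    "fit_axis_line",
    "fit_radius_pitch",
    "chain_orientation",
    "arrangement_order",
    "axial_stagger",
    "assign_register",
    "coil_extent",
    "fit_coiled_coil",
    "HEPTAD",
]

HEPTAD = "abcdefg"
WINDOW = 7
SLOPE_MIN = 2.0 * np.pi / 2000.0  # |dθ/dz| below this ⇒ no supercoil


@dataclass
class AxisPoint:
    """A local helix-axis sample: position, unit tangent, and the residue
    (chain_id, seq_id) at the window center."""

    chain_id: str
    seq_id: int
    point: np.ndarray
    tangent: np.ndarray


@dataclass
class RadiusPitchResult:
    r0: float
    pitch: float
    handedness: str
    low_confidence: bool = False


@dataclass
class CoiledCoilFit:
    """Complete fitted description of a coiled-coil bundle."""

    axis_origin: np.ndarray
    axis_direction: np.ndarray
    r0_fit: float
    pitch_fit: float
    handedness: str
    orientation: dict[str, str]
    arrangement: list[str]
    stagger: dict[str, float]
    extent: float
    crick_phase: dict[str, np.ndarray]
    register: dict[str, str]
    n_heptads: dict[str, int]
    seq_ids: dict[str, list[int]] = field(default_factory=dict)
    low_confidence: bool = False

    def to_dict(self) -> dict:
        """JSON-serializable summary of all fitted quantities."""
        return {
            "axis_origin": [float(v) for v in self.axis_origin],
            "axis_direction": [float(v) for v in self.axis_direction],
            "r0_fit": float(self.r0_fit),
            "pitch_fit": float(self.pitch_fit) if np.isfinite(self.pitch_fit)
            else None,
            "handedness": self.handedness,
            "orientation": self.orientation,
            "arrangement": self.arrangement,
            "stagger": {k: float(v) for k, v in self.stagger.items()},
            "extent": float(self.extent),
            "register": self.register,
            "n_heptads": self.n_heptads,
            "low_confidence": self.low_confidence,
        }

    def register_of(self, chain_id: str, seq_id: int) -> str:
        """Register letter of one residue, '?' if unavailable."""
        reg = self.register.get(chain_id)
        ids = self.seq_ids.get(chain_id)
        if reg is None or ids is None or seq_id not in ids:
            return "?"
        return reg[ids.index(seq_id)]


def local_axis(chain: ChainModel) -> list[AxisPoint]:
    """Sliding window-of-7 centroid axis points with tangents.

    Ends without a full window are omitted (three residues per end); a
    7-residue chain yields exactly one axis point, whose tangent falls back
    to the overall chain direction.
    """
    ca = chain.ca_positions()
    n = len(ca)
    if n < WINDOW:
        raise ValueError(
            f"chain {chain.chain_id}: need >= {WINDOW} CA atoms, got {n}"
        )
    kernel = np.ones(WINDOW) / WINDOW
    pts = np.stack(
        [np.convolve(ca[:, k], kernel, mode="valid") for k in range(3)], axis=1
    )
    if len(pts) == 1:
        tangents = (ca[-1] - ca[0])[None, :]
    else:
        tangents = np.gradient(pts, axis=0)
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    half = WINDOW // 2
    seq_ids = [chain.residues[i + half].seq_id for i in range(len(pts))]
    return [
        AxisPoint(chain.chain_id, sid, p, t)
        for sid, p, t in zip(seq_ids, pts, tangents)
    ]


def fit_axis_line(points: Sequence[AxisPoint]) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through all axis points.

    Returns (origin, unit direction); the direction is signed so that the
    first chain present in ``points`` runs N→C positive along it.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 axis points to fit a line")
    xyz = np.stack([p.point for p in points])
    origin = xyz.mean(axis=0)
    centered = xyz - origin
    if np.allclose(centered, 0.0, atol=1e-9):
        raise ValueError("axis points are coincident; line undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    first_chain = points[0].chain_id
    chain_pts = [p.point for p in points if p.chain_id == first_chain]
    if np.dot(chain_pts[-1] - chain_pts[0], direction) < 0:
        direction = -direction
    return origin, direction / np.linalg.norm(direction)


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed (e1, e2, direction) frame: e1 × e2 = direction."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def _cylindrical(points: np.ndarray, origin: np.ndarray,
                 direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(z, theta, r) of points about the line; theta in a fixed frame."""
    e1, e2 = _frame(direction)
    rel = points - origin
    z = rel @ direction
    x, y = rel @ e1, rel @ e2
    return z, np.arctan2(y, x), np.hypot(x, y)


def fit_radius_pitch(
    points: Sequence[AxisPoint],
    line: tuple[np.ndarray, np.ndarray],
    slope_min: float = SLOPE_MIN,
) -> RadiusPitchResult:
    """Superhelical radius, pitch and handedness about a fitted line.

    Radius: mean perpendicular distance of the axis points, corrected for
    the window-7 chord-averaging bias (see module docstring).  Pitch:
    2π/|slope| of the per-chain unwrapped azimuth-vs-z regression, averaged
    over chains.  Handedness from the slope sign; |slope| < ``slope_min``
    means no supercoil.  Fits spanning under two supercoil turns are
    flagged low-confidence.
    """
    origin, direction = line
    by_chain: dict[str, list[AxisPoint]] = {}
    for p in points:
        by_chain.setdefault(p.chain_id, []).append(p)
    raw_r = float(
        np.mean(
            _cylindrical(np.stack([p.point for p in points]), origin, direction)[2]
        )
    )
    slopes, weights, rises = [], [], []
    for pts in by_chain.values():
        xyz = np.stack([p.point for p in pts])
        z, th, _ = _cylindrical(xyz, origin, direction)
        order = np.argsort(z)
        z, th = z[order], np.unwrap(th[order])
        if len(z) < 2 or np.ptp(z) < 1e-9:
            continue
        slope = np.polyfit(z, th, 1)[0]
        slopes.append(slope)
        weights.append(len(z))
        rises.append(np.mean(np.abs(np.diff(z))))
    if not slopes:
        return RadiusPitchResult(raw_r, np.inf, "none", low_confidence=True)
    slope = float(np.average(slopes, weights=weights))
    if abs(slope) < slope_min:
        return RadiusPitchResult(raw_r, np.inf, "none")
    pitch = 2.0 * np.pi / abs(slope)
    handedness = "left" if slope < 0 else "right"
    # Debias the window-averaged radius using the measured per-residue
    # supercoil step w0 = slope * (axial rise per residue).
    w0 = abs(slope) * float(np.average(rises, weights=weights))
    shrink = 1.0
    if w0 > 1e-9:
        shrink = np.sin(WINDOW * w0 / 2.0) / (WINDOW * np.sin(w0 / 2.0))
    r0 = raw_r / shrink
    z_all = _cylindrical(np.stack([p.point for p in points]), origin, direction)[0]
    turns = abs(slope) * float(np.ptp(z_all)) / (2.0 * np.pi)
    return RadiusPitchResult(r0, pitch, handedness, low_confidence=turns < 2.0)


def chain_orientation(chain: ChainModel,
                      line: tuple[np.ndarray, np.ndarray]) -> str:
    """'U' if the chain runs N→C along +axis, 'D' otherwise."""
    ca = chain.ca_positions()
    if len(ca) < 2:
        raise ValueError("need >= 2 CA atoms")
    proj = float(np.dot(ca[-1] - ca[0], line[1]))
    if abs(proj) < 1e-9:
        raise ValueError(
            f"chain {chain.chain_id} is perpendicular to the axis"
        )
    return "U" if proj > 0 else "D"


def _chain_azimuths(model: StructureModel,
                    axis_points: dict[str, list[AxisPoint]],
                    line: tuple[np.ndarray, np.ndarray]) -> dict[str, float]:
    origin, direction = line
    az = {}
    for chain in model:
        pts = np.stack([p.point for p in axis_points[chain.chain_id]])
        centroid = pts.mean(axis=0)
        _, theta, r = _cylindrical(centroid[None, :], origin, direction)
        if r[0] < 1e-6:
            raise ValueError(
                f"chain {chain.chain_id} centroid lies on the axis"
            )
        az[chain.chain_id] = float(theta[0])
    return az


def arrangement_order(model: StructureModel,
                      axis_points: dict[str, list[AxisPoint]],
                      line: tuple[np.ndarray, np.ndarray]) -> list[str]:
    """Cyclic chain order, clockwise viewed from the +axis end, starting at
    the first chain of the model."""
    if len(model) < 3:
        return list(model.chain_ids)
    az = _chain_azimuths(model, axis_points, line)
    first = model.chain_ids[0]
    ref = az[first]

    def clockwise_key(cid: str) -> float:
        return (ref - az[cid]) % (2.0 * np.pi)

    rest = sorted((c for c in model.chain_ids if c != first), key=clockwise_key)
    others = [az[c] for c in model.chain_ids if c != first]
    if any(
        abs(((a - b + np.pi) % (2 * np.pi)) - np.pi) < 1e-9
        for i, a in enumerate(others) for b in others[i + 1:]
    ):
        raise ValueError("two chains at identical azimuth")
    return [first] + rest


def axial_stagger(model: StructureModel,
                  axis_points: dict[str, list[AxisPoint]],
                  line: tuple[np.ndarray, np.ndarray]) -> dict[str, float]:
    """Axial offset of each chain's axis-point centroid, relative to the
    first chain (Å)."""
    origin, direction = line
    mid = {}
    for chain in model:
        pts = np.stack([p.point for p in axis_points[chain.chain_id]])
        mid[chain.chain_id] = float((pts.mean(axis=0) - origin) @ direction)
    ref = mid[model.chain_ids[0]]
    return {cid: m - ref for cid, m in mid.items()}


def coil_extent(axis_points: dict[str, list[AxisPoint]],
                line: tuple[np.ndarray, np.ndarray]) -> float:
    """Axial span (Å) between the extreme axis points over all chains."""
    origin, direction = line
    z = [
        float((p.point - origin) @ direction)
        for pts in axis_points.values() for p in pts
    ]
    return max(z) - min(z)


def _crick_phases(chain: ChainModel, pts: list[AxisPoint],
                  line: tuple[np.ndarray, np.ndarray]) -> dict[int, float]:
    """Signed Crick phase (deg) per residue with an axis point.

    Zero means the CA points from its local helix axis straight at the
    superhelical axis (the core direction); sign follows the right-hand
    rule about the local tangent.
    """
    origin, direction = line
    ca_by_id = {r.seq_id: r.get("CA").position for r in chain}
    phases: dict[int, float] = {}
    for p in pts:
        foot = origin + np.dot(p.point - origin, direction) * direction
        inward = foot - p.point
        w = ca_by_id[p.seq_id] - p.point
        t = p.tangent
        inward = inward - np.dot(inward, t) * t
        w = w - np.dot(w, t) * t
        ni, nw = np.linalg.norm(inward), np.linalg.norm(w)
        if ni < 1e-9 or nw < 1e-9:
            continue
        inward, w = inward / ni, w / nw
        ang = np.arctan2(np.dot(np.cross(inward, w), t), np.dot(inward, w))
        phases[p.seq_id] = float(np.degrees(ang))
    return phases


def _count_heptads(register: str) -> int:
    """Number of complete consecutive a…g periods in a register string."""
    first_a = register.find("a")
    if first_a < 0:
        return 0
    return (len(register) - first_a) // 7


def assign_register(
    chain: ChainModel,
    pts: list[AxisPoint],
    line: tuple[np.ndarray, np.ndarray],
) -> tuple[str, int, dict[int, float]]:
    """Heptad register of one chain from its Crick phases.

    All seven cyclic offsets of the periodic a–g assignment are scored by
    the mean of cos(Crick phase) over the residues the offset labels a or
    d; the maximizing offset (core faces inward) wins, ties to the smallest
    offset.  The winning cyclic pattern is extended over the whole chain,
    including end residues whose Crick phase is undefined.

    Returns (register string, n_heptads, phase-by-seq_id map).
    """
    n = len(chain)
    if n < 7:
        raise ValueError("chain shorter than one heptad")
    phases = _crick_phases(chain, pts, line)
    if not phases:
        raise ValueError("no Crick phases computable")
    seq_ids = [r.seq_id for r in chain]
    idx_of = {sid: i for i, sid in enumerate(seq_ids)}
    best_offset, best_score = 0, -np.inf
    for offset in range(7):
        cosines = [
            np.cos(np.radians(ph))
            for sid, ph in phases.items()
            if HEPTAD[(idx_of[sid] + offset) % 7] in "ad"
        ]
        score = float(np.mean(cosines)) if cosines else -np.inf
        if score > best_score + 1e-12:
            best_offset, best_score = offset, score
    register = "".join(HEPTAD[(i + best_offset) % 7] for i in range(n))
    return register, _count_heptads(register), phases


def fit_coiled_coil(model: StructureModel) -> CoiledCoilFit:
    """Run the full geometric analysis on a bundle."""
    axis_points = {c.chain_id: local_axis(c) for c in model}
    all_points = [p for c in model for p in axis_points[c.chain_id]]
    line = fit_axis_line(all_points)
    rp = fit_radius_pitch(all_points, line)
    orientation = {c.chain_id: chain_orientation(c, line) for c in model}
    arrangement = (
        arrangement_order(model, axis_points, line)
        if len(model) >= 3 else list(model.chain_ids)
    )
    stagger = axial_stagger(model, axis_points, line)
    extent = coil_extent(axis_points, line)
    register, n_heptads, crick_phase, seq_ids = {}, {}, {}, {}
    for chain in model:
        reg, nh, phases = assign_register(chain, axis_points[chain.chain_id], line)
        register[chain.chain_id] = reg
        n_heptads[chain.chain_id] = nh
        ids = [r.seq_id for r in chain]
        seq_ids[chain.chain_id] = ids
        crick_phase[chain.chain_id] = np.array(
            [phases.get(sid, np.nan) for sid in ids]
        )
    return CoiledCoilFit(
        axis_origin=line[0],
        axis_direction=line[1],
        r0_fit=rp.r0,
        pitch_fit=rp.pitch,
        handedness=rp.handedness,
        orientation=orientation,
        arrangement=arrangement,
        stagger=stagger,
        extent=extent,
        crick_phase=crick_phase,
        register=register,
        n_heptads=n_heptads,
        seq_ids=seq_ids,
        low_confidence=rp.low_confidence,
    )
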