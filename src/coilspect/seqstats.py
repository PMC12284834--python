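"""Per-heptad-position composition statistics.

For register-annotated sequences, computes the mean Kyte–Doolittle
hydropathy, mean residue volume (Zamyatnin 1972, Å³) and alanine fraction
at each heptad position a–g, pooling residues across all chains.  In an
alanine-rich antiparallel coiled coil like honeybee silk, the core-forming
and core-adjacent positions (a, d, e, g) stand out as the most hydrophobic,
smallest and most alanine-rich — the signature these statistics quantify.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .geometry import CoiledCoilFit, HEPTAD
from .structure_io import StructureModel, extract_sequence

__all__ = [
    "KYTE_DOOLITTLE",
    "RESIDUE_VOLUME",
    "per_position_stats",
    "radar_export",
    "registered_sequences",
]

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Zamyatnin (1972) residue volumes, Å³.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

METRICS = ["mean_hydropathy", "mean_volume", "ala_fraction"]


def registered_sequences(model: StructureModel,
                         fit: CoiledCoilFit) -> list[tuple[str, str]]:
    """(sequence, register) pairs for every chain of a fitted model."""
    return [
        (extract_sequence(chain), fit.register[chain.chain_id])
        for chain in model
    ]


def per_position_stats(
    registered: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Composition table indexed a–g with columns n_residues,
    mean_hydropathy, mean_volume, ala_fraction.

    ``registered`` yields (one-letter sequence, register string) pairs of
    equal length.  Residues with unknown amino-acid codes or register
    labels outside a–g are excluded with a warning.
    """
    buckets: dict[str, list[str]] = {p: [] for p in HEPTAD}
    skipped = 0
    n_total = 0
    for seq, reg in registered:
        if len(seq) != len(reg):
            raise ValueError("sequence and register lengths differ")
        n_total += len(seq)
        for aa, pos in zip(seq.upper(), reg):
            if aa not in KYTE_DOOLITTLE or pos not in buckets:
                skipped += 1
                continue
            buckets[pos].append(aa)
    if n_total == 0:
        raise ValueError("no registered sequences supplied")
    if skipped:
        warnings.warn(
            f"excluded {skipped} residues with unknown code or register",
            stacklevel=2,
        )
    rows = []
    for pos in HEPTAD:
        aas = buckets[pos]
        n = len(aas)
        rows.append(
            {
                "position": pos,
                "n_residues": n,
                "mean_hydropathy": (
                    sum(KYTE_DOOLITTLE[a] for a in aas) / n if n else float("nan")
                ),
                "mean_volume": (
                    sum(RESIDUE_VOLUME[a] for a in aas) / n if n else float("nan")
                ),
                "ala_fraction": (
                    sum(a == "A" for a in aas) / n if n else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("position")


def radar_export(table: pd.DataFrame, path: str | Path | None = None,
                 normalize: bool = False) -> pd.DataFrame:
    """Serialize a composition table as 7 rows × 3 metrics (radar-plot data).

    With ``normalize`` each metric column is scaled by its maximum absolute
    value so the largest magnitude becomes ±1.
    """
    out = table[METRICS].copy()
    if normalize:
        for col in METRICS:
            peak = out[col].abs().max()
            if peak > 0:
                out[col] = out[col] / peak
    if path is not None:
        out.to_csv(path)
    return out
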