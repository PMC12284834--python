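"""CD spectrum arithmetic and two-state thermal melt fitting.

The 222/209 nm mean-residue-ellipticity ratio separates isolated α-helices
(≈0.8) from packed coiled coils (>0.9); simulated mixture spectra are
molar-fraction weighted means of component spectra, which is what a
non-interacting mixture would show — deviation of a measured spectrum from
the simulated sum is evidence of complex formation.

Thermal melts are fitted to the two-state model

    y(T) = f·B_F(T) + (1−f)·B_U(T),   f = 1 / (1 + exp((T − Tm)/w)),

with linear folded/unfolded baselines B, by multi-start nonlinear least
squares (Tm starts every 5 °C across the measured range).  A melt is
called cooperative when the two-state fit explains the curve (R² ≥ 0.98)
and the transition width w is below 15 °C — an operational reading of
"sigmoidal, cooperative unfolding".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CdSpectrum",
    "MeltFit",
    "RatioResult",
    "combine_spectra",
    "ratio_222_209",
    "fit_two_state_melt",
    "read_spectrum",
    "read_melt",
]

R2_COOPERATIVE = 0.98
WIDTH_COOPERATIVE = 15.0


@dataclass
class CdSpectrum:
    """A CD spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity lengths differ")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated ellipticity at one wavelength."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(f"{wavelength} nm outside grid [{wl[0]}, {wl[-1]}]")
        return float(np.interp(wavelength, wl, self.ellipticity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "ellipticity": self.ellipticity}
        )


class RatioResult(NamedTuple):
    ratio: float
    coiled_coil: bool


@dataclass
class MeltFit:
    """Fitted two-state melt: midpoint, width, baselines and diagnostics."""

    tm: float
    width: float
    folded_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    rss: float
    r_squared: float
    has_transition: bool
    cooperative: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _two_state(
            np.asarray(t, dtype=float), self.tm, self.width,
            *self.folded_baseline, *self.unfolded_baseline,
        )


def read_spectrum(path: str | Path, label: str = "") -> CdSpectrum:
    """Read a spectrum CSV with columns wavelength_nm,ellipticity."""
    df = pd.read_csv(path)
    return CdSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        ellipticity=df["ellipticity"].to_numpy(),
        label=label or Path(path).stem,
    )


def read_melt(path: str | Path) -> pd.DataFrame:
    """Read a melt-curve CSV with columns temperature_C,ellipticity."""
    df = pd.read_csv(path)
    if not {"temperature_C", "ellipticity"} <= set(df.columns):
        raise ValueError(f"{path}: need columns temperature_C,ellipticity")
    return df


def combine_spectra(
    components: Sequence[CdSpectrum],
    weights: Sequence[float],
    weight_mode: str = "molar",
    molar_masses: Sequence[float] | None = None,
) -> CdSpectrum:
    """Pointwise weighted mean of spectra on identical grids.

    ``weights`` must sum to 1 (tolerance 1e-6).  With
    ``weight_mode='mass'`` the weights are mass fractions, converted to
    molar fractions using ``molar_masses`` before averaging — mean residue
    ellipticity adds per mole of protein, not per gram.
    """
    if len(components) != len(weights) or not components:
        raise ValueError("need one weight per component")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {w.sum()}, expected 1")
    if weight_mode == "mass":
        if molar_masses is None:
            raise ValueError("mass weighting requires molar_masses")
        w = w / np.asarray(molar_masses, dtype=float)
        w = w / w.sum()
    elif weight_mode != "molar":
        raise ValueError("weight_mode must be 'molar' or 'mass'")
    grid = components[0].wavelengths
    for c in components[1:]:
        if c.wavelengths.shape != grid.shape or not np.allclose(
            c.wavelengths, grid
        ):
            raise ValueError("component spectra are on different grids")
    y = sum(wi * c.ellipticity for wi, c in zip(w, components))
    return CdSpectrum(wavelengths=grid.copy(), ellipticity=y, label="mixture")


def ratio_222_209(spectrum: CdSpectrum) -> RatioResult:
    """222/209 nm ellipticity ratio and the coiled-coil call (ratio > 0.9).

    Both ellipticities must be negative (helical signal); otherwise the
    ratio is undefined: returns NaN with a warning and a negative call.
    """
    wl = spectrum.wavelengths
    if wl[0] > 205.0 or wl[-1] < 225.0:
        raise ValueError("spectrum grid must cover 205–225 nm")
    e222, e209 = spectrum.at(222.0), spectrum.at(209.0)
    if e222 >= 0 or e209 >= 0:
        warnings.warn(
            "non-negative ellipticity at 209/222 nm: no helical signal, "
            "ratio undefined",
            stacklevel=2,
        )
        return RatioResult(ratio=float("nan"), coiled_coil=False)
    ratio = e222 / e209
    return RatioResult(ratio=ratio, coiled_coil=ratio > 0.9)


def _two_state(t, tm, width, bf0, bf1, bu0, bu1):
    f = 1.0 / (1.0 + np.exp(np.clip((t - tm) / width, -500, 500)))
    return f * (bf0 + bf1 * t) + (1.0 - f) * (bu0 + bu1 * t)


def fit_two_state_melt(
    curve: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    tm_step: float = 5.0,
) -> MeltFit:
    """Fit the two-state melt model to (temperature, ellipticity) data.

    Multi-start: Tm is initialized on a grid across the measured range
    (``tm_step`` spacing) and the lowest-RSS solution wins.  A curve whose
    fitted transition amplitude does not rise above twice the residual
    noise is reported as having no transition (tm = NaN).
    """
    if isinstance(curve, pd.DataFrame):
        t = curve["temperature_C"].to_numpy(dtype=float)
        y = curve["ellipticity"].to_numpy(dtype=float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in curve)
    if len(t) < 10:
        raise ValueError("need >= 10 points spanning the transition")
    if np.ptp(y) == 0.0:
        return MeltFit(
            tm=float("nan"), width=float("nan"),
            folded_baseline=(float(y[0]), 0.0),
            unfolded_baseline=(float(y[0]), 0.0),
            rss=0.0, r_squared=1.0,
            has_transition=False, cooperative=False,
        )
    n_edge = max(3, len(t) // 5)
    bf = np.polyfit(t[:n_edge], y[:n_edge], 1)
    bu = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    lo = [t[0], 0.05, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 60.0, np.inf, np.inf, np.inf, np.inf]
    best = None
    for tm0 in np.arange(t[0] + tm_step / 2, t[-1], tm_step):
        x0 = [tm0, 3.0, bf[1], bf[0], bu[1], bu[0]]
        try:
            sol = least_squares(
                lambda p: _two_state(t, p[0], p[1], p[3], p[2], p[5], p[4]) - y,
                x0=x0, bounds=(lo, hi),
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("melt fit failed to converge from all starts")
    tm, width, bf1, bf0, bu1, bu0 = best.x
    resid = _two_state(t, tm, width, bf0, bf1, bu0, bu1) - y
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    amplitude = abs((bf0 + bf1 * tm) - (bu0 + bu1 * tm))
    resid_sd = float(np.sqrt(rss / max(len(t) - 6, 1)))
    has_transition = amplitude > 2.0 * resid_sd and amplitude > 1e-12
    cooperative = bool(
        has_transition and r2 >= R2_COOPERATIVE and width < WIDTH_COOPERATIVE
    )
    return MeltFit(
        tm=float(tm) if has_transition else float("nan"),
        width=float(width),
        folded_baseline=(float(bf0), float(bf1)),
        unfolded_baseline=(float(bu0), float(bu1)),
        rss=rss, r_squared=float(r2),
        has_transition=bool(has_transition),
        cooperative=cooperative,
    )
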