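"""Receptor-noise-limited colour vision models.

Quantum catches, chromatic contrasts in just-noticeable-difference (JND)
units, and the perceptual ("quantum-catch") pixel encoding that feeds the
perceptual PCA.

The discrimination model is the standard receptor-noise-limited one: a
colour stimulus is summarised by the quantum catch of each photoreceptor
class,

    Q_i = ∫ R(λ) I(λ) S_i(λ) dλ,

with R the reflectance, I the illuminant and S_i the spectral sensitivity
of receptor class i. Contrast between two stimuli is computed from the
log-catch differences Δf_i = ln(Qa_i / Qb_i), weighted by per-channel noise
e_i derived from a Weber fraction and the relative abundance of each cone
class. ΔS = 1 JND is the conventional discrimination threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ObserverModel",
    "QuantumCatchVector",
    "ContrastResult",
    "gaussian_sensitivity",
    "flat_illuminant",
    "observer_preset",
    "OBSERVER_PRESETS",
    "quantum_catch",
    "class_quantum_catches",
    "receptor_noise",
    "chromatic_contrast_jnd",
    "qc_encode",
    "print_fidelity_check",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """A sampled spectral quantity on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        Per-wavelength values: reflectance in [0, 1], irradiance >= 0, or
        receptor sensitivity >= 0.
    kind : str
        One of ``"reflectance"``, ``"irradiance"``, ``"sensitivity"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.kind in ("irradiance", "sensitivity") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} spectrum must be non-negative")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linearly interpolate onto *grid*; values are held at the edges."""
        return np.interp(np.asarray(grid, dtype=float), self.wavelengths, self.values)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def integrate(self) -> float:
        """Trapezoidal integral over the native grid."""
        return float(np.trapezoid(self.values, self.wavelengths))


def read_spectrum_csv(path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV."""
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    return Spectrum(wl, vals, kind=kind)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "value": spectrum.values}
    ).to_csv(path, index=False)


def gaussian_sensitivity(peak_nm: float, sd_nm: float = 40.0,
                         grid: np.ndarray | None = None) -> Spectrum:
    """Parametric Gaussian pigment template for a receptor class.

    A stand-in for measured photoreceptor sensitivities: unit-peak Gaussian
    centred on ``peak_nm``. Replace with measured curves (CSV) for real work.
    """
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    vals = np.exp(-0.5 * ((grid - peak_nm) / sd_nm) ** 2)
    return Spectrum(grid, vals, kind="sensitivity")


def flat_illuminant(level: float = 1.0, grid: np.ndarray | None = None) -> Spectrum:
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    return Spectrum(grid, np.full(grid.shape, float(level)), kind="irradiance")


# --------------------------------------------------------------------------
# Observers
# --------------------------------------------------------------------------

@dataclass
class ObserverModel:
    """A di-, tri- or tetrachromatic observer.

    ``cone_ratios`` are the relative abundances η_i of each receptor class;
    together with the Weber fraction ω they set the per-channel noise
    e_i = ω·sqrt(η_max / η_i), anchoring ω to the most abundant class.
    """

    name: str
    receptor_names: list[str]
    receptor_sensitivities: list[Spectrum]
    cone_ratios: np.ndarray
    weber_fraction: float = 0.05
    lambda_range: tuple[float, float] = (300.0, 700.0)

    def __post_init__(self) -> None:
        self.cone_ratios = np.asarray(self.cone_ratios, dtype=float)
        n = len(self.receptor_sensitivities)
        if not (2 <= n <= 4):
            raise ValueError("observer must have 2-4 receptor classes")
        if len(self.receptor_names) != n or self.cone_ratios.size != n:
            raise ValueError("names, sensitivities and ratios must align")
        if np.any(self.cone_ratios <= 0):
            raise ValueError("cone ratios must be positive")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        lo, hi = self.lambda_range
        if not lo < hi:
            raise ValueError("lambda_range must be an increasing interval")
        for s in self.receptor_sensitivities:
            slo, shi = s.support
            if slo > lo or shi < hi:
                raise ValueError(
                    f"lambda_range {self.lambda_range} outside sensitivity "
                    f"support ({slo}, {shi}) for observer {self.name!r}"
                )

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_sensitivities)


# Peak wavelengths for the parametric sensitivity templates (nm).
_AVIAN_PEAKS = {"UVS": 370.0, "SWS": 450.0, "MWS": 540.0, "LWS": 605.0}
_HUMAN_PEAKS = {"SWS": 442.0, "MWS": 543.0, "LWS": 570.0}


def _make_preset(name: str, peaks: dict[str, float], ratios: dict[str, float],
                 lambda_range: tuple[float, float]) -> ObserverModel:
    names = list(peaks)
    return ObserverModel(
        name=name,
        receptor_names=names,
        receptor_sensitivities=[gaussian_sensitivity(peaks[r]) for r in names],
        cone_ratios=np.array([ratios[r] for r in names]),
        weber_fraction=0.05,
        lambda_range=lambda_range,
    )


def observer_preset(name: str) -> ObserverModel:
    """Return a fresh copy of a named observer preset.

    ``blue_tit``: tetrachromat with UV-type vision (300-700 nm), cone ratios
    UVS=1, SWS=1.92, MWS=2.68, LWS=2.70. ``peafowl``: tetrachromat with
    V-type vision (400-700 nm), ratios 1 : 1.9 : 2.2 : 2.1. ``human``:
    trichromat (400-700 nm), ratios SWS=1, MWS=16, LWS=32. All use a Weber
    fraction of 0.05 anchored on the most abundant class.
    """
    if name == "blue_tit":
        return _make_preset(
            "blue_tit", _AVIAN_PEAKS,
            {"UVS": 1.0, "SWS": 1.92, "MWS": 2.68, "LWS": 2.70},
            (300.0, 700.0),
        )
    if name == "peafowl":
        peaks = dict(_AVIAN_PEAKS, UVS=420.0)  # violet-sensitive SWS1 class
        return _make_preset(
            "peafowl", peaks,
            {"UVS": 1.0, "SWS": 1.9, "MWS": 2.2, "LWS": 2.1},
            (400.0, 700.0),
        )
    if name == "human":
        return _make_preset(
            "human", _HUMAN_PEAKS,
            {"SWS": 1.0, "MWS": 16.0, "LWS": 32.0},
            (400.0, 700.0),
        )
    raise KeyError(f"unknown observer preset {name!r}")


OBSERVER_PRESETS = ("blue_tit", "peafowl", "human")


# --------------------------------------------------------------------------
# Quantum catches
# --------------------------------------------------------------------------

@dataclass
class QuantumCatchVector:
    Q: np.ndarray
    observer: str
    stimulus: str = ""

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q < 0):
            raise ValueError("quantum catches must be non-negative")


def quantum_catch(reflectance: Spectrum, illuminant: Spectrum,
                  observer: ObserverModel, stimulus: str = "") -> QuantumCatchVector:
    """Photoreceptor quantum catches Q_i = ∫ R·I·S_i dλ.

    All spectra are resampled onto a common 1 nm grid clipped to the
    observer's wavelength range intersected with the reflectance and
    illuminant supports. Linear in both R and I.
    """
    lo = max(observer.lambda_range[0], reflectance.support[0], illuminant.support[0])
    hi = min(observer.lambda_range[1], reflectance.support[1], illuminant.support[1])
    if hi <= lo:
        raise ValueError("empty overlap between spectra supports and lambda_range")
    grid = np.arange(lo, hi + 0.5, 1.0)
    R = reflectance.resample(grid)
    I = illuminant.resample(grid)
    Q = np.array([
        np.trapezoid(R * I * s.resample(grid), grid)
        for s in observer.receptor_sensitivities
    ])
    return QuantumCatchVector(Q=Q, observer=observer.name, stimulus=stimulus)


def class_quantum_catches(reflectances: dict[str, Spectrum], illuminant: Spectrum,
                          observer: ObserverModel) -> dict[str, QuantumCatchVector]:
    """Quantum catches for every colour class under one observer."""
    return {
        cls: quantum_catch(refl, illuminant, observer, stimulus=cls)
        for cls, refl in reflectances.items()
    }


def receptor_noise(observer: ObserverModel) -> np.ndarray:
    """Per-channel noise e_i = ω·sqrt(η_max / η_i).

    The Weber fraction applies to the most abundant cone class, so that
    class has noise exactly ω and rarer classes are noisier.
    """
    eta = observer.cone_ratios
    return observer.weber_fraction * np.sqrt(eta.max() / eta)


# --------------------------------------------------------------------------
# Chromatic contrast (JND)
# --------------------------------------------------------------------------

@dataclass
class ContrastResult:
    delta_s: float
    observer: str
    stimulus_a: str = ""
    stimulus_b: str = ""


def _delta_s(df: np.ndarray, e: np.ndarray) -> float:
    """Receptor-noise chromatic distance for 2-4 channels.

    Closed forms: for a dichromat ΔS = |Δf1 − Δf2| / sqrt(e1² + e2²); for
    tri- and tetrachromats the standard quadratic forms over pairwise
    log-catch differences weighted by the complementary noise products.
    """
    n = df.size
    if n == 2:
        return abs(df[0] - df[1]) / np.sqrt(e[0] ** 2 + e[1] ** 2)
    if n == 3:
        num = (
            e[0] ** 2 * (df[2] - df[1]) ** 2
            + e[1] ** 2 * (df[2] - df[0]) ** 2
            + e[2] ** 2 * (df[1] - df[0]) ** 2
        )
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        return float(np.sqrt(num / den))
    if n == 4:
        num = (
            (e[0] * e[1]) ** 2 * (df[3] - df[2]) ** 2
            + (e[0] * e[2]) ** 2 * (df[3] - df[1]) ** 2
            + (e[0] * e[3]) ** 2 * (df[2] - df[1]) ** 2
            + (e[1] * e[2]) ** 2 * (df[3] - df[0]) ** 2
            + (e[1] * e[3]) ** 2 * (df[2] - df[0]) ** 2
            + (e[2] * e[3]) ** 2 * (df[1] - df[0]) ** 2
        )
        den = (
            (e[0] * e[1] * e[2]) ** 2
            + (e[0] * e[1] * e[3]) ** 2
            + (e[0] * e[2] * e[3]) ** 2
            + (e[1] * e[2] * e[3]) ** 2
        )
        return float(np.sqrt(num / den))
    raise ValueError("contrast defined for 2-4 receptor classes")


def chromatic_contrast_jnd(Qa: QuantumCatchVector, Qb: QuantumCatchVector,
                           observer: ObserverModel) -> ContrastResult:
    """Chromatic contrast ΔS (JND units) between two stimuli.

    Uses log quantum-catch differences Δf_i = ln(Qa_i/Qb_i), so a common
    scaling of both stimuli (e.g. a brighter illuminant) cancels.
    """
    if Qa.observer != observer.name or Qb.observer != observer.name:
        raise ValueError("quantum catches were computed under a different observer")
    if np.any(Qa.Q <= 0) or np.any(Qb.Q <= 0):
        raise ValueError("log contrast requires strictly positive quantum catches")
    df = np.log(Qa.Q / Qb.Q)
    e = receptor_noise(observer)
    return ContrastResult(
        delta_s=_delta_s(df, e),
        observer=observer.name,
        stimulus_a=Qa.stimulus,
        stimulus_b=Qb.stimulus,
    )


# --------------------------------------------------------------------------
# Perceptual (quantum-catch) pixel encoding
# --------------------------------------------------------------------------

def _catch_table(class_catches: dict[str, QuantumCatchVector],
                 class_names: list[str], mode: str) -> np.ndarray:
    observers = {qc.observer for qc in class_catches.values()}
    if len(observers) != 1:
        raise ValueError("class catches must come from a single observer")
    missing = [c for c in class_names if c not in class_catches]
    if missing:
        raise ValueError(f"missing quantum catches for classes: {missing}")
    table = np.stack([class_catches[c].Q for c in class_names])  # C x n_rec
    if mode == "raw":
        return table
    if mode == "log":
        if np.any(table <= 0):
            raise ValueError("log mode requires strictly positive catches")
        return np.log(table)
    if mode == "normalized":
        lo = table.min(axis=0)
        rng = table.max(axis=0) - lo
        out = np.zeros_like(table)
        nz = rng > 0
        out[:, nz] = (table[:, nz] - lo[nz]) / rng[nz]
        return out
    raise ValueError(f"unknown qc encoding mode {mode!r}")


def qc_encode(aligned, class_catches: dict[str, QuantumCatchVector],
              mode: str = "normalized") -> np.ndarray:
    """Quantum-catch pixel encoding of an aligned colour map.

    Each in-mask pixel contributes the (by default range-normalised across
    classes, per receptor channel) quantum catches of its colour class;
    background pixels contribute zeros. Length = n_receptors × n_pixels,
    pixel-major — drop-in replacement for the binary encoding in the PCA.
    Modes: ``normalized`` (default), ``raw``, ``log``.
    """
    if aligned.alignment_transform is None:
        raise ValueError("colormap must be aligned to the template frame")
    table = _catch_table(class_catches, list(aligned.class_names), mode)
    n_rec = table.shape[1]
    labels = aligned.labels
    feat = np.zeros(labels.shape + (n_rec,))
    in_mask = labels >= 0
    feat[in_mask] = table[labels[in_mask]]
    return feat.reshape(-1)


# --------------------------------------------------------------------------
# Print-fidelity check
# --------------------------------------------------------------------------

def print_fidelity_check(actual: dict[str, Spectrum], printed: dict[str, Spectrum],
                         observers: list[ObserverModel],
                         illuminant: Spectrum | None = None,
                         jnd_threshold: float = 1.0) -> pd.DataFrame:
    """Chromatic contrast between actual and reproduced colours, per observer.

    Returns a tidy table (colour_class, observer, delta_s_jnd, above_threshold)
    flagging any pair at or above the discrimination threshold — the check
    that a printed colour is a faithful stand-in for the real one.
    """
    if set(actual) != set(printed):
        raise ValueError("actual and printed colour-class sets differ")
    if illuminant is None:
        illuminant = flat_illuminant()
    rows = []
    for obs in observers:
        for cls in sorted(actual):
            qa = quantum_catch(actual[cls], illuminant, obs, stimulus=cls)
            qb = quantum_catch(printed[cls], illuminant, obs, stimulus=cls)
            ds = chromatic_contrast_jnd(qa, qb, obs).delta_s
            rows.append({
                "colour_class": cls,
                "observer": obs.name,
                "delta_s_jnd": ds,
                "above_threshold": ds >= jnd_threshold,
            })
    out = pd.DataFrame(rows)
    n_flagged = int(out["above_threshold"].sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} colour/observer pairs at or above "
            f"{jnd_threshold} JND", stacklevel=2,
        )
    return out
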