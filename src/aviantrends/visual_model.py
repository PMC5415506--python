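"""Receptor-noise limited model of avian tetrachromatic colour vision.

Reflectance spectra are converted to quantum catches of the four single
cone classes of a violet-sensitive (V-type) avian eye (VS, S, M, L),
von-Kries normalized against the illuminant, and mapped to chromatic
coordinates (x, y, z) in just-noticeable-difference (jnd) units.  The
defining property of the coordinates is that Euclidean distance between two
colours equals their receptor-noise limited discriminability
:func:`delta_s`, so 1 unit of distance is one jnd.

The bundled visual system uses visual-pigment template sensitivities at
standard V-type peak wavelengths and a standard-daylight (d65) illuminant.
Cone proportions default to a generic passerine-style ratio that is a
documented placeholder, not the measured honeyeater values (which are not
bundled); both proportions and the Weber fraction are configurable.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .specimen_data import ReflectanceSpectrum, STANDARD_GRID

__all__ = [
    "VisualSystem",
    "QuantumCatches",
    "ReceptorNoise",
    "ChromaticCoords",
    "pigment_template",
    "quantum_catch",
    "receptor_noise",
    "delta_s",
    "chromatic_coords",
    "patch_coordinates",
    "carotenoid_chroma",
]

#: peak wavelengths (nm) of the VS, S, M, L cones of a generic V-type eye
V_TYPE_PEAKS = (416.0, 452.0, 506.0, 564.0)

#: placeholder VS:S:M:L cone abundances (configurable; not species-measured)
DEFAULT_CONE_PROPORTIONS = (1.0, 2.0, 2.0, 4.0)

#: Weber fraction of the most abundant cone class (field-standard default)
DEFAULT_WEBER_FRACTION = 0.1

CONE_NAMES = ("vs", "s", "m", "l")


def pigment_template(peak: float, wavelengths: np.ndarray = STANDARD_GRID) -> np.ndarray:
    """Vitamin-A1 visual pigment absorbance template (alpha + beta band).

    Standard rhodopsin nomogram: the alpha band is a sum-of-exponentials
    curve in x = peak/lambda, the beta band a Gaussian UV shoulder whose
    position and width scale with the peak.  Output is normalized to 1 at
    its maximum.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = peak / wl
    a = 0.8795 + 0.0459 * np.exp(-((peak - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    beta_peak = 189.0 + 0.315 * peak
    beta_width = -40.5 + 0.195 * peak
    beta = 0.26 * np.exp(-(((wl - beta_peak) / beta_width) ** 2))
    curve = alpha + beta
    return curve / curve.max()


def _load_d65(wavelengths: np.ndarray) -> np.ndarray:
    ref = importlib.resources.files("aviantrends.data") / "d65_5nm.tsv"
    table = np.loadtxt(str(ref))
    return np.interp(wavelengths, table[:, 0], table[:, 1])


@dataclass(frozen=True)
class VisualSystem:
    """Cone sensitivities, cone proportions, Weber fraction and illuminant.

    ``sensitivities`` has shape (4, n_wavelengths) ordered VS, S, M, L on
    ``wavelengths``; ``irradiance`` is the illuminant spectrum on the same
    grid.  All curves must be non-negative and the proportions positive.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray
    cone_proportions: np.ndarray
    weber_fraction: float
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        sens = np.asarray(self.sensitivities, dtype=float)
        eta = np.asarray(self.cone_proportions, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if sens.shape != (4, wl.size):
            raise ValueError("sensitivities must be a 4 x n_wavelengths array")
        if irr.shape != wl.shape:
            raise ValueError("irradiance must be defined on the same grid")
        if np.any(sens < 0) or np.any(irr < 0):
            raise ValueError("sensitivities and irradiance must be non-negative")
        if eta.shape != (4,) or np.any(eta <= 0):
            raise ValueError("four positive cone proportions required")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivities", sens)
        object.__setattr__(self, "cone_proportions", eta)
        object.__setattr__(self, "irradiance", irr)

    @classmethod
    def violet_default(
        cls,
        cone_proportions: Sequence[float] = DEFAULT_CONE_PROPORTIONS,
        weber_fraction: float = DEFAULT_WEBER_FRACTION,
        wavelengths: np.ndarray = STANDARD_GRID,
    ) -> "VisualSystem":
        """Bundled V-type eye: template pigments + d65 daylight."""
        sens = np.vstack([pigment_template(p, wavelengths) for p in V_TYPE_PEAKS])
        return cls(
            wavelengths=wavelengths,
            sensitivities=sens,
            cone_proportions=np.asarray(cone_proportions, dtype=float),
            weber_fraction=weber_fraction,
            irradiance=_load_d65(wavelengths),
        )

    @classmethod
    def from_tables(
        cls,
        sensitivity_path,
        irradiance_path,
        cone_proportions: Sequence[float],
        weber_fraction: float = DEFAULT_WEBER_FRACTION,
        wavelengths: np.ndarray = STANDARD_GRID,
    ) -> "VisualSystem":
        """Load user-supplied wavelength-indexed sensitivity and irradiance tables.

        The sensitivity table has five columns (nm, VS, S, M, L); the
        irradiance table two (nm, irradiance).  Both are interpolated onto
        the analysis grid.
        """
        sens_tab = np.loadtxt(sensitivity_path)
        irr_tab = np.loadtxt(irradiance_path)
        sens = np.vstack(
            [np.interp(wavelengths, sens_tab[:, 0], sens_tab[:, 1 + i]) for i in range(4)]
        )
        irr = np.interp(wavelengths, irr_tab[:, 0], irr_tab[:, 1])
        return cls(wavelengths, sens, np.asarray(cone_proportions, float), weber_fraction, irr)


@dataclass(frozen=True)
class QuantumCatches:
    """Von-Kries-normalized cone catches Q and their logs f = ln Q."""

    q: np.ndarray
    f: np.ndarray


@dataclass(frozen=True)
class ReceptorNoise:
    """Per-cone noise-to-signal ratios omega (VS, S, M, L)."""

    omega: np.ndarray


@dataclass(frozen=True)
class ChromaticCoords:
    """Position of a colour in avian perceptual space (jnd units)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def quantum_catch(spectrum: ReflectanceSpectrum, vs: VisualSystem) -> QuantumCatches:
    """Cone quantum catches of a reflectance spectrum under the illuminant.

    Q_i = integral of R(lambda) I(lambda) C_i(lambda) over 300-700 nm
    (trapezoid rule), divided by the illuminant catch integral of
    I(lambda) C_i(lambda) (von Kries chromatic adaptation); a flat unit
    reflector therefore has Q_i = 1 and f_i = 0 for every cone.
    """
    refl = spectrum.interp(vs.wavelengths)
    wl = vs.wavelengths
    q = np.array(
        [
            np.trapezoid(refl * vs.irradiance * vs.sensitivities[i], wl)
            for i in range(4)
        ]
    )
    norm = np.array(
        [np.trapezoid(vs.irradiance * vs.sensitivities[i], wl) for i in range(4)]
    )
    q = q / norm
    if np.any(q <= 0):
        dead = [CONE_NAMES[i] for i in range(4) if q[i] <= 0]
        raise ValueError(f"zero quantum catch for cone(s) {dead}: log catch undefined")
    return QuantumCatches(q=q, f=np.log(q))


def receptor_noise(vs: VisualSystem) -> ReceptorNoise:
    """Noise of each cone channel from its relative abundance.

    omega_i = nu * sqrt(eta_max / eta_i): the most abundant cone carries
    exactly the Weber fraction nu, rarer cones proportionally more noise.
    """
    eta = vs.cone_proportions
    omega = vs.weber_fraction * np.sqrt(eta.max() / eta)
    return ReceptorNoise(omega=omega)


def delta_s(a: QuantumCatches, b: QuantumCatches, noise: ReceptorNoise) -> float:
    """Receptor-noise limited chromatic distance between two colours (jnd).

    Tetrachromatic closed form in the log-catch differences df_i; uniform
    shifts of all four channels (pure intensity changes) do not register.
    """
    w = noise.omega
    df = a.f - b.f
    num = (
        (w[0] * w[1]) ** 2 * (df[3] - df[2]) ** 2
        + (w[0] * w[2]) ** 2 * (df[3] - df[1]) ** 2
        + (w[0] * w[3]) ** 2 * (df[2] - df[1]) ** 2
        + (w[1] * w[2]) ** 2 * (df[3] - df[0]) ** 2
        + (w[1] * w[3]) ** 2 * (df[2] - df[0]) ** 2
        + (w[2] * w[3]) ** 2 * (df[1] - df[0]) ** 2
    )
    den = (
        (w[0] * w[1] * w[2]) ** 2
        + (w[0] * w[1] * w[3]) ** 2
        + (w[0] * w[2] * w[3]) ** 2
        + (w[1] * w[2] * w[3]) ** 2
    )
    return float(np.sqrt(num / den))


def _metric_matrix(noise: ReceptorNoise) -> np.ndarray:
    """4x4 PSD matrix M with df' M df = delta_s^2 and M @ 1 = 0.

    Built by polarization from the closed form, so the coordinate map below
    is exactly isometric to :func:`delta_s` by construction.
    """

    def q(df: np.ndarray) -> float:
        a = QuantumCatches(q=np.exp(df), f=df)
        b = QuantumCatches(q=np.ones(4), f=np.zeros(4))
        return delta_s(a, b, noise) ** 2

    m = np.empty((4, 4))
    eye = np.eye(4)
    for i in range(4):
        m[i, i] = q(eye[i])
    for i in range(4):
        for j in range(i + 1, 4):
            m[i, j] = m[j, i] = 0.5 * (q(eye[i] + eye[j]) - m[i, i] - m[j, j])
    return m


def _coordinate_map(noise: ReceptorNoise) -> np.ndarray:
    """3x4 linear map T with T @ 1 = 0 and ||T df|| = delta_s.

    Sequential whitening: the rows of the contrast functionals are ordered
    so that x involves cones 1-2 only, y adds cone 3, z adds cone 4; the
    Cholesky factor of the induced Gram matrix then preserves that
    triangular structure.
    """
    c = np.array(
        [
            [1.0, -1.0, 0.0, 0.0],
            [0.5, 0.5, -1.0, 0.0],
            [1 / 3, 1 / 3, 1 / 3, -1.0],
        ]
    )
    m = _metric_matrix(noise)
    p = np.eye(4) - 0.25  # projector onto the contrast (sum-zero) subspace
    b = p @ c.T @ np.linalg.inv(c @ c.T)
    gram = b.T @ m @ b
    # lower-triangular factor S with S'S = gram ("reverse" Cholesky via the
    # flip permutation), so row 1 of S @ c touches only the cone 1-2 contrast
    j = np.eye(3)[::-1]
    upper = np.linalg.cholesky(j @ gram @ j).T
    s = j @ upper @ j
    return s @ c


def chromatic_coords(q: QuantumCatches, noise: ReceptorNoise) -> ChromaticCoords:
    """Map log catches to (x, y, z) jnd coordinates.

    The map is linear in f, annihilates uniform (intensity) shifts, and is
    an exact isometry to :func:`delta_s`; the achromatic point (all
    normalized catches equal) sits at the origin.
    """
    t = _coordinate_map(noise)
    xyz = t @ q.f
    return ChromaticCoords(*map(float, xyz))


def patch_coordinates(
    spectra: Sequence[ReflectanceSpectrum], vs: VisualSystem
) -> ChromaticCoords:
    """One chromatic position per specimen patch: mean of replicate coords.

    Five replicate measurements per patch are expected; fewer is tolerated
    with a warning, zero is an error.  Averaging happens in coordinate
    space, not on the spectra.
    """
    if len(spectra) == 0:
        raise ValueError("at least one replicate spectrum is required")
    if len(spectra) < 5:
        warnings.warn(
            f"only {len(spectra)} replicate spectra (5 expected)", stacklevel=2
        )
    noise = receptor_noise(vs)
    coords = np.array(
        [chromatic_coords(quantum_catch(s, vs), noise).as_array() for s in spectra]
    )
    return ChromaticCoords(*map(float, coords.mean(axis=0)))


def carotenoid_chroma(spectrum: ReflectanceSpectrum) -> float:
    """Carotenoid chroma (R700 - R450) / R700.

    Index of yellow carotenoid absorption depth: carotenoids absorb around
    450 nm and leave long-wave reflectance untouched, so deeper pigment
    deposition pushes the ratio towards 1.
    """
    r450 = float(spectrum.interp(np.array([450.0]))[0])
    r700 = float(spectrum.interp(np.array([700.0]))[0])
    if r700 <= 0:
        raise ValueError("carotenoid chroma undefined: R700 <= 0")
    return (r700 - r450) / r700
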