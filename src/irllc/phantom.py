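"""Digital liver-slice phantom and noisy magnitude image simulation.

A phantom is a stack of nested discs on a pixel grid: liver parenchyma on
background, one lesion disc inside the parenchyma, an optional necrotic
core inside the lesion and optional vessel discs inside the parenchyma.
Rasterization uses pixel-center membership (a pixel belongs to a disc iff
its center lies within the radius), 0-based row-major indices.

Image formation evaluates the three-parameter magnitude IR model per
pixel, with per-compartment equilibrium magnetization M0 and apparent
relaxation ``T1* = T1 / kappa`` (``kappa`` models the Look-Locker readout
acceleration).  Noise is Rician: the magnitude of the noise-free signal
perturbed by independent Gaussian noise of equal sigma in both quadrature
channels.  A spoiled-gradient-echo comparator image can be rendered from
the same tissue maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, GeometryError
from .signal_models import SPGRParams, spgr_signal

__all__ = [
    "LABELS",
    "DEFAULT_TI_MS",
    "REFERENCE_LIVER_T1_MS",
    "PhantomSpec",
    "Phantom",
    "AcquisitionSpec",
    "ImageSeries",
    "render_phantom",
    "simulate_series",
]

#: integer labels of the phantom compartments
LABELS = {"background": 0, "parenchyma": 1, "lesion": 2, "necrosis": 3, "vessel": 4}

#: the eight-point inversion-time grid of the Look-Locker liver protocol (ms)
DEFAULT_TI_MS: tuple[float, ...] = (148.0, 228.0, 548.0, 628.0, 946.0, 1025.0, 1343.0, 1743.0)

#: literature liver parenchyma T1 at 1.5 T, used as the SNR reference tissue
REFERENCE_LIVER_T1_MS = 654.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of one synthetic liver slice.

    Pixel spacing defaults to a 400 mm field of view on a 256 grid
    (1.5625 mm).  Compartment M0 values are relative equilibrium signals;
    the lesion M0 is ``m0_parenchyma * m0_ratio``.
    """

    matrix: tuple[int, int] = (256, 256)
    pixel_mm: float = 400.0 / 256.0
    liver_center_px: tuple[float, float] | None = None  # default: grid center
    liver_radius_mm: float = 110.0
    lesion_center_px: tuple[float, float] | None = None  # default: liver center
    lesion_diameter_mm: float = 19.1
    necrosis_diameter_mm: float | None = None
    vessels: tuple[tuple[float, float, float], ...] = ()  # (row, col, diameter_mm)
    t1_liver_ms: float = 654.0
    t1_lesion_ms: float = 1187.0
    t1_necrosis_ms: float = 1700.0
    t1_vessel_ms: float = 1500.0
    m0_parenchyma: float = 1.0
    m0_ratio: float = 1.0

    def resolved_centers(self) -> tuple[tuple[float, float], tuple[float, float]]:
        grid_center = ((self.matrix[0] - 1) / 2.0, (self.matrix[1] - 1) / 2.0)
        liver_c = self.liver_center_px or grid_center
        lesion_c = self.lesion_center_px or liver_c
        return liver_c, lesion_c


@dataclass(frozen=True)
class Phantom:
    """Rendered phantom: label image plus per-pixel tissue maps."""

    spec: PhantomSpec
    label_map: np.ndarray  # int, {0..4}
    t1_map: np.ndarray  # float ms; 1.0 on background (unused, M0 = 0)
    m0_map: np.ndarray  # float, >= 0


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the phantom and build label / T1 / M0 maps.

    Raises :class:`GeometryError` when the lesion does not fit inside the
    parenchyma, a necrotic core exceeds the lesion, a vessel leaves the
    parenchyma, or the lesion is below 2 pixels in diameter.
    """
    liver_c, lesion_c = spec.resolved_centers()
    r_liver = spec.liver_radius_mm / spec.pixel_mm
    r_lesion = spec.lesion_diameter_mm / 2.0 / spec.pixel_mm
    if spec.lesion_diameter_mm / spec.pixel_mm < 2.0:
        raise GeometryError(
            f"lesion diameter {spec.lesion_diameter_mm} mm is below 2 pixels "
            f"at {spec.pixel_mm} mm spacing"
        )
    d_centers = float(np.hypot(lesion_c[0] - liver_c[0], lesion_c[1] - liver_c[1]))
    if d_centers + r_lesion > r_liver:
        raise GeometryError("lesion disc does not fit inside the parenchyma")
    r_necrosis = None
    if spec.necrosis_diameter_mm is not None:
        r_necrosis = spec.necrosis_diameter_mm / 2.0 / spec.pixel_mm
        if spec.necrosis_diameter_mm > spec.lesion_diameter_mm:
            raise GeometryError("necrotic core larger than lesion")

    label = np.zeros(spec.matrix, dtype=np.int16)
    label[_disc_mask(spec.matrix, liver_c, r_liver)] = LABELS["parenchyma"]
    for row, col, diam in spec.vessels:
        r_v = diam / 2.0 / spec.pixel_mm
        d = float(np.hypot(row - liver_c[0], col - liver_c[1]))
        if d + r_v > r_liver:
            raise GeometryError("vessel disc leaves the parenchyma")
        label[_disc_mask(spec.matrix, (row, col), r_v)] = LABELS["vessel"]
    lesion_mask = _disc_mask(spec.matrix, lesion_c, r_lesion)
    label[lesion_mask] = LABELS["lesion"]
    if r_necrosis is not None:
        label[_disc_mask(spec.matrix, lesion_c, r_necrosis)] = LABELS["necrosis"]

    t1 = np.ones(spec.matrix, dtype=float)  # background placeholder, M0 = 0
    m0 = np.zeros(spec.matrix, dtype=float)
    m0_lesion = spec.m0_parenchyma * spec.m0_ratio
    for name, t1_val, m0_val in (
        ("parenchyma", spec.t1_liver_ms, spec.m0_parenchyma),
        ("vessel", spec.t1_vessel_ms, spec.m0_parenchyma),
        ("lesion", spec.t1_lesion_ms, m0_lesion),
        ("necrosis", spec.t1_necrosis_ms, m0_lesion),
    ):
        sel = label == LABELS[name]
        t1[sel] = t1_val
        m0[sel] = m0_val
    return Phantom(spec=spec, label_map=label, t1_map=t1, m0_map=m0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition settings of the simulated Look-Locker series.

    ``noise_sigma`` is the per-channel Gaussian sigma in units of the
    parenchyma equilibrium signal (sigma = 0.05 is SNR 20 at M0 = 1).
    ``kappa`` maps true to apparent relaxation (``T1* = T1 / kappa``);
    ``b_over_a = 2`` is ideal inversion.  The comparator image gets its
    own channel sigma; by default it is scaled so the reference liver
    tissue has the same SNR in both sequences.
    """

    ti_list_ms: tuple[float, ...] = DEFAULT_TI_MS
    noise_sigma: float = 0.05
    kappa: float = 1.4
    b_over_a: float = 2.0
    include_vibe: bool = True
    spgr: SPGRParams = field(default_factory=SPGRParams)
    vibe_noise_sigma: float | None = None

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_list_ms, dtype=float)
        if ti.size == 0 or np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
            raise ConfigError("ti_list_ms must be strictly increasing and positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kappa <= 0 or self.b_over_a <= 0:
            raise ConfigError("kappa and b_over_a must be > 0")

    def resolved_vibe_sigma(self) -> float:
        if self.vibe_noise_sigma is not None:
            return self.vibe_noise_sigma
        return self.noise_sigma * spgr_signal(REFERENCE_LIVER_T1_MS, self.spgr)


@dataclass(frozen=True)
class ImageSeries:
    """TI-indexed stack of magnitude images with acquisition metadata."""

    data: np.ndarray  # (n_ti, rows, cols), >= 0
    ti_list_ms: tuple[float, ...]
    vibe: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.ti_list_ms):
            raise ValueError("one image per inversion time required")

    def image_at(self, ti_ms: float) -> np.ndarray:
        idx = list(self.ti_list_ms).index(ti_ms)
        return self.data[idx]

    def config_hash(self) -> str:
        payload = json.dumps(
            {"ti": list(self.ti_list_ms), "seed": self.seed, "meta": self.meta},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(re, im)


def simulate_series(
    phantom: Phantom, acq: AcquisitionSpec, seed: int | None = None
) -> ImageSeries:
    """Render the noisy magnitude IR series (and optional SPGR comparator).

    With ``noise_sigma = 0`` every pixel equals the closed-form magnitude
    IR signal at that pixel's (A, B, T1*) exactly.  Draw order is fixed
    (IR volumes in TI order, then the comparator), so a fixed seed yields
    a bit-identical series.
    """
    if acq.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    a_map = phantom.m0_map
    b_map = acq.b_over_a * a_map
    t1_star = phantom.t1_map / acq.kappa
    ti = np.asarray(acq.ti_list_ms, dtype=float)
    clean = np.abs(
        a_map[None] - b_map[None] * np.exp(-ti[:, None, None] / t1_star[None])
    )
    if acq.noise_sigma > 0:
        data = np.stack([_rician(img, acq.noise_sigma, rng) for img in clean])
    else:
        data = clean
    vibe = None
    if acq.include_vibe:
        vibe_clean = phantom.m0_map * np.where(
            phantom.m0_map > 0, spgr_signal(phantom.t1_map, acq.spgr), 0.0
        )
        sig_v = acq.resolved_vibe_sigma()
        vibe = _rician(vibe_clean, sig_v, rng) if acq.noise_sigma > 0 and sig_v > 0 else vibe_clean
    return ImageSeries(
        data=data,
        ti_list_ms=tuple(float(t) for t in acq.ti_list_ms),
        vibe=vibe,
        seed=seed,
        meta={"kappa": acq.kappa, "b_over_a": acq.b_over_a, "noise_sigma": acq.noise_sigma},
    )
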