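"""Synthetic thyroid-like hyperspectral cases for end-to-end testing.

Each case is a raw-count cube plus white/dark reference frames and a label
mask, built from a simple phenomenological scene model:

* per-class *endmember* reflectance curves (smooth sums of Gaussians over the
  wavelength grid) for background, normal tissue, benign and malignant
  nodules, with a controllable benign-vs-malignant spectral-angle separation;
* a smooth low-order polynomial illumination field (so flat-field correction
  is spatially non-trivial) times a smooth lamp spectrum;
* nodules as random-walk-perturbed discs inside a normal-tissue region with a
  background border, exercising purity filtering on irregular boundaries;
* within-class variability as a spatially smooth multiplicative jitter field
  (tissue texture is spatially correlated) plus i.i.d. band noise, then
  quantization to the sensor bit depth.

Flat-field correction of a generated cube recovers each pixel's endmember to
within the noise level, which is the calibration contract the pipeline
relies on.  Endmember reflectances stay below the whiteboard reflectance so
corrected spectra remain inside the calibrated range.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from thyrospec.hsi_io import (
    BENIGN,
    CaseRecord,
    HyperCube,
    LabelMask,
    MALIGNANT,
    NORMAL,
    save_case,
)

_CLASSES = ("background", "normal", "benign", "malignant")


@dataclass
class SynthParams:
    """Scene-model parameters.

    The full acquisition geometry (700 x 600 x 294 at 12 bit over
    400-1000 nm) is the default; :meth:`desk` gives a 160 x 160 x 64 preset
    that keeps the whole pipeline fast on one CPU.
    """

    rows: int = 700
    cols: int = 600
    n_bands: int = 294
    bit_depth: int = 12
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    separation: float = 0.3          # benign-vs-malignant spectral angle, rad
    jitter_sd: float = 0.05          # within-class multiplicative texture sd
    jitter_corr_px: float = 8.0      # correlation length of the texture field
    noise_sd: float = 0.02           # additive band noise, reflectance units
    board_reflectance: float = 0.5
    nodule_count: tuple[int, int] = (1, 2)      # inclusive range per case
    nodule_radius: tuple[float, float] = (35.0, 55.0)
    boundary_roughness: float = 0.15
    border_px: int = 12              # background border width
    illumination_amp: float = 0.15   # spatial illumination variation
    dark_level: float = 100.0        # counts
    dark_noise: float = 2.0          # counts
    signal_scale: float = 3600.0     # counts at unit illumination/reflectance
    quantize: bool = True
    endmember_range: tuple[float, float] = (0.05, 0.45)
    seed: int = 0

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @classmethod
    def desk(cls, **overrides) -> "SynthParams":
        """Small-scene preset: 160 x 160 x 64 cubes, nodule radii 35-55 px."""
        base = dict(rows=160, cols=160, n_bands=64)
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthParams":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("wavelength_range", "nodule_count", "nodule_radius",
                    "endmember_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Endmembers
# ---------------------------------------------------------------------------

def _gaussian_mix(rng: np.random.Generator, grid: np.ndarray,
                  n_bumps: int = 4) -> np.ndarray:
    """A smooth positive curve on [0, 1]: a baseline plus Gaussian bumps."""
    curve = np.full_like(grid, 0.3)
    for _ in range(n_bumps):
        amp = rng.uniform(-0.5, 0.8)
        centre = rng.uniform(0.0, 1.0)
        width = rng.uniform(0.08, 0.35)
        curve = curve + amp * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    lo, hi = curve.min(), curve.max()
    return (curve - lo) / (hi - lo) if hi > lo else np.full_like(grid, 0.5)


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in radians between two spectra viewed as vectors."""
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def make_endmembers(separation: float, seed: int = 0, n_bands: int = 294,
                    lo: float = 0.05, hi: float = 0.45) -> dict[str, np.ndarray]:
    """Per-class smooth reflectance curves with a set benign/malignant angle.

    Curves are sums of a few Gaussians over the wavelength grid, scaled into
    ``[lo, hi]``; the malignant curve is a rotation of the benign one inside
    the spectral simplex, bisected so the realized spectral angle is within
    10% of ``separation`` (exactly equal curves at separation 0).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if separation > np.pi / 2:
        raise ValueError(f"separation {separation} rad unreachable (> pi/2)")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_bands)
    span = hi - lo
    background = lo + 0.12 * span * _gaussian_mix(rng, grid, 2)
    normal = lo + span * _gaussian_mix(rng, grid)
    benign = lo + span * _gaussian_mix(rng, grid)
    if separation == 0:
        malignant = benign.copy()
    else:
        direction = _gaussian_mix(rng, grid) - 0.5
        b_unit = benign / np.linalg.norm(benign)
        perp = direction - np.dot(direction, b_unit) * b_unit
        perp /= np.linalg.norm(perp)

        def candidate(t: float) -> np.ndarray:
            c = np.cos(t) * benign + np.sin(t) * perp * np.linalg.norm(benign)
            return np.clip(c, 0.01, hi + 0.04)

        t_lo, t_hi = 0.0, np.pi / 2
        for _ in range(60):
            t_mid = 0.5 * (t_lo + t_hi)
            if spectral_angle(candidate(t_mid), benign) < separation:
                t_lo = t_mid
            else:
                t_hi = t_mid
        malignant = candidate(0.5 * (t_lo + t_hi))
        achieved = spectral_angle(malignant, benign)
        if abs(achieved - separation) > 0.1 * separation:
            raise ValueError(
                f"separation {separation} rad unreachable under clipping "
                f"(achieved {achieved:.3f})")
    return {"background": np.clip(background, 0.0, 1.0),
            "normal": np.clip(normal, 0.0, 1.0),
            "benign": np.clip(benign, 0.0, 1.0),
            "malignant": np.clip(malignant, 0.0, 1.0)}


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def _illumination(rng: np.random.Generator, rows: int, cols: int,
                  amp: float) -> np.ndarray:
    """Smooth low-order 2-D polynomial field scaled into [1 - amp, 1]."""
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    coef = rng.uniform(-1, 1, size=5)
    surf = coef[0] * x + coef[1] * y + coef[2] * x * y + coef[3] * x ** 2 \
        + coef[4] * y ** 2
    lo_s, hi_s = surf.min(), surf.max()
    if hi_s > lo_s:
        surf = (surf - lo_s) / (hi_s - lo_s)
    else:
        surf = np.zeros_like(surf)
    return 1.0 - amp + amp * surf


def _lamp_spectrum(rng: np.random.Generator, n_bands: int) -> np.ndarray:
    grid = np.linspace(0, 1, n_bands)
    centre = rng.uniform(0.3, 0.7)
    width = rng.uniform(0.4, 0.8)
    curve = 0.75 + 0.25 * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    return curve / curve.max()


def _nodule_blob(rng: np.random.Generator, rows: int, cols: int,
                 radius: float, roughness: float, border: int
                 ) -> np.ndarray | None:
    """Rasterize one random-walk-perturbed disc fully inside the interior."""
    rmax = radius * (1 + roughness)
    margin = border + int(np.ceil(rmax)) + 2
    if 2 * margin >= rows or 2 * margin >= cols:
        return None
    cy = rng.uniform(margin, rows - margin)
    cx = rng.uniform(margin, cols - margin)
    # smooth periodic boundary perturbation from a few harmonics
    n_harm = 4
    amps = rng.normal(0, 1, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for m in range(n_harm):
        pert += amps[m] * np.cos((m + 2) * theta + phases[m])
    pert /= max(np.abs(pert).max(), 1e-12)
    r_theta = radius * (1 + roughness * pert)
    return dy ** 2 + dx ** 2 <= r_theta ** 2


def _make_mask(rng: np.random.Generator, params: SynthParams,
               nodule_code: int) -> np.ndarray:
    rows, cols, b = params.rows, params.cols, params.border_px
    mask = np.zeros((rows, cols), dtype=np.uint8)
    mask[b:rows - b, b:cols - b] = NORMAL
    n_nod = int(rng.integers(params.nodule_count[0],
                             params.nodule_count[1] + 1))
    placed = 0
    attempts = 0
    while placed < max(n_nod, 1) and attempts < 50:
        attempts += 1
        radius = rng.uniform(*params.nodule_radius)
        blob = _nodule_blob(rng, rows, cols, radius,
                            params.boundary_roughness, b)
        if blob is None:
            raise ValueError(
                f"nodule radius {radius:.0f}px incompatible with "
                f"{rows}x{cols} scene")
        mask[blob] = nodule_code
        placed += 1
    return mask


def synth_case(params: SynthParams, diagnosis: str, seed: int,
               case_id: str | None = None,
               endmembers: dict[str, np.ndarray] | None = None) -> CaseRecord:
    """Generate one labelled case: cube, mask and reference frames.

    ``endmembers`` may be supplied to share one spectral library across a
    cohort; otherwise curves are drawn from ``seed`` (which also drives the
    scene geometry, texture and noise).
    """
    if diagnosis not in ("benign", "malignant"):
        raise ValueError(f"diagnosis must be benign/malignant, got {diagnosis!r}")
    rng = np.random.default_rng(seed)
    if endmembers is None:
        endmembers = make_endmembers(params.separation, seed=seed,
                                     n_bands=params.n_bands,
                                     lo=params.endmember_range[0],
                                     hi=params.endmember_range[1])
    nodule_code = BENIGN if diagnosis == "benign" else MALIGNANT
    mask = _make_mask(rng, params, nodule_code)

    lut = np.stack([endmembers["background"], endmembers["normal"],
                    endmembers["benign"], endmembers["malignant"]])
    reflectance = lut[mask].astype(np.float64)          # (rows, cols, B)

    if params.jitter_sd > 0:
        texture = gaussian_filter(
            rng.standard_normal((params.rows, params.cols)),
            sigma=params.jitter_corr_px)
        sd = texture.std()
        if sd > 0:
            texture *= params.jitter_sd / sd
        reflectance = reflectance * (1.0 + texture[:, :, None])
    if params.noise_sd > 0:
        reflectance = reflectance + rng.normal(
            0.0, params.noise_sd, size=reflectance.shape)
    # the scene never exceeds the calibrated range of the reference board
    cal_top = params.board_reflectance * (1.0 + 5.0 * params.noise_sd)
    reflectance = np.clip(reflectance, 0.0, cal_top)

    illum = _illumination(rng, params.rows, params.cols,
                          params.illumination_amp)
    lamp = _lamp_spectrum(rng, params.n_bands)
    gain = illum[:, :, None] * lamp[None, None, :] * params.signal_scale

    top = float(2 ** params.bit_depth - 1)

    def to_counts(signal: np.ndarray) -> np.ndarray:
        clipped = np.clip(signal, 0.0, top)
        if params.quantize:
            return np.rint(clipped).astype(np.uint16)
        return clipped.astype(np.float64)

    counts = to_counts(gain * reflectance + params.dark_level)
    dark = params.dark_level + rng.normal(0.0, params.dark_noise,
                                          size=counts.shape)
    white = gain * params.board_reflectance + params.dark_level \
        + rng.normal(0.0, params.dark_noise, size=counts.shape)
    white = np.maximum(white, dark + 1.0)  # keep the flat-field well posed

    wl = params.wavelengths
    cube = HyperCube(counts, wl, bit_depth=params.bit_depth, units="raw_counts")
    white_ref = HyperCube(to_counts(white), wl, bit_depth=params.bit_depth,
                          units="raw_counts")
    dark_ref = HyperCube(to_counts(dark), wl, bit_depth=params.bit_depth,
                         units="raw_counts")
    if case_id is None:
        case_id = f"{diagnosis[0]}{seed}"
    return CaseRecord(case_id=case_id, diagnosis=diagnosis, cube=cube,
                      mask=LabelMask(mask), white_ref=white_ref,
                      dark_ref=dark_ref,
                      meta={"seed": seed, "endmember": diagnosis})


def synth_cohort(n_benign: int, n_malignant: int,
                 params: SynthParams | None = None,
                 seed: int = 0) -> list[CaseRecord]:
    """Generate a cohort with deterministic per-case seeds from one master seed.

    All cases share one endmember library drawn from the master seed, so the
    between-case variability is geometric and radiometric, not spectral.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one case per diagnosis")
    params = SynthParams() if params is None else params
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_benign + n_malignant + 1) % (2 ** 31)
    endmembers = make_endmembers(params.separation, seed=int(child[0]),
                                 n_bands=params.n_bands,
                                 lo=params.endmember_range[0],
                                 hi=params.endmember_range[1])
    cases = []
    for i in range(n_benign):
        cases.append(synth_case(params, "benign", int(child[1 + i]),
                                case_id=f"b{i:03d}", endmembers=endmembers))
    for j in range(n_malignant):
        cases.append(synth_case(params, "malignant",
                                int(child[1 + n_benign + j]),
                                case_id=f"m{j:03d}", endmembers=endmembers))
    return cases


def write_cohort(cases: list[CaseRecord], out_dir: str | Path,
                 params: SynthParams | None = None) -> Path:
    """Persist a cohort as HDF5 case containers plus a YAML parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        save_case(case, out / f"{case.case_id}.h5")
    if params is not None:
        params.to_yaml(out / "synth_params.yaml")
    return out
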