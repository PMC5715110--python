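"""Beer–Lambert stain math: optical density, color deconvolution and the
forward model used by the synthetic generators.

Brightfield stains absorb light multiplicatively, so a pixel's optical
density ``OD_c = -log10((I_c + 1) / I0_c)`` is (approximately) a linear
mix of per-stain absorbances: ``OD = sum_s a_s * V_s`` with unit stain
vectors ``V_s``.  Color deconvolution inverts that mix (Ruifrok–Johnston);
stain vectors are estimated from stained pixels by an angular-percentile
method in the top-2 singular plane (Macenko-style).

The ``+1`` intensity offset inside the log avoids log(0) on fully dark
pixels; the forward model applies the exact inverse (``I = I0*10^-OD - 1``)
so that forward + inverse round trips are limited only by 8-bit
quantization.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainProfile",
    "DEFAULT_HEMATOXYLIN",
    "DEFAULT_DAB",
    "DEFAULT_EOSIN",
    "hdab_profile",
    "he_profile",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_background",
    "estimate_stain_vectors",
    "deconvolve",
]

# Ruifrok & Johnston reference absorbance vectors (unit-normalized)
DEFAULT_HEMATOXYLIN = np.array([0.651, 0.701, 0.290])
DEFAULT_DAB = np.array([0.269, 0.568, 0.778])
DEFAULT_EOSIN = np.array([0.070, 0.990, 0.110])

STAIN_NAMES = ("hematoxylin", "DAB", "eosin", "residual")
_REFERENCE = {"hematoxylin": DEFAULT_HEMATOXYLIN, "DAB": DEFAULT_DAB, "eosin": DEFAULT_EOSIN}


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass
class StainProfile:
    """Background intensities plus unit stain vectors in OD space.

    ``stains`` is an ordered list of ``(name, 3-vector)``; two-stain
    profiles are completed with a ``residual`` third vector (normalized
    cross product) so the stain matrix is always invertible.
    """

    background: tuple[float, float, float] = (255.0, 255.0, 255.0)
    stains: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bg = tuple(float(b) for b in self.background)
        if any(not (1.0 <= b <= 255.0) for b in bg):
            raise ValueError("background components must lie in [1, 255]")
        self.background = bg
        if not 2 <= len(self.stains) <= 3:
            raise ValueError("a profile needs 2 or 3 stains")
        cleaned = []
        for name, vec in self.stains:
            if name not in STAIN_NAMES:
                raise ValueError(f"unknown stain name {name!r}")
            v = _unit(vec)
            # true stains absorb, so their components are non-negative; the
            # residual completion is orthogonal and may carry mixed signs
            if name != "residual":
                if np.any(v < -1e-9):
                    raise ValueError(f"stain vector for {name} has negative components")
                v = np.clip(v, 0.0, None)
            cleaned.append((name, v))
        self.stains = cleaned

    @property
    def stain_names(self) -> list[str]:
        return [name for name, _ in self.stains]

    def completed(self) -> "StainProfile":
        """Return a 3-stain profile, adding a residual vector if needed."""
        if len(self.stains) == 3:
            return self
        (n1, v1), (n2, v2) = self.stains
        resid = np.cross(v1, v2)
        if np.linalg.norm(resid) < 1e-12:
            raise ValueError("stain vectors are collinear; cannot complete residual")
        return StainProfile(self.background, [(n1, v1), (n2, v2), ("residual", _unit(resid))])

    def matrix(self) -> np.ndarray:
        """3x3 matrix whose rows are the (completed) stain vectors."""
        return np.vstack([v for _, v in self.completed().stains])

    # -- JSON I/O ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "background": list(self.background),
            "stains": [{"name": n, "vector": [float(x) for x in v]} for n, v in self.stains],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "StainProfile":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            tuple(doc["background"]),
            [(s["name"], np.asarray(s["vector"], dtype=float)) for s in doc["stains"]],
        )


def hdab_profile(background=(255.0, 255.0, 255.0)) -> StainProfile:
    """Default hematoxylin + DAB profile for IHC."""
    return StainProfile(background, [("hematoxylin", DEFAULT_HEMATOXYLIN), ("DAB", DEFAULT_DAB)])


def he_profile(background=(255.0, 255.0, 255.0)) -> StainProfile:
    """Default hematoxylin + eosin profile for morphology stains."""
    return StainProfile(background, [("hematoxylin", DEFAULT_HEMATOXYLIN), ("eosin", DEFAULT_EOSIN)])


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB image (H, W, 3) uint8")
    return image


def rgb_to_od(image: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert 8-bit RGB to optical density, clamped at 0.

    ``OD_c = -log10((I_c + 1) / I0_c)``; pixels brighter than the
    background clamp to OD 0.
    """
    image = _check_rgb8(image)
    bg = np.asarray(background, dtype=float)
    if np.any(bg < 1.0):
        raise ValueError("background components must be >= 1")
    od = -np.log10((image.astype(float) + 1.0) / bg)
    return np.clip(od, 0.0, None)


def od_to_rgb(
    concentrations: np.ndarray,
    profile: StainProfile,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Beer–Lambert forward model: render stain amounts to 8-bit RGB.

    ``concentrations`` has shape (H, W, n_stains) in the profile's stain
    order; Gaussian read noise of standard deviation ``noise_sd`` (gray
    levels) is added before rounding.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    prof3 = profile.completed()
    n = len(profile.stains)
    if conc.ndim != 3 or conc.shape[2] != n:
        raise ValueError(f"concentrations must have shape (H, W, {n})")
    m = prof3.matrix()[:n]
    od = conc @ m  # (H, W, 3)
    bg = np.asarray(prof3.background)
    intensity = bg * np.power(10.0, -od) - 1.0
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def estimate_background(image: np.ndarray) -> tuple[float, float, float]:
    """Per-channel mean of the brightest 5% of pixels (by luminance).

    Matches the batch preprocessing step that sets the average RGB
    background per image (scanner-dependent).  Falls back to pure white
    with a warning when even the brightest pixels are dark (no background
    present).
    """
    image = _check_rgb8(image)
    flat = image.reshape(-1, 3).astype(float)
    lum = 0.299 * flat[:, 0] + 0.587 * flat[:, 1] + 0.114 * flat[:, 2]
    cutoff = np.quantile(lum, 0.95)
    sel = flat[lum >= cutoff]
    if sel.size == 0 or (0.299 * sel[:, 0] + 0.587 * sel[:, 1] + 0.114 * sel[:, 2]).mean() < 100:
        warnings.warn("no bright background found; falling back to (255, 255, 255)")
        return (255.0, 255.0, 255.0)
    bg = sel.mean(axis=0)
    bg = np.clip(bg, 1.0, 255.0)
    return (float(bg[0]), float(bg[1]), float(bg[2]))


def estimate_stain_vectors(
    region: np.ndarray,
    background=(255.0, 255.0, 255.0),
    od_threshold: float = 0.15,
    percentile: float = 1.0,
    min_pixels: int = 100,
    stain_names: tuple[str, str] = ("hematoxylin", "DAB"),
) -> StainProfile:
    """Estimate two stain vectors from a representative stained region.

    Pixels with ``||OD|| > od_threshold`` are projected onto the plane of
    the top two singular vectors of the OD cloud; the directions at the
    1st and 99th percentile of the angular distribution are taken as the
    extreme (pure-stain) vectors.  Names are assigned by minimal angle to
    the reference vectors so the result is invariant to which stain
    dominates.
    """
    od = rgb_to_od(region, background).reshape(-1, 3)
    mask = np.linalg.norm(od, axis=1) > od_threshold
    stained = od[mask]
    if stained.shape[0] < min_pixels:
        raise ValueError(
            f"insufficient stained pixels: {stained.shape[0]} above OD {od_threshold}"
        )
    # plane of the two dominant absorbance directions
    _, _, vt = np.linalg.svd(stained, full_matrices=False)
    basis = vt[:2]
    # orient so projections land in a consistent half-plane
    if basis[0].sum() < 0:
        basis[0] = -basis[0]
    if basis[1].sum() < 0:
        basis[1] = -basis[1]
    proj = stained @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [percentile, 100.0 - percentile])
    v_lo = _unit(math.cos(lo) * basis[0] + math.sin(lo) * basis[1])
    v_hi = _unit(math.cos(hi) * basis[0] + math.sin(hi) * basis[1])
    v_lo, v_hi = (np.clip(v, 0.0, None) for v in (v_lo, v_hi))
    v_lo, v_hi = _unit(v_lo), _unit(v_hi)

    ref_a, ref_b = (_unit(_REFERENCE[n]) for n in stain_names)

    def angle(u, v):
        return math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0)))

    # assign extremes to names by total angular mismatch
    straight = angle(v_lo, ref_a) + angle(v_hi, ref_b)
    swapped = angle(v_lo, ref_b) + angle(v_hi, ref_a)
    if straight <= swapped:
        pairs = [(stain_names[0], v_lo), (stain_names[1], v_hi)]
    else:
        pairs = [(stain_names[0], v_hi), (stain_names[1], v_lo)]
    return StainProfile(tuple(np.asarray(background, dtype=float)), pairs).completed()


def deconvolve(image: np.ndarray, profile: StainProfile) -> np.ndarray:
    """Color deconvolution: per-pixel stain concentrations from RGB.

    Returns an (H, W, 3) array with one plane per stain of the completed
    profile (third plane is the residual for two-stain profiles).  Values
    are *not* clamped at zero — negative concentrations are meaningful
    diagnostics and clamping is a scoring-time choice.
    """
    prof3 = profile.completed()
    m = prof3.matrix()
    cond = np.linalg.cond(m)
    if cond > 1e8:
        raise ValueError(f"singular stain matrix (condition number {cond:.3g})")
    od = rgb_to_od(image, prof3.background)
    return od @ np.linalg.inv(m)
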