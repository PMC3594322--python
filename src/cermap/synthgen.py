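"""Synthetic metaphase-cell images and fractionation blots with known truth.

The generator emulates a low-magnification wide-field fluorescence image of
a single metaphase cell: an elliptical cell footprint with a dome-shaped
projected thickness, a bright metaphase plate at the equator, optional
spindle-proximal signal and two centrosome foci, per-cell lognormal
expression variability, Poisson shot noise on the signal photons, and
Gaussian camera read noise on top of a constant electronic offset.

Every generated cell carries ground-truth masks, an emulated hand-drawn
plate ROI (the truth plate boundary perturbed by a seeded smooth
displacement field of up to 2 px, standing in for an imperfect hand
selection on the morphology channel), and the true CER computed on the
noise-free expected image.  Because the metaphase plate sits in the
thickest part of the cell, even a uniformly distributed fluorophore reads
a true CER above 1 whenever the thickness profile is non-flat — the
geometry that explains why a free GFP control does not score 1.0.

Chromosome-enrichment multipliers for named constructs are not set by hand:
:func:`calibrate_chrom_enrich` solves for the multiplier that makes the
noise-free true CER equal a requested target (the expected image is linear
in the multiplier, so two probe evaluations determine it exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fractionation import BlotSample, BlotTruth
from .quantify import compute_cer

__all__ = [
    "CellGeometry",
    "GeometryError",
    "LocalizationProfile",
    "NoiseModel",
    "SaturationError",
    "SyntheticCell",
    "calibrate_chrom_enrich",
    "expected_image",
    "generate_blot",
    "generate_cell_image",
    "generate_cohort",
]


class GeometryError(ValueError):
    """Raised when the cell/plate geometry is inconsistent."""


class SaturationError(ValueError):
    """Raised when the expected intensity exceeds the camera bit depth."""


@dataclass(frozen=True)
class LocalizationProfile:
    """Localization behaviour of one reporter construct.

    Multipliers are dimensionless factors applied to the local cytoplasmic
    concentration: ``chrom_enrich`` on the metaphase plate, ``spindle_enrich``
    in the spindle region between the plate and the poles, and
    ``centrosome_enrich`` at two polar foci.  ``expression_mean`` /
    ``expression_cv`` parameterize the lognormal per-cell expression level
    (arbitrary intensity units).  ``plate_undefined_prob`` is the chance a
    cell's metaphase plate would not be judged well-defined on the
    morphology channel (a human call the generator draws as truth metadata).
    """

    name: str
    chrom_enrich: float = 1.0
    spindle_enrich: float = 1.0
    centrosome_enrich: float = 1.0
    expression_mean: float = 220.0
    expression_cv: float = 1.0
    plate_undefined_prob: float = 0.15

    def __post_init__(self) -> None:
        for attr in ("chrom_enrich", "spindle_enrich", "centrosome_enrich"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{attr} must be finite and >= 0, got {v}")
        if not self.expression_mean > 0:
            raise ValueError("expression_mean must be > 0")
        if self.expression_cv < 0:
            raise ValueError("expression_cv must be >= 0")
        if not 0 <= self.plate_undefined_prob <= 1:
            raise ValueError("plate_undefined_prob must be in [0, 1]")


@dataclass(frozen=True)
class CellGeometry:
    """Pixel geometry of the simulated cell and camera.

    ``thickness_power`` shapes the projected-thickness dome
    ``t = (1 - r^2)^power`` over the elliptical footprint (r = normalized
    elliptical radius); 0 gives a flat slab.  ``soft_sigma`` is the PSF-like
    Gaussian smoothing (px) applied to the compartment-enrichment map, so
    plate edges are not step functions.  ``background_level`` is the
    electronic camera offset and ``bit_depth`` the saturation ceiling.
    """

    image_shape: tuple[int, int] = (160, 160)
    cell_axes: tuple[float, float] = (48.0, 60.0)  # (row, col) semi-axes
    plate_axes: tuple[float, float] = (26.0, 8.0)
    spindle_axes: tuple[float, float] = (22.0, 42.0)
    centrosome_offset: float = 42.0  # px from center along the long (col) axis
    centrosome_sigma: float = 3.0
    thickness_power: float = 0.5
    soft_sigma: float = 2.0
    background_level: float = 20.0
    bit_depth: float = 4095.0
    background_margin: float = 6.0  # px gap between cell rim and bg region

    def __post_init__(self) -> None:
        a_r, a_c = self.cell_axes
        p_r, p_c = self.plate_axes
        if not (p_r < a_r and p_c < a_c):
            raise GeometryError("plate ellipse must lie strictly inside the cell ellipse")
        n_r, n_c = self.image_shape
        if a_r + 10 > n_r / 2 or a_c + 10 > n_c / 2:
            raise GeometryError("image must contain the cell plus a >=10 px background margin")
        if self.thickness_power < 0:
            raise GeometryError("thickness_power must be >= 0")

    def _grids(self) -> tuple[np.ndarray, np.ndarray]:
        n_r, n_c = self.image_shape
        rr, cc = np.meshgrid(
            np.arange(n_r) - (n_r - 1) / 2.0,
            np.arange(n_c) - (n_c - 1) / 2.0,
            indexing="ij",
        )
        return rr, cc

    def masks(self) -> dict[str, np.ndarray]:
        """Truth masks: cell, plate, spindle (excl. plate), background."""
        rr, cc = self._grids()

        def ell(axes):
            return (rr / axes[0]) ** 2 + (cc / axes[1]) ** 2

        cell = ell(self.cell_axes) <= 1.0
        plate = ell(self.plate_axes) <= 1.0
        spindle = (ell(self.spindle_axes) <= 1.0) & ~plate & cell
        bg_axes = (self.cell_axes[0] + self.background_margin, self.cell_axes[1] + self.background_margin)
        background = ell(bg_axes) > 1.0
        return {"cell": cell, "plate": plate, "spindle": spindle, "background": background}

    def thickness(self) -> np.ndarray:
        """Projected-thickness dome, peak 1 at center, 0 outside the cell."""
        rr, cc = self._grids()
        r2 = (rr / self.cell_axes[0]) ** 2 + (cc / self.cell_axes[1]) ** 2
        t = np.zeros(self.image_shape, dtype=float)
        inside = r2 <= 1.0
        t[inside] = (1.0 - r2[inside]) ** self.thickness_power
        return t


@dataclass(frozen=True)
class NoiseModel:
    """CCD camera noise: Poisson shot noise on signal photons + read noise.

    ``photon_scale`` is the expected number of photons per intensity unit
    (``None`` or ``inf`` disables shot noise); ``read_sd`` is the Gaussian
    read-noise SD in intensity units, applied everywhere including the
    offset-only background.  ``bin2x2`` optionally block-averages the final
    image 2×2 (halving the frame), mimicking on-camera binning.
    """

    photon_scale: float | None = 2.0
    read_sd: float = 0.5
    bin2x2: bool = False

    def __post_init__(self) -> None:
        if self.photon_scale is not None and not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0 (or None for no shot noise)")
        if self.read_sd < 0:
            raise ValueError("read_sd must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(photon_scale=None, read_sd=0.0)

    @property
    def is_noiseless(self) -> bool:
        ps = self.photon_scale
        return (ps is None or np.isinf(ps)) and self.read_sd == 0


@dataclass
class SyntheticCell:
    """One generated cell image plus its ground truth."""

    fluor_image: np.ndarray
    chrom_mask_truth: np.ndarray
    cell_mask_truth: np.ndarray
    background_mask: np.ndarray
    chrom_roi: np.ndarray
    true_cer: float
    seed: int
    expression: float
    plate_defined: bool = True
    saturated: bool = False
    cell_id: str = "cell"
    profile_name: str = ""


def _roi_jitter(plate: np.ndarray, rng: np.random.Generator, amplitude: float = 2.0, n_harmonics: int = 3) -> np.ndarray:
    """Emulated hand-drawn plate ROI.

    The truth boundary is displaced by a smooth angular field
    ``eta(theta) = sum_k a_k cos(k theta) + b_k sin(k theta)`` clipped to
    ±amplitude px: the ROI is ``signed_distance(plate) <= eta``.  The field
    is mean-zero, so the hand ROI is locally dilated in some sectors and
    eroded in others, like a tracing error, without a net area bias.
    """
    if amplitude == 0:
        return plate.copy()
    inside = ndimage.distance_transform_edt(plate)
    outside = ndimage.distance_transform_edt(~plate)
    sdist = np.where(plate, -inside, outside)  # negative inside

    com = ndimage.center_of_mass(plate)
    rr, cc = np.meshgrid(np.arange(plate.shape[0]), np.arange(plate.shape[1]), indexing="ij")
    theta = np.arctan2(rr - com[0], cc - com[1])
    coef = rng.normal(0.0, amplitude / 2.0, size=(n_harmonics, 2))
    eta = np.zeros_like(theta)
    for k in range(1, n_harmonics + 1):
        eta += coef[k - 1, 0] * np.cos(k * theta) + coef[k - 1, 1] * np.sin(k * theta)
    eta = np.clip(eta, -amplitude, amplitude)
    roi = sdist <= eta
    return roi


def expected_image(
    profile: LocalizationProfile,
    geometry: CellGeometry,
    expression: float | None = None,
) -> np.ndarray:
    """Noise-free expected image: offset + thickness × expression × enrichment.

    The compartment-enrichment map (plate/spindle/centrosome multipliers on
    a cytoplasmic baseline of 1) is Gaussian-smoothed by ``soft_sigma``
    before being modulated by the thickness dome, so compartment boundaries
    are diffraction-soft while the cell outline stays set by the thickness
    profile.  Smoothing a uniform map is the identity, so a uniform profile
    in a flat cell yields an exactly constant intensity over the footprint.
    """
    if expression is None:
        expression = profile.expression_mean
    masks = geometry.masks()
    mult = np.ones(geometry.image_shape, dtype=float)
    mult[masks["plate"]] = profile.chrom_enrich
    mult[masks["spindle"]] = profile.spindle_enrich
    if profile.centrosome_enrich != 1.0:
        rr, cc = geometry._grids()
        for sign in (-1.0, 1.0):
            d2 = rr**2 + (cc - sign * geometry.centrosome_offset) ** 2
            mult += (profile.centrosome_enrich - 1.0) * np.exp(-d2 / (2.0 * geometry.centrosome_sigma**2))
    if geometry.soft_sigma > 0:
        mult = ndimage.gaussian_filter(mult, geometry.soft_sigma, mode="nearest")
    return geometry.background_level + geometry.thickness() * expression * mult


def _true_cer(expected: np.ndarray, masks: dict[str, np.ndarray], geometry: CellGeometry) -> float:
    chrom_mean = float(expected[masks["plate"]].mean())
    cell_mean = float(expected[masks["cell"]].mean())
    return compute_cer(chrom_mean, cell_mean, geometry.background_level)


def generate_cell_image(
    profile: LocalizationProfile,
    geometry: CellGeometry,
    noise: NoiseModel,
    seed: int,
    expression: float | None = None,
    plate_defined: bool = True,
    clip: bool = False,
    cell_id: str = "cell",
) -> SyntheticCell:
    """Generate one annotated synthetic metaphase cell.

    Raises :class:`SaturationError` if the noise-free expected intensity
    exceeds the camera bit depth, unless ``clip=True``, in which case the
    image is clipped at the ceiling and the cell flagged ``saturated=True``
    (an overexpressor the camera could not record linearly).
    """
    rng = np.random.default_rng(seed)
    masks = geometry.masks()
    expected = expected_image(profile, geometry, expression)

    saturated = bool(expected.max() > geometry.bit_depth)
    if saturated and not clip:
        raise SaturationError(
            f"expected intensity {expected.max():.1f} exceeds bit depth "
            f"{geometry.bit_depth:g}; lower expression or pass clip=True"
        )

    true_cer = _true_cer(expected, masks, geometry)

    img = expected
    if not noise.is_noiseless:
        signal = expected - geometry.background_level
        ps = noise.photon_scale
        if ps is not None and np.isfinite(ps):
            img = geometry.background_level + rng.poisson(np.clip(signal, 0, None) * ps) / ps
        if noise.read_sd > 0:
            img = img + rng.normal(0.0, noise.read_sd, size=img.shape)
    if saturated:
        img = np.minimum(img, geometry.bit_depth)

    roi = _roi_jitter(masks["plate"], rng)

    cell = SyntheticCell(
        fluor_image=np.asarray(img, dtype=float),
        chrom_mask_truth=masks["plate"],
        cell_mask_truth=masks["cell"],
        background_mask=masks["background"],
        chrom_roi=roi,
        true_cer=true_cer,
        seed=int(seed),
        expression=float(expression if expression is not None else profile.expression_mean),
        plate_defined=plate_defined,
        saturated=saturated,
        cell_id=cell_id,
        profile_name=profile.name,
    )
    if noise.bin2x2:
        cell = _bin2x2(cell, geometry)
    return cell


def _bin2x2(cell: SyntheticCell, geometry: CellGeometry) -> SyntheticCell:
    """2×2 block-mean binning of the image; masks kept where ≥2/4 px set."""

    def blk(a):
        n_r, n_c = (a.shape[0] // 2) * 2, (a.shape[1] // 2) * 2
        return a[:n_r, :n_c].reshape(n_r // 2, 2, n_c // 2, 2)

    img = blk(cell.fluor_image).mean(axis=(1, 3))

    def blkmask(m):
        return blk(m.astype(int)).sum(axis=(1, 3)) >= 2

    return replace(
        cell,
        fluor_image=img,
        chrom_mask_truth=blkmask(cell.chrom_mask_truth),
        cell_mask_truth=blkmask(cell.cell_mask_truth),
        background_mask=blkmask(cell.background_mask),
        chrom_roi=blkmask(cell.chrom_roi),
    )


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(
    profile: LocalizationProfile,
    n: int,
    geometry: CellGeometry | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[SyntheticCell]:
    """Generate ``n`` independent cells of one construct.

    Per-cell expression is drawn lognormally with mean ``expression_mean``
    and CV ``expression_cv``; each cell gets a distinct child seed spawned
    from ``seed`` so the cohort is reproducible bit-for-bit.  Cells whose
    expected intensity would saturate the camera are clipped and flagged
    (they are strong overexpressors that the scoring layer will reject).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    geometry = geometry or CellGeometry()
    noise = noise or NoiseModel()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    rng = np.random.default_rng(ss)
    if profile.expression_cv > 0:
        mu, sigma = _lognormal_params(profile.expression_mean, profile.expression_cv)
        expressions = rng.lognormal(mu, sigma, size=n)
    else:
        expressions = np.full(n, profile.expression_mean)
    plate_ok = rng.random(n) >= profile.plate_undefined_prob

    cells = []
    for i in range(n):
        cells.append(
            generate_cell_image(
                profile,
                geometry,
                noise,
                seed=child_seeds[i],
                expression=float(expressions[i]),
                plate_defined=bool(plate_ok[i]),
                clip=True,
                cell_id=f"{profile.name}_{i:03d}",
            )
        )
    return cells


def calibrate_chrom_enrich(
    target_cer: float,
    geometry: CellGeometry | None = None,
    profile: LocalizationProfile | None = None,
) -> float:
    """Chromosome-enrichment multiplier giving a noise-free true CER of ``target_cer``.

    The expected image is affine in ``chrom_enrich``, so the
    background-subtracted plate and cell means are ``A0 + A1·e`` and
    ``B0 + B1·e``; two probe evaluations (e=0, e=1) determine the
    coefficients and the target ratio is solved in closed form.
    """
    geometry = geometry or CellGeometry()
    base = profile or LocalizationProfile(name="calib")
    masks = geometry.masks()
    bg = geometry.background_level

    def means(e):
        exp_img = expected_image(replace(base, chrom_enrich=e), geometry)
        return exp_img[masks["plate"]].mean() - bg, exp_img[masks["cell"]].mean() - bg

    a0, b0 = means(0.0)
    a1, b1 = means(1.0)
    A1, B1 = a1 - a0, b1 - b0
    denom = A1 - target_cer * B1
    if denom <= 0:
        raise ValueError(f"target CER {target_cer} not reachable with this geometry")
    e = (target_cer * b0 - a0) / denom
    if e < 0:
        raise ValueError(f"target CER {target_cer} requires negative enrichment")
    return float(e)


def generate_blot(truth: BlotTruth, seed: int = 0) -> BlotSample:
    """Synthetic fractionation densitometry for one protein.

    Linear mixing model: a fraction ``true_fraction`` of the protein is
    chromosome-associated, and a proportion ``contamination`` of the
    remaining cytoplasmic material pellets with the chromosomes, so

        CHR  = total · (f + c·(1 − f))
        CYTO = total · (1 − f)·(1 − c)
        WCE  = total

    Each band gets independent multiplicative lognormal noise of CV
    ``noise_cv`` (none when 0, so the identity holds exactly).
    """
    f, c = truth.true_fraction, truth.contamination
    chr_band = truth.total_signal * (f + c * (1.0 - f))
    cyto_band = truth.total_signal * (1.0 - f) * (1.0 - c)
    wce = truth.total_signal
    if truth.noise_cv > 0:
        rng = np.random.default_rng(seed)
        mu, sigma = _lognormal_params(1.0, truth.noise_cv)
        wce, chr_band, cyto_band = (
            v * rng.lognormal(mu, sigma) for v in (wce, chr_band, cyto_band)
        )
    return BlotSample(
        protein=truth.protein,
        wce=float(wce),
        chr_band=float(chr_band),
        cyto_band=float(cyto_band),
        truth=truth,
    )
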