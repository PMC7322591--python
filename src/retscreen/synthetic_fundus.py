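"""Synthetic fundus phantoms with grade-dependent lesion load.

A phantom is a bright circular retina disc on a near-black background, with
a brighter optic-disc blob, dark curvilinear vessels (quadratic Bezier
strokes) and two small-lesion populations with speckled interiors: bright
exudate-like blobs and dark hemorrhage/microaneurysm-like blobs.  Lesion
counts are Poisson with a mean that grows strictly with DR grade (0, 2, 6,
12, 20 in total by default, split evenly between the two populations), so
severer grades produce more heterogeneous — higher local-entropy — images,
the property the screening pipeline exploits.

Channel structure mirrors fundus photography: vessel and lesion contrast is
strongest in the green plane (retinal pigmentation reflects green light; a
fraction of dark hemorrhages lie deep below the vessel layer and show up in
red instead), and each channel carries its own grade-independent artifact
population — drusen-like deposits in red, flash/NFL reflection spots in
green — plus diffuse choroidal mottling in red.

The generator reproduces the statistical structure the pipeline needs, not
photorealism: no illumination gradients, camera vignetting or acquisition
artifacts of real screening photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import bezier_curve
from skimage.morphology import dilation, disk as disk_footprint

from .errors import ConfigError
from .image_io import ImageRecord

__all__ = ["PhantomSpec", "generate_phantom", "generate_corpus", "write_corpus"]

#: Poisson means for (bright, dark) lesion counts per grade 0..4
DEFAULT_BRIGHT_MEANS = (0.0, 1.0, 3.0, 6.0, 10.0)
DEFAULT_DARK_MEANS = (0.0, 1.0, 3.0, 6.0, 10.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and lesion statistics for one phantom.

    All contrasts are (R, G, B) triplets subtracted from / added to the base
    fundus color; the green entry is the largest so the green plane carries
    the strongest vessel/lesion contrast.  ``side`` must be >= 32 so the
    disc, optic disc and vessels fit.
    """

    side: int = 100
    grade: int = 0
    seed: int = 0
    vessel_count_range: tuple[int, int] = (8, 10)
    vessel_width_range: tuple[int, int] = (1, 2)
    bright_lesion_means: tuple[float, ...] = DEFAULT_BRIGHT_MEANS
    dark_lesion_means: tuple[float, ...] = DEFAULT_DARK_MEANS
    bright_radius_range: tuple[float, float] = (4.5, 6.5)
    dark_radius_range: tuple[float, float] = (3.0, 4.5)
    background_level: float = 8.0
    disc_rgb: tuple[float, float, float] = (170.0, 110.0, 45.0)
    noise_sigma: float = 0.8
    vessel_contrast_rgb: tuple[float, float, float] = (8.0, 35.0, 6.0)
    bright_contrast_rgb: tuple[float, float, float] = (12.0, 48.0, 7.0)
    dark_contrast_rgb: tuple[float, float, float] = (8.0, 42.0, 5.0)
    lesion_speckle: float = 0.35
    #: per-grade relative growth of lesion radius: severer DR produces
    #: larger hemorrhages and exudate plaques, not just more of them
    lesion_radius_grade_scale: float = 0.08
    choroid_mottle_rgb: tuple[float, float, float] = (10.0, 2.0, 1.0)
    choroid_mottle_scale: float = 3.0
    #: drusen-like deposits: small textured blobs visible almost only in red
    #: light, present at every DR grade — they mimic lesions in the luminance
    #: channel but not in the green component
    distractor_mean: float = 6.0
    distractor_contrast_rgb: tuple[float, float, float] = (32.0, 4.0, 2.0)
    distractor_radius_range: tuple[float, float] = (2.5, 5.0)
    #: flash/nerve-fiber-layer reflection artifacts: small bright textured
    #: spots most visible in green light, independent of DR grade — the
    #: green channel's own nuisance population
    reflection_mean: float = 5.0
    reflection_contrast_rgb: tuple[float, float, float] = (4.0, 26.0, 2.0)
    reflection_radius_range: tuple[float, float] = (2.0, 4.0)
    #: fraction of dark lesions lying deep below the vessel layer: deep
    #: intraretinal hemorrhages are visible in red light but barely in green,
    #: so the luminance channel carries signal the green component misses —
    #: the complementary information the two-channel fusion exploits
    deep_dark_fraction: float = 0.4
    deep_dark_contrast_rgb: tuple[float, float, float] = (34.0, 10.0, 4.0)

    def __post_init__(self) -> None:
        if self.side < 32:
            raise ConfigError(f"side must be >= 32, got {self.side}")
        if not 0 <= self.grade <= 4:
            raise ConfigError(f"grade must be in 0..4, got {self.grade}")
        totals = [b + d for b, d in zip(self.bright_lesion_means, self.dark_lesion_means)]
        if any(later <= earlier for earlier, later in zip(totals, totals[1:])):
            raise ConfigError("expected lesion count must increase strictly with grade")
        for contrast in (self.vessel_contrast_rgb, self.bright_contrast_rgb, self.dark_contrast_rgb):
            if contrast[1] < max(contrast[0], contrast[2]):
                raise ConfigError("green-plane contrast must dominate red and blue")


def _gaussian_blob(shape, center, sigma) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.exp(-(rows**2 + cols**2) / (2.0 * sigma**2))


def _render(spec: PhantomSpec, rng: np.random.Generator):
    s = spec.side
    center = (s - 1) / 2.0
    disc_radius = 0.47 * s
    rows = np.arange(s)[:, None] - center
    cols = np.arange(s)[None, :] - center
    radial = np.sqrt(rows**2 + cols**2)
    disc_mask = radial <= disc_radius

    planes = np.empty((s, s, 3), dtype=np.float64)
    falloff = 1.0 - 0.25 * np.clip(radial / disc_radius, 0, 1) ** 2
    for ch, base in enumerate(spec.disc_rgb):
        planes[:, :, ch] = base * falloff
    # sensor/illumination noise is mostly common-mode across the color
    # planes (shared field) with a smaller independent per-channel part
    planes += rng.normal(0.0, spec.noise_sigma, size=(s, s))[:, :, None]
    planes += rng.normal(0.0, 0.3 * spec.noise_sigma, size=planes.shape)

    # choroidal mottling: diffuse low-frequency texture from the vascular
    # layer beneath the retina, visible almost exclusively in red light —
    # the nuisance texture that makes the green plane the clean channel
    mottle = gaussian_filter(rng.normal(0.0, 1.0, size=(s, s)), spec.choroid_mottle_scale)
    mottle /= max(mottle.std(), 1e-9)
    for ch, amp in enumerate(spec.choroid_mottle_rgb):
        planes[:, :, ch] += amp * mottle

    # optic disc: bright blob off-center
    angle = rng.uniform(0, 2 * np.pi)
    od_center = (
        center + 0.55 * disc_radius * np.sin(angle),
        center + 0.55 * disc_radius * np.cos(angle),
    )
    od_blob = _gaussian_blob((s, s), od_center, 0.09 * s)
    for ch, amp in enumerate((55.0, 70.0, 40.0)):
        planes[:, :, ch] += amp * od_blob

    # vessels: quadratic Bezier strokes radiating from the optic disc
    n_vessels = int(rng.integers(spec.vessel_count_range[0], spec.vessel_count_range[1] + 1))
    for _ in range(n_vessels):
        theta = rng.uniform(0, 2 * np.pi)
        end = (
            center + 0.92 * disc_radius * np.sin(theta),
            center + 0.92 * disc_radius * np.cos(theta),
        )
        mid_theta = theta + rng.uniform(-0.8, 0.8)
        mid_r = disc_radius * rng.uniform(0.3, 0.7)
        ctrl = (center + mid_r * np.sin(mid_theta), center + mid_r * np.cos(mid_theta))
        rr, cc = bezier_curve(
            int(round(od_center[0])), int(round(od_center[1])),
            int(round(ctrl[0])), int(round(ctrl[1])),
            int(round(end[0])), int(round(end[1])),
            weight=1.0, shape=(s, s),
        )
        stroke = np.zeros((s, s), dtype=bool)
        stroke[rr, cc] = True
        width = int(rng.integers(spec.vessel_width_range[0], spec.vessel_width_range[1] + 1))
        if width > 1:
            stroke = dilation(stroke, disk_footprint(width - 1))
        soft = gaussian_filter(stroke.astype(np.float64), 0.7)
        soft /= max(soft.max(), 1e-9)
        for ch, amp in enumerate(spec.vessel_contrast_rgb):
            planes[:, :, ch] -= amp * soft

    # lesions: counts ~ Poisson(grade-dependent mean); none at grade 0
    lesions: list[tuple[str, float, float, float]] = []
    for kind, means, radii, contrast, sign in (
        ("bright", spec.bright_lesion_means, spec.bright_radius_range,
         spec.bright_contrast_rgb, +1.0),
        ("dark", spec.dark_lesion_means, spec.dark_radius_range,
         spec.dark_contrast_rgb, -1.0),
    ):
        mean = means[spec.grade]
        count = int(rng.poisson(mean)) if mean > 0 else 0
        for _ in range(count):
            r = rng.uniform(0, 0.8 * disc_radius)
            phi = rng.uniform(0, 2 * np.pi)
            pos = (center + r * np.sin(phi), center + r * np.cos(phi))
            radius = rng.uniform(*radii) * (1.0 + spec.lesion_radius_grade_scale * spec.grade)
            blob = _gaussian_blob((s, s), pos, radius / 2.0)
            this_kind, this_contrast = kind, contrast
            if kind == "dark" and rng.random() < spec.deep_dark_fraction:
                this_kind, this_contrast = "dark_deep", spec.deep_dark_contrast_rgb
            # lesions are textured, not smooth: speckle across the footprint
            # mimics the granular interior of exudates and hemorrhages and
            # gives them their high local-entropy signature
            tex = rng.normal(0.0, 1.0, size=(s, s)) * (blob > 0.25)
            for ch, amp in enumerate(this_contrast):
                planes[:, :, ch] += sign * amp * blob + spec.lesion_speckle * amp * tex
            lesions.append((this_kind, pos[0], pos[1], radius))

    # grade-independent artifact populations: drusen-like deposits seen in
    # red light, and flash/NFL reflection spots seen in green light — each
    # channel has its own nuisance, and luminance inherits both (diluted)
    for mean, contrast, radii in (
        (spec.distractor_mean, spec.distractor_contrast_rgb, spec.distractor_radius_range),
        (spec.reflection_mean, spec.reflection_contrast_rgb, spec.reflection_radius_range),
    ):
        count = int(rng.poisson(mean)) if mean > 0 else 0
        for _ in range(count):
            r = rng.uniform(0, 0.8 * disc_radius)
            phi = rng.uniform(0, 2 * np.pi)
            pos = (center + r * np.sin(phi), center + r * np.cos(phi))
            radius = rng.uniform(*radii)
            blob = _gaussian_blob((s, s), pos, radius / 2.0)
            tex = rng.normal(0.0, 1.0, size=(s, s)) * (blob > 0.25)
            for ch, amp in enumerate(contrast):
                planes[:, :, ch] += amp * blob + spec.lesion_speckle * amp * tex

    # background outside the retina disc
    bg = spec.background_level + rng.normal(0.0, 1.5, size=(s, s, 3))
    planes = np.where(disc_mask[:, :, None], planes, bg)
    image = np.clip(np.floor(planes + 0.5), 0, 255).astype(np.uint8)
    return image, lesions


def generate_phantom(
    spec: PhantomSpec, return_lesions: bool = False
) -> tuple[np.ndarray, ImageRecord]:
    """Render one phantom; deterministic given the spec (including its seed).

    Returns the (side, side, 3) uint8 image and its :class:`ImageRecord`;
    with ``return_lesions=True`` also the list of drawn lesions
    ``(kind, row, col, radius)`` for inspection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, spec.grade]))
    image, lesions = _render(spec, rng)
    record = ImageRecord(
        image_id=f"phantom_g{spec.grade}_s{spec.seed:08d}",
        path="",
        grade=spec.grade,
    )
    if return_lesions:
        return image, record, lesions
    return image, record


def generate_corpus(
    per_grade_counts: dict[int, int],
    side: int = 100,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> list[tuple[np.ndarray, ImageRecord]]:
    """Exactly the requested number of phantoms per grade.

    Child seeds derive deterministically from the master seed, so the k-th
    image of grade g is identical across runs regardless of the other
    requested counts.
    """
    base = spec if spec is not None else PhantomSpec(side=side)
    out: list[tuple[np.ndarray, ImageRecord]] = []
    for grade in sorted(per_grade_counts):
        count = per_grade_counts[grade]
        if count < 0:
            raise ConfigError(f"negative count for grade {grade}")
        for k in range(count):
            child_seed = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, grade, k]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            child = replace(base, side=side, grade=grade, seed=child_seed)
            image, record = generate_phantom(child)
            record = ImageRecord(
                image_id=f"phantom_g{grade}_{k:05d}", path="", grade=grade
            )
            out.append((image, record))
    return out


def write_corpus(
    corpus: list[tuple[np.ndarray, ImageRecord]], outdir: str | Path
) -> list[ImageRecord]:
    """Write phantom PNGs plus a manifest-ready record list with real paths."""
    from . import image_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for image, record in corpus:
        path = outdir / f"{record.image_id}.png"
        image_io.save_image(image, path)
        records.append(ImageRecord(record.image_id, str(path), record.grade))
    return records
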