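"""Synthetic ground-truthed microscopy: fields, growth series, experiments.

Emulates the two-channel (DAPI nuclei / FITC-VWF) confocal z-stacks the
counting pipeline consumes: fields of elliptical nuclei, rod-shaped
Weibel-Palade bodies rendered as capsules (a rectangle with semicircular
caps, matching their rod/cylinder morphology: 0.1-0.3 um diameter,
1-5 um length), and small round immature vesicles.  Stacks default to
23 slices at a 0.3 um step.  Every object is brightest at its own focal
slice with Gaussian axial fall-off; the lateral point-spread is a
Gaussian blur, plus additive background and Gaussian read noise.

Objects are rasterized with single-pixel antialiasing (per-pixel
coverage), so even 0.1 um-wide rods produce connected digital
footprints.  Placement is rejection sampling against an occupancy mask:
by default objects land fully inside the field, pairwise separated by
``min_separation_um``, with a configurable tolerated overlap fraction to
stress-test counting.  Everything is driven by one seeded RNG per
operation — identical seeds give bit-identical output.

The experiment simulator reproduces the study designs: either constant
incubation time (96 h) across seeding densities 5,000/10,000/30,000
cells/cm^2, or constant density (30,000 cells/cm^2) across 24/48/72/96 h,
with 5 slides x 9 fields per condition over 3 independent experiments.
Local cell counts follow exponential growth scaled to the field area and
the WPB-per-cell yield follows a monotone (logistic) function of local
density, emulating the confluency dependence of WPB formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .growth import GrowthSeries
from .quantification import ConfluencyCutoff
from .segmentation import FieldImage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "NucleusTruth",
    "WpbTruth",
    "ImmatureTruth",
    "ExperimentDesign",
    "WpbPerCellCurve",
    "SimulatedField",
    "PlacementError",
    "render_field",
    "simulate_growth_counts",
    "simulate_experiment",
]


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed within the overlap budget."""


# ---------------------------------------------------------------------------
# Scene specification


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic field.

    Size ranges are (min, max) pairs in microns, sampled uniformly.
    ``psf_sigma_um`` is the lateral Gaussian blur; ``z_sigma_um`` the
    axial intensity fall-off of point-like objects (nuclei span more of
    the stack, ``nucleus_z_sigma_um``).  ``allowed_overlap_fraction`` is
    the tolerated fractional footprint overlap during placement
    (0 = strictly non-overlapping with ``min_separation_um`` margins).
    """

    field_width_px: int = 1024
    field_height_px: int = 1024
    pixel_size_um: float = 0.11
    n_slices: int = 23
    z_step_um: float = 0.3
    nucleus_count: int = 30
    nucleus_radius_um: tuple[float, float] = (4.0, 8.0)
    wpb_count: int = 200
    wpb_length_um: tuple[float, float] = (1.0, 5.0)
    wpb_width_um: tuple[float, float] = (0.1, 0.3)
    immature_count: int = 0
    immature_radius_um: tuple[float, float] = (0.2, 0.45)
    background_level: float = 10.0
    noise_sd: float = 0.0
    psf_sigma_um: float = 0.11
    nucleus_intensity: float = 120.0
    wpb_intensity: float = 120.0
    immature_intensity: float = 120.0
    z_sigma_um: float = 0.6
    nucleus_z_sigma_um: float = 2.5
    min_separation_um: float = 0.6
    allowed_overlap_fraction: float = 0.0
    max_place_retries: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel size and z-step must be positive")
        if self.n_slices <= 0:
            raise ValueError("n_slices must be positive")
        for name in ("nucleus_radius_um", "wpb_length_um", "wpb_width_um", "immature_radius_um"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        for name in ("nucleus_count", "wpb_count", "immature_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.background_level < 0 or self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("background, noise and PSF sigma must be non-negative")
        if not (0 <= self.allowed_overlap_fraction <= 1):
            raise ValueError("allowed_overlap_fraction must lie in [0, 1]")

    @property
    def field_area_um2(self) -> float:
        return (
            self.field_width_px
            * self.field_height_px
            * self.pixel_size_um
            * self.pixel_size_um
        )

    @property
    def field_area_cm2(self) -> float:
        return self.field_area_um2 * 1e-8


@dataclass(frozen=True)
class NucleusTruth:
    centroid_px: tuple[float, float]  # (y, x)
    radii_px: tuple[float, float]  # (semi-major, semi-minor)
    orientation_rad: float


@dataclass(frozen=True)
class WpbTruth:
    centroid_px: tuple[float, float]
    length_px: float
    width_px: float
    orientation_rad: float
    z_center: float  # slice units


@dataclass(frozen=True)
class ImmatureTruth:
    centroid_px: tuple[float, float]
    radius_px: float
    z_center: float


@dataclass(frozen=True)
class GroundTruth:
    """Exact object inventory of one rendered field."""

    nuclei: tuple[NucleusTruth, ...]
    wpbs: tuple[WpbTruth, ...]
    immature: tuple[ImmatureTruth, ...]

    @property
    def nucleus_count(self) -> int:
        return len(self.nuclei)

    @property
    def wpb_count(self) -> int:
        return len(self.wpbs)

    @property
    def immature_count(self) -> int:
        return len(self.immature)


# ---------------------------------------------------------------------------
# Rasterization primitives (pixel units; coverage in [0, 1])


def _ellipse_coverage(a: float, b: float, theta: float, half: int) -> np.ndarray:
    n = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ct, st = math.cos(theta), math.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    f = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # approximate signed edge distance, in pixels
    d = (1.0 - f) * min(a, b)
    return np.clip(d + 0.5, 0.0, 1.0)


def _capsule_coverage(length: float, width: float, theta: float, half: int) -> np.ndarray:
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ct, st = math.cos(theta), math.sin(theta)
    s = max((length - width) / 2.0, 0.0)
    t = np.clip(xx * ct + yy * st, -s, s)
    d = np.hypot(xx - t * ct, yy - t * st)
    return np.clip(width / 2.0 + 0.5 - d, 0.0, 1.0)


def _disc_coverage(radius: float, half: int) -> np.ndarray:
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    d = np.hypot(xx, yy)
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def _disk_structure(radius_px: int) -> np.ndarray:
    if radius_px <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px


class _Placer:
    """Occupancy-mask rejection sampler for one channel."""

    def __init__(self, height: int, width: int, margin_px: int, overlap: float, retries: int):
        self.height = height
        self.width = width
        self.occ = np.zeros((height, width), dtype=bool)
        self.structure = _disk_structure(margin_px)
        self.overlap = overlap
        self.retries = retries

    def place(self, rng: np.random.Generator, coverage_fn, half: int):
        """Try to place one object; returns (cy, cx, coverage) or raises."""
        if 2 * half + 1 > min(self.height, self.width):
            raise PlacementError("object larger than the field")
        cov = None
        for _ in range(self.retries):
            cy = int(rng.integers(half, self.height - half))
            cx = int(rng.integers(half, self.width - half))
            if cov is None:
                cov = coverage_fn(half)
                foot = cov > 0
                foot_n = int(foot.sum())
            window = self.occ[cy - half : cy + half + 1, cx - half : cx + half + 1]
            overlap_n = int(np.count_nonzero(window & foot))
            if overlap_n <= self.overlap * foot_n:
                dilated = ndimage.binary_dilation(foot, structure=self.structure)
                np.logical_or(window, dilated, out=window)
                return cy, cx, cov
        raise PlacementError(
            f"could not place object after {self.retries} retries "
            f"(field too crowded)"
        )


# ---------------------------------------------------------------------------
# Scene population and rendering


@dataclass
class _RenderItem:
    channel: int  # 0 = nuclei, 1 = vwf
    cy: int
    cx: int
    half: int
    coverage: np.ndarray
    amplitude: float
    z_center_um: float
    z_sigma_um: float


def _populate_scene(spec: SceneSpec, rng: np.random.Generator):
    """Sample and place every object; returns (GroundTruth, render items)."""
    height, width = spec.field_height_px, spec.field_width_px
    px = spec.pixel_size_um
    margin_px = max(1, int(round(spec.min_separation_um / px)))
    depth_um = spec.n_slices * spec.z_step_um

    nuc_placer = _Placer(
        height, width, margin_px, spec.allowed_overlap_fraction, spec.max_place_retries
    )
    vwf_placer = _Placer(
        height, width, margin_px, spec.allowed_overlap_fraction, spec.max_place_retries
    )

    items: list[_RenderItem] = []
    nuclei: list[NucleusTruth] = []
    wpbs: list[WpbTruth] = []
    immature: list[ImmatureTruth] = []

    for i in range(spec.nucleus_count):
        a_um, b_um = sorted(rng.uniform(*spec.nucleus_radius_um, size=2), reverse=True)
        theta = float(rng.uniform(0, math.pi))
        a, b = a_um / px, b_um / px
        half = int(math.ceil(max(a, b) + 1.5))
        try:
            cy, cx, cov = nuc_placer.place(
                rng, lambda h: _ellipse_coverage(a, b, theta, h), half
            )
        except PlacementError as exc:
            raise PlacementError(f"nucleus {i + 1}/{spec.nucleus_count}: {exc}") from exc
        zc = float(rng.uniform(0.30, 0.70) * depth_um)
        nuclei.append(NucleusTruth((float(cy), float(cx)), (a, b), theta))
        items.append(
            _RenderItem(0, cy, cx, half, cov, spec.nucleus_intensity, zc, spec.nucleus_z_sigma_um)
        )

    for i in range(spec.wpb_count):
        length_um = float(rng.uniform(*spec.wpb_length_um))
        width_um = float(rng.uniform(*spec.wpb_width_um))
        width_um = min(width_um, length_um)  # a rod is at least as long as wide
        theta = float(rng.uniform(0, math.pi))
        length, rod_w = length_um / px, width_um / px
        half = int(math.ceil(length / 2.0 + 1.5))
        try:
            cy, cx, cov = vwf_placer.place(
                rng, lambda h: _capsule_coverage(length, rod_w, theta, h), half
            )
        except PlacementError as exc:
            raise PlacementError(f"WPB {i + 1}/{spec.wpb_count}: {exc}") from exc
        zc = float(rng.uniform(0.15, 0.85) * depth_um)
        wpbs.append(
            WpbTruth((float(cy), float(cx)), length, rod_w, theta, zc / spec.z_step_um)
        )
        items.append(
            _RenderItem(1, cy, cx, half, cov, spec.wpb_intensity, zc, spec.z_sigma_um)
        )

    for i in range(spec.immature_count):
        r_um = float(rng.uniform(*spec.immature_radius_um))
        r = r_um / px
        half = int(math.ceil(r + 1.5))
        try:
            cy, cx, cov = vwf_placer.place(rng, lambda h: _disc_coverage(r, h), half)
        except PlacementError as exc:
            raise PlacementError(
                f"immature vesicle {i + 1}/{spec.immature_count}: {exc}"
            ) from exc
        zc = float(rng.uniform(0.15, 0.85) * depth_um)
        immature.append(ImmatureTruth((float(cy), float(cx)), r, zc / spec.z_step_um))
        items.append(
            _RenderItem(1, cy, cx, half, cov, spec.immature_intensity, zc, spec.z_sigma_um)
        )

    truth = GroundTruth(tuple(nuclei), tuple(wpbs), tuple(immature))
    return truth, items


def _render_stacks(spec: SceneSpec, items, rng: np.random.Generator):
    """Accumulate objects into two stacks, blur laterally, add noise.

    Rendering is peak-calibrated: each object's intensity parameter is
    the brightness it reaches at its focal slice *after* the lateral
    PSF.  For sub-resolution structures (0.1-0.3 um rods under a
    ~0.11 um blur) an un-calibrated rendering would make peak brightness
    scale with physical width, pushing the thinnest rods below any
    global histogram threshold — a width-dependent detectability the
    simulator deliberately removes so that "SNR >= 5" is a well-defined
    per-object condition (intensity / noise_sd).
    """
    height, width = spec.field_height_px, spec.field_width_px
    shape = (spec.n_slices, height, width)
    stacks = [np.zeros(shape, dtype=np.float64), np.zeros(shape, dtype=np.float64)]
    z_um = np.arange(spec.n_slices) * spec.z_step_um
    sigma_px = spec.psf_sigma_um / spec.pixel_size_um
    for it in items:
        w = np.exp(-0.5 * ((z_um - it.z_center_um) / max(it.z_sigma_um, 1e-9)) ** 2)
        w /= w.max()  # the focal slice reaches full amplitude
        if sigma_px > 0:
            peak = ndimage.gaussian_filter(it.coverage, sigma_px).max()
        else:
            peak = it.coverage.max()
        patch = (it.amplitude / max(peak, 1e-12)) * it.coverage
        y0, y1 = it.cy - it.half, it.cy + it.half + 1
        x0, x1 = it.cx - it.half, it.cx + it.half + 1
        stacks[it.channel][:, y0:y1, x0:x1] += w[:, None, None] * patch[None, :, :]
    for ch in range(2):
        if sigma_px > 0:
            stacks[ch] = ndimage.gaussian_filter(stacks[ch], sigma=(0, sigma_px, sigma_px))
        stacks[ch] += spec.background_level
        if spec.noise_sd > 0:
            stacks[ch] += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(stacks[ch], 0.0, None, out=stacks[ch])
    return stacks[0].astype(np.float32), stacks[1].astype(np.float32)


def render_field(
    spec: SceneSpec,
    field_id: str = "field0",
    slide_id: str = "slide0",
    condition_id: str = "",
) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel z-stack with its exact object inventory.

    Deterministic for a fixed ``spec.seed``: the same spec renders
    bit-identical stacks.  Raises :class:`PlacementError` when the
    requested object density cannot be placed within the overlap budget.
    """
    rng = np.random.default_rng(spec.seed)
    truth, items = _populate_scene(spec, rng)
    nuc, vwf = _render_stacks(spec, items, rng)
    image = FieldImage(
        nuclei_channel=nuc,
        vwf_channel=vwf,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
        field_id=field_id,
        slide_id=slide_id,
        condition_id=condition_id,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Growth simulation


def simulate_growth_counts(
    seed_density: float,
    doubling_time_hr: float,
    times_hr,
    noise: Literal["none", "poisson"] = "none",
    seed: int = 0,
    scale: float = 1.0,
    cell_type: str = "",
) -> GrowthSeries:
    """Exponential growth counts: N(t) = N0 * 2^((t - t0) / DT).

    ``t0`` is the first time point and ``N0 = seed_density * scale``
    (``scale`` converts a per-cm^2 density into e.g. cells per imaged
    area).  ``noise="none"`` returns the expectations exactly;
    ``"poisson"`` draws one Poisson count per time point from them.
    """
    times = [float(t) for t in times_hr]
    if not times:
        raise ValueError("times_hr must be non-empty")
    if sorted(times) != times:
        raise ValueError("times_hr must be sorted ascending")
    if doubling_time_hr <= 0:
        raise ValueError("doubling_time_hr must be positive")
    t0 = times[0]
    n0 = seed_density * scale
    expected = [n0 * 2.0 ** ((t - t0) / doubling_time_hr) for t in times]
    if noise == "none":
        counts = expected
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = [float(rng.poisson(e)) for e in expected]
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return GrowthSeries(times_hr=tuple(times), counts=tuple(counts), cell_type=cell_type)


# ---------------------------------------------------------------------------
# Whole-experiment simulation


@dataclass(frozen=True)
class WpbPerCellCurve:
    """Monotone WPB yield per cell as a function of local density.

    A logistic in cells-per-field with a floor (sparse cultures) and a
    ceiling (confluent cultures); the midpoint defaults to the
    confluency cutoff of the simulated geometry, placing the steepest
    rise where the monolayer closes.  ``floor == ceiling`` gives a
    constant yield.
    """

    floor: float = 6.0
    ceiling: float = 14.0
    midpoint_cells_per_field: float | None = None
    steepness_per_cell: float | None = None

    def __post_init__(self):
        if self.floor < 0 or self.ceiling < self.floor:
            raise ValueError("need 0 <= floor <= ceiling")

    def __call__(self, cells_per_field: float, default_midpoint: float) -> float:
        if self.ceiling == self.floor:
            return self.floor
        mid = (
            self.midpoint_cells_per_field
            if self.midpoint_cells_per_field is not None
            else default_midpoint
        )
        k = (
            self.steepness_per_cell
            if self.steepness_per_cell is not None
            else 4.0 / max(mid, 1e-9)
        )
        z = -k * (cells_per_field - mid)
        return self.floor + (self.ceiling - self.floor) / (1.0 + math.exp(z))


_DEFAULT_DT = {"HUVEC": 33.0, "ECFC": 26.0}

#: Reduced-raster scene used when simulating whole experiments: a 512 px
#: square at 0.12 um/px (a 61 um field, 3.8e-5 cm^2) with 7 slices.  The
#: pixel pitch keeps the PSF properly sampled (sigma ~0.9 px) — coarser
#: grids alias the sub-resolution rods.  Confluency cutoffs are scaled
#: to this area, preserving coverage semantics while keeping hundreds of
#: rendered fields tractable.
EXPERIMENT_SCENE_DEFAULTS = dict(
    field_width_px=512,
    field_height_px=512,
    pixel_size_um=0.12,
    n_slices=7,
    z_step_um=0.3,
    nucleus_radius_um=(3.0, 5.0),
    background_level=10.0,
    noise_sd=10.0,
    psf_sigma_um=0.11,
    max_place_retries=300,
)


@dataclass(frozen=True)
class ExperimentDesign:
    """One culture-method experiment: conditions x slides x fields.

    ``constant_time`` holds incubation at 96 h while sweeping seeding
    density (5,000/10,000/30,000 cells/cm^2); ``constant_density`` holds
    density at 30,000 cells/cm^2 while sweeping 24/48/72/96 h.  Each
    condition is imaged as ``slides_per_condition`` slides x 9 fields,
    repeated over ``n_experiments`` independent experiments.
    """

    method: Literal["constant_time", "constant_density"]
    cell_type: Literal["HUVEC", "ECFC"] = "HUVEC"
    seeding_densities: tuple[float, ...] | None = None
    time_points_hr: tuple[float, ...] | None = None
    slides_per_condition: int = 5
    fields_per_slide: int = 9
    n_experiments: int = 3
    growth_doubling_time_hr: float | None = None
    wpb_curve: WpbPerCellCurve = field(default_factory=WpbPerCellCurve)
    immature_per_cell: float = 2.0
    scene_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method == "constant_time":
            densities = self.seeding_densities or (5000.0, 10000.0, 30000.0)
            times = (96.0,)
            if self.time_points_hr not in (None, (96.0,)):
                raise ValueError("constant_time designs fix time_points_hr = (96,)")
        elif self.method == "constant_density":
            densities = (30000.0,)
            times = self.time_points_hr or (24.0, 48.0, 72.0, 96.0)
            if self.seeding_densities not in (None, (30000.0,)):
                raise ValueError(
                    "constant_density designs fix seeding_densities = (30000,)"
                )
        else:
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "seeding_densities", tuple(float(d) for d in densities))
        object.__setattr__(self, "time_points_hr", tuple(float(t) for t in times))
        if self.slides_per_condition < 5:
            raise ValueError("slides_per_condition must be >= 5")
        if self.fields_per_slide != 9:
            raise ValueError("fields_per_slide is fixed at 9")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        dt = self.growth_doubling_time_hr
        if dt is None:
            dt = _DEFAULT_DT[self.cell_type]
        if dt <= 0:
            raise ValueError("growth_doubling_time_hr must be positive")
        object.__setattr__(self, "growth_doubling_time_hr", float(dt))

    def scene_template(self) -> SceneSpec:
        params = dict(EXPERIMENT_SCENE_DEFAULTS)
        params.update(self.scene_overrides)
        return SceneSpec(**params)

    @property
    def field_area_cm2(self) -> float:
        return self.scene_template().field_area_cm2

    def confluency_cutoff(self) -> ConfluencyCutoff:
        return ConfluencyCutoff.for_cell_type(
            self.cell_type, field_area_um2=self.scene_template().field_area_um2
        )


@dataclass(frozen=True)
class SimulatedField:
    condition: dict
    slide_id: str
    field_index: int
    image: FieldImage | None
    truth: GroundTruth


def simulate_experiment(
    design: ExperimentDesign, render: bool = True
) -> list[SimulatedField]:
    """Simulate a whole experiment design field by field.

    Per condition, the expected local cell count follows the growth
    model scaled to the imaged field area; each field draws a Poisson
    cell count around it, and the WPB count is cells x yield with the
    yield read off the design's WPB-per-cell curve at the local density.
    With ``render=False`` only placement and ground truth are produced
    (``image`` is None), which is much faster for statistics that do not
    need pixels.
    """
    rng = np.random.default_rng(design.seed)
    template = design.scene_template()
    area_cm2 = template.field_area_cm2
    cutoff = design.confluency_cutoff().cells_per_field_cutoff
    dt = design.growth_doubling_time_hr
    out: list[SimulatedField] = []
    for exp in range(1, design.n_experiments + 1):
        for density in design.seeding_densities:
            for t in design.time_points_hr:
                expected = density * area_cm2 * 2.0 ** (t / dt)
                condition = {
                    "method": design.method,
                    "cell_type": design.cell_type,
                    "seeding_density": float(density),
                    "time_hr": float(t),
                    "experiment": exp,
                }
                cond_name = (
                    f"{design.cell_type}_{design.method}_d{int(density)}_t{int(t)}_e{exp}"
                )
                for s in range(1, design.slides_per_condition + 1):
                    slide_id = f"{cond_name}_s{s}"
                    for f_idx in range(design.fields_per_slide):
                        cells = int(rng.poisson(expected))
                        yield_per_cell = design.wpb_curve(cells, cutoff)
                        wpb = int(round(cells * yield_per_cell))
                        imm = int(round(cells * design.immature_per_cell))
                        spec = replace(
                            template,
                            nucleus_count=cells,
                            wpb_count=wpb,
                            immature_count=imm,
                            seed=int(rng.integers(2**31)),
                        )
                        field_id = f"{slide_id}_f{f_idx}"
                        try:
                            if render:
                                image, truth = render_field(
                                    spec,
                                    field_id=field_id,
                                    slide_id=slide_id,
                                    condition_id=cond_name,
                                )
                            else:
                                obj_rng = np.random.default_rng(spec.seed)
                                truth, _ = _populate_scene(spec, obj_rng)
                                image = None
                        except PlacementError as exc:
                            raise PlacementError(
                                f"condition {cond_name}, field {field_id}: {exc}"
                            ) from exc
                        out.append(
                            SimulatedField(
                                condition=condition,
                                slide_id=slide_id,
                                field_index=f_idx,
                                image=image,
                                truth=truth,
                            )
                        )
    return out
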