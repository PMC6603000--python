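"""Synthetic dual-channel 3D fields with known ground truth.

The generator emulates the spinning-disk acquisitions the pipeline was
designed for: 16-bit dual-camera fields, 0.2152 um pixels, 400 nm z-steps,
5 planes for the Rosella-LC3 reporter and 11 for ATP5C1-Rosella.  Objects
are rendered with the class-specific channel signatures of the Rosella
sensor -- phagophores bright in both channels, autophagosomes as hollow
rings bright in both, early autolysosomes red-bright with partial green
retention, late autolysosomes red-bright and green-quenched, mitochondria
as red tubules with matching green except for green-quenched mitophagy
events -- then passed through a per-channel PSF blur, a multiplicative
vignette, and Poisson + Gaussian read noise.  Ground truth references the
pre-optics geometry.

The intensity defaults are a fixed calibration: they place each class on
the correct side of the pipeline's graytone decision thresholds at realistic
signal-to-background (roughly 10:1 for bright organelles over cytoplasm),
see ``scripts/calibration.py`` for the per-threshold margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve

from .preprocessing import PsfModel, generate_psf

__all__ = ["SceneSpec", "GroundTruth", "render_scene", "render_suite", "SUITE_CONFIGS"]

AUTOPHAGY_CLASSES = ("phagophore", "autophagosome", "early_autolysosome", "late_autolysosome")
MITO_CLASSES = ("mitochondria", "mitophagy_event")


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic field.

    Intensities are additive contrasts over the channel background on the
    16-bit graytone scale; a negative green contrast renders quenching
    (darker than cytoplasm).  Lateral sizes are in pixels; objects are
    physically isotropic, so axial extents are scaled by pitch / z-step.
    """

    shape: tuple = (5, 256, 256)
    pixel_pitch: float = 0.2152
    z_step: float = 0.4
    seed: int = 0

    # class counts
    n_phagophore: int = 0
    n_autophagosome: int = 0
    n_early_autolysosome: int = 0
    n_late_autolysosome: int = 0
    n_mitochondria: int = 0
    n_mitophagy_event: int = 0

    # size ranges (lateral radius px; autophagosome: outer radius + rim)
    phagophore_radius: tuple = (2.0, 3.2)
    autophagosome_radius: tuple = (6.0, 8.5)
    autophagosome_rim: float = 2.8
    early_radius: tuple = (7.0, 8.0)
    late_radius: tuple = (3.0, 5.5)
    event_radius: tuple = (2.5, 4.0)
    tubule_radius: float = 1.4
    tubule_steps: tuple = (18, 34)
    tubule_tortuosity: float = 0.45

    # intensity model: (green contrast, red contrast) per class
    background: tuple = (1200.0, 150.0)
    phagophore_intensity: tuple = (9000.0, 3000.0)
    autophagosome_intensity: tuple = (1300.0, 2500.0)
    early_intensity: tuple = (1100.0, 900.0)
    # residual non-acidified cargo patch inside early autolysosomes:
    # (extra green contrast, patch radius as a fraction of the vesicle
    # radius, patch centre offset as a fraction of the vesicle radius)
    early_patch: tuple = (1700.0, 0.40, 0.22)
    late_intensity: tuple = (-600.0, 4000.0)
    mitochondria_intensity: tuple = (1600.0, 2000.0)
    event_intensity: tuple = (-500.0, 3500.0)

    # optics + noise
    psf_blur: bool = True
    wavelength_green_nm: float = 520.0
    wavelength_red_nm: float = 600.0
    vignette_amplitude: float = 0.15
    poisson_noise: bool = True
    poisson_photons_per_graytone: float = 4.0
    read_noise_sd: float = 5.0

    # placement
    border_margin: float = 6.0
    min_separation: float = 5.0
    max_placement_tries: int = 200


@dataclass
class GroundTruth:
    """Pre-optics object geometry: per-class label volumes + object table."""

    labels: dict = field(default_factory=dict)
    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    vignette: np.ndarray | None = None

    def count(self, cls: str) -> int:
        if self.objects.empty:
            return 0
        return int((self.objects["object_class"] == cls).sum())

    def volume(self, cls: str) -> int:
        if cls not in self.labels:
            return 0
        return int(np.count_nonzero(self.labels[cls]))


@dataclass
class FieldStack:
    """One imaged field: channel volumes plus acquisition geometry."""

    green: np.ndarray
    red: np.ndarray | None = None
    pixel_pitch: float = 0.2152
    z_step: float = 0.4
    field_id: str = ""


def _z_scale(spec: SceneSpec) -> float:
    return spec.z_step / spec.pixel_pitch


def _ellipsoid_mask(shape, center, radius_px, z_scale) -> np.ndarray:
    """Boolean mask of a physically spherical object on the voxel grid."""
    nz, ny, nx = shape
    zz = (np.arange(nz) - center[0]) * z_scale
    yy = np.arange(ny) - center[1]
    xx = np.arange(nx) - center[2]
    d2 = (
        zz[:, None, None] ** 2
        + yy[None, :, None] ** 2
        + xx[None, None, :] ** 2
    )
    return d2 <= radius_px**2


def _annulus_mask(shape, center, outer_px, rim_px, z_scale) -> np.ndarray:
    """Hollow ring replicated over the z-range the vesicle equator spans.

    Large hollow vesicles cut by a thin confocal slab image as rings in
    every plane; the simulator renders exactly that (no polar caps).
    """
    nz, ny, nx = shape
    yy = np.arange(ny) - center[1]
    xx = np.arange(nx) - center[2]
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2
    ring = (r2 <= outer_px**2) & (r2 >= (outer_px - rim_px) ** 2)
    half_z = max(outer_px / z_scale * 0.6, 1.0)
    out = np.zeros(shape, dtype=bool)
    for z in range(nz):
        if abs(z - center[0]) <= half_z:
            out[z] = ring
    return out


def _tubule_mask(shape, rng, spec: SceneSpec) -> tuple[np.ndarray, tuple]:
    """Random-walk tubule: a chain of small spheres along a tortuous path."""
    nz, ny, nx = shape
    m = spec.border_margin
    start = np.array(
        [
            rng.uniform(1.0, nz - 2.0),
            rng.uniform(m, ny - m),
            rng.uniform(m, nx - m),
        ]
    )
    heading = rng.uniform(0, 2 * np.pi)
    steps = rng.integers(spec.tubule_steps[0], spec.tubule_steps[1] + 1)
    out = np.zeros(shape, dtype=bool)
    z_scale = _z_scale(spec)
    pos = start.copy()
    points = [pos.copy()]
    for _ in range(steps):
        heading += rng.normal(0.0, spec.tubule_tortuosity)
        pos = pos + np.array(
            [rng.normal(0.0, 0.15), 2.0 * np.sin(heading), 2.0 * np.cos(heading)]
        )
        pos[0] = np.clip(pos[0], 0.5, nz - 1.5)
        pos[1] = np.clip(pos[1], 2.0, ny - 3.0)
        pos[2] = np.clip(pos[2], 2.0, nx - 3.0)
        points.append(pos.copy())
    r = spec.tubule_radius
    for p in points:
        z0 = max(int(np.floor(p[0] - r / z_scale - 1)), 0)
        z1 = min(int(np.ceil(p[0] + r / z_scale + 1)) + 1, nz)
        y0 = max(int(np.floor(p[1] - r - 1)), 0)
        y1 = min(int(np.ceil(p[1] + r + 1)) + 1, ny)
        x0 = max(int(np.floor(p[2] - r - 1)), 0)
        x1 = min(int(np.ceil(p[2] + r + 1)) + 1, nx)
        zz = (np.arange(z0, z1) - p[0]) * z_scale
        yy = np.arange(y0, y1) - p[1]
        xx = np.arange(x0, x1) - p[2]
        d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        out[z0:z1, y0:y1, x0:x1] |= d2 <= r**2
    return out, tuple(start)


def _place_centers(rng, spec: SceneSpec, requests: list) -> list:
    """Rejection-sample non-overlapping lateral positions for round objects.

    ``requests`` is a list of (class, radius) pairs; after
    ``max_placement_tries`` failures an object is allowed to touch.
    """
    nz, ny, nx = spec.shape
    placed = []  # (y, x, radius)
    out = []
    for cls, radius in requests:
        margin = radius + spec.border_margin
        accepted = None
        for _ in range(spec.max_placement_tries):
            y = rng.uniform(margin, ny - margin)
            x = rng.uniform(margin, nx - margin)
            ok = all(
                np.hypot(y - py, x - px) > radius + pr + spec.min_separation
                for py, px, pr in placed
            )
            if ok:
                accepted = (y, x)
                break
        if accepted is None:  # allow touching rather than dropping the object
            accepted = (rng.uniform(margin, ny - margin), rng.uniform(margin, nx - margin))
        z = nz / 2.0 - 0.5 + rng.uniform(-0.5, 0.5)
        placed.append((accepted[0], accepted[1], radius))
        out.append((cls, radius, (z, accepted[0], accepted[1])))
    return out


def render_scene(spec: SceneSpec) -> tuple[FieldStack, GroundTruth]:
    """Render one field; identical spec + seed gives bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    z_scale = _z_scale(spec)
    green = np.full(spec.shape, spec.background[0], dtype=np.float64)
    red = np.full(spec.shape, spec.background[1], dtype=np.float64)

    intensity = {
        "phagophore": spec.phagophore_intensity,
        "autophagosome": spec.autophagosome_intensity,
        "early_autolysosome": spec.early_intensity,
        "late_autolysosome": spec.late_intensity,
        "mitochondria": spec.mitochondria_intensity,
        "mitophagy_event": spec.event_intensity,
    }

    requests = []
    for cls, n, rng_range in (
        ("phagophore", spec.n_phagophore, spec.phagophore_radius),
        ("autophagosome", spec.n_autophagosome, spec.autophagosome_radius),
        ("early_autolysosome", spec.n_early_autolysosome, spec.early_radius),
        ("late_autolysosome", spec.n_late_autolysosome, spec.late_radius),
        ("mitophagy_event", spec.n_mitophagy_event, spec.event_radius),
    ):
        for _ in range(n):
            requests.append((cls, rng.uniform(*rng_range)))

    placements = _place_centers(rng, spec, requests)

    truth = GroundTruth()
    labels = {cls: np.zeros(spec.shape, dtype=np.int32) for cls in
              AUTOPHAGY_CLASSES + MITO_CLASSES}
    counters = {cls: 0 for cls in labels}
    rows = []

    for cls, radius, center in placements:
        if cls == "autophagosome":
            mask = _annulus_mask(spec.shape, center, radius, spec.autophagosome_rim, z_scale)
        else:
            mask = _ellipsoid_mask(spec.shape, center, radius, z_scale)
        g, r = intensity[cls]
        green[mask] += g
        red[mask] += r
        if cls == "early_autolysosome":
            # partial green retention: a residual non-acidified cargo patch
            patch_g, patch_frac, offset_frac = spec.early_patch
            angle = rng.uniform(0, 2 * np.pi)
            patch_center = (
                center[0],
                center[1] + offset_frac * radius * np.sin(angle),
                center[2] + offset_frac * radius * np.cos(angle),
            )
            patch = _ellipsoid_mask(
                spec.shape, patch_center, patch_frac * radius, z_scale
            ) & mask
            green[patch] += patch_g
        counters[cls] += 1
        labels[cls][mask] = counters[cls]
        rows.append(
            dict(object_class=cls, z=center[0], y=center[1], x=center[2],
                 radius_px=radius, volume_voxels=int(mask.sum()))
        )

    # mitochondrial tubules go last; they may cross one another (networks
    # do) but must stay clear of mitophagy-event bodies, which detach from
    # the network once engulfed -- a tubule brushing an event would fuse
    # the two into one connected component and dilute its ratio signature
    if labels["mitophagy_event"].any():
        keepout = ndi.binary_dilation(
            labels["mitophagy_event"] > 0,
            structure=np.ones((3, 17, 17), dtype=bool),
        )
    else:
        keepout = None
    for _ in range(spec.n_mitochondria):
        mask = None
        for _attempt in range(spec.max_placement_tries):
            candidate, start = _tubule_mask(spec.shape, rng, spec)
            if keepout is None or not (candidate & keepout).any():
                mask = candidate
                break
        if mask is None:  # keep the last draw, trimmed clear of the events
            mask = candidate & ~keepout
        g, r = intensity["mitochondria"]
        green[mask] += g
        red[mask] += r
        counters["mitochondria"] += 1
        labels["mitochondria"][mask] = counters["mitochondria"]
        rows.append(
            dict(object_class="mitochondria", z=start[0], y=start[1], x=start[2],
                 radius_px=spec.tubule_radius, volume_voxels=int(mask.sum()))
        )

    truth.labels = {cls: lab for cls, lab in labels.items() if lab.any()}
    truth.objects = pd.DataFrame(
        rows, columns=["object_class", "z", "y", "x", "radius_px", "volume_voxels"]
    )

    # ---- optics ----
    if spec.psf_blur:
        support = (min(nz, 5), 9, 9)
        for channel, wavelength in ((green, spec.wavelength_green_nm),
                                    (red, spec.wavelength_red_nm)):
            psf = generate_psf(
                PsfModel(
                    wavelength_em=wavelength,
                    pixel_pitch=spec.pixel_pitch,
                    z_step=spec.z_step,
                    support=support,
                )
            )
            channel[...] = fftconvolve(channel, psf, mode="same")

    yy, xx = np.mgrid[0:ny, 0:nx]
    rho2 = ((yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2) / ((ny / 2.0) ** 2 + (nx / 2.0) ** 2)
    vignette = 1.0 - spec.vignette_amplitude * rho2
    truth.vignette = vignette
    green *= vignette[None, :, :]
    red *= vignette[None, :, :]

    # ---- noise ----
    if spec.poisson_noise:
        k = spec.poisson_photons_per_graytone
        green = rng.poisson(np.maximum(green, 0.0) * k) / k
        red = rng.poisson(np.maximum(red, 0.0) * k) / k
    if spec.read_noise_sd > 0:
        green += rng.normal(0.0, spec.read_noise_sd, size=green.shape)
        red += rng.normal(0.0, spec.read_noise_sd, size=red.shape)

    green = np.clip(np.rint(green), 0, 65535).astype(np.uint16)
    red = np.clip(np.rint(red), 0, 65535).astype(np.uint16)

    stack = FieldStack(
        green=green, red=red, pixel_pitch=spec.pixel_pitch, z_step=spec.z_step,
        field_id=f"synthetic_{spec.seed:05d}",
    )
    return stack, truth


#: Named study conditions.  LC3 (5-plane) configs fix the class mixture;
#: ATP5C1 (11-plane) configs fix the mitochondrial load and event count.
SUITE_CONFIGS: dict[str, dict] = {
    "basal": dict(
        shape=(5, 256, 256),
        n_phagophore=9, n_autophagosome=4,
        n_early_autolysosome=4, n_late_autolysosome=14,
    ),
    "chloroquine-like": dict(
        shape=(5, 256, 256),
        n_phagophore=18, n_autophagosome=9,
        n_early_autolysosome=4, n_late_autolysosome=11,
    ),
    "cccp-lc3": dict(
        shape=(5, 256, 256),
        n_phagophore=7, n_autophagosome=3,
        n_early_autolysosome=3, n_late_autolysosome=11,
    ),
    # lysotracker assay: single-channel 11-plane stacks of bright solid
    # vesicles (rendered through the solid-vesicle class, green channel)
    "lysotracker": dict(
        shape=(11, 256, 256),
        n_phagophore=15,
        background=(300.0, 150.0),
        phagophore_intensity=(6000.0, 0.0),
        phagophore_radius=(2.5, 5.0),
    ),
    # ATP5C1-Rosella: the reporter sits on mitochondria, so the cytosol is
    # green-dark; engulfed (event) bodies are red-bright and fully quenched
    "basal-mito": dict(
        shape=(11, 256, 256),
        n_mitochondria=22, n_mitophagy_event=3,
        background=(200.0, 150.0),
        event_intensity=(-150.0, 6000.0),
        event_radius=(3.5, 4.5),
    ),
    "cccp-like": dict(
        shape=(11, 256, 256),
        n_mitochondria=22, n_mitophagy_event=8,
        background=(200.0, 150.0),
        event_intensity=(-150.0, 6000.0),
        event_radius=(3.5, 4.5),
    ),
}


def render_suite(
    config: str, n_fields: int = 10, base_seed: int = 0, **overrides
) -> list[tuple[FieldStack, GroundTruth]]:
    """Deterministic battery of fields for one named study condition.

    Seeds are derived as ``base_seed * 1000 + field index`` so batteries for
    paired conditions share placement statistics field by field.
    """
    if config not in SUITE_CONFIGS:
        raise ValueError(
            f"unknown config {config!r}; known: {sorted(SUITE_CONFIGS)}"
        )
    params = dict(SUITE_CONFIGS[config])
    params.update(overrides)
    fields = []
    for i in range(n_fields):
        spec = SceneSpec(seed=(base_seed * 1000 + i) % (2**31 - 1), **params)
        fields.append(render_scene(spec))
    return fields
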