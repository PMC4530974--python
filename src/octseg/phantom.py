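"""Synthetic layered-retina phantoms with exactly known geometry.

A phantom emulates a macular SD-OCT volume: nine piecewise-constant
reflectivity bands (vitreous, RNFL, GCL+IPL, INL, OPL, ONL, IS-OS band, RPE
band, choroid) separated by eight smooth surfaces, a foveal pit (a 2-D
Gaussian depression that affects the inner surfaces most and fades for the
outer ones), multiplicative gamma speckle, and vessel-shadow columns that
brighten a thin sub-ILM band and attenuate everything beneath it.

Band reflectivities are chosen so that every target boundary presents the
transition direction the detection schedule expects: dark-to-bright at the
ILM, INL-OPL, IS-OS and RPE-CH; bright-to-dark at the RNFL_o, IPL-INL,
OPL_o and OS-RPE.  (The RPE band is rendered darker than both the IS-OS
band above and the choroid below to realize the latter two directions.)

Rendering places the transition *through the centre* of the pixel at an
integer surface position (the boundary pixel is the 50/50 mix of the two
band reflectivities) and then applies a 1-px axial Gaussian blur, so the
directional edge response of a noiseless phantom peaks at exactly the true
surface row.  Volumes are fully determined by the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError
from .io_formats import BOUNDARY_ORDER, OCTVolume, SurfaceSet

#: vitreous, RNFL, GCL+IPL, INL, OPL, ONL, IS-OS band, RPE band, choroid
DEFAULT_REFLECTIVITIES = (0.05, 0.55, 0.40, 0.15, 0.40, 0.12, 0.80, 0.35, 0.60)

#: resting depth of each boundary (px), top to bottom, for a 496-row frame
DEFAULT_BASE_DEPTHS = (150.0, 165.0, 190.0, 210.0, 228.0, 260.0, 272.0, 285.0)

#: pit depression depth per boundary (px); outer boundaries are unaffected
DEFAULT_PIT_DEPTHS = (28.0, 24.0, 19.0, 12.0, 6.0, 0.0, 0.0, 0.0)


@dataclass
class VesselSpec:
    """One vessel: a column band shadowed through the whole volume."""

    column: int
    width: int = 6
    attenuation: float = 0.2
    brightening: float = 0.3


@dataclass
class PhantomSpec:
    """Full description of a synthetic volume.

    The default geometry mirrors a cropped macular Spectralis acquisition
    (496-row frames, 3.9 um axial and ~11.6 um lateral sampling, ~125 um
    frame spacing).  ``speckle_shape`` is the gamma shape parameter of the
    multiplicative noise (mean 1, sd 1/sqrt(shape)); 0 or None disables it.
    ``round_surfaces`` snaps the true surfaces to integer rows, which makes
    noiseless phantoms exactly recoverable.
    """

    n_frames: int = 10
    n_rows: int = 496
    n_cols: int = 644
    axial_res_um: float = 3.9
    lateral_res_um: float = 11.6
    frame_spacing_um: float = 125.0
    reflectivities: tuple = DEFAULT_REFLECTIVITIES
    base_depths: tuple = DEFAULT_BASE_DEPTHS
    lateral_amp_px: float = 4.0
    lateral_period_px: float = 200.0
    frame_amp_px: float = 3.0
    frame_period: float = 20.0
    pit_depths: tuple = DEFAULT_PIT_DEPTHS
    pit_sigma_cols: float = 12.0
    pit_sigma_frames: float | None = 2.5  # None: pit uniform across frames
    pit_center: tuple | None = None  # (frame, column); None = volume centre
    speckle_shape: float | None = 16.0
    vessels: int | list = 0
    round_surfaces: bool = False
    seed: int = 0
    name: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["vessels"] and not isinstance(d["vessels"], int):
            d["vessels"] = [asdict(v) if isinstance(v, VesselSpec) else v
                            for v in self.vessels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("reflectivities", "base_depths", "pit_depths"):
            if key in d:
                d[key] = tuple(d[key])
        if "pit_center" in d and d["pit_center"] is not None:
            d["pit_center"] = tuple(d["pit_center"])
        vessels = d.get("vessels", 0)
        if isinstance(vessels, list):
            d["vessels"] = [v if isinstance(v, VesselSpec) else VesselSpec(**v)
                            for v in vessels]
        return cls(**d)


def _true_surfaces(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Ground-truth surfaces (n_frames, n_cols) per boundary label.

    With ``round_surfaces`` each geometry component (lateral curvature,
    inter-frame curvature, per-boundary pit term) is quantized to integer
    pixels *separately* before summing.  Rounding the components rather than
    the summed surfaces keeps differences of surfaces — the coordinates in
    which the detectors actually see the geometry after flattening — free of
    single-column rounding notches, so a noiseless phantom is exactly
    recoverable.
    """
    n, x = np.meshgrid(np.arange(spec.n_frames), np.arange(spec.n_cols),
                       indexing="ij")
    q = np.round if spec.round_surfaces else (lambda a: a)
    curvature = (q(spec.lateral_amp_px * np.sin(2 * np.pi * x / spec.lateral_period_px))
                 + q(spec.frame_amp_px * np.sin(2 * np.pi * n / spec.frame_period)))
    if spec.pit_center is None:
        n0, x0 = (spec.n_frames - 1) / 2.0, (spec.n_cols - 1) / 2.0
    else:
        n0, x0 = spec.pit_center
    pit_shape = np.exp(-0.5 * ((x - x0) / spec.pit_sigma_cols) ** 2)
    if spec.pit_sigma_frames is not None:
        pit_shape = pit_shape * np.exp(
            -0.5 * ((n - n0) / spec.pit_sigma_frames) ** 2)
    surfaces = {}
    for lab, base, pit_depth in zip(BOUNDARY_ORDER, spec.base_depths,
                                    spec.pit_depths):
        surfaces[lab] = q(float(base)) + curvature + q(pit_depth * pit_shape)
    return surfaces


def _validate_surfaces(spec: PhantomSpec, surfaces: dict) -> None:
    zs = [surfaces[lab] for lab in BOUNDARY_ORDER]
    for (lab_u, zu), (lab_l, zl) in zip(zip(BOUNDARY_ORDER, zs),
                                        zip(BOUNDARY_ORDER[1:], zs[1:])):
        gap = zl - zu
        if gap.min() < 2.0:
            raise ConfigurationError(
                f"phantom spec violates the minimum 2 px layer thickness "
                f"between {lab_u} and {lab_l} (min gap {gap.min():.2f} px)")
    for lab, z in surfaces.items():
        if z.min() < 6 or z.max() > spec.n_rows - 7:
            raise ConfigurationError(
                f"phantom surface {lab} leaves the axial image bounds")
        if spec.n_frames > 1:
            step = np.abs(np.diff(z, axis=0)).max()
            if step > 10.0:
                raise ConfigurationError(
                    f"phantom surface {lab} moves {step:.1f} px between "
                    f"adjacent frames (limit 10 px)")


def _resolve_vessels(spec: PhantomSpec, rng: np.random.Generator,
                     x0: float) -> list[VesselSpec]:
    if isinstance(spec.vessels, list):
        return list(spec.vessels)
    count = int(spec.vessels)
    if count == 0:
        return []
    widths = [5, 6, 7, 6]
    # keep vessels off the image border and outside the foveal avascular zone
    candidates = [x for x in range(30, spec.n_cols - 30)
                  if abs(x - x0) > 4 * spec.pit_sigma_cols]
    columns: list[int] = []
    for x in rng.permutation(candidates):
        if all(abs(x - c) > 40 for c in columns):
            columns.append(int(x))
        if len(columns) == count:
            break
    if len(columns) < count:
        raise ConfigurationError("volume too narrow for the requested vessels")
    return [VesselSpec(column=c, width=widths[i % len(widths)])
            for i, c in enumerate(sorted(columns))]


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[OCTVolume, SurfaceSet, np.ndarray]:
    """Generate (volume, ground-truth surfaces, planted vessel mask)."""
    if len(spec.reflectivities) != 9 or len(spec.base_depths) != 8:
        raise ConfigurationError(
            "expected 9 band reflectivities and 8 boundary depths")
    surfaces = _true_surfaces(spec)
    _validate_surfaces(spec, surfaces)
    rng = np.random.default_rng(spec.seed)
    if spec.pit_center is None:
        x0 = (spec.n_cols - 1) / 2.0
    else:
        x0 = spec.pit_center[1]
    vessels = _resolve_vessels(spec, rng, x0)

    refl = np.asarray(spec.reflectivities, dtype=float)
    z_grid = np.arange(spec.n_rows, dtype=float)[:, None]
    frames = np.empty((spec.n_frames, spec.n_rows, spec.n_cols),
                      dtype=np.float32)
    vessel_mask = np.zeros((spec.n_frames, spec.n_cols), dtype=bool)

    ilm = surfaces["ILM"]
    rnflo = surfaces["RNFL_o"]
    for n in range(spec.n_frames):
        img = np.full((spec.n_rows, spec.n_cols), refl[0])
        for i, lab in enumerate(BOUNDARY_ORDER):
            s = surfaces[lab][n][None, :]
            img += (refl[i + 1] - refl[i]) * np.clip(z_grid + 0.5 - s, 0.0, 1.0)
        img = gaussian_filter1d(img, sigma=1.0, axis=0, mode="nearest")
        for v in vessels:
            half = v.width // 2
            lo = max(0, v.column - half)
            hi = min(spec.n_cols, v.column - half + v.width)
            cols = np.arange(lo, hi)
            vessel_mask[n, cols] = True
            # the vessel lumen occupies the nerve fiber layer: bright from
            # the ILM down to the outer RNFL boundary, shadowed below it;
            # blended with the same pixel-coverage convention as the bands
            for x in cols:
                col = img[:, x]
                u = np.clip(z_grid[:, 0] + 0.5 - ilm[n, x], 0.0, 1.0)
                w = np.clip(z_grid[:, 0] + 0.5 - rnflo[n, x], 0.0, 1.0)
                img[:, x] = (col * (1 - u) + (col + v.brightening) * (u - w)
                             + col * v.attenuation * w)
        if spec.speckle_shape:
            img = img * rng.gamma(spec.speckle_shape,
                                  1.0 / spec.speckle_shape, size=img.shape)
        frames[n] = np.clip(img, 0.0, 1.0)

    volume = OCTVolume(frames=frames, axial_res_um=spec.axial_res_um,
                       lateral_res_um=spec.lateral_res_um,
                       frame_spacing_um=spec.frame_spacing_um,
                       source_id=f"phantom:{spec.name or 'custom'}:seed={spec.seed}")
    truth = SurfaceSet(surfaces=surfaces, axial_res_um=spec.axial_res_um,
                       lateral_res_um=spec.lateral_res_um,
                       frame_spacing_um=spec.frame_spacing_um,
                       frame_height=spec.n_rows,
                       source_id=volume.source_id)
    truth.validate()
    return volume, truth, vessel_mask


def default_specs() -> dict[str, PhantomSpec]:
    """Named phantom fixtures.

    ``flat_noiseless`` and ``fovea_clean`` are noise-free with integer
    surfaces (exact recovery expected); ``fovea_speckle`` adds default
    speckle; ``vessels_speckle`` adds four shadowing vessels; and
    ``full_volume`` matches a whole cropped macular acquisition of
    496 x 644 x 51 voxels.
    """
    base = PhantomSpec()
    return {
        "flat_noiseless": replace(
            base, name="flat_noiseless", pit_depths=(0.0,) * 8,
            speckle_shape=None, round_surfaces=True),
        # exact-recovery geometry: integer components; a gentler pit whose
        # slope stays below 1 px/column, uniform across frames (a trough) so
        # inter-frame flattening leaves the ILM exactly flat; boundaries
        # selected through the depth-bias map (OPL_o) stay flat after
        # flattening because the bias weighting shifts near-tied responses
        # at surface steps by one row
        "fovea_clean": replace(
            base, name="fovea_clean", speckle_shape=None, round_surfaces=True,
            pit_depths=(28.0, 28.0, 12.0, 6.0, 0.0, 0.0, 0.0, 0.0),
            pit_sigma_cols=18.0, pit_sigma_frames=None),
        "fovea_speckle": replace(base, name="fovea_speckle"),
        "vessels_speckle": replace(base, name="vessels_speckle", vessels=4),
        "full_volume": replace(base, name="full_volume", n_frames=51,
                               vessels=4),
    }
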