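"""Volume segmentation schedule.

Eight boundaries are detected per frame with one shortest-path search each,
reusing what is already known:

* IS-OS — dark-to-bright.  First frame: whole-image search with the lower
  bias map suppressing the equally strong ILM above it.  Later frames:
  inter-frame flattening with the previous ILM and a +/-margin band around
  the previous IS-OS.
* ILM — dark-to-bright.  First frame: intra-frame flattening with the IS-OS
  and the region above it.  Later frames: inter-frame flattening with the
  previous ILM (which removes the foveal curvature) and the inter-frame band.
* OS-RPE / RPE-CH — intra-frame flattening with the IS-OS; a 40-px band
  below the flattened IS-OS row.  RPE-CH first (dark-to-bright, lower bias
  suppressing the IS-OS response at the band top), then the gradient below
  it is masked and OS-RPE found on the bright-to-dark map.
* IPL-INL / INL-OPL / OPL_o — intra-frame flattening with the IS-OS; the
  rectangle between the lowest ILM point and the flattened IS-OS row, with
  per-column normalization.  Lower bias selects OPL_o (bright-to-dark),
  masking below it yields IPL-INL, and INL-OPL (dark-to-bright) is masked to
  lie between the two.
* RNFL_o — bright-to-dark after flattening with the ILM, searched between
  the flattened ILM row and the highest IPL-INL point.  Columns shadowed by
  vessels (enface map below threshold) have their gradient forced to 1 so
  the path bridges them at minimal cost.

RNFL_o needs the vessel map, which needs the assembled ILM/IS-OS/RPE-CH
surfaces, so the volume is processed in two passes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import DetectionError, InputError
from .gradient_maps import compute_gradient, normalize_columns
from .graph_search import DEFAULT_W_MIN
from .io_formats import OCTVolume, SurfaceSet
from .region_ops import (
    Boundary,
    SearchRegion,
    apply_lower_bias,
    downsample_search_upsample,
    flatten,
    interframe_region,
    intraframe_region,
    mask_relative,
)

logger = logging.getLogger("octseg")

#: rows to keep clear of a reference edge when searching "above" it: the
#: edge kernel responds within its axial half-extent (5 px) of a transition,
#: plus a small allowance for axial blur
_KERNEL_GUARD = 8


@dataclass
class PipelineConfig:
    """Tunables of the segmentation schedule (defaults are the study values).

    ``interframe_margin`` is the assumed bound (px) on boundary motion
    between adjacent frames; ``rpe_band_height`` the RPE search band (px);
    ``enface_threshold`` flags vessel columns where the enface value falls
    below it; ``crop_extent_mm`` the macular region kept around the fovea;
    ``fovea_frame_range`` the 1-based inclusive frame range scanned for the
    foveal pit (clipped, or replaced by the whole volume when it lies
    entirely outside a short volume).
    """

    w_min: float = DEFAULT_W_MIN
    interframe_margin: int = 10
    rpe_band_height: int = 40
    downsample_factor: int = 2
    smooth_window: int = 5
    enface_threshold: float = -0.1
    crop_extent_mm: float = 6.0
    fovea_frame_range: tuple = (21, 40)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config fields: {sorted(unknown)}")
        if "fovea_frame_range" in d:
            d = {**d, "fovea_frame_range": tuple(d["fovea_frame_range"])}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EnfaceMap:
    """Depth-band projection E over (frame, column) and its vessel flags."""

    values: np.ndarray
    threshold: float
    vessel_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.vessel_mask is None:
            self.vessel_mask = self.values < self.threshold


def _search(g: np.ndarray, region: SearchRegion, cfg: PipelineConfig,
            transform=None, vessel_cols=None) -> np.ndarray:
    """Run one boundary search inside a region; returns frame-coordinate z."""
    roi = region.crop(g)
    if transform is not None:
        roi = transform(roi)
    if vessel_cols is not None:
        roi = roi.copy()
        roi[:, np.asarray(vessel_cols, dtype=bool)] = 1.0
    factor = cfg.downsample_factor if roi.shape[1] >= 2 * cfg.downsample_factor else 1
    z = downsample_search_upsample(roi, cfg.w_min, factor, cfg.smooth_window)
    return z + region.z_top


def detect_isos(frame: np.ndarray, cfg: PipelineConfig,
                prev_ilm: Boundary | None = None,
                prev_isos: Boundary | None = None,
                frame_index: int = 0) -> Boundary:
    """Detect the IS-OS junction, the brightest and flattest boundary."""
    h = frame.shape[0]
    if prev_isos is None:
        g = compute_gradient(frame, "dark_to_bright").values
        region = SearchRegion(0, h - 1)
        z = _search(g, region, cfg, transform=apply_lower_bias)
        return Boundary(z=z, label="IS-OS", frame_index=frame_index)
    # the flattening reference must run parallel to the target boundary: the
    # previous-frame IS-OS does, whereas an ILM reference would imprint an
    # inverted foveal pit onto the IS-OS and invite the path to cut across
    # it along the RPE-CH edge
    flat, rec = flatten(frame, prev_isos.z)
    g = compute_gradient(flat, "dark_to_bright").values
    region = interframe_region(rec.apply_to(prev_isos.z), h,
                               cfg.interframe_margin)
    z = _search(g, region, cfg)
    return Boundary(z=rec.invert(z), label="IS-OS", frame_index=frame_index)


def detect_ilm(frame: np.ndarray, isos: Boundary, cfg: PipelineConfig,
               prev_ilm: Boundary | None = None, frame_index: int = 0,
               interframe: bool = True) -> Boundary:
    """Detect the ILM.

    With a previous-frame ILM available (and ``interframe`` true) the frame
    is flattened against it, which removes the foveal curvature that makes
    the path cut across the pit; otherwise the frame is flattened against
    the same-frame IS-OS and the region above it is searched.
    """
    h = frame.shape[0]
    if prev_ilm is None or not interframe:
        flat, rec = flatten(frame, isos.z)
        g = compute_gradient(flat, "dark_to_bright").values
        # stay a kernel half-extent above the IS-OS so its own edge response
        # cannot attract the path
        region = SearchRegion(0, max(rec.target_row - 1 - _KERNEL_GUARD, 11))
        z = _search(g, region, cfg)
    else:
        flat, rec = flatten(frame, prev_ilm.z)
        g = compute_gradient(flat, "dark_to_bright").values
        region = interframe_region(rec.apply_to(prev_ilm.z), h,
                                   cfg.interframe_margin)
        z = _search(g, region, cfg)
    return Boundary(z=rec.invert(z), label="ILM", frame_index=frame_index)


def detect_rpe_pair(frame: np.ndarray, isos: Boundary, cfg: PipelineConfig,
                    frame_index: int = 0) -> tuple[Boundary, Boundary]:
    """Detect OS-RPE and RPE-CH inside the 40-px band below the IS-OS.

    RPE-CH is found first on the dark-to-bright map with the lower bias
    suppressing the IS-OS response at the band's top edge; the gradient
    below RPE-CH is then masked and OS-RPE is the only bright-to-dark edge
    left in the band.
    """
    h = frame.shape[0]
    flat, rec = flatten(frame, isos.z)
    region = intraframe_region(rec.target_row, None, "rect_below",
                               height=cfg.rpe_band_height, frame_height=h)
    g_d2b = compute_gradient(flat, "dark_to_bright").values
    g_b2d = compute_gradient(flat, "bright_to_dark").values

    z_rpech = _search(
        g_d2b, region, cfg,
        transform=lambda roi: normalize_columns(apply_lower_bias(roi)))
    rpech_local = z_rpech - region.z_top

    z_osrpe = _search(
        g_b2d, region, cfg,
        transform=lambda roi: normalize_columns(
            mask_relative(roi, rpech_local, "below")))
    if np.any(z_osrpe > z_rpech + 1e-6):
        raise DetectionError("OS-RPE detected below RPE-CH",
                             boundary="OS-RPE", frame=frame_index)
    os_rpe = Boundary(z=rec.invert(z_osrpe), label="OS-RPE",
                      frame_index=frame_index)
    rpe_ch = Boundary(z=rec.invert(z_rpech), label="RPE-CH",
                      frame_index=frame_index)
    return os_rpe, rpe_ch


def detect_inner_triplet(frame: np.ndarray, ilm: Boundary, isos: Boundary,
                         cfg: PipelineConfig, frame_index: int = 0
                         ) -> tuple[Boundary, Boundary, Boundary]:
    """Detect IPL-INL, INL-OPL and OPL_o between the ILM and the IS-OS."""
    flat, rec = flatten(frame, isos.z)
    ilm_flat = rec.apply_to(ilm.z)
    region = intraframe_region(ilm_flat, rec.target_row,
                               "rect_between_extremes")
    g_b2d = compute_gradient(flat, "bright_to_dark").values
    g_d2b = compute_gradient(flat, "dark_to_bright").values

    z_opl = _search(
        g_b2d, region, cfg,
        transform=lambda roi: normalize_columns(apply_lower_bias(roi)))
    opl_local = z_opl - region.z_top

    # mask from a kernel half-extent above the OPL_o so its edge response
    # (which peaks on, and bleeds above, the boundary row) cannot retain the
    # path; the IPL-INL is then the strongest bright-to-dark edge left
    opl_guard = np.maximum(opl_local - _KERNEL_GUARD, 0.0)
    z_ipl = _search(
        g_b2d, region, cfg,
        transform=lambda roi: normalize_columns(
            mask_relative(roi, opl_guard, "below")))
    ipl_local = z_ipl - region.z_top

    z_inl = _search(
        g_d2b, region, cfg,
        transform=lambda roi: normalize_columns(
            mask_relative(roi, opl_local, "outside_pair", upper=ipl_local)))

    ordering = [("ILM", rec.apply_to(ilm.z), "IPL-INL", z_ipl),
                ("IPL-INL", z_ipl, "INL-OPL", z_inl),
                ("INL-OPL", z_inl, "OPL_o", z_opl),
                ("OPL_o", z_opl, "IS-OS", rec.apply_to(isos.z))]
    for lab_u, zu, lab_l, zl in ordering:
        if np.any(zl < zu - 1e-6):
            raise DetectionError(f"{lab_l} detected above {lab_u}",
                                 boundary=lab_l, frame=frame_index)
    mk = lambda z, lab: Boundary(z=rec.invert(z), label=lab,
                                 frame_index=frame_index)
    return mk(z_ipl, "IPL-INL"), mk(z_inl, "INL-OPL"), mk(z_opl, "OPL_o")


def detect_rnflo(frame: np.ndarray, ilm: Boundary, ipl_inl: Boundary,
                 vessel_cols: np.ndarray, cfg: PipelineConfig,
                 frame_index: int = 0) -> Boundary:
    """Detect the outer RNFL boundary, bridging vessel-shadow columns."""
    vessel_cols = np.asarray(vessel_cols, dtype=bool)
    if vessel_cols.shape[0] != frame.shape[1]:
        raise InputError("vessel_cols length must equal the frame width")
    flat, rec = flatten(frame, ilm.z)
    # stop a kernel half-extent above the highest IPL-INL point so the IPL's
    # own (stronger) bright-to-dark response cannot attract the path
    ipl_flat = rec.apply_to(ipl_inl.z) - _KERNEL_GUARD
    region = intraframe_region(rec.target_row, ipl_flat,
                               "rect_between_extremes")
    g = compute_gradient(flat, "bright_to_dark").values
    z = _search(g, region, cfg, vessel_cols=vessel_cols)
    return Boundary(z=rec.invert(z), label="RNFL_o", frame_index=frame_index)


def _fovea_frame_indices(cfg: PipelineConfig, n_frames: int) -> range:
    lo, hi = cfg.fovea_frame_range
    lo, hi = lo - 1, hi - 1  # 1-based inclusive -> 0-based
    hi = min(hi, n_frames - 1)
    if lo > hi:
        return range(n_frames)
    return range(lo, hi + 1)


def detect_fovea(vol: OCTVolume, cfg: PipelineConfig) -> tuple[int, int]:
    """Locate the foveal pit: the (frame, column) minimizing RPE-CH - ILM.

    Runs the single-frame (intra-frame) ILM and RPE-CH detectors on each
    frame of the configured range; ties resolve to the smaller frame, then
    the smaller column.
    """
    best = (np.inf, -1, -1)
    for n in _fovea_frame_indices(cfg, vol.n_frames):
        frame = np.asarray(vol.frames[n], dtype=float)
        isos = detect_isos(frame, cfg, frame_index=n)
        ilm = detect_ilm(frame, isos, cfg, frame_index=n)
        _, rpe_ch = detect_rpe_pair(frame, isos, cfg, frame_index=n)
        thickness = rpe_ch.z - ilm.z
        x = int(np.argmin(thickness))
        if thickness[x] < best[0]:
            best = (float(thickness[x]), n, x)
    if best[1] < 0:
        raise DetectionError("fovea localization failed: no frames examined")
    return best[1], best[2]


def crop_macula(vol: OCTVolume, fovea: tuple[int, int], cfg: PipelineConfig
                ) -> tuple[OCTVolume, int, int]:
    """Crop to the configured lateral x azimuthal extent around the fovea.

    Returns the cropped volume plus (frame_offset, column_offset); the crop
    clips one-sidedly at volume borders and degenerates to the identity when
    the requested extent exceeds the scan.
    """
    n_star, x_star = fovea
    half_um = cfg.crop_extent_mm * 1000.0 / 2.0
    half_cols = int(half_um / vol.lateral_res_um)
    half_frames = int(half_um / vol.frame_spacing_um)
    c0 = max(0, x_star - half_cols)
    c1 = min(vol.n_cols, x_star + half_cols + 1)
    f0 = max(0, n_star - half_frames)
    f1 = min(vol.n_frames, n_star + half_frames + 1)
    cropped = OCTVolume(frames=vol.frames[f0:f1, :, c0:c1],
                        axial_res_um=vol.axial_res_um,
                        lateral_res_um=vol.lateral_res_um,
                        frame_spacing_um=vol.frame_spacing_um,
                        source_id=vol.source_id)
    return cropped, f0, c0


def compute_enface(vol: OCTVolume, ilm_surf: np.ndarray,
                   isos_surf: np.ndarray, rpech_surf: np.ndarray,
                   threshold: float = -0.1) -> EnfaceMap:
    """Enface projection: mean RPE-band intensity minus mean sub-ILM intensity.

    For each A-scan, E = mean(I[z6..z8]) - mean of the 30 pixels starting at
    z1, where z1/z6/z8 are the ILM, IS-OS and RPE-CH positions.  A shadowing
    vessel attenuates the first term and brightens the second, driving E
    negative; columns with E below ``threshold`` are flagged.  Bands are
    clipped to the frame with renormalized denominators.
    """
    h = vol.n_rows
    z1 = np.clip(np.round(ilm_surf).astype(int), 0, h - 1)
    z6 = np.clip(np.round(isos_surf).astype(int), 0, h - 1)
    z8 = np.clip(np.round(rpech_surf).astype(int), 0, h - 1)
    if np.any(z8 < z6):
        raise InputError("RPE-CH lies above IS-OS in the enface bands")
    e = np.empty((vol.n_frames, vol.n_cols), dtype=float)
    cols = np.arange(vol.n_cols)
    for n in range(vol.n_frames):
        cs = np.cumsum(np.asarray(vol.frames[n], dtype=float), axis=0)

        def band_mean(lo, hi):
            hi = np.minimum(hi, h - 1)
            top = np.where(lo > 0, cs[np.maximum(lo - 1, 0), cols], 0.0)
            return (cs[hi, cols] - top) / (hi - lo + 1)

        e[n] = band_mean(z6[n], z8[n]) - band_mean(z1[n], z1[n] + 29)
    return EnfaceMap(values=e, threshold=threshold)


def segment_volume(vol: OCTVolume, cfg: PipelineConfig | None = None
                   ) -> tuple[SurfaceSet, EnfaceMap]:
    """Segment all eight boundaries of a macular OCT volume.

    Localizes the fovea, crops the macular region, runs the frame-sequential
    first pass (IS-OS, ILM, RPE pair, inner triplet, with the first frame
    bootstrapped intra-frame), derives the vessel map from the enface
    projection, and finishes with the RNFL_o pass.  Deterministic given
    (volume, config); ordering violations raise :class:`DetectionError`.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    fovea = detect_fovea(vol, cfg)
    logger.info("fovea at frame %d, column %d (%.2f s)", fovea[0], fovea[1],
                time.perf_counter() - t0)
    cvol, f_off, c_off = crop_macula(vol, fovea, cfg)

    labels = ("ILM", "IPL-INL", "INL-OPL", "OPL_o", "IS-OS", "OS-RPE", "RPE-CH")
    grids = {lab: np.empty((cvol.n_frames, cvol.n_cols)) for lab in labels}
    prev_ilm = prev_isos = None
    for n in range(cvol.n_frames):
        t_frame = time.perf_counter()
        frame = np.asarray(cvol.frames[n], dtype=float)
        isos = detect_isos(frame, cfg, prev_ilm, prev_isos, frame_index=n)
        ilm = detect_ilm(frame, isos, cfg, prev_ilm, frame_index=n)
        os_rpe, rpe_ch = detect_rpe_pair(frame, isos, cfg, frame_index=n)
        ipl, inl, opl = detect_inner_triplet(frame, ilm, isos, cfg,
                                             frame_index=n)
        for lab, b in zip(labels, (ilm, ipl, inl, opl, isos, os_rpe, rpe_ch)):
            grids[lab][n] = b.z
        prev_ilm, prev_isos = ilm, isos
        logger.debug("frame %d first pass: %.3f s", n,
                     time.perf_counter() - t_frame)

    enface = compute_enface(cvol, grids["ILM"], grids["IS-OS"],
                            grids["RPE-CH"], cfg.enface_threshold)

    rnflo = np.empty((cvol.n_frames, cvol.n_cols))
    for n in range(cvol.n_frames):
        frame = np.asarray(cvol.frames[n], dtype=float)
        b = detect_rnflo(frame,
                         Boundary(grids["ILM"][n], "ILM", n),
                         Boundary(grids["IPL-INL"][n], "IPL-INL", n),
                         enface.vessel_mask[n], cfg, frame_index=n)
        rnflo[n] = b.z
    grids["RNFL_o"] = rnflo

    sset = SurfaceSet(surfaces=grids, axial_res_um=cvol.axial_res_um,
                      lateral_res_um=cvol.lateral_res_um,
                      frame_spacing_um=cvol.frame_spacing_um,
                      column_offset=c_off, frame_offset=f_off,
                      frame_height=cvol.n_rows, source_id=vol.source_id,
                      meta={"fovea_frame": fovea[0], "fovea_column": fovea[1]})
    try:
        sset.validate()
    except InputError as exc:
        raise DetectionError(f"assembled surfaces are inconsistent: {exc}") from exc
    logger.info("segmented %d frames in %.2f s", cvol.n_frames,
                time.perf_counter() - t0)
    return sset, enface
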