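"""Reading OCT volumes and reading/writing segmentation results.

An OCT volume is ingested as a directory of grayscale B-scan images (JPEG,
PNG or TIFF) plus a metadata sidecar giving the physical voxel geometry.
Two sidecar dialects are supported:

* a plain JSON file (the reference format) with keys ``axial_res_um``,
  ``lateral_res_um`` and ``frame_spacing_um``;
* a minimal XML dialect covering vendor exports: either the same micron
  tags, or Spectralis-style ``ScaleZ`` / ``ScaleX`` / ``Distance`` elements
  or attributes interpreted in millimetres.

Segmented surfaces are written as a long-format CSV
(``boundary,frame,column,z_pixels,z_um``) preceded by a single ``#``-prefixed
JSON header line that records grid offsets and resolutions, so a file is
self-describing and round-trips exactly.

Coordinate convention used throughout the package: 0-based indices, ``z``
increases downward (towards the choroid), ``x`` increases left to right and
``n`` is the frame index.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .errors import ConfigurationError, FormatError, InputError

#: Anatomical top-to-bottom order of the eight target boundaries.
BOUNDARY_ORDER = (
    "ILM", "RNFL_o", "IPL-INL", "INL-OPL", "OPL_o", "IS-OS", "OS-RPE", "RPE-CH",
)

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


@dataclass
class OCTVolume:
    """An ordered stack of B-scans with physical voxel geometry.

    ``frames`` has shape ``(n_frames, n_rows, n_cols)`` with intensities in
    [0, 1]; ``axial_res_um`` is microns per pixel along z, ``lateral_res_um``
    along x and ``frame_spacing_um`` between adjacent B-scans.
    """

    frames: np.ndarray
    axial_res_um: float
    lateral_res_um: float
    frame_spacing_um: float
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError("frames must be a (n_frames, rows, cols) array")
        if not (self.axial_res_um > 0 and self.lateral_res_um > 0
                and self.frame_spacing_um > 0):
            raise ConfigurationError("all resolutions must be strictly positive")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise InputError(f"intensities must lie in [0, 1]; got [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rows(self) -> int:
        return self.frames.shape[1]

    @property
    def n_cols(self) -> int:
        return self.frames.shape[2]


@dataclass
class SurfaceSet:
    """Eight boundary surfaces over the (frame, column) grid.

    ``surfaces`` maps boundary label to an ``(n_frames, n_cols)`` array of
    axial positions in pixels (fractional allowed).  ``frame_offset`` and
    ``column_offset`` record any cropping relative to the source volume so
    two sets over different crops of the same volume can be aligned.
    """

    surfaces: dict[str, np.ndarray]
    axial_res_um: float
    lateral_res_um: float
    frame_spacing_um: float
    column_offset: int = 0
    frame_offset: int = 0
    frame_height: int | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {k: np.asarray(v).shape for k, v in self.surfaces.items()}
        if len(set(shapes.values())) > 1:
            raise InputError(f"surface grids have inconsistent shapes: {shapes}")
        self.surfaces = {k: np.asarray(v, dtype=float) for k, v in self.surfaces.items()}

    @property
    def labels(self) -> list[str]:
        order = {lab: i for i, lab in enumerate(BOUNDARY_ORDER)}
        return sorted(self.surfaces, key=lambda k: order.get(k, len(order)))

    @property
    def n_frames(self) -> int:
        return next(iter(self.surfaces.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.surfaces.values())).shape[1]

    def validate(self) -> None:
        """Check top-to-bottom ordering and axial bounds; raise on violation."""
        present = [lab for lab in BOUNDARY_ORDER if lab in self.surfaces]
        for upper, lower in zip(present[:-1], present[1:]):
            gap = self.surfaces[lower] - self.surfaces[upper]
            if gap.min() < -1e-6:
                n, m = np.unravel_index(np.argmin(gap), gap.shape)
                raise InputError(
                    f"surface ordering violated: {upper} below {lower} at "
                    f"frame {n}, column {m} by {-gap[n, m]:.3f} px")
        for lab, z in self.surfaces.items():
            if z.min() < 0:
                raise InputError(f"{lab} has negative axial positions")
            if self.frame_height is not None and z.max() > self.frame_height - 1:
                raise InputError(f"{lab} exceeds the axial image bounds")


def _numeric_key(path: Path) -> tuple:
    """Sort key: trailing numeric component of the stem, then the full name."""
    runs = re.findall(r"\d+", path.stem)
    return (int(runs[-1]) if runs else -1, path.name)


def _to_unit_interval(img: Image.Image) -> np.ndarray:
    """Convert a PIL image to a float [0,1] grayscale array, bit-depth aware."""
    if img.mode in ("RGB", "RGBA", "P", "CMYK"):
        img = img.convert("L")
    arr = np.asarray(img)
    if arr.ndim == 3:  # grayscale stored with channels
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - min(info.min, 0)) / info.max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _parse_xml_metadata(path: Path) -> dict:
    tree = etree.parse(str(path))
    found: dict[str, float] = {}

    def note(name: str, value: str):
        name = name.lower()
        try:
            v = float(value)
        except (TypeError, ValueError):
            return
        if name in ("axial_res_um", "lateral_res_um", "frame_spacing_um"):
            found.setdefault(name, v)
        elif name == "scalez":
            found.setdefault("axial_res_um", v * 1000.0)
        elif name == "scalex":
            found.setdefault("lateral_res_um", v * 1000.0)
        elif name == "distance":
            found.setdefault("frame_spacing_um", v * 1000.0)

    for el in tree.iter():
        tag = etree.QName(el).localname if isinstance(el.tag, str) else ""
        if el.text is not None:
            note(tag, el.text.strip())
        for k, v in el.attrib.items():
            note(k, v)
    return found


def _read_metadata(metadata_path: Path) -> dict:
    if metadata_path.suffix.lower() == ".json":
        with open(metadata_path) as fh:
            return json.load(fh)
    if metadata_path.suffix.lower() == ".xml":
        return _parse_xml_metadata(metadata_path)
    raise FormatError(f"unsupported metadata sidecar: {metadata_path.name}")


def load_volume(path, metadata_path=None, *, axial_res_um=None,
                lateral_res_um=None, frame_spacing_um=None) -> OCTVolume:
    """Load an OCT volume from a directory of B-scan images.

    Frames are sorted by the numeric component of their filenames (ties
    broken lexicographically) and rescaled to [0, 1] according to bit depth.
    Resolutions come from ``metadata_path`` (or a sidecar discovered in the
    directory) and may be overridden / supplied by the keyword defaults.
    """
    path = Path(path)
    if not path.is_dir():
        raise InputError(f"not a directory: {path}")
    files = sorted((p for p in path.iterdir()
                    if p.suffix.lower() in _IMAGE_SUFFIXES), key=_numeric_key)
    if not files:
        raise InputError(f"no B-scan images found in {path}")

    meta: dict = {}
    if metadata_path is None:
        for candidate in sorted(path.glob("*.json")) + sorted(path.glob("*.xml")):
            meta = _read_metadata(candidate)
            if meta:
                break
    else:
        meta = _read_metadata(Path(metadata_path))

    res = {
        "axial_res_um": axial_res_um if axial_res_um is not None else meta.get("axial_res_um"),
        "lateral_res_um": lateral_res_um if lateral_res_um is not None else meta.get("lateral_res_um"),
        "frame_spacing_um": frame_spacing_um if frame_spacing_um is not None else meta.get("frame_spacing_um"),
    }
    missing = [k for k, v in res.items() if v is None]
    if missing:
        raise ConfigurationError(
            f"missing resolutions {missing}: supply a metadata sidecar or defaults")

    frames = []
    shape = None
    for f in files:
        with Image.open(f) as img:
            arr = _to_unit_interval(img)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"inconsistent frame dimensions: {f.name} is {arr.shape}, "
                f"expected {shape}")
        frames.append(arr)

    return OCTVolume(frames=np.stack(frames), source_id=str(path), **res)


# ---------------------------------------------------------------------------
# surfaces CSV

_SURFACE_COLUMNS = ("boundary", "frame", "column", "z_pixels", "z_um")


def write_surfaces(s: SurfaceSet, path) -> None:
    """Write a surface set as long-format CSV with a JSON header line."""
    header = {
        "axial_res_um": s.axial_res_um,
        "lateral_res_um": s.lateral_res_um,
        "frame_spacing_um": s.frame_spacing_um,
        "column_offset": s.column_offset,
        "frame_offset": s.frame_offset,
        "frame_height": s.frame_height,
        "source_id": s.source_id,
    }
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        writer = csv.writer(fh)
        writer.writerow(_SURFACE_COLUMNS)
        for lab in s.labels:
            z = s.surfaces[lab]
            for n in range(z.shape[0]):
                for m in range(z.shape[1]):
                    zp = z[n, m]
                    writer.writerow(
                        [lab, n, m, f"{zp:.8f}", f"{zp * s.axial_res_um:.8f}"])


def read_surfaces(path) -> SurfaceSet:
    """Read a surfaces CSV written by :func:`write_surfaces`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path.name}:1: missing JSON header line")
        try:
            header = json.loads(first.lstrip("# "))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path.name}:1: bad JSON header: {exc}") from exc
        reader = csv.reader(fh)
        try:
            cols = next(reader)
        except StopIteration:
            raise FormatError(f"{path.name}:2: missing column header") from None
        if tuple(c.strip() for c in cols) != _SURFACE_COLUMNS:
            raise FormatError(f"{path.name}:2: unexpected columns {cols}")
        records: dict[str, dict[tuple[int, int], float]] = {}
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            try:
                lab, n, m, zp = row[0], int(row[1]), int(row[2]), float(row[3])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path.name}:{lineno}: malformed row {row}") from exc
            records.setdefault(lab, {})[(n, m)] = zp

    surfaces = {}
    for lab, cells in records.items():
        nmax = max(k[0] for k in cells) + 1
        mmax = max(k[1] for k in cells) + 1
        grid = np.full((nmax, mmax), np.nan)
        for (n, m), zp in cells.items():
            grid[n, m] = zp
        if np.isnan(grid).any():
            raise FormatError(f"{path.name}: boundary {lab} has missing cells")
        surfaces[lab] = grid

    return SurfaceSet(
        surfaces=surfaces,
        axial_res_um=header["axial_res_um"],
        lateral_res_um=header["lateral_res_um"],
        frame_spacing_um=header["frame_spacing_um"],
        column_offset=header.get("column_offset", 0),
        frame_offset=header.get("frame_offset", 0),
        frame_height=header.get("frame_height"),
        source_id=header.get("source_id", ""),
    )


def write_vessel_map(mask: np.ndarray, path, *, frame_offset: int = 0,
                     column_offset: int = 0) -> None:
    """Write a boolean (frame, column) vessel map as ``frame,column,flag`` CSV."""
    mask = np.asarray(mask, dtype=bool)
    header = {"frame_offset": frame_offset, "column_offset": column_offset,
              "n_frames": mask.shape[0], "n_cols": mask.shape[1]}
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        writer = csv.writer(fh)
        writer.writerow(["frame", "column", "flag"])
        for n in range(mask.shape[0]):
            for m in range(mask.shape[1]):
                writer.writerow([n, m, int(mask[n, m])])


def read_vessel_map(path) -> tuple[np.ndarray, dict]:
    """Read a vessel-map CSV; returns (boolean mask, header dict)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path.name}:1: missing JSON header line")
        header = json.loads(first.lstrip("# "))
        reader = csv.reader(fh)
        next(reader)  # column header
        mask = np.zeros((header["n_frames"], header["n_cols"]), dtype=bool)
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            try:
                mask[int(row[0]), int(row[1])] = bool(int(row[2]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path.name}:{lineno}: malformed row {row}") from exc
    return mask, header
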