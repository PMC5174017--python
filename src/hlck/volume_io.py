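"""Volume container and I/O: DICOM series, image stacks, raw arrays.

A volume is an (S, R, C) stack of same-sized grayscale slices. Internally
voxels live in a signed wide integer array so transform intermediates cannot
overflow; the declared ``bit_depth`` (8-16) fixes the value range and the
PSNR peak, not the in-memory width.

Slice ordering is deterministic per format: DICOM series are ordered by
InstanceNumber, image stacks lexicographically by filename, raw arrays in
native order. Slices are 0-indexed internally; user-facing reports number
them Slice-1 .. Slice-S.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Volume",
    "VolumeFormatError",
    "load_volume",
    "save_volume",
]

_RAW_MAGIC = b"HLCKRAW\x01"


class VolumeFormatError(ValueError):
    """Raised for malformed, mixed-geometry or unsupported volume inputs."""


@dataclass
class Volume:
    """An (S, R, C) integer voxel array with bit-depth metadata."""

    data: np.ndarray
    bit_depth: int
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError("voxel data must be integer-typed")
        if not (8 <= self.bit_depth <= 16):
            raise VolumeFormatError(f"bit_depth {self.bit_depth} outside 8..16")
        S, R, C = self.data.shape
        if S < 1 or R < 2 or C < 2:
            raise VolumeFormatError(f"degenerate shape {self.data.shape}")
        self.data = self.data.astype(np.int64)
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > (1 << self.bit_depth) - 1:
            raise VolumeFormatError(
                f"voxel range [{lo}, {hi}] exceeds bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def peak(self) -> int:
        return (1 << self.bit_depth) - 1

    def validate_for_codec(self, L: int | None = None) -> None:
        """Reject geometries the codec cannot address (pre-encode check)."""
        S, R, C = self.shape
        def _pow2(v: int) -> bool:
            return v >= 1 and not (v & (v - 1))
        if R != C or not _pow2(R) or not _pow2(S):
            raise VolumeFormatError(
                f"codec requires square power-of-two slices and a power-of-two"
                f" slice count, got {self.shape}"
            )
        if L is not None and (L < 1 or C % (1 << L) or C >> L < 2):
            raise VolumeFormatError(f"{L} decomposition levels do not fit {R}x{C}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return (self.bit_depth == other.bit_depth
                and self.shape == other.shape
                and bool(np.array_equal(self.data, other.data)))


# ---------------------------------------------------------------------------
# raw array container: 8-byte magic, shape, sample width, little-endian data
# ---------------------------------------------------------------------------

def _save_raw(vol: Volume, path: Path) -> None:
    itemsize = 1 if vol.bit_depth <= 8 else 2
    header = _RAW_MAGIC + struct.pack(
        "<IIIBB", *vol.shape, vol.bit_depth, itemsize
    )
    dtype = np.dtype(f"<u{itemsize}")
    path.write_bytes(header + vol.data.astype(dtype).tobytes())


def _load_raw(path: Path) -> Volume:
    blob = path.read_bytes()
    if blob[:8] != _RAW_MAGIC:
        raise VolumeFormatError(f"{path} is not an hlck raw-array file")
    S, R, C, bit_depth, itemsize = struct.unpack("<IIIBB", blob[8:22])
    expected = S * R * C * itemsize
    body = blob[22:]
    if len(body) != expected:
        raise VolumeFormatError(
            f"{path}: payload is {len(body)} bytes, header promises {expected}"
        )
    data = np.frombuffer(body, dtype=f"<u{itemsize}").reshape(S, R, C)
    return Volume(data=data.astype(np.int64), bit_depth=bit_depth,
                  source=str(path))


# ---------------------------------------------------------------------------
# lossless image stacks (PNG/TIFF)
# ---------------------------------------------------------------------------

_STACK_EXT = {".png", ".tif", ".tiff"}


def _save_stack(vol: Volume, path: Path) -> None:
    import imageio.v3 as iio

    if vol.bit_depth == 8:
        dtype = np.uint8
    elif vol.bit_depth == 16:
        dtype = np.uint16
    else:
        raise VolumeFormatError(
            f"image stacks hold 8- or 16-bit samples, not {vol.bit_depth}-bit;"
            " use the raw_array format"
        )
    path.mkdir(parents=True, exist_ok=True)
    digits = max(3, len(str(vol.shape[0])))
    for s in range(vol.shape[0]):
        iio.imwrite(path / f"slice_{s + 1:0{digits}d}.png",
                    vol.data[s].astype(dtype))


def _load_stack(path: Path) -> Volume:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in _STACK_EXT)
    if not files:
        raise VolumeFormatError(f"no image slices found in {path}")
    slices = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise VolumeFormatError(f"{f}: expected a grayscale slice")
        if not np.issubdtype(img.dtype, np.integer):
            raise VolumeFormatError(f"{f}: non-integer pixel data")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise VolumeFormatError(f"mixed slice dimensions in {path}: {shapes}")
    stack = np.stack(slices)
    bit_depth = 8 * stack.dtype.itemsize
    return Volume(data=stack.astype(np.int64), bit_depth=min(bit_depth, 16),
                  source=str(path))


# ---------------------------------------------------------------------------
# DICOM series (secondary-capture grayscale)
# ---------------------------------------------------------------------------

def _save_dicom(vol: Volume, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    path.mkdir(parents=True, exist_ok=True)
    itemsize = 1 if vol.bit_depth <= 8 else 2
    series_uid = pydicom.uid.generate_uid()
    for s in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.InstanceNumber = s + 1
        ds.Rows, ds.Columns = vol.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 8 * itemsize
        ds.BitsStored = vol.bit_depth
        ds.HighBit = vol.bit_depth - 1
        ds.PixelRepresentation = 0
        ds.PixelData = vol.data[s].astype(f"<u{itemsize}").tobytes()
        ds.save_as(path / f"slice_{s + 1:04d}.dcm", enforce_file_format=True)


def _load_dicom(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise VolumeFormatError(f"no DICOM files found in {path}")
    datasets = [pydicom.dcmread(f) for f in files]
    for ds, f in zip(datasets, files):
        if not str(ds.PhotometricInterpretation).startswith("MONOCHROME"):
            raise VolumeFormatError(
                f"{f}: only monochrome DICOM slices are supported"
            )
    datasets.sort(key=lambda ds: int(ds.InstanceNumber))
    slices = [ds.pixel_array for ds in datasets]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise VolumeFormatError(f"mixed slice dimensions in {path}: {shapes}")
    stack = np.stack(slices)
    if not np.issubdtype(stack.dtype, np.integer):
        raise VolumeFormatError(f"{path}: non-integer DICOM pixel data")
    bit_depth = int(datasets[0].BitsStored)
    return Volume(data=stack.astype(np.int64), bit_depth=max(8, bit_depth),
                  source=str(path))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    if path.is_dir():
        if any(p.suffix.lower() == ".dcm" for p in path.iterdir()):
            return "dicom_dir"
        return "image_stack"
    if path.is_file():
        with path.open("rb") as fh:
            if fh.read(8) == _RAW_MAGIC:
                return "raw_array"
    raise VolumeFormatError(f"cannot infer a volume format for {path}")


def load_volume(path, format_hint: str = "auto") -> Volume:
    """Read a volume from a DICOM directory, image stack or raw-array file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "dicom_dir":
        return _load_dicom(path)
    if fmt == "image_stack":
        return _load_stack(path)
    if fmt == "raw_array":
        return _load_raw(path)
    raise VolumeFormatError(f"unknown format hint {format_hint!r}")


def save_volume(vol: Volume, path, format: str = "raw_array") -> None:
    """Write a volume losslessly; load_volume(save_volume(v)) == v."""
    path = Path(path)
    if format == "dicom_dir":
        _save_dicom(vol, path)
    elif format == "image_stack":
        _save_stack(vol, path)
    elif format == "raw_array":
        path.parent.mkdir(parents=True, exist_ok=True)
        _save_raw(vol, path)
    else:
        raise VolumeFormatError(f"unknown format {format!r}")
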