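"""Readers and writers for on-disk artifacts.

Formats
-------
* **Stacks** — multi-page grayscale TIFF, one page per bin, axis order
  (bin, row, col), plus a JSON sidecar (``<path>.json``) holding the
  acquisition metadata (repetition frequency or spectral band).  Integer
  counts round-trip bit-exactly.
* **Traces** — two-column CSV/TSV ``bin_index, count`` (header optional,
  delimiter sniffed); read back as a ``(B, 1, 1)`` stack.
* **ref containers** — this package's documented multi-harmonic phasor
  dialect (``dialect = "phasorlab-ref-1"``): a little-endian 32-bit float
  multi-page TIFF with plane order ``intensity, phi_1(deg), M_1, phi_2,
  M_2, ...`` for contiguous harmonics 1..N, plus a JSON sidecar with the
  frequency, harmonic count and dialect tag.  Invalid pixels are stored as
  phase 0, modulation 0.  Byte-level compatibility with legacy SimFCS ref
  files is not guaranteed (their byte layout is not published); the
  sidecar's dialect tag makes the distinction explicit.
* **Fraction spreadsheets** — RFC-4180 CSV, one row per valid pixel.
* **Colored exports** — RGB uint8 PNG or single-page TIFF.  8-bit values
  are rounded half-away-from-zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import ColorTableError, FormatError, MetadataError, ValidationError
from .field import PhasorField
from .stacks import DecayStack, SpectralStack

REF_DIALECT = "phasorlab-ref-1"

_TRACE_SUFFIXES = {".csv", ".txt", ".tsv"}


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


# ---------------------------------------------------------------------------
# stacks


def write_stack(stack: DecayStack | SpectralStack, path) -> None:
    """Write a stack as a multi-page TIFF with a JSON metadata sidecar."""
    counts = stack.counts
    if np.issubdtype(counts.dtype, np.integer):
        data = counts.astype(np.uint16 if counts.max(initial=0) < 2**16 else np.uint32)
    else:
        data = counts.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta: dict = {}
    if isinstance(stack, DecayStack):
        meta = {"kind": "decay", "frequency": stack.frequency}
    else:
        meta = {"kind": "spectral", "band": list(stack.band)}
    if stack.calibration_tag:
        meta["calibration_tag"] = stack.calibration_tag
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _read_trace(path) -> np.ndarray:
    """Two-column (bin, count) text trace -> (B, 1, 1) count array."""
    text = Path(path).read_text()
    try:
        dialect = csv.Sniffer().sniff(text[:2048], delimiters=",\t; ")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.split(sep) if p.strip() != ""]
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if rows:
                raise FormatError(f"non-numeric row in trace {path}: {line!r}")
            continue  # header line
    if not rows:
        raise FormatError(f"trace {path} contains no numeric rows")
    arr = np.asarray(rows)
    counts = arr[:, 1] if arr.shape[1] >= 2 else arr[:, 0]
    return counts.reshape(-1, 1, 1)


def read_stack(
    path,
    frequency: float | None = None,
    band: tuple[float, float] | None = None,
    calibration_tag: str | None = None,
) -> DecayStack | SpectralStack:
    """Read a stack from a multi-page TIFF or a CSV/TXT decay trace.

    Metadata (frequency for lifetime data, band for spectral) comes from
    the explicit arguments, falling back to the JSON sidecar written by
    :func:`write_stack`.  A trace file yields a ``(B, 1, 1)`` stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if frequency is None:
        frequency = meta.get("frequency")
    if band is None:
        band = tuple(meta["band"]) if "band" in meta else None
    if calibration_tag is None:
        calibration_tag = meta.get("calibration_tag")

    if path.suffix.lower() in _TRACE_SUFFIXES:
        counts = _read_trace(path)
    else:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"ragged pages in {path}: shapes {sorted(shapes)}")
            counts = tif.asarray()
        if counts.ndim == 2:
            counts = counts[None]
        if counts.shape[0] < 2:
            raise FormatError(f"stack {path} has fewer than 2 pages")
    if counts.size and counts.min() < 0:
        raise ValidationError(f"negative counts in {path}")

    if band is not None:
        return SpectralStack(counts=counts, band=band, calibration_tag=calibration_tag)
    if frequency is None:
        raise MetadataError(
            f"no laser frequency or spectral band available for {path}; "
            "pass frequency=... or band=..."
        )
    return DecayStack(counts=counts, frequency=frequency, calibration_tag=calibration_tag)


# ---------------------------------------------------------------------------
# ref containers


def write_ref(field: PhasorField, path) -> None:
    """Write a phasor field as a ref container (see module docstring).

    Harmonics must be contiguous 1..N.  Each harmonic's (G, S) is encoded
    as a phase plane in degrees and a modulation plane; invalid pixels
    store (0, 0) in every harmonic plane.
    """
    n = len(field.harmonics)
    if field.harmonics != tuple(range(1, n + 1)):
        raise ValidationError(
            f"ref container needs contiguous harmonics 1..N; got {field.harmonics}"
        )
    planes = [field.intensity.astype(np.float32)]
    for i in range(n):
        phase = np.degrees(np.arctan2(field.s[i], field.g[i]))
        mod = np.hypot(field.g[i], field.s[i])
        phase = np.where(field.valid, phase, 0.0)
        mod = np.where(field.valid, mod, 0.0)
        planes.append(phase.astype(np.float32))
        planes.append(mod.astype(np.float32))
    tifffile.imwrite(path, np.stack(planes), photometric="minisblack")
    meta = {
        "dialect": REF_DIALECT,
        "n_harmonics": n,
        "frequency": field.frequency,
        "calibrated": field.calibrated,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_ref(path) -> PhasorField:
    """Read a ref container back into a :class:`PhasorField`.

    Pixels stored as (phase 0, modulation 0) at every harmonic are flagged
    invalid — the documented sentinel convention (a genuinely valid pixel
    sitting exactly at the phasor origin in all harmonics is
    indistinguishable from it).
    """
    path = Path(path)
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.shape[0] < 3 or planes.shape[0] % 2 == 0:
        raise FormatError(
            f"ref container must hold 1 + 2N planes; got {planes.shape[0]}"
        )
    n = (planes.shape[0] - 1) // 2
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if "n_harmonics" in meta and meta["n_harmonics"] != n:
        raise FormatError(
            f"sidecar declares {meta['n_harmonics']} harmonics but file holds {n}"
        )
    intensity = planes[0].astype(float)
    g = np.empty((n,) + intensity.shape)
    s = np.empty_like(g)
    stored_valid = np.zeros(intensity.shape, dtype=bool)
    for i in range(n):
        phase_deg = planes[1 + 2 * i].astype(float)
        mod = planes[2 + 2 * i].astype(float)
        if mod.max(initial=0.0) > 1.05:
            raise FormatError(
                f"modulation plane {i + 1} exceeds 1.05 (max {mod.max():.3f})"
            )
        phase = np.radians(phase_deg)
        g[i] = mod * np.cos(phase)
        s[i] = mod * np.sin(phase)
        stored_valid |= (phase_deg != 0) | (mod != 0)
    return PhasorField(
        harmonics=tuple(range(1, n + 1)),
        g=g,
        s=s,
        intensity=intensity,
        valid=stored_valid,
        frequency=meta.get("frequency"),
        calibrated=bool(meta.get("calibrated", False)),
    )


# ---------------------------------------------------------------------------
# spreadsheets


def export_fraction_table(
    fractions: np.ndarray,
    path,
    intensity: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Write per-pixel component fractions as an RFC-4180 CSV.

    One row per valid pixel: ``row, col, intensity, f_<c1>, ..., f_<cC>``.
    ``fractions`` is ``(C, H, W)`` (a :class:`~phasorlab.unmix.FractionField`
    works too: pass its attributes).  Returns the DataFrame written.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 3:
        raise ValidationError("fractions must have shape (C, H, W)")
    C, H, W = fractions.shape
    if intensity is None:
        intensity = np.ones((H, W))
    if valid is None:
        valid = np.ones((H, W), dtype=bool)
    intensity = np.asarray(intensity, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if intensity.shape != (H, W) or valid.shape != (H, W):
        raise ValidationError("intensity/valid shape mismatch with fraction images")
    if names is None:
        names = [f"component_{i + 1}" for i in range(C)]
    rows, cols = np.nonzero(valid)
    data = {"row": rows, "col": cols, "intensity": intensity[rows, cols]}
    for i, name in enumerate(names):
        data[f"f_{name}"] = fractions[i, rows, cols]
    frame = pd.DataFrame(data)
    with open(path, "w", newline="") as fh:
        frame.to_csv(fh, index=False, lineterminator="\r\n")
    return frame


# ---------------------------------------------------------------------------
# colored exports


@dataclass
class ColorExportSpec:
    """How to colorize a label image: solid (hard) or intensity-weighted (soft)."""

    mode: str = "hard"
    label_colors: dict[int, tuple[int, int, int]] = dc_field(default_factory=dict)
    intensity_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValidationError(f"mode must be 'hard' or 'soft'; got {self.mode!r}")
        if self.intensity_scale not in ("linear", "log"):
            raise ValidationError(
                f"intensity_scale must be 'linear' or 'log'; got {self.intensity_scale!r}"
            )
        for label, rgb in self.label_colors.items():
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise ValidationError(f"bad RGB for label {label}: {rgb}")


def _round_u8(x: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to uint8 (values are >= 0 here)."""
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


def _intensity_weight(intensity: np.ndarray, scale: str) -> np.ndarray:
    w = np.asarray(intensity, dtype=float)
    if scale == "log":
        w = np.log1p(w)
    top = w.max()
    return w / top if top > 0 else np.zeros_like(w)


def colorize_labels(
    labels: np.ndarray, spec: ColorExportSpec, intensity: np.ndarray | None = None
) -> np.ndarray:
    """RGB image from a label image under a hard or soft masking spec."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    missing = [int(v) for v in present if int(v) not in spec.label_colors]
    if missing:
        raise ColorTableError(f"labels {missing} have no assigned color")
    lut = np.zeros((int(present.max()) + 1, 3))
    for label, rgb in spec.label_colors.items():
        if 0 <= label < lut.shape[0]:
            lut[label] = rgb
    rgb = lut[labels]
    if spec.mode == "soft":
        if intensity is None:
            raise ValidationError("soft masking requires an intensity image")
        if np.asarray(intensity).shape != labels.shape:
            raise ValidationError("intensity shape mismatch with label image")
        rgb = rgb * _intensity_weight(intensity, spec.intensity_scale)[..., None]
    return _round_u8(rgb)


def colorize_fractions(
    fractions: np.ndarray,
    colors: list[tuple[int, int, int]],
    intensity: np.ndarray | None = None,
    intensity_scale: str = "linear",
) -> np.ndarray:
    """Linear addition of component colors weighted by their fractions.

    Channel value = sum_i f_i * color_i, optionally further weighted by the
    normalized intensity image (the merged-image rendering of unmixing
    results).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 3 or fractions.shape[0] != len(colors):
        raise ValidationError("need one color per fraction image")
    rgb = np.tensordot(fractions, np.asarray(colors, dtype=float), axes=(0, 0))
    if intensity is not None:
        if np.asarray(intensity).shape != fractions.shape[1:]:
            raise ValidationError("intensity shape mismatch with fraction images")
        rgb = rgb * _intensity_weight(intensity, intensity_scale)[..., None]
    return _round_u8(rgb)


def export_colored_image(path, rgb: np.ndarray) -> None:
    """Write an RGB uint8 image as PNG or single-page TIFF (by extension)."""
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8 or rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) uint8 RGB array")
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb, photometric="rgb")
    else:
        iio.imwrite(path, rgb)
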