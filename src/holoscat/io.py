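"""Readers and writers for every on-disk artifact.

All artifacts are self-describing bundle directories: image data as
multi-page 32-bit TIFF, tables as CSV, metadata as JSON.  Round trips are
loss-free for integer data and accurate to single precision (~1e-7
relative) for floating point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import ComplexField, OpticalGrid
from .medium import VirtualMedium
from .reconstruct import ReconstructionStack
from .retrieval import ConvergenceTrace, RetrievedFieldSet
from .simulate import MaskSet, SpeckleMeasurementSet

__all__ = [
    "SchemaError",
    "write_measurement_bundle", "read_measurement_bundle",
    "write_field_set", "read_field_set",
    "write_complex_field", "read_complex_field",
    "write_medium", "read_medium",
    "write_stack", "read_stack",
    "write_trace", "read_trace",
]


class SchemaError(ValueError):
    """An on-disk bundle violates the expected schema."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise SchemaError(f"missing file: {path}")
    return path


def _load_json(path: Path) -> dict:
    with open(_require(path)) as fh:
        return json.load(fh)


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def _write_tiff(path: Path, data: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32),
                     photometric="minisblack")


def _read_tiff(path: Path) -> np.ndarray:
    return np.asarray(tifffile.imread(_require(path)), dtype=np.float64)


# ---------------------------------------------------------------------------
# measurement bundles

def write_measurement_bundle(measurements: SpeckleMeasurementSet, path) -> Path:
    """Write camera images, mask phases and geometry to a bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_tiff(path / "images.tif", measurements.images)
    _write_tiff(path / "mask_phases.tif", measurements.masks.phases)
    _dump_json({
        "grid": measurements.grid.to_dict(),
        "focus_distance_um": measurements.focus_distance,
        "source_distance_um": measurements.source_distance,
        "mask_macropixel": measurements.masks.macropixel,
        "mask_seed": measurements.masks.seed,
        "noise": measurements.noise,
        "n_images": len(measurements),
    }, path / "meta.json")
    return path


def read_measurement_bundle(path) -> SpeckleMeasurementSet:
    """Read a measurement bundle, validating shapes and mask modulus."""
    path = Path(path)
    meta = _load_json(path / "meta.json")
    try:
        grid = OpticalGrid.from_dict(meta["grid"])
    except KeyError as exc:
        raise SchemaError(f"meta.json: missing grid field {exc}") from exc
    images = np.atleast_3d(_read_tiff(path / "images.tif"))
    phases = np.atleast_3d(_read_tiff(path / "mask_phases.tif"))
    if images.shape[0] != meta.get("n_images", images.shape[0]):
        raise SchemaError("meta.json: n_images does not match images.tif")
    if images.shape != (images.shape[0],) + grid.shape:
        raise SchemaError("images.tif: image shape does not match meta.json grid")
    if np.any(images < 0):
        raise SchemaError("images.tif: negative intensity values")
    if not np.all(np.isfinite(phases)):
        raise SchemaError("mask_phases.tif: non-finite mask phases")
    masks = MaskSet(phases=phases, grid=grid,
                    macropixel=int(meta.get("mask_macropixel", 1)),
                    seed=meta.get("mask_seed"))
    if np.any(np.abs(np.abs(masks.values) - 1.0) > 1e-6):
        raise SchemaError("mask_phases.tif: masks are not unit modulus")
    return SpeckleMeasurementSet(
        images=images, masks=masks, grid=grid,
        focus_distance=float(meta.get("focus_distance_um", 100.0)),
        source_distance=float(meta.get("source_distance_um", 100.0)),
        noise=meta.get("noise"),
    )


# ---------------------------------------------------------------------------
# complex fields

def write_complex_field(fld: ComplexField, path) -> Path:
    """A single field as paired real/imag TIFF pages plus JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_tiff(path / "field.tif",
                np.stack([fld.values.real, fld.values.imag]))
    _dump_json({"grid": fld.grid.to_dict(), "plane_z_um": fld.plane_z,
                "label": fld.label}, path / "meta.json")
    return path


def read_complex_field(path) -> ComplexField:
    path = Path(path)
    meta = _load_json(path / "meta.json")
    pages = _read_tiff(path / "field.tif")
    if pages.shape[0] != 2:
        raise SchemaError("field.tif: expected 2 pages (real, imag)")
    return ComplexField(values=pages[0] + 1j * pages[1],
                        grid=OpticalGrid.from_dict(meta["grid"]),
                        plane_z=float(meta["plane_z_um"]),
                        label=meta.get("label", ""))


def write_field_set(fields: RetrievedFieldSet, path,
                    trace: ConvergenceTrace | None = None) -> Path:
    """N fields as interleaved real/imag TIFF pages (+ residual trace CSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pages = np.empty((2 * len(fields),) + fields.grid.shape, dtype=np.float32)
    pages[0::2] = fields.values.real
    pages[1::2] = fields.values.imag
    _write_tiff(path / "fields.tif", pages)
    _dump_json({"grid": fields.grid.to_dict(), "plane_z_um": fields.plane_z,
                "label": fields.label, "n_states": len(fields)},
               path / "meta.json")
    if trace is not None:
        write_trace(trace, path / "trace.csv")
    return path


def read_field_set(path) -> RetrievedFieldSet:
    path = Path(path)
    meta = _load_json(path / "meta.json")
    pages = _read_tiff(path / "fields.tif")
    n = int(meta["n_states"])
    if pages.shape[0] != 2 * n:
        raise SchemaError(f"fields.tif: expected {2 * n} pages, "
                          f"found {pages.shape[0]}")
    return RetrievedFieldSet(values=pages[0::2] + 1j * pages[1::2],
                             grid=OpticalGrid.from_dict(meta["grid"]),
                             plane_z=float(meta["plane_z_um"]),
                             label=meta.get("label", ""))


# ---------------------------------------------------------------------------
# virtual medium, stacks, traces

def write_medium(medium: VirtualMedium, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_tiff(path / "phase.tif", medium.phase)
    pd.DataFrame(medium.provenance,
                 columns=["field_index", "admission_score"]).to_csv(
        path / "provenance.csv", index=False)
    _dump_json({"grid": medium.grid.to_dict(), "plane_z_um": medium.plane_z,
                "reference_index": medium.reference_index,
                "excluded": list(medium.excluded)}, path / "meta.json")
    return path


def read_medium(path) -> VirtualMedium:
    path = Path(path)
    meta = _load_json(path / "meta.json")
    prov = pd.read_csv(_require(path / "provenance.csv"))
    return VirtualMedium(
        phase=_read_tiff(path / "phase.tif"),
        grid=OpticalGrid.from_dict(meta["grid"]),
        plane_z=float(meta["plane_z_um"]),
        reference_index=int(meta["reference_index"]),
        provenance=[(int(r.field_index), float(r.admission_score))
                    for r in prov.itertuples()],
        excluded=[int(e) for e in meta.get("excluded", [])],
    )


def write_stack(stack: ReconstructionStack, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_tiff(path / "stack.tif", stack.values)
    _dump_json({"grid": stack.grid.to_dict(),
                "z_um": [float(z) for z in stack.z_values],
                "provenance": stack.provenance}, path / "meta.json")
    return path


def read_stack(path) -> ReconstructionStack:
    path = Path(path)
    meta = _load_json(path / "meta.json")
    values = np.clip(np.atleast_3d(_read_tiff(path / "stack.tif")), 0.0, None)
    return ReconstructionStack(values=values,
                               z_values=np.asarray(meta["z_um"], dtype=float),
                               grid=OpticalGrid.from_dict(meta["grid"]),
                               provenance=meta.get("provenance", {}))


def write_trace(trace: ConvergenceTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"epoch": np.arange(1, len(trace.residuals) + 1),
                  "residual": trace.residuals}).to_csv(path, index=False)
    return path


def read_trace(path) -> ConvergenceTrace:
    df = pd.read_csv(_require(Path(path)))
    residuals = [float(r) for r in df["residual"]]
    return ConvergenceTrace(residuals=residuals, n_epochs=len(residuals),
                            stop_reason="loaded")
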