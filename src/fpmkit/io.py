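"""File formats and run configuration.

Stacks, reconstructions and dual-channel images are stored in HDF5 (with a
multi-page float32 TIFF alternative for stacks); grayscale sources are read
from PNG/TIFF into floats in [0, 1].  Every artifact written carries the
seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from imageio.v3 import imread

from .errors import ConfigError, FormatError
from .forward import LowResStack
from .optics import ComplexField, LEDGrid, OpticalConfig
from .recon import GSConfig
from .synthesis import DualChannelInput

__all__ = [
    "RunConfig",
    "load_config",
    "read_image",
    "save_stack",
    "load_stack",
    "save_field",
    "load_field",
    "save_dual_channel",
    "load_dual_channel",
]


@dataclass
class RunConfig:
    """Validated optics + LED grid + reconstruction + dataset + training
    sections, with provenance (config hash, master seed)."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    grid: LEDGrid = field(default_factory=LEDGrid)
    gs: GSConfig = field(default_factory=GSConfig)
    dataset: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "optics": asdict(self.optics),
            "grid": asdict(self.grid),
            "gs": asdict(self.gs),
            "dataset": dict(self.dataset),
            "train": dict(self.train),
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def substream_seed(self, name: str) -> int:
        """Named per-module seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


_SECTIONS = {"optics", "grid", "gs", "dataset", "train", "seed"}


def _build_section(cls, data: dict, section: str, errors: list):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        errors.append(f"{section}: unknown key(s) {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**data)
    except (ConfigError, TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing sections get defaults; unknown keys and invariant violations
    are all collected and reported in a single ``ConfigError``.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: list[str] = []
    unknown = set(raw) - _SECTIONS
    if unknown:
        errors.append(f"unknown section(s) {sorted(unknown)}")
    optics = _build_section(OpticalConfig, raw.get("optics", {}), "optics", errors)
    grid = _build_section(LEDGrid, raw.get("grid", {}), "grid", errors)
    gs_raw = dict(raw.get("gs", {}))
    gs = _build_section(GSConfig, gs_raw, "gs", errors)
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(
        optics=optics,
        grid=grid,
        gs=gs,
        dataset=dict(raw.get("dataset", {})),
        train=dict(raw.get("train", {})),
        seed=seed,
    )


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit PNG or float TIFF as grayscale floats in [0, 1]."""
    arr = np.asarray(imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def _stamp(h5: h5py.File, provenance: dict | None):
    if provenance:
        for k, v in provenance.items():
            h5.attrs[k] = v


def save_stack(stack: LowResStack, path, provenance: dict | None = None) -> None:
    """HDF5 (datasets ``images`` [n,h,w], ``wave_vectors`` [n,2]) plus a
    JSON sidecar with the optics and grid parameters; ``.tif`` paths write
    a multi-page float32 TIFF instead."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.images.astype(np.float32), photometric="minisblack")
        sidecar = {"wave_vectors": stack.wave_vectors.tolist(), "noise_sigma": stack.noise_sigma}
        _write_sidecar(path, stack, sidecar, provenance)
        return
    with h5py.File(path, "w") as h5:
        h5.create_dataset("images", data=stack.images.astype(np.float32))
        h5.create_dataset("wave_vectors", data=stack.wave_vectors)
        h5.attrs["noise_sigma"] = stack.noise_sigma
        _stamp(h5, provenance)
    _write_sidecar(path, stack, {}, provenance)


def _write_sidecar(path: Path, stack: LowResStack, extra: dict, provenance: dict | None):
    meta = dict(extra)
    optics = stack.meta.get("optics")
    grid = stack.meta.get("grid")
    if optics is not None:
        meta["optics"] = asdict(optics)
    if grid is not None:
        meta["grid"] = asdict(grid)
    if provenance:
        meta["provenance"] = dict(provenance)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_stack(path) -> LowResStack:
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if "optics" in raw:
            meta["optics"] = OpticalConfig(**raw["optics"])
        if "grid" in raw:
            meta["grid"] = LEDGrid(**raw["grid"])
    if path.suffix.lower() in (".tif", ".tiff"):
        images = np.asarray(tifffile.imread(path), dtype=float)
        raw = json.loads(sidecar.read_text())
        return LowResStack(
            images=images,
            wave_vectors=np.asarray(raw["wave_vectors"]),
            noise_sigma=raw.get("noise_sigma", 0.0),
            meta=meta,
        )
    with h5py.File(path, "r") as h5:
        if "images" not in h5 or "wave_vectors" not in h5:
            raise FormatError(f"{path} lacks 'images'/'wave_vectors' datasets")
        return LowResStack(
            images=h5["images"][...].astype(float),
            wave_vectors=h5["wave_vectors"][...],
            noise_sigma=float(h5.attrs.get("noise_sigma", 0.0)),
            meta=meta,
        )


def save_field(fld: ComplexField, path, residuals=None, provenance: dict | None = None) -> None:
    """Reconstruction output: ``amplitude``, ``phase`` (and ``residuals``)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("amplitude", data=fld.amplitude)
        h5.create_dataset("phase", data=fld.phase)
        if residuals is not None:
            h5.create_dataset("residuals", data=np.asarray(residuals))
        h5.attrs["pixel_um"] = fld.pixel_um
        _stamp(h5, provenance)


def load_field(path) -> tuple[ComplexField, np.ndarray | None]:
    with h5py.File(path, "r") as h5:
        if "amplitude" not in h5 or "phase" not in h5:
            raise FormatError(f"{path} lacks 'amplitude'/'phase' datasets")
        values = h5["amplitude"][...] * np.exp(1j * h5["phase"][...])
        residuals = h5["residuals"][...] if "residuals" in h5 else None
        return ComplexField(values=values, pixel_um=float(h5.attrs.get("pixel_um", 1.0))), residuals


def save_dual_channel(dual: DualChannelInput, path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("intensity", data=dual.intensity)
        h5.create_dataset("phase", data=dual.phase)
        _stamp(h5, provenance)


def load_dual_channel(path) -> DualChannelInput:
    with h5py.File(path, "r") as h5:
        if "intensity" not in h5 or "phase" not in h5:
            raise FormatError(f"{path} lacks 'intensity'/'phase' datasets")
        return DualChannelInput(intensity=h5["intensity"][...], phase=h5["phase"][...])
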