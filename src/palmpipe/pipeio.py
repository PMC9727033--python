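"""Shared file formats: TIFF stacks with metadata, schema-versioned CSV,
YAML configs and the JSON run manifest.

Every CSV written by the pipeline starts with a schema comment line
(``# palmpipe-table v1 kind=<kind>``); readers reject unknown schemas.
Floats are rounded to six decimals on write so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

SCHEMA_VERSION = 1
_SCHEMA_PREFIX = "# palmpipe-table"


class IOError_(ValueError):
    pass


class MetadataError(IOError_):
    pass


class SchemaError(IOError_):
    pass


# ---------------------------------------------------------------------------
# TIFF stacks


@dataclass
class FrameStack:
    data: np.ndarray  # (frames, y, x)
    pixel_size: float  # nm
    frame_rate: float  # Hz


def write_stack(path, stack: np.ndarray, pixel_size: float, frame_rate: float) -> None:
    """Write a multi-page TIFF with pixel size / frame rate in the description."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {"pixel_size_nm": float(pixel_size), "frame_rate_hz": float(frame_rate),
            "axes": "TYX"}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_stack(path, sidecar: Optional[Path] = None) -> FrameStack:
    """Read a TIFF stack, resolving metadata from tags or a YAML sidecar.

    Metadata resolution order: JSON in the TIFF description, then
    ``<path>.meta.yaml`` (or an explicit ``sidecar``). Missing pixel size or
    frame rate is a hard error — lifetimes depend on both.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except Exception as exc:
        raise IOError_(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if "pixel_size_nm" not in meta or "frame_rate_hz" not in meta:
        sc = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.yaml")
        if sc.exists():
            with open(sc) as fh:
                meta = {**(yaml.safe_load(fh) or {}), **meta}
    if "pixel_size_nm" not in meta or "frame_rate_hz" not in meta:
        raise MetadataError(
            f"{path}: pixel_size_nm and frame_rate_hz must come from TIFF tags "
            "or a .meta.yaml sidecar"
        )
    return FrameStack(
        data=data,
        pixel_size=float(meta["pixel_size_nm"]),
        frame_rate=float(meta["frame_rate_hz"]),
    )


def read_label_image(path) -> np.ndarray:
    """Read an 8-bit label image (region mask) from TIFF/PNG."""
    from skimage import io as skio

    return np.asarray(skio.imread(str(path)))


# ---------------------------------------------------------------------------
# schema-versioned CSV


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    header = f"{_SCHEMA_PREFIX} v{SCHEMA_VERSION} kind={kind}\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_table(path, kind: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_SCHEMA_PREFIX):
            parts = first.strip().split()
            version = parts[2]
            file_kind = dict(p.split("=", 1) for p in parts[3:] if "=" in p).get("kind")
            if version != f"v{SCHEMA_VERSION}":
                raise SchemaError(f"{path}: unsupported schema {version}")
            if kind is not None and file_kind != kind:
                raise SchemaError(f"{path}: expected kind={kind}, found {file_kind}")
            return pd.read_csv(fh)
        if kind is not None:
            raise SchemaError(f"{path}: missing palmpipe schema header")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# config + manifest


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(config_dict: dict) -> str:
    canonical = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written before any stage output.

    ``timestamp`` carries wall-clock time and is the one field excluded
    from byte-identity comparisons between reruns.
    """

    config_hash: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""
    completed_stages: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
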