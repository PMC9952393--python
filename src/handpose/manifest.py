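"""Dataset persistence: 16-bit millimeter depth PNGs and a line-delimited
manifest pairing each raster with its intrinsics and keypoint annotations."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .camera import CameraIntrinsics, DepthFrame

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "write_depth_png",
    "read_depth_png",
    "read_manifest",
    "write_manifest",
    "save_dataset",
    "load_dataset",
]

SCHEMA_VERSION = 1


def write_depth_png(path, frame: DepthFrame) -> None:
    """Depth in mm quantized to integers into a 16-bit single-channel PNG."""
    depth = np.rint(frame.depth).astype(np.uint16)
    Image.fromarray(depth).save(path)   # uint16 -> 16-bit grayscale PNG


def read_depth_png(path, intrinsics: CameraIntrinsics) -> DepthFrame:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    return DepthFrame(depth=arr, intrinsics=intrinsics)


@dataclass
class ManifestRecord:
    depth_path: str
    intrinsics: CameraIntrinsics
    keypoints: np.ndarray                     # (J, 3) world mm
    tags: dict = None

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        if self.keypoints.ndim != 2 or self.keypoints.shape[1] != 3:
            raise ValueError("keypoints must be (J, 3)")
        self.tags = self.tags or {}


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    schema: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        js = {r.keypoints.shape[0] for r in self.records}
        if len(js) > 1:
            raise ValueError(f"mixed keypoint counts in manifest: {sorted(js)}")

    @property
    def J(self) -> int:
        return self.records[0].keypoints.shape[0] if self.records else 0

    def __len__(self) -> int:
        return len(self.records)


def write_manifest(manifest: DatasetManifest, path) -> None:
    """One JSON record per line, preceded by a schema header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"schema": manifest.schema, "J": manifest.J}) + "\n")
        for r in manifest.records:
            K = r.intrinsics
            fh.write(json.dumps({
                "depth": r.depth_path,
                "intrinsics": [K.fx, K.fy, K.cx, K.cy],
                "keypoints": r.keypoints.tolist(),
                "tags": r.tags,
            }) + "\n")


def read_manifest(path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with path.open() as fh:
        header = json.loads(fh.readline())
        if header.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported manifest schema: {header.get('schema')!r}")
        records = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            depth_path = rec["depth"]
            if check_files and not (path.parent / depth_path).exists():
                raise FileNotFoundError(f"depth file missing: {path.parent / depth_path}")
            records.append(ManifestRecord(
                depth_path=depth_path,
                intrinsics=CameraIntrinsics(*rec["intrinsics"]),
                keypoints=np.asarray(rec["keypoints"]),
                tags=rec.get("tags", {}),
            ))
    return DatasetManifest(records=records)


def save_dataset(frames, directory, prefix: str = "frame") -> Path:
    """Write synthetic frames as PNGs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, item in enumerate(frames):
        name = f"{prefix}_{i:05d}.png"
        write_depth_png(directory / name, item.frame)
        records.append(ManifestRecord(
            depth_path=name, intrinsics=item.frame.intrinsics, keypoints=item.keys
        ))
    mpath = directory / "manifest.jsonl"
    write_manifest(DatasetManifest(records=records), mpath)
    return mpath


def load_dataset(manifest_path):
    """Manifest -> list of (DepthFrame, keypoints mm) pairs."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    out = []
    for r in manifest.records:
        frame = read_depth_png(manifest_path.parent / r.depth_path, r.intrinsics)
        out.append((frame, r.keypoints))
    return out
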