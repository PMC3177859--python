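"""Volume, mesh and table I/O plus geometric resampling.

All geometry in this package lives in world millimetres, RAS orientation.
Volumes carry a 4x4 voxel-index -> world-mm affine (NIfTI convention,
0-based indices); distances are never computed in voxel units because
clinical acquisitions are frequently anisotropic (e.g. 3 mm slices with
sub-millimetre in-plane resolution).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage

__all__ = [
    "Volume",
    "Landmark",
    "LandmarkSet",
    "MIDLINE_LANDMARKS",
    "PAIRED_LANDMARKS",
    "CANONICAL_LANDMARKS",
    "read_volume",
    "write_volume",
    "resample_volume",
    "read_mesh",
    "write_mesh",
    "read_vertex_scalars",
    "write_vertex_scalars",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

# Landmark vocabulary: three midline landmarks and three left/right pairs,
# nine locations in total (occipital pole, L/R parieto-occipital sulcus,
# vertex, L/R Heschl's gyrus, L/R inferior frontal gyrus, frontal pole).
MIDLINE_LANDMARKS = ("occipital_pole", "vertex", "frontal_pole")
PAIRED_LANDMARKS = ("parietal_POS", "heschl_gyrus", "IFG")

#: The nine canonical (name, hemisphere) combinations.
CANONICAL_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("occipital_pole", "midline"),
    ("parietal_POS", "left"),
    ("parietal_POS", "right"),
    ("vertex", "midline"),
    ("heschl_gyrus", "left"),
    ("heschl_gyrus", "right"),
    ("IFG", "left"),
    ("IFG", "right"),
    ("frontal_pole", "midline"),
)

#: Default voxel-count ceiling for resampling (~8 GiB of float64).
MAX_RESAMPLE_VOXELS = 1_000_000_000


@dataclass
class Volume:
    """A 3D scalar grid with a voxel-index -> world-mm affine.

    ``data`` holds arbitrary intensity units, or {0, 1} for masks.
    ``affine`` maps 0-based voxel indices to world mm (RAS).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm along each index axis."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) world-mm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def is_mask(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate intensities at world-mm points (linear by default)."""
        idx = self.world_to_index(points)
        return ndimage.map_coordinates(
            self.data.astype(float), idx.T, order=order, mode="constant", cval=0.0
        )


@dataclass(frozen=True)
class Landmark:
    name: str
    hemisphere: str
    position: tuple[float, float, float]


@dataclass
class LandmarkSet:
    """A validated set of named cortical landmarks in world mm."""

    entries: list[Landmark] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for lm in self.entries:
            _check_landmark_name(lm.name, lm.hemisphere)
            key = (lm.name, lm.hemisphere)
            if key in seen:
                raise ValueError(f"duplicate landmark {key}")
            seen.add(key)
            if len(lm.position) != 3 or not all(np.isfinite(lm.position)):
                raise ValueError(f"landmark {key} has invalid coordinates")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str, hemisphere: str = "midline") -> Landmark:
        for lm in self.entries:
            if lm.name == name and lm.hemisphere == hemisphere:
                return lm
        raise KeyError((name, hemisphere))


def _check_landmark_name(name: str, hemisphere: str) -> None:
    if name in MIDLINE_LANDMARKS:
        if hemisphere != "midline":
            raise ValueError(f"landmark {name!r} must be midline, got {hemisphere!r}")
    elif name in PAIRED_LANDMARKS:
        if hemisphere not in ("left", "right"):
            raise ValueError(
                f"paired landmark {name!r} needs hemisphere left/right, got {hemisphere!r}"
            )
    else:
        raise ValueError(f"unknown landmark name {name!r}")


# ---------------------------------------------------------------------------
# Volumes


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume and reorient it to canonical RAS.

    Returns world coordinates in mm.  Raises for missing files, non-3D
    images and non-finite affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"non-finite affine in {path}")
    return Volume(data=data, affine=affine)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz)."""
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume data contains non-finite values")
    data = volume.data
    if volume.is_mask():
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


def resample_volume(
    volume: Volume,
    target_spacing: Sequence[float],
    method: str = "linear",
    max_voxels: int = MAX_RESAMPLE_VOXELS,
) -> Volume:
    """Resample onto a new grid covering the same world extent.

    ``method`` is ``"nearest"`` (masks) or ``"linear"`` (intensities).
    World positions of features are preserved within one target voxel.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target spacing must be three positive numbers")
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown method {method!r}")
    spacing = np.asarray(volume.spacing)
    if np.allclose(target, spacing, rtol=0, atol=1e-12):
        return Volume(data=volume.data.copy(), affine=volume.affine.copy())
    zoom = spacing / target
    new_shape = np.maximum(np.round(np.asarray(volume.shape) * zoom), 1).astype(int)
    if int(np.prod(new_shape)) > max_voxels:
        raise MemoryError(
            f"resampled grid {tuple(new_shape)} exceeds {max_voxels} voxels; "
            "crop a region of interest around the structure first"
        )
    # New affine: same direction cosines, rescaled columns; origin shifted so
    # that voxel centres tile the same world extent.
    direction = volume.affine[:3, :3] / spacing
    new_lin = direction * target
    scale = np.asarray(volume.shape) / new_shape
    # world(new index i) = world(old index (i + 0.5) * scale - 0.5)
    new_origin = volume.affine[:3, 3] + volume.affine[:3, :3] @ (0.5 * scale - 0.5)
    order = 0 if method == "nearest" else 1
    sample_idx = np.indices(new_shape).reshape(3, -1).T
    old_idx = (sample_idx + 0.5) * scale - 0.5
    data = ndimage.map_coordinates(
        volume.data.astype(float), old_idx.T, order=order, mode="nearest"
    ).reshape(new_shape)
    if method == "nearest":
        data = data.astype(volume.data.dtype)
    affine = np.eye(4)
    affine[:3, :3] = new_lin
    affine[:3, 3] = new_origin
    return Volume(data=data, affine=affine)


# ---------------------------------------------------------------------------
# Meshes


def read_mesh(path: str | Path):
    """Read an OBJ/PLY triangle mesh into a SurfaceMesh (world mm)."""
    from .surfaces import SurfaceMesh  # deferred: avoid cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load_mesh(str(path), process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"{path} does not contain a triangle mesh")
    return SurfaceMesh(vertices=np.asarray(tm.vertices, float),
                       faces=np.asarray(tm.faces, int))


def write_mesh(mesh, path: str | Path) -> None:
    """Write a SurfaceMesh to OBJ or PLY (by extension), losslessly."""
    faces = np.asarray(mesh.faces)
    if faces.size == 0:
        raise ValueError("refusing to write a mesh with 0 faces")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError("mesh faces must be triangles")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=faces, process=False)
    path = Path(path)
    if path.suffix.lower() == ".ply":
        # ASCII PLY keeps the deliverable text-only and diffable.
        path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    else:
        tm.export(str(path))


def write_vertex_scalars(values: np.ndarray, path: str | Path,
                         name: str = "value") -> None:
    """Write per-vertex scalars as a CSV sidecar keyed by vertex index."""
    values = np.asarray(values)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_index", name])
        for i, v in enumerate(values):
            writer.writerow([i, repr(float(v)) if np.isfinite(v) else "nan"])


def read_vertex_scalars(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    df = df.sort_values("vertex_index")
    if not np.array_equal(df["vertex_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("vertex_index column must cover 0..n-1 exactly once")
    return df.iloc[:, 1].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Tables


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark TSV with columns name, hemisphere, x, y, z (world mm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        coords = [row["x"], row["y"], row["z"]]
        try:
            coords = [float(c) for c in coords]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric coordinate in row {row.to_dict()}") from exc
        entries.append(Landmark(str(row["name"]), str(row["hemisphere"]),
                                tuple(coords)))
    return LandmarkSet(entries=entries)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    rows = [
        {"name": lm.name, "hemisphere": lm.hemisphere,
         "x": lm.position[0], "y": lm.position[1], "z": lm.position[2]}
        for lm in landmarks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


COHORT_COLUMNS = ("subject", "age_months", "handedness", "landmark",
                  "hemisphere", "distance_mm")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format cohort table.

    Columns: subject, age_months, handedness (left|right|unknown), landmark,
    hemisphere, distance_mm.  Ages must be >= 0, distances > 0, and
    (subject, landmark, hemisphere) unique.
    """
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    df = df.copy()
    df["age_months"] = pd.to_numeric(df["age_months"], errors="raise")
    df["distance_mm"] = pd.to_numeric(df["distance_mm"], errors="raise")
    if (df["age_months"] < 0).any():
        raise ValueError("negative age_months in cohort table")
    if (df["distance_mm"] <= 0).any():
        raise ValueError("non-positive distance_mm in cohort table")
    bad_hand = set(df["handedness"].unique()) - {"left", "right", "unknown"}
    if bad_hand:
        raise ValueError(f"unknown handedness values {sorted(bad_hand)}")
    for name, hemi in df[["landmark", "hemisphere"]].drop_duplicates().itertuples(index=False):
        _check_landmark_name(name, hemi)
    dup = df.duplicated(subset=["subject", "landmark", "hemisphere"])
    if dup.any():
        raise ValueError("duplicate (subject, landmark, hemisphere) rows")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, sep="\t", index=False)
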