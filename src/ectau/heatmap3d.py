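"""3D tau heat maps: score-labeled volumes, coronal renders, isosurface meshes.

Per case, the subfield masks of a label volume are painted with one label per
(unit, SQ score) combination so unit identity survives in the voxel data; a
collapsed score-only view backs the rendering and meshing.  Conventions:
0-based voxel indices, axis 0 anterior -> posterior (the coronal slice axis),
axis 1 the pial -> white direction (pial surface at the low-index face),
axis 2 medial -> lateral.  Hemisphere laterality is carried as metadata in the
JSON sidecar rather than baked into the array, so a cohort mixing left and
right hemispheres renders in a consistent orientation.

Isosurfaces are extracted per score from the binary score region (marching
cubes at iso-level 0.5), colored with the fixed five-color palette, and
exported as PLY (per-face color) or STL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .sq_scoring import color_for_score

__all__ = [
    "LabelEntry",
    "LabelVolume",
    "ScoreSurface",
    "build_label_volume",
    "extract_isosurfaces",
    "mesh_volume",
    "render_slice",
    "write_volume",
    "read_volume",
    "write_surface_ply",
    "VolumeError",
]


class VolumeError(ValueError):
    pass


@dataclass(frozen=True)
class LabelEntry:
    """What one integer label in the volume means."""

    unit: str
    level: int | None = None
    score: int | None = None  # None = masked but unscored (rendered as score 0)

    @property
    def effective_score(self) -> int:
        return 0 if self.score is None else int(self.score)


@dataclass
class LabelVolume:
    """Integer label grid + voxel size (mm) + label table, with axis metadata."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    label_table: dict[int, LabelEntry]
    ap_axis: int = 0
    thickness_axis: int = 1
    ml_axis: int = 2
    pial_side: str = "low"  # pial surface faces the low index along thickness_axis
    hemisphere: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError("label volume must be 3-D")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise VolumeError(f"labels {sorted(missing)} missing from label table")

    def score_field(self) -> np.ndarray:
        """Collapsed per-voxel SQ score; -1 outside any mask."""
        out = np.full(self.data.shape, -1, dtype=np.int16)
        for label, entry in self.label_table.items():
            out[self.data == label] = entry.effective_score
        return out

    def unit_mask(self, unit: str, level: int | None = None) -> np.ndarray:
        m = np.zeros(self.data.shape, bool)
        for label, entry in self.label_table.items():
            if entry.unit == unit and (level is None or entry.level == level):
                m |= self.data == label
        return m

    def voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.data, return_counts=True)
        return {int(lb): int(ct) for lb, ct in zip(labels, counts) if lb != 0}


@dataclass
class ScoreSurface:
    score: int
    vertices: np.ndarray  # (n, 3) mm coordinates
    faces: np.ndarray  # (m, 3) vertex indices
    color: tuple[int, int, int]
    watertight: bool = False


def build_label_volume(
    case_scores: pd.DataFrame,
    unit_masks: dict[tuple[int, str], np.ndarray],
    voxel_size: tuple[float, float, float] | float = 1.0,
) -> LabelVolume:
    """Paint per-(level, unit) masks with (unit, score) labels.

    ``case_scores`` holds one case's rows (level, unit, sq); every scored
    (level, unit) must have a mask, masks must be pairwise disjoint, and a
    masked (level, unit) without a score receives the score-0 label for that
    unit.  Voxel counts per label equal the corresponding mask sizes.
    """
    if isinstance(voxel_size, (int, float)):
        voxel_size = (float(voxel_size),) * 3
    if not unit_masks:
        raise VolumeError("no unit masks given")
    shapes = {m.shape for m in unit_masks.values()}
    if len(shapes) != 1:
        raise VolumeError(f"masks disagree on shape: {shapes}")
    shape = shapes.pop()

    overlap = np.zeros(shape, dtype=np.int32)
    for m in unit_masks.values():
        overlap += np.asarray(m, bool)
    if (overlap > 1).any():
        bad = []
        keys = list(unit_masks)
        for i, ka in enumerate(keys):
            ma = np.asarray(unit_masks[ka], bool)
            for kb in keys[i + 1 :]:
                if (ma & np.asarray(unit_masks[kb], bool)).any():
                    bad.append((ka, kb))
        raise VolumeError(f"overlapping unit masks: {bad}")

    score_of: dict[tuple[int, str], int | None] = {}
    for _, row in case_scores.iterrows():
        key = (int(row["level"]), str(row["unit"]))
        if key not in unit_masks:
            raise VolumeError(f"scored region {key} has no mask")
        sq = row["sq"]
        score_of[key] = None if pd.isna(sq) else int(sq)

    data = np.zeros(shape, dtype=np.int16)
    table: dict[int, LabelEntry] = {}
    label = 0
    for (level, unit), mask in sorted(unit_masks.items(), key=lambda kv: kv[0]):
        label += 1
        data[np.asarray(mask, bool)] = label
        table[label] = LabelEntry(unit=unit, level=level, score=score_of.get((level, unit)))
    return LabelVolume(data, voxel_size, table)


def extract_isosurfaces(volume: LabelVolume, min_score: int = 0) -> list[ScoreSurface]:
    """Triangulated surface per SQ score >= ``min_score`` present in the volume.

    Each score's binary voxel region is padded and contoured with marching
    cubes at iso-level 0.5; vertices come back in mm.  Empty score regions
    yield no surface.  Watertightness is checked and recorded, not required.
    """
    import trimesh

    if volume.data.size == 0:
        return []
    scores = volume.score_field()
    vs = np.asarray(volume.voxel_size)
    surfaces: list[ScoreSurface] = []
    for score in range(max(0, min_score), 5):
        binary = scores == score
        if not binary.any():
            continue
        # 2x supersampling puts the iso-contour on the voxel boundary instead
        # of collapsing single voxels to octahedra, so enclosed mesh volume
        # approximates the voxel-count volume
        up = binary
        for ax in range(3):
            up = np.repeat(up, 2, axis=ax)
        padded = np.pad(up, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=tuple(vs / 2)
        )
        verts = verts - vs / 2 - vs / 4  # undo pad, align supersample centers
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        surfaces.append(
            ScoreSurface(score, verts, faces, color_for_score(score).rgb,
                         watertight=bool(mesh.is_watertight))
        )
    return surfaces


def mesh_volume(surface: ScoreSurface) -> float:
    """Enclosed volume (mm^3) of a score surface."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces, process=False)
    return float(abs(mesh.volume))


def render_slice(volume: LabelVolume, slice_index: int) -> np.ndarray:
    """RGB render of one coronal slice: score colors over black background."""
    n = volume.data.shape[volume.ap_axis]
    if not (0 <= slice_index < n):
        raise VolumeError(f"slice index {slice_index} out of range 0..{n - 1}")
    plane = np.take(volume.data, slice_index, axis=volume.ap_axis)
    rgb = np.zeros(plane.shape + (3,), dtype=np.uint8)
    for label, entry in volume.label_table.items():
        rgb[plane == label] = color_for_score(entry.effective_score).rgb
    return rgb


# --- IO -----------------------------------------------------------------------


def write_volume(volume: LabelVolume, stem) -> dict[str, str]:
    """NIfTI-1 export with a JSON label-table sidecar and a FreeSurfer-style LUT."""
    import nibabel as nib

    stem = str(stem)
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.int16), affine)
    nii_path = f"{stem}.nii"
    nib.save(img, nii_path)

    sidecar = {
        "voxel_size_mm": list(volume.voxel_size),
        "axes": {
            "ap_axis": volume.ap_axis,
            "thickness_axis": volume.thickness_axis,
            "ml_axis": volume.ml_axis,
            "pial_side": volume.pial_side,
        },
        "hemisphere": volume.hemisphere,
        "labels": {
            str(lb): {"unit": e.unit, "level": e.level, "score": e.score}
            for lb, e in volume.label_table.items()
        },
    }
    json_path = f"{stem}.json"
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)

    lut_path = f"{stem}_lut.txt"
    with open(lut_path, "w") as fh:
        fh.write("# label name R G B A\n")
        for lb, e in sorted(volume.label_table.items()):
            r, g, b = color_for_score(e.effective_score).rgb
            fh.write(f"{lb} {e.unit}_L{e.level}_SQ{e.effective_score} {r} {g} {b} 0\n")
    return {"nifti": nii_path, "sidecar": json_path, "lut": lut_path}


def read_volume(nii_path, sidecar_path=None) -> LabelVolume:
    """Round-trip loader for :func:`write_volume` output."""
    import nibabel as nib

    nii_path = str(nii_path)
    if sidecar_path is None:
        sidecar_path = nii_path[: -len(".nii")] + ".json"
    img = nib.load(nii_path)
    data = np.asarray(img.dataobj).astype(np.int16)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    table = {
        int(lb): LabelEntry(unit=d["unit"], level=d["level"], score=d["score"])
        for lb, d in meta["labels"].items()
    }
    ax = meta["axes"]
    return LabelVolume(
        data, tuple(meta["voxel_size_mm"]), table,
        ap_axis=ax["ap_axis"], thickness_axis=ax["thickness_axis"],
        ml_axis=ax["ml_axis"], pial_side=ax["pial_side"],
        hemisphere=meta.get("hemisphere", ""),
    )


def write_surface_ply(surface: ScoreSurface, path, stl: bool = False) -> str:
    """Write one score surface as PLY with per-face color (or colorless STL)."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces, process=False)
    if not stl:
        mesh.visual.face_colors = np.tile(
            np.array(list(surface.color) + [255], dtype=np.uint8), (len(mesh.faces), 1)
        )
    mesh.export(str(path))
    return str(path)
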