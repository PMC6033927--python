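"""Containers and I/O for determinant fields, label atlases and volume tables.

Deformation-based morphometry encodes each scan as a 3-D field of
log-Jacobian determinants over a common study space: the *absolute*
determinant includes the global (affine) brain scaling, the *relative*
determinant only the local deformation.  Structure volumes follow by
summing ``voxel_volume * exp(logdet)`` over atlas labels.

Images travel as NIfTI-1 (via nibabel), tables as UTF-8 CSV, atlas name
tables as two-column TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DeterminantField",
    "LabelAtlas",
    "TABLE_COLUMNS",
    "validate_volume_table",
    "structure_volumes_from_field",
    "relative_volume",
    "write_field",
    "read_field",
    "write_atlas",
    "read_atlas",
    "write_volume_table",
    "read_volume_table",
]

TABLE_COLUMNS = [
    "mouse_id",
    "sex",
    "age_days",
    "timepoint_index",
    "structure",
    "volume_mm3",
    "brain_volume_mm3",
]


@dataclasses.dataclass
class DeterminantField:
    """Log-Jacobian determinant field for one scan.

    ``kind`` is ``"absolute"`` (global + local transform) or ``"relative"``
    (local only); for one scan absolute - relative is spatially constant
    and equals the log global brain scale.
    """

    values: np.ndarray
    kind: str
    voxel_volume: float
    mouse_id: str
    sex: str
    age_days: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("determinant field must be a 3-D array")
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"kind must be 'absolute' or 'relative', got {self.kind!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("determinant field contains non-finite values")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclasses.dataclass
class LabelAtlas:
    """Integer label image plus a label -> structure-name table.

    Label 0 is reserved for background and is excluded from brain volume.
    """

    labels: np.ndarray
    names: dict[int, str]
    voxel_volume: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels absent from the atlas image: {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != 0


def validate_volume_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format structure-volume table contract."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table missing required column(s): {missing}")
    if (table["volume_mm3"] <= 0).any():
        raise ValueError("volume_mm3 must be positive")
    if (table["brain_volume_mm3"] < table["volume_mm3"]).any():
        raise ValueError("brain_volume_mm3 must be >= volume_mm3")
    dup = table.duplicated(subset=["mouse_id", "timepoint_index", "structure"])
    if dup.any():
        raise ValueError("duplicate (mouse, timepoint, structure) rows")
    return table


def structure_volumes_from_field(field: DeterminantField, atlas: LabelAtlas,
                                 timepoint_index: int = 0) -> pd.DataFrame:
    """Per-structure volumes from an absolute determinant field.

    volume(structure) = sum over labelled voxels of voxel_volume * exp(logdet);
    brain volume is the same sum over all non-background labels.
    """
    if field.kind != "absolute":
        raise ValueError("structure volumes require an absolute determinant field")
    if field.values.shape != atlas.labels.shape:
        raise ValueError(
            f"field shape {field.values.shape} does not match atlas {atlas.labels.shape}"
        )
    expdet = np.exp(field.values)
    brain = float(atlas.voxel_volume * expdet[atlas.brain_mask].sum())
    rows = []
    for label, name in sorted(atlas.names.items()):
        m = atlas.labels == label
        if not m.any():
            raise ValueError(f"label {label} ({name}) has zero voxels")
        vol = float(atlas.voxel_volume * expdet[m].sum())
        rows.append(
            dict(
                mouse_id=field.mouse_id,
                sex=field.sex,
                age_days=field.age_days,
                timepoint_index=timepoint_index,
                structure=name,
                volume_mm3=vol,
                brain_volume_mm3=brain,
            )
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def relative_volume(volume_mm3, brain_volume_mm3):
    """Structure volume as a percent of whole-brain volume."""
    brain = np.asarray(brain_volume_mm3, dtype=float)
    if (brain <= 0).any():
        raise ValueError("brain volume must be positive")
    return 100.0 * np.asarray(volume_mm3, dtype=float) / brain


def smooth_field(field: DeterminantField, fwhm_voxels: float) -> DeterminantField:
    """Gaussian pre-smoothing of a determinant field (optional, default off
    everywhere: no smoothing is assumed by the statistical pipeline)."""
    from scipy import ndimage

    if fwhm_voxels <= 0:
        return field
    sigma = fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return DeterminantField(
        values=ndimage.gaussian_filter(field.values, sigma),
        kind=field.kind, voxel_volume=field.voxel_volume,
        mouse_id=field.mouse_id, sex=field.sex, age_days=field.age_days)


# ---------------------------------------------------------------------------
# NIfTI / CSV / TSV round-trips

def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_field(field: DeterminantField, path) -> None:
    voxel_size = field.voxel_volume ** (1.0 / 3.0)
    img = nib.Nifti1Image(field.values.astype(np.float64), _affine(voxel_size))
    img.header["descrip"] = (
        f"kind={field.kind};mouse={field.mouse_id};sex={field.sex};age={field.age_days:g}"
    ).encode()
    nib.save(img, str(path))


def read_field(path) -> DeterminantField:
    img = nib.load(str(path))
    descrip = bytes(img.header["descrip"]).decode(errors="replace").rstrip("\x00")
    meta = {}
    for part in descrip.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            meta[k] = v
    for key in ("kind", "mouse", "sex", "age"):
        if key not in meta:
            raise ValueError(f"NIfTI descrip metadata missing field {key!r}: {descrip!r}")
    voxel_size = float(img.affine[0, 0])
    return DeterminantField(
        values=np.asarray(img.dataobj, dtype=float),
        kind=meta["kind"],
        voxel_volume=voxel_size**3,
        mouse_id=meta["mouse"],
        sex=meta["sex"],
        age_days=float(meta["age"]),
    )


def write_atlas(atlas: LabelAtlas, image_path, names_path) -> None:
    voxel_size = atlas.voxel_volume ** (1.0 / 3.0)
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(voxel_size))
    nib.save(img, str(image_path))
    with open(names_path, "w", encoding="utf-8") as fh:
        for label, name in sorted(atlas.names.items()):
            fh.write(f"{label}\t{name}\n")


def read_atlas(image_path, names_path) -> LabelAtlas:
    img = nib.load(str(image_path))
    names = {}
    for i, line in enumerate(Path(names_path).read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"atlas name table line {i + 1} is not 'label<TAB>name': {line!r}")
        names[int(parts[0])] = parts[1]
    voxel_size = float(img.affine[0, 0])
    return LabelAtlas(
        labels=np.asarray(img.dataobj).astype(np.int32),
        names=names,
        voxel_volume=voxel_size**3,
    )


def write_volume_table(table: pd.DataFrame, path) -> None:
    validate_volume_table(table)
    table.to_csv(path, index=False)


def read_volume_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_volume_table(table)
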