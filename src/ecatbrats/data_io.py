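"""Reading, writing and preprocessing of BraTS-style multi-modal MRI cases.

A case consists of four co-registered 3D MRI modalities (T1, T1-contrast,
T2, T2-FLAIR) plus an optional integer label volume.  Integer tumour labels
follow the BraTS convention — 1: necrotic core, 2: oedema, 4: enhancing
tumour — and are expanded into three overlapping binary evaluation
subregions: whole tumour (WT = 1∪2∪4), tumour core (TC = 1∪4) and enhancing
tumour (ET = 4), which are nested ET ⊆ TC ⊆ WT.

Axis order is (channel, z, y, x) with 0-based indices throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("t1", "t1c", "t2", "flair")
REGIONS = ("WT", "TC", "ET")

#: BraTS label codes -> set of subregions the code belongs to.
DEFAULT_CODE_TABLE: Mapping[int, tuple[str, ...]] = {
    0: (),
    1: ("WT", "TC"),        # necrotic / non-enhancing core
    2: ("WT",),             # peritumoural oedema
    4: ("WT", "TC", "ET"),  # enhancing tumour
}


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclass
class MultiModalVolume:
    """Four co-registered modalities on one voxel grid.

    intensities: float array (4, D, H, W); spacing: mm per (z, y, x) axis;
    affine: 4x4 voxel-to-world map of the shared grid.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality_order: tuple[str, ...] = MODALITIES

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 4 or self.intensities.shape[0] != 4:
            raise ValueError(
                f"expected (4, D, H, W) intensities, got {self.intensities.shape}")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]


@dataclass
class SubregionMask:
    """Binary channels for the three overlapping subregions (WT, TC, ET)."""

    channels: np.ndarray
    region_order: tuple[str, ...] = REGIONS

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError(f"expected (3, D, H, W) mask, got {self.channels.shape}")
        vals = np.unique(self.channels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be binary, found {vals}")
        self.channels = self.channels.astype(np.uint8)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    def nesting_ok(self) -> bool:
        """True when ET ⊆ TC ⊆ WT holds voxel-wise."""
        wt, tc, et = self.channels
        return bool(np.all(et <= tc) and np.all(tc <= wt))

    def check_nesting(self) -> None:
        if not self.nesting_ok():
            wt, tc, et = self.channels
            n_bad = int(np.sum(et > tc) + np.sum(tc > wt))
            raise ValueError(
                f"subregion nesting ET ⊆ TC ⊆ WT violated at {n_bad} voxel(s)")


@dataclass
class CaseRecord:
    case_id: str
    volume: MultiModalVolume
    mask: SubregionMask | None = None

    def __post_init__(self):
        if self.mask is not None and self.mask.grid_shape != self.volume.grid_shape:
            raise GridMismatchError(
                f"case {self.case_id}: mask grid {self.mask.grid_shape} != "
                f"volume grid {self.volume.grid_shape}")


def labels_to_subregions(labels: np.ndarray,
                         code_table: Mapping[int, tuple[str, ...]] = DEFAULT_CODE_TABLE
                         ) -> SubregionMask:
    """Expand an integer label volume to the overlapping (WT, TC, ET) channels.

    Unknown codes raise, listing each offending code with its voxel count.
    """
    labels = np.asarray(labels)
    codes, counts = np.unique(labels, return_counts=True)
    unknown = [(int(c), int(n)) for c, n in zip(codes, counts) if int(c) not in code_table]
    if unknown:
        desc = ", ".join(f"code {c} ({n} voxels)" for c, n in unknown)
        raise ValueError(f"unknown label codes: {desc}")
    channels = np.zeros((3,) + labels.shape, dtype=np.uint8)
    for code, regions in code_table.items():
        if not regions:
            continue
        where = labels == code
        for region in regions:
            channels[REGIONS.index(region)][where] = 1
    return SubregionMask(channels)


def subregions_to_labels(mask: SubregionMask) -> np.ndarray:
    """Collapse (WT, TC, ET) channels back to BraTS integer codes.

    Inverse of :func:`labels_to_subregions` on well-nested masks: ET -> 4,
    TC \\ ET -> 1, WT \\ TC -> 2.
    """
    wt, tc, et = mask.channels
    labels = np.zeros(wt.shape, dtype=np.int16)
    labels[wt == 1] = 2
    labels[tc == 1] = 1
    labels[et == 1] = 4
    return labels


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine)


def load_case(modality_paths: Sequence[str | Path],
              label_path: str | Path | None = None,
              case_id: str | None = None,
              code_table: Mapping[int, tuple[str, ...]] = DEFAULT_CODE_TABLE
              ) -> CaseRecord:
    """Load four modality NIfTI volumes (T1, T1c, T2, FLAIR order) and an
    optional label volume into a :class:`CaseRecord`."""
    if len(modality_paths) != 4:
        raise ValueError(f"expected 4 modality paths, got {len(modality_paths)}")
    volumes, affines = [], []
    for p in modality_paths:
        data, affine = _load_nifti(p)
        volumes.append(np.asarray(data, dtype=np.float32))
        affines.append(affine)
    shapes = [v.shape for v in volumes]
    if len(set(shapes)) != 1:
        listing = ", ".join(f"{Path(p).name}: {s}" for p, s in zip(modality_paths, shapes))
        raise GridMismatchError(f"modality grids differ: {listing}")

    spacing = tuple(float(s) for s in np.sqrt((affines[0][:3, :3] ** 2).sum(axis=0))[::-1])
    volume = MultiModalVolume(np.stack(volumes), spacing=spacing, affine=affines[0])

    mask = None
    if label_path is not None:
        labels, _ = _load_nifti(label_path)
        if labels.shape != shapes[0]:
            raise GridMismatchError(
                f"label grid {labels.shape} != modality grid {shapes[0]}")
        mask = labels_to_subregions(np.rint(labels).astype(np.int64), code_table)

    if case_id is None:
        case_id = Path(modality_paths[0]).stem.replace(".nii", "")
    return CaseRecord(case_id=case_id, volume=volume, mask=mask)


def save_case(case: CaseRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write a case as one NIfTI per modality plus an integer label volume.

    Returns the mapping of written roles ('t1', ..., 'seg') to paths, matching
    the layout :func:`load_case` consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    affine = case.volume.affine
    for i, name in enumerate(case.volume.modality_order):
        p = out_dir / f"{case.case_id}_{name}.nii"
        nib.save(nib.Nifti1Image(case.volume.intensities[i], affine), str(p))
        paths[name] = p
    if case.mask is not None:
        p = out_dir / f"{case.case_id}_seg.nii"
        nib.save(nib.Nifti1Image(subregions_to_labels(case.mask), affine), str(p))
        paths["seg"] = p
    return paths


def write_manifest(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write a case manifest (case_id, 4 modality paths, optional seg path)."""
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"case_id", *MODALITIES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_manifest_cases(path: str | Path) -> list[CaseRecord]:
    df = read_manifest(path)
    base = Path(path).parent
    cases = []
    for _, row in df.iterrows():
        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p
        label = resolve(row["seg"]) if "seg" in row and pd.notna(row.get("seg")) else None
        cases.append(load_case([resolve(row[m]) for m in MODALITIES],
                               label_path=label, case_id=str(row["case_id"])))
    return cases


def _zscore_foreground(channel: np.ndarray) -> np.ndarray:
    fg = channel != 0
    if not fg.any():
        return np.zeros_like(channel)
    mu = channel[fg].mean()
    sd = channel[fg].std()
    if sd == 0:
        logger.warning("zero-variance modality channel; normalised to zeros")
        out = np.zeros_like(channel)
        return out
    out = np.zeros_like(channel)
    out[fg] = (channel[fg] - mu) / sd
    return out


def _centre_crop_pad(arr: np.ndarray, target: tuple[int, int, int],
                     ) -> np.ndarray:
    """Centre crop and/or zero-pad trailing 3 axes of (C, D, H, W) to target."""
    out = arr
    for ax, t in zip((1, 2, 3), target):
        s = out.shape[ax]
        if s > t:
            start = (s - t) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + t)
            out = out[tuple(sl)]
        elif s < t:
            before = (t - s) // 2
            pw = [(0, 0)] * out.ndim
            pw[ax] = (before, t - s - before)
            out = np.pad(out, pw)
    return out


def preprocess(volume: MultiModalVolume,
               target_shape: tuple[int, int, int] = (96, 128, 128)
               ) -> MultiModalVolume:
    """Normalise and regrid a volume to the network's input geometry.

    Per-modality z-score over nonzero (foreground) voxels, then centre
    crop/zero-pad to ``target_shape`` (depth, height, width).  Cropping rather
    than resampling keeps label topology exact; the affine is kept for
    provenance but refers to the original grid.
    """
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target_shape must be positive, got {target_shape}")
    normed = np.stack([_zscore_foreground(c) for c in volume.intensities])
    regridded = _centre_crop_pad(normed, tuple(target_shape))
    return replace(volume, intensities=regridded)


def preprocess_case(case: CaseRecord,
                    target_shape: tuple[int, int, int] = (96, 128, 128)
                    ) -> CaseRecord:
    """Apply :func:`preprocess` to the volume and the identical geometric
    transform (nearest-neighbour semantics: crop/pad moves whole voxels) to
    the mask."""
    volume = preprocess(case.volume, target_shape)
    mask = case.mask
    if mask is not None:
        mask = SubregionMask(_centre_crop_pad(mask.channels, tuple(target_shape)))
    return CaseRecord(case.case_id, volume, mask)


def split_cases(case_ids: Sequence[str], fractions: tuple[float, float, float],
                seed: int) -> dict[str, list[str]]:
    """Deterministic seeded train/val/test split by case id."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {"train": ids[:n_train],
            "val": ids[n_train:n_train + n_val],
            "test": ids[n_train + n_val:]}
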