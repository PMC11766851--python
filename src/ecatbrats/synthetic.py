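"""Synthetic multi-modal phantoms with nested tumour subregions.

Each phantom is a 4-channel volume (T1, T1c, T2, FLAIR) holding a background
tissue intensity plus three concentric (optionally ellipsoidal) tumour
subregions — whole tumour, tumour core, enhancing tumour — with
modality-dependent contrast offsets and additive noise.  The ground-truth
mask is the exact noiseless geometry, so segmentation quality can be scored
against a known answer.  All randomness flows through one seeded generator;
the same spec and seed always reproduce the same case bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import (CaseRecord, MultiModalVolume, SubregionMask,
                      save_case, write_manifest)

__all__ = ["PhantomSpec", "CohortJitter", "generate_phantom",
           "generate_cohort", "save_cohort"]

#: Per-modality additive contrast for (WT, TC, ET) membership, rows ordered
#: (T1, T1c, T2, FLAIR).  Offsets stack along the nesting, mimicking the
#: qualitative appearance of glioma sub-compartments: FLAIR/T2 bright over
#: the oedema-dominated whole tumour, T1c bright over enhancing tumour, T1
#: mildly hypointense across the lesion.
DEFAULT_CONTRAST = np.array([
    [-0.20, -0.10, 0.10],   # T1
    [0.00, 0.10, 0.80],     # T1c
    [0.60, 0.20, 0.10],     # T2
    [0.80, 0.30, 0.10],     # FLAIR
])


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic case."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    centre: tuple[float, float, float] | None = None  # None -> grid centre
    radii: tuple[float, float, float] = (14.0, 9.0, 5.0)  # r_WT >= r_TC >= r_ET
    modality_contrast: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTRAST.copy())
    background: float = 1.0
    noise_sigma: float = 0.10
    noise_model: str = "gaussian"          # or "salt_pepper"
    salt_pepper_fraction: float = 0.01
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)  # ellipsoid axes
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        r = tuple(float(x) for x in self.radii)
        if not (r[0] >= r[1] >= r[2] >= 0):
            raise ValueError(
                f"radii must be nonincreasing WT >= TC >= ET >= 0, got {r}")
        self.radii = r
        self.modality_contrast = np.asarray(self.modality_contrast, dtype=float)
        if self.modality_contrast.shape != (4, 3):
            raise ValueError("modality_contrast must be a 4x3 matrix")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "salt_pepper"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _ellipsoid(grid_shape, centre, radius, axis_ratios) -> np.ndarray:
    if radius <= 0:
        return np.zeros(grid_shape, dtype=np.uint8)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in grid_shape),
                             indexing="ij")
    d2 = sum(((g - c) / (radius * a)) ** 2
             for g, c, a in zip((zz, yy, xx), centre, axis_ratios))
    return (d2 <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, case_id: str | None = None) -> CaseRecord:
    """Render one phantom case from its spec (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    centre = (tuple((s - 1) / 2.0 for s in spec.grid_shape)
              if spec.centre is None else tuple(spec.centre))

    masks = np.stack([_ellipsoid(spec.grid_shape, centre, r, spec.axis_ratios)
                      for r in spec.radii])  # (WT, TC, ET) nested by radii order
    volume = np.full((4,) + tuple(spec.grid_shape), spec.background, dtype=np.float64)
    for m in range(4):
        for r in range(3):  # offsets stack along the nesting
            volume[m] += spec.modality_contrast[m, r] * masks[r]

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            volume = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
        else:  # salt & pepper: a fraction of voxels driven to extremes
            lo, hi = volume.min(), volume.max()
            flip = rng.random(volume.shape) < spec.salt_pepper_fraction
            salt = rng.random(volume.shape) < 0.5
            volume = np.where(flip & salt, hi + spec.noise_sigma, volume)
            volume = np.where(flip & ~salt, lo - spec.noise_sigma, volume)

    if case_id is None:
        case_id = f"phantom_{spec.seed:06d}"
    return CaseRecord(case_id=case_id,
                      volume=MultiModalVolume(volume.astype(np.float32)),
                      mask=SubregionMask(masks))


@dataclass
class CohortJitter:
    """Uniform per-case perturbation ranges applied to a base spec."""

    radius_scale: tuple[float, float] = (0.7, 1.3)
    centre_shift: float = 4.0            # max |voxel| shift per axis
    contrast_scale: tuple[float, float] = (0.8, 1.2)
    noise_sigma: tuple[float, float] | None = None  # None -> keep base value

    def __post_init__(self):
        for name, rng_ in (("radius_scale", self.radius_scale),
                           ("contrast_scale", self.contrast_scale),
                           ("noise_sigma", self.noise_sigma)):
            if rng_ is not None and rng_[1] < rng_[0]:
                raise ValueError(f"empty range for {name}: {rng_}")


def sample_spec(base: PhantomSpec, jitter: CohortJitter,
                rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Draw one jittered spec; consumes a fixed number of variates from ``rng``."""
    rs = rng.uniform(*jitter.radius_scale)
    shift = rng.uniform(-jitter.centre_shift, jitter.centre_shift, size=3)
    cs = rng.uniform(*jitter.contrast_scale)
    sigma = (base.noise_sigma if jitter.noise_sigma is None
             else rng.uniform(*jitter.noise_sigma))
    centre = (tuple((s - 1) / 2.0 for s in base.grid_shape)
              if base.centre is None else base.centre)
    return replace(
        base,
        radii=tuple(r * rs for r in base.radii),
        centre=tuple(c + d for c, d in zip(centre, shift)),
        modality_contrast=base.modality_contrast * cs,
        noise_sigma=float(sigma),
        seed=seed,
    )


def generate_cohort(n: int, base_spec: PhantomSpec | None = None,
                    jitter: CohortJitter | None = None,
                    seed: int = 0) -> list[CaseRecord]:
    """Generate ``n`` phantoms with jittered geometry/contrast/noise.

    Deterministic: the cohort stream and every per-case seed derive from
    ``seed`` alone.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base_spec = base_spec if base_spec is not None else PhantomSpec()
    jitter = jitter if jitter is not None else CohortJitter()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        # per-case noise seed offsets the base seed so that a zero-jitter
        # cohort of one reproduces generate_phantom(base_spec) exactly
        case_seed = int((base_spec.seed + i) % (2 ** 31 - 1))
        spec_i = sample_spec(base_spec, jitter, rng, case_seed)
        cases.append(generate_phantom(spec_i, case_id=f"case_{i:04d}"))
    return cases


def save_cohort(cases: Sequence[CaseRecord], out_dir: str | Path) -> Path:
    """Write a cohort as per-case NIfTI files plus a TSV manifest; returns the
    manifest path (the layout :func:`ecatbrats.data_io.load_manifest_cases`
    consumes)."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        paths = save_case(case, out_dir / case.case_id)
        row = {"case_id": case.case_id}
        row.update({k: str(p.relative_to(out_dir)) for k, p in paths.items()})
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
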