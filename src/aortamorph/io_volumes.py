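"""Label-volume I/O, cohort tables and segmentation-comparison metrics.

The pipeline starts at multi-label segmentations of the dissected aorta:
an integer voxel grid in which the true lumen (TL), circulating false
lumen (CFL) and thrombus (TH) each carry their own code.  Volumes are
always computed in world units (voxel count x voxel volume), never in
voxel counts, so anisotropic spacing is handled uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .errors import LabelValidationError

#: Default voxel codes for the three aortic compartments.
DEFAULT_LABEL_MAP = {"background": 0, "TL": 1, "CFL": 2, "TH": 3}

#: Labels that together form the false lumen.
FALSE_LUMEN_LABELS = ("CFL", "TH")

#: Labels that together form the whole aorta.
AORTA_LABELS = ("TL", "CFL", "TH")


@dataclass
class LabelVolume:
    """A 3D integer label map with world-space geometry.

    Parameters
    ----------
    grid : ndarray of int, shape (nx, ny, nz)
        Voxel label codes.
    spacing : tuple of float
        Voxel edge lengths in mm, all > 0.
    affine : ndarray, shape (4, 4)
        Voxel-index-to-world map in mm (NIfTI convention).
    label_map : dict
        Name -> integer code; must contain background, TL, CFL, TH.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            rounded = np.rint(self.grid)
            if not np.allclose(self.grid, rounded, atol=1e-6):
                raise LabelValidationError(np.unique(self.grid))
            self.grid = rounded.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        declared = set(int(v) for v in self.label_map.values())
        present = set(int(v) for v in np.unique(self.grid))
        bad = present - declared
        if bad:
            raise LabelValidationError(bad)

    # -- geometry ----------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_coordinates(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm coordinates to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    # -- masks -------------------------------------------------------------

    def mask(self, *labels: str) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        codes = [self.label_map[name] for name in labels]
        return np.isin(self.grid, codes)

    @property
    def union_mask(self) -> np.ndarray:
        """TL ∪ CFL ∪ TH: the whole-aorta mask."""
        return self.mask(*AORTA_LABELS)

    @property
    def false_lumen_mask(self) -> np.ndarray:
        """CFL ∪ TH: the false-lumen mask."""
        return self.mask(*FALSE_LUMEN_LABELS)

    def label_volume_ml(self, *labels: str) -> float:
        """Volume of the union of the named labels in mL."""
        return float(self.mask(*labels).sum()) * self.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_label_volume(path, label_map: dict | None = None) -> LabelVolume:
    """Read a NIfTI label volume, validating codes against ``label_map``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    LabelValidationError
        If the data are non-integer or contain undeclared codes.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(
        grid=data,
        spacing=spacing,
        affine=np.asarray(img.affine),
        label_map=dict(label_map or DEFAULT_LABEL_MAP),
    )


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a :class:`LabelVolume` as int16 NIfTI."""
    img = nib.Nifti1Image(vol.grid.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_cohort(path, outcome_col: str = "outcome") -> pd.DataFrame:
    """Read a cohort CSV and validate the binary outcome column."""
    df = pd.read_csv(path)
    if outcome_col in df.columns:
        values = set(df[outcome_col].dropna().unique())
        if not values <= {0, 1}:
            raise ValueError(
                f"outcome column {outcome_col!r} must be binary 0/1, "
                f"found values {sorted(values)}"
            )
    return df


# ---------------------------------------------------------------------------
# Segmentation-comparison metrics
# ---------------------------------------------------------------------------

def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a| + |b|) of two binary masks.

    Two empty masks score 1.0: both raters agree the structure (for
    instance a thrombus) is absent.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def volume_error_metrics(reference, candidate) -> dict:
    """Paired volume agreement: mean absolute error, bias and bias p-value.

    ``bias_p`` is the two-sided paired t-test p-value for mean(candidate -
    reference) = 0; it is 1.0 when every pair agrees exactly.

    Returns a dict with keys ``MAE``, ``bias``, ``bias_p`` (all in the
    units of the inputs, typically mL).
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape or ref.ndim != 1:
        raise ValueError("reference and candidate must be equal-length 1D arrays")
    if ref.size < 2:
        raise ValueError("need at least 2 paired cases")
    diff = cand - ref
    mae = float(np.mean(np.abs(diff)))
    bias = float(np.mean(diff))
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_rel(cand, ref)
        p = float(p) if np.isfinite(p) else 1.0
    return {"MAE": mae, "bias": bias, "bias_p": p}


def dice_table(
    vol_a: LabelVolume,
    vol_b: LabelVolume,
    labels=AORTA_LABELS,
    skip_absent: bool = False,
) -> dict:
    """Per-label Dice between two segmentations of the same scan.

    With ``skip_absent`` the score is reported as NaN when the label is
    empty in both volumes (the convention used when overlap metrics are
    restricted to cases where the structure exists), otherwise the
    empty/empty pair scores 1.0.
    """
    out = {}
    for name in labels:
        a, b = vol_a.mask(name), vol_b.mask(name)
        if skip_absent and not a.any() and not b.any():
            out[name] = float("nan")
        else:
            out[name] = dice_coefficient(a, b)
    out["aorta"] = dice_coefficient(vol_a.union_mask, vol_b.union_mask)
    return out
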