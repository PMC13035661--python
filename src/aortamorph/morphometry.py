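"""Cross-sectional diameter profile, D_max and global volume measures.

Diameters are measured on planes orthogonal to the local centerline
tangent ("double-oblique" planes in clinical reading), not on axial
slices: for each centerline sample the whole-aorta mask is resampled on
such a plane, the connected component containing the centerline point is
kept, and its maximal Feret diameter is recorded.  D_max is the maximum
of the profile over samples outside an end-guard zone, where oblique
cuts through the open vessel ends would otherwise inflate the Feret
diameter.

Component volumes are voxel counts times voxel volume (mL), so the
conservation identities Ao_Glo = TL + CFL + TH and FL_Glo = CFL + TH
hold exactly on every input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .centerline import Centerline
from .errors import PlaneExtentError
from .io_volumes import LabelVolume


@dataclass
class DiameterProfile:
    """Diameter (mm) per centerline arc-length position (mm).

    ``valid`` flags positions usable for peak search; positions inside
    the end guard or with an empty cross-section are flagged invalid but
    never dropped, so the profile stays aligned with the centerline.
    """

    arclen: np.ndarray
    diameter: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.arclen = np.asarray(self.arclen, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.arclen) == len(self.diameter) == len(self.valid)):
            raise ValueError("arclen, diameter and valid must have equal length")


@dataclass
class AortaMeasures:
    """One scan's morphometric marker vector (mm / mL units fixed)."""

    Dmax: float
    Dmax_position: float
    Ao_length: float
    V_TL: float
    V_CFL: float
    V_Th: float
    Ao_Glo: float
    FL_Glo: float
    FL_Loc: float | None
    FL_Glo_over_Ao_Glo: float
    FL_Glo_over_Ao_length: float

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# orthogonal cross-sections
# ---------------------------------------------------------------------------

def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal in-plane frames (u, v) per sample.

    The initial u is any unit vector orthogonal to the first tangent; at
    each step u is re-orthogonalised against the new tangent, which keeps
    the frame rotation-minimising and free of sudden flips.
    """
    n = len(tangents)
    u = np.empty_like(tangents)
    v = np.empty_like(tangents)
    t0 = tangents[0]
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, t0)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u0 = trial - np.dot(trial, t0) * t0
    u[0] = u0 / np.linalg.norm(u0)
    v[0] = np.cross(t0, u[0])
    for i in range(1, n):
        t = tangents[i]
        ui = u[i - 1] - np.dot(u[i - 1], t) * t
        nrm = np.linalg.norm(ui)
        if nrm < 1e-9:  # near-degenerate turn; restart frame
            trial = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(trial, t)) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            ui = trial - np.dot(trial, t) * t
            nrm = np.linalg.norm(ui)
        u[i] = ui / nrm
        v[i] = np.cross(t, u[i])
    return u, v


def _section_mask(
    vol: LabelVolume,
    mask_f: np.ndarray,
    center: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    extent: float,
    res: float,
) -> np.ndarray:
    """Resample a binary mask on the orthogonal plane; returns 2D bool."""
    half = extent / 2.0
    coords_1d = np.arange(-half, half + res / 2, res)
    a, b = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    pts = center + a[..., None] * u + b[..., None] * v
    idx = vol.voxel_coordinates(pts.reshape(-1, 3)).T
    sampled = map_coordinates(mask_f, idx, order=1, mode="constant", cval=0.0)
    return sampled.reshape(a.shape) >= 0.5


def diameter_profile(
    vol: LabelVolume,
    cl: Centerline,
    end_guard: float = 10.0,
    plane_extent: float = 100.0,
    plane_res: float = 0.5,
) -> DiameterProfile:
    """Maximal Feret diameter of the orthogonal aortic cross-section per sample.

    Parameters
    ----------
    vol : LabelVolume
    cl : Centerline
        Centerline extracted from the same volume.
    end_guard : float
        Samples within this arc length (mm) of either end are flagged
        invalid for peak search (oblique end-cap cuts inflate diameters);
        volumes are unaffected.
    plane_extent : float
        Side length (mm) of the square sampling plane; must exceed twice
        the largest expected diameter.
    plane_res : float
        In-plane sampling resolution (mm); the mask is interpolated
        bilinearly and thresholded at 0.5.

    Raises
    ------
    PlaneExtentError
        If a cross-section reaches the plane border.
    """
    if end_guard < 0:
        raise ValueError("end_guard must be >= 0")
    mask_f = vol.union_mask.astype(np.float32)
    u, v = _transport_frames(cl.tangents)
    n = len(cl.points)
    diameters = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    center_pix = int(round((plane_extent / 2.0) / plane_res))

    for i in range(n):
        section = _section_mask(
            vol, mask_f, cl.points[i], u[i], v[i], plane_extent, plane_res
        )
        if not section[center_pix, center_pix]:
            # tolerate sub-voxel offsets: search a small neighbourhood
            lo = max(center_pix - 2, 0)
            hi = center_pix + 3
            patch = section[lo:hi, lo:hi]
            if patch.any():
                di, dj = np.argwhere(patch)[0]
                ci, cj = lo + di, lo + dj
            else:
                warnings.warn(f"empty cross-section at arclen {cl.arclen[i]:.1f} mm")
                valid[i] = False
                diameters[i] = np.nan
                continue
        else:
            ci, cj = center_pix, center_pix
        labels = cc_label(section, connectivity=1)
        comp = labels == labels[ci, cj]
        if (
            comp[0, :].any()
            or comp[-1, :].any()
            or comp[:, 0].any()
            or comp[:, -1].any()
        ):
            raise PlaneExtentError(
                f"cross-section at arclen {cl.arclen[i]:.1f} mm reaches the "
                f"{plane_extent:.0f} mm plane border; increase plane_extent"
            )
        props = regionprops(comp.astype(np.uint8))[0]
        diameters[i] = props.feret_diameter_max * plane_res

    in_guard = (cl.arclen < end_guard) | (cl.arclen > cl.length - end_guard)
    valid &= ~in_guard
    return DiameterProfile(arclen=cl.arclen.copy(), diameter=diameters, valid=valid)


# ---------------------------------------------------------------------------
# global measures
# ---------------------------------------------------------------------------

def global_measures(
    vol: LabelVolume, cl: Centerline, profile: DiameterProfile
) -> AortaMeasures:
    """Populate the per-scan marker vector (FL_Loc left unset).

    Volumes are label voxel counts x voxel volume / 1000 (mL); D_max is
    the maximum of the diameter profile over valid samples.
    """
    if not profile.valid.any():
        raise ValueError("no valid diameter-profile samples")
    v_tl = vol.label_volume_ml("TL")
    v_cfl = vol.label_volume_ml("CFL")
    v_th = vol.label_volume_ml("TH")
    # summed from the per-label values so the identities hold to machine
    # identity, not just to rounding
    fl_glo = v_cfl + v_th
    ao_glo = v_tl + fl_glo

    dvalid = np.where(profile.valid, profile.diameter, -np.inf)
    imax = int(np.argmax(dvalid))
    return AortaMeasures(
        Dmax=float(profile.diameter[imax]),
        Dmax_position=float(profile.arclen[imax]),
        Ao_length=cl.length,
        V_TL=v_tl,
        V_CFL=v_cfl,
        V_Th=v_th,
        Ao_Glo=ao_glo,
        FL_Glo=fl_glo,
        FL_Loc=None,
        FL_Glo_over_Ao_Glo=fl_glo / ao_glo if ao_glo > 0 else 0.0,
        FL_Glo_over_Ao_length=fl_glo / cl.length,
    )
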