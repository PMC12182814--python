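"""Strain engine: velocity cine -> pixel strain maps -> AHA segmental curves.

The pipeline is Lagrangian: end-diastolic (frame 0) myocardial pixels are
treated as material points, advected through the per-frame velocity field
(forward Euler with bilinear interpolation), and the local deformation
gradient ``F`` is estimated per pixel by least squares over the displacements
of its end-diastolic neighborhood.  Strain is stretch-based engineering
strain, ``eps = sqrt(e' C e) - 1`` with ``C = F'F``, projected on the
end-diastolic radial and circumferential directions about the cavity
centroid.  Segmental curves follow the AHA convention: 6 segments on basal
and mid-ventricular slices, 4 on apical slices, apex cap excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityCine", "SliceGeometry", "SegmentMap", "SegmentCurves",
    "StrainSummary", "Trajectories", "StrainMaps", "AHA_SEGMENTS",
    "track_displacements", "compute_strain", "build_segment_map",
    "segment_curves", "summarize",
]

# Segment names ordered counterclockwise from the anterior reference
# (standard short-axis orientation: anterior at top, septum at image left).
AHA_SEGMENTS: dict[str, tuple[str, ...]] = {
    "basal": ("anterior", "anteroseptal", "inferoseptal",
              "inferior", "inferolateral", "anterolateral"),
    "mid": ("anterior", "anteroseptal", "inferoseptal",
            "inferior", "inferolateral", "anterolateral"),
    "apical": ("anterior", "septal", "inferior", "lateral"),
}


@dataclass
class VelocityCine:
    """Per-frame pixel velocity field for one short-axis slice.

    velocity : (n_frames, H, W, 2) array, mm/s, components along (row, col).
    ed_mask  : (H, W) boolean end-diastolic myocardial annulus.
    """

    velocity: np.ndarray
    ed_mask: np.ndarray
    frame_duration_ms: float
    pixel_spacing_mm: tuple[float, float]
    slice_level: str = "mid"

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.ed_mask.shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity field contains non-finite values")
        if self.n_frames < 10:
            raise ValueError(f"n_frames must be >= 10, got {self.n_frames}")
        if self.velocity.shape[1:3] != self.ed_mask.shape:
            raise ValueError("velocity and ed_mask grid shapes disagree")
        _, n_fg = ndimage.label(self.ed_mask)
        if n_fg != 1:
            raise ValueError(f"ed_mask must be a single connected ring, found {n_fg} components")
        _, n_bg = ndimage.label(~self.ed_mask)
        if n_bg != 2:
            raise ValueError(
                f"ed_mask must enclose exactly one hole (cavity); background has {n_bg} components"
            )


@dataclass
class SliceGeometry:
    """LV cavity center and anterior reference direction for one slice."""

    centroid_rc: tuple[float, float]
    anterior_reference_angle_rad: float
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        self.anterior_reference_angle_rad = float(
            np.mod(self.anterior_reference_angle_rad, 2.0 * np.pi))

    @classmethod
    def from_cine(cls, cine: VelocityCine,
                  anterior_reference_angle_rad: float = np.pi / 2) -> "SliceGeometry":
        r, c = np.nonzero(cine.ed_mask)
        return cls(centroid_rc=(float(r.mean()), float(c.mean())),
                   anterior_reference_angle_rad=anterior_reference_angle_rad,
                   slice_level=cine.slice_level)

    def validate(self, cine: VelocityCine) -> None:
        r0 = int(round(self.centroid_rc[0]))
        c0 = int(round(self.centroid_rc[1]))
        h, w = cine.ed_mask.shape
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError("geometry centroid lies outside the image")
        if cine.ed_mask[r0, c0]:
            raise ValueError("geometry centroid must lie in the cavity, not on the myocardium")
        # centroid must be in the hole, i.e. a background component not touching the border
        lab, _ = ndimage.label(~cine.ed_mask)
        border_labels = set(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
        if lab[r0, c0] in border_labels:
            raise ValueError("geometry centroid lies outside the myocardial ring")


def _pixel_angles(rc: np.ndarray, geometry: SliceGeometry,
                  pixel_spacing_mm: tuple[float, float]) -> np.ndarray:
    """Counterclockwise angle (y-up) of pixels about the centroid, in [0, 2pi)."""
    dy = -(rc[:, 0] - geometry.centroid_rc[0]) * pixel_spacing_mm[0]
    dx = (rc[:, 1] - geometry.centroid_rc[1]) * pixel_spacing_mm[1]
    return np.mod(np.arctan2(dy, dx), 2.0 * np.pi)


@dataclass
class SegmentMap:
    """Per-pixel AHA segment labels: ``labels[r, c]`` indexes ``names``, -1 outside."""

    labels: np.ndarray
    names: tuple[str, ...]
    slice_level: str

    def pixels(self, segment: int) -> np.ndarray:
        return np.argwhere(self.labels == segment)


def build_segment_map(cine: VelocityCine, geometry: SliceGeometry) -> SegmentMap:
    """Partition the ED mask into equal angular AHA sectors.

    Sector 0 starts at the anterior reference angle and sectors proceed
    counterclockwise: anterior, anteroseptal, inferoseptal, inferior,
    inferolateral, anterolateral (basal/mid) or anterior, septal, inferior,
    lateral (apical).
    """
    geometry.validate(cine)
    names = AHA_SEGMENTS[geometry.slice_level]
    n_seg = len(names)
    width = 2.0 * np.pi / n_seg
    labels = np.full(cine.ed_mask.shape, -1, dtype=int)
    rc = np.argwhere(cine.ed_mask)
    theta = _pixel_angles(rc, geometry, cine.pixel_spacing_mm)
    sector = np.minimum(
        (np.mod(theta - geometry.anterior_reference_angle_rad, 2.0 * np.pi) // width).astype(int),
        n_seg - 1,
    )
    labels[rc[:, 0], rc[:, 1]] = sector
    return SegmentMap(labels=labels, names=names, slice_level=geometry.slice_level)


@dataclass
class Trajectories:
    """Material-point trajectories of the ED-mask pixels.

    positions_mm : (n_pixels, n_frames, 2), mm, centroid-origin (row, col) frame.
    """

    pixel_rc: np.ndarray
    positions_mm: np.ndarray
    out_of_bounds: np.ndarray
    frame_duration_ms: float
    pixel_spacing_mm: tuple[float, float]
    geometry: SliceGeometry


def track_displacements(cine: VelocityCine,
                        geometry: SliceGeometry | None = None) -> Trajectories:
    """Integrate pixel trajectories through the velocity field.

    Forward Euler: ``x(k+1) = x(k) + v(x(k), k) * dt`` with bilinear
    interpolation of the velocity field inside the grid and nearest-neighbor
    extrapolation beyond it (the velocity field is defined per pixel over the
    whole slice, so points that contract into the cavity keep their local
    velocity).  Pixels whose trajectory leaves the image bounds are flagged
    and later excluded from segment averages.
    """
    cine.validate()
    if geometry is None:
        geometry = SliceGeometry.from_cine(cine)
    h, w = cine.shape
    sp = np.asarray(cine.pixel_spacing_mm, dtype=float)
    dt_s = cine.frame_duration_ms / 1000.0
    vel = cine.velocity

    pix = np.argwhere(cine.ed_mask)
    n_pix, n_frames = len(pix), cine.n_frames
    pos = pix.astype(float)                      # pixel coordinates
    positions = np.empty((n_pix, n_frames, 2))
    oob = np.zeros(n_pix, dtype=bool)
    positions[:, 0] = pos
    for k in range(n_frames - 1):
        vr = ndimage.map_coordinates(vel[k, ..., 0], pos.T, order=1, mode="nearest")
        vc = ndimage.map_coordinates(vel[k, ..., 1], pos.T, order=1, mode="nearest")
        pos = pos + np.column_stack([vr, vc]) / sp * dt_s
        oob |= ((pos[:, 0] < 0) | (pos[:, 0] > h - 1)
                | (pos[:, 1] < 0) | (pos[:, 1] > w - 1))
        positions[:, k + 1] = pos
    if oob.any():
        logger.warning("track_displacements: %d/%d trajectories left the image bounds",
                       int(oob.sum()), n_pix)

    centroid = np.asarray(geometry.centroid_rc)
    positions_mm = (positions - centroid) * sp
    return Trajectories(pixel_rc=pix, positions_mm=positions_mm, out_of_bounds=oob,
                        frame_duration_ms=cine.frame_duration_ms,
                        pixel_spacing_mm=cine.pixel_spacing_mm, geometry=geometry)


@dataclass
class StrainMaps:
    """Per-tracked-pixel strain channels; invalid pixels are flagged, not NaN-filled."""

    pixel_rc: np.ndarray
    radial: np.ndarray          # (n_pixels, n_frames)
    circumferential: np.ndarray
    valid: np.ndarray           # (n_pixels,)
    frame_duration_ms: float


def compute_strain(traj: Trajectories, geometry: SliceGeometry | None = None,
                   neighbor_radius_px: float = 2.0,
                   min_neighbors: int = 3) -> StrainMaps:
    """Estimate per-pixel radial/circumferential strain from trajectories.

    The deformation gradient at pixel i and frame k solves the least-squares
    problem ``min_F sum_j |dx_j(k) - F dX_j|^2`` over the ED neighbors j
    (radius ``neighbor_radius_px``), giving ``F = A B^{-1}`` with
    ``A = sum dx dX'`` and ``B = sum dX dX'``.  Pixels with fewer than
    ``min_neighbors`` tracked neighbors or a singular (collinear) neighborhood
    are flagged and excluded.
    """
    if geometry is None:
        geometry = traj.geometry
    pix = traj.pixel_rc
    n_pix, n_frames = traj.positions_mm.shape[:2]

    # neighbor pair lists over the ED pixel lattice
    index = -np.ones((pix[:, 0].max() + 1, pix[:, 1].max() + 1), dtype=int)
    index[pix[:, 0], pix[:, 1]] = np.arange(n_pix)
    rad = int(np.floor(neighbor_radius_px))
    offsets = [(dr, dc)
               for dr in range(-rad, rad + 1) for dc in range(-rad, rad + 1)
               if 0 < dr * dr + dc * dc <= neighbor_radius_px ** 2]
    usable = ~traj.out_of_bounds
    pi_list, pj_list = [], []
    h_idx, w_idx = index.shape
    for dr, dc in offsets:
        r2, c2 = pix[:, 0] + dr, pix[:, 1] + dc
        ok = (r2 >= 0) & (r2 < h_idx) & (c2 >= 0) & (c2 < w_idx)
        j = np.where(ok, index[np.clip(r2, 0, h_idx - 1), np.clip(c2, 0, w_idx - 1)], -1)
        keep = (j >= 0) & usable & usable[np.clip(j, 0, n_pix - 1)]
        pi_list.append(np.nonzero(keep)[0])
        pj_list.append(j[keep])
    pi = np.concatenate(pi_list)
    pj = np.concatenate(pj_list)

    X = traj.positions_mm[:, 0, :]            # ED positions, centroid origin
    dX = X[pj] - X[pi]                        # (n_pairs, 2)
    n_neighbors = np.bincount(pi, minlength=n_pix)

    B = np.zeros((n_pix, 2, 2))
    for a in range(2):
        for b in range(2):
            B[:, a, b] = np.bincount(pi, weights=dX[:, a] * dX[:, b], minlength=n_pix)
    detB = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    scale = (B[:, 0, 0] + B[:, 1, 1]) ** 2 + 1e-300
    valid = usable & (n_neighbors >= min_neighbors) & (detB / scale > 1e-8)
    n_singular = int((usable & (n_neighbors >= min_neighbors)).sum() - valid.sum()
                     + (usable & (n_neighbors < min_neighbors)).sum())
    if n_singular:
        logger.warning("compute_strain: %d pixels flagged (singular or sparse neighborhood)",
                       n_singular)

    Binv = np.zeros_like(B)
    d = np.where(valid, detB, 1.0)
    Binv[:, 0, 0] = B[:, 1, 1] / d
    Binv[:, 1, 1] = B[:, 0, 0] / d
    Binv[:, 0, 1] = -B[:, 0, 1] / d
    Binv[:, 1, 0] = -B[:, 1, 0] / d

    # ED radial / circumferential unit vectors about the centroid
    r_norm = np.linalg.norm(X, axis=1)
    r_norm = np.where(r_norm > 1e-12, r_norm, 1.0)
    e_r = X / r_norm[:, None]
    e_c = np.column_stack([-e_r[:, 1], e_r[:, 0]])

    radial = np.zeros((n_pix, n_frames))
    circ = np.zeros((n_pix, n_frames))
    for k in range(n_frames):
        dx = traj.positions_mm[pj, k, :] - traj.positions_mm[pi, k, :]
        A = np.zeros((n_pix, 2, 2))
        for a in range(2):
            for b in range(2):
                A[:, a, b] = np.bincount(pi, weights=dx[:, a] * dX[:, b], minlength=n_pix)
        F = np.einsum("nab,nbc->nac", A, Binv)
        C = np.einsum("nba,nbc->nac", F, F)
        lr = np.einsum("na,nab,nb->n", e_r, C, e_r)
        lc = np.einsum("na,nab,nb->n", e_c, C, e_c)
        radial[:, k] = np.sqrt(np.maximum(lr, 0.0)) - 1.0
        circ[:, k] = np.sqrt(np.maximum(lc, 0.0)) - 1.0

    return StrainMaps(pixel_rc=pix, radial=radial, circumferential=circ, valid=valid,
                      frame_duration_ms=traj.frame_duration_ms)


@dataclass
class SegmentCurves:
    """Per-AHA-segment strain and strain-rate time curves for one slice."""

    names: tuple[str, ...]
    times_ms: np.ndarray
    strain: np.ndarray            # (n_segments, n_frames), radial, baseline 0 at frame 0
    strain_rate: np.ndarray       # (n_segments, n_frames), 1/s
    circ_strain: np.ndarray
    pixel_counts: np.ndarray
    frame_duration_ms: float
    slice_level: str

    @property
    def n_frames(self) -> int:
        return self.strain.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, name in enumerate(self.names):
            for k, t in enumerate(self.times_ms):
                rows.append({
                    "slice": self.slice_level, "segment": name, "frame": k,
                    "time_ms": t, "strain": self.strain[s, k],
                    "strain_rate": self.strain_rate[s, k],
                    "circ_strain": self.circ_strain[s, k],
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, slice_level: str | None = None) -> "SegmentCurves":
        if slice_level is not None:
            df = df[df["slice"] == slice_level]
        else:
            slice_level = df["slice"].iloc[0]
        names = AHA_SEGMENTS[slice_level]
        frames = np.sort(df["frame"].unique())
        times = (df.drop_duplicates("frame").sort_values("frame")["time_ms"]
                 .to_numpy(dtype=float))
        n_seg, n_fr = len(names), len(frames)
        strain = np.zeros((n_seg, n_fr))
        rate = np.zeros((n_seg, n_fr))
        circ = np.zeros((n_seg, n_fr))
        for s, name in enumerate(names):
            sub = df[df["segment"] == name].sort_values("frame")
            strain[s] = sub["strain"].to_numpy()
            rate[s] = sub["strain_rate"].to_numpy()
            circ[s] = (sub["circ_strain"].to_numpy()
                       if "circ_strain" in sub else np.zeros(n_fr))
        dt = float(times[1] - times[0]) if n_fr > 1 else 0.0
        return cls(names=names, times_ms=times, strain=strain, strain_rate=rate,
                   circ_strain=circ, pixel_counts=np.ones(n_seg, dtype=int),
                   frame_duration_ms=dt, slice_level=slice_level)


def segment_curves(maps: StrainMaps, segment_map: SegmentMap,
                   frame_duration_ms: float | None = None) -> SegmentCurves:
    """Average pixel strain into AHA segmental time curves.

    Per-segment strain is the mean over the segment's valid pixels per frame,
    baseline-shifted so strain at frame 0 is exactly 0; strain rate is the
    centered finite difference (one-sided at the ends), in 1/s.
    """
    if frame_duration_ms is None:
        frame_duration_ms = maps.frame_duration_ms
    n_seg = len(segment_map.names)
    n_frames = maps.radial.shape[1]
    seg_of_pixel = segment_map.labels[maps.pixel_rc[:, 0], maps.pixel_rc[:, 1]]
    strain = np.zeros((n_seg, n_frames))
    circ = np.zeros((n_seg, n_frames))
    counts = np.zeros(n_seg, dtype=int)
    for s in range(n_seg):
        sel = (seg_of_pixel == s) & maps.valid
        counts[s] = int(sel.sum())
        if counts[s] == 0:
            raise ValueError(
                f"segment {segment_map.names[s]!r} has no valid pixels")
        strain[s] = maps.radial[sel].mean(axis=0)
        circ[s] = maps.circumferential[sel].mean(axis=0)
    strain = strain - strain[:, :1]
    circ = circ - circ[:, :1]
    dt_s = frame_duration_ms / 1000.0
    rate = np.gradient(strain, dt_s, axis=1)
    times = np.arange(n_frames) * frame_duration_ms
    return SegmentCurves(names=segment_map.names, times_ms=times, strain=strain,
                         strain_rate=rate, circ_strain=circ, pixel_counts=counts,
                         frame_duration_ms=frame_duration_ms,
                         slice_level=segment_map.slice_level)


@dataclass
class StrainSummary:
    """Peak radial strain (%) and time to peak per segment, plus the slice global."""

    names: tuple[str, ...]
    peak_rs_pct: np.ndarray
    ttp_ms: np.ndarray
    global_rs_pct: float
    slice_level: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "slice": self.slice_level, "segment": list(self.names),
            "peak_RS_pct": self.peak_rs_pct, "TTP_ms": self.ttp_ms,
        })
        glob = pd.DataFrame({"slice": [self.slice_level], "segment": ["global"],
                             "peak_RS_pct": [self.global_rs_pct], "TTP_ms": [np.nan]})
        return pd.concat([df, glob], ignore_index=True)


def summarize(curves: SegmentCurves, global_rs_rule: str = "peak_of_mean",
              flat_tol: float = 1e-12) -> StrainSummary:
    """Peak strain and time-to-peak summaries.

    Peak RS is 100 x the maximum of the segment curve; TTP is the argmax frame
    times the frame duration (earliest frame on ties); a flat curve yields
    peak 0 with TTP flagged missing (NaN).  Global RS is the peak of the
    pixel-count-weighted mean segmental curve (``peak_of_mean``) or the mean
    of segmental peaks (``mean_of_peaks``).
    """
    if global_rs_rule not in ("peak_of_mean", "mean_of_peaks"):
        raise ValueError(f"unknown global_rs_rule {global_rs_rule!r}")
    n_seg = len(curves.names)
    peak = np.zeros(n_seg)
    ttp = np.full(n_seg, np.nan)
    for s in range(n_seg):
        c = curves.strain[s]
        if np.ptp(c) <= flat_tol:
            peak[s] = 0.0
            continue
        k = int(np.argmax(c))
        peak[s] = 100.0 * c[k]
        ttp[s] = k * curves.frame_duration_ms
    weights = curves.pixel_counts / curves.pixel_counts.sum()
    if global_rs_rule == "peak_of_mean":
        mean_curve = weights @ curves.strain
        global_rs = 100.0 * float(mean_curve.max()) if np.ptp(mean_curve) > flat_tol else 0.0
    else:
        global_rs = float(weights @ peak)
    return StrainSummary(names=curves.names, peak_rs_pct=peak, ttp_ms=ttp,
                         global_rs_pct=global_rs, slice_level=curves.slice_level)
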