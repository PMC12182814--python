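"""Synthetic contracting left-ventricle phantom.

Generates short-axis velocity cines of an incompressible (area-preserving)
annular myocardium with analytically known regional strain and contraction
timing.  The phantom stands in for a pixel-velocity inference step applied to
real cine MRI: its output has the same shape as such a model's output (a
per-frame 2-component velocity field plus an end-diastolic myocardial mask),
but the underlying radial strain and time-to-peak are closed-form, so the
downstream strain engine and dyssynchrony metrics can be validated against
exact truth.

Kinematics
----------
End-diastole is frame 0.  Each angular sector ``s`` contracts with amplitude
``c_s`` (endocardial radius at peak systole is ``(1 - c_s) * r_endo0``) and
activation delay ``delta_s``.  The endocardial radius follows

    R_endo(t) = r_endo0 * (1 - c_s * w(t - delta_s)),   w(u) = sin^2(pi u / T)

with cycle length ``T = n_frames * frame_duration_ms``.  Incompressibility in
the imaging plane maps the material point at end-diastolic radius ``R`` to

    r(R, t) = sqrt(R^2 + R_endo(t)^2 - r_endo0^2)

so the analytic radial engineering strain is ``eps_r(R, t) = R / r(R, t) - 1``
(positive during systolic wall thickening) and the Eulerian radial velocity at
image radius ``rho`` is ``R_endo * dR_endo/dt / rho``.  True time to peak is
``T/2 + delta_s`` by construction of ``w``.

Sector amplitudes/delays are blended linearly over a small angular window at
sector boundaries so the velocity field stays continuous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .strain import VelocityCine

SLICE_LEVELS = ("apical", "mid", "basal")

__all__ = ["PhantomSpec", "StrainTruth", "generate_phantom",
           "write_phantom_bundle", "read_phantom_bundle"]


@dataclass
class PhantomSpec:
    """Geometry, contraction, and acquisition parameters of the phantom.

    Defaults describe a mid-ventricular slice of an adult LV: 20 mm
    end-diastolic endocardial radius, 8 mm wall, 25 % uniform endocardial
    contraction, 1 s cycle sampled at 40 frames.
    """

    grid_size: int = 96
    pixel_spacing_mm: float = 1.0
    n_frames: int = 40
    frame_duration_ms: float = 25.0
    r_endo0_mm: float = 20.0
    r_epi0_mm: float = 28.0
    contraction_fraction: tuple[float, ...] | float = 0.25
    activation_delay_ms: tuple[float, ...] | float = 0.0
    n_sectors: int = 6
    noise_sd_mm_s: float = 0.0
    seed: int = 0
    slice_level: str = "mid"
    blend_deg: float = 5.0
    anterior_reference_angle_rad: float = np.pi / 2  # anterior at 12 o'clock

    def __post_init__(self) -> None:
        if np.isscalar(self.contraction_fraction):
            self.contraction_fraction = (float(self.contraction_fraction),) * self.n_sectors
        else:
            self.contraction_fraction = tuple(float(c) for c in self.contraction_fraction)
        if np.isscalar(self.activation_delay_ms):
            self.activation_delay_ms = (float(self.activation_delay_ms),) * self.n_sectors
        else:
            self.activation_delay_ms = tuple(float(d) for d in self.activation_delay_ms)

    @property
    def cycle_ms(self) -> float:
        return self.n_frames * self.frame_duration_ms

    def validate(self) -> None:
        if self.slice_level not in SLICE_LEVELS:
            raise ValueError(f"slice_level must be one of {SLICE_LEVELS}, got {self.slice_level!r}")
        if not (self.r_epi0_mm > self.r_endo0_mm > 0):
            raise ValueError(
                f"need r_epi0_mm > r_endo0_mm > 0, got r_epi0_mm={self.r_epi0_mm}, "
                f"r_endo0_mm={self.r_endo0_mm}"
            )
        if len(self.contraction_fraction) != self.n_sectors:
            raise ValueError("contraction_fraction length must equal n_sectors")
        if len(self.activation_delay_ms) != self.n_sectors:
            raise ValueError("activation_delay_ms length must equal n_sectors")
        for c in self.contraction_fraction:
            if not (0.0 <= c < 1.0):
                raise ValueError(f"contraction fractions must lie in [0, 1), got {c}")
        for d in self.activation_delay_ms:
            if not (0.0 <= d < self.cycle_ms):
                raise ValueError(f"activation delays must lie in [0, cycle), got {d}")
        if self.n_frames < 10:
            raise ValueError(f"n_frames must be >= 10, got {self.n_frames}")
        wall_px = (self.r_epi0_mm - self.r_endo0_mm) / self.pixel_spacing_mm
        if wall_px < 2.0:
            raise ValueError(
                f"myocardial wall is {wall_px:.2f} pixels thick "
                f"(r_epi0_mm - r_endo0_mm = {self.r_epi0_mm - self.r_endo0_mm} mm at "
                f"{self.pixel_spacing_mm} mm/pixel); need >= 2 pixels"
            )
        peak_endo = self.r_endo0_mm * (1.0 - max(self.contraction_fraction))
        if peak_endo <= 0:
            raise ValueError(f"peak endocardial radius {peak_endo} mm is non-positive")
        if self.grid_size * self.pixel_spacing_mm / 2.0 <= self.r_epi0_mm:
            raise ValueError(
                f"grid_size={self.grid_size} at {self.pixel_spacing_mm} mm/pixel does not "
                f"cover the epicardium (r_epi0_mm={self.r_epi0_mm})"
            )


@dataclass
class StrainTruth:
    """Analytic per-sector truth evaluated at sector mid-wall."""

    times_ms: np.ndarray                 # (n_frames,)
    strain: np.ndarray                   # (n_sectors, n_frames) radial engineering strain
    ttp_ms: np.ndarray                   # (n_sectors,), NaN where contraction is zero
    peak_strain: np.ndarray              # (n_sectors,)
    sector_center_angle_rad: np.ndarray  # (n_sectors,)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.strain.shape[0]):
            for k, t in enumerate(self.times_ms):
                rows.append({"sector": s, "frame": k, "time_ms": t,
                             "strain": self.strain[s, k]})
        return pd.DataFrame(rows)


def _blend_sector_values(theta: np.ndarray, values: np.ndarray,
                         ref_angle: float, blend_rad: float) -> np.ndarray:
    """Per-pixel sector value with linear cross-fade over +-blend_rad at boundaries.

    Sector s spans [ref + s*width, ref + (s+1)*width) counterclockwise.
    """
    n = len(values)
    width = 2.0 * np.pi / n
    blend_rad = min(blend_rad, width / 2.0)
    t = np.mod(theta - ref_angle, 2.0 * np.pi)
    s = np.minimum((t // width).astype(int), n - 1)
    tau = t - s * width
    out = values[s].astype(float)
    if blend_rad > 0:
        # near the leading edge (tau < blend): fade in from the previous sector
        lead = tau < blend_rad
        f = (tau[lead] + blend_rad) / (2.0 * blend_rad)  # in [0.5, 1]
        prev = values[(s[lead] - 1) % n]
        out[lead] = f * values[s[lead]] + (1.0 - f) * prev
        # near the trailing edge (tau > width - blend): fade out to the next sector
        trail = tau > width - blend_rad
        f = (tau[trail] - (width - blend_rad)) / (2.0 * blend_rad)  # in [0, 0.5]
        nxt = values[(s[trail] + 1) % n]
        out[trail] = (1.0 - f) * values[s[trail]] + f * nxt
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[VelocityCine, StrainTruth]:
    """Generate the velocity cine and the analytic strain truth.

    Returns
    -------
    cine : VelocityCine
        Per-frame (row, col) velocity components in mm/s on the full grid and
        the end-diastolic annular mask.
    truth : StrainTruth
        Mid-wall radial strain curve, true time to peak ``T/2 + delta_s`` and
        peak strain for each prescribed sector.
    """
    spec.validate()
    n = spec.grid_size
    sp = spec.pixel_spacing_mm
    center = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    dy = -(rows - center) * sp  # y-up physical frame
    dx = (cols - center) * sp
    rho = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)

    mask = (rho >= spec.r_endo0_mm) & (rho <= spec.r_epi0_mm)

    c_arr = np.asarray(spec.contraction_fraction, dtype=float)
    d_arr = np.asarray(spec.activation_delay_ms, dtype=float)
    blend_rad = np.deg2rad(spec.blend_deg)
    c_px = _blend_sector_values(theta.ravel(), c_arr, spec.anterior_reference_angle_rad,
                                blend_rad).reshape(theta.shape)
    d_px = _blend_sector_values(theta.ravel(), d_arr, spec.anterior_reference_angle_rad,
                                blend_rad).reshape(theta.shape)

    T = spec.cycle_ms
    r0 = spec.r_endo0_mm
    rng = np.random.default_rng(spec.seed)
    velocity = np.zeros((spec.n_frames, n, n, 2), dtype=np.float64)
    safe_rho = np.where(rho > 1e-9, rho, np.inf)
    for k in range(spec.n_frames):
        t = k * spec.frame_duration_ms
        u = np.mod(t - d_px, T)
        phase = u / T
        w = np.sin(np.pi * phase) ** 2
        wprime = (np.pi / T) * np.sin(2.0 * np.pi * phase)      # 1/ms
        r_endo = r0 * (1.0 - c_px * w)
        dr_endo = -r0 * c_px * wprime                            # mm/ms
        # annulus (area-preserving) profile outside the moving endocardium;
        # affine contraction of the blood pool inside it (v = 0 at the
        # center, continuous at rho = R_endo) so the field stays bounded
        v_r = np.where(rho >= r_endo,
                       r_endo * dr_endo / safe_rho,
                       dr_endo * rho / np.maximum(r_endo, 1e-9)) * 1000.0  # mm/s
        velocity[k, ..., 0] = v_r * (-dy) / safe_rho             # row component
        velocity[k, ..., 1] = v_r * dx / safe_rho                # col component
    if spec.noise_sd_mm_s > 0:
        velocity += rng.normal(0.0, spec.noise_sd_mm_s, size=velocity.shape)

    cine = VelocityCine(
        velocity=velocity,
        ed_mask=mask,
        frame_duration_ms=spec.frame_duration_ms,
        pixel_spacing_mm=(sp, sp),
        slice_level=spec.slice_level,
    )

    # analytic truth at sector mid-wall
    times = np.arange(spec.n_frames) * spec.frame_duration_ms
    r_mid = 0.5 * (spec.r_endo0_mm + spec.r_epi0_mm)
    strain = np.zeros((spec.n_sectors, spec.n_frames))
    ttp = np.full(spec.n_sectors, np.nan)
    peak = np.zeros(spec.n_sectors)
    width = 2.0 * np.pi / spec.n_sectors
    centers = np.mod(spec.anterior_reference_angle_rad + (np.arange(spec.n_sectors) + 0.5) * width,
                     2.0 * np.pi)
    for s in range(spec.n_sectors):
        u = np.mod(times - d_arr[s], T)
        w = np.sin(np.pi * u / T) ** 2
        r_endo = r0 * (1.0 - c_arr[s] * w)
        r_t = np.sqrt(r_mid ** 2 + r_endo ** 2 - r0 ** 2)
        strain[s] = r_mid / r_t - 1.0
        if c_arr[s] > 0:
            ttp[s] = T / 2.0 + d_arr[s]
            r_min = np.sqrt(r_mid ** 2 + (r0 * (1.0 - c_arr[s])) ** 2 - r0 ** 2)
            peak[s] = r_mid / r_min - 1.0
    truth = StrainTruth(times_ms=times, strain=strain, ttp_ms=ttp, peak_strain=peak,
                        sector_center_angle_rad=centers)
    return cine, truth


# ---------------------------------------------------------------------------
# bundle I/O: velocity.nii.gz + mask.nii.gz + meta.json + truth.csv
# ---------------------------------------------------------------------------

def write_phantom_bundle(out_dir: str | Path, cine: VelocityCine, truth: StrainTruth,
                         spec: PhantomSpec) -> Path:
    """Write the phantom as a directory bundle (NIfTI arrays + JSON metadata)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp_r, sp_c = cine.pixel_spacing_mm
    affine = np.diag([sp_r, sp_c, 1.0, 1.0])
    # spatial axes first per NIfTI convention: (row, col, frame, component)
    vel = np.transpose(cine.velocity, (1, 2, 0, 3)).astype(np.float32)
    nib.save(nib.Nifti1Image(vel, affine), out / "velocity.nii.gz")
    nib.save(nib.Nifti1Image(cine.ed_mask.astype(np.uint8), affine), out / "mask.nii.gz")
    meta = {
        "pixel_spacing_mm": list(cine.pixel_spacing_mm),
        "frame_duration_ms": cine.frame_duration_ms,
        "n_frames": cine.n_frames,
        "slice_level": cine.slice_level,
        "anterior_reference_angle_rad": spec.anterior_reference_angle_rad,
        "axis_order": ["row", "col", "frame", "component(row,col)"],
        "velocity_units": "mm/s",
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    truth.to_frame().to_csv(out / "truth.csv", index=False)
    return out


def read_phantom_bundle(bundle_dir: str | Path) -> tuple[VelocityCine, dict]:
    """Read a phantom bundle; returns the cine and the raw metadata dict."""
    import nibabel as nib

    d = Path(bundle_dir)
    meta = json.loads((d / "meta.json").read_text())
    vel = np.asarray(nib.load(d / "velocity.nii.gz").dataobj, dtype=np.float64)
    mask = np.asarray(nib.load(d / "mask.nii.gz").dataobj).astype(bool)
    velocity = np.transpose(vel, (2, 0, 1, 3))
    cine = VelocityCine(
        velocity=velocity,
        ed_mask=mask,
        frame_duration_ms=float(meta["frame_duration_ms"]),
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        slice_level=meta["slice_level"],
    )
    return cine, meta
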