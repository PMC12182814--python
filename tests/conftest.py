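import numpy as np
import pytest

from lvmech.phantom import PhantomSpec, generate_phantom
from lvmech.strain import (SegmentCurves, SliceGeometry, build_segment_map,
                           compute_strain, segment_curves, summarize,
                           track_displacements)


def run_strain_pipeline(spec: PhantomSpec) -> dict:
    """Phantom -> trajectories -> strain maps -> segmental curves/summary."""
    cine, truth = generate_phantom(spec)
    geom = SliceGeometry.from_cine(cine, spec.anterior_reference_angle_rad)
    traj = track_displacements(cine, geom)
    maps = compute_strain(traj, geom)
    segmap = build_segment_map(cine, geom)
    curves = segment_curves(maps, segmap, cine.frame_duration_ms)
    return {"spec": spec, "cine": cine, "truth": truth, "geometry": geom,
            "trajectories": traj, "maps": maps, "segment_map": segmap,
            "curves": curves, "summary": summarize(curves)}


@pytest.fixture(scope="session")
def coarse_uniform():
    """Noiseless uniform mid-slice phantom at routine cine resolution."""
    return run_strain_pipeline(
        PhantomSpec(grid_size=64, pixel_spacing_mm=1.0, n_frames=20,
                    frame_duration_ms=50.0))


@pytest.fixture(scope="session")
def fine_uniform():
    """Noiseless uniform phantom at doubled spatial/temporal resolution."""
    return run_strain_pipeline(
        PhantomSpec(grid_size=128, pixel_spacing_mm=0.5, n_frames=40,
                    frame_duration_ms=25.0))


@pytest.fixture(scope="session")
def delayed_pipeline():
    """One sector activated 150 ms (3 frames) late."""
    return run_strain_pipeline(
        PhantomSpec(grid_size=64, pixel_spacing_mm=1.0, n_frames=20,
                    frame_duration_ms=50.0,
                    activation_delay_ms=(0, 0, 0, 0, 0, 150.0)))


def make_curves(strain: np.ndarray, frame_duration_ms: float = 50.0,
                names: tuple[str, ...] | None = None,
                slice_level: str = "mid") -> SegmentCurves:
    """Hand-built SegmentCurves from a (segments x frames) strain array."""
    strain = np.asarray(strain, dtype=float)
    n_seg, n_fr = strain.shape
    if names is None:
        names = tuple(f"seg{i}" for i in range(n_seg))
    dt_s = frame_duration_ms / 1000.0
    return SegmentCurves(
        names=names, times_ms=np.arange(n_fr) * frame_duration_ms,
        strain=strain, strain_rate=np.gradient(strain, dt_s, axis=1),
        circ_strain=np.zeros_like(strain), pixel_counts=np.ones(n_seg, dtype=int),
        frame_duration_ms=frame_duration_ms, slice_level=slice_level)
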