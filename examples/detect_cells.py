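"""Render a small field and recover the cells with the LoG spot detector.

Renders 40 well-separated cells as attenuated Gaussian blobs with Poisson
noise, detects them at the expected 10-μm diameter, and scores the result
against the ground truth.
"""

import numpy as np

from tme3d import (
    AcquisitionConfig,
    ChannelSpec,
    DetectionParams,
    GroundTruth,
    ROI,
    detect_spots,
    match_detections,
    render_volume,
)
from tme3d.points import make_point_set

acq = AcquisitionConfig(channels=[ChannelSpec(name="CD3", excitation_nm=488)])
size = (90.0, 90.0, 300.0)  # μm; ~150×150 px × 150 planes

rng = np.random.default_rng(5)
cells = []
while len(cells) < 40:
    cand = rng.uniform([8, 8, 8], np.array(size) - 8)
    if all(np.linalg.norm(cand - c) >= 20 for c in cells):
        cells.append(cand)
truth = GroundTruth(make_point_set(np.array(cells), "CD3"), [], 5, ROI.from_size(size))

volume = render_volume(truth, acq, "CD3", seed=5)
detected = detect_spots(volume, DetectionParams(expected_diameter_um=10))
report = match_detections(detected, truth.points, tol_um=5.0)

print(f"rendered field: {volume.shape} voxels at {volume.voxel_size_um} μm")
print(f"true cells: {report.n_truth}, detected: {report.n_detected}")
print(f"precision {report.precision:.3f}  recall {report.recall:.3f}  F1 {report.f1:.3f}")
print("F1 near 1 means essentially every cell was found within half a cell")
print("diameter of its true position, with no spurious spots.")
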