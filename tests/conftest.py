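"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (double loops over coordinate
arrays) so they stay independent of the KD-tree-backed implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tme3d import AcquisitionConfig, ChannelSpec


@pytest.fixture
def acq():
    """Acquisition config with one channel per laser line."""
    return AcquisitionConfig(
        channels=[
            ChannelSpec(name="CD3", excitation_nm=488),
            ChannelSpec(name="CD20", excitation_nm=532),
            ChannelSpec(name="FOXP3", excitation_nm=637),
        ]
    )


def brute_force_pair_count(a: np.ndarray, b: np.ndarray, d_max: float) -> int:
    """O(n²) count of (a, b) pairs strictly closer than d_max."""
    n = 0
    for p in a:
        for q in b:
            if np.sqrt(((p - q) ** 2).sum()) < d_max:
                n += 1
    return n


def brute_force_radial_bins(
    centers: np.ndarray, neighbors: np.ndarray, r_max: float, bin_width: float
) -> np.ndarray:
    """O(n²) binned neighbor counts, half-open bins [k·w, (k+1)·w)."""
    nbins = int(round(r_max / bin_width))
    total = np.zeros(nbins, dtype=np.int64)
    for c in centers:
        for q in neighbors:
            d = np.sqrt(((c - q) ** 2).sum())
            if d < r_max:
                total[int(d // bin_width)] += 1
    return total


def spaced_points(
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    n: int,
    min_dist: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n points pairwise at least min_dist apart."""
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = lo + rng.uniform(size=3) * (hi - lo)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
            if len(pts) == n:
                break
    if len(pts) < n:
        raise RuntimeError("could not place spaced points; loosen the constraint")
    return np.array(pts)
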