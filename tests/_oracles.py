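"""Independent reference computations used only for verification.

Deliberately naive: exhaustive loops and grid searches, no spatial
index, no SVD — so they cannot share a defect with the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_sphere_members(ca_xyz: np.ndarray, center: int, d: float) -> set[int]:
    """All residues whose C-alpha lies within d of the center's, by an
    exhaustive O(n^2)-style scan."""
    members = set()
    cx, cy, cz = ca_xyz[center]
    for j, (x, y, z) in enumerate(ca_xyz):
        if ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) ** 0.5 <= d:
            members.add(j)
    return members


def direct_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Per-atom loop RMSD, no vectorized shortcut."""
    assert len(a) == len(b) and len(a) > 0
    total = 0.0
    for (ax, ay, az), (bx, by, bz) in zip(a, b):
        total += (ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2
    return (total / len(a)) ** 0.5


def grid_search_min_rmsd(a: np.ndarray, b: np.ndarray, final_step: float = 1e-3) -> float:
    """Minimum superposed RMSD by brute-force rotation search.

    Centers both sets, scans a full Euler-angle grid, then refines the
    grid around the best rotation until the step is below
    ``final_step`` radians. No SVD anywhere.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_for(angles: np.ndarray) -> float:
        rot = Rotation.from_euler("zyz", angles).as_matrix()
        return direct_rmsd(a, b @ rot.T)

    best_angles = np.zeros(3)
    best = rmsd_for(best_angles)
    # Full coarse scan.
    step = 0.3
    for alpha in np.arange(0.0, 2 * np.pi, step):
        for beta in np.arange(0.0, np.pi + step, step):
            for gamma in np.arange(0.0, 2 * np.pi, step):
                angles = np.array([alpha, beta, gamma])
                r = rmsd_for(angles)
                if r < best:
                    best, best_angles = r, angles
    # Local refinement.
    while step > final_step:
        step /= 4.0
        grid = np.array([-3, -2, -1, 0, 1, 2, 3]) * step
        for da in grid:
            for db in grid:
                for dg in grid:
                    angles = best_angles + np.array([da, db, dg])
                    r = rmsd_for(angles)
                    if r < best:
                        best, best_angles = r, angles
    return best


def two_pass_rmsf(ca_frames: np.ndarray) -> np.ndarray:
    """Per-residue RMSF by an explicit two-pass mean/deviation loop."""
    n_frames, n_res, _ = ca_frames.shape
    out = np.zeros(n_res)
    for r in range(n_res):
        mean = np.zeros(3)
        for f in range(n_frames):
            mean += ca_frames[f, r]
        mean /= n_frames
        acc = 0.0
        for f in range(n_frames):
            diff = ca_frames[f, r] - mean
            acc += float(diff @ diff)
        out[r] = (acc / n_frames) ** 0.5
    return out
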