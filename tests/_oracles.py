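"""Shared independent oracles for superposition tests."""

import numpy as np


def _quat_to_matrices(q):
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((len(q), 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def quaternion_grid_rmsd(ref, mob, n=100_000, seed=0):
    """Brute-force oracle: quaternion sampling of the rotation space with
    shrinking local refinement around the running best (translation is the
    centroid match, optimal for any rotation).  Shares no code with the SVD
    path it checks."""
    rng = np.random.default_rng(seed)
    refc = ref - ref.mean(axis=0)
    mobc = mob - mob.mean(axis=0)

    def best_over(quats):
        R = _quat_to_matrices(quats)
        rotated = np.einsum("nij,kj->nki", R, mobc)
        rmsds = np.sqrt(np.mean(np.sum((rotated - refc) ** 2, axis=2), axis=1))
        k = int(np.argmin(rmsds))
        return float(rmsds[k]), quats[k] / np.linalg.norm(quats[k])

    best_rmsd, best_q = best_over(rng.normal(size=(n, 4)))
    scale = 0.1
    for _ in range(24):
        local = best_q[None, :] + rng.normal(scale=scale, size=(2000, 4))
        r, q = best_over(local)
        if r < best_rmsd:
            best_rmsd, best_q = r, q
        else:
            scale *= 0.5
    return best_rmsd
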