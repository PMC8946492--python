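"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:
superposition is minimised by a zooming quaternion grid instead of SVD, and
the Mann-Whitney permutation distribution is enumerated from the pairwise
comparison matrix instead of rank sums.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from structens.io import StructureModel


# ---------------------------------------------------------------------------
# model-building helpers
# ---------------------------------------------------------------------------


def build_model(
    residue_numbers,
    ca_coords,
    cb_coords=None,
    tag="toy",
    res_names=None,
    chain="A",
) -> StructureModel:
    """Construct a StructureModel from explicit coordinates."""
    residue_numbers = list(residue_numbers)
    ca_coords = np.asarray(ca_coords, dtype=float)
    n_per = 1 if cb_coords is None else 2
    n = n_per * len(residue_numbers)
    arr = struc.AtomArray(n)
    coords = np.empty((n, 3))
    res_id = np.empty(n, dtype=int)
    atom_name = np.empty(n, dtype="U4")
    for k, r in enumerate(residue_numbers):
        coords[n_per * k] = ca_coords[k]
        res_id[n_per * k] = r
        atom_name[n_per * k] = "CA"
        if cb_coords is not None:
            coords[n_per * k + 1] = np.asarray(cb_coords)[k]
            res_id[n_per * k + 1] = r
            atom_name[n_per * k + 1] = "CB"
    arr.coord = coords
    arr.chain_id = np.full(n, chain)
    arr.res_id = res_id
    names = res_names if res_names is not None else ["ALA"] * len(residue_numbers)
    arr.res_name = np.repeat(names, n_per)
    arr.atom_name = atom_name
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("occupancy", np.ones(n))
    return StructureModel(atoms=arr, model_tag=tag)


def score_only_ensemble(scores, tags=None):
    """Ensemble whose models are 3-atom stubs — for selection-layer tests."""
    import pandas as pd
    from structens.ensemble import Ensemble

    scores = list(scores)
    tags = tags or [f"m{i + 1:05d}" for i in range(len(scores))]
    coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0]])
    models = [build_model([1, 2, 3], coords, tag=t) for t in tags]
    return Ensemble(models=models, scores=pd.DataFrame({"total_score": scores, "model_tag": tags}))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_superpose_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Minimum RMSD over proper rigid motions via a zooming quaternion grid.

    The optimal translation for any rotation matches the centroids, so only
    rotations are searched: a seeded covering of SO(3), then iteratively
    refined perturbation shells around the incumbent.
    """
    cm = moving - moving.mean(axis=0)
    cf = fixed - fixed.mean(axis=0)

    def batch_rmsd(rots: Rotation) -> np.ndarray:
        mats = rots.as_matrix().reshape(-1, 3, 3)
        moved = np.einsum("rij,kj->rki", mats, cm)
        return np.sqrt(np.mean(np.sum((moved - cf) ** 2, axis=2), axis=1))

    rots = Rotation.random(4000, random_state=12345)
    vals = batch_rmsd(rots)
    best = rots[int(np.argmin(vals))]
    best_val = float(vals.min())
    rng = np.random.default_rng(0)
    scale = 0.6  # radians
    for _ in range(60):
        axes = rng.normal(size=(400, 3))
        axes *= (scale * rng.random((400, 1))) / np.linalg.norm(axes, axis=1, keepdims=True)
        cand = Rotation.from_rotvec(axes) * best
        vals = batch_rmsd(cand)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best_val = float(vals[i])
            best = cand[i]
        scale *= 0.85
    return best_val


def oracle_mw_two_sided_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by brute-force enumeration of splits,
    with U computed from the pairwise comparison definition (ties → 1/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def u_of(a, b):
        return float(sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b))

    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = u_of(x, y)
    us = []
    for sel in combinations(range(len(pooled)), n):
        rest = [i for i in range(len(pooled)) if i not in sel]
        us.append(u_of(pooled[list(sel)], pooled[rest]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
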