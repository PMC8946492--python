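"""Rigid-body superposition and per-residue flexibility profiling.

The flexibility surrogate works as follows: each ensemble member is
superposed onto a reference model (least-squares, Kabsch), either with one
global fit or — the default for multi-domain proteins — domain by domain, so
that rigid inter-domain shifts do not masquerade as local flexibility.  The
per-residue Cα deviation from the reference is then aggregated across the
ensemble into a mean, an RMS, and a 95% confidence band.

Two per-residue statistics are kept throughout, because "average per-residue
RMSD" is ambiguous between them:

* ``rms_deviation`` — sqrt(mean of squared deviations) over models (default
  statistic in exported maps; for isotropic Gaussian noise of per-axis σ it
  converges to σ·√3);
* ``mean_deviation`` — plain mean deviation (converges to σ·2√(2/π)).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainMap, Region
from .ensemble import Ensemble
from .io import ResidueCorrespondence, StructureModel, write_pdb_with_per_residue_values

__all__ = [
    "kabsch_superpose",
    "whole_structure_rmsd",
    "cross_state_rmsd",
    "per_residue_profile",
    "delta_profile",
    "ensemble_mean_profile_map",
    "PROFILE_COLUMNS",
]

PROFILE_COLUMNS = ["mean_deviation", "rms_deviation", "ci_low", "ci_high", "n_models"]

#: default per-residue statistic used when a single column must be chosen
DEFAULT_STATISTIC = "rms_deviation"


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``moving @ rotation.T + translation`` minimises the RMSD to ``fixed``
    over all proper rigid motions (SVD solution with determinant sign
    correction, so ``det(rotation) = +1``).

    Requires at least 3 paired, non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError(f"point sets must be matching (N, 3) arrays, got {moving.shape} and {fixed.shape}")
    n = moving.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")

    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    for pts, label in ((x, "moving"), (y, "fixed")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) {label} point configuration")

    h = x.T @ y  # covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cf - rotation @ cm
    diff = x @ rotation.T - y
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return rotation, translation, rmsd


def _shared_ca(
    model: StructureModel,
    reference: StructureModel,
    selection: Sequence[int] | None = None,
    correspondence: ResidueCorrespondence | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired Cα coordinates on reference numbering.

    ``correspondence`` maps the *model*'s (variant) numbering onto the
    reference numbering before intersecting.  Returns
    (reference_residue_numbers, model_coords, reference_coords).
    """
    res_m, coord_m = model.ca_table()
    if correspondence is not None:
        mapped = np.array([correspondence.to_reference(int(r)) for r in res_m])
    else:
        mapped = res_m
    res_r, coord_r = reference.ca_table()
    common, im, ir = np.intersect1d(mapped, res_r, return_indices=True)
    if selection is not None:
        keep = np.isin(common, np.asarray(list(selection), dtype=int))
        common, im, ir = common[keep], im[keep], ir[keep]
    return common.astype(int), coord_m[im], coord_r[ir]


def whole_structure_rmsd(
    model: StructureModel,
    reference: StructureModel,
    selection: Sequence[int] | None = None,
    correspondence: ResidueCorrespondence | None = None,
) -> float:
    """Cα RMSD between a model and a reference after one global superposition.

    The RMSD is computed over the Cα atoms shared by both models (optionally
    restricted to ``selection``, on reference numbering).
    """
    common, cm, cr = _shared_ca(model, reference, selection, correspondence)
    if len(common) == 0:
        raise ValueError("no shared Cα atoms between model and reference")
    _, _, rmsd = kabsch_superpose(cm, cr)
    return rmsd


def cross_state_rmsd(model_a: StructureModel, model_b: StructureModel, region: Region) -> float:
    """Cα RMSD between two conformations over a named region's residues."""
    return whole_structure_rmsd(model_a, model_b, selection=region.residues())


# ---------------------------------------------------------------------------
# Per-residue flexibility profiles
# ---------------------------------------------------------------------------


def _deviations_one_model(
    model: StructureModel,
    reference: StructureModel,
    domains: list[Region] | None,
    correspondence: ResidueCorrespondence | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue Cα deviation of one model from the reference.

    If ``domains`` is given, each domain is superposed independently and
    deviations are recorded only for residues inside a domain; otherwise a
    single global superposition over all shared Cα is used.
    """
    common, cm, cr = _shared_ca(model, reference, correspondence=correspondence)
    if domains is None:
        if len(common) < 3:
            raise ValueError("fewer than 3 shared Cα atoms for global superposition")
        rot, trans, _ = kabsch_superpose(cm, cr)
        dev = np.linalg.norm(cm @ rot.T + trans - cr, axis=1)
        return common, dev

    res_out: list[np.ndarray] = []
    dev_out: list[np.ndarray] = []
    assigned = np.zeros(len(common), dtype=bool)
    for region in domains:
        mask = region.mask(common) & ~assigned
        if not np.any(mask):
            continue
        if np.sum(mask) < 3:
            raise ValueError(
                f"domain with ranges {region.ranges} shares only {int(np.sum(mask))} Cα with the reference"
            )
        rot, trans, _ = kabsch_superpose(cm[mask], cr[mask])
        dev_out.append(np.linalg.norm(cm[mask] @ rot.T + trans - cr[mask], axis=1))
        res_out.append(common[mask])
        assigned |= mask
    if not res_out:
        raise ValueError("no residues fall inside the alignment domains")
    res = np.concatenate(res_out)
    dev = np.concatenate(dev_out)
    order = np.argsort(res)
    return res[order], dev[order]


def per_residue_profile(
    ensemble: Ensemble,
    reference: StructureModel,
    domain_map: DomainMap | None = None,
    *,
    per_domain: bool = True,
    domains: Sequence[str] | None = None,
    correspondence: ResidueCorrespondence | None = None,
    ci_method: str = "t",
    ci_level: float = 0.95,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue flexibility profile of an ensemble against a reference.

    Each model is superposed onto the reference — per structural domain when
    ``per_domain`` is set (``domain_map`` required; ``domains`` selects which
    named regions act as alignment domains, defaulting to the regions named in
    the map's interfaces) — and each residue's Cα deviation is recorded.  The
    profile aggregates deviations across models.

    Returns a DataFrame indexed by residue number (reference numbering when a
    ``correspondence`` is supplied) with columns ``mean_deviation``,
    ``rms_deviation``, ``ci_low``, ``ci_high`` (confidence band on the mean
    deviation; Student-t by default, percentile bootstrap when
    ``ci_method="bootstrap"``) and ``n_models``.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    regions: list[Region] | None = None
    if per_domain:
        if domain_map is None:
            raise ValueError("per-domain profiling requires a domain map")
        if domains is None:
            if domain_map.interfaces:
                names: list[str] = []
                for a, b in domain_map.interfaces:
                    for n in (a, b):
                        if n not in names:
                            names.append(n)
            else:
                names = domain_map.names()
            domains = names
        regions = [domain_map[name] for name in domains]

    per_res: dict[int, list[float]] = {}
    for model in ensemble.models:
        res, dev = _deviations_one_model(model, reference, regions, correspondence)
        for r, d in zip(res, dev):
            per_res.setdefault(int(r), []).append(float(d))

    index = sorted(per_res)
    rows = np.full((len(index), 5), np.nan)
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci_level
    for i, r in enumerate(index):
        d = np.asarray(per_res[r])
        n = len(d)
        mean = d.mean()
        rms = float(np.sqrt(np.mean(d**2)))
        if n == 1:
            lo = hi = mean
        elif ci_method == "t":
            sem = d.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        elif ci_method == "bootstrap":
            samples = rng.choice(d, size=(n_bootstrap, n), replace=True).mean(axis=1)
            lo, hi = np.quantile(samples, [alpha / 2, 1 - alpha / 2])
            lo, hi = min(lo, mean), max(hi, mean)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows[i] = [mean, rms, lo, hi, n]

    profile = pd.DataFrame(rows, index=pd.Index(index, name="residue_number"), columns=PROFILE_COLUMNS)
    profile["n_models"] = profile["n_models"].astype(int)
    return profile


def delta_profile(
    profile_a: pd.DataFrame | pd.Series, profile_b: pd.DataFrame | pd.Series
) -> pd.DataFrame | pd.Series:
    """Signed per-residue difference ``a − b`` on the residues both profiles cover.

    Profiles must be indexed on a common numbering (run the variant profile
    through ``align_profiles`` first).  For full profiles the difference is
    taken for both statistics (``mean_deviation`` and ``rms_deviation``).
    """
    if isinstance(profile_a, pd.Series) or isinstance(profile_b, pd.Series):
        common = profile_a.dropna().index.intersection(profile_b.dropna().index)
        if len(common) == 0:
            raise ValueError("profiles share no residues")
        return (profile_a.loc[common] - profile_b.loc[common]).sort_index()
    cols = [c for c in ("mean_deviation", "rms_deviation") if c in profile_a.columns and c in profile_b.columns]
    a = profile_a[cols].dropna()
    b = profile_b[cols].dropna()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("profiles share no residues")
    return (a.loc[common] - b.loc[common]).sort_index()


def ensemble_mean_profile_map(
    profile: pd.DataFrame | pd.Series,
    model: StructureModel,
    lo: float,
    hi: float,
    path: str,
    statistic: str = DEFAULT_STATISTIC,
) -> None:
    """Write a PDB whose B-factors carry profile values clipped to ``[lo, hi]``.

    This is the standard way of colouring a structure by ensemble flexibility
    (or by a signed flexibility difference) in molecular viewers.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    values = profile[statistic] if isinstance(profile, pd.DataFrame) else profile
    clipped = values.dropna().clip(lower=lo, upper=hi)
    write_pdb_with_per_residue_values(model, {int(r): float(v) for r, v in clipped.items()}, path)
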