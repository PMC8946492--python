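"""Residue-pair interaction energies and domain-interface aggregation.

Pair energies come from one of two sources:

* :func:`surrogate_pair_energies` — a transparent 12-6 pair potential on
  side-chain representative atoms (CB, or CA for glycine), truncated and
  shifted so it vanishes continuously at the cutoff.  This is a documented
  stand-in for force-field pair energies, keeping the aggregation and
  statistics layer exercisable without an external scoring run;
* :func:`read_pair_energy_table` — ingestion of externally computed
  per-residue-pair breakdown tables (Rosetta ``residue_energy_breakdown``
  dialect), which flow through the same interface aggregation.

Interface energies are sums of pair energies over residue pairs spanning two
named domains; ensembles of such sums are compared with a two-sided
Mann-Whitney U test (exact for small samples, including ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .domains import DomainMap
from .ensemble import Ensemble
from .io import StructureModel

__all__ = [
    "PairPotentialParams",
    "pair_potential",
    "surrogate_pair_energies",
    "read_pair_energy_table",
    "interface_energy",
    "region_internal_energy",
    "interface_sums",
    "boxplot_stats",
    "MannWhitneyResult",
    "compare_interface_distributions",
    "significance_label",
]

PAIR_TABLE_COLUMNS = ["res_i", "res_j", "energy"]


@dataclass(frozen=True)
class PairPotentialParams:
    """12-6 pair potential parameters (Å, REU-like units)."""

    r0: float = 5.0  # minimum-energy distance
    epsilon: float = 1.0  # well depth
    cutoff: float = 8.0  # truncation distance; the potential is shifted to 0 here

    def __post_init__(self) -> None:
        if not (0 < self.r0 < self.cutoff):
            raise ValueError(f"need 0 < r0 < cutoff, got r0={self.r0}, cutoff={self.cutoff}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


def pair_potential(d: np.ndarray | float, params: PairPotentialParams = PairPotentialParams()) -> np.ndarray | float:
    """Truncated-and-shifted 12-6 potential.

    ``ε·[(r0/d)^12 − 2(r0/d)^6]`` minus its value at the cutoff, and exactly 0
    for ``d ≥ cutoff`` — continuous at the truncation point.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    def lj(r: np.ndarray | float) -> np.ndarray | float:
        q = (params.r0 / r) ** 6
        return params.epsilon * (q * q - 2.0 * q)
    e = np.where(d < params.cutoff, lj(d) - lj(params.cutoff), 0.0)
    return float(e) if e.ndim == 0 else e


def surrogate_pair_energies(
    model: StructureModel, params: PairPotentialParams = PairPotentialParams()
) -> pd.DataFrame:
    """Pair energies between contacting side-chain representatives of one model.

    Contact means representative atoms (CB; CA for glycine) within the cutoff.
    Returns a canonical table (``res_i < res_j``) with a ``model_tag`` attr;
    pairs beyond the cutoff are absent.
    """
    res, coords = model.representative_atoms()
    table = pd.DataFrame(columns=PAIR_TABLE_COLUMNS).astype({"res_i": int, "res_j": int, "energy": float})
    if len(res) >= 2:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(params.cutoff - 1e-12, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            ri, rj = res[pairs[:, 0]], res[pairs[:, 1]]
            lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
            table = pd.DataFrame({"res_i": lo, "res_j": hi, "energy": pair_potential(d, params)})
            table = table.sort_values(["res_i", "res_j"]).reset_index(drop=True)
    table.attrs["model_tag"] = model.model_tag
    return table


def read_pair_energy_table(path: str | Path) -> pd.DataFrame:
    """Read a residue_energy_breakdown-style whitespace table.

    Expects columns ``resi1``, ``resi2`` and ``total`` (a leading ``SCORE:``
    token column is tolerated).  One-body rows (``resi2`` = ``--``) are
    ignored; two-body rows are canonicalised to ``res_i < res_j``.  Duplicate
    pairs — including an (i,j)/(j,i) duplicate — are an error.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.columns[0] == "SCORE:":
        df = df.drop(columns=["SCORE:"])
    for col in ("resi1", "resi2", "total"):
        if col not in df.columns:
            raise ValueError(f"pair-energy table {path} lacks column {col!r}")
    if df.empty:
        return pd.DataFrame(columns=PAIR_TABLE_COLUMNS).astype({"res_i": int, "res_j": int, "energy": float})
    two_body = df[df["resi2"] != "--"].copy()
    try:
        ri = two_body["resi1"].astype(int).to_numpy()
        rj = two_body["resi2"].astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"unparseable residue identifiers in {path}: {exc}") from exc
    energy = two_body["total"].astype(float).to_numpy()
    if np.any(ri == rj):
        raise ValueError(f"self-pair rows in {path}")
    table = pd.DataFrame({"res_i": np.minimum(ri, rj), "res_j": np.maximum(ri, rj), "energy": energy})
    dup = table.duplicated(subset=["res_i", "res_j"], keep=False)
    if dup.any():
        pairs = table.loc[dup, ["res_i", "res_j"]].drop_duplicates().to_records(index=False)
        raise ValueError(f"duplicate residue pairs in {path}: {[tuple(p) for p in pairs]}")
    return table.sort_values(["res_i", "res_j"]).reset_index(drop=True)


def interface_energy(table: pd.DataFrame, domain_map: DomainMap, a: str, b: str) -> float:
    """Sum of pair energies over pairs with one residue in ``a``, the other in ``b``."""
    if a == b:
        raise ValueError("interface requires two distinct domains; "
                         "use region_internal_energy for within-domain sums")
    ra, rb = domain_map[a], domain_map[b]
    ri = table["res_i"].to_numpy()
    rj = table["res_j"].to_numpy()
    cross = (ra.mask(ri) & rb.mask(rj)) | (rb.mask(ri) & ra.mask(rj))
    return float(table.loc[cross, "energy"].sum())


def region_internal_energy(table: pd.DataFrame, domain_map: DomainMap, a: str) -> float:
    """Sum of pair energies with both residues inside region ``a``."""
    ra = domain_map[a]
    inside = ra.mask(table["res_i"].to_numpy()) & ra.mask(table["res_j"].to_numpy())
    return float(table.loc[inside, "energy"].sum())


def interface_sums(
    ensemble: Ensemble,
    domain_map: DomainMap,
    a: str,
    b: str,
    params: PairPotentialParams = PairPotentialParams(),
    pair_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.Series:
    """Interface energy sum per ensemble member, indexed by model tag.

    Pair energies are computed with the surrogate potential unless
    externally computed ``pair_tables`` (model_tag → table) are given.
    """
    sums = {}
    for model in ensemble.models:
        table = (
            pair_tables[model.model_tag]
            if pair_tables is not None
            else surrogate_pair_energies(model, params)
        )
        sums[model.model_tag] = interface_energy(table, domain_map, a, b)
    return pd.Series(sums, name=f"{a}/{b}")


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Quartiles, median and 1.5·IQR whisker bounds of a distribution of sums."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()),
        "whisker_high": float(in_hi.max()),
        "n": int(v.size),
    }


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: significance stars at the conventional thresholds
_SIGNIFICANCE_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]

#: switch to the normal approximation above this many distinct arrangements
_EXACT_LIMIT = 100_000


def significance_label(p: float) -> str:
    for threshold, label in _SIGNIFICANCE_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided p-value
    label: str  # significance stars, or "ns"
    method: str  # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation p-value of the U statistic (ties handled naturally).

    Enumerates every split of the pooled sample into groups of the observed
    sizes, computes U for each, and doubles the smaller tail probability
    (inclusive), capped at 1.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    # U = (sum of midranks of the first group) - n(n+1)/2; enumerate every
    # choice of n pooled elements for the first group
    midranks = stats.rankdata(pooled, method="average")
    combos = np.array(list(combinations(range(n + m), n)))
    us = midranks[combos].sum(axis=1) - n * (n + 1) / 2.0
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def compare_interface_distributions(
    sums_x: Sequence[float], sums_y: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two samples of interface sums.

    Uses exact enumeration while the number of arrangements is small
    (≤ 100 000), and the tie-corrected normal approximation otherwise.  The
    returned label encodes p < 0.05/0.01/0.001/0.0001 as */**/***/****.
    """
    x = np.asarray(sums_x, dtype=float)
    y = np.asarray(sums_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if math.comb(x.size + y.size, x.size) <= _EXACT_LIMIT:
        u, p = _exact_two_sided_p(x, y)
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return MannWhitneyResult(u=u, p=p, label=significance_label(p), method=method)
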