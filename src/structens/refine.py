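"""Refinement parameter selection on tabulated scan data.

Density-guided refinement trades agreement with the experimental map against
model strain: too low a density weight ignores the data, too high overfits
it.  The selection objective scores each candidate weight as

    objective(w) = FSC(w) − c · per_residue_energy(w),      c = 0.04

where FSC is the Fourier shell correlation between the refined ensemble and
the map, and the per-residue energy is a tabulated summary of model strain
at that weight.  The maximising weight is selected.  The scan table is an
input produced by external refinement runs — this module never launches
refinement, and how the per-residue energy was aggregated over models and
residues is recorded by the table's producer.

Fragment-insertion settings (length, rms) are judged by ensemble diversity:
:func:`diversity_report` summarises, per setting, the distribution of
region-restricted Cα RMSDs to the reference, ranked by median (no selection
rule beyond the ranking is imposed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .io import StructureModel
from .superpose import whole_structure_rmsd

__all__ = ["denswt_objective", "read_scan_table", "diversity_report"]

SCAN_COLUMNS = ["weight", "fsc", "per_residue_energy"]

#: default energy coefficient in the density-weight objective
DEFAULT_ENERGY_COEFF = 0.04


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read a density-weight scan TSV (weight, fsc, per_residue_energy[, n_models])."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scan table {path} lacks columns {sorted(missing)}")
    return df


def denswt_objective(
    scan: pd.DataFrame, c: float = DEFAULT_ENERGY_COEFF
) -> tuple[pd.DataFrame, float]:
    """Per-weight objective ``fsc − c·per_residue_energy`` and the argmax weight.

    Requires ≥ 2 rows with unique positive weights and FSC in [0, 1]; ties in
    the objective go to the smaller weight.
    """
    missing = set(SCAN_COLUMNS) - set(scan.columns)
    if missing:
        raise ValueError(f"scan lacks columns {sorted(missing)}")
    if len(scan) < 2:
        raise ValueError(f"need at least 2 scan rows, got {len(scan)}")
    w = scan["weight"].to_numpy(dtype=float)
    if len(np.unique(w)) != len(w):
        dup = sorted({x for x in w if list(w).count(x) > 1})
        raise ValueError(f"duplicate weights in scan: {dup}")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    fsc = scan["fsc"].to_numpy(dtype=float)
    if np.any((fsc < 0) | (fsc > 1)):
        raise ValueError("fsc must lie in [0, 1]")
    out = scan.copy()
    out["objective"] = fsc - c * scan["per_residue_energy"].to_numpy(dtype=float)
    out = out.sort_values("weight", kind="stable").reset_index(drop=True)
    best_idx = int(out["objective"].idxmax())  # idxmax takes the first max: smaller weight
    return out, float(out.loc[best_idx, "weight"])


def diversity_report(
    ensembles: Mapping[str, Ensemble],
    reference: StructureModel,
    region: Sequence[int],
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-setting summary of region-restricted Cα RMSD distributions.

    For each named setting (e.g. a fragment length), computes the
    whole-structure Cα RMSD of every ensemble member to the reference,
    restricted to ``region`` residues, and summarises the distribution
    (median, quartiles, IQR, max).  Rows are ranked by descending median —
    the most diverse ensemble first.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    region = np.asarray(list(region), dtype=int)
    rows = []
    for setting, ens in ensembles.items():
        if len(ens) == 0:
            raise ValueError(f"ensemble {setting!r} is empty")
        rmsds = np.array(
            [whole_structure_rmsd(m, reference, selection=region) for m in ens.models]
        )
        q1, med, q3 = np.percentile(rmsds, [25, 50, 75])
        rows.append(
            {
                "setting": setting,
                "median_rmsd": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(q3 - q1),
                "max_rmsd": float(rmsds.max()),
                "n_models": len(ens),
            }
        )
    report = (
        pd.DataFrame(rows)
        .sort_values(["median_rmsd", "setting"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    report["rank"] = np.arange(1, len(report) + 1)
    if tsv_path is not None:
        report.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    return report
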