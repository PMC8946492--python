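"""Score-based model selection and RMSD-vs-score tables.

Scores follow the Rosetta convention: lower total_score is better.  The
"best" subset of an ensemble is therefore the lowest-scoring tail; taking the
mean score of the lowest-scoring 5% is the ensemble-level statistic used for
stability calibration.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ensemble import Ensemble
from .io import StructureModel
from .superpose import whole_structure_rmsd

__all__ = ["select_best", "score_statistic", "rmsd_vs_score", "write_selection_manifest"]


def _resolve_count(n: int, count: int | None, fraction: float | None) -> int:
    if (count is None) == (fraction is None):
        raise ValueError("give exactly one of count or fraction")
    if n == 0:
        raise ValueError("empty ensemble")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        count = math.ceil(fraction * n)
    assert count is not None
    if not 1 <= count <= n:
        raise ValueError(f"requested {count} models from an ensemble of {n}")
    return count


def select_best(
    ensemble: Ensemble, count: int | None = None, fraction: float | None = None
) -> Ensemble:
    """The ``count`` (or ``ceil(fraction·n)``) lowest-scoring models.

    Ties at the cutoff are broken by a stable secondary sort on model tag, so
    selection is deterministic.
    """
    k = _resolve_count(len(ensemble), count, fraction)
    order = ensemble.scores.sort_values(["total_score", "model_tag"], kind="stable")
    keep = list(order["model_tag"].iloc[:k])
    return ensemble.subset(keep)


def score_statistic(ensemble: Ensemble, fraction: float = 0.05) -> float:
    """Mean total_score over the lowest-scoring ``fraction`` of the ensemble."""
    best = select_best(ensemble, fraction=fraction)
    return float(best.scores["total_score"].mean())


def rmsd_vs_score(
    ensemble: Ensemble,
    reference: StructureModel,
    selection: Sequence[int] | None = None,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per model: (model_tag, ca_rmsd, total_score).

    RMSD is the whole-structure Cα RMSD to ``reference`` after one global
    superposition (optionally over a residue ``selection``).  Raises if any
    model lacks a score-table row, naming the offending tags.
    """
    tags = ensemble.tags
    scored = set(ensemble.scores["model_tag"])
    missing = sorted(t for t in tags if t not in scored)
    if missing:
        raise ValueError(f"models missing from the score table: {missing}")
    score_of = ensemble.scores.set_index("model_tag")["total_score"]
    rows = [
        {
            "model_tag": m.model_tag,
            "ca_rmsd": whole_structure_rmsd(m, reference, selection=selection),
            "total_score": float(score_of[m.model_tag]),
        }
        for m in ensemble.models
    ]
    table = pd.DataFrame(rows, columns=["model_tag", "ca_rmsd", "total_score"])
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    return table


def write_selection_manifest(ensemble: Ensemble, path: str | Path) -> None:
    """Write the retained model tags, one per line."""
    Path(path).write_text("\n".join(ensemble.tags) + "\n")
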