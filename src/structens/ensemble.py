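"""The ensemble container: structural models joined to a score table."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import StructureModel, read_pdb, read_score_table

__all__ = ["Ensemble"]


@dataclass
class Ensemble:
    """A set of structural models joined to a score table by model tag.

    ``scores`` holds one row per model (columns ``model_tag``, ``total_score``
    and optionally more); every model's tag must appear exactly once.
    """

    models: list[StructureModel]
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        tags = [m.model_tag for m in self.models]
        if len(set(tags)) != len(tags):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate model tags in ensemble: {dup}")
        missing = sorted(set(tags) - set(self.scores["model_tag"]))
        if missing:
            raise ValueError(f"models without a score-table row: {missing}")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def tags(self) -> list[str]:
        return [m.model_tag for m in self.models]

    def total_scores(self) -> pd.Series:
        """total_score per model, indexed by tag, in model order."""
        s = self.scores.set_index("model_tag")["total_score"]
        return s.loc[self.tags]

    def subset(self, tags: Sequence[str]) -> "Ensemble":
        wanted = set(tags)
        models = [m for m in self.models if m.model_tag in wanted]
        scores = self.scores[self.scores["model_tag"].isin(wanted)].reset_index(drop=True)
        return Ensemble(models=models, scores=scores)

    def lowest_scoring_model(self) -> StructureModel:
        """The model with the lowest total_score (ties: lexicographic tag)."""
        s = self.scores.sort_values(["total_score", "model_tag"], kind="stable")
        best = s.iloc[0]["model_tag"]
        return next(m for m in self.models if m.model_tag == best)

    @classmethod
    def from_directory(cls, pdb_dir: str | Path, score_path: str | Path) -> "Ensemble":
        """Load all ``*.pdb`` files in a directory and join them to a score table
        by file stem."""
        pdb_dir = Path(pdb_dir)
        scores = read_score_table(score_path)
        models = [read_pdb(p) for p in sorted(pdb_dir.glob("*.pdb"))]
        if not models:
            raise ValueError(f"no PDB files in {pdb_dir}")
        return cls(models=models, scores=scores)
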