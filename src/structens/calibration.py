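"""Calibrating ensemble score statistics against experimental thermostability.

The protocol: for each candidate template count, model every variant (a set
of stabilising second-site suppressor mutations plus WT), take the mean score
of the lowest-scoring 5% of each variant's ensemble, and correlate that
statistic with the experimental ΔTm (°C) and ΔΔG (kcal/mol) of the variants
(both expressed relative to WT).  The template count whose score statistic
correlates best — here, the one maximising the mean of the two Pearson
coefficients — is selected.

The tool correlates the raw columns as given and never flips signs: the
orientation of the experimental axes must be declared by whoever builds the
input table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "CalibrationResult",
    "pearson_r",
    "calibrate",
    "experimental_consistency",
    "read_experimental_table",
]


@dataclass(frozen=True)
class VariantRecord:
    """One variant: its ensemble score statistic and experimental stability shifts."""

    variant: str
    score_stat: float  # mean total_score of the best-5% models (REU-like)
    delta_tm: float | None = None  # °C, relative to WT
    delta_dg: float | None = None  # kcal/mol, relative to WT
    source: str = ""


@dataclass(frozen=True)
class CalibrationResult:
    table: pd.DataFrame  # per template_count: r_dtm, r_ddg, mean_r, n_variants
    chosen_count: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its square.

    Requires n ≥ 3 and non-constant inputs (the coefficient is undefined for
    a constant sample).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def _records_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": [r.variant for r in records],
            "score_stat": [r.score_stat for r in records],
            "delta_tm": [r.delta_tm for r in records],
            "delta_dg": [r.delta_dg for r in records],
        }
    )


def calibrate(records_by_count: Mapping[int, Sequence[VariantRecord]]) -> CalibrationResult:
    """Correlate score statistics with experimental data per template count.

    For each count, computes Pearson r of score_stat against ΔTm and against
    ΔΔG over its variants (each needs ≥ 3 variants with experimental values;
    missing values are an error).  The chosen count maximises the mean of the
    two coefficients; ties (to 6 decimals) go to the smaller count.
    """
    if not records_by_count:
        raise ValueError("no template counts given")
    rows = []
    for count in sorted(records_by_count):
        df = _records_frame(records_by_count[count])
        missing = df.loc[df["delta_tm"].isna() | df["delta_dg"].isna(), "variant"]
        if len(missing):
            raise ValueError(
                f"variants without experimental values at template count {count}: {sorted(missing)}"
            )
        if len(df) < 3:
            raise ValueError(f"need at least 3 variants per template count, got {len(df)} at {count}")
        r_dtm, _ = pearson_r(df["score_stat"], df["delta_tm"])
        r_ddg, _ = pearson_r(df["score_stat"], df["delta_dg"])
        rows.append(
            {
                "template_count": count,
                "r_dtm": r_dtm,
                "r_ddg": r_ddg,
                "mean_r": (r_dtm + r_ddg) / 2.0,
                "n_variants": len(df),
            }
        )
    table = pd.DataFrame(rows).set_index("template_count")
    rounded = table["mean_r"].round(6)
    chosen = int(rounded[rounded == rounded.max()].index.min())
    return CalibrationResult(table=table, chosen_count=chosen)


def experimental_consistency(records: Sequence[VariantRecord]) -> float:
    """r² between the experimental ΔTm and ΔΔG values of the variants.

    A sanity check on the experimental table itself: the two stability axes
    should agree before either is used as a calibration target.
    """
    df = _records_frame(records).dropna(subset=["delta_tm", "delta_dg"])
    if len(df) < 3:
        raise ValueError(f"need at least 3 variants with both experimental values, got {len(df)}")
    _, r2 = pearson_r(df["delta_tm"], df["delta_dg"])
    return r2


def read_experimental_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant stability table (TSV: variant, delta_tm, delta_dG, source).

    Values must be expressed relative to WT; a WT row with both deltas 0 is
    mandatory (it anchors the sign convention of the table).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "delta_tm", "delta_dG"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"experimental table {path} lacks columns {sorted(missing)}")
    wt = df[df["variant"].str.upper() == "WT"]
    if wt.empty:
        raise ValueError(f"experimental table {path} lacks the mandatory WT row")
    if not np.allclose(wt[["delta_tm", "delta_dG"]].astype(float), 0.0):
        raise ValueError("WT row must have delta_tm = delta_dG = 0 (values are relative to WT)")
    return [
        VariantRecord(
            variant=str(row["variant"]),
            score_stat=float("nan"),
            delta_tm=float(row["delta_tm"]),
            delta_dg=float(row["delta_dG"]),
            source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    ]
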