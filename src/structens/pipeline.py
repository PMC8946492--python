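"""End-to-end comparison and calibration workflows with reproducible reports.

The comparison workflow mirrors the variant-vs-reference analysis sequence:
select the best-scoring fraction of each ensemble, build RMSD-vs-score
tables, per-residue flexibility profiles (per-domain alignment) and their
variant-minus-reference difference maps, then aggregate residue-pair
energies over every declared domain interface and test variant and reference
interface-sum distributions against each other (Mann-Whitney, starred).

Configs are declarative (YAML or dict, validated with field paths); every
run directory contains a ``run.log`` recording the seed, versions and the
analysis decisions actually exercised, and a ``manifest.json`` with a SHA-256
per output, so reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__ as _version
from .calibration import CalibrationResult, VariantRecord, calibrate, read_experimental_table
from .domains import DomainMap, Region
from .energetics import (
    PairPotentialParams,
    boxplot_stats,
    compare_interface_distributions,
    interface_sums,
)
from .ensemble import Ensemble
from .io import (
    Edit,
    ResidueCorrespondence,
    StructureModel,
    build_correspondence,
    read_pdb,
    read_score_table,
)
from .selection import select_best, rmsd_vs_score, write_selection_manifest
from .superpose import delta_profile, ensemble_mean_profile_map, per_residue_profile

__all__ = [
    "ComparisonConfig",
    "CalibrationConfig",
    "run_comparison",
    "run_calibration",
    "shift_region",
    "shift_domain_map",
]


# ---------------------------------------------------------------------------
# Config models
# ---------------------------------------------------------------------------


class EditConfig(BaseModel):
    kind: Literal["deletion", "substitution"]
    position: int = Field(ge=1)
    detail: str = ""


class EnsembleConfig(BaseModel):
    pdb_dir: str
    score_file: str
    edits: list[EditConfig] = []
    reference_length: int | None = None  # required when edits are present

    @model_validator(mode="after")
    def _edits_need_length(self) -> "EnsembleConfig":
        if self.edits and self.reference_length is None:
            raise ValueError("reference_length is required when edits are given")
        return self


class ComparisonConfig(BaseModel):
    out_dir: str
    domain_map: str  # YAML file (see DomainMap.from_yaml)
    reference: EnsembleConfig
    variants: dict[str, EnsembleConfig] = Field(min_length=1)
    selection_fraction: float = Field(default=0.05, gt=0, le=1)
    reference_policy: Literal["lowest_scoring", "published"] = "lowest_scoring"
    published_model: str | None = None
    statistic: Literal["rms_deviation", "mean_deviation"] = "rms_deviation"
    map_range: tuple[float, float] = (0.0, 4.0)
    delta_map_range: tuple[float, float] = (-2.0, 2.0)
    seed: int = 0

    @model_validator(mode="after")
    def _policy_needs_model(self) -> "ComparisonConfig":
        if self.reference_policy == "published" and not self.published_model:
            raise ValueError("published_model is required under the 'published' reference policy")
        return self


class CalibrationConfig(BaseModel):
    out_dir: str
    experimental_table: str  # TSV: variant, delta_tm, delta_dG[, source]
    # template_count -> variant name -> score.sc path
    score_tables: dict[int, dict[str, str]] = Field(min_length=1)
    selection_fraction: float = Field(default=0.05, gt=0, le=1)


# ---------------------------------------------------------------------------
# Numbering helpers
# ---------------------------------------------------------------------------


def shift_region(region: Region, corr: ResidueCorrespondence) -> Region:
    """Re-express a reference-numbered region in variant numbering."""
    new_ranges = []
    for lo, hi in region.ranges:
        mapped = [corr.to_variant(r) for r in range(lo, hi + 1)]
        kept = [v for v in mapped if v is not None]
        if kept:
            new_ranges.append((min(kept), max(kept)))
    if not new_ranges:
        raise ValueError(f"region {region.ranges} vanishes under the correspondence")
    return Region(tuple(new_ranges), chain=region.chain)


def shift_domain_map(domain_map: DomainMap, corr: ResidueCorrespondence) -> DomainMap:
    """Re-express every region of a map in variant numbering."""
    dm = DomainMap()
    for name, region in domain_map.regions.items():
        dm.regions[name] = shift_region(region, corr)
    dm.interfaces = list(domain_map.interfaces)
    return dm


# ---------------------------------------------------------------------------
# Comparison workflow
# ---------------------------------------------------------------------------


def _load_config(config, model):
    if isinstance(config, model):
        return config
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    return model.model_validate(config)


def _correspondence_of(cfg: EnsembleConfig) -> ResidueCorrespondence | None:
    if not cfg.edits:
        return None
    edits = [Edit(e.kind, e.position, e.detail) for e in cfg.edits]
    return build_correspondence(cfg.reference_length, edits)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path) -> None:
    entries = {
        str(p.relative_to(out_dir)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out_dir / "manifest.json").write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def run_comparison(
    config: "ComparisonConfig | dict | str | Path" = None,
    *,
    reference_ensemble: Ensemble | None = None,
    variant_ensembles: Mapping[str, tuple[Ensemble, ResidueCorrespondence | None]] | None = None,
    domain_map: DomainMap | None = None,
    out_dir: str | Path | None = None,
    selection_fraction: float = 0.05,
    reference_policy: str = "lowest_scoring",
    published_model: StructureModel | None = None,
    statistic: str = "rms_deviation",
    map_range: tuple[float, float] = (0.0, 4.0),
    delta_map_range: tuple[float, float] = (-2.0, 2.0),
    potential: PairPotentialParams = PairPotentialParams(),
    seed: int = 0,
) -> dict:
    """Run the variant-vs-reference comparison and write a report bundle.

    Either pass a config (file, dict or :class:`ComparisonConfig`) describing
    ensembles on disk, or pass in-memory objects (``reference_ensemble``,
    ``variant_ensembles``, ``domain_map``, ``out_dir``).  Returns a report
    dict; all artefacts land under ``out_dir``.
    """
    if config is not None:
        cfg = _load_config(config, ComparisonConfig)
        domain_map = DomainMap.from_yaml(cfg.domain_map)
        reference_ensemble = Ensemble.from_directory(cfg.reference.pdb_dir, cfg.reference.score_file)
        variant_ensembles = {
            name: (Ensemble.from_directory(v.pdb_dir, v.score_file), _correspondence_of(v))
            for name, v in cfg.variants.items()
        }
        out_dir = cfg.out_dir
        selection_fraction = cfg.selection_fraction
        reference_policy = cfg.reference_policy
        if cfg.reference_policy == "published":
            published_model = read_pdb(cfg.published_model)
        statistic = cfg.statistic
        map_range = cfg.map_range
        delta_map_range = cfg.delta_map_range
        seed = cfg.seed
    if reference_ensemble is None or variant_ensembles is None or domain_map is None or out_dir is None:
        raise ValueError("run_comparison needs a config or all in-memory inputs")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"structens {_version}",
        f"seed {seed}",
        f"selection_fraction {selection_fraction}",
        f"reference_policy {reference_policy}",
        f"per_residue_statistic {statistic} (mean_deviation also emitted)",
        "superposition per-domain Kabsch, equal weights, no outlier rejection",
        "ties in selection broken by model tag (lexicographic)",
    ]

    # 1. selection
    best: dict[str, Ensemble] = {"reference": select_best(reference_ensemble, fraction=selection_fraction)}
    corr_of: dict[str, ResidueCorrespondence | None] = {"reference": None}
    for name, (ens, corr) in sorted(variant_ensembles.items()):
        best[name] = select_best(ens, fraction=selection_fraction)
        corr_of[name] = corr
    for name, ens in best.items():
        write_selection_manifest(ens, out_dir / f"{name}.selected.txt")
        log.append(f"ensemble {name}: {len(ens)} of "
                   f"{len(reference_ensemble) if name == 'reference' else len(variant_ensembles[name][0])} models selected")

    # 2. reference model
    if reference_policy == "lowest_scoring":
        ref_model = reference_ensemble.lowest_scoring_model()
        log.append(f"reference model: lowest-scoring member ({ref_model.model_tag})")
    elif reference_policy == "published":
        if published_model is None:
            raise ValueError("published_model is required under the 'published' reference policy")
        ref_model = published_model
        log.append(f"reference model: published ({ref_model.model_tag})")
    else:
        raise ValueError(f"unknown reference policy {reference_policy!r}")

    # 3. RMSD vs score
    for name, ens in best.items():
        rmsd_vs_score(ens, ref_model, tsv_path=out_dir / f"{name}.rmsd_vs_score.tsv")

    # 4. profiles and difference maps
    profiles: dict[str, pd.DataFrame] = {}
    for name, ens in best.items():
        profiles[name] = per_residue_profile(
            ens, ref_model, domain_map, per_domain=True, correspondence=corr_of[name], seed=seed
        )
        profiles[name].to_csv(out_dir / f"{name}.profile.tsv", sep="\t", float_format="%.6g")
    ensemble_mean_profile_map(
        profiles["reference"], ref_model, *map_range, str(out_dir / "reference.profile_map.pdb"),
        statistic=statistic,
    )

    report: dict = {"ensembles": {n: {"n_selected": len(e)} for n, e in best.items()},
                    "variants": {}, "interfaces": {}}

    score_ref = best["reference"].scores["total_score"].to_numpy()
    for name in sorted(variant_ensembles):
        delta = delta_profile(profiles[name], profiles["reference"])
        delta.to_csv(out_dir / f"{name}.delta_profile.tsv", sep="\t", float_format="%.6g")
        for stat in ("rms_deviation", "mean_deviation"):
            ensemble_mean_profile_map(
                delta, ref_model, *delta_map_range,
                str(out_dir / f"{name}.delta_map.{stat}.pdb"), statistic=stat,
            )
        mw_scores = compare_interface_distributions(
            best[name].scores["total_score"].to_numpy(), score_ref
        )
        report["variants"][name] = {
            "score_shift_u": mw_scores.u,
            "score_shift_p": mw_scores.p,
            "score_shift_label": mw_scores.label,
            "delta_profile_max": float(delta["rms_deviation"].max()),
            "delta_profile_argmax": int(delta["rms_deviation"].idxmax()),
        }
        log.append(f"variant {name}: score-shift Mann-Whitney p={mw_scores.p:.3g} [{mw_scores.label}]")

    # 5. interface energetics
    long_rows = []
    mw_rows = []
    for a, b in domain_map.interfaces:
        key = f"{a}/{b}"
        sums: dict[str, pd.Series] = {}
        for name, ens in best.items():
            dm = domain_map if corr_of[name] is None else shift_domain_map(domain_map, corr_of[name])
            sums[name] = interface_sums(ens, dm, a, b, params=potential)
            for tag, val in sums[name].items():
                long_rows.append({"ensemble": name, "interface": key, "model_tag": tag,
                                  "interface_sum": val})
        report["interfaces"][key] = {"reference": boxplot_stats(sums["reference"])}
        for name in sorted(variant_ensembles):
            mw = compare_interface_distributions(sums[name].to_numpy(), sums["reference"].to_numpy())
            report["interfaces"][key][name] = {**boxplot_stats(sums[name]),
                                               "u": mw.u, "p": mw.p, "label": mw.label}
            mw_rows.append({"interface": key, "variant": name, "u": mw.u, "p": mw.p,
                            "label": mw.label, "method": mw.method})
            log.append(f"interface {key} {name} vs reference: p={mw.p:.3g} [{mw.label}]")
    pd.DataFrame(long_rows).to_csv(out_dir / "interface_sums.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    pd.DataFrame(mw_rows).to_csv(out_dir / "interface_tests.tsv", sep="\t", index=False,
                                 float_format="%.6g")

    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_manifest(out_dir)
    return report


# ---------------------------------------------------------------------------
# Calibration workflow
# ---------------------------------------------------------------------------


def _score_stat_from_table(scores: pd.DataFrame, fraction: float) -> float:
    n = len(scores)
    if n == 0:
        raise ValueError("empty score table")
    k = int(np.ceil(fraction * n))
    ordered = scores.sort_values(["total_score", "model_tag"], kind="stable")
    return float(ordered["total_score"].iloc[:k].mean())


def run_calibration(
    config: "CalibrationConfig | dict | str | Path" = None,
    *,
    score_tables: Mapping[int, Mapping[str, pd.DataFrame]] | None = None,
    experimental: Sequence[VariantRecord] | None = None,
    out_dir: str | Path | None = None,
    selection_fraction: float = 0.05,
) -> CalibrationResult:
    """Run the template-count calibration and write its report.

    For each template count, each variant's score statistic (mean of the
    best-``selection_fraction`` scores) is correlated against the
    experimental ΔTm and ΔΔG; the count with the best mean correlation is
    chosen.  Inputs come from a config (score.sc files + experimental TSV) or
    from in-memory tables/records.
    """
    if config is not None:
        cfg = _load_config(config, CalibrationConfig)
        experimental = read_experimental_table(cfg.experimental_table)
        score_tables = {
            count: {variant: read_score_table(path) for variant, path in sorted(tables.items())}
            for count, tables in cfg.score_tables.items()
        }
        out_dir = cfg.out_dir
        selection_fraction = cfg.selection_fraction
    if score_tables is None or experimental is None or out_dir is None:
        raise ValueError("run_calibration needs a config or all in-memory inputs")

    exp_by_name = {r.variant: r for r in experimental}
    records_by_count: dict[int, list[VariantRecord]] = {}
    for count, tables in sorted(score_tables.items()):
        recs = []
        for variant, scores in sorted(tables.items()):
            if variant not in exp_by_name:
                raise ValueError(f"variant {variant!r} has no row in the experimental table")
            exp = exp_by_name[variant]
            recs.append(
                VariantRecord(
                    variant=variant,
                    score_stat=_score_stat_from_table(scores, selection_fraction),
                    delta_tm=exp.delta_tm,
                    delta_dg=exp.delta_dg,
                    source=exp.source,
                )
            )
        records_by_count[count] = recs

    result = calibrate(records_by_count)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "calibration.tsv", sep="\t", float_format="%.6g")
    for count, recs in records_by_count.items():
        pd.DataFrame(
            [{"variant": r.variant, "score_stat": r.score_stat,
              "delta_tm": r.delta_tm, "delta_dG": r.delta_dg} for r in recs]
        ).to_csv(out_dir / f"scatter.templates_{count}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    chosen = result.table.loc[result.chosen_count]
    (out_dir / "summary.txt").write_text(
        f"chosen template count: {result.chosen_count}\n"
        f"r vs dTm: {chosen['r_dtm']:.3f}\n"
        f"r vs ddG: {chosen['r_ddg']:.3f}\n"
        f"criterion: max mean(r_dTm, r_ddG); ties to the smaller count\n"
    )
    _write_manifest(out_dir)
    return result
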