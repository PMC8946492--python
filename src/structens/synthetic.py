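"""Synthetic multi-domain scaffolds and scored ensembles with known ground truth.

The generator emulates the statistical structure of a refinement/comparative-
modelling ensemble without any physics: a deterministic ideal-helix Cα trace
per domain (rise 1.5 Å, 100° per residue) with pseudo-CB atoms at 1.53 Å,
domains laid out on a grid; per-residue isotropic Gaussian positional noise
whose amplitude is elevated inside named "hot" regions (an SDR-like segment
in the reference, plus an α-helical-subdomain-like segment in the
destabilised variant); a deletion variant with shifted numbering; and total
scores that increase with the realised perturbation magnitude plus Gaussian
noise, so destabilised ensembles score higher (worse) than the reference.

Cross-domain "interface contacts" are planted geometrically: the pseudo-CB
of each designated residue pair is oriented so that the CB-CB distance
equals the inverse of the surrogate pair potential at the pair's target
energy.  Weakening a contact (the variant) moves the pair apart.

Every quantity the pipeline later estimates — per-residue σ, contact
energies, score-model parameters — is exportable as ground truth, and all
randomness flows from the single declared seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from scipy.optimize import brentq

from .domains import DomainMap
from .energetics import PairPotentialParams, pair_potential
from .ensemble import Ensemble
from .io import Edit, ResidueCorrespondence, StructureModel, build_correspondence

__all__ = [
    "DomainLayout",
    "HotRegion",
    "Contact",
    "ScoreModel",
    "GeneratorSpec",
    "make_scaffold",
    "perturb_ensemble",
    "make_variant_spec",
    "export_ground_truth",
    "load_ground_truth",
    "cftr_like_spec",
    "two_domain_spec",
    "contact_distance",
]

# ideal-helix geometry of the scaffold trace
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TURN = math.radians(100.0)  # per residue
_HELIX_RADIUS = 2.3  # Å
_CB_OFFSET = 1.53  # Å, pseudo-side-chain distance from CA
_CLASH_TOL = 2.0  # Å, minimum allowed cross-domain CA distance


@dataclass(frozen=True)
class DomainLayout:
    """One domain: first residue number, length, and grid cell of its helix axis."""

    name: str
    start: int
    length: int
    grid: tuple[int, int] = (0, 0)

    @property
    def stop(self) -> int:  # inclusive
        return self.start + self.length - 1


@dataclass(frozen=True)
class HotRegion:
    """A segment (reference numbering, inclusive) with a σ multiplier."""

    start: int
    end: int
    multiplier: float = 1.0


@dataclass(frozen=True)
class Contact:
    """A planted cross-domain residue pair with a target pair energy (< 0)."""

    res_i: int
    res_j: int
    energy: float


@dataclass(frozen=True)
class ScoreModel:
    """total_score = baseline + coupling·Σ_res ‖displacement‖² + N(0, noise²)."""

    baseline: float = -1000.0
    coupling: float = 1.0
    noise: float = 15.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic study condition (seed mandatory)."""

    domains: tuple[DomainLayout, ...]
    seed: int
    base_sigma: float = 0.4  # Å per axis
    sigma_profile: tuple[tuple[int, float], ...] = ()  # per-residue overrides (reference numbering)
    hot_regions: tuple[tuple[str, HotRegion], ...] = ()
    deletion_position: int | None = None
    score_model: ScoreModel = ScoreModel()
    interface_contacts: tuple[Contact, ...] = ()
    domain_spacing: float = 12.0  # Å between grid cells
    domain_shift_sigma: float = 0.0  # Å; per-model rigid translation noise per domain
    potential: PairPotentialParams = PairPotentialParams()

    def __post_init__(self) -> None:
        if self.base_sigma < 0 or any(s < 0 for _, s in self.sigma_profile):
            raise ValueError("σ values must be non-negative")
        spans = sorted((d.start, d.stop) for d in self.domains)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi:
                raise ValueError("domain residue ranges overlap")
        if self.deletion_position is not None and self._domain_of(self.deletion_position) is None:
            raise ValueError(f"deletion position {self.deletion_position} lies outside every domain")
        for c in self.interface_contacts:
            di, dj = self._domain_of(c.res_i), self._domain_of(c.res_j)
            if di is None or dj is None or di.name == dj.name:
                raise ValueError(f"contact ({c.res_i}, {c.res_j}) is not a cross-domain pair")
            if c.energy >= 0:
                raise ValueError(f"contact energies must be negative, got {c.energy}")

    def _domain_of(self, residue: int) -> DomainLayout | None:
        for d in self.domains:
            if d.start <= residue <= d.stop:
                return d
        return None

    # -- derived quantities --------------------------------------------------

    def reference_residues(self) -> np.ndarray:
        return np.concatenate([np.arange(d.start, d.stop + 1) for d in self.domains])

    def sigma_for(self, reference_residue: int) -> float:
        """Per-axis σ of a residue: profile value × product of hot-region multipliers."""
        sigma = dict(self.sigma_profile).get(reference_residue, self.base_sigma)
        for _, hot in self.hot_regions:
            if hot.start <= reference_residue <= hot.end:
                sigma *= hot.multiplier
        return sigma

    def correspondence(self) -> ResidueCorrespondence | None:
        """Reference→variant numbering map, if this spec carries a deletion."""
        if self.deletion_position is None:
            return None
        length = int(max(d.stop for d in self.domains))
        return build_correspondence(length, [Edit("deletion", self.deletion_position)])

    def domain_map(self) -> DomainMap:
        """Domain map on the *output* numbering (shifted past a deletion)."""
        corr = self.correspondence()
        dm = DomainMap()
        for d in self.domains:
            lo, hi = d.start, d.stop
            if corr is not None:
                residues = [corr.to_variant(r) for r in range(lo, hi + 1)]
                kept = [v for v in residues if v is not None]
                lo, hi = min(kept), max(kept)
            dm.add(d.name, [(lo, hi)])
        names = [d.name for d in self.domains]
        dm.interfaces = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        return dm


def contact_distance(energy: float, params: PairPotentialParams = PairPotentialParams()) -> float:
    """Distance (on the soft outer branch, r0 ≤ d < cutoff) at which the
    shifted pair potential equals ``energy``."""
    e_min = pair_potential(params.r0, params)
    if not e_min <= energy < 0:
        raise ValueError(f"target energy must lie in [{e_min:.4f}, 0), got {energy}")
    return float(brentq(lambda d: pair_potential(d, params) - energy, params.r0, params.cutoff - 1e-9))


def _helix_trace(layout: DomainLayout, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """(CA coords, CB coords) of one domain's ideal helix."""
    j = np.arange(layout.length)
    theta = j * _HELIX_TURN
    axis = np.array([layout.grid[0] * spacing, layout.grid[1] * spacing, 0.0])
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    ca = axis + _HELIX_RADIUS * radial + np.outer(j * _HELIX_RISE, [0.0, 0.0, 1.0])
    cb = ca + _CB_OFFSET * radial  # outward-pointing pseudo side chain
    return ca, cb


def _place_contact_cbs(
    ca: dict[int, np.ndarray], cb: dict[int, np.ndarray], contacts: Sequence[Contact],
    params: PairPotentialParams,
) -> None:
    """Re-orient the pseudo-CBs of each planted contact pair (in place) so the
    CB-CB distance realises the pair's target energy."""
    touched: set[int] = set()
    for c in contacts:
        if c.res_i in touched or c.res_j in touched:
            raise ValueError(f"residue reused across contacts: ({c.res_i}, {c.res_j})")
        touched.update((c.res_i, c.res_j))
        d_t = contact_distance(c.energy, params)
        pi, pj = ca[c.res_i], ca[c.res_j]
        e_ij = pj - pi
        dist = np.linalg.norm(e_ij)
        e_ij = e_ij / dist
        cb_i = pi + _CB_OFFSET * e_ij  # point straight at the partner
        # CB_j on the intersection of spheres |q - cb_i| = d_t and |q - pj| = CB offset
        dvec = pj - cb_i
        dd = np.linalg.norm(dvec)
        if not (abs(d_t - _CB_OFFSET) <= dd <= d_t + _CB_OFFSET):
            raise ValueError(
                f"contact ({c.res_i}, {c.res_j}) infeasible: CA separation {dist:.2f} Å "
                f"cannot realise a CB-CB distance of {d_t:.2f} Å"
            )
        e_d = dvec / dd
        a = (dd**2 + d_t**2 - _CB_OFFSET**2) / (2 * dd)
        h = math.sqrt(max(d_t**2 - a**2, 0.0))
        normal = np.array([0.0, 0.0, 1.0])
        perp = normal - np.dot(normal, e_d) * e_d
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([1.0, 0.0, 0.0]) - e_d[0] * e_d
        perp = perp / np.linalg.norm(perp)
        cb[c.res_i] = cb_i
        cb[c.res_j] = cb_i + a * e_d + h * perp


def make_scaffold(spec: GeneratorSpec) -> StructureModel:
    """Deterministic multi-domain scaffold (CA + pseudo-CB per residue).

    The returned model carries the spec's *output* numbering: if the spec has
    a deletion, that residue is absent and downstream residues are shifted by
    −1 (consistent with the residue correspondence).
    """
    ca: dict[int, np.ndarray] = {}
    cb: dict[int, np.ndarray] = {}
    for layout in spec.domains:
        ca_d, cb_d = _helix_trace(layout, spec.domain_spacing)
        for j in range(layout.length):
            ca[layout.start + j] = ca_d[j]
            cb[layout.start + j] = cb_d[j]

    # clash check between domains
    for da in spec.domains:
        for db in spec.domains:
            if da.name >= db.name:
                continue
            pa = np.array([ca[r] for r in range(da.start, da.stop + 1)])
            pb = np.array([ca[r] for r in range(db.start, db.stop + 1)])
            dmin = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1))
            if dmin < _CLASH_TOL:
                raise ValueError(
                    f"domains {da.name} and {db.name} overlap (min CA distance {dmin:.2f} Å)"
                )

    _place_contact_cbs(ca, cb, spec.interface_contacts, spec.potential)

    corr = spec.correspondence()
    residues = [int(r) for r in spec.reference_residues()]
    out_number: dict[int, int] = {}
    for r in residues:
        if corr is None:
            out_number[r] = r
        else:
            v = corr.to_variant(r)
            if v is not None:
                out_number[r] = v

    kept = sorted(out_number)
    n_atoms = 2 * len(kept)
    arr = struc.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    res_ids = np.empty(n_atoms, dtype=int)
    atom_names = np.empty(n_atoms, dtype="U4")
    for k, r in enumerate(kept):
        coords[2 * k] = ca[r]
        coords[2 * k + 1] = cb[r]
        res_ids[2 * k] = res_ids[2 * k + 1] = out_number[r]
        atom_names[2 * k], atom_names[2 * k + 1] = "CA", "CB"
    arr.coord = coords
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = res_ids
    arr.res_name = np.full(n_atoms, "ALA")
    arr.atom_name = atom_names
    arr.element = np.full(n_atoms, "C")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    arr.set_annotation("b_factor", np.zeros(n_atoms))
    arr.set_annotation("occupancy", np.ones(n_atoms))
    return StructureModel(atoms=arr, model_tag="scaffold", source_path="")


def perturb_ensemble(
    scaffold: StructureModel,
    spec: GeneratorSpec,
    n_models: int,
    seed: int | None = None,
    tag_prefix: str = "m",
) -> Ensemble:
    """Scored ensemble: scaffold + per-residue isotropic Gaussian noise.

    Each residue's CA and pseudo-CB move together by one N(0, σ_r²·I₃) draw
    per model (σ_r from the spec's profile and hot-region multipliers); if
    ``domain_shift_sigma`` is set, each domain additionally receives a rigid
    per-model translation.  total_score couples to the realised local
    displacement: baseline + coupling·Σ_r ‖d_r‖² + N(0, noise²).  All
    randomness flows from ``seed`` (default: the spec's seed).
    """
    if n_models < 2:
        raise ValueError(f"need at least 2 models, got {n_models}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    corr = spec.correspondence()

    res_out = scaffold.residue_numbers()
    ref_of = {r: r for r in res_out} if corr is None else {corr.to_variant(r): r for r in
              (int(x) for x in spec.reference_residues()) if corr.to_variant(r) is not None}
    sigma = np.array([spec.sigma_for(ref_of[int(r)]) for r in res_out])
    n_res = len(res_out)

    atom_res = scaffold.atoms.res_id
    res_index = {int(r): i for i, r in enumerate(res_out)}
    atom_to_res = np.array([res_index[int(r)] for r in atom_res])

    noise = rng.normal(size=(n_models, n_res, 3)) * sigma[None, :, None]
    disp_sq = np.sum(noise**2, axis=(1, 2))
    sm = spec.score_model
    scores = sm.baseline + sm.coupling * disp_sq + rng.normal(scale=sm.noise, size=n_models)

    shifts = None
    if spec.domain_shift_sigma > 0:
        shifts = rng.normal(scale=spec.domain_shift_sigma, size=(n_models, len(spec.domains), 3))
        dom_of_res = np.empty(n_res, dtype=int)
        for di, d in enumerate(spec.domains):
            for r_ref in range(d.start, d.stop + 1):
                v = r_ref if corr is None else corr.to_variant(r_ref)
                if v is not None and v in res_index:
                    dom_of_res[res_index[v]] = di

    width = max(4, len(str(n_models)))
    models: list[StructureModel] = []
    tags: list[str] = []
    for i in range(n_models):
        per_res = noise[i]
        if shifts is not None:
            per_res = per_res + shifts[i][dom_of_res]
        arr = scaffold.atoms.copy()
        arr.coord = scaffold.atoms.coord + per_res[atom_to_res]
        tag = f"{tag_prefix}{i + 1:0{width}d}"
        tags.append(tag)
        models.append(StructureModel(atoms=arr, model_tag=tag))

    score_df = pd.DataFrame({"total_score": scores, "model_tag": tags})
    return Ensemble(models=models, scores=score_df)


def make_variant_spec(
    spec: GeneratorSpec,
    deletion_position: int | None = None,
    destabilized_regions: Mapping[str, float] | None = None,
    weaken_contacts: float = 1.0,
) -> GeneratorSpec:
    """Derive a variant study condition from a reference spec.

    Applies a single-residue deletion (output numbering shifts past the
    site), raises the σ multiplier of the named hot regions, and scales
    planted contact energies toward zero by ``weaken_contacts`` (< 1 weakens).
    The variant draws its own noise stream (seed + 1).
    """
    destabilized_regions = dict(destabilized_regions or {})
    known = {name for name, _ in spec.hot_regions}
    unknown = set(destabilized_regions) - known
    if unknown:
        raise KeyError(f"unknown hot regions: {sorted(unknown)}; known: {sorted(known)}")
    if not 0 < weaken_contacts <= 1:
        raise ValueError(f"weaken_contacts must be in (0, 1], got {weaken_contacts}")
    hot = tuple(
        (name, replace(region, multiplier=destabilized_regions.get(name, region.multiplier)))
        for name, region in spec.hot_regions
    )
    if deletion_position is not None:
        for c in spec.interface_contacts:
            if deletion_position in (c.res_i, c.res_j):
                raise ValueError(f"cannot delete residue {deletion_position}: it anchors a planted contact")
    contacts = tuple(replace(c, energy=c.energy * weaken_contacts) for c in spec.interface_contacts)
    return replace(
        spec,
        deletion_position=deletion_position if deletion_position is not None else spec.deletion_position,
        hot_regions=hot,
        interface_contacts=contacts,
        seed=spec.seed + 1,
    )


# ---------------------------------------------------------------------------
# Ground-truth export / reload
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: GeneratorSpec) -> dict:
    return {
        "domains": [
            {"name": d.name, "start": d.start, "length": d.length, "grid": list(d.grid)}
            for d in spec.domains
        ],
        "seed": spec.seed,
        "base_sigma": spec.base_sigma,
        "sigma_profile": [[r, s] for r, s in spec.sigma_profile],
        "hot_regions": [
            {"name": n, "start": h.start, "end": h.end, "multiplier": h.multiplier}
            for n, h in spec.hot_regions
        ],
        "deletion_position": spec.deletion_position,
        "score_model": {
            "baseline": spec.score_model.baseline,
            "coupling": spec.score_model.coupling,
            "noise": spec.score_model.noise,
        },
        "interface_contacts": [
            {"res_i": c.res_i, "res_j": c.res_j, "energy": c.energy} for c in spec.interface_contacts
        ],
        "domain_spacing": spec.domain_spacing,
        "domain_shift_sigma": spec.domain_shift_sigma,
        "potential": {
            "r0": spec.potential.r0,
            "epsilon": spec.potential.epsilon,
            "cutoff": spec.potential.cutoff,
        },
    }


def _spec_from_dict(doc: dict) -> GeneratorSpec:
    return GeneratorSpec(
        domains=tuple(
            DomainLayout(d["name"], int(d["start"]), int(d["length"]), tuple(d["grid"]))
            for d in doc["domains"]
        ),
        seed=int(doc["seed"]),
        base_sigma=float(doc["base_sigma"]),
        sigma_profile=tuple((int(r), float(s)) for r, s in doc["sigma_profile"]),
        hot_regions=tuple(
            (h["name"], HotRegion(int(h["start"]), int(h["end"]), float(h["multiplier"])))
            for h in doc["hot_regions"]
        ),
        deletion_position=doc["deletion_position"],
        score_model=ScoreModel(**doc["score_model"]),
        interface_contacts=tuple(
            Contact(int(c["res_i"]), int(c["res_j"]), float(c["energy"]))
            for c in doc["interface_contacts"]
        ),
        domain_spacing=float(doc["domain_spacing"]),
        domain_shift_sigma=float(doc["domain_shift_sigma"]),
        potential=PairPotentialParams(**doc["potential"]),
    )


def export_ground_truth(spec: GeneratorSpec, out_dir: str | Path) -> None:
    """Lossless dump of the study condition for recovery tests.

    Writes ``truth_sigma.tsv`` (per reference residue: variant residue — empty
    at a deleted position — and true per-axis σ), ``truth_contacts.tsv``
    (planted pair energies) and ``spec.yaml`` (the full spec, reloadable with
    :func:`load_ground_truth`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corr = spec.correspondence()
    rows = []
    for r in (int(x) for x in spec.reference_residues()):
        v = r if corr is None else corr.to_variant(r)
        rows.append(
            {
                "reference_residue": r,
                "variant_residue": v if v is not None else pd.NA,
                "sigma": spec.sigma_for(r) if v is not None else pd.NA,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "truth_sigma.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"res_i": c.res_i, "res_j": c.res_j, "energy": c.energy} for c in spec.interface_contacts],
        columns=["res_i", "res_j", "energy"],
    ).to_csv(out_dir / "truth_contacts.tsv", sep="\t", index=False)
    (out_dir / "spec.yaml").write_text(yaml.safe_dump(_spec_to_dict(spec), sort_keys=True))


def load_ground_truth(out_dir: str | Path) -> GeneratorSpec:
    """Reload a spec written by :func:`export_ground_truth`."""
    return _spec_from_dict(yaml.safe_load((Path(out_dir) / "spec.yaml").read_text()))


# ---------------------------------------------------------------------------
# Ready-made study conditions
# ---------------------------------------------------------------------------


def _feasible_cross_pairs(
    spec: GeneratorSpec, name_a: str, name_b: str, energy: float, n_pairs: int,
    minimum: int = None,
) -> list[Contact]:
    """Deterministically pick up to ``n_pairs`` cross-domain residue pairs
    whose CA separation can realise ``energy``; raises if fewer than
    ``minimum`` (default: ``n_pairs``) can be placed."""
    minimum = n_pairs if minimum is None else minimum
    d_t = contact_distance(energy, spec.potential)
    lo, hi = d_t, d_t + 2 * _CB_OFFSET  # realizable CA-separation window
    dom = {d.name: d for d in spec.domains}
    ca_a, _ = _helix_trace(dom[name_a], spec.domain_spacing)
    ca_b, _ = _helix_trace(dom[name_b], spec.domain_spacing)
    dists = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
    ia, ib = np.where((dists >= lo + 0.1) & (dists <= hi - 0.1))
    chosen: list[Contact] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for k in np.argsort(dists[ia, ib], kind="stable"):
        ra, rb = dom[name_a].start + int(ia[k]), dom[name_b].start + int(ib[k])
        # keep pairs at least 3 residues apart within each domain so the
        # re-oriented CBs never collide
        if any(abs(ra - u) < 3 for u in used_a) or any(abs(rb - u) < 3 for u in used_b):
            continue
        chosen.append(Contact(ra, rb, energy))
        used_a.add(ra)
        used_b.add(rb)
        if len(chosen) == n_pairs:
            return chosen
    if len(chosen) >= minimum:
        return chosen
    raise ValueError(
        f"could only place {len(chosen)}/{n_pairs} contacts between {name_a} and {name_b}"
    )


def two_domain_spec(
    seed: int,
    length: int = 30,
    base_sigma: float = 0.4,
    hot: tuple[int, int] | None = None,
    hot_multiplier: float = 2.5,
    n_contacts: int = 0,
    contact_energy: float = -0.8,
    **overrides,
) -> GeneratorSpec:
    """Small two-domain condition for unit-scale work.

    Domains ``A`` (1..length) and ``B`` (length+11 .. 2·length+10) sit one
    grid cell apart; ``hot`` optionally marks a flexible segment in ``A``.
    """
    domains = (
        DomainLayout("A", 1, length, (0, 0)),
        DomainLayout("B", length + 11, length, (1, 0)),
    )
    spec = GeneratorSpec(
        domains=domains,
        seed=seed,
        base_sigma=base_sigma,
        hot_regions=(("hot", HotRegion(hot[0], hot[1], hot_multiplier)),) if hot else (),
        **overrides,
    )
    if n_contacts:
        contacts = _feasible_cross_pairs(spec, "A", "B", contact_energy, n_contacts)
        spec = replace(spec, interface_contacts=tuple(contacts))
    return spec


def cftr_like_spec(seed: int, scale: float = 1.0) -> GeneratorSpec:
    """Four-domain study condition echoing the CFTR layout.

    Domain names and landmark numbering follow the real protein — NBD1 spans
    the SDR (526-547) and α-helical subdomain (500-540) presets, and residue
    508 sits inside NBD1 so the canonical deletion variant is expressible.
    ``scale`` < 1 shrinks domain lengths (landmark regions are preserved) for
    cheaper runs.  The reference condition carries an elevated-σ SDR and
    planted contacts on the NBD1/TMD2 and TMD1/NBD2 interfaces.
    """
    def s(n: int) -> int:
        return max(20, int(round(n * scale)))

    domains = (
        DomainLayout("TMD1", 1, s(120), (0, 0)),
        DomainLayout("NBD1", 440, 211, (1, 0)),  # fixed: must cover 500-547
        DomainLayout("TMD2", 845, s(120), (1, 1)),
        DomainLayout("NBD2", 1207, s(120), (0, 1)),
    )
    spec = GeneratorSpec(
        domains=domains,
        seed=seed,
        base_sigma=0.4,
        hot_regions=(
            ("SDR", HotRegion(526, 547, 2.5)),
            ("alpha_subdomain", HotRegion(500, 540, 1.0)),
        ),
    )
    contacts = tuple(
        _feasible_cross_pairs(spec, "NBD1", "TMD2", -0.8, 4, minimum=2)
        + _feasible_cross_pairs(spec, "TMD1", "NBD2", -0.8, 4, minimum=2)
    )
    return replace(spec, interface_contacts=contacts)
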