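"""Structure and score-table I/O, plus residue bookkeeping across deletion variants.

Structural models are stored as :class:`StructureModel`, a thin wrapper around a
biotite ``AtomArray`` carrying a model tag (the identifier used to join a model
to its row in a score table).  Score tables use the Rosetta ``score.sc``
dialect: whitespace-separated lines starting with the token ``SCORE:``, the
first such line being the header and the last column the model tag.

Deletion variants (e.g. a single-residue deletion that shifts all downstream
numbering by one) are handled through :class:`ResidueCorrespondence`, which
maps reference residue numbers to variant residue numbers and back.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Edit",
    "ResidueCorrespondence",
    "PDBFormatError",
    "ScoreTableError",
    "read_pdb",
    "write_pdb",
    "write_pdb_with_per_residue_values",
    "read_score_table",
    "write_score_table",
    "build_correspondence",
    "align_profiles",
    "write_profile_tsv",
]

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PDBFormatError(ValueError):
    """Raised for unreadable or malformed PDB input."""


class ScoreTableError(ValueError):
    """Raised for malformed score tables."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structural model (PDB numbering, Ångström coordinates)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")


@dataclass
class StructureModel:
    """A single structural model: an atom collection plus its ensemble tag."""

    atoms: struc.AtomArray
    model_tag: str = ""
    source_path: str = ""

    def __len__(self) -> int:
        return self.atoms.array_length()

    def __iter__(self) -> Iterator[AtomRecord]:
        a = self.atoms
        for i in range(a.array_length()):
            yield AtomRecord(
                chain_id=str(a.chain_id[i]),
                residue_number=int(a.res_id[i]),
                residue_name=str(a.res_name[i]),
                atom_name=str(a.atom_name[i]),
                position=a.coord[i].copy(),
                occupancy=float(a.occupancy[i]) if "occupancy" in a.get_annotation_categories() else 1.0,
                b_factor=float(a.b_factor[i]) if "b_factor" in a.get_annotation_categories() else 0.0,
                hetero=bool(a.hetero[i]),
            )

    # -- residue-level views -------------------------------------------------

    def ca_table(self, selection: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (residue_numbers, coords) for Cα atoms, ascending residue number.

        ``selection`` optionally restricts to a set of residue numbers.
        """
        a = self.atoms
        mask = (a.atom_name == "CA") & ~a.hetero
        res = a.res_id[mask]
        coord = a.coord[mask]
        order = np.argsort(res, kind="stable")
        res, coord = res[order], coord[order]
        if selection is not None:
            keep = np.isin(res, np.asarray(list(selection), dtype=int))
            res, coord = res[keep], coord[keep]
        return res.astype(int), coord

    def representative_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """Side-chain representative per residue: CB, or CA for glycine.

        Residues lacking both are skipped with a warning.  Returns
        (residue_numbers, coords), ascending residue number.
        """
        a = self.atoms
        prot = a[~a.hetero]
        res_ids: list[int] = []
        coords: list[np.ndarray] = []
        for res_id in np.unique(prot.res_id):
            sub = prot[prot.res_id == res_id]
            cb = sub[sub.atom_name == "CB"]
            if cb.array_length() > 0:
                res_ids.append(int(res_id))
                coords.append(cb.coord[0])
                continue
            ca = sub[sub.atom_name == "CA"]
            if ca.array_length() > 0:
                res_ids.append(int(res_id))
                coords.append(ca.coord[0])
            else:
                warnings.warn(
                    f"residue {res_id} has neither CB nor CA; skipped as interaction site",
                    stacklevel=2,
                )
        if not coords:
            return np.empty(0, dtype=int), np.empty((0, 3))
        return np.asarray(res_ids, dtype=int), np.asarray(coords)

    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue numbers of non-hetero residues."""
        a = self.atoms
        return np.unique(a.res_id[~a.hetero]).astype(int)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _locate_malformed_line(path: Path) -> int | None:
    """Best-effort scan for the first fixed-column ATOM/HETATM line that does
    not parse, to report a line number in error messages."""
    try:
        lines = path.read_text().splitlines()
    except OSError:
        return None
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        try:
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except (ValueError, IndexError):
            return lineno
    return None


def read_pdb(
    path: str | Path,
    *,
    keep_hetatm: bool = False,
    model_tag: str | None = None,
) -> StructureModel:
    """Read a fixed-column PDB file into a :class:`StructureModel`.

    Alternate locations: atoms with alt-loc blank or ``A`` are kept; any other
    alt-loc is discarded with a warning.  Waters are always dropped; HETATM
    records (ligands, ions) are kept only when ``keep_hetatm`` is set.
    Insertion codes are not supported and raise :class:`PDBFormatError`.
    """
    path = Path(path)
    if not path.is_file():
        raise PDBFormatError(f"cannot read PDB file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, extra_fields=["b_factor", "occupancy"], altloc="all")
    except Exception as exc:  # biotite raises several types for bad input
        lineno = _locate_malformed_line(path)
        if lineno is not None:
            raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno} of {path}") from exc
        raise PDBFormatError(f"failed to parse PDB file {path}: {exc}") from exc

    if arr.array_length() == 0:
        raise PDBFormatError(f"no ATOM records in {path}")

    ins = arr.get_annotation("ins_code")
    if np.any(ins != ""):
        bad = np.unique(arr.res_id[ins != ""])
        raise PDBFormatError(f"insertion codes are unsupported (residues {bad.tolist()} in {path})")

    altloc = arr.get_annotation("altloc_id")
    keep_alt = np.isin(altloc, [" ", "", ".", "A"])
    if not np.all(keep_alt):
        dropped = sorted(set(altloc[~keep_alt]))
        warnings.warn(
            f"discarding {int(np.sum(~keep_alt))} atoms with alternate locations {dropped} in {path}",
            stacklevel=2,
        )
    arr = arr[keep_alt]

    arr = arr[~np.isin(arr.res_name, list(_WATER_NAMES))]
    if not keep_hetatm:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise PDBFormatError(f"no atoms left after filtering in {path}")

    return StructureModel(atoms=arr, model_tag=model_tag or path.stem, source_path=str(path))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as a fixed-column PDB file."""
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


# B-factor column is 6 characters, %6.2f
_B_FACTOR_MIN, _B_FACTOR_MAX = -99.99, 999.99


def write_pdb_with_per_residue_values(
    model: StructureModel,
    values: Mapping[int, float],
    path: str | Path,
) -> None:
    """Write a PDB whose B-factor column carries a per-residue value.

    Every atom of a residue gets that residue's value (clipped to the numeric
    width of the B-factor field); residues without a value get 0.00.  Values
    keyed on residues absent from the model are ignored with a warning.
    """
    present = set(int(r) for r in np.unique(model.atoms.res_id))
    missing = [r for r in values if int(r) not in present]
    if missing:
        warnings.warn(
            f"per-residue values for residues absent from the model ignored: {sorted(missing)}",
            stacklevel=2,
        )
    for v in values.values():
        if not math.isfinite(v):
            raise ValueError("per-residue values must be finite")

    arr = model.atoms.copy()
    b = np.zeros(arr.array_length())
    for res, val in values.items():
        b[arr.res_id == int(res)] = float(np.clip(val, _B_FACTOR_MIN, _B_FACTOR_MAX))
    arr.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Score tables (Rosetta score.sc dialect)
# ---------------------------------------------------------------------------


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Parse a ``score.sc``-style table.

    Lines starting with ``SCORE:`` are data; the first is the header.  The
    last column holds the model tag (Rosetta's ``description``).  Returns a
    DataFrame with a ``model_tag`` column, a ``total_score`` float column and
    any extra numeric columns, in file order.
    """
    path = Path(path)
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        if line.startswith("SCORE:"):
            rows.append(line.split()[1:])
    if not rows:
        raise ScoreTableError(f"no SCORE: header line in {path}")
    header, data = rows[0], rows[1:]
    if "total_score" not in header:
        raise ScoreTableError(f"score table {path} lacks a total_score column")
    tag_col = header[-1]
    records = []
    for fields in data:
        if len(fields) != len(header):
            raise ScoreTableError(
                f"score table {path}: row with {len(fields)} fields does not match header ({len(header)})"
            )
        records.append(fields)
    df = pd.DataFrame(records, columns=header)
    df = df.rename(columns={tag_col: "model_tag"})
    for col in df.columns:
        if col != "model_tag":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if df.empty:
        return pd.DataFrame({"total_score": pd.Series(dtype=float), "model_tag": pd.Series(dtype=str)})
    if not np.all(np.isfinite(df["total_score"].to_numpy(dtype=float))):
        raise ScoreTableError(f"non-finite total_score in {path}")
    dup = df["model_tag"][df["model_tag"].duplicated()]
    if len(dup):
        raise ScoreTableError(f"duplicate model tags in {path}: {sorted(set(dup))}")
    return df.reset_index(drop=True)


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table in the ``score.sc`` dialect (tag last, as ``description``)."""
    cols = [c for c in scores.columns if c != "model_tag"]
    buf = _io.StringIO()
    buf.write("SCORE: " + " ".join(cols + ["description"]) + "\n")
    for _, row in scores.iterrows():
        vals = [f"{row[c]:.3f}" for c in cols]
        buf.write("SCORE: " + " ".join(vals + [str(row["model_tag"])]) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Residue correspondence across deletion variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """A sequence edit relative to the reference numbering."""

    kind: Literal["deletion", "substitution"]
    reference_position: int
    detail: str = ""


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Mapping between reference and variant residue numbering.

    Deletions shift all downstream variant numbers by −1 each; substitutions
    leave numbering intact but are recorded.  The mapping is strictly
    increasing on mapped positions and invertible on its image.
    """

    reference_length: int
    edits: tuple[Edit, ...] = field(default_factory=tuple)

    @property
    def deleted_positions(self) -> frozenset[int]:
        return frozenset(e.reference_position for e in self.edits if e.kind == "deletion")

    def to_variant(self, reference_position: int) -> int | None:
        """Variant residue number for a reference position, or None if deleted."""
        if not 1 <= reference_position <= self.reference_length:
            raise KeyError(f"reference position {reference_position} outside 1..{self.reference_length}")
        deleted = self.deleted_positions
        if reference_position in deleted:
            return None
        shift = sum(1 for d in deleted if d < reference_position)
        return reference_position - shift

    def to_reference(self, variant_position: int) -> int:
        """Reference residue number for a variant position."""
        n_del = len(self.deleted_positions)
        if not 1 <= variant_position <= self.reference_length - n_del:
            raise KeyError(
                f"variant position {variant_position} outside 1..{self.reference_length - n_del}"
            )
        # invert the monotone shift by walking the sorted deletions
        ref = variant_position
        for d in sorted(self.deleted_positions):
            if d <= ref:
                ref += 1
        return ref

    def mapping(self) -> dict[int, int | None]:
        """Full reference → variant mapping (None at deleted positions)."""
        return {i: self.to_variant(i) for i in range(1, self.reference_length + 1)}


def build_correspondence(reference_length: int, edits: Sequence[Edit]) -> ResidueCorrespondence:
    """Validate edits and build a :class:`ResidueCorrespondence`.

    Deletions must be non-overlapping (distinct positions) and all edit
    positions must lie within ``1..reference_length``.
    """
    for e in edits:
        if not 1 <= e.reference_position <= reference_length:
            raise ValueError(
                f"edit position {e.reference_position} outside 1..{reference_length}"
            )
    del_pos = [e.reference_position for e in edits if e.kind == "deletion"]
    if len(del_pos) != len(set(del_pos)):
        raise ValueError(f"overlapping deletions at {sorted(set(p for p in del_pos if del_pos.count(p) > 1))}")
    return ResidueCorrespondence(reference_length=reference_length, edits=tuple(edits))


def align_profiles(
    profile: pd.DataFrame | pd.Series,
    correspondence: ResidueCorrespondence,
) -> pd.DataFrame | pd.Series:
    """Re-index a per-residue profile from variant numbering to reference numbering.

    Reference positions that are deleted in the variant carry NaN.  Raises if
    the profile contains residues outside the correspondence's variant range.
    """
    n_del = len(correspondence.deleted_positions)
    variant_max = correspondence.reference_length - n_del
    idx = np.asarray(profile.index, dtype=int)
    bad = idx[(idx < 1) | (idx > variant_max)]
    if len(bad):
        raise KeyError(f"profile residues outside the correspondence: {bad.tolist()}")
    ref_index = range(1, correspondence.reference_length + 1)
    variant_of = [correspondence.to_variant(r) for r in ref_index]
    out = profile.reindex([v if v is not None else -1 for v in variant_of])
    out.index = pd.Index(ref_index, name="residue_number")
    return out


def write_profile_tsv(profile: pd.DataFrame | pd.Series, path: str | Path, value_name: str = "value") -> None:
    """Export a per-residue profile as a 2+-column TSV (residue_number first)."""
    df = profile.to_frame(name=value_name) if isinstance(profile, pd.Series) else profile
    df = df.copy()
    df.index.name = "residue_number"
    df.to_csv(path, sep="\t", float_format="%.6g")
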