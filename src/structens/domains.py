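"""Named residue ranges: domains, interfaces, and analysis regions.

A :class:`DomainMap` names sets of residue ranges (e.g. the four structured
domains of an ABC transporter) and the domain pairs whose interfaces are
analysed.  Ranges are inclusive, in PDB numbering.  Maps round-trip through a
plain YAML config so region definitions live outside code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = ["Region", "DomainMap", "cftr_domain_map", "CFTR_NBD1_PRESETS"]


@dataclass(frozen=True)
class Region:
    """A named set of inclusive residue ranges on one chain."""

    ranges: tuple[tuple[int, int], ...]
    chain: str = "A"

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"empty range {lo}-{hi}")
        spans = sorted(self.ranges)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi:
                raise ValueError(f"overlapping ranges in region: {self.ranges}")

    def contains(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.ranges)

    def residues(self) -> np.ndarray:
        return np.concatenate([np.arange(lo, hi + 1) for lo, hi in self.ranges])

    def mask(self, residue_numbers: np.ndarray) -> np.ndarray:
        out = np.zeros(len(residue_numbers), dtype=bool)
        for lo, hi in self.ranges:
            out |= (residue_numbers >= lo) & (residue_numbers <= hi)
        return out


@dataclass
class DomainMap:
    """Named regions plus the list of domain pairs treated as interfaces."""

    regions: dict[str, Region] = field(default_factory=dict)
    interfaces: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.interfaces:
            for name in (a, b):
                if name not in self.regions:
                    raise KeyError(f"interface names unknown region {name!r}")

    def __getitem__(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}; known: {sorted(self.regions)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return list(self.regions)

    def add(self, name: str, ranges: Iterable[tuple[int, int]], chain: str = "A") -> None:
        if name in self.regions:
            raise ValueError(f"region {name!r} already defined")
        self.regions[name] = Region(tuple((int(a), int(b)) for a, b in ranges), chain=chain)

    # -- config round-trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "regions": {
                name: {"chain": r.chain, "ranges": [list(span) for span in r.ranges]}
                for name, r in self.regions.items()
            },
            "interfaces": [list(pair) for pair in self.interfaces],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        doc = yaml.safe_load(Path(path).read_text())
        regions = {
            name: Region(
                tuple((int(a), int(b)) for a, b in entry["ranges"]),
                chain=entry.get("chain", "A"),
            )
            for name, entry in doc.get("regions", {}).items()
        }
        interfaces = [tuple(pair) for pair in doc.get("interfaces", [])]
        return cls(regions=regions, interfaces=interfaces)


# ---------------------------------------------------------------------------
# CFTR presets
# ---------------------------------------------------------------------------

# Determined residue ranges of the two experimental multi-domain human CFTR
# structures.  The dephosphorylated/inactive structure (PDB 5UAK) misses the
# regulatory insertion (403-438); the phosphorylated/active structure
# (PDB 6MSM) has NBD1 determined only to 637.
_CFTR_RANGES = {
    "inactive": {  # 5UAK
        "TMD1": [(5, 402)],
        "NBD1": [(439, 645)],
        "TMD2": [(845, 883), (909, 1172)],
        "NBD2": [(1207, 1436)],
    },
    "active": {  # 6MSM
        "TMD1": [(1, 409)],
        "NBD1": [(435, 637)],
        "TMD2": [(845, 889), (900, 1173)],
        "NBD2": [(1202, 1451)],
    },
}

# Three NBD1 range sets in circulation for the same construct; all are kept
# as named presets rather than silently merged.
CFTR_NBD1_PRESETS: dict[str, tuple[tuple[int, int], ...]] = {
    # truncation used to build the single-domain construct (Y385..M645, RI gap removed)
    "nbd1_truncation": ((385, 402), (439, 645)),
    # range quoted for the suppressor-mutation simulations
    "nbd1_sss": ((385, 402), (435, 644)),
    # residues determined in both conformations, used for cross-state superposition
    "nbd1_cross_state": ((385, 402), (439, 637)),
}

# Flexibility landmarks within NBD1 (PDB numbering).  The structurally
# diverse region is quoted both as 526-547 and 527-547 in the literature;
# the wider span is used here.
_CFTR_REGIONS = {
    "SDR": [(526, 547)],
    "alpha_subdomain": [(500, 540)],
}

_CFTR_INTERFACES = [("NBD1", "NBD2"), ("NBD1", "TMD2"), ("TMD1", "NBD2"), ("TMD1", "TMD2")]


def cftr_domain_map(state: str = "inactive") -> DomainMap:
    """Domain map for human CFTR in the ``inactive`` (5UAK-numbered) or
    ``active`` (6MSM-numbered) conformation, with SDR / α-helical-subdomain
    regions and the three NBD1 range presets included as named regions."""
    if state not in _CFTR_RANGES:
        raise KeyError(f"state must be one of {sorted(_CFTR_RANGES)}, got {state!r}")
    dm = DomainMap()
    for name, ranges in _CFTR_RANGES[state].items():
        dm.add(name, ranges)
    for name, ranges in _CFTR_REGIONS.items():
        dm.add(name, ranges)
    for name, ranges in CFTR_NBD1_PRESETS.items():
        dm.add(name, ranges)
    dm.interfaces = list(_CFTR_INTERFACES)
    return dm
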