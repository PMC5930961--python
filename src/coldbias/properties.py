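"""Per-amino-acid numeric property tables.

Five default tables ship with the package, read from 2-column TSVs
(amino-acid letter, value) with a header naming the property:

- ``molecular_weight`` — free-amino-acid masses in Da (Gly 75.07 smallest,
  Trp 204.23 largest).
- ``size`` — residue volume in cubic angstroms (Zamyatnin-style), shipped as
  a substitute for the original size index.
- ``graph_shape`` — side-chain graph shape index, shipped as a substitute
  for the original shape index.
- ``polarity`` — Grantham polarity.
- ``hydrophobicity`` — Kyte-Doolittle hydropathy.

The size/graph-shape/polarity/hydrophobicity defaults are well-known
published AAindex-style scales chosen as reasonable substitutes; users with
a specific index should load their own TSV via :func:`read_property_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .codon_core import AMINO_ACIDS

DEFAULT_PROPERTIES = (
    "molecular_weight",
    "size",
    "graph_shape",
    "polarity",
    "hydrophobicity",
)


@dataclass(frozen=True)
class PropertyTable:
    """A named numeric index over the 20 standard amino acids."""

    property_name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            raise ValueError(
                f"property table {self.property_name!r} must cover exactly the 20 "
                f"standard amino acids; got {len(keys)} entries"
            )

    def __getitem__(self, amino_acid: str) -> float:
        return self.values[amino_acid]


def read_property_table(path: str | Path) -> PropertyTable:
    """Read a 2-column TSV (header row names the property) into a table."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty property table")
    header = lines[0].split("\t")
    if len(header) != 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns, got {len(header)}")
    name = header[1].strip()
    values: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        aa = fields[0].strip()
        values[aa] = float(fields[1])
    return PropertyTable(property_name=name, values=values)


def default_property_table(name: str) -> PropertyTable:
    """Load one of the five bundled property tables by name."""
    if name not in DEFAULT_PROPERTIES:
        raise KeyError(f"unknown default property {name!r}; choose from {DEFAULT_PROPERTIES}")
    ref = resources.files("coldbias.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return read_property_table(path)


def default_property_tables() -> dict[str, PropertyTable]:
    return {name: default_property_table(name) for name in DEFAULT_PROPERTIES}
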