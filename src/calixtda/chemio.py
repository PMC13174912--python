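"""Molecular geometry and dataset-manifest I/O.

Structures are plain atomic point clouds: element symbols plus Cartesian
coordinates in Angstrom, read from standard XYZ files.  Dataset manifests are
CSV tables pairing structure identifiers with scaffold family, substitution
site, substituent SMILES, conformation label and (for labelled rows) the CO2
adsorption enthalpy in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MoleculePointCloud",
    "ManifestRow",
    "ElementTable",
    "DEFAULT_ELEMENT_TABLE",
    "FAMILIES",
    "SITES",
    "CONFORMATIONS",
    "XYZParseError",
    "ManifestError",
    "read_xyz",
    "write_xyz",
    "load_manifest",
    "write_manifest",
]

FAMILIES = ("calix", "aza", "oxa", "thia")
SITES = ("para", "meta", "bridge", "lower", "none")
CONFORMATIONS = ("cone", "partial_cone", "alt12", "alt13", "undetermined")

#: Families whose bridging atom (O, S) carries no substitutable hydrogen.
FAMILIES_WITHOUT_BRIDGE_SITE = ("oxa", "thia")


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the expected dialect."""


class ManifestError(ValueError):
    """Raised when a manifest row violates the family/site rules."""


class ElementTable:
    """Pauling electronegativities and standard valences for the supported elements.

    Lookups of unknown symbols raise ``KeyError`` rather than silently
    defaulting; descriptor pipelines must fail loudly on exotic atoms.
    """

    _CHI = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98, "S": 2.58}
    _VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "S": 2}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._CHI

    def electronegativity(self, symbol: str) -> float:
        try:
            return self._CHI[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in element table") from None

    def valence(self, symbol: str) -> int:
        try:
            return self._VALENCE[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in element table") from None

    def symbols(self) -> tuple[str, ...]:
        return tuple(self._CHI)


DEFAULT_ELEMENT_TABLE = ElementTable()


@dataclass
class MoleculePointCloud:
    """One host structure as an atomic point cloud (symbols + Cartesian Å)."""

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray
    comment: str = ""

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{self.id}: {len(self.elements)} symbols but "
                f"{len(self.coords)} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        for sym in self.elements:
            if sym not in DEFAULT_ELEMENT_TABLE:
                raise ValueError(f"{self.id}: unknown element {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def _normalize_symbol(token: str) -> str:
    return token[:1].upper() + token[1:].lower()


def read_xyz(path: str | Path) -> MoleculePointCloud:
    """Parse a standard XYZ file into a point cloud.

    Line 1 is the atom count, line 2 a free-form comment, then one
    ``El x y z`` record per atom.  The declared count must match the number
    of atom records exactly.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}:1: atom count is not an integer") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise XYZParseError(
            f"{path}: declared {n} atoms but found {len(body)} atom lines"
        )
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for k, ln in enumerate(body, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}:{k}: expected 'El x y z'")
        sym = _normalize_symbol(parts[0])
        if sym not in DEFAULT_ELEMENT_TABLE:
            raise XYZParseError(f"{path}:{k}: unknown element {parts[0]!r}")
        try:
            xyz = tuple(float(v) for v in parts[1:4])
        except ValueError:
            raise XYZParseError(f"{path}:{k}: non-numeric coordinate") from None
        if not all(math.isfinite(v) for v in xyz):
            raise XYZParseError(f"{path}:{k}: non-finite coordinate")
        elements.append(sym)
        coords.append(xyz)
    arr = np.array(coords, dtype=float) if coords else np.zeros((0, 3))
    return MoleculePointCloud(id=path.stem, elements=tuple(elements), coords=arr, comment=comment)


def write_xyz(cloud: MoleculePointCloud, path: str | Path) -> None:
    """Write a point cloud as XYZ text with 6-decimal fixed formatting."""
    path = Path(path)
    lines = [str(cloud.n_atoms), ""]
    for sym, (x, y, z) in zip(cloud.elements, cloud.coords):
        lines.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ManifestRow:
    """One dataset entry: structure identity, provenance metadata and label.

    ``delta_h`` is the CO2 adsorption enthalpy in kcal/mol; ``None`` marks an
    unlabelled candidate row.
    """

    structure_id: str
    family: str
    site: str = "none"
    substituent: str = ""
    conformation: str = ""
    delta_h: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ManifestError(
                f"{self.structure_id}: unknown family {self.family!r}"
            )
        if self.site not in SITES:
            raise ManifestError(f"{self.structure_id}: unknown site {self.site!r}")
        if self.family in FAMILIES_WITHOUT_BRIDGE_SITE and self.site == "bridge":
            raise ManifestError(
                f"{self.structure_id}: family {self.family!r} has no bridge "
                "substitution site"
            )
        if self.conformation and self.conformation not in CONFORMATIONS:
            raise ManifestError(
                f"{self.structure_id}: unknown conformation {self.conformation!r}"
            )
        if self.delta_h is not None and not math.isfinite(self.delta_h):
            raise ManifestError(f"{self.structure_id}: non-finite delta_h")

    @property
    def is_candidate(self) -> bool:
        """True when the row carries no enthalpy label."""
        return self.delta_h is None


MANIFEST_COLUMNS = (
    "structure_id",
    "family",
    "site",
    "substituent",
    "conformation",
    "delta_h",
)


def load_manifest(path: str | Path) -> list[ManifestRow]:
    """Read and validate a manifest CSV; missing delta_h marks candidates."""
    df = pd.read_csv(path, dtype={"structure_id": str}, keep_default_na=True)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {sorted(missing)}")
    rows: list[ManifestRow] = []
    for rec in df.to_dict(orient="records"):
        dh = rec["delta_h"]
        dh = None if dh is None or (isinstance(dh, float) and math.isnan(dh)) else float(dh)

        def _s(v: object) -> str:
            return "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)

        rows.append(
            ManifestRow(
                structure_id=str(rec["structure_id"]),
                family=_s(rec["family"]),
                site=_s(rec["site"]) or "none",
                substituent=_s(rec["substituent"]),
                conformation=_s(rec["conformation"]),
                delta_h=dh,
            )
        )
    return rows


def write_manifest(rows: Iterable[ManifestRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "family": r.family,
                "site": r.site,
                "substituent": r.substituent,
                "conformation": r.conformation,
                "delta_h": "" if r.delta_h is None else r.delta_h,
            }
            for r in rows
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)
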