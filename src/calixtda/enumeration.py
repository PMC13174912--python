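"""Candidate library enumeration for the four calix[4]arene scaffold families.

The four parent macrocycles (calix[4]arene, azacalix[4]arene,
oxacalix[4]arene, thiacalix[4]arene) are functionalized symmetrically: one
substituent SMILES is attached at all four equivalent positions of a chosen
site class (para, meta, lower rim, or — for calix and aza only — the bridging
atom).  Attachment semantics: the FIRST atom of the substituent SMILES bonds
to the scaffold site by a single bond, so a substituent is viable only when
that atom retains at least one free valence (an implicit hydrogen to give
up).  ``FC`` is therefore rejected — its leading fluorine is already
saturated — while bare ``O`` and ``CO`` are retained but rewritten to
explicit single-bond hydroxyl / hydroxymethyl attachment.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .chemio import ElementTable, DEFAULT_ELEMENT_TABLE, FAMILIES

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "SubstituentRecord",
    "ScaffoldSpec",
    "CandidateIdentity",
    "SCAFFOLDS",
    "SubstituentError",
    "EnumerationError",
    "load_substituent_list",
    "bundled_substituents",
    "filter_substituents",
    "build_product_smiles",
    "enumerate_library",
    "write_library_csv",
]

ALLOWED_SUBSTITUENT_ELEMENTS = {"C", "N", "O", "F"}

#: Substituent used for the manually-added p-tert-butyl variants.
TERT_BUTYL = "C(C)(C)C"

#: Manual single-bond rewrites for strings whose naive attachment would
#: otherwise be read as a double-bonded oxygen / carbonyl.
CORRECTIONS = {"O": "[OH]", "CO": "C[OH]"}

BRIDGE_ATOM = {"calix": "C", "aza": "N", "oxa": "O", "thia": "S"}


class SubstituentError(ValueError):
    """Raised for unparseable or out-of-alphabet substituent SMILES."""


class EnumerationError(ValueError):
    """Raised for incompatible (family, site) requests."""


@dataclass
class SubstituentRecord:
    """Outcome of the valency filter for one raw substituent SMILES."""

    smiles: str
    attachment_atom: str
    status: str  # accepted | rejected | corrected
    corrected_smiles: str = ""
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == "rejected" and not self.reason:
            raise ValueError("rejected substituent needs a reason")
        if self.status == "corrected" and not self.corrected_smiles:
            raise ValueError("corrected substituent needs a corrected SMILES")

    @property
    def effective_smiles(self) -> str:
        """SMILES actually used for attachment (corrected form if any)."""
        return self.corrected_smiles if self.status == "corrected" else self.smiles


@dataclass(frozen=True)
class ScaffoldSpec:
    """One macrocycle family and its substitutable site classes."""

    family: str
    bridge_atom: str
    has_bridge_site: bool

    @property
    def sites(self) -> tuple[str, ...]:
        base = ("para", "meta", "lower")
        return base + (("bridge",) if self.has_bridge_site else ())

    @property
    def parent_smiles(self) -> str:
        return build_product_smiles(self.family, "none", "")


SCAFFOLDS: dict[str, ScaffoldSpec] = {
    fam: ScaffoldSpec(
        family=fam,
        bridge_atom=BRIDGE_ATOM[fam],
        has_bridge_site=fam in ("calix", "aza"),
    )
    for fam in FAMILIES
}


@dataclass
class CandidateIdentity:
    """One enumerated candidate: identity plus product SMILES."""

    candidate_id: str
    family: str
    site: str
    substituent: str
    product_smiles: str
    status: str = "ok"  # ok | failed


def load_substituent_list(path: str | Path) -> list[str]:
    """Read one SMILES per line; '#' comments and blank lines are skipped."""
    out: list[str] = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        s = ln.split("#", 1)[0].strip()
        if s:
            out.append(s)
    return out


def bundled_substituents() -> list[str]:
    """The bundled 26-string small-substituent library (1-3 heavy atoms)."""
    text = resources.files("calixtda.data").joinpath("substituents_gdb3.smi").read_text()
    return [s.split("#", 1)[0].strip() for s in text.splitlines() if s.split("#", 1)[0].strip()]


def filter_substituents(
    smiles_list: Sequence[str],
    element_table: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> list[SubstituentRecord]:
    """Apply the attachment-valency filter to a raw SMILES list.

    A string is accepted when its first atom carries at least one hydrogen
    (implicit or explicit) that can be traded for the new single bond to the
    scaffold.  The two known problem strings (``O``, ``CO``) are accepted
    with a corrected explicit-hydroxyl form.
    """
    records: list[SubstituentRecord] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            raise SubstituentError(f"unparseable substituent SMILES {smi!r}")
        bad = {a.GetSymbol() for a in mol.GetAtoms()} - ALLOWED_SUBSTITUENT_ELEMENTS
        if bad:
            raise SubstituentError(
                f"substituent {smi!r} uses elements outside C/N/O/F: {sorted(bad)}"
            )
        first = mol.GetAtomWithIdx(0)
        sym = first.GetSymbol()
        element_table.valence(sym)  # fail loudly on unknown symbols
        if smi in CORRECTIONS:
            records.append(
                SubstituentRecord(
                    smiles=smi,
                    attachment_atom=sym,
                    status="corrected",
                    corrected_smiles=CORRECTIONS[smi],
                    reason="rewritten to explicit single-bond attachment",
                )
            )
        elif first.GetTotalNumHs() >= 1:
            records.append(
                SubstituentRecord(smiles=smi, attachment_atom=sym, status="accepted")
            )
        else:
            records.append(
                SubstituentRecord(
                    smiles=smi,
                    attachment_atom=sym,
                    status="rejected",
                    reason=(
                        f"first atom {sym} is saturated: no free valence for a "
                        "single bond to the scaffold site"
                    ),
                )
            )
    return records


_RING_DIGIT = re.compile(r"%\d{2}|\d")


def _remap_ring_digits(sub: str) -> str:
    """Renumber ring-closure digits in a substituent to 7/8/9.

    The scaffold template reserves digits 1-4 and %91; substituent ring
    closures are local, so a fixed remap avoids collisions across the four
    symmetric copies.
    """
    mapping: dict[str, str] = {}
    pool = iter(["7", "8", "9", "%94", "%95", "%96"])

    def repl(m: re.Match[str]) -> str:
        tok = m.group(0)
        if tok not in mapping:
            mapping[tok] = next(pool)
        return mapping[tok]

    return _RING_DIGIT.sub(repl, sub)


def _unit(digit: int, para: str, meta: str, lower: str, closure: str) -> str:
    p = f"({para})" if para else ""
    m = f"({meta})" if meta else ""
    return f"c{digit}c{m}c{p}cc{closure}(c{digit}O{lower})"


def build_product_smiles(family: str, site: str, substituent: str) -> str:
    """Assemble the SMILES of a symmetrically tetra-functionalized macrocycle.

    ``site='none'`` (with empty substituent) yields the unfunctionalized
    parent.  Lower-rim substitution replaces the phenolic hydrogen (O-R).
    """
    spec = SCAFFOLDS[family]
    if site == "none":
        if substituent:
            raise EnumerationError("site 'none' admits no substituent")
        sub = ""
    else:
        if site not in spec.sites:
            raise EnumerationError(f"family {family!r} has no {site!r} site")
        sub = _remap_ring_digits(substituent)
    parts: list[str] = []
    for i in range(4):
        bridge = spec.bridge_atom + ("%91" if i == 0 else "")
        if site == "bridge" and sub:
            bridge += f"({sub})"
        parts.append(bridge)
        parts.append(
            _unit(
                i + 1,
                para=sub if site == "para" else "",
                meta=sub if site == "meta" else "",
                lower=sub if site == "lower" else "",
                closure="%91" if i == 3 else "",
            )
        )
    return "".join(parts)


def enumerate_library(
    families: Iterable[str] = FAMILIES,
    substituents: Sequence[SubstituentRecord] | None = None,
    include_manual_extras: bool = False,
) -> list[CandidateIdentity]:
    """Enumerate one candidate per (family, site, substituent).

    With ``include_manual_extras`` the unfunctionalized parent and the
    p-tert-butyl para variant are appended per family.  Products that fail
    SMILES round-trip parsing are flagged ``failed`` rather than dropped, so
    the exclusion is auditable.
    """
    if substituents is None:
        substituents = filter_substituents(bundled_substituents())
    usable = [r for r in substituents if r.status in ("accepted", "corrected")]
    out: list[CandidateIdentity] = []
    for fam in families:
        spec = SCAFFOLDS[fam]
        for site in spec.sites:
            for k, rec in enumerate(usable):
                smi = build_product_smiles(fam, site, rec.effective_smiles)
                mol = Chem.MolFromSmiles(smi)
                status = "ok" if mol is not None else "failed"
                product = Chem.MolToSmiles(mol) if mol is not None else smi
                out.append(
                    CandidateIdentity(
                        candidate_id=f"{fam}-{site}-{k:03d}",
                        family=fam,
                        site=site,
                        substituent=rec.smiles,
                        product_smiles=product,
                        status=status,
                    )
                )
        if include_manual_extras:
            for tag, site, sub in (
                ("parent", "none", ""),
                ("ptbu", "para", TERT_BUTYL),
            ):
                smi = build_product_smiles(fam, site, sub)
                mol = Chem.MolFromSmiles(smi)
                out.append(
                    CandidateIdentity(
                        candidate_id=f"{fam}-{tag}",
                        family=fam,
                        site=site,
                        substituent=sub,
                        product_smiles=Chem.MolToSmiles(mol) if mol else smi,
                        status="ok" if mol is not None else "failed",
                    )
                )
    ids = [c.candidate_id for c in out]
    if len(ids) != len(set(ids)):
        raise EnumerationError("duplicate candidate ids in library")
    return out


def write_library_csv(candidates: Iterable[CandidateIdentity], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["candidate_id", "family", "site", "substituent", "product_smiles", "status"])
        for c in candidates:
            w.writerow([c.candidate_id, c.family, c.site, c.substituent, c.product_smiles, c.status])
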