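"""Compound curation: structure standardization, filtering, deduplication, labeling.

The curation stage mirrors the preprocessing conventions of regulatory DILI
(drug-induced liver injury) datasets: SMILES are standardized (counterion and
solvent removal, neutralization, tautomer canonicalization), compounds that
are mixtures, inorganic, metal-organic or heavier than 1 kDa are discarded
with an explicit rejection reason, cross-source duplicates are resolved in
favor of the severity-annotated source, and the remaining severity classes
are binarized under one of three dataset schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements considered "organic subset"; anything else is treated as a metal.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Molecular-weight cutoff in Da; strictly greater is rejected ("above 1 kDa").
MW_LIMIT = 1000.0


class DiliClass(str, Enum):
    """Severity/causality annotation classes of the input compound tables."""

    vMost = "vMost"
    vLess = "vLess"
    vNo = "vNo"
    SIDER_inactive = "SIDER_inactive"


class Scheme(str, Enum):
    """Binarization schemes over the severity classes.

    minus_vLess keeps only the high-confidence extremes (vMost vs vNo);
    full adds vLess to the positive class; plus_SIDER additionally adds
    text-mined inactives to the negative class.
    """

    minus_vLess = "minus_vLess"
    full = "full"
    plus_SIDER = "plus_SIDER"


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    source: str  # "DILIrank" | "SIDER" | "other"
    dili_class: DiliClass


@dataclass(frozen=True)
class Rejection:
    compound_id: str
    rule: str
    detail: str


@dataclass(frozen=True)
class CuratedCompound:
    compound_id: str
    standardized_smiles: str
    mol_weight: float
    source: str
    dili_class: DiliClass


class StandardizationError(ValueError):
    pass


_uncharger = rdMolStandardize.Uncharger()
_tautomer = rdMolStandardize.TautomerEnumerator()


def _has_carbon(frag: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "C" for a in frag.GetAtoms())


def standardize_structure(smiles: str) -> str:
    """Standardize a SMILES string to a canonical parent form.

    Steps: parse; drop carbon-free fragments (counterions, water, inorganic
    solvents) as long as at least one organic fragment remains; collapse
    duplicate organic fragments (salt stoichiometry); neutralize; canonicalize
    the tautomer with the RDKit rule set; emit canonical SMILES. Distinct
    organic fragments are kept joined so that true mixtures remain visible to
    the downstream mixture filter. Idempotent by construction.

    Raises
    ------
    StandardizationError
        If the SMILES cannot be parsed or sanitized.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _has_carbon(f)]
    kept = organic if organic else list(frags)

    # collapse identical fragments (e.g. dihydrochloride → one parent copy)
    seen: dict[str, Chem.Mol] = {}
    for f in kept:
        seen.setdefault(Chem.MolToSmiles(f), f)

    out_frags = []
    for f in seen.values():
        f = _uncharger.uncharge(f)
        try:
            f = _tautomer.Canonicalize(f)
        except Exception as exc:  # pragma: no cover - rdkit internal failures
            raise StandardizationError(f"tautomer canonicalization failed: {exc}")
        out_frags.append(Chem.MolToSmiles(f))

    return ".".join(sorted(out_frags))


def _first_violation(smiles: str) -> tuple[str, str] | None:
    """Return (rule, detail) for the first filter a standardized SMILES fails."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "parse_error", smiles
    frags = Chem.GetMolFrags(mol, asMols=True)
    organic = [f for f in frags if _has_carbon(f)]
    if len(organic) >= 2:
        return "mixture", f"{len(organic)} organic components"
    if not organic:
        return "inorganic", "no carbon atom"
    metals = sorted(
        {a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in ORGANIC_ELEMENTS}
    )
    if metals:
        return "metal", ",".join(metals)
    mw = Descriptors.MolWt(mol)
    if mw > MW_LIMIT:
        return "mw_above_1kDa", f"{mw:.1f} Da"
    return None


def curate(
    records: Iterable[CompoundRecord],
) -> tuple[list[CuratedCompound], list[Rejection]]:
    """Standardize and filter a compound table.

    Every input record ends up exactly once in either the kept list or the
    rejection log (conservation), with the violated rule recorded.
    """
    kept: list[CuratedCompound] = []
    rejected: list[Rejection] = []
    for rec in records:
        try:
            std = standardize_structure(rec.smiles)
        except StandardizationError as exc:
            rejected.append(Rejection(rec.compound_id, "parse_error", str(exc)))
            continue
        violation = _first_violation(std)
        if violation is not None:
            rejected.append(Rejection(rec.compound_id, *violation))
            continue
        mw = Descriptors.MolWt(Chem.MolFromSmiles(std))
        kept.append(
            CuratedCompound(rec.compound_id, std, mw, rec.source, rec.dili_class)
        )
    return kept, rejected


def apply_filters(
    compounds: Iterable[CuratedCompound],
) -> tuple[list[CuratedCompound], list[Rejection]]:
    """Apply the inclusion/exclusion rules to already-standardized compounds.

    Rejects mixtures (≥2 distinct organic components), inorganics (no carbon),
    metal-organics (any non-organic-subset atom) and parents above 1 kDa.
    """
    kept: list[CuratedCompound] = []
    rejected: list[Rejection] = []
    for c in compounds:
        violation = _first_violation(c.standardized_smiles)
        if violation is None:
            kept.append(c)
        else:
            rejected.append(Rejection(c.compound_id, *violation))
    return kept, rejected


def deduplicate(
    dilirank: Sequence[CuratedCompound], sider: Sequence[CuratedCompound]
) -> list[CuratedCompound]:
    """Merge two curated sources, dropping SIDER records whose standardized
    structure already occurs in the severity-annotated source.

    Raises
    ------
    ValueError
        On duplicate compound ids within a single source.
    """
    for name, source in (("DILIrank", dilirank), ("SIDER", sider)):
        ids = [c.compound_id for c in source]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids within {name}: {dupes}")
    dili_structures = {c.standardized_smiles for c in dilirank}
    merged = list(dilirank)
    merged.extend(c for c in sider if c.standardized_smiles not in dili_structures)
    return merged


_SCHEME_MAP: dict[Scheme, dict[DiliClass, int]] = {
    Scheme.minus_vLess: {DiliClass.vMost: 1, DiliClass.vNo: 0},
    Scheme.full: {DiliClass.vMost: 1, DiliClass.vLess: 1, DiliClass.vNo: 0},
    Scheme.plus_SIDER: {
        DiliClass.vMost: 1,
        DiliClass.vLess: 1,
        DiliClass.vNo: 0,
        DiliClass.SIDER_inactive: 0,
    },
}


def binarize(
    compounds: Sequence[CuratedCompound], scheme: Scheme | str
) -> list[tuple[CuratedCompound, int]]:
    """Binarize severity classes under a dataset scheme (1=DILI, 0=NoDILI).

    Compounds whose class is not part of the scheme are excluded; an unknown
    class raises.
    """
    scheme = Scheme(scheme)
    mapping = _SCHEME_MAP[scheme]
    out = []
    for c in compounds:
        cls = DiliClass(c.dili_class)
        if cls in mapping:
            out.append((c, mapping[cls]))
    return out
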