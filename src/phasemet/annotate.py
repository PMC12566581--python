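"""Confidence levels, novelty classes and assembly of the compound database.

Annotation confidence follows the Metabolomics Standards Initiative tiers
used by the study: level 1 for compounds confirmed against an authentic
standard, level 2 when the experimental fragmentation matches an external
spectral record, level 3 otherwise (tentative).  A metabolite is *novel*
when it originated from rule-based discovery or prediction software alone,
with no literature record.

The shipped reference database (``data/neuroactive_db.tsv``) is the
transcribed compound table of the neuroactive-compounds study: 274 entries
covering 94 parent compounds and 182 metabolites, two compounds occurring
in both roles and therefore condensed into single Parent/Metabolite rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import ElementalFormula, adduct_mz, parse_formula

__all__ = [
    "EvidenceRecord",
    "DatabaseEntry",
    "DatabaseSummary",
    "assign_confidence",
    "classify_novelty",
    "condense_dual_role",
    "assemble_database",
    "summarize",
    "load_reference_database",
    "write_database",
    "read_database",
    "KNOWN_MZ_DEVIATIONS",
]

#: Reference-table entries whose printed m/z differs from the computed
#: [M+H]+ of the printed formula by more than 3e-4: one organotin parent
#: whose observed ion species is unstated, and eight rule-suffixed
#: metabolite rows printed with lower-precision mass arithmetic.  They are
#: carried through as-reported, never recomputed.
KNOWN_MZ_DEVIATIONS = frozenset(
    {
        "Tributyltin chloride",
        "2-n-Octyl-4-isothiazolin-3-one -Hydrogenation + Epoxide-hydration",
        "2-n-Octyl-4-isothiazolin-3-one -Mono-hydroxylation/oxidation + Epoxide-hydration",
        "4,4_-Methylene-bis(2-methylaniline)_Oxidation_Dehydrogenation",
        "4-Chloro-2-cyano-N,N-dimethyl-5-(4-methylphenyl)-1H-imidazole-1-sulfonamide - Deamination + Methylation",
        "N-(3,4-dichloro-2-hydroxyphenyl)acetamide",
        "Propiconazole - Mono-hydroxylation/oxidation + Dehydrogenation1",
        "Thiazopyr_Oxidation_Dehydrogenation",
        "Thiazopyr_Oxidation_N/O-Dealkylation/demethylation",
    }
)

VALID_SOURCES = ("standard", "literature", "prediction_tool", "nta_discovery")


@dataclass(frozen=True)
class EvidenceRecord:
    """Provenance and verification evidence behind one annotation."""

    compound_id: str
    source: str
    has_authentic_standard: bool = False
    external_fragmentation_match: bool = False

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.has_authentic_standard and self.source != "standard":
            raise ValueError("an authentic standard implies source='standard'")


def assign_confidence(evidence: EvidenceRecord) -> int:
    """MSI-style annotation confidence: 1 with an authentic standard, 2 on
    an external fragmentation match, else 3."""
    if evidence.has_authentic_standard:
        return 1
    if evidence.external_fragmentation_match:
        return 2
    return 3


def classify_novelty(evidence: EvidenceRecord) -> str:
    """'novel' iff the compound is known only from prediction software or
    rule-based discovery (no literature or standard record)."""
    return "novel" if evidence.source in ("prediction_tool", "nta_discovery") else "known"


@dataclass(frozen=True)
class DatabaseEntry:
    """One row of the output compound database."""

    name: str
    formula: Optional[ElementalFormula]
    compound_type: str  # Parent | Metabolite | Parent/Metabolite
    mz: float
    rt: float
    confidence: int = 3
    novelty: str = "known"
    parent_links: Tuple[str, ...] = ()
    mz_as_reported: bool = False
    evidence: Optional[EvidenceRecord] = None

    def __post_init__(self) -> None:
        if self.compound_type not in ("Parent", "Metabolite", "Parent/Metabolite"):
            raise ValueError(f"bad compound type {self.compound_type!r}")
        if self.confidence not in (1, 2, 3):
            raise ValueError("confidence must be 1, 2 or 3")
        if self.novelty not in ("known", "novel"):
            raise ValueError("novelty must be 'known' or 'novel'")


@dataclass(frozen=True)
class DatabaseSummary:
    """Bookkeeping totals over an assembled database."""

    n_total: int
    n_parents: int
    n_metabolites: int
    n_dual_role: int
    n_novel: int
    confidence_counts: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        assert self.n_total == self.n_parents + self.n_metabolites - self.n_dual_role


def condense_dual_role(entries: Sequence[DatabaseEntry]) -> List[DatabaseEntry]:
    """Merge compounds that occur as both Parent and Metabolite into single
    Parent/Metabolite entries.

    The merged entry keeps the parent's m/z and retention time and the union
    of parent links; the best (lowest) confidence wins and novelty 'known'
    dominates.  Conflicting formulas under one name are a hard error.
    """
    by_name: Dict[str, List[DatabaseEntry]] = {}
    for e in entries:
        by_name.setdefault(e.name, []).append(e)

    out: List[DatabaseEntry] = []
    for name, group in by_name.items():
        types = {e.compound_type for e in group}
        if not ({"Parent", "Metabolite"} <= types or "Parent/Metabolite" in types):
            out.extend(group)
            continue
        formulas = {e.formula.hill() for e in group if e.formula is not None}
        if len(formulas) > 1:
            raise ValueError(f"conflicting formulas for {name!r}: {sorted(formulas)}")
        parents = [e for e in group if "Parent" in e.compound_type]
        anchor = parents[0] if parents else group[0]
        links: Tuple[str, ...] = tuple(
            sorted({l for e in group for l in e.parent_links})
        )
        merged = replace(
            anchor,
            compound_type="Parent/Metabolite",
            confidence=min(e.confidence for e in group),
            novelty="known" if any(e.novelty == "known" for e in group) else "novel",
            parent_links=links,
        )
        out.append(merged)
    return out


def summarize(entries: Sequence[DatabaseEntry]) -> DatabaseSummary:
    """Count parents, metabolites, dual-role compounds and novel entries.

    Each entry is one compound; Parent/Metabolite entries contribute to both
    the parent and metabolite tallies but once to the total, so
    total = parents + metabolites - dual_role by construction.
    """
    n_parents = sum(1 for e in entries if "Parent" in e.compound_type)
    n_mets = sum(1 for e in entries if "Metabolite" in e.compound_type)
    n_dual = sum(1 for e in entries if e.compound_type == "Parent/Metabolite")
    n_novel = sum(1 for e in entries if e.novelty == "novel")
    conf = tuple(
        sorted(
            (level, sum(1 for e in entries if e.confidence == level))
            for level in (1, 2, 3)
        )
    )
    return DatabaseSummary(len(entries), n_parents, n_mets, n_dual, n_novel, conf)


def assemble_database(
    parents: Iterable[DatabaseEntry],
    targeted_hits: Iterable[DatabaseEntry] = (),
    nta_hits: Iterable[DatabaseEntry] = (),
) -> Tuple[List[DatabaseEntry], DatabaseSummary]:
    """Assemble the final compound database.

    Confidence and novelty are (re)derived from each entry's evidence
    record when present, dual-role compounds are condensed, and entries are
    sorted by name then retention time.  Returns the entries plus summary
    counts.
    """
    raw: List[DatabaseEntry] = []
    for entry in list(parents) + list(targeted_hits) + list(nta_hits):
        if entry.evidence is not None:
            entry = replace(
                entry,
                confidence=assign_confidence(entry.evidence),
                novelty=classify_novelty(entry.evidence),
            )
        raw.append(entry)
    condensed = condense_dual_role(raw)
    condensed.sort(key=lambda e: (e.name.lower(), e.rt))
    return condensed, summarize(condensed)


_COLUMNS = [
    "name",
    "formula",
    "compound_type",
    "mz",
    "rt",
    "confidence",
    "novelty",
    "parent_links",
    "mz_as_reported",
]


def write_database(entries: Sequence[DatabaseEntry], path: Path) -> None:
    """Export as tab-delimited text (m/z at 4 dp, half-even)."""
    rows = []
    for e in entries:
        rows.append(
            {
                "name": e.name,
                "formula": e.formula.hill() if e.formula else "",
                "compound_type": e.compound_type,
                "mz": f"{e.mz:.4f}",
                "rt": e.rt,
                "confidence": e.confidence,
                "novelty": e.novelty,
                "parent_links": ";".join(e.parent_links),
                "mz_as_reported": int(e.mz_as_reported),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_database(path: Path) -> List[DatabaseEntry]:
    """Inverse of :func:`write_database`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            DatabaseEntry(
                name=row["name"],
                formula=parse_formula(row["formula"]) if row["formula"] else None,
                compound_type=row["compound_type"],
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                confidence=int(row.get("confidence", 3) or 3),
                novelty=row.get("novelty", "known") or "known",
                parent_links=tuple(
                    l for l in str(row.get("parent_links", "")).split(";") if l
                ),
                mz_as_reported=bool(int(row.get("mz_as_reported", 0) or 0)),
            )
        )
    return entries


def load_reference_database() -> List[DatabaseEntry]:
    """Load the shipped reference compound table (274 entries).

    Entries named in :data:`KNOWN_MZ_DEVIATIONS` keep their printed m/z and
    are flagged ``mz_as_reported``; for every other entry the printed m/z
    agrees with the computed [M+H]+ of the formula to within 3e-4.
    """
    text = (
        resources.files("phasemet.data").joinpath("neuroactive_db.tsv").read_text()
    )
    entries: List[DatabaseEntry] = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, formula_text, ctype, mz, rt = line.split("\t")
        formula = parse_formula(formula_text)
        printed = float(mz)
        deviates = abs(adduct_mz(formula) - printed) > 3e-4
        entries.append(
            DatabaseEntry(
                name=name,
                formula=formula,
                compound_type=ctype,
                mz=printed,
                rt=float(rt),
                mz_as_reported=deviates,
            )
        )
    return entries
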