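"""Resolution outcomes: classification taxonomy, summaries, evidence tables.

When a putative orphan enzyme is resolved — its sequence located — the
*reason* it was an orphan falls into one of seven categories, grouped in
two families:

Annotation updates (the sequence was present but its annotation lagged):
    CLASS_LEVEL_ONLY          annotated only to a generic/class-level activity
    ADDITIONAL_ACTIVITY       correctly annotated with another activity the
                              enzyme also carries out
    NO_ACTIVITY_ASSIGNED      no activity annotated at all
    SIMILAR_ACTIVITY_REPLACED a different specific same-class activity replaced

Data labeling errors (the activity was nominally attached but unfindable):
    MISSING_EC        correct activity name present, EC number absent
    MISSING_SYNONYM   activity present only under names not in the EC listing
    WRONG_EC          an incorrect EC number attached to the correct activity

:func:`classify` applies a fixed decision ladder over an explicitly coded
annotation state (this package does not infer states from free text — that
judgment call stays with the curator).  :func:`summarize` produces the
count/percentage table; per-publication identification-information rows
(organism, purification/assay availability, MW, pI, kinetics) are written
with :func:`write_identification_table`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, List, Optional, Sequence, Set, Union

from ._util import percentage
from .ec_catalog import ECNumber, normalize_name, parse_ec

__all__ = [
    "ResolutionStatus",
    "Category",
    "CategoryGroup",
    "Method",
    "AnnotationState",
    "NewAssignment",
    "ResolutionRecord",
    "IdentificationInfo",
    "LedgerSummary",
    "ClassificationError",
    "category_group",
    "classify",
    "summarize",
    "write_ledger_tsv",
    "read_ledger_tsv",
    "write_identification_table",
    "read_identification_table",
]


class ResolutionStatus(enum.Enum):
    RESOLVED = "resolved"
    OPEN = "open"


class Category(enum.Enum):
    CLASS_LEVEL_ONLY = "class_level_only"
    ADDITIONAL_ACTIVITY = "additional_activity"
    NO_ACTIVITY_ASSIGNED = "no_activity_assigned"
    SIMILAR_ACTIVITY_REPLACED = "similar_activity_replaced"
    MISSING_EC = "missing_ec"
    MISSING_SYNONYM = "missing_synonym"
    WRONG_EC = "wrong_ec"


class CategoryGroup(enum.Enum):
    ANNOTATION_UPDATE = "annotation_update"
    DATA_LABELING = "data_labeling"


class Method(enum.Enum):
    LITERATURE_DATABASE = "literature_database"
    NTERM_MATCH = "nterm_match"
    MW_MATCH = "mw_match"


_GROUP_OF = {
    Category.CLASS_LEVEL_ONLY: CategoryGroup.ANNOTATION_UPDATE,
    Category.ADDITIONAL_ACTIVITY: CategoryGroup.ANNOTATION_UPDATE,
    Category.NO_ACTIVITY_ASSIGNED: CategoryGroup.ANNOTATION_UPDATE,
    Category.SIMILAR_ACTIVITY_REPLACED: CategoryGroup.ANNOTATION_UPDATE,
    Category.MISSING_EC: CategoryGroup.DATA_LABELING,
    Category.MISSING_SYNONYM: CategoryGroup.DATA_LABELING,
    Category.WRONG_EC: CategoryGroup.DATA_LABELING,
}


def category_group(category: Category) -> CategoryGroup:
    """Pure mapping of subtype to family."""
    return _GROUP_OF[category]


class ClassificationError(ValueError):
    """Contradictory or underdetermined annotation state."""


@dataclass(frozen=True)
class AnnotationState:
    """Pre-existing database annotation of the sequence, explicitly coded.

    ``describes_orphan_activity`` marks records whose annotation refers to
    the orphan activity even when none of the annotated names is in the
    official EC listing.  ``annotated_activity_also_correct`` distinguishes
    a genuinely bifunctional enzyme (the annotated activity stays) from a
    mis-specific annotation that the new assignment replaces.
    """

    annotated_names: frozenset = frozenset()
    annotated_ec: Optional[ECNumber] = None
    class_level_only: bool = False
    no_activity: bool = False
    describes_orphan_activity: bool = False
    annotated_activity_also_correct: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotated_names", frozenset(self.annotated_names))
        if self.no_activity and (self.annotated_names or self.class_level_only
                                 or self.describes_orphan_activity
                                 or self.annotated_ec is not None):
            raise ClassificationError(
                "state claims no activity yet carries annotation facts")


@dataclass(frozen=True)
class NewAssignment:
    """The orphan activity being assigned: its EC and officially listed names."""

    ec: ECNumber
    listed_names: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "listed_names", frozenset(self.listed_names))


def classify(old: AnnotationState, new: NewAssignment) -> Category:
    """Fixed decision ladder over the annotation state; first match wins."""
    listed = {normalize_name(n) for n in new.listed_names}
    name_match = any(normalize_name(n) in listed for n in old.annotated_names)
    describes = old.describes_orphan_activity or name_match

    if name_match and old.annotated_ec is None:
        return Category.MISSING_EC
    if describes and not name_match:
        return Category.MISSING_SYNONYM
    if describes and old.annotated_ec is not None:
        if old.annotated_ec == new.ec:
            raise ClassificationError(
                "sequence already correctly annotated; not an orphan resolution")
        return Category.WRONG_EC
    if old.class_level_only:
        return Category.CLASS_LEVEL_ONLY
    if old.no_activity or (not old.annotated_names and old.annotated_ec is None):
        return Category.NO_ACTIVITY_ASSIGNED
    if old.annotated_activity_also_correct:
        return Category.ADDITIONAL_ACTIVITY
    if old.annotated_names or old.annotated_ec is not None:
        return Category.SIMILAR_ACTIVITY_REPLACED
    raise ClassificationError("annotation state is underdetermined")


@dataclass(frozen=True)
class ResolutionRecord:
    ec: ECNumber
    status: ResolutionStatus
    category: Optional[Category] = None
    method: Optional[Method] = None
    accession_or_sequence: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.status is ResolutionStatus.RESOLVED:
            if self.category is None or self.method is None or not self.accession_or_sequence:
                raise ValueError(f"{self.ec}: RESOLVED requires category, method "
                                 "and a non-empty accession/sequence")
        else:
            if self.category is not None or self.method is not None \
                    or self.accession_or_sequence:
                raise ValueError(f"{self.ec}: OPEN records carry no resolution fields")

    @property
    def category_group(self) -> Optional[CategoryGroup]:
        return None if self.category is None else category_group(self.category)


@dataclass(frozen=True)
class LedgerSummary:
    n_total: int
    n_resolved: int
    n_open: int
    resolved_pct: float
    open_pct: float
    category_counts: Dict[Category, int]
    category_pcts: Dict[Category, float]
    group_counts: Dict[CategoryGroup, int]
    group_pcts: Dict[CategoryGroup, float]
    method_counts: Dict[Method, int]
    method_pcts: Dict[Method, float]
    denominators: Dict[str, int]


def summarize(ledger: Sequence[ResolutionRecord], decimals: int = 2) -> LedgerSummary:
    """Counts and half-up percentages, ledger-order independent.

    Resolved/open shares are over all records; category, group and method
    shares are over the resolved records only.  All denominators are echoed
    so downstream tables are self-describing.
    """
    if not ledger:
        raise ValueError("ledger is empty")
    n_total = len(ledger)
    resolved = [r for r in ledger if r.status is ResolutionStatus.RESOLVED]
    n_resolved = len(resolved)
    n_open = n_total - n_resolved

    cat_counts = {c: 0 for c in Category}
    grp_counts = {g: 0 for g in CategoryGroup}
    mth_counts = {m: 0 for m in Method}
    for rec in resolved:
        cat_counts[rec.category] += 1
        grp_counts[rec.category_group] += 1
        mth_counts[rec.method] += 1

    def pcts(counts, denom):
        return {k: percentage(v, denom, decimals) if denom else 0.0
                for k, v in counts.items()}

    return LedgerSummary(
        n_total=n_total, n_resolved=n_resolved, n_open=n_open,
        resolved_pct=percentage(n_resolved, n_total, decimals),
        open_pct=percentage(n_open, n_total, decimals),
        category_counts=cat_counts, category_pcts=pcts(cat_counts, n_resolved),
        group_counts=grp_counts, group_pcts=pcts(grp_counts, n_resolved),
        method_counts=mth_counts, method_pcts=pcts(mth_counts, n_resolved),
        denominators={"resolved_open": n_total, "category": n_resolved,
                      "group": n_resolved, "method": n_resolved},
    )


# ---------------------------------------------------------------- TSV I/O

_LEDGER_COLS = ["ec", "status", "category", "method", "accession_or_sequence", "notes"]


def write_ledger_tsv(ledger: Iterable[ResolutionRecord], sink: IO[str]) -> int:
    w = csv.writer(sink, delimiter="\t", lineterminator="\n")
    w.writerow(_LEDGER_COLS)
    n = 0
    for rec in ledger:
        w.writerow([
            str(rec.ec), rec.status.value,
            rec.category.value if rec.category else "",
            rec.method.value if rec.method else "",
            rec.accession_or_sequence or "", rec.notes,
        ])
        n += 1
    return n


def read_ledger_tsv(stream: Union[IO[str], Iterable[str]]) -> List[ResolutionRecord]:
    out = []
    for row in csv.DictReader(stream, delimiter="\t"):
        out.append(ResolutionRecord(
            ec=parse_ec(row["ec"]),
            status=ResolutionStatus(row["status"]),
            category=Category(row["category"]) if row["category"] else None,
            method=Method(row["method"]) if row["method"] else None,
            accession_or_sequence=row["accession_or_sequence"] or None,
            notes=row["notes"],
        ))
    return out


@dataclass(frozen=True)
class IdentificationInfo:
    """One publication's identification information for one (EC, organism, sequence)."""

    ec: ECNumber
    citation: str  # numeric document ID or free-text citation
    organism: str
    has_purification: bool = False
    has_assay: bool = False
    sequence_info: Optional[str] = None
    mw_kda: Optional[float] = None
    isoelectric_point: Optional[float] = None
    has_kinetics: bool = False
    notes: str = ""

    @property
    def key(self):
        return (self.ec, self.citation, self.organism, self.sequence_info)


_IDINFO_COLS = ["ec", "citation", "organism", "purification", "assay",
                "sequence", "mw_kda", "isoelectric_point", "kinetics", "notes"]


def write_identification_table(rows: Sequence[IdentificationInfo], sink: IO[str]) -> int:
    """S2-style identification-information TSV; absent numbers are empty cells."""
    keys = [r.key for r in rows]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (ec, citation, organism, sequence) row")
    w = csv.writer(sink, delimiter="\t", lineterminator="\n")
    w.writerow(_IDINFO_COLS)
    n = 0
    for r in rows:
        w.writerow([
            str(r.ec), r.citation, r.organism,
            "yes" if r.has_purification else "no",
            "yes" if r.has_assay else "no",
            r.sequence_info or "",
            "" if r.mw_kda is None else repr(r.mw_kda),
            "" if r.isoelectric_point is None else repr(r.isoelectric_point),
            "yes" if r.has_kinetics else "no",
            r.notes,
        ])
        n += 1
    return n


def read_identification_table(stream: Union[IO[str], Iterable[str]]) -> List[IdentificationInfo]:
    out = []
    for row in csv.DictReader(stream, delimiter="\t"):
        out.append(IdentificationInfo(
            ec=parse_ec(row["ec"]), citation=row["citation"], organism=row["organism"],
            has_purification=row["purification"] == "yes",
            has_assay=row["assay"] == "yes",
            sequence_info=row["sequence"] or None,
            mw_kda=float(row["mw_kda"]) if row["mw_kda"] else None,
            isoelectric_point=(float(row["isoelectric_point"])
                               if row["isoelectric_point"] else None),
            has_kinetics=row["kinetics"] == "yes",
            notes=row["notes"],
        ))
    return out
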