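"""Orphan census: reconcile EC activities against sequence-evidence sources.

An "orphan enzyme" is an experimentally characterized activity with no
associated amino-acid sequence in any major database.  The census takes a
catalog of EC activities and per-source evidence tables (one row = one
(source, EC, accession) assertion) and partitions the ACTIVE activities into
*sequenced* and *putative orphan* sets: an activity is a putative orphan
only if it lacks unflagged evidence across *all* sources.

Two realities of database evidence are modeled explicitly:

* Systematic mis-assignments — a single submitting center attaching one EC
  to a whole cluster of accessions with no corroboration anywhere else —
  can fabricate "sequenced" status.  :func:`flag_systematic` mechanizes the
  discard of such clusters; flagged evidence never de-orphans.
* Evidence annotated only to a class-level identifier (e.g. "1.1.1.-")
  is recorded but never counts as sequence for any full EC number.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import IO, Iterable, List, Optional, Sequence, Union

from ._util import percentage
from .ec_catalog import ECNumber, EntryStatus, EnzymeActivity, parse_ec

__all__ = [
    "SequenceEvidence",
    "CensusResult",
    "CensusSummary",
    "reconcile",
    "flag_systematic",
    "census_summary",
    "summary_from_counts",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "write_census_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceEvidence:
    """One assertion that `accession` (from `source`) carries activity `ec`."""

    source: str
    ec: ECNumber
    accession: str
    submitter: Optional[str] = None
    flagged: bool = False

    @property
    def key(self):
        return (self.source, self.ec, self.accession)


@dataclass(frozen=True)
class CensusResult:
    evaluated: frozenset
    sequenced: frozenset
    putative_orphans: frozenset
    removed: frozenset
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if self.sequenced & self.putative_orphans:
            raise ValueError("sequenced and putative_orphans overlap")
        if (self.sequenced | self.putative_orphans) != self.evaluated:
            raise ValueError("sequenced ∪ putative_orphans != evaluated")
        if self.removed & self.evaluated:
            raise ValueError("removed entries leaked into the evaluated set")


def reconcile(
    catalog: Sequence[EnzymeActivity],
    evidence: Iterable[SequenceEvidence],
) -> CensusResult:
    """Partition ACTIVE catalog entries into sequenced vs putative orphans.

    An activity counts as sequenced iff at least one unflagged evidence row
    cites its full EC number.  DELETED/TRANSFERRED entries go to ``removed``.
    Evidence citing an EC absent from the catalog is collected into the
    result's ``warnings`` (and logged), never fatal.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    active = {a.ec for a in catalog if a.status is EntryStatus.ACTIVE}
    removed = {a.ec for a in catalog if a.status is not EntryStatus.ACTIVE}

    seen_keys: set = set()
    sequenced: set = set()
    warnings: List[str] = []
    for ev in evidence:
        if ev.key in seen_keys:
            raise ValueError(f"duplicate evidence triple {ev.key}")
        seen_keys.add(ev.key)
        if ev.ec.is_class_level:
            continue  # recorded, but class-level evidence never de-orphans
        if ev.ec not in active:
            if ev.ec in removed:
                msg = f"evidence {ev.accession} ({ev.source}) cites removed EC {ev.ec}"
            else:
                msg = f"evidence {ev.accession} ({ev.source}) cites unknown EC {ev.ec}"
            warnings.append(msg)
            logger.warning(msg)
            continue
        if not ev.flagged:
            sequenced.add(ev.ec)

    return CensusResult(
        evaluated=frozenset(active),
        sequenced=frozenset(sequenced),
        putative_orphans=frozenset(active - sequenced),
        removed=frozenset(removed),
        warnings=tuple(warnings),
    )


def flag_systematic(
    evidence: Sequence[SequenceEvidence], min_cluster: int = 3
) -> List[SequenceEvidence]:
    """Flag uncorroborated single-submitter EC assignment clusters.

    A cluster is every evidence row for one (ec, submitter) pair when that
    submitter supports the EC with >= ``min_cluster`` accessions *and* no
    other submitter or source mentions the EC at all.  Rows without
    submitter metadata are never flagged (there is no center to attribute
    the systematic error to).  Pure function: input order is irrelevant and
    re-application changes nothing.
    """
    if min_cluster < 2:
        raise ValueError("min_cluster must be >= 2")
    by_pair: dict = {}
    by_ec: dict = {}
    for ev in evidence:
        by_ec.setdefault(ev.ec, []).append(ev)
        if ev.submitter is not None:
            by_pair.setdefault((ev.ec, ev.submitter), set()).add(ev.accession)

    suspect_pairs = set()
    for (ec, submitter), accessions in by_pair.items():
        if len(accessions) < min_cluster:
            continue
        # any row for this EC from anyone else (incl. submitterless sources)
        corroborated = any(other.submitter != submitter for other in by_ec[ec])
        if not corroborated:
            suspect_pairs.add((ec, submitter))

    return [
        replace(ev, flagged=True)
        if ev.submitter is not None and (ev.ec, ev.submitter) in suspect_pairs
        else ev
        for ev in evidence
    ]


@dataclass(frozen=True)
class CensusSummary:
    n_evaluated: int
    n_orphans: int
    pct_orphans: float


def summary_from_counts(n_orphans: int, n_evaluated: int, decimals: int = 0) -> CensusSummary:
    if n_evaluated == 0:
        raise ValueError("cannot summarize a census with zero evaluated activities")
    return CensusSummary(n_evaluated, n_orphans, percentage(n_orphans, n_evaluated, decimals))


def census_summary(result: CensusResult, decimals: int = 0) -> CensusSummary:
    """Orphan burden: percentage of evaluated activities lacking sequence."""
    return summary_from_counts(len(result.putative_orphans), len(result.evaluated), decimals)


# ---------------------------------------------------------------- TSV I/O

_EVIDENCE_COLS = ["source", "ec", "accession", "submitter", "flagged"]


def write_evidence_tsv(evidence: Iterable[SequenceEvidence], sink: IO[str]) -> int:
    w = csv.writer(sink, delimiter="\t", lineterminator="\n")
    w.writerow(_EVIDENCE_COLS)
    n = 0
    for ev in evidence:
        w.writerow([ev.source, str(ev.ec), ev.accession, ev.submitter or "",
                    "1" if ev.flagged else "0"])
        n += 1
    return n


def read_evidence_tsv(stream: Union[IO[str], Iterable[str]]) -> List[SequenceEvidence]:
    reader = csv.DictReader(stream, delimiter="\t")
    out = []
    for row in reader:
        out.append(SequenceEvidence(
            source=row["source"], ec=parse_ec(row["ec"]), accession=row["accession"],
            submitter=row["submitter"] or None, flagged=row["flagged"] == "1",
        ))
    return out


def write_census_tsv(
    result: CensusResult, evidence: Sequence[SequenceEvidence], sink: IO[str]
) -> int:
    """Per-EC census status TSV: ec, status, n_sources (distinct unflagged)."""
    n_sources: dict = {}
    for ev in evidence:
        if not ev.flagged and not ev.ec.is_class_level:
            n_sources.setdefault(ev.ec, set()).add(ev.source)
    w = csv.writer(sink, delimiter="\t", lineterminator="\n")
    w.writerow(["ec", "status", "n_sources"])
    rows = 0
    for ec in sorted(result.evaluated | result.removed, key=str):
        if ec in result.removed:
            status = "removed"
        elif ec in result.sequenced:
            status = "sequenced"
        else:
            status = "putative_orphan"
        w.writerow([str(ec), status, len(n_sources.get(ec, ()))])
        rows += 1
    return rows
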