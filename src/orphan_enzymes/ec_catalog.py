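"""EC activity catalog: identifiers, name sets, entry status, flat-file I/O.

The Enzyme Commission (EC) system assigns every experimentally characterized
enzymatic activity a four-component identifier (e.g. 1.1.1.3, homoserine
dehydrogenase): class, subclass, sub-subclass, and a serial number.  A
class-level identifier leaves the serial absent ("1.1.1.-"); preliminary
entries carry an "n"-prefixed serial ("1.1.1.n5") while they await review.

This module models catalog entries and reads/writes an ENZYME-dialect flat
file: records terminated by "//", with two-letter line codes

    ID  EC identifier          DE  accepted name (or Deleted/Transferred marker)
    AN  one alternate name     CA  catalyzed reaction, stored verbatim
    CC  free comment

Entries removed from the hierarchy ("Deleted entry.") or merged elsewhere
("Transferred entry: x.y.z.w.") are retained with a non-ACTIVE status so a
census can exclude them from its denominators.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

__all__ = [
    "ECNumber",
    "EnzymeActivity",
    "EntryStatus",
    "ECParseError",
    "CatalogError",
    "parse_ec",
    "normalize_name",
    "parse_enzyme_catalog",
    "write_enzyme_catalog",
    "write_catalog_tsv",
    "name_index",
]


class ECParseError(ValueError):
    """Malformed EC identifier text."""


class CatalogError(ValueError):
    """Structurally invalid catalog stream (missing ID, duplicate EC, ...)."""


_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "υ": "upsilon", "φ": "phi", "χ": "chi",
    "ψ": "psi", "ω": "omega",
    "Α": "alpha", "Β": "beta", "Γ": "gamma", "Δ": "delta", "Ε": "epsilon",
    "Ω": "omega",
}


def normalize_name(name: str) -> str:
    """Canonical form for comparing enzyme names across sources.

    Lowercases, transliterates Greek letters, collapses internal whitespace
    and strips the trailing period that flat-file name lines carry.
    Heterogeneously formatted sources (flat files, web pages, abstracts)
    render the same name many ways; all lookups go through this form.
    """
    out = "".join(_GREEK.get(ch, ch) for ch in name)
    out = out.lower()
    out = re.sub(r"\s+", " ", out).strip()
    return out.rstrip(".").strip()


_SERIAL_RE = re.compile(r"^(?:(\d+)|(n\d+)|(-))$")


@dataclass(frozen=True)
class ECNumber:
    """Four-component EC identifier; ``serial is None`` means class-level.

    Instances are hashable; for a stable order sort by :attr:`sort_key`
    (plain integer serials, then preliminary "n" serials, then class-level).
    """

    c1: int
    c2: int
    c3: int
    serial: Union[int, str, None] = None

    def __post_init__(self) -> None:
        for label, v in (("class", self.c1), ("subclass", self.c2),
                         ("sub-subclass", self.c3)):
            if not isinstance(v, int) or v < 1:
                raise ECParseError(f"EC {label} must be a positive integer, got {v!r}")
        if self.c1 > 6:
            raise ECParseError(f"EC class must be 1-6, got {self.c1}")
        s = self.serial
        if s is not None:
            if isinstance(s, int):
                if s < 1:
                    raise ECParseError(f"EC serial must be positive, got {s}")
            elif not (isinstance(s, str) and re.fullmatch(r"n\d+", s)):
                raise ECParseError(f"EC serial must be int, 'n<digits>' or None, got {s!r}")

    @property
    def is_class_level(self) -> bool:
        return self.serial is None

    @property
    def sort_key(self):
        if self.serial is None:
            tier, serial = 2, 0
        elif isinstance(self.serial, str):
            tier, serial = 1, int(self.serial[1:])
        else:
            tier, serial = 0, self.serial
        return (self.c1, self.c2, self.c3, tier, serial)

    @property
    def is_preliminary(self) -> bool:
        return isinstance(self.serial, str)

    def __str__(self) -> str:
        tail = "-" if self.serial is None else str(self.serial)
        return f"{self.c1}.{self.c2}.{self.c3}.{tail}"


def parse_ec(text: str) -> ECNumber:
    """Parse an EC identifier such as ``"EC # 1.1.1.3"``, ``"1.1.1.-"`` or
    ``"2.8.2.n1"``.  An optional leading "EC" and "#" are tolerated."""
    raw = text.strip()
    body = re.sub(r"^EC\b\s*#?\s*", "", raw, flags=re.IGNORECASE).strip()
    parts = body.split(".")
    if len(parts) != 4:
        raise ECParseError(f"expected 4 dot-separated components in {raw!r}, got {len(parts)}")
    nums = []
    for label, p in zip(("class", "subclass", "sub-subclass"), parts):
        if not p.isdigit():
            raise ECParseError(f"EC {label} component {p!r} in {raw!r} is not an integer")
        nums.append(int(p))
    m = _SERIAL_RE.match(parts[3])
    if not m:
        raise ECParseError(f"EC serial component {parts[3]!r} in {raw!r} is malformed")
    serial: Union[int, str, None]
    if m.group(1):
        serial = int(m.group(1))
    elif m.group(2):
        serial = m.group(2)
    else:
        serial = None
    return ECNumber(nums[0], nums[1], nums[2], serial)


class EntryStatus(enum.Enum):
    ACTIVE = "active"
    DELETED = "deleted"
    TRANSFERRED = "transferred"


@dataclass(frozen=True)
class EnzymeActivity:
    """One catalogued EC activity with its synonym set and status."""

    ec: ECNumber
    accepted_name: str = ""
    systematic_name: Optional[str] = None
    other_names: frozenset = frozenset()
    status: EntryStatus = EntryStatus.ACTIVE
    transferred_to: Optional[str] = None
    ca_lines: tuple = ()
    cc_lines: tuple = ()

    def __post_init__(self) -> None:
        if self.status is EntryStatus.ACTIVE:
            if not self.accepted_name:
                raise CatalogError(f"ACTIVE entry {self.ec} lacks an accepted name")
            if self.ec.is_class_level:
                raise CatalogError(f"ACTIVE entry {self.ec} must have a full EC number")
        object.__setattr__(self, "other_names", frozenset(self.other_names))

    @property
    def name_set(self) -> frozenset:
        """All names for the activity; the accepted name is always a member."""
        names = set(self.other_names)
        if self.accepted_name:
            names.add(self.accepted_name)
        if self.systematic_name:
            names.add(self.systematic_name)
        return frozenset(names)

    def has_name(self, name: str) -> bool:
        target = normalize_name(name)
        return any(normalize_name(n) == target for n in self.name_set)


_SYSTEMATIC_CC = re.compile(r"^-!-\s*Systematic name:\s*(.+?)\.?\s*$")
_TRANSFERRED_DE = re.compile(r"^Transferred entry:?\s*(.+?)\.?\s*$", re.IGNORECASE)


def parse_enzyme_catalog(stream: Union[IO[str], Iterable[str]]) -> list:
    """Parse an ENZYME-dialect flat file into a list of :class:`EnzymeActivity`.

    Records are delimited by ``//``.  Status is detected from the DE line
    ("Deleted entry", "Transferred entry: ...").  Trailing periods on name
    lines are stripped.  A record without an ID line, or a duplicate EC,
    raises :class:`CatalogError`.
    """
    activities: list = []
    seen: set = set()
    record: list = []
    index = 0
    for line in stream:
        line = line.rstrip("\n")
        if line.strip() == "//":
            if record:
                activities.append(_parse_record(record, index, seen))
                index += 1
                record = []
            continue
        if line.strip():
            record.append(line)
    if record:
        activities.append(_parse_record(record, index, seen))
    return activities


def _parse_record(lines: list, index: int, seen: set) -> EnzymeActivity:
    ec: Optional[ECNumber] = None
    de_parts: list = []
    an: list = []
    ca: list = []
    cc: list = []
    systematic: Optional[str] = None
    for line in lines:
        code, _, rest = line.partition("   ")
        rest = rest.strip()
        if code == "ID":
            ec = parse_ec(rest)
        elif code == "DE":
            de_parts.append(rest)
        elif code == "AN":
            an.append(rest.rstrip("."))
        elif code == "CA":
            ca.append(rest)
        elif code == "CC":
            m = _SYSTEMATIC_CC.match(rest)
            if m:
                systematic = m.group(1)
            else:
                cc.append(rest)
    if ec is None:
        raise CatalogError(f"record {index} has no ID line")
    if ec in seen:
        raise CatalogError(f"duplicate EC {ec} at record {index}")
    seen.add(ec)

    de = " ".join(de_parts).strip()
    status = EntryStatus.ACTIVE
    transferred_to = None
    accepted = de.rstrip(".")
    if re.match(r"^Deleted entry\.?$", de, re.IGNORECASE):
        status, accepted = EntryStatus.DELETED, ""
    else:
        m = _TRANSFERRED_DE.match(de)
        if m:
            status, accepted, transferred_to = EntryStatus.TRANSFERRED, "", m.group(1)
    return EnzymeActivity(
        ec=ec, accepted_name=accepted, systematic_name=systematic,
        other_names=frozenset(an), status=status, transferred_to=transferred_to,
        ca_lines=tuple(ca), cc_lines=tuple(cc),
    )


def write_enzyme_catalog(activities: Iterable[EnzymeActivity], sink: IO[str]) -> int:
    """Write activities back to the flat-file dialect; returns record count."""
    n = 0
    for act in activities:
        sink.write(f"ID   {act.ec}\n")
        if act.status is EntryStatus.DELETED:
            sink.write("DE   Deleted entry.\n")
        elif act.status is EntryStatus.TRANSFERRED:
            sink.write(f"DE   Transferred entry: {act.transferred_to}.\n")
        else:
            sink.write(f"DE   {act.accepted_name}.\n")
        for name in sorted(act.other_names):
            sink.write(f"AN   {name}.\n")
        for line in act.ca_lines:
            sink.write(f"CA   {line}\n")
        if act.systematic_name:
            sink.write(f"CC   -!- Systematic name: {act.systematic_name}.\n")
        for line in act.cc_lines:
            sink.write(f"CC   {line}\n")
        sink.write("//\n")
        n += 1
    return n


def write_catalog_tsv(activities: Iterable[EnzymeActivity], sink: IO[str]) -> int:
    """TSV export: ec, accepted_name, systematic_name, other_names (pipe-joined), status."""
    writer = csv.writer(sink, delimiter="\t", lineterminator="\n")
    writer.writerow(["ec", "accepted_name", "systematic_name", "other_names", "status"])
    n = 0
    for act in activities:
        writer.writerow([
            str(act.ec), act.accepted_name, act.systematic_name or "",
            "|".join(sorted(act.other_names)), act.status.value,
        ])
        n += 1
    return n


def name_index(activities: Iterable[EnzymeActivity]):
    """Map normalized name -> EC for a catalog.

    Returns ``(index, collisions)`` where collisions maps each normalized
    name claimed by more than one EC to the sorted list of claimant ECs;
    collided names are excluded from the index rather than silently won.
    """
    claims: dict = {}
    for act in activities:
        for name in act.name_set:
            claims.setdefault(normalize_name(name), set()).add(act.ec)
    index = {k: next(iter(v)) for k, v in claims.items() if len(v) == 1}
    collisions = {k: sorted(v, key=str) for k, v in claims.items() if len(v) > 1}
    return index, collisions
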