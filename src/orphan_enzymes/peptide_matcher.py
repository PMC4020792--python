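"""Identify proteins from N-terminal peptide reads and molecular weights.

Edman degradation reads the first 10–33 residues of a purified protein, one
cycle per residue.  The chemistry has characteristic artifacts: cysteine is
destroyed during the procedure (the cycle yields no call), and deamidation
converts asparagine to aspartate and glutamine to glutamate, so an observed
D may really be N and an observed E may really be Q.  Some cycles simply
give an ambiguous call between two residues.

This module turns such an error-prone read into the set of concrete peptide
variants it could represent (:func:`enumerate_variants`) and scans a
proteome for near-exact placements of any variant anchored at or near the
N-terminus (:func:`scan_proteome`).  At desk scale — one read against one
organism's proteome — the exhaustive anchored scan is exact, so no heuristic
aligner is needed.  Candidate identifications can be cross-validated
against an experimentally determined molecular weight
(:func:`validate_mw`), and in favorable cases the molecular weight alone
suffices to single out one protein (:func:`mw_only_match`).

Read mini-format: one line, one token per position —  a plain letter for an
unambiguous call, ``{S|T}`` for an ambiguous call, ``X`` for a cycle with
no call (UNKNOWN).  Example: ``MA{S|T}KXLD``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import AVERAGE_RESIDUE_MASS, WATER_AVERAGE_MASS

__all__ = [
    "AMINO_ACIDS",
    "NTerminalRead",
    "ErrorModel",
    "ProteomeEntry",
    "MatchCandidate",
    "MWCheck",
    "MWOnlyResult",
    "PeptideVariant",
    "VariantCapError",
    "parse_read",
    "render_read",
    "enumerate_variants",
    "scan_proteome",
    "compute_mw",
    "check_mw",
    "validate_mw",
    "mw_only_match",
    "read_proteome_fasta",
    "write_proteome_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class VariantCapError(ValueError):
    """Variant expansion would exceed the configured cap."""

    def __init__(self, count: int, cap: int):
        super().__init__(f"read expands to {count} variants, exceeding cap {cap}")
        self.count = count
        self.cap = cap


@dataclass(frozen=True)
class NTerminalRead:
    """Position-wise residue calls; ``None`` marks an UNKNOWN cycle."""

    positions: Tuple[Optional[FrozenSet[str]], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("read has no positions")
        for i, calls in enumerate(self.positions):
            if calls is None:
                continue
            if not calls or not calls <= _AA_SET:
                raise ValueError(f"position {i + 1}: call set {sorted(calls)} "
                                 "is empty or outside the 20 standard codes")

    @property
    def length(self) -> int:
        return len(self.positions)


def parse_read(text: str) -> NTerminalRead:
    """Parse the one-line read mini-format (``MA{S|T}KXLD``)."""
    text = text.strip()
    positions: List[Optional[FrozenSet[str]]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "{":
            end = text.find("}", i)
            if end < 0:
                raise ValueError(f"unclosed ambiguity set at column {i + 1}")
            calls = frozenset(text[i + 1:end].split("|"))
            positions.append(calls)
            i = end + 1
        elif ch == "X":
            positions.append(None)
            i += 1
        else:
            positions.append(frozenset(ch))
            i += 1
    return NTerminalRead(tuple(positions))


def render_read(read: NTerminalRead) -> str:
    out = []
    for calls in read.positions:
        if calls is None:
            out.append("X")
        elif len(calls) == 1:
            out.append(next(iter(calls)))
        else:
            out.append("{" + "|".join(sorted(calls)) + "}")
    return "".join(out)


@dataclass(frozen=True)
class ErrorModel:
    """Which Edman artifacts to compensate for when expanding a read.

    cys_loss: UNKNOWN cycles may be destroyed cysteines.
    deamidation: observed D admits true N; observed E admits true Q
        (artifacts corrupt the read, not the database sequence).
    met_start: the database sequence may retain an initiator methionine the
        mature, sequenced protein had cleaved.
    unknown_alphabet: residues substituted for UNKNOWN cycles.
    variant_cap: hard limit on the Cartesian expansion.
    """

    cys_loss: bool = True
    deamidation: bool = True
    met_start: bool = True
    unknown_alphabet: FrozenSet[str] = _AA_SET
    variant_cap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.variant_cap < 1:
            raise ValueError("variant_cap must be >= 1")


@dataclass(frozen=True)
class ProteomeEntry:
    protein_id: str
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - _AA_SET - {"X"}
        if self.sequence != self.sequence.upper() or bad:
            raise ValueError(f"{self.protein_id}: non-standard residues {sorted(bad)}")


@dataclass(frozen=True)
class PeptideVariant:
    """One concrete expansion of a read, with its correction trace."""

    sequence: str
    corrections: Tuple[Tuple[int, str], ...] = ()  # (0-based position, rule)


@dataclass(frozen=True)
class MWCheck:
    calc_kda: float
    exp_kda: float
    rel_dev: float
    passed: bool


@dataclass(frozen=True)
class MatchCandidate:
    protein_id: str
    start_offset: int
    mismatches: int
    corrections: Tuple[Tuple[int, str], ...] = ()
    variant_sequence: str = ""
    mw_check: Optional[MWCheck] = None


def enumerate_variants(read: NTerminalRead, model: ErrorModel) -> List[PeptideVariant]:
    """Cartesian expansion of per-position options, lexicographic order.

    Options at a position are the explicit call set plus model-induced
    additions; each model-induced residue carries a correction label so
    downstream ranking can prefer placements needing fewer corrections.
    """
    per_position: List[List[Tuple[str, Optional[str]]]] = []
    for i, calls in enumerate(read.positions):
        options: dict = {}
        if calls is None:
            alphabet = set(model.unknown_alphabet)
            if model.cys_loss:
                alphabet.add("C")
            for aa in alphabet:
                rule = "cys_loss" if (aa == "C" and model.cys_loss
                                      and aa not in model.unknown_alphabet) else "unknown"
                options[aa] = rule
        else:
            for aa in calls:
                options[aa] = None
            if model.deamidation:
                if "D" in calls:
                    options.setdefault("N", "deamidation")
                if "E" in calls:
                    options.setdefault("Q", "deamidation")
        per_position.append(sorted(options.items()))

    count = 1
    for opts in per_position:
        count *= len(opts)
    if count > model.variant_cap:
        raise VariantCapError(count, model.variant_cap)

    variants = []
    for combo in itertools.product(*per_position):
        seq = "".join(aa for aa, _ in combo)
        corrections = tuple((i, rule) for i, (_, rule) in enumerate(combo) if rule)
        variants.append(PeptideVariant(seq, corrections))
    return variants


def scan_proteome(
    variants: Sequence[PeptideVariant],
    proteome: Sequence[ProteomeEntry],
    max_mismatch: int = 2,
    max_start_offset: int = 1,
    met_start: bool = True,
) -> List[MatchCandidate]:
    """Exhaustive anchored scan of every variant against every protein.

    Placements start in ``[0, max_start_offset]``; when ``met_start`` and a
    protein begins with M, the offset-1 placement (initiator-Met retained in
    the database but absent from the mature read) is tested too.  An ``X``
    in a database sequence never matches.  Candidates within the mismatch
    budget are ranked by (mismatches, corrections, start_offset, protein_id).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    if max_mismatch < 0 or max_start_offset < 0:
        raise ValueError("max_mismatch and max_start_offset must be >= 0")

    # Variants expanded from one read share a per-position residue profile;
    # a window failing the profile in more than max_mismatch positions can
    # match no variant, so whole windows are pruned before the per-variant
    # Hamming pass.  Output is identical to the naive double loop.
    by_length: dict = {}
    for variant in variants:
        by_length.setdefault(len(variant.sequence), []).append(variant)
    profiles = {
        length: [frozenset(v.sequence[i] for v in group) for i in range(length)]
        for length, group in by_length.items()
    }

    candidates = []
    for entry in proteome:
        offsets = set(range(max_start_offset + 1))
        if met_start and entry.sequence.startswith("M"):
            offsets.add(1)
        for length, group in by_length.items():
            profile = profiles[length]
            for off in sorted(offsets):
                window = entry.sequence[off:off + length]
                if len(window) < length:
                    continue
                bound = 0
                for allowed, b in zip(profile, window):
                    if b == "X" or b not in allowed:
                        bound += 1
                        if bound > max_mismatch:
                            break
                if bound > max_mismatch:
                    continue
                for variant in group:
                    mism = 0
                    for a, b in zip(variant.sequence, window):
                        if b == "X" or a != b:
                            mism += 1
                            if mism > max_mismatch:
                                break
                    if mism <= max_mismatch:
                        candidates.append(MatchCandidate(
                            protein_id=entry.protein_id, start_offset=off,
                            mismatches=mism, corrections=variant.corrections,
                            variant_sequence=variant.sequence,
                        ))
    candidates.sort(key=lambda c: (c.mismatches, len(c.corrections),
                                   c.start_offset, c.protein_id, c.variant_sequence))
    return candidates


def compute_mw(sequence: str) -> float:
    """Average molecular weight of a peptide chain, Daltons.

    Sum of pinned average residue masses plus one water.  ``X`` and any
    other non-standard character are rejected (a mass for an unknown
    residue would silently bias the weight).
    """
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    total = WATER_AVERAGE_MASS
    for i, aa in enumerate(sequence):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}") from None
    return total


def check_mw(calc_kda: float, exp_kda: float, rel_tolerance: float = 0.15) -> MWCheck:
    """Compare a calculated vs experimentally determined weight (kDa)."""
    if exp_kda <= 0:
        raise ValueError("experimental molecular weight must be positive")
    if not 0 < rel_tolerance < 1:
        raise ValueError("rel_tolerance must be in (0, 1)")
    rel_dev = abs(calc_kda - exp_kda) / exp_kda
    return MWCheck(calc_kda=calc_kda, exp_kda=exp_kda, rel_dev=rel_dev,
                   passed=rel_dev <= rel_tolerance)


def validate_mw(
    candidate: MatchCandidate,
    sequence: str,
    exp_kda: float,
    rel_tolerance: float = 0.15,
) -> MatchCandidate:
    """Attach an MW cross-check (full-sequence weight vs experimental kDa)."""
    calc_kda = compute_mw(sequence) / 1000.0
    return replace(candidate, mw_check=check_mw(calc_kda, exp_kda, rel_tolerance))


@dataclass(frozen=True)
class MWOnlyResult:
    candidates: Tuple[MatchCandidate, ...]
    unique: bool


def mw_only_match(
    exp_kda: float,
    proteome: Sequence[ProteomeEntry],
    rel_tolerance: float = 0.15,
) -> MWOnlyResult:
    """All proteins whose computed weight passes the tolerance, best first.

    ``unique`` is set when exactly one protein passes — the case in which a
    molecular weight alone suffices to identify the enzyme in a fully
    sequenced genome.
    """
    passing = []
    for entry in proteome:
        chk = check_mw(compute_mw(entry.sequence) / 1000.0, exp_kda, rel_tolerance)
        if chk.passed:
            passing.append(MatchCandidate(
                protein_id=entry.protein_id, start_offset=0, mismatches=0,
                mw_check=chk,
            ))
    passing.sort(key=lambda c: (c.mw_check.rel_dev, c.protein_id))
    return MWOnlyResult(candidates=tuple(passing), unique=len(passing) == 1)


# ---------------------------------------------------------------- FASTA I/O
# Header convention: >protein_id organism=<free text>

def read_proteome_fasta(source: Union[str, Path, IO[str]]) -> List[ProteomeEntry]:
    entries = []
    for rec in SeqIO.parse(source, "fasta"):
        organism = ""
        _, _, rest = rec.description.partition("organism=")
        if rest:
            organism = rest.strip()
        entries.append(ProteomeEntry(protein_id=rec.id, organism=organism,
                                     sequence=str(rec.seq)))
    return entries


def write_proteome_fasta(entries: Iterable[ProteomeEntry],
                         sink: Union[str, Path, IO[str]]) -> int:
    records = [
        SeqRecord(Seq(e.sequence), id=e.protein_id, description=f"organism={e.organism}")
        for e in entries
    ]
    return SeqIO.write(records, sink, "fasta")
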