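"""Seeded synthetic fixtures with recorded ground truth.

Every other module in this package consumes files — EC catalogs, evidence
tables, document corpora, proteomes, peptide reads — that in production
come from curated databases and publications.  The generators here emulate
those inputs at desk scale with *planted*, recorded ground truth, so the
whole toolchain is exercisable and verifiable offline:

* :func:`make_census_fixture` plants a known orphan set (default fraction
  0.23, the observed orphan burden among EC activities) and a configurable
  number of systematic single-submitter mis-assignment clusters (default 3,
  the number of such incidents observed in practice), then writes an
  ENZYME-dialect catalog, per-source evidence TSVs, and a truth TSV.
* :func:`make_nterm_fixture` builds a random proteome, designates a target
  protein, and emits an N-terminal read of its prefix with seeded Edman
  artifacts injected: ambiguous two-residue calls (default 2 per read),
  plus up to ``injected_errors_per_read`` errors drawn from {substitution,
  cysteine lost to an UNKNOWN cycle, deamidation flip} (default 2).  Read
  lengths default to 10–33 residues, the range amino-terminal sequencing
  typically yields.

Generation uses only :class:`random.Random` integer state — identical spec
and seed give byte-identical files on any platform.  Truth lives in
sidecar TSVs, never in FASTA headers or record comments, so consumers
cannot shortcut past the real parsers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .ec_catalog import ECNumber, EntryStatus, EnzymeActivity, write_enzyme_catalog
from .orphan_census import SequenceEvidence, write_evidence_tsv
from .peptide_matcher import (
    AMINO_ACIDS,
    NTerminalRead,
    ProteomeEntry,
    compute_mw,
    render_read,
    write_proteome_fasta,
)

__all__ = ["FixtureSpec", "make_census_fixture", "make_nterm_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the generators; defaults are the emulated study conditions."""

    seed: int = 0
    n_activities: int = 200
    orphan_fraction: float = 0.23
    n_sources: int = 5
    systematic_error_clusters: int = 3
    n_proteins: int = 500
    protein_length_range: Tuple[int, int] = (200, 400)
    read_length_range: Tuple[int, int] = (10, 33)
    injected_errors_per_read: int = 2
    ambiguity_positions_per_read: int = 2
    n_deleted: int = 3
    n_transferred: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise ValueError("orphan_fraction must be in [0, 1]")
        for name in ("n_activities", "n_sources", "systematic_error_clusters",
                     "n_proteins", "injected_errors_per_read",
                     "ambiguity_positions_per_read", "n_deleted", "n_transferred"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("protein_length_range", "read_length_range"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi")


_SUBSTRATES = [
    "alanine", "arabinitol", "butanal", "choline", "citrate", "fluorene",
    "galactarate", "glycerol", "hexanoate", "inositol", "lactate", "malonate",
    "mannitol", "mevaldate", "nicotinate", "octanol", "putrescine", "quinate",
    "rhamnose", "sarcosine", "shikimate", "sorbitol", "tartronate", "threonate",
    "urocanate", "valerate", "xylitol", "xylose",
]
_SUFFIX_BY_CLASS = {
    1: ["dehydrogenase", "reductase", "oxidase"],
    2: ["transferase", "kinase", "sulfotransferase"],
    3: ["hydrolase", "esterase", "amidase"],
    4: ["lyase", "decarboxylase", "dehydratase"],
    5: ["isomerase", "epimerase", "mutase"],
    6: ["ligase", "synthetase", "carboxylase"],
}


def _gen_activities(spec: FixtureSpec, rng: random.Random) -> List[EnzymeActivity]:
    """Deterministic catalog: unique ECs, synthesized plausible name sets."""
    activities = []
    serial_counter: Dict[Tuple[int, int, int], int] = {}
    total = spec.n_activities + spec.n_deleted + spec.n_transferred
    for i in range(total):
        c1 = (i % 6) + 1
        c2 = (i // 6) % 9 + 1
        c3 = (i // 54) % 9 + 1
        key = (c1, c2, c3)
        serial_counter[key] = serial_counter.get(key, 0) + 1
        # sprinkle preliminary serials to exercise the "n"-token path
        serial = (f"n{serial_counter[key]}" if i % 37 == 36
                  else serial_counter[key])
        ec = ECNumber(c1, c2, c3, serial)
        if i >= spec.n_activities:
            if i < spec.n_activities + spec.n_deleted:
                activities.append(EnzymeActivity(ec=ec, status=EntryStatus.DELETED))
            else:
                target = f"{c1}.{c2}.{c3}.{serial_counter[key] + 50}"
                activities.append(EnzymeActivity(
                    ec=ec, status=EntryStatus.TRANSFERRED, transferred_to=target))
            continue
        substrate = _SUBSTRATES[i % len(_SUBSTRATES)]
        suffix = _SUFFIX_BY_CLASS[c1][(i // len(_SUBSTRATES)) % 3]
        qualifier = i // (len(_SUBSTRATES) * 3)
        accepted = f"{substrate} {suffix}"
        if qualifier:
            accepted += f" {qualifier + 1}"
        locant = rng.randint(1, 9)
        other = {f"{substrate}-{locant}-{suffix}"}
        if rng.random() < 0.5:
            other.add(f"L-{substrate} {suffix}")
        systematic = (f"{substrate}:NAD+ {suffix}" if rng.random() < 0.6 else None)
        activities.append(EnzymeActivity(
            ec=ec, accepted_name=accepted, systematic_name=systematic,
            other_names=frozenset(other),
            ca_lines=(f"{substrate} + acceptor = product",),
        ))
    return activities


def make_census_fixture(spec: FixtureSpec, out_dir) -> Dict[str, object]:
    """Write catalog + per-source evidence TSVs + truth TSV; return paths and truth.

    The planted orphan count is ``floor(orphan_fraction * n_activities)``
    (recorded in the truth file).  Orphans get *no* unflagged evidence;
    each cluster orphan instead gets >= 3 accessions from one fabricated
    submitting center with no corroboration, so the downstream
    flag-and-reconcile pass must discard the cluster to recover the truth
    set.  Non-orphans receive 1–3 accessions spread over the sources, with
    per-accession submitters chosen so no genuine entry trips the cluster
    rule.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    activities = _gen_activities(spec, rng)
    active = [a for a in activities if a.status is EntryStatus.ACTIVE]

    n_orphans = int(spec.orphan_fraction * spec.n_activities)
    orphan_idx = sorted(rng.sample(range(len(active)), n_orphans))
    orphans = [active[i].ec for i in orphan_idx]
    orphan_set = set(orphans)

    sources = [f"source_{chr(ord('a') + s)}" for s in range(max(spec.n_sources, 1))]
    evidence: List[SequenceEvidence] = []
    acc_counter = 0

    def next_acc(prefix: str) -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"{prefix}{acc_counter:06d}"

    for act in active:
        if act.ec in orphan_set:
            continue
        n_rows = rng.randint(1, 3)
        row_sources = [sources[rng.randrange(len(sources))] for _ in range(n_rows)]
        for j, src in enumerate(row_sources):
            # distinct submitters (or none) per accession keep genuine
            # entries below the uncorroborated-cluster threshold
            submitter = f"lab_{rng.randint(1, 40)}" if rng.random() < 0.5 else None
            if j > 0 and submitter is not None:
                submitter = f"{submitter}_{j}"
            evidence.append(SequenceEvidence(
                source=src, ec=act.ec, accession=next_acc("ACC"),
                submitter=submitter))

    clusters = []
    n_clusters = min(spec.systematic_error_clusters, len(orphans))
    cluster_ecs = orphans[:n_clusters]
    for k, ec in enumerate(cluster_ecs):
        center = f"center_{k + 1}"
        src = sources[k % len(sources)]
        n_accs = rng.randint(3, 6)
        for _ in range(n_accs):
            evidence.append(SequenceEvidence(
                source=src, ec=ec, accession=next_acc("SYS"), submitter=center))
        clusters.append((ec, center, src, n_accs))

    catalog_path = out_dir / "catalog.enzyme"
    with open(catalog_path, "w") as fh:
        write_enzyme_catalog(activities, fh)

    evidence_paths = []
    for src in sources:
        path = out_dir / f"evidence_{src}.tsv"
        with open(path, "w") as fh:
            write_evidence_tsv([e for e in evidence if e.source == src], fh)
        evidence_paths.append(path)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("kind\tec\tsubmitter\tsource\tdetail\n")
        fh.write(f"meta\t\t\t\tn_orphans_planted={n_orphans}\n")
        for ec in orphans:
            fh.write(f"orphan\t{ec}\t\t\t\n")
        for ec, center, src, n_accs in clusters:
            fh.write(f"cluster\t{ec}\t{center}\t{src}\tn_accessions={n_accs}\n")

    return {
        "catalog": catalog_path,
        "evidence": evidence_paths,
        "truth": truth_path,
        "orphans": orphans,
        "clusters": clusters,
    }


def make_nterm_fixture(spec: FixtureSpec, out_dir) -> Dict[str, object]:
    """Write proteome FASTA + read file + truth TSV; return paths and truth.

    The read is the target protein's N-terminal prefix (offset 0, or 1 when
    the target starts with M and the mature protein lost the initiator)
    with seeded injections.  The injection trace (position, type, true
    residue, observed call) and the target's computed molecular weight are
    recorded in the truth file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    lo, hi = spec.protein_length_range
    proteome = []
    for i in range(spec.n_proteins):
        length = rng.randint(lo, hi)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
        proteome.append(ProteomeEntry(
            protein_id=f"prot_{i:05d}", organism="Synthetica exempli",
            sequence=seq))

    target = proteome[rng.randrange(len(proteome))]
    rlo, rhi = spec.read_length_range
    read_len = rng.randint(rlo, min(rhi, len(target.sequence) - 1))
    start_offset = 1 if (target.sequence.startswith("M") and rng.random() < 0.5) else 0
    if read_len + start_offset > len(target.sequence):
        raise ValueError("read longer than target protein")
    true_prefix = list(target.sequence[start_offset:start_offset + read_len])

    # choose injection/ambiguity positions; rewrite the underlying protein
    # residue where an error type needs a specific true residue (C for
    # cysteine loss, N/Q for deamidation), keeping truth and FASTA in sync
    n_err = min(spec.injected_errors_per_read, read_len)
    n_amb = min(spec.ambiguity_positions_per_read, read_len - n_err)
    special = rng.sample(range(read_len), n_err + n_amb)
    err_pos, amb_pos = special[:n_err], special[n_err:]

    trace: List[Tuple[int, str, str, str]] = []
    positions: List[Optional[frozenset]] = [frozenset(r) for r in true_prefix]

    for p in err_pos:
        kind = rng.choice(["substitution", "cys_unknown", "deamidation"])
        if kind == "cys_unknown":
            true_res = "C"
            observed = "X"
            positions[p] = None
        elif kind == "deamidation":
            true_res = rng.choice("NQ")
            observed = "D" if true_res == "N" else "E"
            positions[p] = frozenset(observed)
        else:
            true_res = true_prefix[p]
            observed = rng.choice([a for a in AMINO_ACIDS if a != true_res])
            positions[p] = frozenset(observed)
        true_prefix[p] = true_res
        trace.append((p, kind, true_res, observed))

    for p in amb_pos:
        true_res = true_prefix[p]
        alt = rng.choice([a for a in AMINO_ACIDS if a != true_res])
        positions[p] = frozenset({true_res, alt})
        trace.append((p, "ambiguity", true_res, f"{true_res}|{alt}"))

    new_seq = (target.sequence[:start_offset] + "".join(true_prefix)
               + target.sequence[start_offset + read_len:])
    proteome = [
        ProteomeEntry(e.protein_id, e.organism, new_seq)
        if e.protein_id == target.protein_id else e
        for e in proteome
    ]
    target = next(e for e in proteome if e.protein_id == target.protein_id)

    read = NTerminalRead(tuple(positions))
    mw_kda = compute_mw(target.sequence) / 1000.0

    proteome_path = out_dir / "proteome.fasta"
    write_proteome_fasta(proteome, str(proteome_path))
    read_path = out_dir / "read.txt"
    read_path.write_text(render_read(read) + "\n")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("kind\tposition\ttype\ttrue_residue\tobserved\tdetail\n")
        fh.write(f"target\t\t\t\t\tprotein_id={target.protein_id}\n")
        fh.write(f"offset\t\t\t\t\tstart_offset={start_offset}\n")
        fh.write(f"mw\t\t\t\t\tmw_kda={mw_kda:.6f}\n")
        for p, kind, true_res, observed in sorted(trace):
            fh.write(f"injection\t{p}\t{kind}\t{true_res}\t{observed}\t\n")

    return {
        "proteome": proteome_path,
        "read": read_path,
        "truth": truth_path,
        "target_id": target.protein_id,
        "start_offset": start_offset,
        "trace": sorted(trace),
        "mw_kda": mw_kda,
    }
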