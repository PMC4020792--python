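# Methods

This note documents the models, rules, and numerical choices behind
`orphan_enzymes`, in the order a census-to-resolution workflow uses them.

## The problem being modeled

An *orphan enzyme* is an enzymatic activity that has been experimentally
characterized — typically purified and assayed, and classified with a
four-part EC number — but has no associated amino-acid sequence in any major
sequence database. Orphans arise at three chokepoints: the protein was never
sequenced; it was sequenced but the data never deposited; or it was deposited
but mis-annotated so the activity cannot be found. The toolkit mechanizes the
desk work of finding and fixing the third kind and of book-keeping the rest:
counting orphans, searching robustly across name variants, identifying
proteins from partial N-terminal sequence and molecular weight, and
classifying why each resolved orphan was orphaned.

## EC catalog model

EC identifiers are class.subclass.sub-subclass.serial with all three leading
components positive integers (classes 1–6, the hierarchy in force for the
catalogs this package targets). The serial may be a plain integer, a
preliminary "n"-prefixed token (temporary numbers awaiting Enzyme Commission
review; preserved verbatim), or absent — a *class-level* identifier such as
`1.1.1.-`.

The flat-file dialect uses two-letter line codes (`ID`, `DE`, `AN`, `CA`,
`CC`) with `//` record terminators. Two deliberate dialect decisions:

* Each `AN` line holds one complete alternate name (the writer never wraps
  names), so the reader can treat lines as names without guessing at
  period-delimited continuations.
* The systematic name has no line code of its own in the classic dialect, but
  the activity model carries it as a first-class field; the writer emits it
  as a recognized comment (`CC   -!- Systematic name: ...`) and the reader
  lifts it back out. All other `CA`/`CC` content is stored verbatim and never
  interpreted.

Name comparison everywhere uses one normalization: lowercase, Greek-letter
transliteration (α→alpha, ...), whitespace collapse, trailing-period strip.
`name_index` either yields an injective name→EC map or reports the colliding
names explicitly; collisions are never silently resolved.

Entries marked "Deleted entry" or "Transferred entry: x.y.z.w" keep a
non-ACTIVE status (transferred entries retain the target pointer) and are
excluded from census denominators — the census measures the burden among
activities that still exist.

## Census semantics

`reconcile` partitions ACTIVE activities: an activity is a *putative orphan*
iff no source contributes an unflagged evidence row citing its full EC
number. Three asymmetries matter:

* **Class-level evidence never de-orphans.** An annotation to `1.1.1.-` says
  "some oxidoreductase", which is exactly the situation that leaves specific
  activities orphaned; it is recorded but never counts as sequence for any
  full EC.
* **Flagged evidence never de-orphans.** Sequence–EC pairings judged suspect
  are kept for audit but contribute nothing.
* **Unknown ECs warn, never fail.** Evidence citing an EC absent from (or
  removed from) the catalog goes to a structured warnings list and the module
  logger, since heterogeneous sources routinely lag the catalog.

`flag_systematic` mechanizes the discard of systematic mis-assignments: all
rows for an (EC, submitter) pair are flagged when that submitter supports the
EC with at least `min_cluster` accessions and *nobody else* — any other
submitter, or any row without submitter metadata — mentions the EC. The
default `min_cluster=3` is conservative: two accessions from one center is
ordinary redundancy, three-plus with zero outside corroboration is the
signature of a pipeline error. Rows without submitter metadata are never
flagged (there is no center to attribute the error to). The operation is a
pure function: idempotent and independent of input order.

The orphan burden is reported as `100 × n_orphans / n_evaluated` with
half-up rounding (default 0 decimals for this statistic, matching how such
burdens are conventionally quoted).

## Name permutation rules

`permute_name` computes the closure of five rewrite rules, breadth-first,
deduplicating on the normalized form, origin always first, each term
carrying the rule labels that produced it:

| rule | effect | example |
|---|---|---|
| `strip_locants_joined` | drop digit runs with their flanking hyphens, fuse fragments | fluoren-9-ol → fluorenol |
| `strip_locants_spaced` | same, but separate fragments with a space | rhamnose-1-dehydrogenase → rhamnose dehydrogenase |
| `hyphens_to_spaces` | replace every hyphen with a space | oxido-reductase → oxido reductase |
| `strip_cofactor` | drop a *terminal* parenthetical naming a cofactor (NAD+, NADH, NADP+, NADPH, FAD, FMN, ATP, GTP, CoA, quinone, cytochrome) | mevaldate reductase (NADPH) → mevaldate reductase |
| `strip_chirality` | drop token-leading chirality prefixes (L-, D-, DL-, (R)-, (S)-, (±)-, cis-, trans-, meso-) | L-rhamnose → rhamnose |

Two locant rules exist because real name drift goes both ways: locants
inside a fused chemical token disappear without trace ("fluorenol"), while
locants joining separate words leave a word boundary ("rhamnose
dehydrogenase"). Generating both shapes costs a few extra terms and loses
nothing — search treats the term set as a disjunction. Locant removal only
targets digit runs adjacent to hyphens, never digits embedded in plain
tokens (so "Delta4" survives intact). Cofactor parentheticals are removed
only in terminal position, the EC naming convention.

The closure is capped (default 64 terms per name) with a logged warning on
overflow; the default rules converge in a handful of terms on real enzyme
names, so the cap exists only to bound pathological or user-supplied rule
sets. The rule set is a plain dict argument and therefore restrictable and
extensible; adding rules can only grow the term set (monotonicity is
property-tested).

`search_corpus` ranks documents by (distinct matched terms desc, earliest
match position asc, doc_id asc), matching on normalized text, either as
whole-word phrases (`EXACT`) or raw substrings (`SUBSTRING`).

## N-terminal read matching

A read is a per-cycle list of call sets: a single residue, an explicit
ambiguity set like `{S|T}`, or UNKNOWN (`X`) for a cycle that yielded no
call. The error model reflects Edman-degradation chemistry:

* **Cysteine loss** — cysteine is destroyed during the procedure, so an
  UNKNOWN cycle may be a C (on by default).
* **Deamidation** — modeled in the observed→true direction, since the
  artifact corrupts the read, not the database: an observed D admits true N,
  an observed E admits true Q (on by default).
* **Initiator methionine** — the database sequence may retain an initiator M
  that the mature, sequenced protein had cleaved; when enabled, proteins
  beginning with M are additionally tested at offset 1.

`enumerate_variants` is the Cartesian expansion of per-position option sets
in deterministic lexicographic order; each model-induced residue carries a
`(position, rule)` correction so ranking can prefer explanations needing
fewer corrections. The expansion is counted before it is built and a
`variant_cap` (default 1,000,000) turns runaway reads into a hard error
reporting the would-be count; a 25-cycle read with two UNKNOWN cycles, two
ambiguous cycles, and a few deamidation-eligible positions legitimately
expands to ~10⁴–10⁵ variants, which the cap must accommodate.

`scan_proteome` is an exhaustive anchored scan: every variant against every
protein at start offsets 0..`max_start_offset` (default 1) plus the
initiator-Met placement. At desk scale — one read against one organism's
proteome — this is exact, needs no statistical significance machinery, and
replaces any heuristic aligner. Internally, windows are pre-screened against
the per-position residue profile of the variant set (a lower bound on the
best achievable mismatch count) before the per-variant Hamming pass; this
pruning changes nothing about the output and keeps 500-protein scans with
10⁴ variants under a few milliseconds. Candidates are ranked by
(mismatches, |corrections|, start_offset, protein_id, variant sequence) —
the last key only to make ties deterministic. A database `X` never matches
anything. Larger placements (signal peptides) require explicitly raising
`max_start_offset`; by default matching is anchored at the N-terminus,
which is where the chemistry reads.

## Molecular weights

`compute_mw` sums **average** residue masses (gel- and column-derived
experimental weights are average masses) plus one water, from a table pinned
in `masses.py` (version `avg-2023.1`) so results never drift with library
upgrades; the test suite cross-checks it against an independent proteomics
mass calculator. `X` is rejected — an invented mass would silently bias the
weight. kDa conversion is by 1000; rounding happens only at presentation.

`validate_mw` compares the calculated full-sequence weight against the
experimental estimate as a relative deviation, with default tolerance 0.15:
gel estimates are commonly off by ±10–15%, so a 33 kDa computed weight
rightly passes against a "≈30 kDa" gel value (rel_dev 0.10).
`mw_only_match` applies the same filter proteome-wide and sets a uniqueness
flag when exactly one protein passes — the favorable case in which a
molecular weight alone identifies the enzyme in a sequenced genome.

## Resolution taxonomy

`classify` is a fixed first-match-wins ladder over an explicitly coded
annotation state — this package deliberately does not infer states from free
text; that judgment call stays with the curator:

1. listed activity name present, EC absent → `MISSING_EC`
2. activity present under unlisted names only → `MISSING_SYNONYM`
3. correct activity with a wrong EC attached → `WRONG_EC`
4. class-level annotation only → `CLASS_LEVEL_ONLY`
5. no activity annotated → `NO_ACTIVITY_ASSIGNED`
6. annotated with a different activity the enzyme also has → `ADDITIONAL_ACTIVITY`
7. a different specific same-class activity, replaced → `SIMILAR_ACTIVITY_REPLACED`

Rungs 1–3 are *data labeling errors* (the activity was nominally attached
but unfindable), rungs 4–7 *annotation updates* (the sequence was present,
its annotation lagged). A state that is contradictory (e.g. "no activity"
plus a class-level name) or describes an already-correct annotation raises
rather than guesses.

`summarize` uses half-up rounding to 2 decimals and two denominators, both
echoed in the output: total records for resolved/open shares, resolved
records for category, group, and method shares. Published tabulations of
this kind occasionally contain internally inconsistent subtype percentages
(consistent group and method cells alongside subtype cells implying a
slightly different denominator); this package always uses the resolved
count and does not reproduce such anomalies.

## Synthetic fixtures

The generators emulate the data regimes of a real orphan-enzyme census at
desk scale; their defaults are the emulated study conditions, not tuning
knobs:

* census: orphan fraction 0.23 (the observed orphan burden), 5 evidence
  sources (the number of databases such a census cross-references), 3
  systematic-error clusters (the number of single-center incidents observed
  in practice), plus a few deleted/transferred entries;
* proteomes: 500 proteins of 200–400 uniform-random residues (~22–44 kDa,
  the range of the weights used for cross-validation);
* reads: 10–33 cycles (the yield range of amino-terminal sequencing), 2
  ambiguous calls and up to 2 injected errors per read, drawn from
  {substitution, cysteine-lost-to-UNKNOWN, deamidation flip}.

Residues are drawn uniformly over the 20-letter alphabet — adequate for
matcher testing, where only collision probabilities matter; there is no
compositional or codon model. Generation uses `random.Random` integer state
only, so identical spec+seed yields byte-identical files across platforms.
Ground truth (planted orphans, error clusters, target protein, injection
trace, target weight) is written to sidecar TSVs, never encoded in FASTA
headers, so consumers must go through the real parsers.

What passing fixture-based tests does *not* show about real data: real
evidence tables have correlated errors beyond single-center clusters; real
proteomes contain homologs and low-complexity regions that make N-terminal
reads less unique than uniform-random sequence suggests; and real name drift
is richer than the five rewrite rules. The planted-recovery rate measured
here is therefore an upper bound on real-world recovery.

## Problem sizes and determinism

The shipped verification suite sizes are chosen to make every check exact or
strongly powered while remaining quick: brute-force census oracles at ≤30
ECs × ≤100 evidence rows over 200 seeded instances; brute-force scan oracles
at ≤50 proteins × ≤500 residues over 100 instances; planted-read recovery
over 100 replicates of 500-protein proteomes. All randomness is seeded; the
acceptance script derives every generator seed from its `--seed` argument,
and the published-count arithmetic is seed-independent by construction.

## Known limitations

* The census models evidence as flat (source, EC, accession, submitter)
  assertions; no provenance chains, dates, or retraction semantics.
* `classify` consumes coded states, so inter-curator disagreement lives
  outside the package boundary.
* The anchored scan is exact but quadratic in the worst case; it is meant
  for one-read-vs-one-proteome work, not proteome-vs-proteome search.
* No isoelectric-point prediction: pI is carried as metadata in
  identification-information rows only.
* Catalog parsing targets the dialect written by this package and the
  classic line-code layout; heavily wrapped multi-line names from other
  emitters may need pre-normalization.
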