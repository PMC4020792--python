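# orphan-enzymes

A toolkit for resolving **orphan enzymes** — enzymatic activities that have
been experimentally characterized, and classified with an EC number, but
have no associated amino-acid sequence in any major database. Every such
activity is knowledge stranded in the literature: invisible to BLAST,
genome annotation, and every sequence-based prediction tool. The package is
written for the people who do the stranding-recovery work — database
curators, annotation teams, and computational biologists auditing EC
coverage.

It mechanizes the four desk operations of an orphan-enzyme campaign:

1. **Census** (`ec_catalog`, `orphan_census`) — parse an ENZYME-dialect EC
   catalog, reconcile it against per-source evidence tables
   (source, EC, accession, submitter), and partition activities into
   *sequenced* vs *putative orphan*. An activity is an orphan only if it
   lacks unflagged evidence across **all** sources; class-level annotations
   (`1.1.1.-`) never count, and uncorroborated single-submitter assignment
   clusters are auto-flagged as systematic errors before counting.
2. **Synonym-robust search** (`name_permuter`) — generate the closure of
   name rewrite rules (drop locants: *fluoren-9-ol* → *fluorenol*; strip
   chirality prefixes and trailing cofactor parentheticals; hyphens to
   spaces) and rank a local document corpus against the term set.
3. **Peptide and weight identification** (`peptide_matcher`) — expand an
   error-prone Edman N-terminal read (ambiguous calls `{S|T}`, unknown
   cycles `X`, cysteine loss, deamidation D⇒N / E⇒Q) into its concrete
   variants and scan a proteome exhaustively near the N-terminus; validate
   candidates against experimental molecular weights (average masses,
   default ±15%), or identify by weight alone.
4. **Outcome bookkeeping** (`resolution_ledger`) — classify *why* each
   resolved orphan was orphaned (a seven-rung decision ladder split between
   *annotation updates* and *data labeling errors*), summarize ledgers with
   exact half-up percentages, and write per-publication
   identification-information tables.

A seeded fixture generator (`synth_fixtures`) emulates all the input data
regimes with recorded ground truth, so the full pipeline runs and is
verifiable entirely offline.

## Worked example

Generate a census fixture (200 activities, 23% planted orphans, 3 planted
systematic-error clusters) and reconcile it:

```console
$ oe fixture census --seed 7 --out fx
catalog=fx/catalog.enzyme truth=fx/truth.tsv n_orphans=46
$ oe census --catalog fx/catalog.enzyme \
    --evidence fx/evidence_source_a.tsv --evidence fx/evidence_source_b.tsv \
    --evidence fx/evidence_source_c.tsv --evidence fx/evidence_source_d.tsv \
    --evidence fx/evidence_source_e.tsv --out census.tsv
evaluated=200 orphans=46 orphan_burden=23%
```

46 of 200 evaluated activities (23%) lack credible sequence evidence — and
they are exactly the 46 planted in `fx/truth.tsv`: the three orphans backed
only by a single sequencing center's uncorroborated accession cluster were
flagged and correctly kept orphan. `census.tsv` lists each EC with its
status and supporting-source count.

Permute a name the way a curator searches:

```console
$ oe permute --name "fluoren-9-ol dehydrogenase"
fluoren-9-ol dehydrogenase	origin
fluorenol dehydrogenase	strip_locants_joined
fluoren ol dehydrogenase	strip_locants_spaced
fluoren 9 ol dehydrogenase	hyphens_to_spaces
```

The second term is the spelling actually used in the literature when the
locant is dropped — the form an exact-name search would miss.

Identify a protein from a corrupted N-terminal read. The fixture read below
carries two ambiguous calls, one unknown cycle (`X`), and an injected
error; the scan still pins the planted target, and its computed weight
passes against a 46 kDa gel estimate:

```console
$ oe fixture nterm --seed 3 --out nt
proteome=nt/proteome.fasta read=nt/read.txt target=prot_00124
$ cat nt/read.txt
MDYRXGNKC{M|Y}RMHMNWLNDFF{G|L}
$ oe nterm --read nt/read.txt --proteome nt/proteome.fasta --mw-kda 46 --top 2
protein_id	offset	mismatches	corrections	mw_check
prot_00124	0	1	4:unknown	calc=45.8kDa dev=0.00 pass
prot_00124	0	2	4:unknown	calc=45.8kDa dev=0.00 pass
```

One substitution mismatch remains after the unknown cycle is filled
(`4:unknown`), the placement is at the N-terminus (offset 0), and the
calculated 45.8 kDa deviates 0% from the experimental estimate.

Summarize a resolution ledger:

```console
$ oe summarize --ledger ledger.tsv
{
  "n_total": 2,
  "n_resolved": 1,
  ...
  "resolved_pct": 50.0,
  ...
}
```

All commands are thin wrappers; the same operations are importable
(`from orphan_enzymes import reconcile, permute_name, scan_proteome, summarize`).

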