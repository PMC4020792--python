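"""Synonym-robust enzyme-name permutation and local corpus search.

Enzyme names drift between the official EC listing and the literature: a
paper may write "fluorenol dehydrogenase" where the listing says
"fluoren-9-ol dehydrogenase", drop a chirality prefix, or omit the cofactor
parenthetical.  Searching with only the listed spelling therefore misses
documents.  :func:`permute_name` generates the closure of a small set of
rewrite rules over a name — dropping locant numbers and their hyphens,
replacing hyphens with spaces, stripping terminal cofactor parentheticals
and leading chirality prefixes — and :func:`search_corpus` ranks a local
document corpus against the resulting term set.

The rule inventory is deliberately configurable: published search protocols
describe their permutations open-endedly, so the default set covers the
standard rewrites and callers may restrict or extend it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .ec_catalog import normalize_name

__all__ = [
    "TermSet",
    "DocumentRecord",
    "SearchMode",
    "permute_name",
    "search_corpus",
    "DEFAULT_RULES",
    "MAX_TERMS",
]

logger = logging.getLogger(__name__)

MAX_TERMS = 64

#: Cofactor tokens recognized in a trailing parenthetical, e.g. "(NADPH)".
COFACTOR_TOKENS = (
    "NAD+", "NADH", "NADP+", "NADPH", "FAD", "FMN", "ATP", "GTP",
    "CoA", "quinone", "cytochrome",
)

#: Chirality/stereochemistry prefixes stripped from the start of a token.
CHIRALITY_PREFIXES = ("DL-", "L-", "D-", "(R)-", "(S)-", "(±)-", "cis-", "trans-", "meso-")

# locant = digit run attached to hyphens: "-9-" internal, "4-" token-initial,
# "-2" token-final.  Internal locants are rewritten with a configurable
# separator: joining the fragments recovers fused forms ("fluoren-9-ol" ->
# "fluorenol"), spacing them recovers split forms ("rhamnose-1-dehydrogenase"
# -> "rhamnose dehydrogenase"); both shapes occur in the literature, so both
# rules are in the default set.
_LOCANT_INTERNAL = re.compile(r"-\d+(?:,\d+)*-")
_LOCANT_LEADING = re.compile(r"(?:(?<=\s)|^)\d+(?:,\d+)*-")
_LOCANT_TRAILING = re.compile(r"-\d+(?:,\d+)*(?=\s|$)")


def _strip_locants(name: str, sep: str) -> str:
    out = _LOCANT_INTERNAL.sub(sep, name)
    out = _LOCANT_LEADING.sub("", out)
    out = _LOCANT_TRAILING.sub("", out)
    return re.sub(r"\s+", " ", out).strip()


def _rule_locants_joined(name: str) -> str:
    return _strip_locants(name, "")


def _rule_locants_spaced(name: str) -> str:
    return _strip_locants(name, " ")


def _rule_hyphens_to_spaces(name: str) -> str:
    return re.sub(r"\s+", " ", name.replace("-", " ")).strip()


_PARENTHETICAL = re.compile(r"\s*\(([^()]*)\)\s*$")


def _rule_strip_cofactor(name: str) -> str:
    m = _PARENTHETICAL.search(name)
    if not m:
        return name
    content = m.group(1).lower()
    if any(tok.lower() in content for tok in COFACTOR_TOKENS):
        return name[: m.start()].strip()
    return name


def _rule_strip_chirality(name: str) -> str:
    tokens = name.split()
    out = []
    for tok in tokens:
        changed = True
        while changed:
            changed = False
            for prefix in CHIRALITY_PREFIXES:
                if tok.lower().startswith(prefix.lower()) and len(tok) > len(prefix):
                    tok = tok[len(prefix):]
                    changed = True
                    break
        out.append(tok)
    return " ".join(out)


DEFAULT_RULES: Dict[str, Callable[[str], str]] = {
    "strip_locants_joined": _rule_locants_joined,
    "strip_locants_spaced": _rule_locants_spaced,
    "hyphens_to_spaces": _rule_hyphens_to_spaces,
    "strip_cofactor": _rule_strip_cofactor,
    "strip_chirality": _rule_strip_chirality,
}


@dataclass(frozen=True)
class TermSet:
    """Ordered set of search terms derived from one origin name."""

    origin: str
    terms: Tuple[str, ...]
    rules_applied: Tuple[Tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.terms or self.terms[0] != self.origin:
            raise ValueError("terms[0] must be the origin name")
        norms = [normalize_name(t) for t in self.terms]
        if len(set(norms)) != len(norms):
            raise ValueError("duplicate terms after normalization")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


def permute_name(
    name: str,
    rules: Optional[Dict[str, Callable[[str], str]]] = None,
    max_terms: int = MAX_TERMS,
) -> TermSet:
    """Closure of the rewrite rules over ``name``, origin first.

    Breadth-first: rules are applied in a fixed order to every term already
    in the set until no rule produces a new (normalization-distinct) term.
    The closure is capped at ``max_terms`` terms; overflow is logged and
    further expansion stops.
    """
    if not name or not name.strip():
        raise ValueError("name is empty")
    if rules is None:
        rules = DEFAULT_RULES
    terms: List[str] = [name]
    paths: List[Tuple[str, ...]] = [()]
    seen: Set[str] = {normalize_name(name)}
    i = 0
    truncated = False
    while i < len(terms):
        base, path = terms[i], paths[i]
        for label, fn in rules.items():
            candidate = fn(base)
            norm = normalize_name(candidate)
            if not norm or norm in seen:
                continue
            if len(terms) >= max_terms:
                truncated = True
                break
            seen.add(norm)
            terms.append(candidate)
            paths.append(path + (label,))
        if truncated:
            break
        i += 1
    if truncated:
        logger.warning("permutation closure for %r capped at %d terms", name, max_terms)
    return TermSet(origin=name, terms=tuple(terms), rules_applied=tuple(paths))


@dataclass(frozen=True)
class DocumentRecord:
    """A title/abstract document addressable by a unique doc_id."""

    doc_id: str
    title: str
    abstract: Optional[str] = None
    matched_terms: frozenset = frozenset()

    @property
    def text(self) -> str:
        return self.title if not self.abstract else f"{self.title} {self.abstract}"


class SearchMode:
    EXACT = "exact"          # whole-word phrase match
    SUBSTRING = "substring"  # plain substring match


def search_corpus(
    terms: TermSet,
    corpus: Sequence[DocumentRecord],
    mode: str = SearchMode.EXACT,
) -> List[DocumentRecord]:
    """Rank corpus documents by how many distinct terms they contain.

    Matching is normalization-aware (both term and document text go through
    :func:`~orphan_enzymes.ec_catalog.normalize_name`).  Ranking key:
    number of distinct matched terms (desc), earliest match position (asc),
    doc_id (lexicographic).  Documents with no match are omitted.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if len(terms) == 0:
        raise ValueError("empty term set")
    if mode not in (SearchMode.EXACT, SearchMode.SUBSTRING):
        raise ValueError(f"unknown search mode {mode!r}")

    ids = [d.doc_id for d in corpus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate doc_id in corpus")

    scored = []
    for doc in corpus:
        text = normalize_name(doc.text)
        matched: Set[str] = set()
        first_pos = len(text) + 1
        for term in terms:
            tnorm = normalize_name(term)
            if mode == SearchMode.EXACT:
                m = re.search(rf"(?<!\w){re.escape(tnorm)}(?!\w)", text)
                pos = m.start() if m else -1
            else:
                pos = text.find(tnorm)
            if pos >= 0:
                matched.add(term)
                first_pos = min(first_pos, pos)
        if matched:
            scored.append((-len(matched), first_pos, doc.doc_id,
                           replace(doc, matched_terms=frozenset(matched))))
    scored.sort(key=lambda t: t[:3])
    return [t[3] for t in scored]
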