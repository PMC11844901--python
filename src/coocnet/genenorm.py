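"""Gene mention detection and normalization to reference symbols.

The normalizer is precision-oriented: exact alias matches of whitespace- or
punctuation-delimited tokens, with hyphen/slash handling that first tries the
whole token against the alias table and only splits when every part is itself
an alias. Two per-abstract blocking filters remove ambiguous matches:
abbreviations whose spelled-out definitions do not align to any alias of the
matched gene (Schwartz–Hearst detection + Needleman–Wunsch scoring), and
tokens inside recognized cell-line/cell-type entities. Multiple mentions of
one gene in an abstract count once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

from Bio import Align

from .corpus import DocumentRecord

logger = logging.getLogger(__name__)

GREEK_TRANSLITERATION = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
    "Α": "Alpha", "Β": "Beta", "Γ": "Gamma", "Δ": "Delta", "Ε": "Epsilon",
    "Ζ": "Zeta", "Η": "Eta", "Θ": "Theta", "Ι": "Iota", "Κ": "Kappa",
    "Λ": "Lambda", "Μ": "Mu", "Ν": "Nu", "Ξ": "Xi", "Ο": "Omicron",
    "Π": "Pi", "Ρ": "Rho", "Σ": "Sigma", "Τ": "Tau", "Υ": "Upsilon",
    "Φ": "Phi", "Χ": "Chi", "Ψ": "Psi", "Ω": "Omega",
}

_GREEK_RE = re.compile("|".join(GREEK_TRANSLITERATION))

#: Word tokens: alphanumeric runs optionally joined by hyphens or slashes.
_TOKEN_RE = re.compile(r"\w+(?:[-/]\w+)*")


def transliterate_greek(text: str) -> str:
    """Replace every Greek letter with its Latin-script name."""
    return _GREEK_RE.sub(lambda m: GREEK_TRANSLITERATION[m.group(0)], text)


# ---------------------------------------------------------------------------
# Alias lookup table
# ---------------------------------------------------------------------------

class AliasLookup:
    """Many-to-one alias -> reference-symbol table.

    Aliases are Greek-transliterated at load time. An alias recorded under two
    different reference symbols is an error, mirroring upstream manual
    disambiguation of the table.
    """

    def __init__(self, table: dict[str, Iterable[str]] | None = None) -> None:
        self._alias_to_ref: dict[str, str] = {}
        self._ref_to_aliases: dict[str, set[str]] = {}
        for ref, aliases in (table or {}).items():
            for alias in aliases:
                self.add(ref, alias)
            self.add(ref, ref)

    def add(self, reference: str, alias: str) -> None:
        alias = transliterate_greek(alias.strip())
        reference = reference.strip()
        if not alias or not reference:
            raise ValueError("empty alias or reference symbol")
        existing = self._alias_to_ref.get(alias)
        if existing is not None and existing != reference:
            raise ValueError(
                f"alias {alias!r} maps to both {existing!r} and {reference!r}"
            )
        self._alias_to_ref[alias] = reference
        self._ref_to_aliases.setdefault(reference, set()).add(alias)

    def __contains__(self, alias: str) -> bool:
        return alias in self._alias_to_ref

    def __len__(self) -> int:
        return len(self._alias_to_ref)

    def reference_of(self, alias: str) -> str:
        return self._alias_to_ref[alias]

    def aliases_of(self, reference: str) -> set[str]:
        return set(self._ref_to_aliases[reference])

    @property
    def references(self) -> list[str]:
        return sorted(self._ref_to_aliases)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasLookup":
        """Read ``reference_symbol<TAB>alias`` rows (one alias per row)."""
        lookup = cls()
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                reference, alias = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields") from exc
            lookup.add(reference, alias)
            lookup.add(reference, reference)
        return lookup


def load_word_list(path: str | Path) -> set[str]:
    """Plain-text word list (one word per line), lower-cased."""
    return {
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    }


def bundled_english_words() -> set[str]:
    return load_word_list(Path(__file__).parent / "data" / "english_words.txt")


def bundled_cell_names() -> list[str]:
    path = Path(__file__).parent / "data" / "cell_names.txt"
    return [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# Schwartz–Hearst abbreviation-definition detection (single-word short forms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbbreviationPair:
    short_form: str
    long_form: str
    offsets: tuple[int, int]  # (long-form start, short-form start) in the text


def _is_valid_short_form(sf: str) -> bool:
    if not 2 <= len(sf) <= 10:
        return False
    if " " in sf:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(short_form: str, candidate: str) -> int | None:
    """Right-to-left character matching; returns the long-form start index.

    Every character of the short form must appear in order in the candidate;
    the short form's first character must match at the start of a word.
    """
    s = len(short_form) - 1
    l = len(candidate) - 1
    sf = short_form.lower()
    cand = candidate.lower()
    while s >= 0:
        c = sf[s]
        if not c.isalnum():
            s -= 1
            continue
        while l >= 0 and (
            cand[l] != c or (s == 0 and l > 0 and cand[l - 1].isalnum())
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    return l + 1


def detect_abbreviations(text: str) -> list[AbbreviationPair]:
    """Find ``long form (SF)`` patterns with single-word short forms.

    The candidate long form is the window of min(|SF|+5, 2|SF|) words
    immediately preceding the parenthesis.
    """
    pairs: list[AbbreviationPair] = []
    for match in re.finditer(r"\(([^()]*)\)", text):
        sf = match.group(1).strip()
        if not _is_valid_short_form(sf):
            continue
        prefix = text[: match.start()]
        words = list(re.finditer(r"\S+", prefix))
        if not words:
            continue
        window = min(len(sf) + 5, 2 * len(sf))
        window_words = words[-window:]
        cand_start = window_words[0].start()
        candidate = prefix[cand_start:].rstrip()
        if not candidate:
            continue
        rel = _best_long_form(sf, candidate)
        if rel is None:
            continue
        long_form = candidate[rel:]
        if not long_form or long_form.lower() == sf.lower():
            continue
        sf_start = match.start() + match.group(0).index(sf)
        pairs.append(
            AbbreviationPair(
                short_form=sf,
                long_form=long_form,
                offsets=(cand_start + rel, sf_start),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Global alignment (Needleman–Wunsch, affine gaps)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner

_ALIGNER = _make_aligner()


def align_global(a: str, b: str, normalize: bool = True) -> float:
    """Optimal global affine-gap alignment score of two strings.

    Scoring: match +1, mismatch −1, gap open −1 (cost of a length-1 gap),
    gap extension −0.5 per additional gapped position. With ``normalize`` the
    raw score is divided by the length of the longer string and clamped to be
    non-negative, giving a value in [0, 1] comparable across string lengths.
    """
    if not a or not b:
        raise ValueError("align_global requires non-empty strings")
    raw = float(_ALIGNER.score(a, b))
    if not normalize:
        return raw
    return max(raw / max(len(a), len(b)), 0.0)


def validate_abbreviation(
    pair: AbbreviationPair,
    lookup: AliasLookup,
    threshold: float = 0.15,
) -> Literal["keep", "block"]:
    """Keep an alias-matching abbreviation iff its definition aligns to an
    alias of the matched gene with a normalized score >= threshold."""
    reference = lookup.reference_of(pair.short_form)
    long_form = pair.long_form.lower()
    best = max(
        align_global(long_form, alias.lower())
        for alias in sorted(lookup.aliases_of(reference))
    )
    return "keep" if best >= threshold else "block"


# ---------------------------------------------------------------------------
# Cell-entity blocking (pluggable recognizer)
# ---------------------------------------------------------------------------

class DictionaryCellRecognizer:
    """Regex/dictionary recognizer over a list of cell-line/cell-type names.

    A stand-in interface for model-based recognizers: any callable mapping
    text to a list of (start, end) character spans can be plugged in.
    """

    def __init__(self, names: Iterable[str]) -> None:
        names = sorted({n for n in names if n.strip()}, key=len, reverse=True)
        if names:
            self._pattern = re.compile(
                "|".join(re.escape(n) for n in names), re.IGNORECASE
            )
        else:
            self._pattern = None

    def __call__(self, text: str) -> list[tuple[int, int]]:
        if self._pattern is None:
            return []
        return [m.span() for m in self._pattern.finditer(text)]


def recognize_cell_entities(
    text: str,
    recognizer: Callable[[str], list[tuple[int, int]]] | None = None,
) -> list[tuple[int, int]]:
    if recognizer is None:
        logger.debug("no cell recognizer registered; skipping cell blocking")
        return []
    return list(recognizer(text))


# ---------------------------------------------------------------------------
# Tokenization and the full normalization pipeline
# ---------------------------------------------------------------------------

def tokenize_abstract(
    text: str,
    lookup: AliasLookup,
    english_words: set[str],
) -> list[tuple[str, int]]:
    """Candidate alias-matching tokens with character offsets.

    Splits on whitespace/punctuation except hyphen and slash. A hyphen- or
    slash-joined token is first tried whole against the lookup; if unmatched
    it is split into parts only when every part is itself an alias. Tokens in
    the English word list are discarded before lookup.
    """
    candidates: list[tuple[str, int]] = []
    for match in _TOKEN_RE.finditer(text):
        token = match.group(0)
        if token.lower() in english_words:
            continue
        if "-" in token or "/" in token:
            if token in lookup:
                candidates.append((token, match.start()))
                continue
            parts = re.split(r"[-/]", token)
            if all(p in lookup and p.lower() not in english_words for p in parts):
                offset = match.start()
                for p in parts:
                    candidates.append((p, offset))
                    offset += len(p) + 1
            continue
        if token in lookup:
            candidates.append((token, match.start()))
    return candidates


@dataclass
class GeneMentionSet:
    """Deduplicated reference symbols found in one document.

    ``mentions`` keeps traceability: each emitted symbol maps to the set of
    alias tokens that supported it.
    """

    pmid: str
    mentions: dict[str, set[str]] = field(default_factory=dict)

    @property
    def symbols(self) -> set[str]:
        return set(self.mentions)

    def add(self, symbol: str, token: str) -> None:
        self.mentions.setdefault(symbol, set()).add(token)


def build_blocklist(
    text: str,
    lookup: AliasLookup,
    threshold: float = 0.15,
    cell_recognizer: Callable[[str], list[tuple[int, int]]] | None = None,
    use_abbreviation_filter: bool = True,
) -> set[str]:
    """Per-document set of blocked token strings."""
    blocked: set[str] = set()
    if use_abbreviation_filter:
        for pair in detect_abbreviations(text):
            if pair.short_form in lookup:
                if validate_abbreviation(pair, lookup, threshold) == "block":
                    blocked.add(pair.short_form)
    spans = recognize_cell_entities(text, cell_recognizer)
    if spans:
        for match in _TOKEN_RE.finditer(text):
            for start, end in spans:
                if match.start() < end and match.end() > start:
                    blocked.add(match.group(0))
                    # hyphen/slash parts inside a span are blocked too
                    blocked.update(re.split(r"[-/]", match.group(0)))
                    break
    return blocked


def normalize_genes(
    record: DocumentRecord,
    lookup: AliasLookup,
    english_words: set[str],
    threshold: float = 0.15,
    cell_recognizer: Callable[[str], list[tuple[int, int]]] | None = None,
    use_abbreviation_filter: bool = True,
) -> GeneMentionSet:
    """Full pipeline: transliterate, block, tokenize, map, deduplicate."""
    text = transliterate_greek(record.mining_text)
    blocked = build_blocklist(
        text,
        lookup,
        threshold=threshold,
        cell_recognizer=cell_recognizer,
        use_abbreviation_filter=use_abbreviation_filter,
    )
    result = GeneMentionSet(pmid=record.pmid)
    for token, _offset in tokenize_abstract(text, lookup, english_words):
        if token in blocked:
            continue
        result.add(lookup.reference_of(token), token)
    return result
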