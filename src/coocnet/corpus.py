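"""Literature corpus data model: parsing, filtering, serialization.

A corpus is an ordered collection of article records keyed by PMID. Records
carry the title, abstract, author keywords ("Other Term" fields), and the
MEDLINE MeSH annotations (descriptor/qualifier pairs). The text that is mined
for gene mentions is the concatenation of title, abstract, and keywords.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: MeSH top-level categories retained by default: Anatomy, Diseases,
#: Chemicals and Drugs, Phenomena and Processes.
DEFAULT_MESH_CATEGORIES = ("A", "C", "D", "G")
#: G sub-trees excluded by default (physical/chemical phenomena, mathematics).
DEFAULT_MESH_EXCLUDED_SUBTREES = ("G01", "G02", "G17")


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text or "")


@dataclass
class DocumentRecord:
    """One article: identifiers, text fields, and MeSH annotations."""

    pmid: str
    title: str = ""
    abstract: str = ""
    other_terms: list[str] = field(default_factory=list)
    mesh_annotations: list[tuple[str, str]] = field(default_factory=list)
    is_review: bool = False

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("DocumentRecord requires a non-empty pmid")
        self.title = _nfc(self.title)
        self.abstract = _nfc(self.abstract)
        self.other_terms = [_nfc(t) for t in self.other_terms]
        self.mesh_annotations = [
            (_nfc(d), _nfc(q)) for d, q in self.mesh_annotations
        ]

    @property
    def mining_text(self) -> str:
        """Title, abstract, and keywords joined with single spaces."""
        parts = [self.title, self.abstract, *self.other_terms]
        return " ".join(p for p in parts if p)

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "other_terms": list(self.other_terms),
            "mesh_annotations": [list(p) for p in self.mesh_annotations],
            "is_review": self.is_review,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DocumentRecord":
        return cls(
            pmid=str(payload["pmid"]),
            title=payload.get("title", ""),
            abstract=payload.get("abstract", ""),
            other_terms=list(payload.get("other_terms", [])),
            mesh_annotations=[
                (str(d), str(q)) for d, q in payload.get("mesh_annotations", [])
            ],
            is_review=bool(payload.get("is_review", False)),
        )


class Corpus:
    """Ordered, PMID-unique collection of :class:`DocumentRecord`."""

    def __init__(
        self,
        records: Iterable[DocumentRecord] = (),
        iteration_index: int = 0,
        provenance: Sequence[str] = (),
    ) -> None:
        self._records: dict[str, DocumentRecord] = {}
        self.iteration_index = int(iteration_index)
        if self.iteration_index < 0:
            raise ValueError("iteration_index must be non-negative")
        self.provenance: list[str] = list(provenance)
        for rec in records:
            self.add(rec)

    def add(self, record: DocumentRecord) -> None:
        if record.pmid in self._records:
            raise ValueError(f"duplicate pmid {record.pmid!r} in corpus")
        self._records[record.pmid] = record

    @property
    def pmids(self) -> list[str]:
        return list(self._records)

    @property
    def records(self) -> list[DocumentRecord]:
        return list(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self._records.values())

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._records

    def __getitem__(self, pmid: str) -> DocumentRecord:
        return self._records[pmid]

    def merged_with(
        self, other: "Corpus", iteration_index: int | None = None
    ) -> "Corpus":
        """Union of the two corpora; existing records win on pmid clash."""
        out = Corpus(
            iteration_index=(
                self.iteration_index + 1 if iteration_index is None else iteration_index
            ),
            provenance=self.provenance + other.provenance,
        )
        for rec in self:
            out.add(rec)
        for rec in other:
            if rec.pmid not in out:
                out.add(rec)
        return out

    # -- serialization -----------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        with tmp.open("w", encoding="utf-8") as fh:
            for rec in self:
                fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
        tmp.replace(path)


class MeshVocabulary:
    """Mapping from MeSH descriptor to its set of tree numbers."""

    def __init__(self, trees: dict[str, set[str]] | None = None) -> None:
        self._trees: dict[str, set[str]] = {}
        for descriptor, numbers in (trees or {}).items():
            self.add(descriptor, numbers)

    def add(self, descriptor: str, tree_numbers: Iterable[str]) -> None:
        numbers = {str(t) for t in tree_numbers}
        for t in numbers:
            if not t or not ("A" <= t[0] <= "Z"):
                raise ValueError(f"malformed tree number {t!r} for {descriptor!r}")
        self._trees.setdefault(_nfc(descriptor), set()).update(numbers)

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self._trees

    def trees(self, descriptor: str) -> set[str]:
        return set(self._trees[descriptor])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeshVocabulary":
        """Read ``descriptor<TAB>tree1;tree2`` rows."""
        vocab = cls()
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                descriptor, numbers = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields") from exc
            vocab.add(descriptor, [t for t in numbers.split(";") if t])
        return vocab


def read_pmid_list(path: str | Path) -> list[str]:
    """PMIDs one per line; blank lines and ``#`` comments allowed."""
    pmids: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            pmids.append(line)
    return pmids


# ---------------------------------------------------------------------------
# MEDLINE citation XML
# ---------------------------------------------------------------------------

def parse_medline_xml(xml_payload: str | bytes) -> Corpus:
    """Parse a PubMed efetch MEDLINE citation XML payload into a corpus.

    Citations without a PMID are skipped with a warning. MeSH headings are
    captured as (descriptor, qualifier) pairs, one pair per qualifier and a
    single pair with an empty qualifier for unqualified descriptors. A
    ``Review`` publication type sets ``is_review``.
    """
    if isinstance(xml_payload, str):
        xml_payload = xml_payload.encode("utf-8")
    try:
        root = etree.fromstring(xml_payload)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed MEDLINE XML: {exc}") from exc

    corpus = Corpus()
    for article in root.iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            citation = article
        pmid_el = citation.find("PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            logger.warning("citation without PMID skipped")
            continue
        pmid = pmid_el.text.strip()

        title = "".join(citation.find("Article/ArticleTitle").itertext()) \
            if citation.find("Article/ArticleTitle") is not None else ""
        abstract_parts = [
            "".join(el.itertext())
            for el in citation.findall("Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p)

        other_terms = [
            "".join(el.itertext())
            for el in citation.findall("KeywordList/Keyword")
            if "".join(el.itertext()).strip()
        ]

        mesh: list[tuple[str, str]] = []
        for heading in citation.findall("MeshHeadingList/MeshHeading"):
            desc_el = heading.find("DescriptorName")
            if desc_el is None or not (desc_el.text or "").strip():
                continue
            descriptor = desc_el.text.strip()
            qualifiers = [
                (q.text or "").strip()
                for q in heading.findall("QualifierName")
                if (q.text or "").strip()
            ]
            if qualifiers:
                mesh.extend((descriptor, q) for q in qualifiers)
            else:
                mesh.append((descriptor, ""))

        is_review = any(
            (pt.text or "").strip().lower() == "review"
            for pt in citation.findall("Article/PublicationTypeList/PublicationType")
        )

        corpus.add(
            DocumentRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                other_terms=other_terms,
                mesh_annotations=mesh,
                is_review=is_review,
            )
        )
    return corpus


def load_offline_corpus(path: str | Path) -> Corpus:
    """Load a JSONL corpus (one record per line); duplicates are rejected."""
    corpus = Corpus()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                payload = json.loads(line)
                record = DocumentRecord.from_dict(payload)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid record: {exc}") from exc
            if record.pmid in corpus:
                raise ValueError(f"{path}:{lineno}: duplicate pmid {record.pmid!r}")
            corpus.add(record)
    return corpus


# ---------------------------------------------------------------------------
# MeSH category filtering
# ---------------------------------------------------------------------------

def mesh_entity_name(descriptor: str, qualifier: str = "") -> str:
    """Render a MeSH annotation as an entity name, e.g. ``melanoma/immunology``."""
    return f"{descriptor}/{qualifier}" if qualifier else descriptor


def filter_mesh_terms(
    record: DocumentRecord,
    vocab: MeshVocabulary,
    categories: Sequence[str] = DEFAULT_MESH_CATEGORIES,
    excluded_subtrees: Sequence[str] = DEFAULT_MESH_EXCLUDED_SUBTREES,
) -> set[str]:
    """Keep biomedically relevant MeSH annotations of one record.

    A descriptor is retained if any of its tree numbers falls under a retained
    category, except that a descriptor whose only qualifying trees are G trees
    under the excluded sub-trees is dropped. Retained annotations are rendered
    as ``descriptor`` or ``descriptor/qualifier``.
    """
    retained: set[str] = set()
    for descriptor, qualifier in record.mesh_annotations:
        if descriptor not in vocab:
            logger.warning("descriptor %r absent from MeSH vocabulary; dropped", descriptor)
            continue
        keep = False
        for tree in vocab.trees(descriptor):
            letter = tree[0]
            if letter not in categories:
                continue
            if any(tree.startswith(sub) for sub in excluded_subtrees):
                continue
            keep = True
            break
        if keep:
            retained.add(mesh_entity_name(descriptor, qualifier))
    return retained
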