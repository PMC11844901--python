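"""Synthetic literature corpora with planted co-mention structure.

The generator emulates the study conditions every stage of the pipeline is
exercised under: a corpus of short abstracts in which blocks of entities
(genes and MeSH terms) are co-mentioned at a high within-block rate against a
low background rate. Gene entities are embedded as alias tokens inside
generated abstract text; MeSH entities are attached as MEDLINE-style
annotations. Identical seeds yield byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, DocumentRecord, MeshVocabulary

#: Filler vocabulary for generated abstracts; all words are common English
#: words so the tokenizer discards them before alias lookup.
_FILLER_WORDS = (
    "the study of cells and tissue shows that expression levels were "
    "measured in patients with disease and the results indicate a role "
    "for signaling during treatment response while control samples show "
    "reduced activity across groups over time"
).split()


@dataclass(frozen=True)
class Entity:
    name: str
    kind: str  # "gene" | "mesh"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "mesh"):
            raise ValueError(f"unknown entity kind {self.kind!r}")


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic corpus."""

    n_docs: int
    blocks: list[list[Entity]]
    within_block_rate: float = 0.6
    background_rate: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        for rate in (self.within_block_rate, self.background_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        seen: set[str] = set()
        for block in self.blocks:
            for entity in block:
                if entity.name in seen:
                    raise ValueError(f"blocks are not disjoint: {entity.name!r}")
                seen.add(entity.name)

    @property
    def entities(self) -> list[Entity]:
        return [e for block in self.blocks for e in block]

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """All unordered within-block entity-name pairs."""
        pairs: set[tuple[str, str]] = set()
        for block in self.blocks:
            names = sorted(e.name for e in block)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    pairs.add((names[i], names[j]))
        return pairs


def default_planted_spec(
    n_docs: int = 200,
    n_blocks: int = 3,
    genes_per_block: int = 4,
    mesh_per_block: int = 2,
    within_block_rate: float = 0.6,
    background_rate: float = 0.06,
    seed: int = 0,
) -> SyntheticSpec:
    """Three blocks of co-studied entities, within-rate 10x the background."""
    blocks: list[list[Entity]] = []
    for b in range(1, n_blocks + 1):
        block = [Entity(f"GB{b}X{i}", "gene") for i in range(1, genes_per_block + 1)]
        block += [Entity(f"Topic B{b} M{i}", "mesh") for i in range(1, mesh_per_block + 1)]
        blocks.append(block)
    return SyntheticSpec(
        n_docs=n_docs,
        blocks=blocks,
        within_block_rate=within_block_rate,
        background_rate=background_rate,
        seed=seed,
    )


def unstructured_spec(
    n_entities: int = 12,
    rate: float = 0.25,
    n_docs: int = 40,
    seed: int = 0,
    kind: str = "gene",
) -> SyntheticSpec:
    """No planted structure: singleton blocks, within rate equal to background."""
    blocks = [[Entity(f"NE{i}", kind)] for i in range(1, n_entities + 1)]
    return SyntheticSpec(
        n_docs=n_docs,
        blocks=blocks,
        within_block_rate=rate,
        background_rate=rate,
        seed=seed,
    )


def generate_synthetic_corpus(spec: SyntheticSpec) -> tuple[Corpus, set[tuple[str, str]]]:
    """Sample a corpus under ``spec``; returns (corpus, planted pairs)."""
    rng = np.random.default_rng(spec.seed)
    corpus = Corpus(iteration_index=0, provenance=["synthetic"])
    entities = spec.entities
    block_of = {
        e.name: b for b, block in enumerate(spec.blocks) for e in block
    }
    n_blocks = max(len(spec.blocks), 1)

    for d in range(spec.n_docs):
        pmid = f"{9_000_000 + d}"
        doc_block = int(rng.integers(0, n_blocks)) if spec.blocks else 0
        present: list[Entity] = []
        for entity in entities:
            rate = (
                spec.within_block_rate
                if block_of[entity.name] == doc_block
                else spec.background_rate
            )
            if rng.random() < rate:
                present.append(entity)

        gene_tokens = [e.name for e in present if e.kind == "gene"]
        mesh_terms = [e.name for e in present if e.kind == "mesh"]

        n_filler = 20
        filler = [
            _FILLER_WORDS[int(i)]
            for i in rng.integers(0, len(_FILLER_WORDS), size=n_filler)
        ]
        words = list(filler)
        for token in gene_tokens:
            pos = int(rng.integers(0, len(words) + 1))
            words.insert(pos, token)
        abstract = " ".join(words)

        corpus.add(
            DocumentRecord(
                pmid=pmid,
                title=f"Synthetic report {pmid}",
                abstract=abstract,
                other_terms=[],
                mesh_annotations=[(m, "") for m in mesh_terms],
                is_review=False,
            )
        )
    return corpus, spec.planted_pairs


def synthetic_alias_table(spec: SyntheticSpec) -> dict[str, set[str]]:
    """Reference symbol -> aliases for the generator's gene entities.

    Each gene gets its own symbol as an alias plus a spelled-out long form so
    abbreviation validation has something to align against.
    """
    table: dict[str, set[str]] = {}
    for entity in spec.entities:
        if entity.kind == "gene":
            table[entity.name] = {entity.name, f"{entity.name.lower()} factor"}
    return table


def synthetic_mesh_vocabulary(spec: SyntheticSpec) -> MeshVocabulary:
    """Tree numbers under C (Diseases) for every generated MeSH descriptor."""
    vocab = MeshVocabulary()
    for i, entity in enumerate(e for e in spec.entities if e.kind == "mesh"):
        vocab.add(entity.name, {f"C{i + 1:02d}.{100 + i}"})
    return vocab
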