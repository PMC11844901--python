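"""Shared fixtures: crafted corpora exercising every pipeline stage."""

from __future__ import annotations

import pytest

from coocnet.corpus import Corpus, DocumentRecord, MeshVocabulary
from coocnet.genenorm import AliasLookup, bundled_english_words
from coocnet.synthetic import (
    default_planted_spec,
    generate_synthetic_corpus,
    synthetic_alias_table,
    synthetic_mesh_vocabulary,
)


def make_doc(pmid, genes=(), mesh=(), review=False, title=None):
    """Minimal article embedding gene tokens in the abstract text."""
    return DocumentRecord(
        pmid=str(pmid),
        title=title or f"Report {pmid}",
        abstract="we studied " + " and ".join(genes) if genes else "we studied cells",
        mesh_annotations=[(m, "") for m in mesh],
        is_review=review,
    )


@pytest.fixture(scope="session")
def english_words():
    return bundled_english_words()


@pytest.fixture(scope="session")
def planted():
    """Default planted-block corpus plus its lookup tables (study conditions)."""
    spec = default_planted_spec(seed=11)
    corpus, truth = generate_synthetic_corpus(spec)
    return {
        "spec": spec,
        "corpus": corpus,
        "truth": truth,
        "lookup": AliasLookup(synthetic_alias_table(spec)),
        "vocab": synthetic_mesh_vocabulary(spec),
    }


def bridged_inputs(seed=3, n_docs=400, n_gene_bridge=40, n_mesh_bridge=0):
    """Planted blocks plus bridge documents wiring the blocks together.

    Bridge documents co-mention one entity from each of two blocks far above
    the background, so the crossing edges survive the configuration-model
    test and the three blocks form one connected component with three
    communities.
    """
    spec = default_planted_spec(n_docs=n_docs, seed=seed)
    corpus, truth = generate_synthetic_corpus(spec)
    records = list(corpus)
    pid = 7000
    gene_bridges = [("GB1X1", "GB2X1"), ("GB2X2", "GB3X1"), ("GB1X2", "GB3X2")]
    mesh_bridges = [
        ("Topic B1 M1", "Topic B2 M1"),
        ("Topic B2 M2", "Topic B3 M1"),
        ("Topic B1 M2", "Topic B3 M2"),
    ]
    for pair in gene_bridges:
        for _ in range(n_gene_bridge):
            records.append(make_doc(pid, genes=list(pair))); pid += 1
    for pair in mesh_bridges:
        for _ in range(n_mesh_bridge):
            records.append(make_doc(pid, mesh=list(pair))); pid += 1
    return {
        "spec": spec,
        "corpus": Corpus(records),
        "truth": truth,
        "lookup": AliasLookup(synthetic_alias_table(spec)),
        "vocab": synthetic_mesh_vocabulary(spec),
    }


@pytest.fixture(scope="session")
def bridged():
    return bridged_inputs()


@pytest.fixture(scope="session")
def expansion_pool(bridged):
    """Bridged corpus plus extra findable documents for the offline source."""
    extra = [
        make_doc(
            8000 + i,
            genes=["GB1X1", "GB1X2", "GB2X1", "GB2X2", "GB3X1", "GB3X2"],
            mesh=["Topic B1 M1", "Topic B2 M1", "Topic B3 M1"],
        )
        for i in range(5)
    ]
    return Corpus(list(bridged["corpus"]) + extra)


@pytest.fixture()
def tiny_lookup():
    return AliasLookup(
        {
            "TNF": {"TNF", "TNF-alpha", "tumor necrosis factor", "TNFA"},
            "IL1B": {"IL1B", "interleukin 1-beta", "IL-1beta"},
            "ESR1": {"ER", "estrogen receptor 1", "estrogen receptor alpha"},
            "AKT1": {"Akt"},
            "PIK3CA": {"PI3K"},
            "MTOR": {"mTOR"},
        }
    )


@pytest.fixture()
def tiny_vocab():
    return MeshVocabulary(
        {
            "Melanoma": {"C04.557.465"},
            "Physical Phenomena": {"G01.249"},
            "Geographic Locations": {"Z01.433"},
            "Immune System": {"A15.382"},
            "Glutathione": {"D12.125.068"},
            "Mathematical Concepts": {"G17.035"},
            "Signal Transduction": {"G04.835", "G02.111"},
        }
    )
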