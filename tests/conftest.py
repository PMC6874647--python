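"""Shared fixtures: one full synthetic run at the default study
conditions (500 genes, 20 classes per ontology, seed 7), reused across
embedding, classifier and acceptance tests to keep the suite fast."""

from __future__ import annotations

import pytest

from ontodriver.classifier import DriverGeneClassifier
from ontodriver.embedding import EmbeddingParams
from ontodriver.pipeline import build_features, train_all_tables
from ontodriver.simulate import (
    SOURCE_TAGS,
    SyntheticConfig,
    generate_gene_data,
    generate_network,
    generate_ontology,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    ontologies = {
        tag: generate_ontology(default_config, tag, stream=i)
        for i, tag in enumerate(SOURCE_TAGS)
    }
    annotations, labels = generate_gene_data(ontologies, default_config)
    return ontologies, annotations, labels


@pytest.fixture(scope="session")
def default_network(default_config, default_dataset):
    _, _, labels = default_dataset
    return generate_network(labels, default_config)


@pytest.fixture(scope="session")
def default_tables(default_config, default_dataset):
    ontologies, annotations, _ = default_dataset
    return train_all_tables(
        ontologies, annotations, EmbeddingParams(seed=default_config.seed)
    )


@pytest.fixture(scope="session")
def union_features(default_tables, default_dataset):
    _, annotations, _ = default_dataset
    return build_features("union", default_tables, annotations)


@pytest.fixture(scope="session")
def union_report(union_features, default_dataset):
    _, _, labels = default_dataset
    return DriverGeneClassifier(union_features, labels).cross_validate(k=10, seed=7)
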