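import pathlib

import pytest

import pepclip as pc
from pepclip.model import ModelConfig, PepClipModel
from pepclip.pipeline import load_graphs
from pepclip.prep import read_labels_csv


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory) -> pathlib.Path:
    """A small deterministic corpus shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("corpus")
    spec = pc.FixtureSpec(
        n_peptides=40, length_range=(5, 15), positive_fraction=0.4, seed=13
    )
    pc.generate_corpus(spec, out)
    return out


@pytest.fixture(scope="session")
def corpus_records(corpus_dir):
    return read_labels_csv(corpus_dir / "labels.csv")


@pytest.fixture(scope="session")
def corpus_graphs(corpus_dir, corpus_records):
    return load_graphs(corpus_records, corpus_dir)


@pytest.fixture()
def tiny_config() -> ModelConfig:
    return ModelConfig(
        max_length=20,
        text_width=32,
        text_layers=1,
        text_heads=2,
        graph_hidden_width=16,
        graph_mlp_widths=(16,),
        graph_out_width=16,
        latent_width=16,
        seed=0,
    )


@pytest.fixture()
def tiny_model(tiny_config) -> PepClipModel:
    return PepClipModel(tiny_config)
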