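import numpy as np
import pytest

from dynetm import (
    RawDocument,
    TrainConfig,
    preprocess_corpus,
    random_parameters,
    sample_corpus,
    train,
)


@pytest.fixture(scope="session")
def toy_raw_docs():
    """12 hand-written documents over 3 years and 2 labels."""
    texts = [
        "gene expression tumor cell growth pathway signal tumor gene cell",
        "neuron brain synapse signal circuit memory neuron brain cell gene",
        "tumor cancer therapy drug target gene expression cell tumor drug",
        "brain imaging neuron memory cognition circuit signal brain gene cell",
        "virus immune vaccine antibody response cell infection virus immune gene",
        "immune cell antibody virus infection response vaccine therapy drug gene",
        "gene pathway expression protein cell signal tumor growth cancer drug",
        "memory cognition brain neuron imaging circuit synapse signal cell gene",
        "vaccine trial immune response antibody virus infection cell drug gene",
        "cancer tumor drug therapy target growth pathway cell gene expression",
        "synapse circuit neuron brain signal memory imaging cognition cell gene",
        "infection virus immune antibody vaccine response trial cell drug gene",
    ]
    years = [2000, 2000, 2000, 2000, 2001, 2001, 2001, 2001, 2002, 2002, 2002, 2002]
    labels = ["NCI", "NIMH", "NCI", "NIMH", "NIAID", "NIAID",
              "NCI", "NIMH", "NIAID", "NCI", "NIMH", "NIAID"]
    return [RawDocument(t, y, lab) for t, y, lab in zip(texts, years, labels)]


@pytest.fixture(scope="session")
def tiny_corpus(toy_raw_docs):
    return preprocess_corpus(toy_raw_docs, stopwords=(), max_df=1.0,
                             min_count=0, min_doc_len=1)


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained small model with heterogeneous topic proportions."""
    params = random_parameters(K=3, V=60, L=8, T=3, eps=1.0, delta=0.05,
                               gamma=0.05, seed=7)
    corpus, truth = sample_corpus(params, [80, 80, 80], tokens_per_doc=40, seed=7)
    cfg = TrainConfig(K=3, L=8, epochs=120, learning_rate=3e-3, batch_size=256,
                      seed=7, eps=1.0, delta=0.05, gamma=0.05, hidden=64)
    mp, vs, log = train(corpus, cfg, init_rho=params.rho)
    return {"true_params": params, "corpus": corpus, "truth": truth,
            "params": mp, "state": vs, "log": log}
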