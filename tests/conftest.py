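import numpy as np
import pytest

from motionseg.classifier import (ClassifierConfig, SequenceClassifier,
                                  TrainingWindowSet, class_weights, make_windows)
from motionseg.features import Standardizer, extract_features
from motionseg.model import build_model, bundled_config_path, load_model
from motionseg.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def kick_model():
    return load_model(bundled_config_path("soccer_kick"))


@pytest.fixture(scope="session")
def throw_model():
    return load_model(bundled_config_path("two_hand_throw"))


@pytest.fixture
def single_phase_model():
    return build_model({
        "name": "mono",
        "phases": [{"name": "only", "start": "s", "performing": "p", "end": "e"}],
    })


def chain_model(n_phases: int):
    """A generic strictly-linear model with n phases, labels B0,P1,B1,..."""
    return build_model({
        "name": f"chain{n_phases}",
        "phases": [
            {"name": f"ph{i}", "start": f"B{i}", "performing": f"P{i}", "end": f"B{i + 1}"}
            for i in range(n_phases)
        ],
    })


@pytest.fixture(scope="session")
def trained_setup(kick_model):
    """A small but converged classifier plus its corpus, shared by tests.

    10 recordings (8 train / 2 test), thinned windows, few epochs: the
    synthetic task is easy enough that this reaches high per-frame
    accuracy while keeping the suite fast.
    """
    model = kick_model
    spec = SyntheticSpec(model=model, seed=11)
    corpus = generate_corpus(spec, 10, 0.8, seed=11)
    feats = [extract_features(s) for _, s, _ in corpus["train"]]
    std = Standardizer.fit(np.concatenate([f.values for f in feats]))
    parts = [
        make_windows(std.transform(f), lab, 100, 10, model.n_classes)
        for f, (_, _, lab) in zip(feats, corpus["train"])
    ]
    windows = TrainingWindowSet.concatenate(parts)
    cfg = ClassifierConfig(num_classes=model.n_classes, epochs=10, seed=11)
    clf = SequenceClassifier(cfg, std)
    history = clf.train(windows, class_weights(windows.class_counts))
    return {"model": model, "classifier": clf, "corpus": corpus,
            "windows": windows, "history": history, "standardizer": std}
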