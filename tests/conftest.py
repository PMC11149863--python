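import warnings

import numpy as np
import pytest

from ziphid.network import TrainConfig, balance_classes, build_and_train, feature_vector
from ziphid.simulate import sample_cluster_summaries
from ziphid.templates import builtin_templates, template_by_name

warnings.filterwarnings("ignore", message="band_high.*Nyquist")

#: classes used for the small session classifier (all six beaked whale types
#: plus the two distractors that matter for delimitation tests)
MODEL_CLASSES = ["Zc", "Me", "Mm", "Mb", "Md", "BWG", "De spp", "Gg"]


@pytest.fixture(scope="session")
def templates():
    return {t.name: t for t in builtin_templates()}


@pytest.fixture(scope="session")
def trained_model():
    """Small dense classifier over the eight session classes (60 summaries of
    20 clicks per class), shared by delimitation/pipeline tests."""
    X, y = [], []
    for i, name in enumerate(MODEL_CLASSES):
        summ = sample_cluster_summaries(template_by_name(name), 60, seed=100 + i, n_clicks=20)
        X.extend(feature_vector(s) for s in summ)
        y.extend([name] * len(summ))
    X = np.stack(X)
    y = np.array(y)
    cfg = TrainConfig(examples_per_class=60, train_count=45)
    model = build_and_train(balance_classes(X, y, cfg, seed=0), cfg, seed=0)
    return model
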