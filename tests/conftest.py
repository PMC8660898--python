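import numpy as np
import pytest

from snmtfvar import HyperParams, SyntheticConfig, generate, to_bundle


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted dataset shared by read-only tests."""
    cfg = SyntheticConfig(n_genes=12, variants_per_gene=(3, 6), n_diseases=8,
                          seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    return to_bundle(small_dataset, "two_source")


@pytest.fixture(scope="session")
def small_bundle3(small_dataset):
    return to_bundle(small_dataset, "three_source")


@pytest.fixture()
def fast_hp():
    """Hyper-parameters dialed down for quick unit tests."""
    return HyperParams(k_V=4, k_S=3, k_D=3, max_iter=40, n_restarts=1, seed=0)


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture()
def tsv_writer():
    return write_tsv


def brute_force_auc(labels, scores):
    """O(n^2) pair-counting Mann-Whitney AUC with half-credit ties."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
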