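import numpy as np
import pytest

import methylsite as ms


@pytest.fixture(scope="session")
def vocab3():
    return ms.canonical_vocabulary(3)


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">s1\nACGTACGTAA\n>s2\nTTTTACGT\n")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """120 labeled 21-nt windows with a fully planted motif."""
    spec = ms.SyntheticSpec(
        n_pos=60, neg_per_pos=1, window_length=21,
        motif_insert_prob=1.0, short_seq_frac=0.2, seed=7,
    )
    windows, log = ms.generate_dataset(spec)
    return windows, log


def random_confusion(rng):
    tp, tn, fp, fn = (int(x) for x in rng.integers(0, 40, size=4))
    if tp + tn + fp + fn == 0:
        tp = 1
    return ms.ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
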