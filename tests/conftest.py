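import dataclasses

import numpy as np
import pytest

from glycorbf import sequence_io, synthetic


@pytest.fixture(scope="session")
def implanted_dataset():
    """A motif-bearing dataset: pair (+3 T, +9 E) implanted at penetrance 0.9."""
    cfg = synthetic.SimConfig(
        n_proteins=50,
        length_range=(80, 200),
        fraction_tm=0.0,
        implanted_saaps=(synthetic.ImplantSpec(3, "T", 9, ("E",), 0.9),),
        n_positive_sites=50,
        n_negative_sites=500,
        seed=7,
    )
    records, sites, topology = synthetic.generate(cfg)
    fragments = sequence_io.build_fragments(records, sites, 14)
    sequences = {r.id: r.sequence for r in records}
    return records, sites, fragments, sequences


@pytest.fixture(scope="session")
def separable_dataset():
    """Two high-penetrance implanted pairs: near-separable classes."""
    cfg = synthetic.SimConfig(
        n_proteins=50,
        length_range=(80, 200),
        fraction_tm=0.0,
        implanted_saaps=(
            synthetic.ImplantSpec(3, "T", 9, ("E",), 0.95),
            synthetic.ImplantSpec(-2, "P", 5, ("G",), 0.95),
        ),
        n_positive_sites=50,
        n_negative_sites=500,
        seed=11,
    )
    records, sites, topology = synthetic.generate(cfg)
    fragments = sequence_io.build_fragments(records, sites, 14)
    sequences = {r.id: r.sequence for r in records}
    return records, sites, fragments, sequences


def permute_labels(fragments, seed):
    rng = np.random.default_rng(seed)
    labels = np.array([f.label for f in fragments])
    rng.shuffle(labels)
    return [dataclasses.replace(f, label=l) for f, l in zip(fragments, labels)]
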