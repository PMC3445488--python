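import numpy as np
import pytest

from cleavesite.dataset import ProteinRecord, positive_windows, sample_negatives
from cleavesite.features import build_frequency_table, synthetic_providers
from cleavesite.synthesize import MotifSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_record():
    return ProteinRecord("TOY1", "ACDEFGHIKLMNPQRSTVWY", (10,))


@pytest.fixture(scope="session")
def small_bundle():
    """A small generated protein set with providers and labelled windows."""
    rng = np.random.default_rng(7)
    records, table, providers = generate_dataset(
        12, (40, 120), 3, motif=MotifSpec(), rng=rng
    )
    pos = positive_windows(records, 22)
    neg = sample_negatives(records, 22, 3, rng)
    freq = build_frequency_table(pos)
    return {
        "records": records,
        "table": table,
        "providers": providers,
        "positives": pos,
        "negatives": neg,
        "freq": freq,
    }


@pytest.fixture(scope="session")
def small_matrix(small_bundle):
    from cleavesite.features import encode_windows

    b = small_bundle
    return encode_windows(b["positives"] + b["negatives"], b["providers"],
                          b["freq"])
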