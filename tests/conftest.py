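import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodeid.barcode_io import BarcodeRecord
from barcodeid.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def records_from_counts(counts, seq_len=40, seed=0):
    """One placeholder record per (species, index) pair for count arithmetic."""
    rng = np.random.default_rng(seed)
    records = []
    for s, n in enumerate(counts):
        for j in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=seq_len))
            records.append(BarcodeRecord(f"R{s:02d}_{j:04d}", f"Species_{s:03d}", seq))
    return records


@pytest.fixture(scope="session")
def separable_dataset():
    """Small, cleanly separable corpus: 4 species x 10 records."""
    config = SyntheticConfig(
        n_species=4,
        counts=[10] * 4,
        length_range=(80, 160),
        divergence=0.15,
        noise=0.005,
        seed=7,
    )
    dataset, _ = generate_dataset(config)
    return dataset
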