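import pandas as pd
import pytest

from ppsdt import dataset as ds, envelope, paillier


@pytest.fixture(scope="session")
def tiny_key():
    """Hand-checkable key: p=11, q=13 → n=143, λ=60, g=144."""
    return paillier.keypair_from_primes(11, 13)


@pytest.fixture(scope="session")
def test_key():
    """512-bit Paillier pair — large enough for blinded counts, fast enough for CI."""
    return paillier.generate_keypair(512, seed=2024)


@pytest.fixture(scope="session")
def rsa_key():
    return envelope.rsa_generate(512, seed=2024)


@pytest.fixture
def toy_dataset():
    """Six records over two binary attributes and two classes."""
    schema = ds.AttributeSchema(
        attribute_names=("A", "B"),
        value_domains={"A": ("0", "1"), "B": ("0", "1")},
        class_labels=("x", "y"),
    )
    frame = pd.DataFrame(
        {
            "A": ["0", "0", "0", "1", "1", "1"],
            "B": ["0", "1", "1", "0", "0", "1"],
            "class": ["x", "x", "y", "y", "y", "x"],
        }
    )
    return ds.ClinicalDataset(schema=schema, frame=frame)


def pooled(datasets):
    """Union of horizontally partitioned datasets (order: hospital blocks)."""
    return ds.ClinicalDataset(
        schema=datasets[0].schema,
        frame=pd.concat([d.frame for d in datasets], ignore_index=True),
    )
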