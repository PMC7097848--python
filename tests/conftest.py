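import numpy as np
import pytest

from ifnsig import ExpressionMatrix, GeneSignature, SampleTable


def make_matrix(data: dict[str, list[float]], sample_ids: list[str], value_kind="rpkm",
                gene_lengths=None) -> ExpressionMatrix:
    """Build a small matrix from {gene: row-of-values}."""
    return ExpressionMatrix(
        gene_ids=list(data),
        sample_ids=sample_ids,
        values=np.array(list(data.values()), dtype=float),
        value_kind=value_kind,
        gene_lengths=gene_lengths,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_gene_signature():
    return GeneSignature(name="sig", genes=("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def gpp_sample_table():
    """17 GPP patients (8 destined high / 9 low) with a flares flag matching
    the 7/8 vs 3/9 prevalence split, plus two controls."""
    n_high, n_low = 8, 9
    ids = [f"hi_{i}" for i in range(n_high)] + [f"lo_{i}" for i in range(n_low)]
    flares = {f"hi_{i}": i < 7 for i in range(n_high)}
    flares.update({f"lo_{i}": i < 3 for i in range(n_low)})
    ids += ["c0", "c1"]
    flares.update({"c0": None, "c1": None})
    return SampleTable(
        sample_ids=ids,
        group=["case"] * 17 + ["control"] * 2,
        cohort=["neutrophil"] * 19,
        subtype=["GPP"] * 17 + ["healthy"] * 2,
        flags={"flares": flares},
    )
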