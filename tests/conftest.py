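import numpy as np
import pandas as pd
import pytest

from coexnet.datatypes import CoexpressionNetwork, ExpressionStudy


def make_annotation(rows):
    """rows: (gene, chrom, start, end, strand) tuples, 0-based half-open."""
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def make_network(edges, score_kind="mi", n_samples_used=100):
    """edges: (gene_a, gene_b, score) or (gene_a, gene_b, score, p) tuples."""
    rows = []
    for e in edges:
        a, b = sorted(e[:2])
        score = e[2]
        p = e[3] if len(e) > 3 else np.nan
        rows.append((a, b, score, p))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "p_value"])
    return CoexpressionNetwork(edges=df, score_kind=score_kind, n_samples_used=n_samples_used)


def make_study(values: np.ndarray, genes, groups_per_sample):
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(groups_per_sample, index=samples),
    )


@pytest.fixture
def two_chrom_annotation():
    return make_annotation(
        [
            ("gA", "1", 1000, 3000, "+"),
            ("gB", "1", 5000, 7000, "-"),
            ("gC", "2", 1000, 3000, "+"),
            ("gD", "2", 5000, 7000, "+"),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
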