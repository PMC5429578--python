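import numpy as np
import pytest

from epinorm import (
    ChromSizes,
    build_rci_matrix,
    default_truth,
    extend_reads,
    generate_dataset,
    make_bins,
    quantile_normalize,
    remove_clonal_reads,
)


@pytest.fixture(scope="session")
def pair_truth():
    """Two samples sharing peaks, library depths 1x vs 3x."""
    truth = default_truth(n_samples=2, scale_factors=[1.0, 3.0], seed=5)
    truth.datasets = generate_dataset(truth)
    return truth


@pytest.fixture(scope="session")
def trio_truth():
    """Three samples at unequal depth: the reconstruction/closure dataset."""
    truth = default_truth(n_samples=3, scale_factors=[1.0, 1.3, 0.8], seed=2)
    truth.datasets = generate_dataset(truth)
    return truth


@pytest.fixture(scope="session")
def trio_pipeline(trio_truth):
    """Preprocessed reads, bin scheme, raw matrix and quantile result for the trio."""
    cs = ChromSizes(trio_truth.chrom_sizes)
    scheme = make_bins(cs, 200)
    counting, recon = {}, {}
    for name, reads in trio_truth.datasets.items():
        deduped, _ = remove_clonal_reads(reads)
        counting[name] = extend_reads(deduped, 200, cs)
        recon[name] = deduped
    matrix, unassigned = build_rci_matrix(counting, scheme)
    qres = quantile_normalize(matrix)
    return {
        "chrom_sizes": cs,
        "scheme": scheme,
        "counting": counting,
        "recon": recon,
        "matrix": matrix,
        "unassigned": unassigned,
        "qres": qres,
    }


def naive_quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Independent reference implementation: explicit argsort loops.

    Sort each column, average rank-wise across columns for the reference,
    assign back by rank, and give tied raw values the mean of the reference
    over their tied span.  Deliberately dict/loop based, sharing no code with
    the package implementation.
    """
    X = np.asarray(matrix, dtype=float)
    B, N = X.shape
    ref = np.zeros(B)
    for j in range(N):
        col_sorted = sorted(X[:, j])
        for r in range(B):
            ref[r] += col_sorted[r] / N
    out = np.zeros_like(X)
    for j in range(N):
        col = X[:, j]
        order = sorted(range(B), key=lambda i: col[i])
        ranks_of_value: dict[float, list[int]] = {}
        for r, i in enumerate(order):
            ranks_of_value.setdefault(col[i], []).append(r)
        for i in range(B):
            spans = ranks_of_value[col[i]]
            out[i, j] = sum(ref[r] for r in spans) / len(spans)
    return out
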