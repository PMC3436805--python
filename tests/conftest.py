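"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import settings

from svdelver import SimConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

NEG = -1e18


@pytest.fixture(scope="session")
def del_dataset(tmp_path_factory):
    """Small deletion benchmark dataset shared across module tests."""
    cfg = SimConfig(genome_length=1_000_000, n_del=10, coverage=15, seed=101)
    return simulate_dataset(cfg, str(tmp_path_factory.mktemp("del_ds")))


@pytest.fixture(scope="session")
def null_dataset(tmp_path_factory):
    """SV-free genome at the default cell settings."""
    cfg = SimConfig(genome_length=1_000_000, coverage=15, seed=202)
    return simulate_dataset(cfg, str(tmp_path_factory.mktemp("null_ds")))


def make_bam(path: str, contigs: dict[str, int], records: list[dict]) -> str:
    """Write a tiny coordinate-sorted indexed BAM from record dicts."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()]}
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(bam.header)
            for key, val in rec.items():
                setattr(a, key, val)
            bam.write(a)
    pysam.sort("-o", path, tmp)
    pysam.index(path)
    return path


def oracle_fit_scores(query, ref, match=5.0, mismatch=-4.0, gap_open=-10.0,
                      gap_extend=-1.0):
    """Brute-force fit alignment: best score of each query prefix anywhere in ref.

    Full-matrix affine-gap DP, independent of the production kernel.
    """
    n, m = len(query), len(ref)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        H[i][0] = gap_open + gap_extend * (i - 1)
        F[i][0] = H[i][0]
    best = np.full(n + 1, NEG)
    best[0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if query[i - 1] == ref[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
        best[i] = H[i].max()
    return best


def oracle_split(consensus, ref, min_side=7, match=5.0, mismatch=-4.0,
                 gap_open=-10.0, gap_extend=-1.0):
    """Exhaustive split enumeration with independent global fit alignments.

    Tries every (i, j) split of the consensus (prefix c[:i], suffix c[j-1:],
    microinsertion between) and scores each side with the brute-force DP.
    Returns (best_score, i, j) with the implementation's tie preferences
    (smaller microinsertion, then smaller i).
    """
    from svdelver._util import encode

    c = encode(consensus)
    r = encode(ref)
    n = len(c)
    f = oracle_fit_scores(c, r, match, mismatch, gap_open, gap_extend)
    rv = oracle_fit_scores(c[::-1], r[::-1], match, mismatch, gap_open, gap_extend)
    best = None
    max_ins = n // 2
    for i in range(min_side, n - min_side + 1):
        for j in range(i + 1, min(i + 1 + max_ins, n - min_side + 1) + 1):
            l = n - j + 1
            if l < min_side:
                continue
            key = (f[i] + rv[l], -(j - i), -i)
            if best is None or key > best[0]:
                best = (key, i, j)
    return best[0][0], best[1], best[2]
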