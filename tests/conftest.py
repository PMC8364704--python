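"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive everything from first principles
(explicit padded strings, subword sets, pairwise comparisons, nested
convolution loops) so they stay independent of the vectorized package
code they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from morfnet.io_formats import STANDARD_AMINO_ACIDS, AnnotatedSequence, PropertyScale


# ---------------------------------------------------------------------------
# oracles


def oracle_residue_features(residues: str, values: dict[str, float], N: int):
    """Brute-force windowed-average features for one scale channel.

    Physically constructs the padded value list, averages every
    length-N slice, then averages per residue over the windows that
    contain it.
    """
    left = (N - 1) // 2
    right = (N - 1) - left
    padded = [0.0] * left + [values[ch] for ch in residues] + [0.0] * right
    L = len(residues)
    wins = [sum(padded[i : i + N]) / N for i in range(L)]
    out = []
    for j in range(L):  # residue j (0-based) sits at padded index j + left
        cover = [
            wins[i] for i in range(L) if i <= j + left <= i + N - 1
        ]
        out.append(sum(cover) / len(cover))
    return out


def oracle_topological_entropy(bits: str) -> float:
    """Subword-enumeration topological entropy (string-slicing version)."""
    n = len(bits)
    k = 1
    while 2 ** (k + 1) + (k + 1) - 1 <= n:
        k += 1
    prefix = bits[: 2**k + k - 1]
    subwords = set()
    for i in range(len(prefix) - k + 1):
        subwords.add(prefix[i : i + k])
    return math.log2(len(subwords)) / k


def oracle_auc(scores, labels) -> float:
    """Mann-Whitney pair counting: (concordant + ties/2) / (n1 * n0)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_cnn_forward(x, conv_weights, conv_biases, fc_w, fc_b,
                       activation="relu"):
    """Naive direct-convolution forward pass (nested loops)."""

    def act(v):
        if activation == "relu":
            return max(v, 0.0)
        if activation == "tanh":
            return math.tanh(v)
        return 1.0 / (1.0 + math.exp(-v))

    a = np.asarray(x, dtype=float)[None]  # channel-first: (1, H, W)
    for W, b in zip(conv_weights, conv_biases):
        C, H, Wd = a.shape
        O = W.shape[0]
        out = np.zeros((O, H, Wd))
        for o in range(O):
            for i in range(H):
                for j in range(Wd):
                    s = b[o]
                    for c in range(C):
                        for p in range(2):
                            for q in range(2):
                                ii, jj = i + p, j + q
                                if ii < H and jj < Wd:
                                    s += W[o, c, p, q] * a[c, ii, jj]
                    out[o, i, j] = act(s)
        a = out
    C, H, Wd = a.shape
    ph, pw = -(-H // 2), -(-Wd // 2)
    pooled = np.full((C, ph, pw), -np.inf)
    for c in range(C):
        for i in range(ph):
            for j in range(pw):
                block = a[c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                pooled[c, i, j] = block.max()
    flat = pooled.reshape(-1)
    z = float(flat @ fc_w + fc_b)
    return 1.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# fixtures


AAINDEX_FIXTURE = """\
H TSTA000101
D synthetic hydropathy-like fixture scale
R none
A none
T none
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H TSTA000201
D synthetic flexibility-like fixture scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.357   0.529   0.463   0.511   0.346   0.493   0.497   0.544   0.323   0.462
     0.365   0.466   0.295   0.314   0.509   0.507   0.444   0.305   0.420   0.386
//
"""

AAINDEX_NA_FIXTURE = """\
H TSTB000301
D fixture scale with a missing cell
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.2     NA      0.4     0.5     0.6     0.7     0.8     0.9     1.0
     1.1     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9     2.0
//
"""


@pytest.fixture
def aaindex_file(tmp_path):
    path = tmp_path / "fixture.aaindex"
    path.write_text(AAINDEX_FIXTURE)
    return path


@pytest.fixture
def random_scale():
    rng = np.random.default_rng(7)
    return PropertyScale(
        "RND0000001",
        "random test scale",
        dict(zip(STANDARD_AMINO_ACIDS, rng.normal(size=20))),
    )


def random_sequence(rng, L, labeled=True):
    letters = rng.choice(list(STANDARD_AMINO_ACIDS), size=L)
    labels = tuple(int(v) for v in rng.integers(0, 2, size=L)) if labeled else None
    return AnnotatedSequence(f"r{rng.integers(1e6)}", "".join(letters), labels)
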