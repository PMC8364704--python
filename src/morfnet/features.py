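"""Per-residue feature extraction from sequence property scales.

A window of length ``N`` slides along the zero-padded sequence with step
1.  For each window, each scale channel takes the mean of its per-residue
values over the window (padded positions contribute 0), and the optional
topological-entropy channel takes the complexity of the binary-mapped
window content.  Each residue is then assigned the uniform average of the
window vectors of every window that covers it.  Stacking this over
several window lengths (default 10 / 45 / 90) gives each residue an
``N_win x F`` feature matrix — the input of the per-residue CNN.

Padding: ``floor((N-1)/2)`` zeros on the left and ``ceil((N-1)/2)`` on
the right, so every window length yields exactly ``L`` window start
positions and the per-residue indexing ``1 <= j <= L`` is preserved for
even and odd ``N`` alike.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .io_formats import STANDARD_AMINO_ACIDS, AnnotatedSequence, PropertyScale

__all__ = [
    "BinaryMapping",
    "DISORDER_PROMOTING_MAPPING",
    "ScaleChannel",
    "EntropyChannel",
    "FeatureSetSpec",
    "WindowConfig",
    "ResidueFeatureMatrix",
    "pad_counts",
    "topological_entropy",
    "window_vectors",
    "residue_features",
    "build_feature_matrices",
    "feature_tensor",
    "ChannelStandardizer",
]


@dataclass(frozen=True)
class BinaryMapping:
    """Partition of the amino-acid alphabet into 1-residues and 0-residues."""

    ones: frozenset[str]
    name: str = "custom"

    def __post_init__(self) -> None:
        bad = set(self.ones) - set(STANDARD_AMINO_ACIDS)
        if bad:
            raise ValueError(f"mapping {self.name}: letters {sorted(bad)} "
                             "outside the 20-letter alphabet")

    def bit(self, residue: str) -> int:
        return 1 if residue in self.ones else 0


#: Default 0-1 mapping: disorder-promoting residues map to 1.
DISORDER_PROMOTING_MAPPING = BinaryMapping(
    frozenset("AGRQSPEK"), name="disorder-promoting"
)


@dataclass(frozen=True)
class ScaleChannel:
    """A per-residue lookup channel (physicochemical or disorder scale)."""

    scale: PropertyScale
    disorder: bool = False

    @property
    def name(self) -> str:
        return self.scale.accession


@dataclass(frozen=True)
class EntropyChannel:
    """Topological entropy of the binary-mapped window content."""

    mapping: BinaryMapping = DISORDER_PROMOTING_MAPPING

    @property
    def name(self) -> str:
        return f"topological_entropy[{self.mapping.name}]"


Channel = Union[ScaleChannel, EntropyChannel]


@dataclass(frozen=True)
class FeatureSetSpec:
    """An ordered list of feature channels defining one feature set."""

    name: str
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError(f"feature set {self.name}: needs >= 1 channel")
        n_entropy = sum(isinstance(c, EntropyChannel) for c in self.channels)
        if n_entropy > 1:
            raise ValueError(
                f"feature set {self.name}: at most one entropy channel"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class WindowConfig:
    """Ordered window lengths used for preprocessing (default 10/45/90)."""

    lengths: tuple[int, ...] = (10, 45, 90)

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.lengths):
            raise ValueError("window lengths must be >= 2")
        if list(self.lengths) != sorted(set(self.lengths)):
            raise ValueError("window lengths must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class ResidueFeatureMatrix:
    """The N_win x F feature matrix of one residue (1-based position)."""

    sequence_id: str
    position: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (N_win x F)")
        if not np.all(np.isfinite(m)):
            raise ValueError(
                f"{self.sequence_id}:{self.position}: non-finite entries"
            )
        object.__setattr__(self, "matrix", m)


def pad_counts(N: int) -> tuple[int, int]:
    """Zero-padding on each side for window length ``N``.

    Left pad is ``floor((N-1)/2)``, right pad ``ceil((N-1)/2)``; together
    they add ``N - 1`` positions so a length-``L`` sequence has exactly
    ``L`` window start positions for any ``N``.
    """
    if N < 2:
        raise ValueError(f"window length must be >= 2, got {N}")
    left = (N - 1) // 2
    return left, N - 1 - left


def topological_entropy(bits: Sequence[int] | str) -> float:
    """Topological entropy of a finite binary sequence, normalized to [0, 1].

    With ``n = len(bits)``, let ``k`` be the largest integer such that
    ``2**k + k - 1 <= n``.  The entropy is ``log2(m) / k`` where ``m`` is
    the number of distinct length-``k`` subwords occurring in the first
    ``2**k + k - 1`` symbols.  Constant sequences give 0; a sequence whose
    counted prefix realizes all ``2**k`` subwords (a de Bruijn prefix)
    gives 1.
    """
    seq = [int(b) for b in bits]
    if any(b not in (0, 1) for b in seq):
        raise ValueError("bits must be over {0, 1}")
    n = len(seq)
    if n < 2:
        raise ValueError(f"topological entropy needs length >= 2, got {n}")
    k = _entropy_k(n)
    prefix = seq[: 2**k + k - 1]
    subwords = {tuple(prefix[i : i + k]) for i in range(2**k)}
    return math.log2(len(subwords)) / k


def _entropy_k(n: int) -> int:
    k = 1
    while 2 ** (k + 1) + k <= n:
        k += 1
    return k


# ---------------------------------------------------------------------------
# windowed feature computation


def _channel_track(sequence: AnnotatedSequence, channel: Channel) -> np.ndarray:
    """Per-residue raw values of one channel (scale value or mapped bit)."""
    lookup = np.zeros(128)
    if isinstance(channel, ScaleChannel):
        for aa in STANDARD_AMINO_ACIDS:
            lookup[ord(aa)] = channel.scale.values[aa]
        lookup[ord("X")] = channel.scale.mean
    else:
        for aa in channel.mapping.ones:
            lookup[ord(aa)] = 1.0
    codes = np.frombuffer(sequence.residues.encode("ascii"), dtype=np.uint8)
    return lookup[codes]


def _all_tracks(sequence: AnnotatedSequence, spec: FeatureSetSpec) -> np.ndarray:
    return np.column_stack(
        [_channel_track(sequence, ch) for ch in spec.channels]
    )


def window_vectors(
    sequence: AnnotatedSequence,
    spec: FeatureSetSpec,
    N: int,
    _tracks: np.ndarray | None = None,
) -> np.ndarray:
    """The L x F matrix of per-window feature vectors for one window length.

    Window ``i`` (1-based, ``i = 1..L``) covers positions
    ``i .. i+N-1`` of the padded sequence.  Scale channels average the
    window's per-position values with padded positions contributing 0;
    the entropy channel evaluates the binary-mapped window content with
    padded positions contributing symbol 0.
    """
    L = len(sequence)
    left, right = pad_counts(N)
    tracks = _all_tracks(sequence, spec) if _tracks is None else _tracks
    out = np.empty((L, spec.n_channels), dtype=float)
    for c, channel in enumerate(spec.channels):
        padded = np.concatenate(
            [np.zeros(left), tracks[:, c], np.zeros(right)]
        )
        if isinstance(channel, ScaleChannel):
            csum = np.concatenate([[0.0], np.cumsum(padded)])
            out[:, c] = (csum[N:] - csum[:-N]) / N
        else:
            out[:, c] = _window_entropies(padded.astype(np.int64), N, L)
    return out


def _window_entropies(bits: np.ndarray, N: int, L: int) -> np.ndarray:
    """Topological entropy of every length-N window (vectorized over L)."""
    k = _entropy_k(N)
    m = 2**k + k - 1
    # integer code of each length-k subword, via sliding windows
    powers = 2 ** np.arange(k - 1, -1, -1)
    codes = np.lib.stride_tricks.sliding_window_view(bits, k) @ powers
    out = np.empty(L, dtype=float)
    for i in range(L):
        distinct = len(np.unique(codes[i : i + 2**k]))
        out[i] = math.log2(distinct) / k
    return out


def residue_features(v: np.ndarray, L: int, N: int) -> np.ndarray:
    """Average each residue's covering-window vectors (L x F in, L x F out).

    Residue ``j`` sits at padded position ``j + left_pad``; the windows
    covering it are ``i = j + left_pad - N + 1 .. j + left_pad``, clamped
    to the valid range ``1..L``.  Weights within the average are uniform.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] != L:
        raise ValueError(f"expected {L} window vectors, got shape {v.shape}")
    left, _ = pad_counts(N)
    j = np.arange(1, L + 1)
    lo = np.maximum(j + left - N + 1, 1)
    hi = np.minimum(j + left, L)
    csum = np.vstack([np.zeros(v.shape[1]), np.cumsum(v, axis=0)])
    return (csum[hi] - csum[lo - 1]) / (hi - lo + 1)[:, None]


def feature_tensor(
    sequence: AnnotatedSequence,
    spec: FeatureSetSpec,
    windows: WindowConfig = WindowConfig(),
) -> np.ndarray:
    """The L x N_win x F feature tensor of a sequence for one feature set."""
    L = len(sequence)
    tracks = _all_tracks(sequence, spec)
    stack = np.empty((L, windows.n_windows, spec.n_channels), dtype=float)
    for r, N in enumerate(windows.lengths):
        v = window_vectors(sequence, spec, N, _tracks=tracks)
        stack[:, r, :] = residue_features(v, L, N)
    return stack


def build_feature_matrices(
    sequence: AnnotatedSequence,
    spec: FeatureSetSpec,
    windows: WindowConfig = WindowConfig(),
) -> list[ResidueFeatureMatrix]:
    """One ``N_win x F`` feature matrix per residue (1-based positions)."""
    tensor = feature_tensor(sequence, spec, windows)
    return [
        ResidueFeatureMatrix(sequence.id, j + 1, tensor[j])
        for j in range(len(sequence))
    ]


# ---------------------------------------------------------------------------
# standardization


class ChannelStandardizer:
    """Per-cell z-scoring of feature tensors, fitted on training data only.

    Every ``(window, channel)`` cell of the N_win x F matrix is treated
    as an independent feature.  Cells with zero variance on the fitting
    set are flagged constant and passed through unchanged (with a
    warning); applying the stored transform to new data always uses the
    training mean/sd.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.constant_: np.ndarray | None = None

    def fit(self, tensors: np.ndarray) -> "ChannelStandardizer":
        x = np.asarray(tensors, dtype=float)
        if x.ndim != 3 or x.shape[0] < 2:
            raise ValueError("fit needs an (n, N_win, F) stack with n >= 2")
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0, ddof=0)
        self.constant_ = self.sd_ == 0.0
        if self.constant_.any():
            warnings.warn(
                f"{int(self.constant_.sum())} constant feature cell(s) left "
                "unstandardized",
                stacklevel=2,
            )
        return self

    def transform(self, tensors: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer not fitted")
        x = np.asarray(tensors, dtype=float)
        sd = np.where(self.constant_, 1.0, self.sd_)
        mean = np.where(self.constant_, 0.0, self.mean_)
        return (x - mean) / sd

    def fit_transform(self, tensors: np.ndarray) -> np.ndarray:
        return self.fit(tensors).transform(tensors)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "constant": self.constant_.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ChannelStandardizer":
        obj = cls()
        obj.mean_ = np.asarray(data["mean"], dtype=float)
        obj.sd_ = np.asarray(data["sd"], dtype=float)
        obj.constant_ = np.asarray(data["constant"]).astype(bool)
        return obj
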