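"""Synthetic labeled sequence datasets with a plantable MoRF signal.

Real MoRF data are long, mostly disordered chains carrying one short
(5-25 residue) binding element whose amino-acid composition differs from
its context.  The generator emulates exactly that structure: background
residues are drawn i.i.d. from a background composition, and each
sequence carries (with probability ``p_morf``) one contiguous, interior
MoRF segment drawn from a biased composition.

The compositional bias is tied to a designated *signal* property scale:
``composition_for_shift`` exponentially tilts the background composition
along the standardized scale values until the mean scale value of a
MoRF-drawn residue exceeds the background mean by a requested number of
scale standard deviations.  Two presets are shipped:

- ``strong-signal``: the designated channel is shifted by 2 standard
  deviations, a clearly learnable planted effect;
- ``null``: MoRF segments are drawn from the background composition
  (labels exist, signal does not), for leakage checks.

Synthetic scales stand in for unpublished amino-acid index selections;
they are seeded standard-normal draws (standardized across the 20
residues), except the first, which is built to load on the designated
MoRF-enriched residues so the planted composition bias is detectable
through it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import (
    DISORDER_PROMOTING_MAPPING,
    EntropyChannel,
    FeatureSetSpec,
    ScaleChannel,
)
from .io_formats import STANDARD_AMINO_ACIDS, AnnotatedSequence, PropertyScale

__all__ = [
    "SyntheticConfig",
    "PresetBundle",
    "SIGNAL_RESIDUES",
    "UNIFORM_COMPOSITION",
    "generate_dataset",
    "generate_scales",
    "composition_for_shift",
    "default_feature_sets",
    "make_preset",
    "PRESET_NAMES",
]

#: Residues the designated signal scale loads on (MoRF-enriched letters;
#: aromatics/hydrophobics are the classic MoRF enrichment).
SIGNAL_RESIDUES = ("W", "F")

UNIFORM_COMPOSITION = tuple([1.0 / 20.0] * 20)

PRESET_NAMES = ("strong-signal", "null")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Compositions are probability vectors over the 20 standard amino
    acids in alphabetical one-letter order.  MoRF segments are 5-25
    residues by default and always interior (at least one flanking
    residue on each side).
    """

    n_sequences: int = 300
    length_range: tuple[int, int] = (50, 200)
    morf_length_range: tuple[int, int] = (5, 25)
    p_morf: float = 1.0
    background_composition: tuple[float, ...] = UNIFORM_COMPOSITION
    morf_composition: tuple[float, ...] = UNIFORM_COMPOSITION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        lmin, lmax = self.length_range
        mmin, mmax = self.morf_length_range
        if not (1 <= lmin <= lmax):
            raise ValueError("invalid length_range")
        if not (1 <= mmin <= mmax):
            raise ValueError("invalid morf_length_range")
        if mmax + 2 > lmin:
            raise ValueError(
                "infeasible ranges: shortest sequence cannot hold the "
                "longest MoRF with one flanking residue per side"
            )
        if not (0.0 <= self.p_morf <= 1.0):
            raise ValueError("p_morf must be in [0, 1]")
        for name in ("background_composition", "morf_composition"):
            comp = np.asarray(getattr(self, name), dtype=float)
            if comp.shape != (20,) or np.any(comp < 0):
                raise ValueError(f"{name} must be 20 non-negative entries")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


def generate_dataset(config: SyntheticConfig) -> list[AnnotatedSequence]:
    """Draw a seeded, reproducible labeled dataset."""
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(STANDARD_AMINO_ACIDS))
    bg = np.asarray(config.background_composition, dtype=float)
    mc = np.asarray(config.morf_composition, dtype=float)
    lmin, lmax = config.length_range
    mmin, mmax = config.morf_length_range
    out: list[AnnotatedSequence] = []
    for i in range(config.n_sequences):
        L = int(rng.integers(lmin, lmax + 1))
        residues = rng.choice(letters, size=L, p=bg)
        labels = np.zeros(L, dtype=int)
        if rng.random() < config.p_morf:
            m = int(rng.integers(mmin, mmax + 1))
            # interior placement: >= 1 flanking residue on each side
            start = int(rng.integers(1, L - m))
            residues[start : start + m] = rng.choice(letters, size=m, p=mc)
            labels[start : start + m] = 1
        out.append(
            AnnotatedSequence(f"syn{i:05d}", "".join(residues), tuple(labels))
        )
    return out


def generate_scales(
    n: int = 40,
    seed: int = 0,
    signal_residues: Sequence[str] = SIGNAL_RESIDUES,
    signal_noise: float = 0.15,
) -> list[PropertyScale]:
    """Seeded stand-in property scales; the first is the signal scale.

    All scales are standardized to zero mean / unit standard deviation
    across the 20 residues.  Scale 0 is a noisy indicator of the
    signal residues so that compositions biased toward them shift its
    mean; the rest are independent standard-normal draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scales = []
    for i in range(n):
        if i == 0:
            vals = np.array(
                [1.0 if aa in signal_residues else 0.0
                 for aa in STANDARD_AMINO_ACIDS]
            )
            vals = vals + rng.normal(0.0, signal_noise, 20)
            descr = "synthetic signal scale (loads on MoRF-enriched residues)"
        else:
            vals = rng.normal(0.0, 1.0, 20)
            descr = "synthetic background scale"
        vals = (vals - vals.mean()) / vals.std()
        scales.append(
            PropertyScale(
                accession=f"SYN{i:04d}",
                description=descr,
                values=dict(zip(STANDARD_AMINO_ACIDS, vals)),
            )
        )
    return scales


def composition_for_shift(
    scale: PropertyScale,
    shift_sd: float,
    background: Sequence[float] = UNIFORM_COMPOSITION,
    tol: float = 1e-10,
) -> tuple[float, ...]:
    """Exponentially tilt a composition to shift a scale's mean value.

    Returns the composition ``w_a \\propto bg_a * exp(c * z_a)`` (``z``
    the standardized scale values) with ``c >= 0`` chosen by bisection
    so that the mean of ``z`` under ``w`` exceeds its mean under the
    background by ``shift_sd`` standard deviations.  ``shift_sd`` must
    be below the largest achievable shift (concentration on the
    top-scoring residue).
    """
    bg = np.asarray(background, dtype=float)
    vals = np.array([scale.values[aa] for aa in STANDARD_AMINO_ACIDS])
    z = (vals - vals.mean()) / vals.std()
    base = float(bg @ z)
    if shift_sd < 0:
        raise ValueError("shift_sd must be >= 0")
    if shift_sd == 0:
        return tuple(bg)

    def shift(c: float) -> float:
        w = bg * np.exp(c * (z - z.max()))  # stable tilt
        w /= w.sum()
        return float(w @ z) - base

    hi = 1.0
    while shift(hi) < shift_sd:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(
                f"requested shift {shift_sd} exceeds the achievable maximum "
                f"{z.max() - base:.3f} for scale {scale.accession}"
            )
    lo = 0.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if shift(mid) < shift_sd:
            lo = mid
        else:
            hi = mid
    w = bg * np.exp(hi * (z - z.max()))
    w /= w.sum()
    return tuple(w)


def default_feature_sets(
    scales: Sequence[PropertyScale],
    mapping=DISORDER_PROMOTING_MAPPING,
) -> tuple[FeatureSetSpec, FeatureSetSpec, FeatureSetSpec]:
    """Partition a pool of >= 40 scales into the three default sets.

    Set 1: 13 physicochemical channels + 2 disorder-propensity channels
    + topological entropy (16 channels); sets 2 and 3: 13 and 14
    physicochemical channels.  The designated signal scale (pool index
    0) is shared by all three sets so that each network sees the
    plantable channel; the exact channel lists are configuration data,
    not a published selection.
    """
    if len(scales) < 40:
        raise ValueError("need a pool of at least 40 scales")
    set1 = FeatureSetSpec(
        "set1",
        tuple(ScaleChannel(s) for s in scales[0:13])
        + tuple(ScaleChannel(s, disorder=True) for s in scales[38:40])
        + (EntropyChannel(mapping),),
    )
    set2 = FeatureSetSpec(
        "set2",
        (ScaleChannel(scales[0]),)
        + tuple(ScaleChannel(s) for s in scales[13:25]),
    )
    set3 = FeatureSetSpec(
        "set3",
        (ScaleChannel(scales[0]),)
        + tuple(ScaleChannel(s) for s in scales[25:38]),
    )
    return set1, set2, set3


@dataclass(frozen=True)
class PresetBundle:
    """A named study condition: dataset config, scale pool, feature sets."""

    name: str
    config: SyntheticConfig
    scales: tuple[PropertyScale, ...]
    feature_sets: tuple[FeatureSetSpec, FeatureSetSpec, FeatureSetSpec]


def make_preset(
    name: str, seed: int = 0, n_sequences: int = 300
) -> PresetBundle:
    """Build one of the named presets ("strong-signal" or "null")."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    scales = generate_scales(seed=seed)
    if name == "strong-signal":
        morf_comp = composition_for_shift(scales[0], shift_sd=2.0)
    else:
        morf_comp = UNIFORM_COMPOSITION
    config = SyntheticConfig(
        n_sequences=n_sequences,
        morf_composition=morf_comp,
        seed=seed,
    )
    return PresetBundle(
        name=name,
        config=config,
        scales=tuple(scales),
        feature_sets=default_feature_sets(scales),
    )
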