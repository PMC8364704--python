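"""End-to-end orchestration: features -> three CNNs -> ensemble track.

Three networks are trained independently, one per feature set, on the
per-residue feature matrices of a labeled training set; prediction
averages their per-residue probabilities.  Channel standardization is
fitted on the training residues only and stored with each model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import cnn as _cnn
from .cnn import CNNConfig, TrainedCNN
from .ensemble_eval import ScoreTrack, ensemble_average
from .features import (
    ChannelStandardizer,
    FeatureSetSpec,
    WindowConfig,
    feature_tensor,
)
from .io_formats import AnnotatedSequence

__all__ = ["EnsembleModel", "extract_set", "train_ensemble", "predict_tracks"]


def extract_set(
    sequences: Sequence[AnnotatedSequence],
    spec: FeatureSetSpec,
    windows: WindowConfig = WindowConfig(),
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pool per-residue feature matrices over a sequence set.

    Returns (x, y, lengths): the (n_residues, N_win, F) stack, the 0/1
    labels (-1 where a sequence carries no label track), and per-sequence
    lengths in input order.
    """
    xs, ys, lengths = [], [], []
    for seq in sequences:
        xs.append(feature_tensor(seq, spec, windows))
        if seq.labels is None:
            ys.append(np.full(len(seq), -1, dtype=int))
        else:
            ys.append(np.asarray(seq.labels, dtype=int))
        lengths.append(len(seq))
    return np.concatenate(xs), np.concatenate(ys), lengths


@dataclass
class EnsembleModel:
    """Three trained per-feature-set CNNs plus their specs."""

    models: tuple[TrainedCNN, ...]
    feature_sets: tuple[FeatureSetSpec, ...]
    windows: WindowConfig


def train_ensemble(
    sequences: Sequence[AnnotatedSequence],
    feature_sets: Sequence[FeatureSetSpec],
    config: CNNConfig = CNNConfig(),
    windows: WindowConfig = WindowConfig(),
) -> EnsembleModel:
    """Train one CNN per feature set on a labeled sequence set.

    Each network gets the same optimizer settings but its own input
    width; seeds are offset per network so their initializations and
    shuffles are independent yet reproducible.
    """
    models = []
    for k, spec in enumerate(feature_sets):
        x, y, _ = extract_set(sequences, spec, windows)
        if np.any(y < 0):
            raise ValueError("training sequences must all carry labels")
        std = ChannelStandardizer().fit(x)
        xs = std.transform(x)
        cfg = replace(
            config,
            input_shape=(windows.n_windows, spec.n_channels),
            seed=config.seed + 1000 * k,
        )
        model = _cnn.build_model(cfg)
        _cnn.train(model, xs, y, standardizer=std)
        models.append(model)
    return EnsembleModel(tuple(models), tuple(feature_sets), windows)


def predict_tracks(
    ensemble: EnsembleModel, sequences: Sequence[AnnotatedSequence]
) -> dict[str, list[ScoreTrack]]:
    """Score tracks per model ("cnn1".."cnnK") plus the "ensemble" mean."""
    names = [f"cnn{k + 1}" for k in range(len(ensemble.models))]
    out: dict[str, list[ScoreTrack]] = {n: [] for n in names}
    out["ensemble"] = []
    for seq in sequences:
        per_model = []
        for name, model, spec in zip(
            names, ensemble.models, ensemble.feature_sets
        ):
            x = feature_tensor(seq, spec, ensemble.windows)
            scores = _cnn.predict_track(model, x)
            track = ScoreTrack(seq.id, tuple(scores))
            out[name].append(track)
            per_model.append(track)
        out["ensemble"].append(ensemble_average(per_model))
    return out
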