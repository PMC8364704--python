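"""Ensemble combination and residue-level ROC evaluation.

The final propensity track is the element-wise mean of the three
feature-set-specific CNN tracks.  Evaluation pools the residues of all
sequences in a set as independent binary instances and reports the ROC
curve, its area (AUC), and the false-positive rate reached when the
threshold is set so the true-positive rate attains a target (FPR at
fixed TPR).  A residue is called positive when its score is >= the
threshold; tied scores contribute 1/2 to the AUC (Mann-Whitney
convention), so constant scores give exactly 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from sklearn import metrics as _skmetrics

from .io_formats import AnnotatedSequence

__all__ = [
    "ScoreTrack",
    "ROCResult",
    "ensemble_average",
    "confusion_counts",
    "roc_curve",
    "fpr_at_tpr",
    "pool_residues",
    "evaluation_summary",
    "write_score_tsv",
    "read_score_tsv",
]


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue MoRF propensity in [0, 1] for one sequence."""

    sequence_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        if any(not (0.0 <= s <= 1.0) for s in scores):
            raise ValueError(f"{self.sequence_id}: scores must lie in [0, 1]")
        if len(scores) == 0:
            raise ValueError(f"{self.sequence_id}: empty track")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ROCResult:
    """A ROC curve with thresholds (descending), FPR/TPR arrays and AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def ensemble_average(tracks: Sequence[ScoreTrack]) -> ScoreTrack:
    """Element-wise arithmetic mean of score tracks for one sequence."""
    if not tracks:
        raise ValueError("no tracks to average")
    sid = tracks[0].sequence_id
    n = len(tracks[0])
    for t in tracks[1:]:
        if t.sequence_id != sid:
            raise ValueError(
                f"track id mismatch: {t.sequence_id!r} vs {sid!r}"
            )
        if len(t) != n:
            raise ValueError(f"{sid}: track length mismatch")
    mean = np.mean([t.scores for t in tracks], axis=0)
    return ScoreTrack(sid, tuple(mean))


def confusion_counts(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at a threshold, calling positive at score >= t."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, tn, fn


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Residue-level ROC over all distinct score thresholds.

    FPR = FP / N_non and TPR = TP / N_MoRF; the curve runs from (0, 0)
    to (1, 1) and the AUC is its trapezoidal integral, which equals the
    tie-adjusted Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def fpr_at_tpr(roc: ROCResult, tpr_target: float) -> float:
    """Smallest FPR among curve points whose TPR reaches the target.

    Conservative step-function reading of the finite curve; no
    interpolation between operating points.
    """
    if not (0.0 < tpr_target <= 1.0):
        raise ValueError("tpr_target must be in (0, 1]")
    ok = roc.tpr >= tpr_target
    return float(roc.fpr[ok].min())


def pool_residues(
    sequences: Sequence[AnnotatedSequence], tracks: Sequence[ScoreTrack]
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate (scores, labels) over a labeled sequence set."""
    by_id = {t.sequence_id: t for t in tracks}
    scores, labels = [], []
    for seq in sequences:
        if seq.labels is None:
            raise ValueError(f"{seq.id}: labels required for evaluation")
        track = by_id[seq.id]
        if len(track) != len(seq):
            raise ValueError(f"{seq.id}: track/sequence length mismatch")
        scores.extend(track.scores)
        labels.extend(seq.labels)
    return np.asarray(scores, dtype=float), np.asarray(labels)


def evaluation_summary(
    scores: Sequence[float],
    labels: Sequence[int],
    tpr_targets: Sequence[float] = (0.2, 0.3, 0.4),
) -> dict:
    """AUC plus FPR at the requested TPR levels, as a JSON-ready dict."""
    roc = roc_curve(scores, labels)
    return {
        "auc": roc.auc,
        "n_residues": int(len(np.asarray(labels))),
        "n_morf": int(np.sum(np.asarray(labels) == 1)),
        "fpr_at_tpr": {
            f"{t:g}": fpr_at_tpr(roc, t) for t in tpr_targets
        },
    }


# ---------------------------------------------------------------------------
# score track I/O (TSV: sequence_id, position, score...)


def write_score_tsv(
    tracks_by_model: dict[str, Sequence[ScoreTrack]],
    dest: str | Path | IO[str],
) -> None:
    """Write per-model score columns plus position keys as TSV."""
    names = list(tracks_by_model)
    first = tracks_by_model[names[0]]
    handle, close = _open(dest, "w")
    try:
        handle.write("sequence_id\tposition\t" + "\t".join(names) + "\n")
        for i, track in enumerate(first):
            rows = [tracks_by_model[n][i] for n in names]
            for pos in range(len(track)):
                vals = "\t".join(f"{r.scores[pos]:.6f}" for r in rows)
                handle.write(f"{track.sequence_id}\t{pos + 1}\t{vals}\n")
    finally:
        if close:
            handle.close()


def read_score_tsv(source: str | Path | IO[str]) -> dict[str, list[ScoreTrack]]:
    handle, close = _open(source, "r")
    try:
        header = handle.readline().rstrip("\n").split("\t")
        names = header[2:]
        acc: dict[str, dict[str, list[float]]] = {n: {} for n in names}
        order: list[str] = []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            sid = parts[0]
            if sid not in order:
                order.append(sid)
            for n, val in zip(names, parts[2:]):
                acc[n].setdefault(sid, []).append(float(val))
        return {
            n: [ScoreTrack(sid, tuple(acc[n][sid])) for sid in order]
            for n in names
        }
    finally:
        if close:
            handle.close()


def _open(source, mode):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False
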