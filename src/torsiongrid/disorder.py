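"""Disorder scoring from angle-bin probability distributions.

Residues in intrinsically disordered regions sample a broad range of
backbone conformations, so a well-calibrated angle predictor should
spread probability mass over many bins there.  The per-residue score is
the Shannon entropy of the predicted bin distribution,

    H = -sum_i p_i ln p_i,

normalized by its maximum ln K (the uniform distribution over K bins)
so it lies in [0, 1] regardless of bin count, then smoothed by a
centered moving average (default window 21 residues) because disorder
occurs in contiguous segments.  Discrimination of disordered from
structured residues is evaluated by ranking AUC; since AUC depends only
on the score ordering, the normalization (and the logarithm base)
cannot change it.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .binning import ProbabilityProfile, UndefinedMetricError
from .geometry import ANGLE_KINDS

__all__ = [
    "DisorderScoreTrack",
    "entropy",
    "entropy_track",
    "window_average",
    "auc",
    "score_disorder",
]

DEFAULT_WINDOW = 21


def entropy(dist: np.ndarray, atol: float = 1e-6) -> float:
    """Normalized Shannon entropy of a probability vector, in [0, 1].

    Natural log; 0*log 0 := 0.  Raises if the input is not a
    probability vector within ``atol``.
    """
    p = np.asarray(dist, dtype=float)
    if np.any(p < -atol):
        raise ValueError("negative probability entries")
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"probabilities sum to {total}, not 1")
    p = np.clip(p, 0.0, None)
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    h_norm = h / np.log(len(p))
    return float(min(max(h_norm, 0.0), 1.0))


def entropy_track(profile: ProbabilityProfile, kind: str) -> np.ndarray:
    """Normalized entropy per residue for one angle's probability block."""
    if kind not in ANGLE_KINDS:
        raise ValueError(f"unknown angle kind {kind!r}")
    block = profile.blocks[kind]
    K = block.shape[1]
    p = np.clip(block, 1e-300, None)
    h = -np.sum(np.where(block > 0, block * np.log(p), 0.0), axis=1)
    return np.clip(h / np.log(K), 0.0, 1.0)


def window_average(track: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving average with window shrinkage at the termini.

    Near the ends the mean runs over the positions that exist (the
    window shrinks); zero-padding would artificially deflate terminal
    scores.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    t = np.asarray(track, dtype=float)
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(t, kernel, mode="same")
    counts = np.convolve(np.ones_like(t), kernel, mode="same")
    return sums / counts


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Ranking AUC (Mann-Whitney with midrank ties).

    Convention: higher score means more likely disordered; labels are
    1 for disordered, 0 for structured.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


class DisorderScoreTrack:
    """Raw, normalized and window-averaged entropy for one angle kind."""

    def __init__(self, profile: ProbabilityProfile, kind: str,
                 window: int = DEFAULT_WINDOW):
        block = profile.blocks[kind]
        K = block.shape[1]
        self.kind = kind
        self.window = window
        self.normalized = entropy_track(profile, kind)
        self.raw = self.normalized * np.log(K)
        self.smoothed = window_average(self.normalized, window)

    def __len__(self) -> int:
        return len(self.raw)

    def to_tsv(self) -> str:
        lines = ["residue\traw_entropy\tnormalized_entropy\tsmoothed_score"]
        for i, (r, n, s) in enumerate(zip(self.raw, self.normalized,
                                          self.smoothed), start=1):
            lines.append(f"{i}\t{r:.6f}\t{n:.6f}\t{s:.6f}")
        return "\n".join(lines) + "\n"


def score_disorder(profile: ProbabilityProfile, kind: str = "tau",
                   window: int = DEFAULT_WINDOW,
                   labels: np.ndarray | None = None) -> dict:
    """End-to-end disorder scoring for one angle kind.

    Returns the track plus, when binary labels are supplied, the AUC of
    both the per-residue normalized entropy and the window-averaged
    score.
    """
    track = DisorderScoreTrack(profile, kind, window)
    result = {"track": track}
    if labels is not None:
        result["auc_smoothed"] = auc(track.smoothed, labels)
        result["auc_per_residue"] = auc(track.normalized, labels)
    return result
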