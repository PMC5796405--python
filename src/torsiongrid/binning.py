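"""Fixed-width angle binning, target encoding and evaluation metrics.

The predictor treats angle prediction as multi-class classification on
a fine grid: every backbone angle is discretized into fixed-width bins
(5 degrees by default).  Dihedrals (phi, psi, tau) span [-180, 180) and
give 72 bins at width 5; the planar angle theta spans [0, 180] and
gives 36, for a total output dimension of 252.  Bins are half-open
[low, low + width) except the final theta bin, which is closed at 180
so that every in-range angle maps to exactly one bin.

This module also implements the evaluation metrics used for grid
predictions: bin accuracy (argmax bin equals the true bin), top-k
accuracy (true bin among the k highest-probability bins), evaluation
after merging neighboring bins into a coarser grid, and a two-state
summary that splits each dihedral's range into its two dominant
conformational regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ANGLE_KINDS, AngleTable, wrap_dihedral

__all__ = [
    "BinScheme",
    "TargetMatrix",
    "ProbabilityProfile",
    "UndefinedMetricError",
    "MASKED_BIN",
    "make_scheme",
    "angle_to_bin",
    "bin_center",
    "encode_targets",
    "bin_accuracy",
    "topk_accuracy",
    "merge_to_coarse",
    "two_state",
    "two_state_accuracy",
]

#: Sentinel bin index for undefined (masked) angles.
MASKED_BIN = -1

_DIHEDRAL_RANGE = (-180.0, 180.0)
_THETA_RANGE = (0.0, 180.0)


class UndefinedMetricError(ValueError):
    """A metric was requested on an input where it is undefined."""


@dataclass(frozen=True)
class BinScheme:
    """The discretization: bin width and per-angle ranges/counts."""

    width: float
    ranges: dict = field(default_factory=dict)   # kind -> (low, high)
    counts: dict = field(default_factory=dict)   # kind -> n_bins

    @property
    def total(self) -> int:
        return sum(self.counts[k] for k in ANGLE_KINDS)

    def offset(self, kind: str) -> int:
        """Start column of this kind's block in the concatenated layout."""
        off = 0
        for k in ANGLE_KINDS:
            if k == kind:
                return off
            off += self.counts[k]
        raise ValueError(f"unknown angle kind {kind!r}")


def make_scheme(width: float = 5.0) -> BinScheme:
    """Build the scheme for a given bin width (must divide 360 and 180)."""
    if width <= 0 or (360.0 % width) or (180.0 % width):
        raise ValueError(f"bin width must divide both 360 and 180, got {width}")
    ranges = {k: _DIHEDRAL_RANGE for k in ("phi", "psi", "tau")}
    ranges["theta"] = _THETA_RANGE
    counts = {k: int(round((hi - lo) / width)) for k, (lo, hi) in ranges.items()}
    return BinScheme(width=float(width), ranges=ranges, counts=counts)


def angle_to_bin(angle, kind: str, scheme: BinScheme):
    """Map angle(s) in degrees to bin index(es); NaN maps to MASKED_BIN.

    Dihedrals are wrapped into [-180, 180) first; theta = 180 falls in
    the last bin.
    """
    lo, hi = scheme.ranges[kind]
    count = scheme.counts[kind]
    a = np.asarray(angle, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a).copy()
    defined = ~np.isnan(a)
    if kind != "theta":
        a[defined] = np.vectorize(wrap_dihedral)(a[defined]) if defined.any() else a[defined]
    else:
        if np.any((a[defined] < lo) | (a[defined] > hi)):
            raise ValueError("theta outside [0, 180]")
    idx = np.full(a.shape, MASKED_BIN, dtype=int)
    raw = np.floor((a[defined] - lo) / scheme.width).astype(int)
    # theta == 180 (and any float-edge overshoot) goes to the last bin
    idx[defined] = np.clip(raw, 0, count - 1)
    return int(idx[0]) if scalar else idx


def bin_center(index: int, kind: str, scheme: BinScheme) -> float:
    """Midpoint of a bin in degrees."""
    count = scheme.counts[kind]
    if not 0 <= index < count:
        raise ValueError(f"bin index {index} out of range for {kind} ({count} bins)")
    lo, _ = scheme.ranges[kind]
    return lo + (index + 0.5) * scheme.width


@dataclass
class TargetMatrix:
    """One-hot training targets per residue and angle kind.

    ``onehot[kind]`` is (n, K_kind); rows for undefined angles are all
    zero and flagged False in ``mask[kind]``.
    """

    scheme: BinScheme
    onehot: dict                     # kind -> (n, K) float array
    mask: dict                       # kind -> (n,) bool array

    @property
    def n_residues(self) -> int:
        return len(self.mask["phi"])

    def true_bins(self, kind: str) -> np.ndarray:
        """Bin index per residue (MASKED_BIN where undefined)."""
        bins = np.full(self.n_residues, MASKED_BIN, dtype=int)
        m = self.mask[kind]
        bins[m] = np.argmax(self.onehot[kind][m], axis=1)
        return bins

    def concat(self) -> np.ndarray:
        """(n, total) concatenation in phi/psi/theta/tau block order."""
        return np.concatenate([self.onehot[k] for k in ANGLE_KINDS], axis=1)


@dataclass
class ProbabilityProfile:
    """Per-residue probability vectors over each angle's bins.

    The network output: ``blocks[kind]`` is (n, K_kind) with each row a
    probability distribution (non-negative, summing to 1 within 1e-6).
    """

    scheme: BinScheme
    blocks: dict                     # kind -> (n, K) float array

    @property
    def n_residues(self) -> int:
        return len(self.blocks["phi"])

    def validate(self, atol: float = 1e-6) -> None:
        for k in ANGLE_KINDS:
            block = self.blocks[k]
            if block.shape[1] != self.scheme.counts[k]:
                raise ValueError(f"{k} block has {block.shape[1]} bins, "
                                 f"expected {self.scheme.counts[k]}")
            if np.any(block < -atol):
                raise ValueError(f"negative probabilities in {k} block")
            sums = block.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValueError(f"{k} block rows do not sum to 1")


def encode_targets(angles: AngleTable, scheme: BinScheme) -> TargetMatrix:
    """One-hot encode an angle table; undefined angles give zero rows."""
    n = len(angles)
    onehot = {}
    mask = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        block = np.zeros((n, K))
        m = angles.mask(kind).copy()
        if m.any():
            bins = angle_to_bin(angles.values(kind)[m], kind, scheme)
            block[np.flatnonzero(m), bins] = 1.0
        onehot[kind] = block
        mask[kind] = m
    return TargetMatrix(scheme=scheme, onehot=onehot, mask=mask)


def _check_aligned(pred: ProbabilityProfile, truth: TargetMatrix, kind: str) -> np.ndarray:
    if pred.blocks[kind].shape != truth.onehot[kind].shape:
        raise ValueError("prediction and truth shapes disagree")
    m = truth.mask[kind]
    if not m.any():
        raise UndefinedMetricError(f"no defined residues for {kind}")
    return m


def bin_accuracy(pred: ProbabilityProfile, truth: TargetMatrix, kind: str) -> float:
    """Fraction of defined residues whose argmax bin is the true bin.

    Argmax ties resolve to the lowest bin index.
    """
    m = _check_aligned(pred, truth, kind)
    predicted = np.argmax(pred.blocks[kind][m], axis=1)
    true = np.argmax(truth.onehot[kind][m], axis=1)
    return float(np.mean(predicted == true))


def topk_accuracy(pred: ProbabilityProfile, truth: TargetMatrix, kind: str,
                  k: int = 5) -> float:
    """Fraction of defined residues whose true bin is among the top-k.

    The top-k set is the k highest-probability bins, ties resolved
    toward the lower bin index (a stable sort on descending
    probability).
    """
    K = pred.scheme.counts[kind]
    if not 1 <= k <= K:
        raise ValueError(f"k must be in [1, {K}]")
    m = _check_aligned(pred, truth, kind)
    block = pred.blocks[kind][m]
    true = np.argmax(truth.onehot[kind][m], axis=1)
    # stable argsort of -p keeps lower indices first among ties
    order = np.argsort(-block, axis=1, kind="stable")[:, :k]
    hit = (order == true[:, None]).any(axis=1)
    return float(np.mean(hit))


def merge_to_coarse(pred: ProbabilityProfile, factor: int = 2) -> ProbabilityProfile:
    """Sum neighboring bins to evaluate a fine model on a coarser grid.

    A 5-degree profile merged with factor 2 is directly comparable to a
    model trained at 10 degrees.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    for kind in ANGLE_KINDS:
        if pred.scheme.counts[kind] % factor:
            raise ValueError(f"factor {factor} does not divide "
                             f"{kind}'s {pred.scheme.counts[kind]} bins")
    coarse = make_scheme(pred.scheme.width * factor)
    blocks = {}
    for kind in ANGLE_KINDS:
        block = pred.blocks[kind]
        n, K = block.shape
        blocks[kind] = block.reshape(n, K // factor, factor).sum(axis=2)
    return ProbabilityProfile(scheme=coarse, blocks=blocks)


def profile_to_tsv(profile: ProbabilityProfile) -> str:
    """Tab-delimited profile: residue index, angle kind, bin probabilities.

    Row length varies by kind (72 values for dihedrals, 36 for theta at
    width 5).  A comment line records the bin width.
    """
    lines = [f"# bin_width={profile.scheme.width:g}"]
    for i in range(profile.n_residues):
        for kind in ANGLE_KINDS:
            probs = "\t".join(f"{p:.8g}" for p in profile.blocks[kind][i])
            lines.append(f"{i + 1}\t{kind}\t{probs}")
    return "\n".join(lines) + "\n"


def profile_from_tsv(text: str) -> ProbabilityProfile:
    """Inverse of :func:`profile_to_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    width = 5.0
    if lines and lines[0].startswith("#"):
        for token in lines[0].lstrip("# ").split():
            if token.startswith("bin_width="):
                width = float(token.split("=", 1)[1])
        lines = lines[1:]
    scheme = make_scheme(width)
    rows: dict = {k: {} for k in ANGLE_KINDS}
    for ln in lines:
        parts = ln.split("\t")
        idx, kind = int(parts[0]), parts[1]
        if kind not in ANGLE_KINDS:
            raise ValueError(f"unknown angle kind {kind!r} in profile")
        rows[kind][idx] = np.array([float(p) for p in parts[2:]])
    n = max(max(d) for d in rows.values() if d)
    blocks = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        block = np.full((n, K), 1.0 / K)
        for idx, vec in rows[kind].items():
            if len(vec) != K:
                raise ValueError(f"{kind} row {idx} has {len(vec)} bins, expected {K}")
            block[idx - 1] = vec
        blocks[kind] = block
    profile = ProbabilityProfile(scheme=scheme, blocks=blocks)
    profile.validate(atol=1e-5)
    return profile


def two_state(angle: float, kind: str) -> str:
    """Collapse a dihedral into its two dominant conformational states.

    phi: state 'A' on the closed interval [0, 150]; 'B' elsewhere
    (i.e. (150, 180) and [-180, 0)).  psi: state 'A' on [-100, 60],
    'B' elsewhere.  The split reflects the bimodal Ramachandran
    distribution of each angle.
    """
    if np.isnan(angle):
        raise ValueError("two_state requires a defined angle")
    a = wrap_dihedral(float(angle))
    if kind == "phi":
        return "A" if 0.0 <= a <= 150.0 else "B"
    if kind == "psi":
        return "A" if -100.0 <= a <= 60.0 else "B"
    raise ValueError(f"two-state split is defined for phi/psi only, got {kind!r}")


def two_state_accuracy(pred: ProbabilityProfile, angles: AngleTable, kind: str) -> float:
    """Fraction of residues where the argmax bin's center falls in the
    same two-state region as the true angle."""
    m = angles.mask(kind)
    if not m.any():
        raise UndefinedMetricError(f"no defined residues for {kind}")
    predicted_bins = np.argmax(pred.blocks[kind][m], axis=1)
    centers = [bin_center(b, kind, pred.scheme) for b in predicted_bins]
    true_states = [two_state(a, kind) for a in angles.values(kind)[m]]
    pred_states = [two_state(c, kind) for c in centers]
    return float(np.mean([t == p for t, p in zip(true_states, pred_states)]))
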