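"""Model quality assessment from predicted angle probabilities.

A candidate model structure can be scored without its native structure
by asking how plausible its realized backbone angles are under the
predicted bin distributions.  The pseudo-energy score for one angle
kind is

    PE = sum_i ln( P_i / P0_i ),

where P_i is the predicted probability of the bin the model's residue i
actually occupies and P0_i is the background (expected) probability of
that bin, estimated as pseudocounted bin frequencies over a corpus of
experimental structures.  Higher PE means the model's angles sit in
bins the predictor considers likely beyond chance; PE is exactly zero
when predictions coincide with the background.

For evaluation against known natives, model accuracy is measured after
optimal rigid superposition (Kabsch): the per-residue S-score
1/(1 + (d_i/d0)^2) with d0 = 3 A, and a GDT-style score, the mean over
cutoffs {1, 2, 4, 8} A of the fraction of native residues within the
cutoff.  Ranking power is the per-target Pearson correlation between
PE-score and the GDT-style score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .geometry import ANGLE_KINDS, AngleTable
from .binning import (BinScheme, ProbabilityProfile, UndefinedMetricError,
                      angle_to_bin)

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundDistribution",
    "DecoyScore",
    "estimate_background",
    "pe_score",
    "kabsch_superpose",
    "s_score",
    "gdt_like",
    "rank_models",
    "GDT_CUTOFFS",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
DEFAULT_D0 = 3.0


@dataclass
class BackgroundDistribution:
    """Expected per-bin probability for each angle kind.

    Estimated from an angle corpus with additive (Laplace) smoothing so
    every bin has strictly positive probability when pseudocount > 0.
    """

    scheme: BinScheme
    probs: dict                      # kind -> (K,) probabilities
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for kind in ANGLE_KINDS:
            p = np.asarray(self.probs[kind], dtype=float)
            if len(p) != self.scheme.counts[kind]:
                raise ValueError(f"{kind} background has wrong length")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{kind} background does not sum to 1")
            self.probs[kind] = p

    def to_tsv(self) -> str:
        lines = ["kind\tbin\tprobability"]
        for kind in ANGLE_KINDS:
            for i, p in enumerate(self.probs[kind]):
                lines.append(f"{kind}\t{i}\t{p:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, scheme: BinScheme) -> "BackgroundDistribution":
        probs = {k: np.zeros(scheme.counts[k]) for k in ANGLE_KINDS}
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            kind, idx, p = line.split("\t")
            probs[kind][int(idx)] = float(p)
        return cls(scheme=scheme, probs=probs)


@dataclass
class DecoyScore:
    """Scores for one candidate model."""

    model_id: str
    pe: dict = field(default_factory=dict)       # kind -> PE-score
    pe_combined: float = float("nan")
    gdt: float = float("nan")
    mean_s: float = float("nan")
    per_residue_s: np.ndarray | None = None


def estimate_background(angle_tables, scheme: BinScheme,
                        pseudocount: float = 1.0) -> BackgroundDistribution:
    """Pseudocounted bin frequencies over a corpus of angle tables."""
    tables = list(angle_tables)
    if not tables:
        raise ValueError("empty angle corpus")
    probs = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        counts = np.zeros(K)
        for table in tables:
            m = table.mask(kind)
            if m.any():
                bins = angle_to_bin(table.values(kind)[m], kind, scheme)
                counts += np.bincount(bins, minlength=K)
        total = counts.sum()
        if total == 0 and pseudocount == 0:
            raise ValueError(f"no defined {kind} angles and no pseudocount")
        probs[kind] = (counts + pseudocount) / (total + pseudocount * K)
    return BackgroundDistribution(scheme=scheme, probs=probs,
                                  pseudocount=pseudocount)


def pe_score(profile: ProbabilityProfile, model_angles: AngleTable,
             background: BackgroundDistribution, kind: str,
             eps: float = 1e-8, per_residue_mean: bool = False) -> float:
    """Pseudo-energy of a model under the predicted probabilities.

    Sums ln(P/P0) at the bin each residue of the model occupies,
    skipping residues whose angle is undefined.  Predicted
    probabilities below ``eps`` are floored (with a logged count) so a
    single zero cannot produce -inf.  ``per_residue_mean`` divides by
    the number of contributing residues, useful when comparing models
    of different length.
    """
    if kind not in ANGLE_KINDS:
        raise ValueError(f"unknown angle kind {kind!r}")
    if profile.n_residues != len(model_angles):
        raise ValueError("profile and model angle table lengths disagree")
    m = model_angles.mask(kind)
    if not m.any():
        return 0.0
    bins = angle_to_bin(model_angles.values(kind)[m], kind, profile.scheme)
    p = profile.blocks[kind][np.flatnonzero(m), bins]
    floored = int(np.sum(p < eps))
    if floored:
        logger.info("pe_score(%s): floored %d probabilities below %g",
                    kind, floored, eps)
    p = np.clip(p, eps, None)
    p0 = background.probs[kind][bins]
    total = float(np.sum(np.log(p / p0)))
    return total / m.sum() if per_residue_mean else total


def pe_score_all(profile: ProbabilityProfile, model_angles: AngleTable,
                 background: BackgroundDistribution, **kw) -> dict:
    """PE-score per angle kind plus their sum under 'combined'."""
    scores = {k: pe_score(profile, model_angles, background, k, **kw)
              for k in ANGLE_KINDS}
    scores["combined"] = sum(scores[k] for k in ANGLE_KINDS)
    return scores


def kabsch_superpose(model_ca: np.ndarray, native_ca: np.ndarray):
    """Least-squares rigid superposition of model onto native CA traces.

    Returns (rotation matrix, translation vector, per-residue distances)
    such that ``model @ R.T + t`` best fits the native in the
    least-squares sense; the rotation is always proper (det = +1).
    Requires at least 3 matched residues.
    """
    X = np.asarray(model_ca, dtype=float)
    Y = np.asarray(native_ca, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    if len(X) < 3:
        raise ValueError("superposition needs at least 3 matched residues")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    rot, _ = Rotation.align_vectors(Y - cy, X - cx)
    R = rot.as_matrix()
    t = cy - cx @ R.T
    aligned = X @ R.T + t
    d = np.linalg.norm(aligned - Y, axis=1)
    return R, t, d


def s_score(d: float, d0: float = DEFAULT_D0):
    """Local quality 1/(1 + (d/d0)^2); 1 at d = 0, 0.5 at d = d0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def gdt_like(d: np.ndarray, n_native: int | None = None,
             cutoffs=GDT_CUTOFFS) -> float:
    """Mean fraction of native residues within each distance cutoff.

    ``n_native`` defaults to len(d); passing the full native length
    penalizes unmodeled residues, which contribute to no cutoff.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    n = n_native if n_native is not None else len(d)
    if n < len(d):
        raise ValueError("n_native smaller than number of scored residues")
    return float(np.mean([(d <= c).sum() / n for c in cutoffs]))


def rank_models(decoys, quality_key: str = "gdt",
                pe_key: str = "combined") -> dict:
    """Ranking summary for one target's decoy set.

    Pearson correlation between PE-score and model quality, plus the
    quality of the top-1 model by PE.  Raises ``UndefinedMetricError``
    when either variable has zero variance.
    """
    decoys = list(decoys)
    if len(decoys) < 2:
        raise ValueError("ranking needs at least 2 decoys")
    pe = np.array([d.pe_combined if pe_key == "combined" else d.pe[pe_key]
                   for d in decoys])
    q = np.array([getattr(d, quality_key) for d in decoys])
    if np.ptp(pe) == 0 or np.ptp(q) == 0:
        raise UndefinedMetricError("zero variance in PE or quality scores")
    r = float(pearsonr(pe, q).statistic)
    top1 = int(np.argmax(pe))
    return {
        "pcc": r,
        "top1_id": decoys[top1].model_id,
        "top1_quality": float(q[top1]),
        "best_quality": float(q.max()),
        "n_models": len(decoys),
    }


def rank_targets(per_target_summaries) -> dict:
    """Aggregate ranking summaries across targets (mean/median PCC)."""
    summaries = list(per_target_summaries)
    pccs = np.array([s["pcc"] for s in summaries])
    top1 = np.array([s["top1_quality"] for s in summaries])
    return {
        "mean_pcc": float(pccs.mean()),
        "median_pcc": float(np.median(pccs)),
        "mean_top1_quality": float(top1.mean()),
        "n_targets": len(summaries),
    }
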