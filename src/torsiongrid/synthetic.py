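"""Synthetic inputs for building and testing the whole pipeline.

Every external input the package consumes -- backbone structures,
sequence profiles, structure-property tables, probability profiles with
disorder labels, and decoy model sets -- can be generated here from a
seed, so the pipeline runs end to end without any downloads.  The
generators are deliberately idealized:

* ``build_fragment`` constructs backbones with ideal covalent geometry
  from (phi, psi) recipes per secondary-structure state, so the
  geometry code can be validated by round trip (angles in ->
  coordinates -> angles out).
* ``make_training_set`` emits a deterministic residue-class -> angle-bin
  mapping with small feature noise: a learnable surface on which a
  correctly implemented network must approach perfect bin accuracy.
* ``make_disorder_profiles`` draws concentrated (ordered) vs
  near-uniform (disordered) bin distributions with a separation dial;
  at separation 0 the two classes are identically distributed.
* ``make_decoys`` perturbs a native structure with Gaussian coordinate
  noise of graded magnitude plus a random rigid motion, producing a
  quality ladder for superposition and ranking code.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ANGLE_KINDS, AngleTable, BackboneChain
from .binning import (BinScheme, ProbabilityProfile, TargetMatrix,
                      angle_to_bin, bin_center, make_scheme)
from .features import M1_WINDOW

__all__ = [
    "IDEAL_GEOMETRY",
    "SS_ANGLES",
    "build_fragment",
    "make_training_set",
    "make_disorder_profiles",
    "make_decoys",
    "place_atom",
]

#: Ideal backbone covalent geometry (bond lengths in Angstrom, angles in
#: degrees) used for chain building: Engh-Huber-style standard values.
IDEAL_GEOMETRY = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "omega": 180.0,
}

#: (phi, psi) recipes per secondary-structure state.
SS_ANGLES = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates.

    d is at distance ``bond`` from c, with angle(b, c, d) = ``angle_deg``
    and dihedral(a, b, c, d) = ``torsion_deg`` (standard NeRF
    construction).
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_fragment(ss: str, seed: int = 0) -> BackboneChain:
    """Build an ideal-geometry backbone from a secondary-structure string.

    'H' residues get (phi, psi) = (-57, -47), 'E' gets (-120, 120) and
    'C' gets seeded random coil angles.  Recomputing angles from the
    returned coordinates recovers the generating values (interior
    residues, well within 0.5 degrees).
    """
    if len(ss) < 4:
        raise ValueError("fragment needs at least 4 residues")
    bad = set(ss) - {"H", "E", "C"}
    if bad:
        raise ValueError(f"invalid secondary-structure characters: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    g = IDEAL_GEOMETRY

    def angles_for(state: str) -> tuple:
        if state in SS_ANGLES:
            return SS_ANGLES[state]
        # generic coil: spread over the allowed Ramachandran regions
        phi = rng.uniform(-160.0, -50.0)
        psi = rng.uniform(-60.0, 160.0)
        return phi, psi

    L = len(ss)
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))

    # first residue in a canonical frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["n_ca"], 0.0, 0.0)
    ang = math.radians(g["angle_n_ca_c"])
    C[0] = CA[0] + g["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])

    phis, psis = zip(*(angles_for(s) for s in ss))
    for i in range(1, L):
        # psi of residue i-1 positions N_i; omega positions CA_i;
        # phi of residue i positions C_i
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          g["c_n"], g["angle_ca_c_n"], psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           g["n_ca"], g["angle_c_n_ca"], g["omega"])
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          g["ca_c"], g["angle_n_ca_c"], phis[i])

    return BackboneChain(
        residue_ids=np.arange(1, L + 1),
        residue_names=["ALA"] * L,
        coords_N=N, coords_CA=CA, coords_C=C,
        chain_id="A",
    )


def _class_bins(n_classes: int, scheme: BinScheme) -> dict:
    """Deterministic class -> bin assignment, distinct bins per angle."""
    bins = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        stride = max(K // n_classes, 1)
        bins[kind] = [(2 + c * stride) % K for c in range(n_classes)]
    return bins


def make_training_set(n_chains: int, chain_len: int, seed: int = 0,
                      n_classes: int = 8, noise: float = 0.05,
                      feature_dim: int = 27 * M1_WINDOW,
                      scheme: BinScheme | None = None):
    """A learnable synthetic dataset: residue classes map to fixed bins.

    Each residue is assigned a class uniformly at random; each class
    deterministically maps to one (phi, psi, theta, tau) quadruple
    placed at a bin center, with distinct bins across classes.
    Features are a one-hot class indicator embedded in an M1-sized
    vector plus Gaussian noise of scale ``noise``.  Returns
    (features, targets, chain_ids).
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    scheme = scheme or make_scheme(5.0)
    rng = np.random.default_rng(seed)
    class_bins = _class_bins(n_classes, scheme)
    n = n_chains * chain_len
    classes = rng.integers(0, n_classes, size=n)
    chain_ids = np.repeat(np.arange(n_chains), chain_len)

    X = rng.normal(0.0, noise, size=(n, feature_dim)) if noise > 0 else \
        np.zeros((n, feature_dim))
    X[np.arange(n), classes] += 1.0

    onehot = {}
    mask = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        block = np.zeros((n, K))
        bins = np.array(class_bins[kind])[classes]
        block[np.arange(n), bins] = 1.0
        onehot[kind] = block
        mask[kind] = np.ones(n, dtype=bool)
    targets = TargetMatrix(scheme=scheme, onehot=onehot, mask=mask)
    return X, targets, chain_ids


def _segment_labels(n_res: int, frac_disordered: float,
                    rng: np.random.Generator,
                    mean_len: int = 30) -> np.ndarray:
    """Contiguous-segment disorder labels hitting ~frac_disordered."""
    labels = np.zeros(n_res, dtype=int)
    if frac_disordered <= 0:
        return labels
    if frac_disordered >= 1:
        return np.ones(n_res, dtype=int)
    target = int(round(frac_disordered * n_res))
    placed = 0
    attempts = 0
    while placed < target and attempts < 200:
        attempts += 1
        length = max(5, int(rng.geometric(1.0 / mean_len)))
        length = min(length, target - placed + 5)
        start = int(rng.integers(0, max(n_res - length, 1)))
        segment = slice(start, start + length)
        new = int(np.sum(labels[segment] == 0))
        if new == 0:
            continue
        labels[segment] = 1
        placed += new
    return labels


def make_disorder_profiles(n_res: int, frac_disordered: float = 0.3,
                           separation: float = 1.0, seed: int = 0,
                           scheme: BinScheme | None = None):
    """Probability profiles with segment-structured disorder labels.

    Ordered residues draw bin distributions from a symmetric Dirichlet
    whose concentration interpolates from the disordered value (at
    separation 0, the classes are identically distributed) down to a
    spiky low-concentration regime (at separation 1, ordered rows are
    strongly peaked and their entropy is far below the disordered
    rows').  Disordered residues always draw near-uniform rows.
    Returns (profile, labels).
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    scheme = scheme or make_scheme(5.0)
    rng = np.random.default_rng(seed)
    labels = _segment_labels(n_res, frac_disordered, rng)

    alpha_disordered = 20.0
    alpha_ordered = (1.0 - separation) * alpha_disordered + separation * 0.1

    blocks = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        rows = np.empty((n_res, K))
        for i in range(n_res):
            a = alpha_disordered if labels[i] else alpha_ordered
            rows[i] = rng.dirichlet(np.full(K, a))
        blocks[kind] = rows
    return ProbabilityProfile(scheme=scheme, blocks=blocks), labels


def make_decoys(native: BackboneChain, sigmas, n_per_sigma: int = 5,
                seed: int = 0):
    """Noise-graded decoy models of a native structure.

    Each decoy applies isotropic Gaussian noise of scale sigma to every
    backbone atom, then a uniformly random rotation and a random
    translation (so downstream code must actually superpose).  Returns
    a list of (decoy_chain, sigma) pairs.
    """
    from scipy.spatial.transform import Rotation

    sigmas = list(sigmas)
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    rng = np.random.default_rng(seed)
    decoys = []
    for sigma in sigmas:
        for _ in range(n_per_sigma):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-20.0, 20.0, size=3)
            chain = BackboneChain(
                residue_ids=native.residue_ids.copy(),
                residue_names=list(native.residue_names),
                coords_N=(native.coords_N + rng.normal(0, sigma, native.coords_N.shape)) @ R.T + t,
                coords_CA=(native.coords_CA + rng.normal(0, sigma, native.coords_CA.shape)) @ R.T + t,
                coords_C=(native.coords_C + rng.normal(0, sigma, native.coords_C.shape)) @ R.T + t,
                chain_id=native.chain_id,
            )
            decoys.append((chain, float(sigma)))
    return decoys


def profile_from_angles(angles: AngleTable, scheme: BinScheme | None = None,
                        kernel_sigma_deg: float = 12.0,
                        uniform_floor: float = 0.02) -> ProbabilityProfile:
    """An idealized predictor output concentrated at a structure's bins.

    Probability mass is placed as a Gaussian kernel (circular for
    dihedrals, truncated for theta) centered on each residue's true
    angle, mixed with a small uniform floor -- mimicking a confident
    but not needle-sharp predictor.  Residues with undefined angles get
    uniform rows.  Useful as a stand-in for a trained predictor when
    testing downstream consumers.
    """
    scheme = scheme or make_scheme(5.0)
    n = len(angles)
    blocks = {}
    for kind in ANGLE_KINDS:
        K = scheme.counts[kind]
        lo, hi = scheme.ranges[kind]
        centers = np.array([bin_center(i, kind, scheme) for i in range(K)])
        rows = np.full((n, K), 1.0 / K)
        m = angles.mask(kind)
        for i in np.flatnonzero(m):
            a = angles.values(kind)[i]
            delta = centers - a
            if kind != "theta":  # circular distance
                delta = (delta + 180.0) % 360.0 - 180.0
            kernel = np.exp(-0.5 * (delta / kernel_sigma_deg) ** 2)
            kernel /= kernel.sum()
            rows[i] = (1.0 - uniform_floor) * kernel + uniform_floor / K
        blocks[kind] = rows
    return ProbabilityProfile(scheme=scheme, blocks=blocks)
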