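"""Backbone geometry: PDB parsing and the four backbone angles.

A protein backbone conformation is described here by four per-residue
angles: the classic Ramachandran dihedrals phi (about N-CA) and psi
(about CA-C), plus two coarser Calpha-trace angles -- theta, the planar
angle over three consecutive CA atoms, and tau, the dihedral over four
consecutive CA atoms (about the CA_i - CA_{i+1} virtual bond).  The
CA-trace angles carry longer-range information than phi/psi because
they span 3-4 residues.

Angle conventions
-----------------
Dihedrals follow the IUPAC sign convention (positive = clockwise
rotation viewed from the second toward the third point) and live on the
half-open interval [-180, 180): an exact +180 wraps to -180 so that
fixed-width binning is unambiguous.  Planar angles live on [0, 180].
Undefined angles (chain termini, chain breaks, degenerate geometry) are
reported as NaN with a False entry in the corresponding mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneChain",
    "AngleTable",
    "PdbParseError",
    "EmptyChainError",
    "parse_backbone",
    "write_backbone_pdb",
    "dihedral",
    "planar_angle",
    "compute_angles",
    "ANGLE_KINDS",
]

ANGLE_KINDS = ("phi", "psi", "theta", "tau")

#: CA-CA distance beyond which two consecutive residues are treated as a
#: chain break (peptide-bonded CA pairs sit near 3.8 A).
CA_BREAK_DISTANCE = 4.5


class PdbParseError(ValueError):
    """A PDB ATOM record could not be interpreted."""


class EmptyChainError(ValueError):
    """No complete backbone residues were found for the requested chain."""


@dataclass
class BackboneChain:
    """Ordered N/CA/C coordinates for one chain.

    Residues are indexed 0..L-1 in file order; ``residue_ids`` keeps the
    original author-assigned residue numbers so that gaps can be
    detected downstream.
    """

    residue_ids: np.ndarray          # (L,) int
    residue_names: list[str]         # 3-letter codes
    coords_N: np.ndarray             # (L, 3) float, Angstrom
    coords_CA: np.ndarray
    coords_C: np.ndarray
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        for name in ("coords_N", "coords_CA", "coords_C"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (L, 3), got {arr.shape}")
            setattr(self, name, arr)
        L = len(self.residue_ids)
        if not (len(self.residue_names) == L
                == len(self.coords_N) == len(self.coords_CA) == len(self.coords_C)):
            raise ValueError("inconsistent per-residue array lengths")
        if L < 1:
            raise EmptyChainError("backbone chain must contain at least one residue")
        for name in ("coords_N", "coords_CA", "coords_C"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite coordinates in {name}")

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class AngleTable:
    """Per-residue backbone angles in degrees with defined-ness masks.

    ``phi``/``psi``/``tau`` are dihedrals in [-180, 180); ``theta`` is a
    planar angle in [0, 180].  Entries are NaN wherever the matching
    mask is False.
    """

    phi: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    tau: np.ndarray
    defined_phi: np.ndarray
    defined_psi: np.ndarray
    defined_theta: np.ndarray
    defined_tau: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)

    def values(self, kind: str) -> np.ndarray:
        if kind not in ANGLE_KINDS:
            raise ValueError(f"unknown angle kind {kind!r}")
        return getattr(self, kind)

    def mask(self, kind: str) -> np.ndarray:
        if kind not in ANGLE_KINDS:
            raise ValueError(f"unknown angle kind {kind!r}")
        return getattr(self, f"defined_{kind}")


# ---------------------------------------------------------------------------
# PDB I/O
#
# Fixed-width ATOM records per the v3.3 format description.  A dedicated
# reader (rather than a general structure library) is used because the
# contract here is column-level: first-altloc selection, insertion-coded
# residues kept in file order, and parse errors that name the offending
# line.  Only N/CA/C of a single chain are of interest.
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C")


def parse_backbone(pdb_text: str, chain: str = "A") -> BackboneChain:
    """Extract N/CA/C coordinates of one chain from PDB-format text.

    Only the first MODEL is read.  For atoms with alternate locations
    the first-seen altloc is kept.  Residues missing any of N, CA or C
    are dropped with a logged warning.

    Raises
    ------
    PdbParseError
        If an ATOM record is malformed (the message names the line).
    EmptyChainError
        If no complete backbone residue remains.
    """
    residues: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    order: list[tuple[int, str]] = []
    names: dict[tuple[int, str], str] = {}
    in_first_model = True
    model_seen = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if model_seen:
                in_first_model = False
            model_seen = True
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if record != "ATOM" or not in_first_model:
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: ATOM record too short ({len(line)} chars)")
        atom_name = line[12:16].strip()
        if atom_name not in _BACKBONE_ATOMS:
            continue
        if line[21].strip() != chain:
            continue
        altloc = line[16]
        try:
            res_id = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError as exc:
            raise PdbParseError(f"line {lineno}: cannot parse ATOM fields: {exc}") from exc
        icode = line[26]
        key = (res_id, icode)
        if key not in residues:
            residues[key] = {}
            order.append(key)
            names[key] = line[17:20].strip()
        if atom_name in residues[key] and altloc not in (" ", "A"):
            continue  # first altloc wins
        residues[key].setdefault(atom_name, xyz)

    kept = [k for k in order if all(a in residues[k] for a in _BACKBONE_ATOMS)]
    dropped = [k for k in order if k not in set(kept)]
    for res_id, icode in dropped:
        logger.warning(
            "chain %s residue %d%s missing backbone atoms; dropped",
            chain, res_id, icode.strip(),
        )
    if not kept:
        raise EmptyChainError(f"no complete backbone residues for chain {chain!r}")

    return BackboneChain(
        residue_ids=np.array([k[0] for k in kept]),
        residue_names=[names[k] for k in kept],
        coords_N=np.array([residues[k]["N"] for k in kept]),
        coords_CA=np.array([residues[k]["CA"] for k in kept]),
        coords_C=np.array([residues[k]["C"] for k in kept]),
        chain_id=chain,
    )


def write_backbone_pdb(chain: BackboneChain) -> str:
    """Serialize a backbone chain as minimal PDB ATOM records."""
    lines = []
    serial = 1
    for i in range(len(chain)):
        for atom, coords in (("N", chain.coords_N), ("CA", chain.coords_CA),
                             ("C", chain.coords_C)):
            x, y, z = coords[i]
            name_field = f" {atom:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name_field}{' '}{chain.residue_names[i]:>3s} "
                f"{chain.chain_id}{chain.residue_ids[i]:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def angle_table_to_tsv(angles: "AngleTable") -> str:
    """Tab-delimited angle table: residue, phi, psi, theta, tau (NA = undefined)."""
    lines = ["residue\tphi\tpsi\ttheta\ttau"]
    for i in range(len(angles)):
        vals = []
        for kind in ANGLE_KINDS:
            v = angles.values(kind)[i]
            vals.append("NA" if np.isnan(v) else f"{v:.4f}")
        lines.append("\t".join([str(i + 1)] + vals))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Angle primitives
# ---------------------------------------------------------------------------

_DEGENERACY_TOL = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees on [-180, 180).

    Computed by projecting the two outer bonds onto the plane normal to
    the central bond p2->p3 and taking the signed angle between the
    projections.  Collinear degeneracies return NaN.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < _DEGENERACY_TOL:
        return math.nan
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _DEGENERACY_TOL or np.linalg.norm(w) < _DEGENERACY_TOL:
        return math.nan
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return wrap_dihedral(ang)


def wrap_dihedral(angle_deg: float) -> float:
    """Map any angle onto [-180, 180), with +180 wrapping to -180."""
    wrapped = (angle_deg + 180.0) % 360.0 - 180.0
    # modulo can return +180.0 - eps artifacts but never 180 itself;
    # guard against -0.0 for tidy output
    return wrapped + 0.0


def planar_angle(p1, p2, p3) -> float:
    """Bond angle at p2 in degrees on [0, 180]; NaN for zero-length arms.

    Uses atan2(|u x v|, u.v), which is numerically stable near 0 and 180.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    if np.linalg.norm(u) < _DEGENERACY_TOL or np.linalg.norm(v) < _DEGENERACY_TOL:
        return math.nan
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return math.degrees(math.atan2(cross, dot))


def _connectivity(chain: BackboneChain) -> np.ndarray:
    """Boolean per consecutive pair: True when i and i+1 are bonded.

    A pair is disconnected when the residue numbering jumps or the CA-CA
    distance exceeds ``CA_BREAK_DISTANCE``; angles spanning the break
    are then left undefined.
    """
    L = len(chain)
    if L < 2:
        return np.zeros(0, dtype=bool)
    gaps = np.diff(chain.residue_ids)
    dists = np.linalg.norm(np.diff(chain.coords_CA, axis=0), axis=1)
    return (gaps <= 1) & (dists <= CA_BREAK_DISTANCE)


def compute_angles(chain: BackboneChain, tau_anchor: int = 0) -> AngleTable:
    """Compute phi/psi/theta/tau for every residue of a chain.

    phi_i   = dihedral(C_{i-1}, N_i, CA_i, C_i)
    psi_i   = dihedral(N_i, CA_i, C_i, N_{i+1})
    theta_i = planar_angle(CA_{i-1}, CA_i, CA_{i+1})
    tau_i   = dihedral(CA_{i-1}, CA_i, CA_{i+1}, CA_{i+2})

    ``tau_anchor`` shifts the residue tau is assigned to: with the
    default 0 the dihedral over CA_{i-1}..CA_{i+2} belongs to residue i
    (undefined at the first residue and the last two); ``tau_anchor=1``
    assigns it to residue i+1 instead.  The underlying quantity -- the
    rotation about the CA_i - CA_{i+1} virtual bond -- sits between two
    residues, so the assignment is a convention.
    """
    if tau_anchor not in (0, 1):
        raise ValueError("tau_anchor must be 0 or 1")
    L = len(chain)
    N, CA, C = chain.coords_N, chain.coords_CA, chain.coords_C
    conn = _connectivity(chain)

    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    theta = np.full(L, np.nan)
    tau = np.full(L, np.nan)

    for i in range(L):
        if i >= 1 and conn[i - 1]:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i + 1 < L and conn[i]:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
        if 1 <= i < L - 1 and conn[i - 1] and conn[i]:
            theta[i] = planar_angle(CA[i - 1], CA[i], CA[i + 1])
        j = i - tau_anchor  # index of CA_{i-1} quadruple start offset
        if 1 <= j and j + 2 < L and conn[j - 1] and conn[j] and conn[j + 1]:
            tau[i] = dihedral(CA[j - 1], CA[j], CA[j + 1], CA[j + 2])

    return AngleTable(
        phi=phi, psi=psi, theta=theta, tau=tau,
        defined_phi=~np.isnan(phi),
        defined_psi=~np.isnan(psi),
        defined_theta=~np.isnan(theta),
        defined_tau=~np.isnan(tau),
    )
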