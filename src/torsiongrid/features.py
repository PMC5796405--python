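"""Per-residue input features for the grid predictor.

Two feature sets are supported, mirroring the two model flavors:

* M1 -- sequence-only: 7 physico-chemical amino-acid properties plus the
  20 PSSM substitution scores per residue (27 values), concatenated over
  a sliding window of 13 residues (6 on each side) -> 351 features.
* M2 -- sequence + predicted structure properties: the 20 PSSM scores
  plus an 18-column per-residue structure-property table (3 secondary-
  structure probabilities, RSA, sin/cos of phi/psi/theta/tau, two
  contact numbers, four half-sphere exposures), i.e. 38 values per
  residue, over a window of 7 (3 on each side) -> 266 features.

Windows are zero-padded past the chain termini.  PSSM log-odds scores
are squashed by a logistic 1/(1+e^-x) by default so every input lies in
[0, 1]; raw and z-score alternatives are available.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import ANGLE_KINDS, AngleTable

__all__ = [
    "PssmProfile",
    "StructPropertyTable",
    "FeatureMatrix",
    "PssmParseError",
    "read_pssm",
    "write_pssm",
    "aa_properties",
    "aa_property_table",
    "build_m1",
    "build_m2",
    "props_from_angles",
    "read_fasta",
    "STRUCT_COLUMNS",
    "M1_WINDOW",
    "M2_WINDOW",
]

M1_WINDOW = 13
M2_WINDOW = 7

#: Column order of the 18-value structure-property table.
STRUCT_COLUMNS = (
    "ss_helix", "ss_sheet", "ss_coil",
    "rsa",
    "sin_phi", "cos_phi", "sin_psi", "cos_psi",
    "sin_theta", "cos_theta", "sin_tau", "cos_tau",
    "cn_ca", "cn_cb",
    "hse_b_up", "hse_b_down", "hse_a_up", "hse_a_down",
)

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST column order


class PssmParseError(ValueError):
    """An ASCII PSSM file could not be interpreted."""


@dataclass
class PssmProfile:
    """A sequence profile: per-residue 20 substitution log-odds scores."""

    sequence: str
    scores: np.ndarray               # (L, 20), PSI-BLAST column order

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"scores must be (L, 20), got {self.scores.shape}")
        if len(self.sequence) != len(self.scores):
            raise ValueError("sequence length does not match score rows")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PSSM scores")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class StructPropertyTable:
    """Per-residue predicted structure properties (18 columns).

    Layout follows ``STRUCT_COLUMNS``.  May be read from the output of a
    secondary-structure/accessibility predictor or generated
    synthetically; this package never runs an external predictor.
    """

    values: np.ndarray               # (L, 18)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(STRUCT_COLUMNS):
            raise ValueError(
                f"expected (L, {len(STRUCT_COLUMNS)}) values, got {self.values.shape}")
        ss = self.values[:, :3]
        if np.any((ss < -1e-9) | (ss > 1 + 1e-9)):
            raise ValueError("secondary-structure probabilities outside [0, 1]")
        for pair in ((4, 5), (6, 7), (8, 9), (10, 11)):
            norms = np.hypot(self.values[:, pair[0]], self.values[:, pair[1]])
            if np.any(norms > 1 + 1e-6):
                raise ValueError("sin/cos pair exceeds unit norm")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.values, columns=list(STRUCT_COLUMNS))
        df.insert(0, "residue", np.arange(1, len(df) + 1))
        return df.to_csv(sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, text: str) -> "StructPropertyTable":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        missing = [c for c in STRUCT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"structure-property table missing columns: {missing}")
        return cls(values=df[list(STRUCT_COLUMNS)].to_numpy(dtype=float))


@dataclass
class FeatureMatrix:
    """Windowed per-residue features with column metadata."""

    values: np.ndarray               # (L, D)
    columns: list

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match feature width")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# PSSM I/O (PSI-BLAST -out_ascii_pssm layout)
# ---------------------------------------------------------------------------

def read_pssm(text: str) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM.

    Uses the first 20 (log-odds) columns; the 20 weighted-percentage
    columns and the information/weight footer columns are ignored.  A
    missing footer is tolerated; a garbled body row raises
    ``PssmParseError`` naming the line.
    """
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and tokens[:20] == list(_AA_ORDER):
            header_idx = i
            break
    if header_idx is None:
        raise PssmParseError("no PSSM column header (A R N D ...) found")

    sequence = []
    rows = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break  # blank line ends the body; footer follows
        if not tokens[0].isdigit():
            break  # footer (K, Lambda, ...) reached
        if len(tokens) < 22 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise PssmParseError(f"line {lineno}: malformed PSSM row")
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PssmParseError(f"line {lineno}: non-numeric score: {exc}") from exc
        sequence.append(tokens[1].upper())
        rows.append(scores)
    if not rows:
        raise PssmParseError("PSSM contains no residue rows")
    return PssmProfile(sequence="".join(sequence), scores=np.array(rows))


def write_pssm(profile: PssmProfile) -> str:
    """Serialize a profile in the PSI-BLAST ASCII PSSM layout.

    The percentage columns are written as zeros; only the log-odds block
    carries information.  Useful for fixtures and round-trip tests.
    """
    out = ["", "Last position-specific scoring matrix computed, weighted observed "
              "percentages rounded down, information per position, and relative "
              "weight of gapless real matches to pseudocounts"]
    header = "           " + "".join(f"{a:>4s}" for a in _AA_ORDER) * 2
    out.append(header)
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        scores = "".join(f"{int(round(v)):>4d}" for v in row)
        pcts = "".join(f"{0:>4d}" for _ in range(20))
        out.append(f"{i:>5d} {aa}  {scores}{pcts}  0.00 0.00")
    out.append("")
    return "\n".join(out) + "\n"


def transform_pssm(scores: np.ndarray, mode: str = "logistic") -> np.ndarray:
    """Squash raw log-odds scores: 'logistic' (default), 'raw' or 'zscore'."""
    if mode == "raw":
        return np.asarray(scores, dtype=float)
    if mode == "logistic":
        return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=float)))
    if mode == "zscore":
        s = np.asarray(scores, dtype=float)
        sd = s.std()
        return (s - s.mean()) / (sd if sd > 0 else 1.0)
    raise ValueError(f"unknown PSSM transform {mode!r}")


# ---------------------------------------------------------------------------
# Amino-acid property table
# ---------------------------------------------------------------------------

_PROPERTY_CACHE: dict = {}


def aa_property_table() -> pd.DataFrame:
    """The shipped 7-property table, indexed by 1-letter code."""
    if "table" not in _PROPERTY_CACHE:
        path = resources.files("torsiongrid.data").joinpath("aa_properties.tsv")
        df = pd.read_csv(io.StringIO(path.read_text()), sep="\t", comment="#")
        _PROPERTY_CACHE["table"] = df.set_index("aa")
    return _PROPERTY_CACHE["table"]


def aa_properties(residue: str) -> np.ndarray:
    """Seven physico-chemical values for a 1-letter residue code.

    'X' (unknown residue) maps to the column-wise mean over the 20
    standard residues.
    """
    table = aa_property_table()
    code = residue.upper()
    if code == "X":
        return table.to_numpy().mean(axis=0)
    if code not in table.index:
        raise KeyError(f"unknown residue code {residue!r}")
    return table.loc[code].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Window assembly
# ---------------------------------------------------------------------------

def _windowed(base: np.ndarray, window: int) -> np.ndarray:
    """Concatenate each row with its +-half window, zero-padded at ends."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    L, D = base.shape
    half = window // 2
    padded = np.zeros((L + 2 * half, D))
    padded[half:half + L] = base
    return np.concatenate([padded[i:i + L] for i in range(window)], axis=1)


def _window_columns(names: list, window: int) -> list:
    half = window // 2
    return [f"{name}@{off:+d}" for off in range(-half, half + 1) for name in names]


def build_m1(pssm: PssmProfile, window: int = M1_WINDOW,
             pssm_transform: str = "logistic") -> FeatureMatrix:
    """Sequence-only features: (7 properties + 20 PSSM) x window = 351."""
    if len(pssm) == 0:
        raise ValueError("empty profile")
    props = np.array([aa_properties(aa) for aa in pssm.sequence])
    scores = transform_pssm(pssm.scores, pssm_transform)
    base = np.concatenate([props, scores], axis=1)
    names = list(aa_property_table().columns) + [f"pssm_{a}" for a in _AA_ORDER]
    return FeatureMatrix(values=_windowed(base, window),
                         columns=_window_columns(names, window))


def build_m2(pssm: PssmProfile, props: StructPropertyTable,
             window: int = M2_WINDOW,
             pssm_transform: str = "logistic") -> FeatureMatrix:
    """Sequence + structure-property features: (20 + 18) x window = 266."""
    if len(pssm) != len(props):
        raise ValueError(
            f"PSSM ({len(pssm)}) and property table ({len(props)}) lengths differ")
    scores = transform_pssm(pssm.scores, pssm_transform)
    base = np.concatenate([scores, props.values], axis=1)
    names = [f"pssm_{a}" for a in _AA_ORDER] + list(STRUCT_COLUMNS)
    return FeatureMatrix(values=_windowed(base, window),
                         columns=_window_columns(names, window))


def props_from_angles(angles: AngleTable,
                      ss_probs: np.ndarray | None = None,
                      rsa: np.ndarray | None = None,
                      cn: np.ndarray | None = None,
                      hse: np.ndarray | None = None) -> StructPropertyTable:
    """Assemble a structure-property table from an angle table plus extras.

    sin/cos are computed from degrees; undefined angles contribute
    (0, 0), a neutral off-circle point that flags missingness.  Omitted
    extras default to zeros (SS probabilities to the uniform 1/3).
    """
    L = len(angles)
    values = np.zeros((L, len(STRUCT_COLUMNS)))
    values[:, :3] = ss_probs if ss_probs is not None else 1.0 / 3.0
    if rsa is not None:
        values[:, 3] = rsa
    for j, kind in enumerate(ANGLE_KINDS):
        rad = np.deg2rad(angles.values(kind))
        m = angles.mask(kind)
        values[m, 4 + 2 * j] = np.sin(rad[m])
        values[m, 5 + 2 * j] = np.cos(rad[m])
    if cn is not None:
        values[:, 12:14] = cn
    if hse is not None:
        values[:, 14:18] = hse
    return StructPropertyTable(values=values)


def read_fasta(text: str) -> dict:
    """FASTA reader: mapping of record id -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(io.StringIO(text), "fasta")}
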