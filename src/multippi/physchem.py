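"""Physicochemical sequence features: descriptor table and auto-covariance encoding.

Each of the 20 standard amino acids carries six physicochemical descriptors —
net charge index of side chains (NCISC), side-chain volume (VSC), polarity
(P1), solvent-accessible surface area (SASA), hydrophobicity (H) and
polarizability (P2).  The descriptor columns are standardized to zero mean and
unit population standard deviation over the 20 amino acids, a protein sequence
is mapped to a 6-track numeric signal, and the auto-covariance (AC) of each
track at lags 1..D summarizes residue-residue coupling at a distance.  With
the default D = 30 every protein becomes a 30 x 6 = 180-dimensional vector.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "DESCRIPTORS",
    "AMINO_ACIDS",
    "PhysChemTable",
    "ProteinSequence",
    "ACProfile",
    "UnknownResidueError",
    "SequenceTooShortError",
    "load_physchem_table",
    "normalize_table",
    "encode_sequence",
    "read_fasta",
    "write_feature_tsv",
    "read_feature_tsv",
]

DESCRIPTORS = ("NCISC", "VSC", "P1", "SASA", "H", "P2")

# One-letter codes in the order the raw descriptor table is transcribed.
AMINO_ACIDS = ("C", "D", "E", "I", "G", "L", "V", "M", "W", "N",
               "H", "Q", "A", "R", "Y", "P", "K", "S", "T", "F")

# Raw descriptor values per amino acid: NCISC, VSC, P1, SASA, H, P2.
_RAW = np.array([
    [-0.03661, 44.6, 5.5, 1.461, 0.29, 0.128],    # Cys
    [-0.02382, 40.0, 13.0, 1.587, -0.90, 0.105],  # Asp
    [0.006802, 62.0, 12.3, 1.862, -0.74, 0.151],  # Glu
    [0.021631, 93.5, 5.2, 1.810, 1.38, 0.186],    # Ile
    [0.179052, 0.0, 9.0, 0.881, 0.48, 0.0],       # Gly
    [0.051672, 93.5, 4.9, 1.931, 1.06, 0.186],    # Leu
    [0.057004, 71.5, 5.9, 1.645, 1.08, 0.140],    # Val
    [0.002683, 94.1, 5.7, 2.034, 0.64, 0.221],    # Met
    [0.037977, 145.5, 5.4, 2.663, 0.81, 0.409],   # Trp
    [0.005392, 58.7, 11.6, 1.655, -0.78, 0.134],  # Asn
    [-0.01069, 79.0, 10.4, 2.025, -0.40, 0.230],  # His
    [0.049211, 80.7, 10.5, 1.932, -0.85, 0.180],  # Gln
    [0.007187, 27.5, 8.1, 1.181, 0.62, 0.046],    # Ala
    [0.043587, 105.0, 10.5, 2.560, -2.53, 0.291], # Arg
    [0.023599, 117.3, 6.2, 2.368, 0.26, 0.298],   # Tyr
    [0.239531, 41.9, 8.0, 1.468, 0.12, 0.131],    # Pro
    [0.017708, 100.0, 11.3, 2.258, -1.50, 0.219], # Lys
    [0.004627, 29.3, 9.2, 1.298, -0.18, 0.062],   # Ser
    [0.003352, 51.3, 8.6, 1.525, -0.05, 0.108],   # Thr
    [0.037552, 115.5, 5.2, 2.228, 1.19, 0.290],   # Phe
], dtype=np.float64)


class UnknownResidueError(ValueError):
    """A residue outside the 20-letter alphabet under the ``strict`` policy."""


class SequenceTooShortError(ValueError):
    """Effective sequence length too small for the requested maximum lag."""


@dataclass
class PhysChemTable:
    """The 20 x 6 amino-acid descriptor matrix, raw and standardized."""

    amino_acids: tuple = AMINO_ACIDS
    descriptors: tuple = DESCRIPTORS
    raw: np.ndarray = field(default_factory=lambda: _RAW.copy())
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def row_index(self, residue: str) -> int:
        return self.amino_acids.index(residue)

    def value(self, residue: str, descriptor: str, normalized: bool = False) -> float:
        mat = self.normalized if normalized else self.raw
        if mat is None:
            raise ValueError("table not normalized yet")
        return float(mat[self.row_index(residue), self.descriptors.index(descriptor)])


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ACProfile:
    """Auto-covariance feature vector for one protein.

    ``values`` is descriptor-major with lag fastest: the entry for descriptor
    j (0-based) at lag d (1-based) sits at index ``j * max_lag + (d - 1)``.
    """

    protein_id: str
    max_lag: int
    n_descriptors: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.max_lag * self.n_descriptors,):
            raise ValueError("AC vector length must be max_lag * n_descriptors")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite AC values for protein {self.protein_id!r}")


def load_physchem_table() -> PhysChemTable:
    """Return the compiled-in raw descriptor table (normalization not applied)."""
    return PhysChemTable()


def normalize_table(table: PhysChemTable) -> PhysChemTable:
    """Standardize each descriptor column to zero mean, unit population SD.

    The population convention (divisor 20, the number of amino acids) is used
    for the standard deviation.
    """
    means = table.raw.mean(axis=0)
    sds = table.raw.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [table.descriptors[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"descriptor column(s) with zero spread: {bad}")
    return PhysChemTable(
        amino_acids=table.amino_acids,
        descriptors=table.descriptors,
        raw=table.raw,
        means=means,
        sds=sds,
        normalized=(table.raw - means) / sds,
    )


def _residue_matrix(seq: ProteinSequence, table: PhysChemTable,
                    residue_policy: str) -> np.ndarray:
    """Map residues to rows of the normalized table, applying the policy.

    ``mean_impute`` maps non-standard residues to the standardized column mean
    (all zeros); ``drop`` removes them before the length is measured; ``strict``
    raises.
    """
    if table.normalized is None:
        table = normalize_table(table)
    index = {aa: i for i, aa in enumerate(table.amino_acids)}
    rows = []
    for ch in seq.residues.upper():
        i = index.get(ch)
        if i is not None:
            rows.append(table.normalized[i])
        elif residue_policy == "strict":
            raise UnknownResidueError(
                f"unknown residue {ch!r} in protein {seq.id!r}")
        elif residue_policy == "mean_impute":
            rows.append(np.zeros(len(table.descriptors)))
        elif residue_policy == "drop":
            continue
        else:
            raise ValueError(f"unknown residue_policy {residue_policy!r}")
    return np.asarray(rows, dtype=np.float64).reshape(-1, len(table.descriptors))


def encode_sequence(seq: ProteinSequence, table: PhysChemTable,
                    max_lag: int = 30,
                    residue_policy: str = "mean_impute") -> ACProfile:
    """Encode a protein as lagged auto-covariances of its descriptor tracks.

    For descriptor j with per-residue standardized values X[1..N, j] and
    per-sequence track mean m_j,

        AC(d, j) = (1 / (N - d)) * sum_{i=1..N-d} (X[i,j] - m_j) (X[i+d,j] - m_j)

    for lags d = 1..max_lag.  Requires N >= max_lag + 1 so every lag has at
    least one term.
    """
    X = _residue_matrix(seq, table, residue_policy)
    n = X.shape[0]
    if n < max_lag + 1:
        raise SequenceTooShortError(
            f"protein {seq.id!r}: effective length {n} < max_lag + 1 = {max_lag + 1}")
    # Anchor each track at its first residue before centering: covariance is
    # shift-invariant, and this makes the homopolymer case exactly zero.
    X = X - X[0]
    centered = X - X.mean(axis=0)
    n_desc = X.shape[1]
    ac = np.empty((n_desc, max_lag), dtype=np.float64)
    for d in range(1, max_lag + 1):
        ac[:, d - 1] = (centered[:-d] * centered[d:]).sum(axis=0) / (n - d)
    return ACProfile(protein_id=seq.id, max_lag=max_lag,
                     n_descriptors=n_desc, values=ac.ravel())


def feature_names(max_lag: int = 30,
                  descriptors: Iterable[str] = DESCRIPTORS) -> list[str]:
    return [f"{desc}_lag{d}" for desc in descriptors for d in range(1, max_lag + 1)]


def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into ProteinSequence records.

    The id is the first whitespace-delimited token of the header; sequences
    are upper-cased.  A sequence line before the first header and duplicate
    ids are rejected.
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise ValueError(
                f"{path}: line {lineno}: sequence data before first '>' header")
        break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return records


def write_feature_tsv(profiles: Iterable[ACProfile], path) -> None:
    """Write AC profiles as TSV: protein_id followed by 180 named columns."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    lag, nd = profiles[0].max_lag, profiles[0].n_descriptors
    header = ["protein_id"] + feature_names(lag, DESCRIPTORS[:nd])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            if (p.max_lag, p.n_descriptors) != (lag, nd):
                raise ValueError("mixed AC dimensionalities in one table")
            fh.write(p.protein_id + "\t"
                     + "\t".join(f"{v:.10g}" for v in p.values) + "\n")


def read_feature_tsv(path) -> Mapping[str, np.ndarray]:
    """Read a feature TSV written by :func:`write_feature_tsv`."""
    store: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width + 1:
                raise ValueError(f"{path}: line {lineno}: expected {width + 1} fields")
            store[parts[0]] = np.array([float(x) for x in parts[1:]])
    return store
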