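"""Supervised pair dataset assembly.

Positive protein-protein interaction pairs come from a two-column TSV;
negatives are sampled uniformly from the unordered protein pairs not listed
as positive (the usual positive-unlabeled simplification).  Pairs are
canonicalized by lexicographic id order so (A, B) and (B, A) are one pair.
Every protein contributes a feature vector: the mandatory 180-dim
auto-covariance sequence part, concatenated with its network embedding — or
a zero vector, flagged as imputed, for cold-start proteins absent from the
association network.  A labeled pair is the concatenation of its two protein
vectors.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .deepwalk import EmbeddingTable

__all__ = [
    "PPIPair",
    "ProteinFeatureVector",
    "PairFeatureMatrix",
    "MissingSequenceFeaturesError",
    "canonical_pair",
    "load_positive_pairs",
    "sample_negatives",
    "protein_vector",
    "assemble_vectors",
    "build_pair_matrix",
    "write_dataset",
]

logger = logging.getLogger(__name__)


class MissingSequenceFeaturesError(KeyError):
    """A referenced protein has no auto-covariance profile."""


@dataclass(frozen=True)
class PPIPair:
    protein_a: str
    protein_b: str
    label: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-pair not allowed: {self.protein_a!r}")
        if self.protein_a > self.protein_b:
            raise ValueError("pair not in canonical (lexicographic) order")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ProteinFeatureVector:
    protein_id: str
    seq_part: np.ndarray
    net_part: np.ndarray
    net_imputed: bool

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.seq_part, self.net_part])


@dataclass
class PairFeatureMatrix:
    pairs: list[PPIPair]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate canonical pairs in matrix")
        if self.X.shape[0] != len(self.pairs) or self.y.shape[0] != len(self.pairs):
            raise ValueError("matrix rows must align with pairs and labels")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def load_positive_pairs(path) -> set[tuple[str, str]]:
    """Read a two-column TSV of interacting protein ids.

    Pairs are canonicalized and deduplicated; self-pairs are dropped with a
    logged count.
    """
    pairs: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: line {lineno}: expected 2 protein ids")
            if parts[0] == parts[1]:
                n_self += 1
                continue
            pairs.add(canonical_pair(parts[0], parts[1]))
    if n_self:
        logger.warning("%s: dropped %d self-pairs", path, n_self)
    return pairs


def sample_negatives(protein_universe: Iterable[str],
                     positives: set[tuple[str, str]],
                     n: int,
                     rng: np.random.Generator) -> set[tuple[str, str]]:
    """Draw n non-interacting pairs uniformly without replacement.

    The candidate space is all unordered protein pairs over the universe
    minus the positives and self-pairs.  Deterministic for a fixed seed.
    """
    universe = sorted(set(protein_universe))
    candidates = [p for p in itertools.combinations(universe, 2)
                  if p not in positives]
    if n > len(candidates):
        raise ValueError(
            f"requested {n} negatives but only {len(candidates)} "
            f"non-positive pairs exist")
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return {candidates[i] for i in chosen}


def protein_vector(protein_id: str,
                   ac_store: Mapping[str, np.ndarray],
                   emb_store: EmbeddingTable | Mapping[str, np.ndarray] | None,
                   dim: int,
                   net_key: str | None = None) -> ProteinFeatureVector:
    """Assemble one protein's feature vector.

    The sequence part is mandatory; the network part is the embedding when
    the protein is in the network and a flagged zero vector otherwise
    (cold-start fallback).  ``net_key`` is the embedding lookup key when it
    differs from the raw id (e.g. the namespaced "protein:<id>").
    """
    if protein_id not in ac_store:
        raise MissingSequenceFeaturesError(
            f"missing sequence features for protein {protein_id!r}")
    seq_part = np.asarray(ac_store[protein_id], dtype=np.float64)
    key = net_key if net_key is not None else protein_id
    if dim == 0:
        return ProteinFeatureVector(protein_id, seq_part,
                                    np.zeros(0), net_imputed=False)
    if emb_store is not None and key in emb_store:
        net = np.asarray(emb_store.vector(key)
                         if isinstance(emb_store, EmbeddingTable)
                         else emb_store[key], dtype=np.float64)
        if net.shape != (dim,):
            raise ValueError(f"embedding for {key!r} has wrong dimension")
        return ProteinFeatureVector(protein_id, seq_part, net, net_imputed=False)
    return ProteinFeatureVector(protein_id, seq_part,
                                np.zeros(dim), net_imputed=True)


def assemble_vectors(protein_ids: Iterable[str],
                     ac_store: Mapping[str, np.ndarray],
                     emb_store: EmbeddingTable | Mapping[str, np.ndarray] | None,
                     dim: int,
                     mode: str = "combined",
                     net_prefix: str = "protein:") -> dict[str, ProteinFeatureVector]:
    """Build feature vectors for many proteins under an ablation mode.

    ``combined`` concatenates sequence and network parts; ``sequence_only``
    uses the sequence part alone; ``network_only`` the embedding alone (still
    zero-imputed for cold-start proteins).
    """
    if mode not in ("combined", "sequence_only", "network_only"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, ProteinFeatureVector] = {}
    for pid in protein_ids:
        vec = protein_vector(pid, ac_store, emb_store,
                             dim if mode != "sequence_only" else 0,
                             net_key=net_prefix + pid)
        if mode == "network_only":
            vec = ProteinFeatureVector(pid, np.zeros(0), vec.net_part,
                                       vec.net_imputed)
        out[pid] = vec
    return out


def build_pair_matrix(pairs: Iterable[PPIPair],
                      vector_store: Mapping[str, ProteinFeatureVector]
                      ) -> PairFeatureMatrix:
    """Stack concatenated per-protein vectors into the supervised matrix.

    Rows follow sorted canonical pair order (positives and negatives
    interleave by sort), making the matrix independent of input ordering.
    """
    pairs = sorted(pairs, key=lambda p: p.key)
    missing = sorted({pid for p in pairs for pid in p.key
                      if pid not in vector_store})
    if missing:
        raise MissingSequenceFeaturesError(
            f"no feature vectors for {len(missing)} protein(s): {missing[:10]}")
    widths = {vector_store[pid].combined.size
              for p in pairs for pid in p.key}
    if len(widths) > 1:
        raise ValueError(f"inconsistent per-protein feature widths: {widths}")
    rows = [np.concatenate([vector_store[p.protein_a].combined,
                            vector_store[p.protein_b].combined])
            for p in pairs]
    X = np.vstack(rows) if rows else np.zeros((0, 0))
    y = np.array([p.label for p in pairs], dtype=np.int64)
    return PairFeatureMatrix(pairs=pairs, X=X, y=y)


def make_pairs(positives: set[tuple[str, str]],
               negatives: set[tuple[str, str]]) -> list[PPIPair]:
    overlap = positives & negatives
    if overlap:
        raise ValueError(f"{len(overlap)} pairs are both positive and negative")
    return ([PPIPair(a, b, 1) for a, b in sorted(positives)]
            + [PPIPair(a, b, 0) for a, b in sorted(negatives)])


def write_dataset(matrix: PairFeatureMatrix, path_tsv, path_manifest,
                  seed: int | None = None,
                  imputed_proteins: Sequence[str] = ()) -> None:
    """Write the dataset as TSV (ids, label, features) plus a JSON manifest."""
    with open(path_tsv, "w") as fh:
        width = matrix.n_features
        fh.write("protein_a\tprotein_b\tlabel\t"
                 + "\t".join(f"f{i}" for i in range(width)) + "\n")
        for pair, row in zip(matrix.pairs, matrix.X):
            fh.write(f"{pair.protein_a}\t{pair.protein_b}\t{pair.label}\t"
                     + "\t".join(f"{v:.10g}" for v in row) + "\n")
    manifest = {
        "n_pairs": len(matrix.pairs),
        "n_positive": int(matrix.y.sum()),
        "n_negative": int((1 - matrix.y).sum()),
        "n_features": matrix.n_features,
        "seed": seed,
        "n_imputed_proteins": len(imputed_proteins),
    }
    with open(path_manifest, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
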