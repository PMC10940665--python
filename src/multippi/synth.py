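"""Seeded synthetic inputs: sequences, association network, planted PPI labels.

The generator emulates, at desk scale, the structure of the real inputs: five
typed molecule classes, undirected cross-type association edges with planted
community (block) structure, random protein sequences over the 20 standard
amino acids, and a positive PPI set whose pairs are biased toward network
proximity (same block) and/or a shared sequence motif.

Signal enters through two dials in [0, 1]:

* ``ppi_signal`` — weight of block co-membership on the interaction
  probability.  Pair weights are multiplicative per signal:
  ``(1 - s) + s * odds * [indicator]``, so s = 0 is exactly uniform and
  s = 1 restricts positives to pairs satisfying the indicator.  Block
  co-membership is what the random-walk embedding can recover, so this dial
  controls how much the network features can help.
* ``seq_signal`` — same construction on a shared implanted k-mer motif,
  recoverable (weakly) by the auto-covariance sequence features.

With both dials at zero the positives are a uniform draw and no classifier
can beat chance, which calibrates the null of the end-to-end test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .network import ASSOCIATION_TYPES, EdgeRecord, node_key
from .physchem import AMINO_ACIDS, ProteinSequence

__all__ = ["SynthConfig", "SyntheticBundle", "generate", "make_fixture",
           "gen_sequences", "gen_network", "gen_ppi_labels"]

_ID_PREFIX = {"protein": "P", "mirna": "MI", "lncrna": "LN",
              "drug": "DR", "disease": "DS"}

DEFAULT_MOTIF = "WKRHGDCEPM"


@dataclass(frozen=True)
class SynthConfig:
    n_proteins: int = 300
    n_mirna: int = 100
    n_lncrna: int = 100
    n_drug: int = 100
    n_disease: int = 100
    n_blocks: int = 6
    p_in: float = 0.15
    p_out: float = 0.01
    seq_len_range: tuple[int, int] = (50, 250)
    ppi_signal: float = 1.0
    seq_signal: float = 0.0
    block_odds: float = 99.0
    motif_odds: float = 99.0
    motif: str = DEFAULT_MOTIF
    carrier_frac: float = 0.3
    n_positive_pairs: int = 2000
    seed: int = 7

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.ppi_signal, self.seq_signal,
                  self.carrier_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and signals must be in [0, 1]")
        if self.seq_len_range[0] < 31:
            raise ValueError("minimum sequence length must be >= 31 so the "
                             "default 30-lag encoding is defined")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def node_ids(self, molecule_type: str) -> list[str]:
        n = {"protein": self.n_proteins, "mirna": self.n_mirna,
             "lncrna": self.n_lncrna, "drug": self.n_drug,
             "disease": self.n_disease}[molecule_type]
        return [f"{_ID_PREFIX[molecule_type]}{i:04d}" for i in range(n)]


@dataclass
class SyntheticBundle:
    config: SynthConfig
    sequences: list[ProteinSequence]
    edges: dict[str, list[EdgeRecord]]
    positives: set[tuple[str, str]]           # raw protein-id pairs
    blocks: dict[str, int] = field(repr=False, default_factory=dict)
    carriers: set[str] = field(repr=False, default_factory=set)

    @property
    def protein_ids(self) -> list[str]:
        return [s.id for s in self.sequences]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("blocks", "carriers", "sequences", "network", "labels")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _assign_blocks(config: SynthConfig, rng: np.random.Generator) -> dict[str, int]:
    blocks: dict[str, int] = {}
    for mtype in _ID_PREFIX:
        for raw in config.node_ids(mtype):
            blocks[node_key(mtype, raw)] = int(rng.integers(config.n_blocks))
    return blocks


def gen_sequences(config: SynthConfig, rng: np.random.Generator,
                  carriers: set[str] | None = None) -> list[ProteinSequence]:
    """I.i.d. uniform residues; motif carriers get the k-mer implanted."""
    carriers = carriers or set()
    lo, hi = config.seq_len_range
    alphabet = np.array(list(AMINO_ACIDS))
    out = []
    for pid in config.node_ids("protein"):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(alphabet[rng.integers(20, size=length)])
        if pid in carriers and config.seq_signal > 0:
            k = len(config.motif)
            pos = int(rng.integers(0, length - k + 1))
            residues = residues[:pos] + config.motif + residues[pos + k:]
        out.append(ProteinSequence(id=pid, residues=residues))
    return out


def gen_network(config: SynthConfig, blocks: Mapping[str, int],
                rng: np.random.Generator) -> dict[str, list[EdgeRecord]]:
    """One Bernoulli edge set per association type, block-structured.

    A cross-type pair gains an edge with probability p_in when the two nodes
    share a block and p_out otherwise.
    """
    edges: dict[str, list[EdgeRecord]] = {}
    for label in ASSOCIATION_TYPES:
        src_type, tgt_type = label.split("-")
        src_ids = config.node_ids(src_type)
        tgt_ids = config.node_ids(tgt_type)
        src_blocks = np.array([blocks[node_key(src_type, i)] for i in src_ids])
        tgt_blocks = np.array([blocks[node_key(tgt_type, i)] for i in tgt_ids])
        same = src_blocks[:, None] == tgt_blocks[None, :]
        prob = np.where(same, config.p_in, config.p_out)
        hit = rng.random(prob.shape) < prob
        recs = []
        for i, j in zip(*np.nonzero(hit)):
            recs.append(EdgeRecord(node_key(src_type, src_ids[i]),
                                   node_key(tgt_type, tgt_ids[j]), label))
        edges[label] = recs
    return edges


def gen_ppi_labels(config: SynthConfig, blocks: Mapping[str, int],
                   rng: np.random.Generator,
                   carriers: set[str] | None = None) -> set[tuple[str, str]]:
    """Sample distinct positive pairs weighted toward planted structure.

    Weight of pair (a, b) = f_block * f_motif with
    f = (1 - signal) + signal * odds * [indicator]; weighted sampling without
    replacement by exponential races (Gumbel keys).
    """
    carriers = carriers or set()
    pids = config.node_ids("protein")
    n = len(pids)
    ii, jj = np.triu_indices(n, k=1)
    pblocks = np.array([blocks[node_key("protein", p)] for p in pids])
    same_block = (pblocks[ii] == pblocks[jj]).astype(float)
    is_carrier = np.array([p in carriers for p in pids])
    shared_motif = (is_carrier[ii] & is_carrier[jj]).astype(float)
    w = (((1 - config.ppi_signal) + config.ppi_signal * config.block_odds * same_block)
         * ((1 - config.seq_signal) + config.seq_signal * config.motif_odds * shared_motif))
    n_pos = config.n_positive_pairs
    if (w > 0).sum() < n_pos:
        raise ValueError(
            f"requested {n_pos} positives but only {(w > 0).sum()} pairs have "
            f"non-zero weight")
    with np.errstate(divide="ignore"):
        keys = np.log(rng.random(w.size)) / w     # -inf where w == 0
    top = np.argpartition(keys, -n_pos)[-n_pos:]
    return {(pids[ii[t]], pids[jj[t]]) for t in top}


def generate(config: SynthConfig) -> SyntheticBundle:
    """Run all stages with independent per-stage seeded generators."""
    rngs = _stage_rngs(config.seed)
    blocks = _assign_blocks(config, rngs["blocks"])
    carriers: set[str] = set()
    if config.seq_signal > 0:
        mask = rngs["carriers"].random(config.n_proteins) < config.carrier_frac
        carriers = {p for p, m in zip(config.node_ids("protein"), mask) if m}
    sequences = gen_sequences(config, rngs["sequences"], carriers)
    edges = gen_network(config, blocks, rngs["network"])
    positives = gen_ppi_labels(config, blocks, rngs["labels"], carriers)
    return SyntheticBundle(config=config, sequences=sequences, edges=edges,
                           positives=positives, blocks=blocks, carriers=carriers)


def make_fixture(config: SynthConfig, outdir) -> Path:
    """Write a self-contained input bundle runnable end-to-end.

    Layout: proteins.fasta, edges/<label>.tsv, edges_manifest.yaml,
    ppi_positives.tsv, manifest.json.
    """
    outdir = Path(outdir)
    (outdir / "edges").mkdir(parents=True, exist_ok=True)
    bundle = generate(config)
    with open(outdir / "proteins.fasta", "w") as fh:
        for seq in bundle.sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, 60):
                fh.write(seq.residues[i:i + 60] + "\n")
    manifest_entries = []
    for label, recs in bundle.edges.items():
        path = outdir / "edges" / f"{label}.tsv"
        with open(path, "w") as fh:
            for rec in recs:
                fh.write(f"{rec.source.split(':', 1)[1]}\t"
                         f"{rec.target.split(':', 1)[1]}\n")
        src_type, tgt_type = label.split("-")
        manifest_entries.append({"path": f"edges/{label}.tsv",
                                 "source_type": src_type,
                                 "target_type": tgt_type, "label": label})
    with open(outdir / "edges_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_entries, fh)
    with open(outdir / "ppi_positives.tsv", "w") as fh:
        for a, b in sorted(bundle.positives):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "manifest.json", "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["seq_len_range"] = list(config.seq_len_range)
        json.dump({"config": cfg, "seed": config.seed}, fh, indent=2)
        fh.write("\n")
    return outdir
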