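"""End-to-end orchestration: features -> network -> embedding -> dataset -> CV.

The stages mirror the method itself: encode every protein sequence into its
180-dim auto-covariance vector; build the multi-source association network
(protein-protein edges excluded so the labels never leak into the features);
embed the network with DeepWalk; assemble labeled pairs with concatenated
per-protein feature vectors; cross-validate a Random Forest.

``mode`` selects the feature ablation: ``combined`` (sequence + network),
``sequence_only``, or ``network_only``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import deepwalk, network, pairs, physchem, synth
from .evaluate import CVResult, RFConfig, kfold_cv

__all__ = ["PipelineResult", "run_pipeline", "load_fixture"]


@dataclass
class PipelineResult:
    cv: CVResult
    mode: str
    n_features: int
    n_pairs: int
    n_imputed_proteins: int
    graph_stats: dict | None = None
    embedding: deepwalk.EmbeddingTable | None = None


def load_fixture(fixture_dir) -> synth.SyntheticBundle:
    """Read a written fixture directory back into an in-memory bundle."""
    fixture_dir = Path(fixture_dir)
    sequences = physchem.read_fasta(fixture_dir / "proteins.fasta")
    entries = network.load_manifest(fixture_dir / "edges_manifest.yaml")
    edges = {}
    for e in entries:
        edges[e["label"]] = network.load_edge_list(
            e["path"], e["source_type"], e["target_type"], e["label"],
            header=bool(e.get("header", False)))
    positives = pairs.load_positive_pairs(fixture_dir / "ppi_positives.tsv")
    import json
    with open(fixture_dir / "manifest.json") as fh:
        cfg = json.load(fh)["config"]
    cfg["seq_len_range"] = tuple(cfg["seq_len_range"])
    config = synth.SynthConfig(**cfg)
    return synth.SyntheticBundle(config=config, sequences=sequences,
                                 edges=edges, positives=positives)


def run_pipeline(bundle: synth.SyntheticBundle,
                 mode: str = "combined",
                 walk_config: deepwalk.WalkConfig | None = None,
                 rf: RFConfig | None = None,
                 k: int = 5,
                 seed: int = 0,
                 max_lag: int = 30,
                 residue_policy: str = "mean_impute",
                 embedding: deepwalk.EmbeddingTable | None = None,
                 ) -> PipelineResult:
    """Run the full method on an input bundle and cross-validate.

    A precomputed ``embedding`` may be passed to reuse one network embedding
    across ablation modes; otherwise one is trained when the mode needs it.
    All randomness (walks, negative sampling, fold splits, forest) derives
    from the stage seeds recorded in the configs.
    """
    walk_config = walk_config or deepwalk.WalkConfig(seed=seed)
    rf = rf or RFConfig(seed=seed)

    table = physchem.normalize_table(physchem.load_physchem_table())
    ac_store = {
        seq.id: physchem.encode_sequence(seq, table, max_lag=max_lag,
                                         residue_policy=residue_policy).values
        for seq in bundle.sequences}

    graph = None
    stats = None
    if mode != "sequence_only" and embedding is None:
        graph = network.build_graph(bundle.edges.values(),
                                    exclude_assoc_labels=("protein-protein",))
        stats = network.graph_stats(graph)
        corpus = deepwalk.generate_walks(graph, walk_config)
        embedding = deepwalk.train_skipgram(corpus, walk_config)

    positives = bundle.positives
    rng = np.random.default_rng(seed + 1)
    negatives = pairs.sample_negatives(bundle.protein_ids, positives,
                                       len(positives), rng)
    all_pairs = pairs.make_pairs(positives, negatives)
    vectors = pairs.assemble_vectors(bundle.protein_ids, ac_store, embedding,
                                     walk_config.dim, mode=mode)
    n_imputed = sum(v.net_imputed for v in vectors.values())
    matrix = pairs.build_pair_matrix(all_pairs, vectors)
    cv = kfold_cv(matrix, rf, k=k, seed=seed)
    return PipelineResult(cv=cv, mode=mode, n_features=matrix.n_features,
                          n_pairs=len(all_pairs), n_imputed_proteins=n_imputed,
                          graph_stats=stats, embedding=embedding)


def cv_summary(result: PipelineResult) -> dict:
    """JSON-friendly per-fold and mean/sd metric summary."""
    return {
        "mode": result.mode,
        "n_pairs": result.n_pairs,
        "n_features": result.n_features,
        "n_imputed_proteins": result.n_imputed_proteins,
        "folds": [f.as_dict() for f in result.cv.folds],
        "mean": result.cv.mean,
        "sd": result.cv.sd,
    }
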