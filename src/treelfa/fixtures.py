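"""Deterministic fixture generation for tests and demos.

Fixtures are generated, never committed: each named fixture writes plain-text
artifacts (tree tables, diagnosis matrices, configs) to a directory, and
regenerating with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .generative import make_sim_topics, simulate_dataset
from .ontology import ROOT, OntologyTree, build_sim_tree

__all__ = ["FIXTURES", "make_fixture", "tiny_enum_tree"]


def tiny_enum_tree() -> OntologyTree:
    """Two codes directly under the root: small enough that all latent
    states of the model (Z over D x S variables, I over K x 2 nodes) can be
    enumerated exactly for oracle checks."""
    return OntologyTree(
        nodes=["c1", "c2"],
        parent_of={"c1": ROOT, "c2": ROOT},
        is_code={"c1": True, "c2": True},
    )


def _write_tiny_enum(out: Path, seed: int) -> list[str]:
    tree = tiny_enum_tree()
    tree.save(out / "tree.tsv")
    rng = np.random.default_rng(seed)
    W = rng.integers(0, 2, size=(3, 2))
    pd.DataFrame(W, columns=tree.code_order,
                 index=[f"ind{i}" for i in range(3)]).to_csv(
        out / "W.tsv", sep="\t", index_label="individual")
    (out / "config.json").write_text(
        json.dumps({"K": 2, "D": 3, "S": 2, "seed": seed}, indent=1))
    return ["tree.tsv", "W.tsv", "config.json"]


def _write_fig2(out: Path, seed: int, setting: str) -> list[str]:
    """The full 8-group replicated-benchmark configuration for one topic
    setting: 4 (alpha, D) cells x 20 paired train/test datasets, written as
    a config table plus the tree and true topics."""
    tree = build_sim_tree()
    tree.save(out / "tree.tsv")
    topics = make_sim_topics(tree, setting=setting)
    pd.DataFrame(topics.phi, columns=tree.code_order).to_csv(
        out / "true_topics.tsv", sep="\t", index=False)
    cells = [(1.0, 2500), (1.0, 5000), (0.1, 300), (0.1, 1000)]
    rows = []
    ss = np.random.SeedSequence(seed)
    for (alpha, D), cell_seed in zip(cells, ss.spawn(len(cells))):
        for ds, pair_seed in enumerate(cell_seed.spawn(20)):
            train_seed, test_seed = pair_seed.spawn(2)
            rows.append({
                "setting": setting, "alpha": alpha, "D": D, "dataset": ds,
                "train_entropy": str(train_seed.entropy),
                "test_entropy": str(test_seed.entropy),
            })
    pd.DataFrame(rows).to_csv(out / "datasets.tsv", sep="\t", index=False)
    (out / "config.json").write_text(json.dumps(
        {"setting": setting, "seed": seed, "n_datasets": 20,
         "active_prob": 0.5}, indent=1))
    return ["tree.tsv", "true_topics.tsv", "datasets.tsv", "config.json"]


def _write_healthy_mix(out: Path, seed: int) -> list[str]:
    """A small dataset in which 30% of individuals have all-zero rows,
    exercising empty-topic behaviour."""
    tree = build_sim_tree()
    tree.save(out / "tree.tsv")
    topics = make_sim_topics(tree, setting="correct_prior")
    data, theta, _ = simulate_dataset(topics, 1.0, 700, seed=seed,
                                      code_ids=tree.code_order)
    rng = np.random.default_rng(seed + 1)
    healthy = rng.choice(700, size=300, replace=False)
    W = data.W.copy()
    W[healthy] = 0
    pd.DataFrame(W, columns=tree.code_order,
                 index=data.individual_ids).to_csv(
        out / "W.tsv", sep="\t", index_label="individual")
    (out / "config.json").write_text(
        json.dumps({"seed": seed, "n_healthy": 300, "D": 700}, indent=1))
    return ["tree.tsv", "W.tsv", "config.json"]


FIXTURES = {
    "tiny-enum": _write_tiny_enum,
    "fig2-correct": lambda out, seed: _write_fig2(out, seed, "correct_prior"),
    "fig2-incorrect": lambda out, seed: _write_fig2(out, seed, "incorrect_prior"),
    "healthy-mix": _write_healthy_mix,
}


def make_fixture(name: str, out_dir, seed: int = 0) -> list[Path]:
    """Write the named fixture into ``out_dir`` and return the files made."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = FIXTURES[name](out, seed)
    return [out / f for f in files]
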