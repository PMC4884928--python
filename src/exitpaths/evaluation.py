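"""Benchmark scenarios: quantitative recovery of planted structure.

Each function builds a synthetic scenario with the generators in
:mod:`exitpaths.synthetic`, runs the corresponding analysis stage, and
measures how well the planted structure is recovered. They are the package's
self-validation surface: the same runners back the test suite and the
acceptance script.

All randomness flows through explicit seeds; scenario sizes are chosen to
finish in seconds to a few minutes on one CPU (the methods note records the
problem sizes).
"""

from __future__ import annotations


import networkx as nx
import numpy as np
import pandas as pd

from . import capnet as cn
from . import screening, similarity, trajectory
from .synthetic import (
    SimConfig,
    gen_capnet_scenario,
    gen_expression_dataset,
    gen_screen_table,
)


def _subseed(seed: int, k: int) -> int:
    """Derive a stable 31-bit stage seed from a base seed."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# shortest-path oracle
# ---------------------------------------------------------------------------

def spnet_oracle_agreement(n_graphs: int = 100, seed: int = 0, max_nodes: int = 12) -> float:
    """Fraction of random small graphs where the SPNet edge set equals the
    brute-force enumeration of every shortest path.

    Graphs are Erdos-Renyi with up to ``max_nodes`` nodes and random edge
    density; two random targets and two random DEGs per graph.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "confidence")
        nodes = list(g.nodes)
        picks = rng.choice(len(nodes), size=min(4, n), replace=False)
        targets = [nodes[i] for i in picks[:2]]
        degs = [nodes[i] for i in picks[2:]] or [nodes[picks[0]]]
        sp = cn.build_spnet(g, targets, degs, min_conf=0.0, drug="x")
        brute = cn.spnet_edges_bruteforce(g, targets, degs, min_conf=0.0)
        agree += sp.edge_set == brute
    return agree / n_graphs


# ---------------------------------------------------------------------------
# planted-pathway recovery
# ---------------------------------------------------------------------------

def capnet_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    n_drugs: int = 6,
    ppi_nodes: int = 200,
    ppi_edge_prob: float = 0.02,
    planted_path_length: int = 3,
) -> pd.DataFrame:
    """CAP-Net precision/recall against the planted backbone, one row per seed."""
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=_subseed(seed, 100 + i),
            n_drugs=n_drugs,
            ppi_nodes=ppi_nodes,
            ppi_edge_prob=ppi_edge_prob,
            planted_path_length=planted_path_length,
        )
        net, targets, degs, truth = gen_capnet_scenario(cfg)
        spnets = [cn.build_spnet(net, targets[d], degs[d], drug=d) for d in targets]
        cap = cn.intersect_spnets(spnets, min_support=2)
        r = cn.recover_planted(cap, truth)
        rows.append({"seed": cfg.seed, "recall": r["recall"], "precision": r["precision"],
                     "n_cap_edges": r["n_cap_edges"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory category recovery
# ---------------------------------------------------------------------------

def category_recovery(
    n_seeds: int = 10, seed: int = 0, n_genes: int = 1000
) -> pd.DataFrame:
    """Pooled confusion counts for the planted C1/C3/C4 classes.

    Returns one row per class with pooled true-positive, false-negative and
    false-positive counts plus precision and recall across seeds.
    """
    tp = {c: 0 for c in ("C1", "C3", "C4")}
    fn = dict(tp)
    fp = dict(tp)
    for i in range(n_seeds):
        cfg = SimConfig(seed=_subseed(seed, 200 + i), n_genes=n_genes)
        data, truth = gen_expression_dataset(cfg)
        detected = trajectory.filter_detected(data)
        model = trajectory.fit_control_model(detected)
        assignment = trajectory.assign_categories(detected, model)
        true_labels = truth.gene_categories.loc[detected.genes]
        for c in tp:
            is_true = true_labels == c
            is_called = assignment.labels == c
            tp[c] += int((is_true & is_called).sum())
            fn[c] += int((is_true & ~is_called).sum())
            fp[c] += int((~is_true & is_called).sum())
    rows = []
    for c in tp:
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        rows.append({"category": c, "tp": tp[c], "fp": fp[c], "fn": fn[c],
                     "precision": prec, "recall": rec})
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# dispersion shape
# ---------------------------------------------------------------------------

def dispersion_day3_minimum_fraction(
    seed: int = 0, n_reps: int = 100, n_genes: int = 500
) -> float:
    """Fraction of gene-subsample repetitions where mean cross-drug
    correlation is minimal at day 3 (the planted divergence peak)."""
    cfg = SimConfig(seed=_subseed(seed, 300))
    data, _ = gen_expression_dataset(cfg)
    detected = trajectory.filter_detected(data)
    model = trajectory.fit_control_model(detected)
    disp = trajectory.subsample_dispersion(
        detected, model, n_genes=n_genes, n_reps=n_reps, seed=_subseed(seed, 301)
    )
    means = disp.groupby(["rep", "day"])["r"].mean().unstack()
    is_min = (means[3] < means[1]) & (means[3] < means[5])
    return float(is_min.mean())


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def permutation_calibration(
    seed: int = 0,
    n_trials: int = 1000,
    n_perm: int = 2000,
    n_drugs: int = 200,
    targets_per_drug: int = 8,
    target_universe: int = 70,
    alpha: float = 0.05,
) -> float:
    """Type-I error rate of the shared-target permutation test under the null.

    Each trial simulates a fresh library whose drugs draw
    ``targets_per_drug`` targets uniformly from a common universe, tests one
    random pair and rejects at ``alpha``. Library size and target geometry
    are chosen so the attainable exceedance tail sits inside the nominal
    level rather than on a discreteness boundary.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:03d}" for i in range(n_drugs)]
    rejections = 0
    for _ in range(n_trials):
        rows = [
            (d, f"t{x}", 0.9)
            for d in drugs
            for x in rng.choice(target_universe, targets_per_drug, replace=False)
        ]
        table = pd.DataFrame(rows, columns=["drug", "target", "confidence"])
        a, b = rng.choice(n_drugs, 2, replace=False)
        p, _ = similarity.shared_target_pvalue(
            (drugs[a], drugs[b]), table, drugs, n_perm=n_perm, rng=rng
        )
        rejections += p <= alpha
    return rejections / n_trials


# ---------------------------------------------------------------------------
# screen recovery
# ---------------------------------------------------------------------------

def screen_recovery(seed: int = 0, n_library: int = 100, n_effective: int = 5,
                    n_toxic: int = 3) -> dict:
    """Hit calling on a planted screen; exact-recovery flag plus counts."""
    cfg = SimConfig(seed=_subseed(seed, 400))
    table, truth = gen_screen_table(
        cfg, n_library=n_library, n_effective=n_effective, n_toxic=n_toxic
    )
    calls = screening.screen(table)
    hits = set(screening.select_effective(calls))
    planted = set(truth.effective_drugs)
    return {
        "exact": hits == planted,
        "n_hits": len(hits),
        "n_planted": len(planted),
        "n_correct": len(hits & planted),
    }


def pairwise_pair_count(n_drugs: int = 16) -> int:
    """Number of unordered drug pairs the divergence machinery produces."""
    cfg = SimConfig(n_drugs=n_drugs, n_genes=20, seed=0)
    data, _ = gen_expression_dataset(cfg)
    return trajectory.pairwise_diffs(data, day=3).n_pairs
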