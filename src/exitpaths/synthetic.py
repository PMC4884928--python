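"""Synthetic-data generators with planted, recoverable structure.

Every pipeline input — expression time courses, a drug screen table, a
protein-interaction network, a drug-target table and chemical fingerprints —
can be generated here with known ground truth, so each downstream stage has a
quantitative recovery surface.

The expression generator emulates a study design of D drugs profiled at days
1, 3 and 5 on a log-intensity scale, with a shared pool of untreated
replicates standing in for Day 0. Genes are partitioned into trajectory
categories:

* ``C1`` — drug-specific excursions at days 1/3 that return to baseline by
  day 5 (divergent-convergent, no net change);
* ``C2`` — a transient excursion shared by all drugs, back to baseline;
* ``C3`` — drug-specific excursions that converge onto a common shifted
  day-5 level (divergent-convergent with net change);
* ``C4`` — a concordant, monotone shift to a common day-5 level in every
  drug (net change without divergence);
* ``C5`` — an idiosyncratic transient in a single drug;
* ``background`` — pure replicate noise.

Divergent excursions are drawn half-size at day 1 and full-size at day 3, so
between-drug dispersion peaks at day 3 — the qualitative time-course shape
the pipeline is designed to detect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import CONTROL_LABEL, ExpressionDataset, GroundTruth

CATEGORIES = ("C1", "C2", "C3", "C4", "C5", "background")

DEFAULT_FRACTIONS = {
    "C1": 0.05,
    "C2": 0.05,
    "C3": 0.05,
    "C4": 0.10,
    "C5": 0.05,
    "background": 0.70,
}

#: screening doses in uM; the last (highest) one is the reference dose.
DEFAULT_DOSES = (0.08, 0.4, 2.0, 10.0)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic scenario.

    ``noise_sd`` is the replicate SD of log2 intensity per gene (jittered
    +-30% gene to gene); ``effect_sd_multiplier`` sizes every planted effect
    in units of that per-gene SD, so the 3-sigma calls downstream see a
    fixed signal-to-noise ratio regardless of the noise scale.
    """

    n_genes: int = 1000
    n_drugs: int = 16
    n_controls: int = 14
    days: tuple[int, ...] = (0, 1, 3, 5)
    noise_sd: float = 0.2
    effect_sd_multiplier: float = 6.0
    category_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    undetected_fraction: float = 0.05
    ppi_nodes: int = 200
    ppi_edge_prob: float = 0.02
    ppi_conf_range: tuple[float, float] = (0.0, 1.0)
    planted_path_length: int = 3
    targets_per_drug: int = 2
    low_conf_target_fraction: float = 0.2
    fingerprint_bits: int = 256
    fingerprint_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_drugs", "n_controls", "ppi_nodes",
                     "planted_path_length", "targets_per_drug", "fingerprint_bits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2 (replicate SD undefined otherwise)")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions must sum to 1 (got {total})")
        unknown = set(self.category_fractions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if list(self.days) != sorted(set(self.days)) or 0 not in self.days:
            raise ValueError("days must be strictly increasing and include 0")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise ValueError("ppi_edge_prob must lie in [0, 1]")
        if not 0.0 <= self.undetected_fraction <= 1.0:
            raise ValueError("undetected_fraction must lie in [0, 1]")
        if self.fingerprint_bits < 8:
            raise ValueError("fingerprint_bits must be >= 8")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(cfg: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def drug_names(n: int) -> list[str]:
    return [f"drug{i + 1:02d}" for i in range(n)]


def _category_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder partition, then shuffled over genes."""
    counts = {}
    fracs = {c: cfg.category_fractions.get(c, 0.0) for c in CATEGORIES}
    raw = {c: f * cfg.n_genes for c, f in fracs.items()}
    for c in CATEGORIES:
        counts[c] = int(np.floor(raw[c]))
    short = cfg.n_genes - sum(counts.values())
    for c in sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return labels


def gen_expression_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the full expression input: controls + drug time courses.

    Returns the dataset (values, detection p-values, metadata) and the ground
    truth (per-gene category, undetected genes). Effects are planted per the
    category semantics in the module docstring, with magnitudes of at least
    ``effect_sd_multiplier`` per-gene SDs.
    """
    rng = _rng(cfg, rng)
    m = cfg.effect_sd_multiplier
    days = [d for d in cfg.days if d != 0]
    drugs = drug_names(cfg.n_drugs)
    genes = [f"gene{i + 1:05d}" for i in range(cfg.n_genes)]

    labels = _category_labels(cfg, rng)
    baseline = rng.uniform(6.0, 12.0, cfg.n_genes)
    sigma = cfg.noise_sd * rng.uniform(0.7, 1.3, cfg.n_genes)

    # planted effect parameters, per gene
    is_cat = {c: labels == c for c in CATEGORIES}
    sign = rng.choice([-1.0, 1.0], cfg.n_genes)              # per-gene common sign
    common_mag = rng.uniform(m, 2 * m, cfg.n_genes) * sigma   # C2/C3/C4 shared shifts

    # drug-specific excursion for C1/C3: sign and size vary per (gene, drug)
    exc_sign = rng.choice([-1.0, 1.0], (cfg.n_genes, cfg.n_drugs))
    exc_mag = rng.uniform(m, 2 * m, (cfg.n_genes, cfg.n_drugs)) * sigma[:, None]
    excursion = exc_sign * exc_mag

    n_days = len(days)
    # effect[gene, drug, day_index]
    effect = np.zeros((cfg.n_genes, cfg.n_drugs, n_days))
    # ramp of the divergent excursion over the course: half at the first
    # perturbed day, full at the middle day(s), gone at the final day
    div_ramp = np.zeros(n_days)
    if n_days >= 2:
        div_ramp[0] = 0.5
        div_ramp[1:-1] = 1.0
    final = n_days - 1

    for c in ("C1", "C3"):
        idx = np.where(is_cat[c])[0]
        effect[idx] += excursion[idx, :, None] * div_ramp[None, None, :]
    idx = np.where(is_cat["C3"])[0]
    effect[idx, :, final] = (sign * common_mag)[idx, None]

    idx = np.where(is_cat["C4"])[0]
    mono = np.arange(1, n_days + 1) / n_days  # 1/3, 2/3, 1 for three days
    effect[idx] += (sign * common_mag)[idx, None, None] * mono[None, None, :]

    # transient plateau: full-size at every early day, gone at the final day.
    # C2's excursion is *shared* across drugs, so a ramped profile would add
    # shared variance specifically at the divergence peak; a plateau keeps
    # the planted between-drug dispersion maximum purely drug-specific.
    plateau = np.ones(n_days)
    plateau[final] = 0.0
    idx = np.where(is_cat["C2"])[0]
    effect[idx] += (sign * common_mag)[idx, None, None] * plateau[None, None, :]

    # C5 and background genes stay within noise: C1/C3/C4 are the
    # quantitatively planted classes, C5 is a classifier-side residual label

    # assemble columns: controls first, then drug x day
    cols, meta_rows = [], []
    data = np.empty((cfg.n_genes, cfg.n_controls + cfg.n_drugs * n_days))
    j = 0
    for r in range(cfg.n_controls):
        data[:, j] = baseline + rng.normal(0.0, sigma)
        cols.append(f"ctrl{r + 1:02d}")
        meta_rows.append((cols[-1], CONTROL_LABEL, 0, 0.0))
        j += 1
    for di, drug in enumerate(drugs):
        for ti, day in enumerate(days):
            data[:, j] = baseline + effect[:, di, ti] + rng.normal(0.0, sigma)
            cols.append(f"{drug}_day{day}")
            meta_rows.append((cols[-1], drug, day, DEFAULT_DOSES[-1]))
            j += 1

    values = pd.DataFrame(data, index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "drug", "day", "dose"])
    meta = meta.set_index("sample_id")

    # detection p-values: near zero for expressed genes, uniform above the
    # conventional 0.05 cut for the planted undetected fraction
    detection = pd.DataFrame(
        rng.uniform(0.0, 0.01, values.shape), index=genes, columns=cols
    )
    n_undet = int(round(cfg.undetected_fraction * cfg.n_genes))
    bg_pool = np.where(is_cat["background"])[0]
    if n_undet > len(bg_pool):
        raise ValueError(
            "undetected_fraction exceeds the background fraction; "
            "undetected genes are drawn from the background pool"
        )
    undet_idx = rng.choice(bg_pool, size=n_undet, replace=False)
    detection.iloc[undet_idx] = rng.uniform(0.05, 1.0, (n_undet, len(cols)))

    truth = GroundTruth(
        gene_categories=pd.Series(labels, index=genes, name="category"),
        undetected_genes=frozenset(np.asarray(genes)[undet_idx]),
        effective_drugs=frozenset(drugs),
    )
    return ExpressionDataset(values, meta, detection), truth


def gen_screen_table(
    cfg: SimConfig,
    n_library: int = 100,
    n_effective: int = 5,
    n_toxic: int = 0,
    basal_pct: float = 25.0,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a differentiation screen: drug x dose -> (%positive, live cells).

    Ineffective drugs sit at a dose-independent basal differentiation level
    (default 25%, SD 5). Planted effective drugs reach 60-90% at the top dose
    with at-or-above-average viability, so they clear both hit-calling
    thresholds by construction. Toxic decoys reach effective-like
    differentiation but with collapsed live-cell counts.
    """
    if n_effective > n_library:
        raise ValueError("n_effective cannot exceed n_library")
    if n_effective + n_toxic > n_library:
        raise ValueError("effective + toxic drugs cannot exceed n_library")
    rng = _rng(cfg, rng)

    eff = drug_names(n_effective)
    tox = [f"toxin{i + 1:03d}" for i in range(n_toxic)]
    rest = [f"lib{i + 1:04d}" for i in range(n_library - n_effective - n_toxic)]
    all_drugs = eff + tox + rest
    top = max(doses)

    rows = []
    for drug in all_drugs:
        if drug in eff or drug in tox:
            top_pct = rng.uniform(60.0, 90.0)
        for dose in doses:
            if drug in eff or drug in tox:
                # dose-dependent induction on top of the basal level
                pct = basal_pct + (top_pct - basal_pct) * (dose / top) + rng.normal(0, 3.0)
                if dose == top:
                    pct = top_pct
            else:
                pct = rng.normal(basal_pct, 5.0)
            pct = float(np.clip(pct, 0.0, 100.0))
            if drug in tox:
                live = rng.normal(150.0, 30.0)
            elif drug in eff and dose == top:
                live = 500.0 + abs(rng.normal(0.0, 40.0))  # at/above library mean
            else:
                live = rng.normal(500.0, 40.0)
            rows.append((drug, dose, pct, max(0, int(round(live)))))

    table = pd.DataFrame(rows, columns=["drug", "dose", "pct_differentiated", "live_cells"])
    truth = GroundTruth(effective_drugs=frozenset(eff))
    return table, truth


def gen_ppi_network(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, GroundTruth]:
    """Erdos-Renyi interaction background with a planted backbone pathway.

    The backbone is a chain of ``planted_path_length`` confidence-1.0 edges
    from an entry node to a designated differentially-expressed endpoint.
    Each drug gets its own entry target, attached to the chain start by one
    confidence-1.0 spoke edge — distinct targets feeding a shared pathway.
    Background edges receive confidences drawn uniformly from
    ``ppi_conf_range``; at the default range only ~20% survive the standard
    0.8 confidence filter, keeping the filtered background sparse.
    """
    L = cfg.planted_path_length
    if cfg.ppi_nodes < L + 1 + cfg.n_drugs:
        raise ValueError("ppi_nodes too small for the planted chain plus per-drug entries")
    rng = _rng(cfg, rng)

    nodes = [f"P{i + 1:04d}" for i in range(cfg.ppi_nodes)]
    chain = nodes[: L + 1]
    spokes = {d: nodes[L + 1 + i] for i, d in enumerate(drug_names(cfg.n_drugs))}

    g = nx.Graph()
    g.add_nodes_from(nodes)
    backbone = []
    for a, b in itertools.pairwise(chain):
        g.add_edge(a, b, confidence=1.0)
        backbone.append(tuple(sorted((a, b))))
    entry_edges = {}
    for d, s in spokes.items():
        g.add_edge(s, chain[0], confidence=1.0)
        entry_edges[d] = tuple(sorted((s, chain[0])))

    if cfg.ppi_edge_prob > 0:
        # background edges may touch the planted pathway but never connect two
        # planted nodes to each other: the chain must stay the unique planted
        # route, per this generator's contract (single-background-node
        # bypasses remain possible and are the stochastic failure mode)
        planted = set(chain) | set(spokes.values())
        pairs = list(itertools.combinations(nodes, 2))
        draw = rng.random(len(pairs)) < cfg.ppi_edge_prob
        lo, hi = cfg.ppi_conf_range
        confs = rng.uniform(lo, hi, len(pairs))
        for (a, b), keep, conf in zip(pairs, draw, confs):
            if keep and not g.has_edge(a, b) and not (a in planted and b in planted):
                g.add_edge(a, b, confidence=float(conf))

    truth = GroundTruth(
        backbone_edges=frozenset(backbone),
        entry_edges=entry_edges,
        entry_node=chain[0],
        deg_node=chain[-1],
    )
    return g, truth


def gen_drug_targets(
    cfg: SimConfig,
    truth: GroundTruth | None = None,
    nodes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Assign each drug its targets with STITCH-like confidence scores.

    If a planted network's ground truth is supplied, each drug's first target
    is its backbone entry node (always high confidence, so the planted
    pathway survives the 0.8 filter). Remaining targets are random network
    nodes whose confidence falls below 0.8 with probability
    ``low_conf_target_fraction``, exercising the confidence filter.
    """
    rng = _rng(cfg, rng)
    drugs = drug_names(cfg.n_drugs)
    if nodes is None:
        nodes = [f"P{i + 1:04d}" for i in range(cfg.ppi_nodes)]

    rows = []
    planted: dict[str, tuple[str, ...]] = {}
    for d in drugs:
        picked: list[str] = []
        if truth is not None and d in truth.entry_edges:
            spoke = next(n for n in truth.entry_edges[d] if n != truth.entry_node)
            rows.append((d, spoke, float(rng.uniform(0.85, 1.0))))
            picked.append(spoke)
        while len(picked) < cfg.targets_per_drug:
            t = nodes[rng.integers(len(nodes))]
            if t in picked:
                continue
            if rng.random() < cfg.low_conf_target_fraction:
                conf = float(rng.uniform(0.3, 0.8))
            else:
                conf = float(rng.uniform(0.8, 1.0))
            rows.append((d, t, conf))
            picked.append(t)
        planted[d] = tuple(t for (dd, t, c) in rows if dd == d and c >= 0.8)

    table = pd.DataFrame(rows, columns=["drug", "target", "confidence"])
    out = truth if truth is not None else GroundTruth()
    out.drug_targets = planted
    return table, out


def gen_capnet_scenario(
    cfg: SimConfig,
    extra_degs_per_drug: int = 2,
    min_conf: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, dict[str, tuple[str, ...]], dict[str, tuple[str, ...]], GroundTruth]:
    """Network + per-drug target and DEG sets for pathway-recovery runs.

    Every drug's target set is its planted entry target plus drug-specific
    extras; every DEG set is the planted common endpoint plus drug-specific
    extras. Extras are disjoint across drugs and planted in the network
    periphery — outside the planted pathway's component of the
    confidence-filtered graph — so they exercise unreachable-pair and
    drug-specific-path handling while the shared backbone remains the only
    structure supported by two or more drugs. Recovering exactly that
    backbone is the scenario's acceptance surface.
    """
    from .capnet import filter_network  # local import; no cycle at module load

    rng = _rng(cfg, rng)
    net, truth = gen_ppi_network(cfg, rng=rng)

    filtered = filter_network(net, min_conf)
    core = nx.node_connected_component(filtered, truth.entry_node)
    pool = [n for n in net.nodes if n not in core]
    extra_targets = cfg.targets_per_drug - 1
    need = cfg.n_drugs * (extra_targets + extra_degs_per_drug)
    if len(pool) < need:
        raise ValueError(
            f"need {need} peripheral nodes for drug-specific extras, found {len(pool)}"
        )
    perm = [str(n) for n in rng.permutation(pool)]

    targets: dict[str, tuple[str, ...]] = {}
    degs: dict[str, tuple[str, ...]] = {}
    k = 0
    for d in drug_names(cfg.n_drugs):
        spoke = next(n for n in truth.entry_edges[d] if n != truth.entry_node)
        targets[d] = (spoke, *perm[k : k + extra_targets])
        k += extra_targets
        degs[d] = (truth.deg_node, *perm[k : k + extra_degs_per_drug])
        k += extra_degs_per_drug
    truth.drug_targets = dict(targets)
    return net, targets, degs, truth


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def expected_tanimoto(share_fraction: float, density: float) -> float:
    """Expected Tanimoto score between two group members.

    Each member copies the group template bit with probability
    ``share_fraction`` and otherwise resamples it Bernoulli(``density``).
    """
    f, d = share_fraction, density
    p11 = d * (f + (1 - f) * d) ** 2 + (1 - d) * ((1 - f) * d) ** 2
    return p11 / (2 * d - p11)


def share_fraction_for_ts(target_ts: float, density: float) -> float:
    """Invert :func:`expected_tanimoto` for a desired pairwise TS."""
    lo = expected_tanimoto(0.0, density)
    if not lo <= target_ts <= 1.0:
        raise ValueError(f"target TS {target_ts} not attainable (floor {lo:.3f})")
    if target_ts == 1.0:
        return 1.0
    return float(brentq(lambda f: expected_tanimoto(f, density) - target_ts, 0.0, 1.0))


def gen_fingerprints(
    cfg: SimConfig,
    similarity_groups: dict[str, list[str]] | None = None,
    share_fraction: float = 1.0,
    target_ts: float | None = None,
    drugs: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Random binary fingerprints, with optional planted similarity groups.

    Drugs in the same group copy a fraction of a shared template's bits so
    their pairwise Tanimoto score is tunable (``share_fraction`` directly,
    or via ``target_ts``). Ungrouped drugs get independent Bernoulli bits at
    ``fingerprint_density``.
    """
    rng = _rng(cfg, rng)
    if drugs is None:
        drugs = drug_names(cfg.n_drugs)
    d = cfg.fingerprint_density
    nbits = cfg.fingerprint_bits
    if target_ts is not None:
        share_fraction = share_fraction_for_ts(target_ts, d)

    fps = {drug: rng.random(nbits) < d for drug in drugs}
    if similarity_groups:
        for members in similarity_groups.values():
            template = rng.random(nbits) < d
            for drug in members:
                copy = rng.random(nbits) < share_fraction
                fresh = rng.random(nbits) < d
                fps[drug] = np.where(copy, template, fresh)
    return fps
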