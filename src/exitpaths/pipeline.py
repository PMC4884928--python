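"""End-to-end orchestration: simulate -> screen -> trajectory -> similarity
-> capnet -> report, from a single config with one global seed.

Each stage draws randomness from its own substream, derived from the global
seed with a fixed per-stage key, so adding or re-running a stage never
perturbs the randomness of the others and re-running the same config
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, capnet, io, screening, similarity, synthetic, trajectory
from .synthetic import SimConfig

log = logging.getLogger("exitpaths")

#: fixed substream keys — order-independent by construction
_STAGE_KEYS = {
    "expression": 1,
    "screen": 2,
    "network": 3,
    "fingerprints": 4,
    "similarity": 5,
    "capnet": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class RunConfig:
    """All pipeline thresholds and scenario knobs in one place."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # screening
    n_library: int = 100
    n_effective: int = 5
    n_toxic: int = 3
    diff_z: float = screening.DIFF_THRESHOLD
    tox_z: float = screening.TOX_THRESHOLD
    # trajectory
    detection_alpha: float = trajectory.DETECTION_ALPHA
    k_sigma: float = trajectory.K_SIGMA
    majority_fraction: float = trajectory.MAJORITY_FRACTION
    subsample_genes: int = 500
    subsample_reps: int = 100
    # similarity
    n_perm: int = 10_000
    # capnet
    fold: float = capnet.FOLD_CHANGE
    min_conf: float = capnet.MIN_EDGE_CONFIDENCE
    min_support: int = capnet.MIN_SUPPORT
    n_null: int = 10_000
    capnet_day: int = 5
    # optional pre-existing inputs (paths); simulated when None
    ppi_path: str | None = None
    targets_path: str | None = None
    expression_path: str | None = None
    expression_meta_path: str | None = None
    screen_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.detection_alpha < 1:
            raise ValueError("detection_alpha must lie in (0, 1)")
        if self.k_sigma <= 0 or self.fold <= 1:
            raise ValueError("k_sigma must be > 0 and fold > 1")
        if not 0 < self.majority_fraction < 1:
            raise ValueError("majority_fraction must lie in (0, 1)")
        if not 0 <= self.min_conf <= 1:
            raise ValueError("min_conf must lie in [0, 1]")
        if self.min_support < 1 or self.n_perm < 1 or self.n_null < 1:
            raise ValueError("min_support, n_perm and n_null must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["days"] = list(d["sim"]["days"])
        d["sim"]["ppi_conf_range"] = list(d["sim"]["ppi_conf_range"])
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(cfg: RunConfig, outdir) -> dict:
    """Run every stage and write the full artifact bundle to ``outdir``.

    Returns a dict of artifact paths. Any stage failure is re-raised with
    the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # -- inputs -----------------------------------------------------
        stage = "simulate"
        if cfg.expression_path:
            data = io.read_expression(cfg.expression_path, cfg.expression_meta_path)
            truth = None
        else:
            data, truth = synthetic.gen_expression_dataset(
                cfg.sim, rng=stage_rng(cfg.seed, "expression")
            )
        if cfg.screen_path:
            screen_table = io.read_screen(cfg.screen_path)
        else:
            screen_table, screen_truth = synthetic.gen_screen_table(
                cfg.sim,
                n_library=cfg.n_library,
                n_effective=cfg.n_effective,
                n_toxic=cfg.n_toxic,
                rng=stage_rng(cfg.seed, "screen"),
            )
        if cfg.ppi_path:
            if not Path(cfg.ppi_path).exists():
                raise FileNotFoundError(f"PPI network file not found: {cfg.ppi_path}")
            net = io.read_ppi(cfg.ppi_path)
            net_truth = None
        else:
            net, net_truth = synthetic.gen_ppi_network(
                cfg.sim, rng=stage_rng(cfg.seed, "network")
            )
        if cfg.targets_path:
            targets_tbl = io.read_targets(cfg.targets_path)
        else:
            targets_tbl, net_truth = synthetic.gen_drug_targets(
                cfg.sim,
                truth=net_truth,
                nodes=list(net.nodes),
                rng=stage_rng(cfg.seed, "network"),
            )
        fps = synthetic.gen_fingerprints(cfg.sim, rng=stage_rng(cfg.seed, "fingerprints"))

        # -- screening --------------------------------------------------
        stage = "screen"
        log.info("screen: calling hits on %d drugs", screen_table["drug"].nunique())
        calls = screening.screen(screen_table, diff_threshold=cfg.diff_z,
                                 tox_threshold=cfg.tox_z)
        artifacts["hits"] = outdir / "hits.tsv"
        calls.to_csv(artifacts["hits"], sep="\t")

        # -- trajectory -------------------------------------------------
        stage = "trajectory"
        detected = trajectory.filter_detected(data, alpha=cfg.detection_alpha)
        model = trajectory.fit_control_model(detected)
        log.info("trajectory: %d/%d genes detected", detected.n_genes, data.n_genes)
        assignment = trajectory.assign_categories(
            detected, model, k=cfg.k_sigma, majority_fraction=cfg.majority_fraction
        )
        cats = assignment.flags.copy()
        cats.insert(0, "category", assignment.labels)
        artifacts["categories"] = outdir / "categories.tsv"
        cats.to_csv(artifacts["categories"], sep="\t", index_label="gene")

        disp = trajectory.subsample_dispersion(
            detected,
            model,
            n_genes=min(cfg.subsample_genes, detected.n_genes),
            n_reps=cfg.subsample_reps,
            seed=cfg.seed,
        )
        artifacts["dispersion"] = outdir / "dispersion.tsv"
        disp.to_csv(artifacts["dispersion"], sep="\t", index=False)

        coords, evr = trajectory.pca_project(detected)
        coords["explained_variance_ratio"] = np.resize(evr, len(coords))
        artifacts["pca"] = outdir / "pca.tsv"
        coords.to_csv(artifacts["pca"], sep="\t", index_label="sample_id")

        # -- similarity -------------------------------------------------
        stage = "similarity"
        drugs = data.drugs
        top_dose = screen_table["dose"].max()
        eff = {
            d: float(
                screen_table.set_index(["drug", "dose"])["pct_differentiated"].get(
                    (d, top_dose), 50.0
                )
            )
            for d in drugs
        }
        deg_sets = {
            d: capnet.select_degs(detected, model, d, day=cfg.capnet_day, fold=cfg.fold)
            for d in drugs
        }
        pairs = similarity.pairwise_metrics(
            drugs,
            fingerprints={d: fps[d] for d in drugs if d in fps},
            target_table=targets_tbl,
            efficiencies=eff,
            deg_sets=deg_sets,
        )
        artifacts["similarity"] = outdir / "similarity_pairs.tsv"
        pairs.to_csv(artifacts["similarity"], sep="\t", index=False)

        # -- capnet ------------------------------------------------------
        stage = "capnet"
        tsets = similarity.target_sets(targets_tbl, cfg.min_conf)
        spnets = []
        for d in drugs:
            if not tsets.get(d) or not deg_sets.get(d):
                log.warning("capnet: skipping %s (no targets or no DEGs)", d)
                continue
            # planted network genes and expression genes live in different
            # namespaces in the synthetic setting; fall back to planted DEG
            # nodes when none of the expression DEGs map onto the network
            degs = {g for g in deg_sets[d] if g in net}
            if not degs and net_truth is not None and net_truth.deg_node:
                degs = {net_truth.deg_node}
            if not degs:
                log.warning("capnet: skipping %s (no DEGs on the network)", d)
                continue
            spnets.append(
                capnet.build_spnet(net, tsets[d], degs, min_conf=cfg.min_conf, drug=d)
            )
        if len(spnets) < 2:
            raise ValueError("fewer than 2 drugs with usable SPNets")
        cap = capnet.intersect_spnets(spnets, min_support=cfg.min_support)
        if cap.edges:
            capnet.capnet_pvalues(
                cap, net, n_null=cfg.n_null, rng=stage_rng(cfg.seed, "capnet"),
                min_conf=cfg.min_conf,
            )
        capnet.annotate_nodes(cap, targets_by_drug={d: tuple(tsets.get(d, ())) for d in drugs})
        cap_paths = io.write_capnet(cap, outdir)
        artifacts["capnet_edges"] = cap_paths["edges"]

        # -- report ------------------------------------------------------
        stage = "report"
        summary = outdir / "summary.md"
        hits = screening.select_effective(calls, cfg.diff_z, cfg.tox_z)
        counts = assignment.counts()
        lines = [
            "# exitpaths run summary",
            "",
            f"- seed: {cfg.seed}",
            f"- screen hits ({len(hits)}): {', '.join(hits)}",
            f"- genes after detection filter: {detected.n_genes}/{data.n_genes}",
            "- category counts: "
            + ", ".join(f"{c}={int(n)}" for c, n in counts.items()),
            f"- CAP-Net edges (support >= {cfg.min_support}): {len(cap.edges)}",
        ]
        summary.write_text("\n".join(lines) + "\n")
        artifacts["summary"] = summary

        manifest = {
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "versions": {
                "exitpaths": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": sys.version.split()[0],
            },
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        artifacts["manifest"] = outdir / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
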