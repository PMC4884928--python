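"""Time-course trajectory analysis: error model, differential calls,
divergence-convergence classification and dispersion statistics.

The analysis rests on an empirical error model fitted to untreated
replicates: per-gene mean ``x0_i`` and SD ``sigma0_i``. A gene in a treated
sample is *differential* when its expression departs from the control mean by
more than ``k * sigma0_i`` (default k=3, strict inequality).

Divergence between drugs at a given day is measured by the mean absolute
pairwise difference of a gene's expression across all unordered drug pairs
(M = D(D-1)/2 pairs). A gene is *divergent-convergent* when that mean exceeds
``3 sigma0_i`` at one of the early days but falls below it at the final day —
trajectories fan out, then converge.

Combining three per-gene flags — divergent-convergent (D), net change at the
final day (N), transient differential response (T) — genes are classified
into five trajectory categories:

====== ==============================
label  definition
====== ==============================
C1     D and not N
C3     D and N
C4     not D and N
C2     not D, T (and therefore not N)
C5     any other gene differential in >= 1 drug at >= 1 day
====== ==============================

with everything else labelled ``background``. N and T use a configurable
majority quorum across drugs (default: more than half).

Sample-to-sample dispersion is quantified by a modified Pearson correlation:
each gene's deviation is taken from its own temporal mean over that drug's
time course (day 0 = control mean, then the treated days) rather than from
the sample-wide mean, i.e. it correlates temporal departures, not absolute
expression levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import ControlErrorModel, ExpressionDataset

K_SIGMA = 3.0
MAJORITY_FRACTION = 0.5
DETECTION_ALPHA = 0.05

CATEGORY_LABELS = ("C1", "C2", "C3", "C4", "C5", "background")


# ---------------------------------------------------------------------------
# error model and filtering
# ---------------------------------------------------------------------------

def fit_control_model(data: ExpressionDataset) -> ControlErrorModel:
    """Per-gene mean and sample SD over the untreated replicate columns."""
    cols = data.control_columns()
    if len(cols) < 2:
        raise ValueError(f"need >= 2 control replicates, found {len(cols)}")
    ctrl = data.values[cols]
    return ControlErrorModel(
        mean=ctrl.mean(axis=1), sd=ctrl.std(axis=1, ddof=1), n_replicates=len(cols)
    )


def filter_detected(data: ExpressionDataset, alpha: float = DETECTION_ALPHA) -> ExpressionDataset:
    """Keep genes detected (p <= alpha) in at least one sample of any series.

    A gene passes if any of its time-series samples (any drug, any day,
    controls included) has detection p-value at or below ``alpha``.
    """
    if data.detection is None:
        raise ValueError("dataset has no detection p-value matrix")
    keep = (data.detection <= alpha).any(axis=1)
    return data.subset_genes(data.genes[keep])


# ---------------------------------------------------------------------------
# differential calls
# ---------------------------------------------------------------------------

def is_differential(
    x: float, model: ControlErrorModel, gene: str, k: float = K_SIGMA
) -> bool:
    """Whether one expression value departs from control by more than k sigma."""
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in control model")
    sd = model.sd[gene]
    if sd == 0:
        raise ValueError(f"sigma0 = 0 for gene {gene!r}: k-sigma test undefined")
    return bool(abs(x - model.mean[gene]) > k * sd)


def differential_matrix(
    data: ExpressionDataset,
    model: ControlErrorModel,
    day: int,
    k: float = K_SIGMA,
) -> pd.DataFrame:
    """Genes x drugs boolean matrix of k-sigma differential calls at one day.

    Genes with zero control SD yield ``False`` everywhere here; callers that
    need them surfaced should consult ``model.degenerate_genes()``.
    """
    drugs = data.drugs
    cols = [data.sample_for(d, day) for d in drugs]
    x = data.values.loc[model.genes, cols].to_numpy()
    dev = np.abs(x - model.mean.to_numpy()[:, None])
    thr = k * model.sd.to_numpy()[:, None]
    flags = (dev > thr) & (model.sd.to_numpy()[:, None] > 0)
    return pd.DataFrame(flags, index=model.genes, columns=drugs)


# ---------------------------------------------------------------------------
# pairwise divergence
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDiffs:
    """Per-gene absolute expression differences over all drug pairs at a day."""

    diffs: pd.DataFrame          # genes x pair labels, non-negative
    pairs: list[tuple[str, str]]
    day: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mean_per_gene(self) -> pd.Series:
        """(1/M) sum over pairs of |x_a - x_b|, per gene."""
        return self.diffs.mean(axis=1)


def pairwise_diffs(data: ExpressionDataset, day: int) -> PairwiseDiffs:
    """Absolute between-drug differences |x_i^a(day) - x_i^b(day)| per gene.

    Every unordered pair of distinct drugs contributes one column;
    M = D(D-1)/2 for D drugs.
    """
    drugs = data.drugs
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs for pairwise differences")
    cols = {}
    for d in drugs:
        cols[d] = data.sample_for(d, day)  # raises naming the missing drug/day
    mat = data.values[[cols[d] for d in drugs]].to_numpy()
    pairs = list(itertools.combinations(range(len(drugs)), 2))
    ia = [a for a, _ in pairs]
    ib = [b for _, b in pairs]
    diffs = np.abs(mat[:, ia] - mat[:, ib])
    labels = [f"{drugs[a]}|{drugs[b]}" for a, b in pairs]
    return PairwiseDiffs(
        diffs=pd.DataFrame(diffs, index=data.genes, columns=labels),
        pairs=[(drugs[a], drugs[b]) for a, b in pairs],
        day=day,
    )


def classify_divergent_convergent(
    diffs_by_day: dict[int, PairwiseDiffs],
    model: ControlErrorModel,
    k: float = K_SIGMA,
) -> tuple[pd.Series, list[str]]:
    """Flag genes whose between-drug dispersion spikes early and resolves late.

    Condition: mean pairwise difference > k*sigma0 at any non-final day, AND
    < k*sigma0 at the final day (strict inequalities on both sides).

    Returns the boolean flag per gene and the list of genes excluded because
    their control SD is zero.
    """
    days = sorted(diffs_by_day)
    if len(days) < 2:
        raise ValueError("need diffs for at least an early and a final day")
    means = {t: diffs_by_day[t].mean_per_gene() for t in days}
    genes = means[days[0]].index
    thr = k * model.sd.reindex(genes)

    early = np.zeros(len(genes), dtype=bool)
    for t in days[:-1]:
        early |= (means[t] > thr).to_numpy()
    final_ok = (means[days[-1]] < thr).to_numpy()
    flags = early & final_ok

    degenerate = model.sd.reindex(genes) == 0
    flags = pd.Series(flags & ~degenerate.to_numpy(), index=genes, name="divergent_convergent")
    return flags, list(genes[degenerate])


# ---------------------------------------------------------------------------
# category assignment
# ---------------------------------------------------------------------------

@dataclass
class CategoryAssignment:
    """Per-gene trajectory category plus the three defining flags."""

    labels: pd.Series            # gene -> C1..C5 / background
    flags: pd.DataFrame          # divergent_convergent, net_changed, transient, any_differential
    excluded: list[str]          # sigma0 == 0, left out of classification

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CATEGORY_LABELS, fill_value=0)


def assign_categories(
    data: ExpressionDataset,
    model: ControlErrorModel,
    dc_flags: pd.Series | None = None,
    k: float = K_SIGMA,
    majority_fraction: float = MAJORITY_FRACTION,
) -> CategoryAssignment:
    """Classify genes into trajectory categories C1-C5 / background.

    ``dc_flags`` may carry precomputed divergent-convergent flags; otherwise
    they are derived here from the dataset's treated days.
    """
    days = [t for t in data.days if t != 0]
    final = days[-1]
    early = days[:-1]

    if dc_flags is None:
        diffs = {t: pairwise_diffs(data, t) for t in days}
        dc_flags, excluded = classify_divergent_convergent(diffs, model, k=k)
    else:
        excluded = list(model.degenerate_genes())

    diff_by_day = {t: differential_matrix(data, model, t, k=k) for t in days}
    n_drugs = len(data.drugs)

    net = diff_by_day[final].sum(axis=1) > majority_fraction * n_drugs
    early_per_drug = diff_by_day[early[0]].copy()
    for t in early[1:]:
        early_per_drug |= diff_by_day[t]
    transient = (early_per_drug.sum(axis=1) > majority_fraction * n_drugs) & ~net
    any_diff = diff_by_day[days[0]].any(axis=1)
    for t in days[1:]:
        any_diff |= diff_by_day[t].any(axis=1)

    d = dc_flags.reindex(model.genes).fillna(False).astype(bool)
    labels = pd.Series("background", index=model.genes, name="category")
    labels[any_diff] = "C5"
    labels[~d & transient & ~net] = "C2"
    labels[~d & net] = "C4"
    labels[d & net] = "C3"
    labels[d & ~net] = "C1"
    labels[labels.index.isin(excluded)] = "background"

    flags = pd.DataFrame(
        {
            "divergent_convergent": d,
            "net_changed": net,
            "transient": transient,
            "any_differential": any_diff,
        }
    )
    return CategoryAssignment(labels=labels, flags=flags, excluded=excluded)


# ---------------------------------------------------------------------------
# modified Pearson correlation and dispersion
# ---------------------------------------------------------------------------

def modified_pearson(
    sample_a,
    sample_b,
    temporal_means,
    temporal_means_b=None,
) -> float:
    """Pearson-form correlation of deviations from temporal means.

    r = sum_i (a_i - m_i)(b_i - m'_i) / (||a - m|| * ||b - m'||)

    where m is each gene's mean over its own drug's time course. When
    ``temporal_means_b`` is omitted both samples deviate from the same means
    vector. With per-sample constant means equal to each sample's cross-gene
    mean, this reduces exactly to the standard Pearson correlation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    ma = np.asarray(temporal_means, dtype=float)
    mb = ma if temporal_means_b is None else np.asarray(temporal_means_b, dtype=float)
    if not (a.shape == b.shape == ma.shape == mb.shape):
        raise ValueError("samples and means must share one gene set")
    if a.size < 2:
        raise ValueError("need >= 2 genes")
    da, db = a - ma, b - mb
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("degenerate sample: zero deviation norm")
    return float(np.clip(np.dot(da, db) / (na * nb), -1.0, 1.0))


def temporal_means(data: ExpressionDataset, model: ControlErrorModel) -> pd.DataFrame:
    """Per-drug gene means over that drug's course (control mean as day 0)."""
    days = [t for t in data.days if t != 0]
    out = {}
    for drug in data.drugs:
        cols = [data.sample_for(drug, t) for t in days]
        course = pd.concat([model.mean.rename("day0"), data.values[cols]], axis=1)
        out[drug] = course.mean(axis=1)
    return pd.DataFrame(out)


def dispersion_by_day(
    data: ExpressionDataset,
    model: ControlErrorModel,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """All same-day cross-drug modified-Pearson correlations.

    Each sample's deviations are taken from its *own* drug's temporal means.
    Returns a long DataFrame (day, drug_a, drug_b, r).
    """
    drugs = data.drugs
    days = [t for t in data.days if t != 0]
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs")
    means = temporal_means(data, model)
    if genes is not None:
        means = means.loc[genes]
    rows = []
    for day in days:
        devs = {}
        for d in drugs:
            col = data.values[data.sample_for(d, day)]
            if genes is not None:
                col = col.loc[genes]
            devs[d] = (col - means[d]).to_numpy()
        for a, b in itertools.combinations(drugs, 2):
            da, db = devs[a], devs[b]
            r = float(np.dot(da, db) / (np.linalg.norm(da) * np.linalg.norm(db)))
            rows.append((day, a, b, r))
    return pd.DataFrame(rows, columns=["day", "drug_a", "drug_b", "r"])


def subsample_dispersion(
    data: ExpressionDataset,
    model: ControlErrorModel,
    n_genes: int = 500,
    n_reps: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dispersion distributions over repeated random gene subsets.

    Repeats :func:`dispersion_by_day` on ``n_reps`` random subsets of
    ``n_genes`` genes. Deterministic under a fixed seed. Returns a long
    DataFrame (rep, day, drug_a, drug_b, r).
    """
    if n_genes > data.n_genes:
        raise ValueError(f"requested {n_genes} genes but dataset has {data.n_genes}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    all_genes = data.genes.to_numpy()
    for rep in range(n_reps):
        subset = pd.Index(rng.choice(all_genes, size=n_genes, replace=False))
        d = dispersion_by_day(data, model, genes=subset)
        d.insert(0, "rep", rep)
        out.append(d)
    return pd.concat(out, ignore_index=True)


def pca_project(data: ExpressionDataset, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples in gene space.

    Returns per-sample coordinates on the top components and the
    explained-variance fractions.
    """
    if data.n_samples < n_components:
        raise ValueError("fewer samples than requested components")
    x = data.values.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=data.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
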