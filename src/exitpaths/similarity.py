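"""Chemical, target and efficacy similarity statistics among drugs.

Three pairwise metrics:

* Tanimoto score ``TS = XY / (X + Y - XY)`` on binary structure
  fingerprints, where X and Y are the set-bit counts of the two
  fingerprints and XY the set-bit count of their AND;
* Jaccard index ``JI = |A & B| / |A | B|`` on (filtered) target sets;
* Efficiency similarity ``Eff-Sim(a, b) = 100 - |E(a) - E(b)|`` on
  differentiation efficiencies in percent.

Target sharing between a drug pair is tested against a permutation null:
draw random pairs from the whole library and count how often they share at
least as many high-confidence targets as the observed pair. Drug-target
rows are filtered at confidence >= 0.8 (inclusive) before any counting.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

MIN_TARGET_CONFIDENCE = 0.8


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity of two equal-length binary fingerprints."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    x = int(a.sum())
    y = int(b.sum())
    xy = int((a & b).sum())
    denom = x + y - xy
    if denom == 0:
        raise ValueError("both fingerprints empty: Tanimoto undefined (0/0)")
    return xy / denom


def jaccard(set_a, set_b) -> float:
    """Jaccard index of two sets; undefined (error) when both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both sets empty: Jaccard undefined")
    return len(a & b) / len(union)


def efficiency_similarity(e_a: float, e_b: float) -> float:
    """100 minus the absolute difference of two efficiencies (in percent)."""
    for e in (e_a, e_b):
        if not 0.0 <= e <= 100.0:
            raise ValueError(f"efficiency {e} outside [0, 100]")
    return 100.0 - abs(e_a - e_b)


# ---------------------------------------------------------------------------
# target tables
# ---------------------------------------------------------------------------

def filter_targets(
    table: pd.DataFrame, min_conf: float = MIN_TARGET_CONFIDENCE
) -> pd.DataFrame:
    """Rows with confidence >= min_conf (inclusive boundary), schema preserved."""
    for col in ("drug", "target", "confidence"):
        if col not in table.columns:
            raise ValueError(f"target table missing column {col!r}")
    if ((table["confidence"] < 0) | (table["confidence"] > 1)).any():
        raise ValueError("confidence outside [0, 1]")
    if table.duplicated(["drug", "target"]).any():
        raise ValueError("duplicate (drug, target) rows")
    return table[table["confidence"] >= min_conf].reset_index(drop=True)


def target_sets(
    table: pd.DataFrame, min_conf: float = MIN_TARGET_CONFIDENCE
) -> dict[str, frozenset]:
    """Drug -> high-confidence target set (possibly empty for listed drugs)."""
    filtered = filter_targets(table, min_conf)
    sets = {d: frozenset(g["target"]) for d, g in filtered.groupby("drug")}
    for d in table["drug"].unique():
        sets.setdefault(d, frozenset())
    return sets


def shared_target_pvalue(
    pair: tuple[str, str],
    table: pd.DataFrame,
    library: list[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_conf: float = MIN_TARGET_CONFIDENCE,
) -> tuple[float, int]:
    """Permutation p-value for the shared-target count of one drug pair.

    Draws ``n_perm`` random drug pairs (uniform, distinct within a pair, with
    replacement across draws) from ``library`` and computes

        p = (1 + #{draws with shared count >= k_obs}) / (n_perm + 1)

    the add-one empirical estimate, which never returns exactly zero.
    Returns ``(p, k_obs)``.
    """
    if len(library) < 10:
        raise ValueError("library must contain >= 10 drugs")
    sets = target_sets(table, min_conf)
    for d in pair:
        if d not in library:
            raise ValueError(f"drug {d!r} not in library")
        sets.setdefault(d, frozenset())
    k_obs = len(sets[pair[0]] & sets[pair[1]])
    if rng is None:
        rng = np.random.default_rng(seed)

    # incidence matrix over the library's target universe -> pair counts
    lib = list(library)
    universe = sorted(set().union(*(sets.get(d, frozenset()) for d in lib)) or set())
    if universe:
        col = {t: j for j, t in enumerate(universe)}
        inc = np.zeros((len(lib), len(universe)), dtype=np.int32)
        for i, d in enumerate(lib):
            for t in sets.get(d, frozenset()):
                inc[i, col[t]] = 1
        shared = inc @ inc.T
    else:
        shared = np.zeros((len(lib), len(lib)), dtype=np.int32)

    ia = rng.integers(0, len(lib), n_perm)
    ib = rng.integers(0, len(lib) - 1, n_perm)
    ib = np.where(ib >= ia, ib + 1, ib)  # distinct partner, uniform
    exceed = int((shared[ia, ib] >= k_obs).sum())
    return (1 + exceed) / (n_perm + 1), k_obs


def library_baselines(
    effective: list[str],
    library: list[str],
    fingerprints: dict[str, np.ndarray],
    table: pd.DataFrame,
    min_conf: float = MIN_TARGET_CONFIDENCE,
) -> pd.DataFrame:
    """Per library drug: max shared-target count and max TS vs the hit set.

    Histogram-ready vectors for comparing the whole library against the
    effective (hit) drugs.
    """
    sets = target_sets(table, min_conf)
    rows = []
    for d in library:
        own = sets.get(d, frozenset())
        max_shared = max(
            (len(own & sets.get(e, frozenset())) for e in effective), default=0
        )
        max_ts = max((tanimoto(fingerprints[d], fingerprints[e]) for e in effective
                      if d in fingerprints and e in fingerprints), default=np.nan)
        rows.append((d, max_shared, max_ts))
    return pd.DataFrame(rows, columns=["drug", "max_shared_targets", "max_ts"]).set_index("drug")


# ---------------------------------------------------------------------------
# pairwise similarity tables and correlations
# ---------------------------------------------------------------------------

def pairwise_metrics(
    drugs: list[str],
    fingerprints: dict[str, np.ndarray] | None = None,
    target_table: pd.DataFrame | None = None,
    efficiencies: dict[str, float] | None = None,
    deg_sets: dict[str, set] | None = None,
    min_conf: float = MIN_TARGET_CONFIDENCE,
) -> pd.DataFrame:
    """One row per unordered drug pair with every available similarity metric.

    Columns among ``ts``, ``target_jaccard``, ``shared_targets``,
    ``deg_jaccard``, ``eff_sim`` depending on which inputs are given. Jaccard
    entries are NaN when both sets are empty.
    """
    sets = target_sets(target_table, min_conf) if target_table is not None else None
    rows = []
    for a, b in itertools.combinations(drugs, 2):
        row: dict = {"drug_a": a, "drug_b": b}
        if fingerprints is not None:
            row["ts"] = tanimoto(fingerprints[a], fingerprints[b])
        if sets is not None:
            sa, sb = sets.get(a, frozenset()), sets.get(b, frozenset())
            row["shared_targets"] = len(sa & sb)
            row["target_jaccard"] = jaccard(sa, sb) if (sa | sb) else np.nan
        if deg_sets is not None:
            da, db = set(deg_sets.get(a, set())), set(deg_sets.get(b, set()))
            row["deg_jaccard"] = jaccard(da, db) if (da | db) else np.nan
        if efficiencies is not None:
            row["eff_sim"] = efficiency_similarity(efficiencies[a], efficiencies[b])
        rows.append(row)
    return pd.DataFrame(rows)


def similarity_correlations(
    pairs: pd.DataFrame, against: str = "eff_sim"
) -> pd.Series:
    """Pearson correlation of each similarity metric with efficacy similarity.

    ``pairs`` is the output of :func:`pairwise_metrics`; every numeric metric
    column other than ``against`` is correlated with it across pairs.
    """
    if against not in pairs.columns:
        raise ValueError(f"column {against!r} absent")
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    y = pairs[against].to_numpy(dtype=float)
    out = {}
    for col in pairs.columns:
        if col in ("drug_a", "drug_b", against):
            continue
        x = pairs[col].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3:
            continue
        if np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
            raise ValueError(f"degenerate (constant) vector for {col!r} or {against!r}")
        out[col] = float(stats.pearsonr(x[mask], y[mask]).statistic)
    return pd.Series(out, name=f"pearson_vs_{against}")
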