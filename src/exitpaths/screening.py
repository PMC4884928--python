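"""Hit calling for a differentiation drug screen.

Each drug in the library is summarized at a reference dose by two library-wide
Z-scores: ``z_diff`` for the percentage of differentiated (marker-positive)
cells and ``z_tox`` for the surviving live-cell count. A drug is called
*effective* when it differentiates well above the library (``z_diff`` above a
high threshold, default 1.8) without being toxic (``z_tox`` above a lower
bound, default -1). Z-scores use the sample standard deviation (ddof=1)
across the library at that dose.
"""

from __future__ import annotations

import pandas as pd

DIFF_THRESHOLD = 1.8
TOX_THRESHOLD = -1.0

REQUIRED_COLUMNS = ("drug", "dose", "pct_differentiated", "live_cells")


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    pct = table["pct_differentiated"]
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("pct_differentiated outside [0, 100]")
    if (table["live_cells"] < 0).any():
        raise ValueError("negative live_cells")
    if table.duplicated(["drug", "dose"]).any():
        raise ValueError("duplicate (drug, dose) rows")


def compute_zscores(table: pd.DataFrame, dose: float | None = None) -> pd.DataFrame:
    """Per-drug Z-scores of differentiation and viability at one dose.

    Parameters
    ----------
    table
        Long-format screen table with columns ``drug``, ``dose``,
        ``pct_differentiated``, ``live_cells``.
    dose
        Reference dose; defaults to the highest dose present.

    Returns
    -------
    DataFrame indexed by drug with columns ``pct_differentiated``,
    ``live_cells``, ``z_diff``, ``z_tox``.
    """
    _validate_table(table)
    if dose is None:
        dose = table["dose"].max()
    at_dose = table[table["dose"] == dose]
    if at_dose.empty:
        raise ValueError(f"no rows at dose {dose}")
    missing = sorted(set(table["drug"]) - set(at_dose["drug"]))
    if missing:
        raise ValueError(f"drugs missing a row at dose {dose}: {missing}")
    if len(at_dose) < 2:
        raise ValueError("need >= 2 drugs at the reference dose")

    out = at_dose.set_index("drug")[["pct_differentiated", "live_cells"]].astype(float)
    for col, zcol in (("pct_differentiated", "z_diff"), ("live_cells", "z_tox")):
        sd = out[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate library: zero SD of {col} at dose {dose}")
        out[zcol] = (out[col] - out[col].mean()) / sd
    return out


def hit_calls(
    zscores: pd.DataFrame,
    diff_threshold: float = DIFF_THRESHOLD,
    tox_threshold: float = TOX_THRESHOLD,
) -> pd.DataFrame:
    """Attach the dual-criterion ``effective`` flag to a Z-score table."""
    out = zscores.copy()
    out["effective"] = (out["z_diff"] > diff_threshold) & (out["z_tox"] > tox_threshold)
    return out


def select_effective(
    calls: pd.DataFrame,
    diff_threshold: float = DIFF_THRESHOLD,
    tox_threshold: float = TOX_THRESHOLD,
) -> list[str]:
    """Drugs passing both thresholds, stably sorted by ``z_diff`` descending."""
    passing = calls[(calls["z_diff"] > diff_threshold) & (calls["z_tox"] > tox_threshold)]
    ordered = passing.sort_values("z_diff", ascending=False, kind="mergesort")
    return list(ordered.index)


def screen(
    table: pd.DataFrame,
    dose: float | None = None,
    diff_threshold: float = DIFF_THRESHOLD,
    tox_threshold: float = TOX_THRESHOLD,
) -> pd.DataFrame:
    """Z-scores plus hit flags in one call; convenience over the two steps."""
    return hit_calls(compute_zscores(table, dose), diff_threshold, tox_threshold)
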