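"""Core in-memory containers for expression time courses and control error models.

The central object is :class:`ExpressionDataset`: a genes x samples matrix of
log-scale expression intensities together with per-sample metadata (which drug,
which day) and an optional matrix of detection p-values of identical shape.
Untreated replicate samples carry the drug label ``"control"`` and day 0; they
serve both as the Day-0 point of every drug's time course and as the input to
the control error model (per-gene mean and standard deviation across
replicates) that underlies every 3-sigma differential call downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Drug label reserved for untreated replicate samples.
CONTROL_LABEL = "control"


@dataclass
class ExpressionDataset:
    """Genes x samples log-expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame of log-scale intensities, index = gene ids, columns =
        sample ids.
    meta
        DataFrame indexed by sample id with at least columns ``drug`` and
        ``day``. Must cover every column of ``values``.
    detection
        Optional DataFrame of detection p-values, same shape/labels as
        ``values``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(
                f"metadata missing for {len(missing)} sample(s): {sorted(missing)[:5]}"
            )
        for col in ("drug", "day"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata must have a '{col}' column")
        if self.detection is not None:
            if self.detection.shape != self.values.shape:
                raise ValueError("detection matrix shape differs from value matrix")
            if not (
                self.detection.index.equals(self.values.index)
                and self.detection.columns.equals(self.values.columns)
            ):
                raise ValueError("detection matrix labels differ from value matrix")
        # keep metadata aligned and restricted to present samples
        self.meta = self.meta.loc[self.values.columns]

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    @property
    def drugs(self) -> list[str]:
        """Treatment drug labels (controls excluded), in first-seen order."""
        seen = self.meta["drug"][self.meta["drug"] != CONTROL_LABEL]
        return list(dict.fromkeys(seen))

    @property
    def days(self) -> list[int]:
        return sorted(set(int(d) for d in self.meta["day"]))

    def control_columns(self) -> list[str]:
        return list(self.meta.index[self.meta["drug"] == CONTROL_LABEL])

    def columns_for(self, drug: str, day: int | None = None) -> list[str]:
        mask = self.meta["drug"] == drug
        if day is not None:
            mask &= self.meta["day"] == day
        return list(self.meta.index[mask])

    def sample_for(self, drug: str, day: int) -> str:
        """The unique sample of ``drug`` at ``day``; error if absent/ambiguous."""
        cols = self.columns_for(drug, day)
        if not cols:
            raise KeyError(f"no sample for drug {drug!r} at day {day}")
        if len(cols) > 1:
            raise KeyError(f"multiple samples for drug {drug!r} at day {day}: {cols}")
        return cols[0]

    def subset_genes(self, genes) -> "ExpressionDataset":
        det = self.detection.loc[genes] if self.detection is not None else None
        return ExpressionDataset(self.values.loc[genes], self.meta.copy(), det)


@dataclass
class ControlErrorModel:
    """Per-gene baseline mean and SD estimated from untreated replicates.

    ``sd`` is the sample standard deviation (ddof=1) across replicates; genes
    with zero SD cannot support a sigma-based differential call and are
    surfaced explicitly by consumers.
    """

    mean: pd.Series
    sd: pd.Series
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("control error model requires >= 2 replicates")
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd indexed on different gene sets")
        if (self.sd < 0).any():
            raise ValueError("negative standard deviation")

    @property
    def genes(self) -> pd.Index:
        return self.mean.index

    def degenerate_genes(self) -> pd.Index:
        """Genes with zero replicate SD (3-sigma test undefined)."""
        return self.sd.index[self.sd == 0]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic scenario.

    Only the fields relevant to the generator that produced the object are
    populated; the rest stay ``None``.
    """

    gene_categories: pd.Series | None = None
    undetected_genes: frozenset = frozenset()
    effective_drugs: frozenset = frozenset()
    backbone_edges: frozenset = frozenset()
    entry_edges: dict = field(default_factory=dict)
    drug_targets: dict = field(default_factory=dict)
    entry_node: str | None = None
    deg_node: str | None = None
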