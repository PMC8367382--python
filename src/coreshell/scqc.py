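"""scRNA-seq bookkeeping: CPM, exclusion filters and the retained ledger.

The quality-control rules are applied sequentially: putative
non-neuronal cells are removed first by low Snap25 (CPM < 0.001), then
remaining non-excitatory cells by low Slc17a7 (CPM < 1e-10).  A cell
failing rule *i* is attributed to rule *i* and never re-tested, so the
ledger satisfies n_input = sum(exclusions) + n_retained by
construction; swapping the rule order may change the attribution but
never the retained count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projections import ContingencyTable, contingency_from_counts

log = logging.getLogger(__name__)

#: (gene, strict CPM cutoff) pairs, in application order.
DEFAULT_QC_RULES: tuple[tuple[str, float], ...] = (
    ("Snap25", 1e-3),
    ("Slc17a7", 1e-10),
)


@dataclass
class QCLedger:
    n_input: int
    exclusions: dict[str, int]        # rule gene -> cells excluded by it
    n_retained: int
    reasons: pd.Series                # per-cell: "retained" or rule gene
    rules: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.n_input != sum(self.exclusions.values()) + self.n_retained:
            raise AssertionError("ledger does not conserve cells")

    @property
    def retained_cells(self) -> pd.Index:
        return self.reasons.index[self.reasons == "retained"]


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per cell: 1e6 * count / cell library size."""
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {list(counts.columns[zero][:5])}")
    return pd.DataFrame(1e6 * mat / totals, index=counts.index,
                        columns=counts.columns)


def qc_filter(cpm: pd.DataFrame,
              rules: tuple[tuple[str, float], ...] = DEFAULT_QC_RULES,
              ) -> QCLedger:
    """Sequential low-expression filters with per-rule attribution."""
    for gene, _ in rules:
        if gene not in cpm.index:
            raise KeyError(f"QC gene {gene!r} missing from matrix")
    reasons = pd.Series("retained", index=cpm.columns, dtype=object)
    remaining = pd.Series(True, index=cpm.columns)
    exclusions: dict[str, int] = {}
    for gene, cutoff in rules:
        fail = remaining & (cpm.loc[gene] < cutoff)
        exclusions[gene] = int(fail.sum())
        reasons[fail] = gene
        remaining &= ~fail
    ledger = QCLedger(n_input=len(cpm.columns), exclusions=exclusions,
                      n_retained=int(remaining.sum()), reasons=reasons,
                      rules=tuple(rules))
    log.info("QC: input %d, excluded %s, retained %d", ledger.n_input,
             ledger.exclusions, ledger.n_retained)
    return ledger


def marker_max_classes(cpm: pd.DataFrame,
                       markers: dict[str, str] | None = None) -> pd.Series:
    """Assign each cell the class of its maximal marker CPM.

    A deliberately simple stand-in for full transcriptomic clustering:
    among the core / shell / deep-L6 markers, the highest-CPM marker
    wins (ties -> first marker in order).
    """
    markers = markers or {"synpr_high": "Synpr", "nnat_high": "Nnat",
                          "cortical": "Pcp4"}
    sub = cpm.loc[[g for g in markers.values()]]
    order = list(markers.keys())
    win = np.argmax(sub.to_numpy(), axis=0)
    return pd.Series([order[i] for i in win], index=cpm.columns, name="cls")


def class_projection_contingency(
    class_labels: pd.Series,
    projection_labels: pd.DataFrame,
    class_subset: tuple[str, ...] = ("synpr_high", "nnat_high"),
) -> ContingencyTable:
    """Cross transcriptomic classes with RSC/LEC projection annotations.

    Same count / modal-percentage contract as the mFISH contingency:
    only single-projection cells enter, and the reported percentage per
    projection is its modal class share, integer-rounded.
    """
    common = class_labels.index.intersection(projection_labels.index)
    cls = class_labels.loc[common]
    proj = projection_labels.loc[common]
    single = proj[(proj["rsc"] ^ proj["lec"])]
    counts = pd.DataFrame(0, index=list(class_subset), columns=["RSC", "LEC"])
    for name, col in (("RSC", "rsc"), ("LEC", "lec")):
        sel = cls[single.index[single[col]]]
        vc = sel[sel.isin(class_subset)].value_counts()
        for c, n in vc.items():
            counts.loc[c, name] = int(n)
    return contingency_from_counts(counts)


__all__ = [
    "DEFAULT_QC_RULES", "QCLedger", "compute_cpm", "qc_filter",
    "marker_max_classes", "class_projection_contingency",
]
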