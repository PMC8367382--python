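"""Retrograde projection overlay: label calls, dual exclusion, contingency.

Registered RSC / LEC tracer channels are binarized with an Otsu
threshold guarded by a robust noise floor (tracer fills are areal and
bright, unlike the punctate probe signal, and an empty channel must
yield no calls), and a cell is called labeled when its label PAC
reaches the threshold (default 1, symmetric with the excitatory gate).  Cells labeled for both targets ("dual-projecting")
are excluded before any RSC-vs-LEC comparison, and the remaining
single-projection cells are crossed with core/shell phenotypes into
the contingency table whose column percentages summarize how strongly
each projection maps onto one subtype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_typing import differential_expression, box_summary
from .quantification import PACMatrix, compute_pac
from .segmentation import LabelMask

log = logging.getLogger(__name__)

PROJECTION_CHANNELS = ("RSC", "LEC")


def label_threshold(image: np.ndarray, noise_sigmas: float = 5.0) -> float:
    """Binarization threshold for an areal tracer channel.

    Otsu's threshold separates the bright somatic fill from background,
    floored at median + ``noise_sigmas`` robust (MAD-based) standard
    deviations so a channel with no labeled cells produces no positive
    pixels beyond stray noise.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=np.float64)
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    floor = med + noise_sigmas * 1.4826 * max(mad, 1e-12)
    if np.ptp(img) == 0:
        return floor
    return max(float(threshold_otsu(img)), floor)


def detect_labels(
    label_images: dict[str, np.ndarray],
    rois: LabelMask,
    min_label_pac: float = 1.0,
) -> pd.DataFrame:
    """Per-cell projection calls from registered tracer channels.

    Returns a DataFrame indexed by cell id with per-channel label PACs,
    boolean RSC / LEC flags and ``dual = RSC & LEC``.  A missing channel
    leaves that projection uncalled (all False) with a warning.
    """
    n = rois.n_labels
    idx = pd.RangeIndex(1, n + 1, name="cell_id")
    out = pd.DataFrame(index=idx)
    for ch in PROJECTION_CHANNELS:
        if ch not in label_images:
            warnings.warn(f"label channel {ch} missing; projection uncalled",
                          stacklevel=2)
            out[f"pac_{ch.lower()}"] = 0.0
            out[ch.lower()] = False
            continue
        pos = np.asarray(label_images[ch]) > label_threshold(label_images[ch])
        pac = compute_pac(pos, rois)
        out[f"pac_{ch.lower()}"] = pac
        out[ch.lower()] = pac >= min_label_pac
    out["dual"] = out["rsc"] & out["lec"]
    log.info("label calls: %d RSC, %d LEC, %d dual of %d cells",
             int(out["rsc"].sum()), int(out["lec"].sum()),
             int(out["dual"].sum()), n)
    return out


def exclude_dual(calls: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop dual-projecting cells from RSC-vs-LEC comparisons.

    Returns the retained labeled cells (single projection only) and the
    dual fraction as a percentage of all labeled cells, rounded to one
    decimal.  Unlabeled cells are not counted in the denominator.
    """
    labeled = calls[calls["rsc"] | calls["lec"]]
    n_total = len(labeled)
    n_dual = int(labeled["dual"].sum())
    retained = labeled[~labeled["dual"]].copy()
    frac = round(100.0 * n_dual / n_total, 1) if n_total else 0.0
    return retained, frac


@dataclass
class ContingencyTable:
    """Phenotype x projection counts with modal-phenotype percentages.

    ``percent[proj]`` is 100 * count(modal phenotype, proj) / column
    total, rounded to the nearest integer (NA when the column is empty).
    Percentages always recompute exactly from the stored counts.
    """

    counts: pd.DataFrame               # index phenotypes, columns projections
    modal_phenotype: dict[str, str | None]
    percent: dict[str, float | None]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative contingency counts")
        for proj in self.counts.columns:
            tot = int(self.counts[proj].sum())
            if tot == 0:
                assert self.percent[proj] is None
                continue
            modal = self.modal_phenotype[proj]
            expect = int(round(100.0 * self.counts.loc[modal, proj] / tot))
            if self.percent[proj] != expect:
                raise AssertionError("percentage does not recompute from counts")

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def contingency_from_counts(counts: pd.DataFrame,
                            modal: dict[str, str] | None = None,
                            ) -> ContingencyTable:
    """Build the table (and its percentages) from raw counts.

    ``modal`` optionally pins the phenotype whose share is reported per
    projection; by default the most frequent phenotype in each column.
    """
    counts = counts.astype(int)
    modal_phenotype: dict[str, str | None] = {}
    percent: dict[str, float | None] = {}
    for proj in counts.columns:
        tot = int(counts[proj].sum())
        if tot == 0:
            modal_phenotype[proj] = None
            percent[proj] = None
            continue
        m = (modal or {}).get(proj) or counts[proj].idxmax()
        modal_phenotype[proj] = m
        percent[proj] = int(round(100.0 * counts.loc[m, proj] / tot))
    return ContingencyTable(counts=counts, modal_phenotype=modal_phenotype,
                            percent=percent)


def build_contingency(
    phenotypes: pd.Series,
    calls: pd.DataFrame,
    phenotype_subset: tuple[str, ...] = ("core", "shell"),
) -> ContingencyTable:
    """Cross single-projection calls with cell phenotypes.

    ``phenotypes`` is indexed by cell id; ``calls`` are the retained
    (dual-excluded) projection calls.  Only cells whose phenotype is in
    ``phenotype_subset`` enter the table, matching the claustral focus
    of the projection comparison.
    """
    common = calls.index.intersection(phenotypes.index)
    missing = calls.index.difference(phenotypes.index)
    if len(missing):
        raise KeyError(f"calls reference unknown cells: {list(missing)[:5]}")
    ph = phenotypes.loc[common]
    sub = calls.loc[common]
    counts = pd.DataFrame(0, index=list(phenotype_subset),
                          columns=list(PROJECTION_CHANNELS))
    for proj in PROJECTION_CHANNELS:
        sel = ph[sub[proj.lower()]]
        vc = sel[sel.isin(phenotype_subset)].value_counts()
        for pheno, c in vc.items():
            counts.loc[pheno, proj] = int(c)
    return contingency_from_counts(counts)


def projection_de(
    pac_raw: PACMatrix,
    calls: pd.DataFrame,
    genes: tuple[str, ...] = ("Synpr", "Nnat"),
) -> tuple[pd.DataFrame, dict[str, dict[str, dict[str, float]]]]:
    """Marker DE between RSC- and LEC-projecting cells, with box summaries.

    ``calls`` must already be dual-excluded.  Returns the Mann-Whitney /
    Bonferroni table plus, per gene and projection group, the quartile
    hinges and 1.5*IQR whiskers used for box plots.
    """
    idx = pac_raw.values.index
    rsc_cells = calls.index[calls["rsc"]].intersection(idx)
    lec_cells = calls.index[calls["lec"]].intersection(idx)
    if len(rsc_cells) == 0 or len(lec_cells) == 0:
        raise ValueError("both projection groups must be non-empty")
    de = differential_expression(pac_raw, rsc_cells, lec_cells,
                                 genes=list(genes))
    de = de.rename(columns={"median_a": "median_rsc", "median_b": "median_lec"})
    boxes = {
        g: {"RSC": box_summary(pac_raw.values.loc[rsc_cells, g].to_numpy()),
            "LEC": box_summary(pac_raw.values.loc[lec_cells, g].to_numpy())}
        for g in genes
    }
    return de, boxes


__all__ = [
    "PROJECTION_CHANNELS", "ContingencyTable", "detect_labels",
    "exclude_dual", "contingency_from_counts", "build_contingency",
    "projection_de",
]
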