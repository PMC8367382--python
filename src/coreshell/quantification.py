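"""Percent-area-covered (PAC) quantification of probe signal.

Each registered probe image is binarized at the last 0.2-1% of its
intensity histogram (a per-section, per-gene quantile threshold); a
cell's PAC for a gene is then 100 x (positive pixels inside the cell's
somatic ROI) / (ROI pixel area).  Cells are gated as excitatory when
Slc17a7 PAC >= 1, after which Slc17a7 is dropped from the matrix, and
profiles are normalized within each cell to unit sum for embedding and
clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .segmentation import LabelMask

log = logging.getLogger(__name__)

#: Allowed histogram-tail range; the default sits at its midpoint.
TAIL_FRACTION_BOUNDS = (0.002, 0.01)
DEFAULT_TAIL_FRACTION = 0.005


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-gene histogram-tail fractions (scope: one section)."""

    default: float = DEFAULT_TAIL_FRACTION
    per_gene: dict[str, float] = field(default_factory=dict)
    allow_out_of_bounds: bool = False

    def __post_init__(self) -> None:
        lo, hi = TAIL_FRACTION_BOUNDS
        if not self.allow_out_of_bounds:
            for name, f in {"default": self.default, **self.per_gene}.items():
                if not lo <= f <= hi:
                    raise ValueError(
                        f"tail fraction for {name} ({f}) outside [{lo}, {hi}]; "
                        "set allow_out_of_bounds=True to override")

    def fraction(self, gene: str) -> float:
        return self.per_gene.get(gene, self.default)


@dataclass
class PACMatrix:
    """Cells x genes PAC values with per-cell and per-gene metadata."""

    values: pd.DataFrame                 # index = cell id, columns = genes
    cells: pd.DataFrame                  # index = cell id: x_um, y_um, ...
    genes: pd.DataFrame | None = None    # index = gene: round, channel
    normalized: bool = False
    zero_rows: pd.Index | None = None    # all-zero rows flagged at normalization

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.cells.index):
            raise ValueError("values and cell metadata must share an index")
        if not self.normalized:
            v = self.values.to_numpy()
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError("raw PAC values must lie in [0, 100]")

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def copy(self) -> "PACMatrix":
        return PACMatrix(values=self.values.copy(), cells=self.cells.copy(),
                         genes=None if self.genes is None else self.genes.copy(),
                         normalized=self.normalized, zero_rows=self.zero_rows)


def compute_threshold(probe_image: np.ndarray, tail_fraction: float) -> float:
    """Smallest intensity t with strictly-above-t fraction <= tail_fraction.

    The quantile is taken over the full image histogram, so the
    resulting binarization is invariant to any monotone intensity
    rescaling applied beforehand.
    """
    if not 0.0 < tail_fraction < 1.0:
        raise ValueError("tail_fraction must be in (0, 1)")
    img = np.asarray(probe_image)
    flat = img.ravel()
    if flat.size == 0:
        raise ValueError("empty image")
    if np.ptp(flat) == 0:
        warnings.warn("constant image: threshold equals the constant",
                      stacklevel=2)
        return float(flat[0])
    k = int(np.floor(tail_fraction * flat.size))
    if k == 0:
        return float(flat.max())
    # t = (k+1)-th largest value: exactly the k larger values can exceed it
    t = np.partition(flat, flat.size - k - 1)[flat.size - k - 1]
    return float(t)


def binarize(probe_image: np.ndarray, tail_fraction: float) -> np.ndarray:
    """Positive-pixel mask: strictly above the tail threshold."""
    t = compute_threshold(probe_image, tail_fraction)
    return np.asarray(probe_image) > t


def compute_pac(binary_positive: np.ndarray, rois: LabelMask) -> pd.Series:
    """Per-cell PAC: 100 x positive pixels in ROI / ROI pixel area."""
    mask = np.asarray(binary_positive, dtype=bool)
    if mask.shape != rois.labels.shape:
        raise ValueError("mask and ROI image must share a shape")
    n = rois.n_labels
    areas = np.bincount(rois.labels.ravel(), minlength=n + 1)[1: n + 1]
    if np.any(areas == 0):
        raise ValueError("ROI with zero pixel area")
    pos = np.bincount(rois.labels.ravel(), weights=mask.ravel(),
                      minlength=n + 1)[1: n + 1]
    return pd.Series(100.0 * pos / areas, index=np.arange(1, n + 1))


def quantify_rounds(
    registered_rounds: list,
    rois: LabelMask,
    panel: dict[str, tuple[int, int]],
    thresholds: ThresholdSpec | None = None,
    cell_meta: pd.DataFrame | None = None,
) -> tuple[PACMatrix, dict[str, float]]:
    """Binarize every probe channel and assemble the raw PAC matrix.

    Returns the matrix plus the per-gene intensity thresholds used.
    """
    spec = thresholds or ThresholdSpec()
    by_round = {s.round_index: s for s in registered_rounds}
    cols = {}
    used: dict[str, float] = {}
    for gene, (rnd, _chan) in panel.items():
        stack = by_round.get(rnd)
        if stack is None or gene not in stack.channels:
            raise KeyError(f"gene {gene} (round {rnd}) missing from input")
        frac = spec.fraction(gene)
        t = compute_threshold(stack.channels[gene], frac)
        used[gene] = t
        cols[gene] = compute_pac(stack.channels[gene] > t, rois)
    values = pd.DataFrame(cols)
    if cell_meta is None:
        cents = rois.centroids_px()
        cell_meta = pd.DataFrame({
            "x_um": cents["x_px"] * rois.pixel_size_um,
            "y_um": cents["y_px"] * rois.pixel_size_um,
        }, index=cents.index)
    cell_meta = cell_meta.loc[values.index]
    genes = pd.DataFrame(
        {"round": [panel[g][0] for g in values.columns],
         "channel": [panel[g][1] for g in values.columns]},
        index=values.columns)
    return PACMatrix(values=values, cells=cell_meta, genes=genes), used


class GateResult(NamedTuple):
    pac: PACMatrix
    n_retained: int
    n_total: int


def gate_excitatory(pac: PACMatrix, gate_gene: str = "Slc17a7",
                    min_pac: float = 1.0) -> GateResult:
    """Keep cells with PAC(gate_gene) >= min_pac; drop the gate column.

    The gate gene is used only for selecting excitatory cells and is
    excluded from all downstream analysis.
    """
    if gate_gene not in pac.values.columns:
        raise KeyError(f"gate gene {gate_gene!r} not in PAC matrix")
    if pac.normalized:
        raise ValueError("gate on the raw PAC matrix, not the normalized one")
    keep = pac.values[gate_gene] >= min_pac
    values = pac.values.loc[keep].drop(columns=[gate_gene])
    gated = PACMatrix(values=values, cells=pac.cells.loc[keep],
                      genes=None if pac.genes is None
                      else pac.genes.drop(index=gate_gene))
    log.info("excitatory gate (%s PAC >= %g): retained %d / %d cells",
             gate_gene, min_pac, len(values), pac.n_cells)
    return GateResult(pac=gated, n_retained=len(values), n_total=pac.n_cells)


def normalize_within_cell(pac: PACMatrix) -> PACMatrix:
    """Divide each cell's profile by its sum (L1); zero rows are flagged.

    Raises if the matrix is already normalized (idempotence misuse).
    """
    if pac.normalized:
        raise ValueError("matrix is already within-cell normalized")
    v = pac.values.to_numpy(dtype=float)
    sums = v.sum(axis=1)
    zero = sums == 0
    out = np.zeros_like(v)
    np.divide(v, sums[:, None], out=out, where=~zero[:, None])
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell profiles left "
                      "unnormalized", stacklevel=2)
    return PACMatrix(
        values=pd.DataFrame(out, index=pac.values.index,
                            columns=pac.values.columns),
        cells=pac.cells.copy(), genes=None if pac.genes is None
        else pac.genes.copy(),
        normalized=True, zero_rows=pac.values.index[zero])


__all__ = [
    "ThresholdSpec", "PACMatrix", "GateResult", "compute_threshold",
    "binarize", "compute_pac", "quantify_rounds", "gate_excitatory",
    "normalize_within_cell", "DEFAULT_TAIL_FRACTION", "TAIL_FRACTION_BOUNDS",
]
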