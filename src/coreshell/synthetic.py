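"""Ground-truth simulator for iterative multiplexed FISH of the claustrum.

Generates (a) a spatial field of excitatory cells arranged in the
core / shell / deep-L6 / cortex geometry characteristic of the mouse
claustrum, (b) multi-round multi-channel fluorescence images of a
12-gene probe panel with per-round rigid drift and smooth elastic
warping, (c) retrograde-label channel images (RSC / LEC), and (d) an
scRNA-seq-like negative-binomial count matrix with planted contaminant
cells.  Every output carries its planted truth so the downstream
registration, segmentation, quantification, typing and projection
modules can be tested against a known answer.

Units: cell geometry is specified in micrometres; images are rendered
on a pixel grid of ``optics.pixel_size_um`` µm per pixel.  Spot
densities are spots per 100 µm² of somatic footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

PHENOTYPES = ("core", "shell", "deep_L6", "cortex_a", "cortex_b")

#: The 12-gene probe panel, in probe-tail order (T1..T12), split into
#: 3 imaging rounds of 4 probes each: gene -> (round 1..3, channel 1..4).
DEFAULT_PANEL: dict[str, tuple[int, int]] = {
    "Cdh9": (1, 1), "Ctgf": (1, 2), "Slc17a6": (1, 3), "Lxn": (1, 4),
    "Slc30a3": (2, 1), "Gfra1": (2, 2), "Spon1": (2, 3), "Gnb4": (2, 4),
    "Nnat": (3, 1), "Synpr": (3, 2), "Pcp4": (3, 3), "Slc17a7": (3, 4),
}

PANEL_GENES = tuple(DEFAULT_PANEL)
LABEL_CHANNELS = ("RSC", "LEC")

# Spot densities (spots / 100 µm² of soma) per phenotype.  Each class has a
# distinct marker signature: Synpr marks core, Nnat marks shell, Ctgf marks
# deep layer-6, Pcp4 is strongest in cortex; Slc17a7 is expressed by every
# (excitatory) cell.  The residual 0.3 stands in for off-target background.
_BASE = 0.3
_EXPRESSION = {
    "core":     {"Synpr": 20, "Gnb4": 8, "Lxn": 6, "Slc17a6": 6, "Cdh9": 4,
                 "Slc17a7": 12},
    "shell":    {"Nnat": 20, "Gnb4": 6, "Slc30a3": 6, "Gfra1": 5, "Spon1": 4,
                 "Slc17a7": 12},
    "deep_L6":  {"Ctgf": 20, "Pcp4": 8, "Slc17a7": 12},
    "cortex_a": {"Pcp4": 16, "Cdh9": 6, "Slc17a7": 12},
    "cortex_b": {"Pcp4": 10, "Slc17a6": 8, "Gfra1": 3, "Slc17a7": 12},
}

# Retrograde label affinities.  Calibrated by direct enumeration over the
# default phenotype proportions so that the *reported* contingency
# statistic — the core/shell share among single-projection cells after
# dual exclusion — is ~85% core for RSC and ~84% shell for LEC, with a
# dual-labeled fraction of ~2% of labeled cells (see
# expected_label_composition for the exact arithmetic).
_AFFINITY = {
    "core":     {"RSC": 0.15,  "LEC": 0.039},
    "shell":    {"RSC": 0.025, "LEC": 0.15},
    "deep_L6":  {"RSC": 0.006, "LEC": 0.011},
    "cortex_a": {"RSC": 0.006, "LEC": 0.011},
    "cortex_b": {"RSC": 0.006, "LEC": 0.011},
}

DEFAULT_PROPORTIONS = {
    "core": 0.25, "shell": 0.30, "deep_L6": 0.15,
    "cortex_a": 0.15, "cortex_b": 0.15,
}


@dataclass(frozen=True)
class PhenotypeModel:
    """Expression and projection model for one simulated cell class."""

    name: str
    expression: dict[str, float]        # gene -> spots / 100 µm² soma
    label_affinity: dict[str, float]    # {"RSC": p, "LEC": p}

    def __post_init__(self) -> None:
        if self.name not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.name!r}")
        if self.expression.get("Slc17a7", 0.0) <= 0:
            raise ValueError(f"{self.name}: all simulated cells are "
                             "excitatory; Slc17a7 density must be > 0")
        for ch, p in self.label_affinity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: affinity {ch}={p} not in [0,1]")
        for g, d in self.expression.items():
            if d < 0:
                raise ValueError(f"{self.name}: negative density for {g}")

    def density(self, gene: str) -> float:
        return float(self.expression.get(gene, 0.0))


def default_phenotype_models() -> list[PhenotypeModel]:
    models = []
    for name in PHENOTYPES:
        expr = {g: _BASE for g in PANEL_GENES}
        expr.update(_EXPRESSION[name])
        models.append(PhenotypeModel(name, expr, dict(_AFFINITY[name])))
    # marker-maximum invariants
    for marker, pheno in (("Synpr", "core"), ("Nnat", "shell"),
                          ("Ctgf", "deep_L6")):
        top = max(models, key=lambda m: m.density(marker))
        assert top.name == pheno, f"{marker} must peak in {pheno}"
    return models


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition model: pixel grid, PSF blur, background and noise."""

    pixel_size_um: float = 1.0
    psf_sigma_px: float = 0.6
    background_level: float = 100.0
    read_noise_sigma: float = 2.0
    bit_depth: int = 16
    spot_amplitude: float = 1500.0      # photons per mRNA spot (pre-blur)
    spot_brightness_sigma: float = 0.5  # lognormal spread of spot amplitudes
    dapi_amplitude: float = 3000.0
    label_amplitude: float = 1200.0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("psf_sigma_px", "background_level", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class Geometry:
    """Concentric core / shell / deep-L6 geometry, radii in µm.

    Absolute claustrum dimensions are not standardized; these defaults are
    an exposed modelling choice, not a measured quantity.
    """

    core_radius_um: float = 90.0
    shell_radius_um: float = 150.0
    deep_l6_radius_um: float = 190.0
    edge_margin_um: float = 10.0

    def region(self, name: str) -> tuple[float, float]:
        """Radial interval (r_min, r_max) occupied by a phenotype."""
        if name == "core":
            return (0.0, self.core_radius_um)
        if name == "shell":
            return (self.core_radius_um, self.shell_radius_um)
        if name == "deep_L6":
            return (self.shell_radius_um, self.deep_l6_radius_um)
        # both cortical classes share everything beyond the deep-L6 ring
        return (self.deep_l6_radius_um, float("inf"))


@dataclass(frozen=True)
class ElasticParams:
    """Coarse-grid elastic warp: control-point displacements in px."""

    control_u: np.ndarray   # (gy, gx) column displacements
    control_v: np.ndarray   # (gy, gx) row displacements

    def dense_field(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Upsample control displacements to a smooth per-pixel field.

        The dense field is centered to zero mean: by convention any net
        translation belongs to the rigid component of the round
        transform, keeping the planted rigid/elastic split identifiable.
        """
        def up(c: np.ndarray) -> np.ndarray:
            zy = shape[0] / c.shape[0]
            zx = shape[1] / c.shape[1]
            d = ndi.zoom(c, (zy, zx), order=3, mode="nearest")
            d = d[: shape[0], : shape[1]]
            return d - d.mean()
        return up(self.control_u), up(self.control_v)


@dataclass(frozen=True)
class RoundTransform:
    """Planted motion of one imaging round relative to round 1."""

    dx_px: float = 0.0
    dy_px: float = 0.0
    elastic: ElasticParams | None = None

    def displacement(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Dense (u, v) = (col, row) displacement in px at every pixel.

        The rendered image of the round satisfies
        ``image(y, x) = scene(y + v(y, x), x + u(y, x))``.
        """
        if self.elastic is None:
            u = np.full(shape, self.dx_px)
            v = np.full(shape, self.dy_px)
        else:
            u, v = self.elastic.dense_field(shape)
            u = u + self.dx_px
            v = v + self.dy_px
        return u, v

    @property
    def is_identity(self) -> bool:
        return self.dx_px == 0 and self.dy_px == 0 and self.elastic is None


@dataclass
class GroundTruth:
    """Planted cells, panel and per-round transforms for one section."""

    cells: pd.DataFrame          # cell_id, x_um, y_um, nucleus_radius_um,
                                 # phenotype, rsc, lec
    transforms: dict[int, RoundTransform]
    panel: dict[str, tuple[int, int]]
    field_size_um: tuple[float, float]
    geometry: Geometry
    phenotype_models: dict[str, PhenotypeModel]
    animal_id: str = "A1"
    section_id: str = "S1"
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def center_um(self) -> tuple[float, float]:
        return (self.field_size_um[0] / 2.0, self.field_size_um[1] / 2.0)


@dataclass
class RoundStack:
    """One imaging round: a DAPI anchor plus named probe/label channels."""

    round_index: int
    dapi: np.ndarray
    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def channel_images(self) -> list[np.ndarray]:
        return [self.dapi, *self.channels.values()]


# ---------------------------------------------------------------------------
# ground truth generation


def _round_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to phenotypes."""
    if n == 0:
        return {k: 0 for k in proportions}
    total = sum(proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"proportions sum to {total}, expected 1")
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _sample_elastic(rng: np.random.Generator, grid: int,
                    amplitude_px: float) -> ElasticParams:
    # zero-mean: any net translation belongs to the rigid component, so
    # the planted rigid/elastic decomposition stays identifiable
    u = rng.uniform(-amplitude_px, amplitude_px, (grid, grid))
    v = rng.uniform(-amplitude_px, amplitude_px, (grid, grid))
    return ElasticParams(control_u=u - u.mean(), control_v=v - v.mean())


def generate_ground_truth(
    field_size_um: tuple[float, float] = (512.0, 512.0),
    n_cells: int = 150,
    phenotype_models: list[PhenotypeModel] | None = None,
    geometry: Geometry | None = None,
    seed: int = 0,
    proportions: dict[str, float] | None = None,
    nucleus_radius_um: float = 4.0,
    rigid_shifts_px: dict[int, tuple[float, float]] | None = None,
    elastic_grid: int = 4,
    elastic_amplitude_px: float = 3.0,
    animal_id: str = "A1",
    section_id: str = "S1",
) -> GroundTruth:
    """Place cells in the core/shell/cortex geometry and draw labels.

    Cells are placed by rejection sampling with a hard minimum
    centre-to-centre distance of two nucleus radii (non-overlapping
    nuclei).  Projection flags are independent Bernoulli draws per
    channel from the phenotype's label affinities, so a small
    dual-labeled fraction arises naturally.

    Deterministic for a fixed seed.
    """
    models = phenotype_models or default_phenotype_models()
    by_name = {m.name: m for m in models}
    geom = geometry or Geometry()
    props = proportions or {
        k: v for k, v in DEFAULT_PROPORTIONS.items() if k in by_name
    }
    missing = set(props) - set(by_name)
    if missing:
        raise ValueError(f"proportions reference unknown phenotypes {missing}")
    fx, fy = float(field_size_um[0]), float(field_size_um[1])
    if geom.deep_l6_radius_um * 2 > min(fx, fy):
        raise ValueError("geometry radii do not fit inside the field")

    ss = np.random.SeedSequence(seed)
    place_rng, label_rng, warp_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    counts = _round_counts(n_cells, props)
    cx, cy = fx / 2.0, fy / 2.0
    margin = geom.edge_margin_um
    min_dist = 2.0 * nucleus_radius_um

    placed_xy: list[tuple[float, float]] = []
    rows: list[dict] = []
    max_attempts = max(10 * n_cells, 100)
    attempts = 0
    xy_arr = np.empty((0, 2))
    for pheno in PHENOTYPES:
        if pheno not in counts:
            continue
        r_min, r_max = geom.region(pheno)
        need = counts[pheno]
        got = 0
        while got < need:
            attempts += 1
            if attempts > max_attempts:
                density = len(placed_xy) / (fx * fy) * 1e4
                raise RuntimeError(
                    "cell placement failed after "
                    f"{max_attempts} attempts; achievable density at this "
                    f"minimum spacing is ~{density:.1f} cells / 100x100 um"
                )
            if np.isfinite(r_max):
                # sample uniformly within the annulus (inverse-CDF radius)
                r = float(np.sqrt(place_rng.uniform(r_min**2, r_max**2)))
                ang = place_rng.uniform(0.0, 2 * np.pi)
                x = cx + r * np.cos(ang)
                y = cy + r * np.sin(ang)
                if not (margin <= x <= fx - margin
                        and margin <= y <= fy - margin):
                    continue
            else:
                x = place_rng.uniform(margin, fx - margin)
                y = place_rng.uniform(margin, fy - margin)
                if np.hypot(x - cx, y - cy) < r_min:
                    continue
            if len(placed_xy):
                d2 = np.min(np.sum((xy_arr - (x, y)) ** 2, axis=1))
                if d2 < min_dist**2:
                    continue
            placed_xy.append((x, y))
            xy_arr = np.asarray(placed_xy)
            rows.append({
                "cell_id": len(rows) + 1,
                "x_um": x, "y_um": y,
                "nucleus_radius_um": nucleus_radius_um,
                "phenotype": pheno,
            })
            got += 1

    cells = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "nucleus_radius_um",
                       "phenotype"],
    )
    if len(cells):
        aff_rsc = cells["phenotype"].map(
            lambda p: by_name[p].label_affinity.get("RSC", 0.0)).to_numpy()
        aff_lec = cells["phenotype"].map(
            lambda p: by_name[p].label_affinity.get("LEC", 0.0)).to_numpy()
        cells["rsc"] = label_rng.random(len(cells)) < aff_rsc
        cells["lec"] = label_rng.random(len(cells)) < aff_lec
    else:
        cells["rsc"] = pd.Series(dtype=bool)
        cells["lec"] = pd.Series(dtype=bool)

    shifts = rigid_shifts_px or {2: (3.0, -2.0), 3: (-4.0, 3.0)}
    transforms: dict[int, RoundTransform] = {1: RoundTransform()}
    for rnd in (2, 3):
        dx, dy = shifts.get(rnd, (0.0, 0.0))
        elastic = (_sample_elastic(warp_rng, elastic_grid, elastic_amplitude_px)
                   if elastic_amplitude_px > 0 else None)
        transforms[rnd] = RoundTransform(dx_px=dx, dy_px=dy, elastic=elastic)
    transforms[0] = RoundTransform()   # pre-round label imaging, ref frame

    return GroundTruth(
        cells=cells, transforms=transforms, panel=dict(DEFAULT_PANEL),
        field_size_um=(fx, fy), geometry=geom, phenotype_models=by_name,
        animal_id=animal_id, section_id=section_id, seed=seed,
    )


def expected_label_composition(
    models: list[PhenotypeModel], proportions: dict[str, float],
) -> dict[str, float]:
    """Enumerate affinity-implied label expectations (no simulation).

    Exact mixture arithmetic over phenotype proportions:

    * ``p_core_given_rsc`` / ``p_shell_given_lec`` — at the level of raw
      planted flags (any phenotype, dual cells included);
    * ``rsc_core_pct_expected`` / ``lec_shell_pct_expected`` — the
      expectation of the *reported* contingency percentage: share of the
      modal phenotype among single-projection cells restricted to the
      core/shell rows, after dual exclusion;
    * ``dual_fraction_of_labeled`` — expected dual cells / labeled cells.
    """
    by = {m.name: m for m in models}
    mass = {ch: {} for ch in LABEL_CHANNELS}         # raw flag mass
    single = {ch: {} for ch in LABEL_CHANNELS}       # single-projection mass
    labeled = dual = 0.0
    for name, p in proportions.items():
        a_r = by[name].label_affinity.get("RSC", 0.0)
        a_l = by[name].label_affinity.get("LEC", 0.0)
        mass["RSC"][name] = p * a_r
        mass["LEC"][name] = p * a_l
        single["RSC"][name] = p * a_r * (1.0 - a_l)
        single["LEC"][name] = p * a_l * (1.0 - a_r)
        labeled += p * (a_r + a_l - a_r * a_l)
        dual += p * a_r * a_l
    tot_r = sum(mass["RSC"].values())
    tot_l = sum(mass["LEC"].values())
    cs_r = single["RSC"].get("core", 0.0) + single["RSC"].get("shell", 0.0)
    cs_l = single["LEC"].get("core", 0.0) + single["LEC"].get("shell", 0.0)
    return {
        "p_core_given_rsc": mass["RSC"].get("core", 0.0) / tot_r if tot_r else np.nan,
        "p_shell_given_lec": mass["LEC"].get("shell", 0.0) / tot_l if tot_l else np.nan,
        "rsc_core_pct_expected":
            100.0 * single["RSC"].get("core", 0.0) / cs_r if cs_r else np.nan,
        "lec_shell_pct_expected":
            100.0 * single["LEC"].get("shell", 0.0) / cs_l if cs_l else np.nan,
        "p_rsc": tot_r,
        "p_lec": tot_l,
        "dual_fraction_of_labeled": dual / labeled if labeled else np.nan,
    }


# ---------------------------------------------------------------------------
# image rendering


def _splat_bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                    amp: np.ndarray | float) -> None:
    """Deposit spots at sub-pixel positions by bilinear spreading."""
    amp = np.broadcast_to(np.asarray(amp, dtype=float), ys.shape)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    h, w = img.shape
    for dy2, dx2, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                          (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy = y0 + dy2
        xx = x0 + dx2
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(img, (yy[ok], xx[ok]), amp[ok] * wgt[ok])


def _disc_paint(img: np.ndarray, y: float, x: float, radius: float,
                amp: float) -> None:
    h, w = img.shape
    r = int(np.ceil(radius)) + 1
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] = amp


def _warp_scene(scene: np.ndarray, transform: RoundTransform) -> np.ndarray:
    if transform.is_identity:
        return scene
    u, v = transform.displacement(scene.shape)
    yy, xx = np.mgrid[0: scene.shape[0], 0: scene.shape[1]]
    return ndi.map_coordinates(scene, [yy + v, xx + u], order=1,
                               mode="constant", cval=0.0)


def _acquire(scene: np.ndarray, optics: OpticsModel,
             rng: np.random.Generator) -> np.ndarray:
    blurred = ndi.gaussian_filter(scene, optics.psf_sigma_px)
    expected = blurred + optics.background_level
    if optics.poisson_noise:
        img = rng.poisson(expected).astype(np.float64)
    else:
        img = expected
    if optics.read_noise_sigma > 0 and optics.poisson_noise:
        img = img + rng.normal(0.0, optics.read_noise_sigma, img.shape)
    return np.clip(np.round(img), 0, optics.max_intensity).astype(np.uint16)


def render_rounds(
    gt: GroundTruth,
    optics: OpticsModel | None = None,
    seed: int = 0,
    soma_expansion_um: float = 5.0,
    label_fill_expansion_um: float = 0.0,
) -> tuple[list[RoundStack], RoundStack]:
    """Render 3 probe rounds plus the pre-round retrograde-label stack.

    Round 1 is the reference frame; rounds 2-3 are resampled through the
    stored rigid + elastic transforms (emulating drift and tissue
    warping between re-coverslipping cycles).  Probe channels contain
    Poisson numbers of PSF-blurred diffraction-limited spots at a rate
    proportional to the phenotype's density over each cell's somatic
    footprint; DAPI renders every nucleus in every round; the label
    stack fills flagged cells perinuclearly (nucleus radius +
    ``label_fill_expansion_um``), where retrograde tracer accumulates.

    Returns ``(rounds, label_stack)``; the label stack has channels
    "RSC" and "LEC" and is rendered in the reference frame.
    """
    optics = optics or OpticsModel()
    px = optics.pixel_size_um
    shape = (int(round(gt.field_size_um[1] / px)),
             int(round(gt.field_size_um[0] / px)))
    ss = np.random.SeedSequence([seed, gt.seed])
    spot_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    # reference-frame scenes -------------------------------------------------
    dapi_scene = np.zeros(shape)
    label_scenes = {ch: np.zeros(shape) for ch in LABEL_CHANNELS}
    cells = gt.cells
    soma_r_um = (cells["nucleus_radius_um"] + soma_expansion_um
                 if len(cells) else pd.Series(dtype=float))
    for i, row in cells.iterrows():
        y, x = row.y_um / px, row.x_um / px
        _disc_paint(dapi_scene, y, x, row.nucleus_radius_um / px,
                    optics.dapi_amplitude)
        rr = (row.nucleus_radius_um + label_fill_expansion_um) / px
        if row.rsc:
            _disc_paint(label_scenes["RSC"], y, x, rr, optics.label_amplitude)
        if row.lec:
            _disc_paint(label_scenes["LEC"], y, x, rr, optics.label_amplitude)

    gene_scenes: dict[str, np.ndarray] = {}
    for gene in gt.panel:
        scene = np.zeros(shape)
        for i, row in cells.iterrows():
            dens = gt.phenotype_models[row.phenotype].density(gene)
            if dens <= 0:
                continue
            r_um = soma_r_um.loc[i]
            area = np.pi * r_um**2
            n = spot_rng.poisson(dens * area / 100.0)
            if n == 0:
                continue
            # uniform positions in the somatic disc; lognormal brightness
            # (hybridization efficiency / axial position variation)
            rad = r_um * np.sqrt(spot_rng.random(n)) / px
            ang = spot_rng.uniform(0, 2 * np.pi, n)
            if optics.spot_brightness_sigma > 0:
                amps = optics.spot_amplitude * spot_rng.lognormal(
                    -optics.spot_brightness_sigma**2 / 2,
                    optics.spot_brightness_sigma, n)
            else:
                amps = np.full(n, optics.spot_amplitude)
            _splat_bilinear(scene, row.y_um / px + rad * np.sin(ang),
                            row.x_um / px + rad * np.cos(ang), amps)
        gene_scenes[gene] = scene

    # per-round acquisition --------------------------------------------------
    rounds: list[RoundStack] = []
    for rnd in (1, 2, 3):
        tf = gt.transforms.get(rnd, RoundTransform())
        genes = [g for g, (r, _) in gt.panel.items() if r == rnd]
        genes.sort(key=lambda g: gt.panel[g][1])
        chans = {}
        for g in genes:
            chans[g] = _acquire(_warp_scene(gene_scenes[g], tf), optics,
                                noise_rng)
        dapi = _acquire(_warp_scene(dapi_scene, tf), optics, noise_rng)
        rounds.append(RoundStack(round_index=rnd, dapi=dapi, channels=chans,
                                 pixel_size_um=px))

    tf0 = gt.transforms.get(0, RoundTransform())
    label_chans = {
        ch: _acquire(_warp_scene(label_scenes[ch], tf0), optics, noise_rng)
        for ch in LABEL_CHANNELS
    }
    label_stack = RoundStack(
        round_index=0,
        dapi=_acquire(_warp_scene(dapi_scene, tf0), optics, noise_rng),
        channels=label_chans, pixel_size_um=px,
    )
    return rounds, label_stack


# ---------------------------------------------------------------------------
# scRNA-seq-like count matrix

#: mean counts per gene for the count-matrix generator.  Contaminant
#: classes have structural zeros in the gene that excludes them: the QC
#: cutoffs (Snap25 CPM < 0.001, Slc17a7 CPM < 1e-10) are below a single
#: read at any realistic library size, i.e. zero-count filters.
_COUNT_CLASSES = ("synpr_high", "nnat_high", "cortical",
                  "snap25_low", "slc17a7_low")

_COUNT_MEANS = {
    "synpr_high":  {"Snap25": 100, "Slc17a7": 150, "Synpr": 80, "Gnb4": 30,
                    "Lxn": 25, "Cdh9": 15, "Slc17a6": 20},
    "nnat_high":   {"Snap25": 100, "Slc17a7": 150, "Nnat": 80, "Gnb4": 25,
                    "Slc30a3": 20, "Gfra1": 15, "Spon1": 12},
    "cortical":    {"Snap25": 100, "Slc17a7": 150, "Pcp4": 60, "Ctgf": 25,
                    "Cdh9": 10},
    "snap25_low":  {"Snap25": 0, "Slc17a7": 0, "Pcp4": 5},
    "slc17a7_low": {"Snap25": 100, "Slc17a7": 0, "Pcp4": 20, "Ctgf": 10},
}

# Calibrated (same restricted-share arithmetic as the mFISH affinities)
# so that among single-projection excitatory cells ~85% of RSC cells are
# Synpr-class and ~84% of LEC cells are Nnat-class.
_COUNT_AFFINITY = {
    "synpr_high":  {"RSC": 0.15, "LEC": 0.0374},
    "nnat_high":   {"RSC": 0.0262, "LEC": 0.15},
    "cortical":    {"RSC": 0.006, "LEC": 0.011},
    "snap25_low":  {"RSC": 0.0, "LEC": 0.0},
    "slc17a7_low": {"RSC": 0.0, "LEC": 0.0},
}

#: Default class proportions reproduce the study's QC ledger: 27/1112
#: Snap25-low putative non-neuronal cells and 74/1112 Slc17a7-low cells;
#: the excitatory remainder is split core-like / shell-like / cortical.
DEFAULT_COUNT_PROPORTIONS = {
    "snap25_low": 27 / 1112,
    "slc17a7_low": 74 / 1112,
    "synpr_high": 0.28,
    "nnat_high": 0.32,
    "cortical": 1.0 - 27 / 1112 - 74 / 1112 - 0.28 - 0.32,
}

_HOUSEKEEPING = [f"Hk{i:02d}" for i in range(1, 18)]
COUNT_GENES = list(PANEL_GENES) + ["Snap25"] + _HOUSEKEEPING


def generate_count_matrix(
    n_cells: int = 1112,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 5.0,
    class_means: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial genes x cells counts with planted contaminants.

    Class sizes are fixed by largest-remainder rounding of `proportions`
    (deterministic composition); gene counts are NB(mean, dispersion)
    draws.  Returns ``(counts, truth)`` where counts is a genes x cells
    integer DataFrame and truth a per-cell table with the planted class
    and RSC/LEC projection annotations.
    """
    props = proportions if proportions is not None else DEFAULT_COUNT_PROPORTIONS
    means = class_means or _COUNT_MEANS
    unknown = set(props) - set(_COUNT_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {unknown}")
    if not np.isclose(sum(props.values()), 1.0):
        raise ValueError(f"proportions sum to {sum(props.values())}, expected 1")
    rng = np.random.default_rng(seed)
    counts_per_class = _round_counts(n_cells, props)

    hk_mean = 40.0
    order = [c for c in _COUNT_CLASSES if c in counts_per_class]

    mat = np.zeros((len(COUNT_GENES), n_cells), dtype=np.int64)
    cls_col: list[str] = []
    rsc = np.zeros(n_cells, dtype=bool)
    lec = np.zeros(n_cells, dtype=bool)
    col = 0
    for cname in order:
        n_c = counts_per_class[cname]
        if n_c == 0:
            continue
        mu = np.array([
            means[cname].get(g, hk_mean if g in _HOUSEKEEPING else 0.5)
            for g in COUNT_GENES
        ])[:, None]
        shape = (len(COUNT_GENES), n_c)
        lam = np.where(
            mu > 0,
            rng.gamma(dispersion, np.broadcast_to(
                np.maximum(mu, 1e-12) / dispersion, shape)),
            0.0)
        mat[:, col: col + n_c] = rng.poisson(lam)
        aff = _COUNT_AFFINITY[cname]
        rsc[col: col + n_c] = rng.random(n_c) < aff["RSC"]
        lec[col: col + n_c] = rng.random(n_c) < aff["LEC"]
        cls_col.extend([cname] * n_c)
        col += n_c
    assert col == n_cells
    cell_ids = [f"C{i + 1:04d}" for i in range(n_cells)]
    counts = pd.DataFrame(mat, index=COUNT_GENES, columns=cell_ids)
    truth = pd.DataFrame({"cell_id": cell_ids, "cls": cls_col,
                          "rsc": rsc, "lec": lec})
    return counts, truth


# ---------------------------------------------------------------------------
# serialization


def _transform_to_json(tf: RoundTransform) -> dict:
    d = {"dx_px": tf.dx_px, "dy_px": tf.dy_px}
    if tf.elastic is not None:
        d["elastic"] = {
            "control_u": tf.elastic.control_u.tolist(),
            "control_v": tf.elastic.control_v.tolist(),
        }
    return d


def write_dataset(gt: GroundTruth, rounds: list[RoundStack],
                  label_stack: RoundStack, outdir: str | Path) -> None:
    """Write TIFFs plus ground_truth.csv / transforms.json / panel.json."""
    import tifffile

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stack in rounds:
        pages = np.stack(stack.channel_images())
        tifffile.imwrite(out / f"round{stack.round_index}.tif", pages)
    tifffile.imwrite(out / "labels.tif",
                     np.stack(label_stack.channel_images()))
    gt.cells.to_csv(out / "ground_truth.csv", index=False)
    with open(out / "transforms.json", "w") as fh:
        json.dump({str(k): _transform_to_json(v)
                   for k, v in gt.transforms.items()}, fh, indent=1)
    with open(out / "panel.json", "w") as fh:
        json.dump({g: {"round": r, "channel": c}
                   for g, (r, c) in gt.panel.items()}, fh, indent=1)


def write_count_matrix(counts: pd.DataFrame, truth: pd.DataFrame,
                       outdir: str | Path) -> None:
    """Write MatrixMarket counts.mtx + genes.tsv + cells.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "counts.mtx"), csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(out / "genes.tsv", sep="\t", index=False,
                                   header=False)
    truth.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_count_matrix(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    from scipy.io import mmread

    out = Path(outdir)
    genes = pd.read_csv(out / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(out / "cells.tsv", sep="\t")
    mat = np.asarray(mmread(str(out / "counts.mtx")).todense(), dtype=np.int64)
    counts = pd.DataFrame(mat, index=genes, columns=cells["cell_id"].tolist())
    return counts, cells


__all__ = [
    "PHENOTYPES", "DEFAULT_PANEL", "PANEL_GENES", "LABEL_CHANNELS",
    "PhenotypeModel", "OpticsModel", "Geometry", "ElasticParams",
    "RoundTransform", "GroundTruth", "RoundStack",
    "default_phenotype_models", "generate_ground_truth",
    "expected_label_composition", "render_rounds",
    "generate_count_matrix", "DEFAULT_COUNT_PROPORTIONS", "COUNT_GENES",
    "write_dataset", "write_count_matrix", "read_count_matrix",
    "DEFAULT_PROPORTIONS",
]
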