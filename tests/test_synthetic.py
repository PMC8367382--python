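"""Generator contracts: geometry, determinism, label statistics, rendering."""

import numpy as np
import pandas as pd
import pytest

from coreshell.synthetic import (
    DEFAULT_PROPORTIONS, OpticsModel, PhenotypeModel, RoundTransform,
    default_phenotype_models, expected_label_composition,
    generate_count_matrix, generate_ground_truth, render_rounds,
    write_dataset, write_count_matrix, read_count_matrix,
)


def test_empty_field_has_no_cells_but_valid_transforms():
    gt = generate_ground_truth(n_cells=0, seed=1)
    assert gt.n_cells == 0
    assert set(gt.transforms) == {0, 1, 2, 3}
    assert gt.transforms[1].is_identity


def test_ground_truth_deterministic_per_seed():
    a = generate_ground_truth(seed=11)
    b = generate_ground_truth(seed=11)
    c = generate_ground_truth(seed=12)
    assert a.cells.to_csv() == b.cells.to_csv()
    for rnd in (2, 3):
        ta, tb = a.transforms[rnd], b.transforms[rnd]
        assert ta.dx_px == tb.dx_px and ta.dy_px == tb.dy_px
        np.testing.assert_array_equal(ta.elastic.control_u,
                                      tb.elastic.control_u)
    assert a.cells.to_csv() != c.cells.to_csv()


@pytest.mark.parametrize("seed", [0, 5, 9])
def test_phenotype_spatial_ordering(seed):
    """Core cells sit nearest the center, then shell, then cortex."""
    gt = generate_ground_truth(seed=seed)
    cx, cy = gt.center_um
    r = np.hypot(gt.cells["x_um"] - cx, gt.cells["y_um"] - cy)
    med = r.groupby(gt.cells["phenotype"]).median()
    assert med["core"] < med["shell"] < med["deep_L6"]
    assert med["shell"] < med["cortex_a"] and med["shell"] < med["cortex_b"]


def test_min_centroid_distance_invariant():
    gt = generate_ground_truth(seed=4, n_cells=200)
    xy = gt.cells[["x_um", "y_um"]].to_numpy()
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 2 * gt.cells["nucleus_radius_um"].iloc[0] - 1e-9


def test_placement_failure_names_achievable_density():
    with pytest.raises(RuntimeError, match="achievable density"):
        generate_ground_truth(field_size_um=(400.0, 400.0), n_cells=3000,
                              seed=0)


def test_label_marginals_within_three_binomial_se():
    """Realized RSC/LEC/dual fractions match the affinity arithmetic."""
    models = default_phenotype_models()
    exp = expected_label_composition(models, DEFAULT_PROPORTIONS)
    cells = pd.concat([
        generate_ground_truth(seed=s, n_cells=600,
                              field_size_um=(1024.0, 1024.0)).cells
        for s in (1, 2, 3)
    ])
    n = len(cells)
    for key, frac in (("p_rsc", cells["rsc"].mean()),
                      ("p_lec", cells["lec"].mean())):
        se = np.sqrt(exp[key] * (1 - exp[key]) / n)
        assert abs(frac - exp[key]) <= 3 * se
    labeled = cells[cells["rsc"] | cells["lec"]]
    p_dual = exp["dual_fraction_of_labeled"]
    se = np.sqrt(p_dual * (1 - p_dual) / len(labeled))
    assert abs((labeled["rsc"] & labeled["lec"]).mean() - p_dual) <= 3 * se


def test_high_affinity_config_matches_enumeration_oracle():
    """With 0.95 core->RSC / shell->LEC affinities, ~85% of RSC-flagged
    cells are core, as predicted by exact mixture enumeration."""
    affinity = {
        "core": {"RSC": 0.95, "LEC": 0.12},
        "shell": {"RSC": 0.10, "LEC": 0.95},
        "deep_L6": {"RSC": 0.027, "LEC": 0.054},
        "cortex_a": {"RSC": 0.027, "LEC": 0.054},
        "cortex_b": {"RSC": 0.027, "LEC": 0.054},
    }
    models = [PhenotypeModel(m.name, m.expression, affinity[m.name])
              for m in default_phenotype_models()]
    exp = expected_label_composition(models, DEFAULT_PROPORTIONS)
    assert exp["p_core_given_rsc"] == pytest.approx(0.85, abs=0.01)
    gt = generate_ground_truth(seed=7, n_cells=600,
                               field_size_um=(1024.0, 1024.0),
                               phenotype_models=models)
    rsc = gt.cells[gt.cells["rsc"]]
    p = exp["p_core_given_rsc"]
    se = np.sqrt(p * (1 - p) / len(rsc))
    assert abs((rsc["phenotype"] == "core").mean() - p) <= 3 * se


def test_phenotype_model_invariants_enforced():
    with pytest.raises(ValueError, match="Slc17a7"):
        PhenotypeModel("core", {"Synpr": 5.0}, {"RSC": 0.1})
    with pytest.raises(ValueError, match="affinity"):
        PhenotypeModel("core", {"Slc17a7": 5.0}, {"RSC": 1.5})
    with pytest.raises(ValueError):
        OpticsModel(pixel_size_um=0.0)


def test_zero_expression_renders_pure_background():
    models = [PhenotypeModel(m.name,
                             {g: (1e-9 if g == "Slc17a7" else 0.0)
                              for g in m.expression},
                             m.label_affinity)
              for m in default_phenotype_models()]
    gt = generate_ground_truth(seed=2, n_cells=40, phenotype_models=models)
    optics = OpticsModel()
    rounds, _ = render_rounds(gt, optics, seed=3)
    for stack in rounds:
        for img in stack.channels.values():
            se = np.sqrt(optics.background_level) / np.sqrt(img.size)
            assert abs(img.mean() - optics.background_level) < 3 * se


def test_identity_transforms_make_rounds_identical():
    gt = generate_ground_truth(seed=5, n_cells=60,
                               rigid_shifts_px={2: (0, 0), 3: (0, 0)},
                               elastic_amplitude_px=0.0)
    optics = OpticsModel(poisson_noise=False)
    rounds, _ = render_rounds(gt, optics, seed=1)
    np.testing.assert_array_equal(rounds[0].dapi, rounds[1].dapi)
    np.testing.assert_array_equal(rounds[0].dapi, rounds[2].dapi)


def test_planted_rigid_shift_recovered_by_exhaustive_correlation():
    """An exhaustive integer-shift correlation oracle peaks at the
    planted (dx, dy) = (3, -2) of round 2."""
    gt = generate_ground_truth(seed=6, n_cells=80,
                               rigid_shifts_px={2: (3.0, -2.0), 3: (0, 0)},
                               elastic_amplitude_px=0.0)
    rounds, _ = render_rounds(gt, OpticsModel(poisson_noise=False), seed=0)
    ref = rounds[0].dapi.astype(float)
    mov = rounds[1].dapi.astype(float)
    best, best_score = None, -np.inf
    for dx in range(-6, 7):
        for dy in range(-6, 7):
            shifted = np.roll(np.roll(mov, dy, axis=0), dx, axis=1)
            score = np.corrcoef(ref.ravel(), shifted.ravel())[0, 1]
            if score > best_score:
                best, best_score = (dx, dy), score
    # moving(x) = scene(x + d): rolling the moving image by +d restores it
    assert best == (3, -2)


def test_dapi_renders_every_nucleus_in_every_round(default_run):
    gt = default_run.ground_truth
    assert default_run.report["counts"]["planted_cells"] == gt.n_cells
    assert len(gt.cells) == gt.n_cells


class TestCountMatrix:
    def test_deterministic_per_seed(self):
        a, ta = generate_count_matrix(seed=9)
        b, tb = generate_count_matrix(seed=9)
        assert a.equals(b) and ta.equals(tb)
        c, _ = generate_count_matrix(seed=10)
        assert not a.equals(c)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_count_matrix(proportions={"synpr_high": 0.5}, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            generate_count_matrix(proportions={"bogus": 1.0}, seed=0)

    def test_contaminants_have_structural_zeros(self):
        counts, truth = generate_count_matrix(seed=3)
        snap_low = truth.loc[truth["cls"] == "snap25_low", "cell_id"]
        slc_low = truth.loc[truth["cls"] == "slc17a7_low", "cell_id"]
        assert (counts.loc["Snap25", snap_low] == 0).all()
        assert (counts.loc["Slc17a7", slc_low] == 0).all()
        assert len(snap_low) == 27 and len(slc_low) == 74

    def test_mtx_roundtrip(self, tmp_path):
        counts, truth = generate_count_matrix(n_cells=50, seed=1,
                                              proportions={"synpr_high": 0.5,
                                                           "nnat_high": 0.5})
        write_count_matrix(counts, truth, tmp_path)
        counts2, cells2 = read_count_matrix(tmp_path)
        pd.testing.assert_frame_equal(counts, counts2)
        assert list(cells2["cell_id"]) == list(counts.columns)


def test_dataset_files_written(tmp_path):
    gt = generate_ground_truth(seed=8, n_cells=30)
    rounds, labels = render_rounds(gt, OpticsModel(), seed=8)
    write_dataset(gt, rounds, labels, tmp_path)
    for name in ("round1.tif", "round2.tif", "round3.tif", "labels.tif",
                 "ground_truth.csv", "transforms.json", "panel.json"):
        assert (tmp_path / name).exists()
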