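import numpy as np
import pandas as pd
import pytest

import nichemap as nm
from nichemap.errors import ContractError, ParameterError
from nichemap.io_tables import RegionMetadata
from nichemap.spatial import feature_columns
from conftest import random_labeled_image
from _oracles import brute_distance_summary, brute_neighborhood


def _image_df(points, labels):
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(points))],
            "image_id": "img",
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "phenotype": list(labels),
        }
    )


# ------------------------------------------------------------- neighborhood

def test_single_cell_has_no_neighbors():
    res = nm.neighborhood_matrix(_image_df([(5, 5)], ["A"]))
    assert res.matrix.shape == (1, 1)
    assert res.matrix[0, 0] == 0.0


def test_threshold_geometry_two_cells():
    df = _image_df([(0, 0), (0, 10)], ["A", "B"])
    r20 = nm.neighborhood_matrix(df, radius=20.0)
    a, b = r20.clusters.index("A"), r20.clusters.index("B")
    assert r20.matrix[a, b] == 1.0 and r20.matrix[b, a] == 1.0
    r5 = nm.neighborhood_matrix(df, radius=5.0)
    assert r5.matrix[a, b] == 0.0 and r5.matrix[b, a] == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_neighborhood_equals_brute_force(seed):
    df = random_labeled_image(seed, n_cells=300)
    clusters = sorted(set(df["phenotype"]))
    res = nm.neighborhood_matrix(df, radius=20.0, clusters=clusters)
    oracle, counts = brute_neighborhood(
        df[["x_um", "y_um"]].to_numpy(), df["phenotype"], clusters, 20.0
    )
    np.testing.assert_array_equal(res.counts, counts)
    np.testing.assert_allclose(res.matrix, oracle, rtol=0, atol=0)


def test_pair_count_symmetry_exact():
    df = random_labeled_image(11, n_cells=400, n_clusters=5)
    res = nm.neighborhood_matrix(df, radius=25.0)
    P = res.pair_counts
    np.testing.assert_array_equal(P, P.T)  # n_i N[i,j] = n_j N[j,i] exactly


def test_unlabeled_cells_rejected():
    df = _image_df([(0, 0), (1, 1)], ["A", "B"]).drop(columns="phenotype")
    with pytest.raises(ContractError):
        nm.neighborhood_matrix(df)


def test_neighborhood_rigid_motion_and_scaling_invariance():
    df = random_labeled_image(2, n_cells=200)
    base = nm.neighborhood_matrix(df, radius=20.0)
    # translation and exact 90-degree rotation preserve distances exactly
    moved = df.copy()
    moved["x_um"], moved["y_um"] = -df["y_um"] + 50.0, df["x_um"] + 7.0
    rot = nm.neighborhood_matrix(moved, radius=20.0)
    np.testing.assert_array_equal(base.pair_counts, rot.pair_counts)
    # doubling coordinates is equivalent to doubling the radius
    scaled = df.copy()
    scaled["x_um"] *= 2.0
    scaled["y_um"] *= 2.0
    sc = nm.neighborhood_matrix(scaled, radius=40.0)
    np.testing.assert_array_equal(base.pair_counts, sc.pair_counts)


# ----------------------------------------------------------------- distance

def test_distance_nearest_of_two():
    df = _image_df([(0, 0), (3, 4), (30, 40)], ["A", "B", "B"])
    res = nm.distance_summary(df)
    a, b = res.clusters.index("A"), res.clusters.index("B")
    assert res.matrix[a, b] == 5.0  # nearest B is the 3-4-5 triangle


def test_distance_single_cell_self_undefined():
    res = nm.distance_summary(_image_df([(0, 0)], ["A"]))
    assert np.isnan(res.matrix[0, 0])


@pytest.mark.parametrize("seed", range(5))
def test_distance_equals_brute_force(seed):
    df = random_labeled_image(100 + seed, n_cells=250)
    clusters = sorted(set(df["phenotype"]))
    res = nm.distance_summary(df, clusters=clusters)
    oracle = brute_distance_summary(
        df[["x_um", "y_um"]].to_numpy(), df["phenotype"], clusters
    )
    np.testing.assert_allclose(res.matrix, oracle, rtol=1e-12, atol=0, equal_nan=True)


# ---------------------------------------------------------------- abundance

def test_abundance_arithmetic_and_normalisation():
    df = _image_df([(i, i) for i in range(157)], ["A"] * 157)
    res = nm.cluster_abundance(df, nm.DEFAULT_CORE_AREA_MM2)
    assert res.density[0] == pytest.approx(157 / nm.DEFAULT_CORE_AREA_MM2)
    assert res.density[0] == pytest.approx(199.899, abs=1e-3)
    assert res.percentage.sum() == pytest.approx(100.0)


def test_abundance_empty_image_and_zero_clusters():
    res = nm.cluster_abundance(_image_df(np.empty((0, 2)), []), 0.785398, clusters=["A", "B"])
    assert (res.counts == 0).all()
    assert np.isnan(res.percentage).all()
    with pytest.raises(ParameterError):
        nm.cluster_abundance(_image_df([(0, 0)], ["A"]), 0.0)


# ----------------------------------------------------------------- assembly

def _meta_for(images, patient="P01", area=nm.DEFAULT_CORE_AREA_MM2):
    rows = []
    for img, region, rep in images:
        rows.append(
            {"image_id": img, "patient_id": patient, "region_class": region,
             "replicate": rep, "area_mm2": area}
        )
    return RegionMetadata(pd.DataFrame(rows))


def test_feature_slot_accounting_formula(small_cohort):
    cells, meta, _ = small_cohort
    fm = nm.assemble_features(cells, meta)
    K = len(fm.clusters)
    assert fm.data.shape[1] == 3 * K + 2 * K * K
    assert len(feature_columns(fm.clusters)) == len(set(feature_columns(fm.clusters)))
    assert fm.n_feature_slots_per_patient == 3 * (3 * K + 2 * K * K)


def test_single_core_pooling_policies_agree():
    frames, images = [], []
    for k, region in enumerate(nm.REGION_CLASSES):
        df = random_labeled_image(30 + k, n_cells=150)
        df = df.assign(image_id=f"img_{region}",
                       cell_id=[f"{region}{i}" for i in range(len(df))])
        frames.append(df)
        images.append((f"img_{region}", region, 1))
    cells = nm.CellTable(pd.concat(frames, ignore_index=True).assign(M=1.0), ("M",))
    meta = _meta_for(images)
    fm_pool = nm.assemble_features(cells, meta, pooling="pool_cells")
    fm_mean = nm.assemble_features(cells, meta, pooling="mean_of_cores")
    pd.testing.assert_frame_equal(fm_pool.data, fm_mean.data)


def test_identical_replicates_pool_to_per_core_density():
    df1 = random_labeled_image(5, n_cells=120).assign(image_id="a")
    df2 = df1.assign(image_id="b", cell_id=[f"b{i}" for i in range(len(df1))])
    cells = nm.CellTable(pd.concat([df1, df2], ignore_index=True).assign(M=1.0), ("M",))
    meta = _meta_for([("a", "tumor", 1), ("b", "tumor", 2)])
    fm = nm.assemble_features(cells, meta, pooling="pool_cells")
    single = nm.cluster_abundance(df1, nm.DEFAULT_CORE_AREA_MM2,
                                  clusters=fm.clusters)
    row = fm.data.iloc[0]
    for k, c in enumerate(fm.clusters):
        assert row[f"density_{c}"] == pytest.approx(single.density[k])


def test_assembly_invariant_to_image_order(small_cohort):
    cells, meta, _ = small_cohort
    fm = nm.assemble_features(cells, meta)
    shuffled_meta = RegionMetadata(
        meta.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    fm2 = nm.assemble_features(cells, shuffled_meta)
    pd.testing.assert_frame_equal(fm.data, fm2.data)


# -------------------------------------------------------- log2 fold change

def test_lfc_identities():
    idx = pd.MultiIndex.from_tuples(
        [("P01", "tumor"), ("P01", "nontumor"), ("P02", "tumor"), ("P02", "nontumor")],
        names=["patient_id", "region_class"],
    )
    df = pd.DataFrame({"density_A": [3.0, 3.0, 4.0, 1.0]}, index=idx)
    fm = nm.FeatureMatrix(data=df, clusters=["A"])
    lfc = nm.log2_fold_change(fm, "density_A", "tumor", "nontumor", pseudo=0.0)
    assert lfc["P01"] == 0.0
    assert lfc["P02"] == 2.0


def test_lfc_recovers_simulated_density_ratio():
    """A phenotype whose cells are exclusively niche-driven doubles in
    density under a tumor enrichment multiplier of 2: median LFC ~ 1."""
    import dataclasses
    cfg = nm.small_config(n_patients=8, n_phenotypes=5, replicates_per_region=3, seed=21)
    member = cfg.phenotype_by_role("aggregate_member")[0].name
    bg = dict(cfg.background_intensity)
    bg[member] = 0.0  # purely niche-driven
    cfg = dataclasses.replace(cfg, background_intensity=bg)
    cells, meta, _ = nm.simulate_cohort(cfg)
    fm = nm.assemble_features(cells, meta)
    lfc = nm.log2_fold_change(fm, f"density_{member}", "tumor", "nontumor", pseudo=1.0)
    assert 0.4 < lfc.median() < 1.6
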