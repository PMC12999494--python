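import numpy as np
import pandas as pd
import pytest

from atf6scope import simulate, spatial
from atf6scope.datatypes import LabelImage


def disc_image(side, centers_radii_labels):
    arr = np.zeros((side, side), dtype=int)
    yy, xx = np.mgrid[0:side, 0:side]
    for (cy, cx), r, lab in centers_radii_labels:
        arr[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = lab
    return LabelImage(labels=arr)


class TestDeriveCytoplasm:
    def test_subtracts_nucleus_pixels(self):
        cells = disc_image(11, [((5, 5), 2, 1)])
        nuclei = np.zeros((11, 11), dtype=int)
        nuclei[5, 5] = 1
        cyto = spatial.derive_cytoplasm(cells, LabelImage(labels=nuclei))
        assert (cyto.labels == 1).sum() == (cells.labels == 1).sum() - 1

    def test_nucleus_covering_cell_leaves_no_cytoplasm(self):
        cells = disc_image(11, [((5, 5), 2, 1)])
        cyto = spatial.derive_cytoplasm(cells, cells)
        assert cyto.n_objects == 0

    def test_empty_nuclei_is_identity(self):
        cells = disc_image(11, [((5, 5), 2, 1)])
        empty = LabelImage(labels=np.zeros((11, 11), dtype=int))
        cyto = spatial.derive_cytoplasm(cells, empty)
        assert np.array_equal(cyto.labels, cells.labels)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            spatial.derive_cytoplasm(
                LabelImage(labels=np.zeros((4, 4), dtype=int)),
                LabelImage(labels=np.zeros((5, 5), dtype=int)),
            )


class TestMapCompartments:
    def test_concentric_nucleus_assigned_to_its_cell(self):
        cells = disc_image(15, [((7, 7), 4, 1)])
        nuclei = disc_image(15, [((7, 7), 2, 1)])
        rec = spatial.map_compartments(cells, nuclei)
        assert rec.loc[1, "nucleus_id"] == 1
        assert rec.loc[1, "nucleus_area_px"] < rec.loc[1, "area_px"]

    def test_nucleus_on_background_stays_unassigned(self):
        cells = disc_image(21, [((5, 5), 3, 1)])
        nuclei = disc_image(21, [((15, 15), 2, 1)])  # far from the cell
        rec = spatial.map_compartments(cells, nuclei)
        assert np.isnan(rec.loc[1, "nucleus_id"])

    def test_conflict_resolved_by_largest_overlap(self):
        # two nuclei whose centroids both land inside cell 1
        cells = disc_image(21, [((10, 10), 6, 1)])
        nuclei = np.zeros((21, 21), dtype=int)
        nuclei[8:13, 8:13] = 1  # 25 px, centroid (10, 10)
        nuclei[13:15, 10:12] = 2  # 4 px, centroid (13.5, 10.5) -> inside cell
        rec = spatial.map_compartments(cells, LabelImage(labels=nuclei))
        assert rec.loc[1, "nucleus_id"] == 1

    def test_synthetic_tissue_mapping_matches_truth_and_overlap_oracle(self):
        spec = simulate.SimulationSpec(n_cells=50, seed=31)
        cells, nuclei, truth = simulate.gen_tissue_image(spec)
        rec = spatial.map_compartments(cells, nuclei)
        # truth: concentric nucleus shares the cell id
        assert (rec["nucleus_id"] == rec.index).all()
        # brute-force maximal-overlap oracle
        for nuc_id in np.unique(nuclei.labels[nuclei.labels > 0]):
            overlap_per_cell = {}
            mask = nuclei.labels == nuc_id
            for cell_id in np.unique(cells.labels[cells.labels > 0]):
                overlap_per_cell[cell_id] = int(np.sum(mask & (cells.labels == cell_id)))
            best = max(overlap_per_cell, key=overlap_per_cell.get)
            assert rec.loc[best, "nucleus_id"] == nuc_id

    def test_area_conservation_with_contained_nucleus(self):
        cells = disc_image(15, [((7, 7), 4, 1)])
        nuclei = disc_image(15, [((7, 7), 2, 1)])
        rec = spatial.map_compartments(cells, nuclei)
        assert (
            rec.loc[1, "nucleus_area_px"] + rec.loc[1, "cytoplasm_area_px"]
            == rec.loc[1, "area_px"]
        )

    def test_label_renumbering_invariance(self):
        spec = simulate.SimulationSpec(n_cells=12, seed=32)
        cells, nuclei, _ = simulate.gen_tissue_image(spec)
        rec = spatial.map_compartments(cells, nuclei)
        # renumber labels: i -> 2i
        cells2 = LabelImage(labels=cells.labels * 2)
        nuclei2 = LabelImage(labels=nuclei.labels * 2)
        rec2 = spatial.map_compartments(cells2, nuclei2)
        assert (rec2["nucleus_id"].to_numpy() == 2 * rec["nucleus_id"].to_numpy()).all()
        assert (rec2["area_px"].to_numpy() == rec["area_px"].to_numpy()).all()


class TestExtractIntensities:
    def test_constant_plane_gives_constant_means(self):
        cells = disc_image(15, [((7, 7), 4, 1)])
        nuclei = disc_image(15, [((7, 7), 2, 1)])
        rec = spatial.map_compartments(cells, nuclei)
        planes = {"m": np.full((15, 15), 7.0)}
        out = spatial.extract_intensities(
            planes, rec, {"cell": cells, "nucleus": nuclei}
        )
        assert out.loc[1, "m_cell"] == 7.0
        assert out.loc[1, "m_nucleus"] == 7.0

    def test_single_pixel_compartment_mean_is_that_pixel(self):
        cells = np.zeros((5, 5), dtype=int)
        cells[2, 2] = 1
        img = LabelImage(labels=cells)
        rec = spatial.map_compartments(img, img)
        plane = np.arange(25, dtype=float).reshape(5, 5)
        out = spatial.extract_intensities({"m": plane}, rec, {"cell": img})
        assert out.loc[1, "m_cell"] == plane[2, 2]

    def test_random_plane_matches_loop_oracle(self):
        spec = simulate.SimulationSpec(n_cells=20, seed=33)
        cells, nuclei, _ = simulate.gen_tissue_image(spec)
        rng = np.random.default_rng(34)
        plane = rng.random(cells.shape)
        rec = spatial.map_compartments(cells, nuclei)
        out = spatial.extract_intensities({"m": plane}, rec, {"cell": cells})
        for cid in rec.index:
            expected = plane[cells.labels == cid].mean()
            assert out.loc[cid, "m_cell"] == pytest.approx(expected, abs=1e-12)


class TestGating:
    def _records(self, values):
        return pd.DataFrame({"m_cell": values}, index=range(len(values)))

    def test_threshold_boundary_inclusive(self):
        out = spatial.gate_markers(self._records([5.0, 4.999]), {("m", "cell"): 5.0})
        assert out["m_pos"].tolist() == [True, False]

    def test_infinite_gate_everything_negative(self):
        with pytest.raises(ValueError, match="non-finite"):
            spatial.gate_markers(self._records([5.0]), {("m", "cell"): np.inf})
        out = spatial.gate_markers(self._records([1e9]), {("m", "cell"): 1e300})
        assert not out["m_pos"].any()

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown column"):
            spatial.gate_markers(self._records([1.0]), {("nope", "cell"): 0.5})

    def test_lineage_recovery_on_separated_lognormal_markers(self):
        spec = simulate.SimulationSpec(n_cells=120, seed=35, marker_separation_sd=4.0)
        cells, nuclei, truth = simulate.gen_tissue_image(spec)
        planes = simulate.render_intensity_planes(cells, truth)
        rec = spatial.map_compartments(cells, nuclei)
        rec = spatial.extract_intensities(planes, rec, {"cell": cells})
        markers = [c[: -len("_marker")] for c in truth.columns if c.endswith("_marker")]
        # gate at the midpoint of the two log-means (2 SD from either)
        cut = float(np.exp(0.5 * spec.marker_separation_sd * spec.marker_log_sd))
        gates = {(f"{m}_marker", "cell"): cut for m in markers}
        rules = [(m, {f"{m}_marker": True}) for m in markers]
        rec = spatial.gate_markers(rec, gates, lineage_rules=rules)
        accuracy = (rec["lineage"] == truth["phenotype"]).mean()
        assert accuracy >= 0.99


class TestClassifyTissue:
    def _records(self, fractions, cells_per_region=10):
        rows = []
        for i, f in enumerate(fractions):
            n_pos = int(round(f * cells_per_region))
            for j in range(cells_per_region):
                rows.append({"region": f"r{i}", "atf6_pos": j < n_pos})
        return pd.DataFrame(rows)

    def test_two_regions_split_hi_low(self):
        out = spatial.classify_tissue(self._records([0.8, 0.1]), "atf6_pos")
        assert out.loc["r0", "class"] == "hi"
        assert out.loc["r1", "class"] == "low"

    def test_identical_fractions_all_low(self):
        out = spatial.classify_tissue(self._records([0.5, 0.5, 0.5]), "atf6_pos")
        assert (out["class"] == "low").all()

    def test_planted_six_regions_recovered(self):
        out = spatial.classify_tissue(
            self._records([0.9, 0.8, 0.7, 0.2, 0.1, 0.0]), "atf6_pos"
        )
        assert out["class"].tolist() == ["hi"] * 3 + ["low"] * 3

    def test_absolute_cutoff_override(self):
        out = spatial.classify_tissue(
            self._records([0.9, 0.8]), "atf6_pos", absolute_cutoff=0.5
        )
        assert (out["class"] == "hi").all()


class TestNeighborhood:
    def _records(self, points, area=78.5, lineages=None):
        lineages = lineages or ["a"] * len(points)
        return pd.DataFrame(
            {
                "centroid_row": [p[0] for p in points],
                "centroid_col": [p[1] for p in points],
                "area_px": area,
                "lineage": lineages,
            },
            index=range(1, len(points) + 1),
        )

    def test_distant_cells_have_no_neighbors(self):
        prof, r = spatial.neighborhood_profile(self._records([(0, 0), (0, 1000)]))
        assert r < 100
        assert (prof["n_neighbors"] == 0).all()

    def test_collinear_spacing_geometry(self):
        rec = self._records([(0, 0), (0, 14), (0, 28)])  # r ~ 15 for area 78.5
        prof, r = spatial.neighborhood_profile(rec)
        assert 14 < r < 28
        assert prof["n_neighbors"].tolist() == [1, 2, 1]

    def test_matches_all_pairs_brute_force(self):
        spec = simulate.SimulationSpec(n_cells=100, seed=36)
        cells, nuclei, truth = simulate.gen_tissue_image(spec)
        rec = spatial.map_compartments(cells, nuclei)
        rec["lineage"] = truth["phenotype"]
        prof, r = spatial.neighborhood_profile(rec)
        xy = rec[["centroid_row", "centroid_col"]].to_numpy()
        for i, cid in enumerate(rec.index):
            d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
            expected = {int(rec.index[j]) for j in np.flatnonzero(d <= r) if j != i}
            assert set(prof.loc[cid, "neighbor_ids"]) == expected

    def test_neighbor_relation_is_symmetric(self):
        spec = simulate.SimulationSpec(n_cells=60, seed=37)
        cells, nuclei, truth = simulate.gen_tissue_image(spec)
        rec = spatial.map_compartments(cells, nuclei)
        rec["lineage"] = truth["phenotype"]
        prof, _ = spatial.neighborhood_profile(rec)
        nbrs = {cid: set(prof.loc[cid, "neighbor_ids"]) for cid in prof.index}
        for i, js in nbrs.items():
            for j in js:
                assert i in nbrs[j]

    def test_segregated_lineages_show_self_colocalization(self):
        # two spatial blocks of different lineage: same-lineage neighbor
        # frequency must exceed the global lineage proportion
        pts_a = [(0, 10 * i) for i in range(10)]
        pts_b = [(1000, 10 * i) for i in range(10)]
        rec = self._records(pts_a + pts_b, lineages=["a"] * 10 + ["b"] * 10)
        prof, _ = spatial.neighborhood_profile(rec)
        summary = spatial.neighborhood_summary(rec, prof)
        assert summary.loc["a", "freq_a"] > 0.5
        assert summary.loc["b", "freq_b"] > 0.5

    def test_no_labelled_cells_rejected(self):
        rec = self._records([(0, 0)]).drop(columns="lineage")
        with pytest.raises(ValueError, match="labelled"):
            spatial.neighborhood_profile(rec)
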