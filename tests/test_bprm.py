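"""Severity contributions, grid aggregation and export conservation."""

import numpy as np
import pandas as pd
import pytest

from bprm.bprm import (
    aggregate_grid,
    export_bprm,
    severity_volume,
    voxel_contribution,
)
from bprm.core import CatalogError, RegionMask, Volume3D
from bprm.densitometry import PRMMap, Thresholds
from bprm.lac import LACRecord
from bprm.pipeline import scale_model_from_boundaries
from bprm.scaling_model import AirflowModel, ModelTerm, predictor_name


def _scales():
    b = np.linspace(0.01, 0.09, 9)
    return {"emph950": scale_model_from_boundaries(b),
            "fsad": scale_model_from_boundaries(b)}


def _model(terms):
    return AirflowModel(intercept=80.0, terms=[
        ModelTerm(name=n, scale=None, group=None, lesion_type=None,
                  coefficient=c, p_value=0.01) for n, c in terms.items()])


def _rec(rid, phase, lad, group, voxels, lac_class="plain", fsad_voxels=0):
    return LACRecord(id=rid, phase=phase, threshold=-950, voxel_count=voxels,
                     lad=lad, max_erosion_depth=0, centroid_mm=(0, 0, 0),
                     side="left", group=group, lac_class=lac_class,
                     fsad_voxels=fsad_voxels)


class TestVoxelContribution:
    def test_normal_voxels_zero(self):
        labels = np.zeros((4, 4, 4), np.int32)
        out = voxel_contribution({"emph950": labels}, {"emph950": []},
                                 _model({}), _scales(), 1000)
        assert not out.any()

    def test_cluster_share_arithmetic(self):
        # 500-voxel cluster, parenchyma 1e5, beta -0.8 on its term
        labels = np.zeros((10, 10, 10), np.int32)
        labels.ravel()[:500] = 1
        lad = 500 / 1e5
        rec = _rec(1, "inspiratory", lad, "upper", 500)
        name = predictor_name(1, "upper", "emph950")  # lad 0.005 -> scale 1
        out = voxel_contribution({"emph950": labels}, {"emph950": [rec]},
                                 _model({name: -0.8}), _scales(), 100_000)
        per_voxel = out[labels == 1]
        assert per_voxel == pytest.approx(-0.8 * 100 / 1e5)
        assert per_voxel.sum() == pytest.approx(-0.8 * 100 * lad)

    def test_unselected_term_contributes_zero(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0, 0, :4] = 1
        rec = _rec(1, "inspiratory", 0.004, "upper", 4)
        out = voxel_contribution({"emph950": labels}, {"emph950": [rec]},
                                 _model({}), _scales(), 1000)
        assert not out.any()

    def test_fsad_uses_effective_density(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0, 0, :4] = 1
        rec = _rec(1, "expiratory", 0.004, "upper", 4, "fsad", fsad_voxels=2)
        name = predictor_name(1, "upper", "fsad")  # effective lad 0.002
        out = voxel_contribution({"fsad": labels}, {"fsad": [rec]},
                                 _model({name: -2.0}), _scales(), 1000)
        assert out.sum() == pytest.approx(-2.0 * 100 * 0.002)

    def test_missing_region_rejected(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[0, 0, 0] = 1
        rec = _rec(1, "inspiratory", 0.1, "upper", 1)
        rec.group = None
        with pytest.raises(CatalogError):
            voxel_contribution({"emph950": labels}, {"emph950": [rec]},
                               _model({}), _scales(), 10)


def _toy_subject():
    """Two 27-voxel cubes, one upper one lower, distinct betas."""
    shape = (20, 12, 12)
    side = np.zeros(shape, np.uint8)
    side[1:19, 1:11, 1:11] = 1  # all left lung
    group = np.zeros(shape, np.uint8)
    group[10:] = 1  # upper half (z >= 10)
    group[:10] = 2
    group[side == 0] = 0
    regions = RegionMask(side=side, group=group,
                         airway=np.zeros(shape, bool))
    labels = np.zeros(shape, np.int32)
    labels[14:17, 4:7, 4:7] = 1  # upper cube
    labels[3:6, 4:7, 4:7] = 2  # lower cube
    par = regions.parenchyma_count
    recs = [
        _rec(1, "inspiratory", 27 / par, "upper", 27),
        _rec(2, "inspiratory", 27 / par, "lower", 27),
    ]
    s = int(_scales()["emph950"].assign([27 / par])[0])
    nup = predictor_name(s, "upper", "emph950")
    nlo = predictor_name(s, "lower", "emph950")
    model = _model({nup: -0.5, nlo: -2.0})
    contrib = voxel_contribution({"emph950": labels}, {"emph950": recs},
                                 model, _scales(), par)
    prm = PRMMap(classes=np.where(regions.parenchyma, 1, 0).astype(np.uint8),
                 thresholds=Thresholds())
    return regions, labels, recs, model, contrib, prm


class TestAggregateGrid:
    def test_degenerate_single_cell(self):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        grid = aggregate_grid(contrib, regions, prm, model.intercept,
                              cell_size_mm=1000.0)
        assert len(grid.cells) == 1
        total = -100 * (0.5 + 2.0) * 27 / regions.parenchyma_count
        assert grid.cells.iloc[0]["severity"] == pytest.approx(total)
        assert grid.whole_lung_prediction == pytest.approx(80.0 + total)

    def test_two_bullae_ranking_follows_beta(self):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        grid = aggregate_grid(contrib, regions, prm, model.intercept,
                              cell_size_mm=10.0)
        worst = grid.cells.iloc[0]
        # the beta=-2 (lower) cube dominates: most severe cell is low in z
        assert worst["severity"] == pytest.approx(-2.0 * 100 * 27
                                                  / regions.parenchyma_count)
        assert worst["center_z_mm"] < 10

    def test_refinement_preserves_total_and_ranking(self):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        g1 = aggregate_grid(contrib, regions, prm, model.intercept, 20.0)
        g2 = aggregate_grid(contrib, regions, prm, model.intercept, 10.0)
        assert g1.cells["severity"].sum() == pytest.approx(
            g2.cells["severity"].sum(), rel=1e-12)
        assert g1.whole_lung_prediction == pytest.approx(
            g2.whole_lung_prediction, rel=1e-12)

    def test_conservation_against_prediction(self):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        from bprm.scaling_model import assemble_predictors

        x = assemble_predictors(recs, _scales())
        pred = model.predict(x)[0]
        grid = aggregate_grid(contrib, regions, prm, model.intercept, 15.0)
        assert abs(grid.whole_lung_prediction - pred) <= 1e-9 * abs(pred)

    def test_empty_cells_carry_no_contribution(self):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        grid = aggregate_grid(contrib, regions, prm, model.intercept, 6.0)
        empty = grid.cells[grid.cells["n_parenchyma"] == 0]
        assert (empty["severity"] == 0).all()


class TestExport:
    def test_round_trip_float32(self, tmp_path):
        regions, labels, recs, model, contrib, prm = _toy_subject()
        grid = aggregate_grid(contrib, regions, prm, model.intercept, 10.0)
        geom = Volume3D(np.zeros(regions.side.shape, np.float32), (1, 1, 1))
        nii = tmp_path / "sev.nii.gz"
        csv = tmp_path / "cells.csv"
        export_bprm(grid, geom, nii, csv)
        from bprm.io import read_volume

        back = read_volume(nii)
        expect = severity_volume(grid, geom).astype(np.float32)
        assert np.allclose(back.values, expect, atol=0)
        cells = pd.read_csv(csv)
        assert (cells["severity"].to_numpy()[:-1]
                <= cells["severity"].to_numpy()[1:] + 1e-12).all()

    def test_no_lesions_uniform_zero(self, tmp_path):
        regions, *_ = _toy_subject()
        prm = PRMMap(classes=np.where(regions.parenchyma, 1, 0).astype(np.uint8),
                     thresholds=Thresholds())
        contrib = np.zeros(regions.side.shape)
        grid = aggregate_grid(contrib, regions, prm, 75.0, 10.0)
        geom = Volume3D(np.zeros(regions.side.shape, np.float32), (1, 1, 1))
        sev = severity_volume(grid, geom)
        assert not sev.any()
        assert grid.whole_lung_prediction == pytest.approx(75.0)
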