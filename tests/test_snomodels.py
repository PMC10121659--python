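"""Ensemble metrics, PMF, pair taxonomy and variant classification."""

import numpy as np
import pandas as pd
import pytest

from snotools import fixtures as fx
from snotools.structure_io import Ensemble, Residue, StructureModel
from snotools.snomodels import (
    GAS_CONSTANT_KCAL, PAIR_CLASSES, EnsembleParams, VariantParams,
    analyze_ensemble, classify_pair_ss, classify_variant_effect,
    cofactor_proximity_flag, fraction_below, pmf_1d,
    summary_from_metric_samples, variants_table,
)

from conftest import make_atom, make_cys


def _distance_ensemble(distances):
    models = []
    for i, d in enumerate(distances):
        m = fx.place_cys_pair(fx.ScaffoldSpec(sequence="GAGCGAG"),
                              fx.ScaffoldSpec(sequence="GAGCGAG"),
                              float(d), -90.0)
        m.model_id = i + 1
        models.append(m)
    return Ensemble(models=models)


class TestAnalyzeEnsemble:
    def test_arithmetic_on_constructed_distances(self):
        summary = analyze_ensemble(_distance_ensemble([3, 5, 7, 9]), 4, 30)
        assert summary.mean["sg_sg_distance"] == pytest.approx(6.0, abs=0.01)
        assert summary.sd["sg_sg_distance"] == pytest.approx(np.sqrt(5), abs=0.01)
        assert summary.fraction_below == pytest.approx(0.5)
        assert len(summary.per_model) == 4

    def test_sentinel_pka_excluded_from_means(self):
        # 2.05 Å models are disulfide-locked (sentinel); 5 Å models are not
        summary = analyze_ensemble(_distance_ensemble([2.05, 5.0, 5.0]), 4, 30)
        assert summary.per_model["pka_sno"].iloc[0] == 99.99
        non_sentinel = summary.per_model.loc[
            ~summary.per_model["pka_sno_unphysical"], "pka_sno"]
        assert summary.mean["pka_sno"] == pytest.approx(non_sentinel.mean())
        assert summary.mean["pka_sno"] < 20

    def test_single_model_sd_zero(self):
        summary = analyze_ensemble(_distance_ensemble([5.0]), 4, 30)
        assert summary.sd["sg_sg_distance"] == 0.0
        assert summary.mean["sg_sg_distance"] == pytest.approx(5.0, abs=0.01)

    def test_means_match_independent_per_model_loop(self):
        from snotools.geometry import pair_geometry

        ens = _distance_ensemble([3, 4.5, 8])
        summary = analyze_ensemble(ens, 4, 30)
        manual = []
        for model in ens:
            sno = model.find(4)
            proxy = model.find(30)
            manual.append(pair_geometry(model, sno, proxy)[0].sg_sg_distance)
        assert summary.mean["sg_sg_distance"] == pytest.approx(np.mean(manual))

    def test_non_cys_position_raises(self):
        ens = _distance_ensemble([5.0])
        with pytest.raises(TypeError):
            analyze_ensemble(ens, 1, 30)


class TestFractionBelow:
    def test_half_below(self):
        assert fraction_below([3, 5, 7, 9], 6) == 0.5

    def test_all_below(self):
        assert fraction_below([1, 2, 3], 6) == 1.0

    def test_boundary_counts_as_higher(self):
        assert fraction_below([6.0, 7.0], 6.0) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fraction_below([], 6)


class TestPmf:
    def test_two_equal_bins_flat(self):
        _, f = pmf_1d([0.25] * 50 + [0.75] * 50, n_bins=2)
        assert np.allclose(f, [0.0, 0.0])

    def test_e_to_1_ratio_gives_rt(self):
        n1 = 100000
        n2 = int(round(n1 / np.e))
        _, f = pmf_1d([0.25] * n1 + [0.75] * n2, n_bins=2, temperature_K=298.0)
        assert np.nanmax(f) == pytest.approx(GAS_CONSTANT_KCAL * 298.0, rel=1e-3)

    def test_empty_bin_undefined_not_zero(self):
        _, f = pmf_1d([0.1] * 10 + [0.9] * 10, n_bins=3, bin_range=(0, 1))
        assert np.isnan(f[1])
        assert np.isfinite(f[0]) and np.isfinite(f[2])

    def test_count_rescaling_invariance(self):
        samples = [0.1] * 30 + [0.5] * 10 + [0.9] * 60
        _, f1 = pmf_1d(samples, n_bins=3, bin_range=(0, 1))
        _, f2 = pmf_1d(samples * 2, n_bins=3, bin_range=(0, 1))
        assert np.allclose(f1, f2, equal_nan=True)

    def test_all_identical_single_bin(self):
        _, f = pmf_1d([2.0] * 10, n_bins=2)
        assert np.nanmin(f) == 0.0


class TestPairClass:
    def test_nine_class_bijection(self):
        seen = set()
        for a in "HEC":
            for b in "HEC":
                seen.add(classify_pair_ss(a, b))
        assert seen == set(PAIR_CLASSES)
        assert len(seen) == 9

    @pytest.mark.parametrize("pair,label", [
        (("E", "E"), "strand-strand"),
        (("E", "H"), "strand-helix"),
        (("C", "H"), "loop-helix"),
    ])
    def test_sno_element_first(self, pair, label):
        assert classify_pair_ss(*pair) == label

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            classify_pair_ss("X", "H")


def _summary(mean_pka, mean_dist, rng=None, n=20, noise=0.0):
    rows = {"sg_sg_distance": np.full(n, mean_dist, dtype=float),
            "pka_sno": np.full(n, mean_pka, dtype=float),
            "pka_sno_unphysical": np.zeros(n, dtype=bool)}
    if noise and rng is not None:
        rows["sg_sg_distance"] = rows["sg_sg_distance"] + rng.normal(0, noise, n)
        rows["pka_sno"] = rows["pka_sno"] + rng.normal(0, noise, n)
    return summary_from_metric_samples(pd.DataFrame(rows), 124, 141)


class TestVariantClassification:
    @pytest.mark.parametrize("dp,dd,label", [
        (-1.0, -1.0, "stabilizing"),
        (0.0, 0.0, "neutral"),
        (+1.0, +1.0, "destabilizing"),
        (+3.0, -0.2, "destabilizing"),   # large pKa increase wins alone
        (+1.0, -1.0, "uncertain"),       # mixed signals
        (-1.0, +1.0, "uncertain"),
    ])
    def test_rule_regions(self, dp, dd, label):
        wt = _summary(9.0, 5.0)
        mut = _summary(9.0 + dp, 5.0 + dd)
        assert classify_variant_effect(wt, mut).label == label

    def test_antisymmetry_where_defined(self):
        wt = _summary(9.0, 5.0)
        mut = _summary(8.0, 4.0)
        assert classify_variant_effect(wt, mut).label == "stabilizing"
        assert classify_variant_effect(mut, wt).label == "destabilizing"

    def test_sentinel_only_is_uncertain(self):
        wt = _summary(9.0, 5.0)
        rows = pd.DataFrame({
            "sg_sg_distance": [2.0] * 5,
            "pka_sno": [99.99] * 5,
            "pka_sno_unphysical": [True] * 5,
        })
        mut = summary_from_metric_samples(rows, 124, 141)
        effect = classify_variant_effect(wt, mut)
        assert effect.label == "uncertain"
        assert "sentinel" in effect.reason

    def test_mismatched_pairs_raise(self):
        wt = _summary(9.0, 5.0)
        mut = summary_from_metric_samples(
            wt.per_model, sno_pos=1, proxy_pos=2)
        with pytest.raises(ValueError):
            classify_variant_effect(wt, mut)

    def test_recovery_under_sampling_noise(self):
        """Imposed (delta pKa, delta distance) in each rule region is
        recovered from noisy 20-model summaries in >= 95% of seeds."""
        regions = {"stabilizing": (-1.0, -1.0), "neutral": (0.0, 0.0),
                   "destabilizing": (+1.0, +1.0), "uncertain": (+1.0, -1.0)}
        for label, (dp, dd) in regions.items():
            hits = 0
            for seed in range(100):
                rng = np.random.default_rng(seed)
                wt = _summary(9.0, 5.0, rng, noise=0.3)
                mut = _summary(9.0 + dp, 5.0 + dd, rng, noise=0.3)
                if classify_variant_effect(wt, mut).label == label:
                    hits += 1
            assert hits >= 95, label

    def test_variants_table_columns(self):
        wt = _summary(9.0, 5.0)
        table = variants_table(wt, {"N235H": _summary(8.0, 4.0),
                                    "V274I": _summary(10.0, 6.0)})
        assert list(table["mutation"]) == ["N235H", "V274I"]
        assert list(table["label"]) == ["stabilizing", "destabilizing"]


class TestCofactorFlag:
    def _model_with_ligand(self, resname, distance, element="ZN"):
        cys = make_cys(10, [0, 0, 0], [0, 0, 0])
        ligand = Residue("A", 200, "", resname)
        ligand.atoms = [make_atom(element, element, [distance, 0, 0], is_het=True)]
        return StructureModel(1, [cys, ligand]), cys

    def test_zinc_within_cutoff_flagged(self):
        model, cys = self._model_with_ligand("ZN", 3.0)
        flag, ligand = cofactor_proximity_flag(model, cys)
        assert flag and ligand == "ZN"

    def test_water_never_flagged(self):
        model, cys = self._model_with_ligand("HOH", 3.0, element="O")
        flag, ligand = cofactor_proximity_flag(model, cys)
        assert not flag and ligand is None

    def test_no_hetatm_not_flagged(self):
        cys = make_cys(10, [0, 0, 0], [0, 0, 0])
        flag, ligand = cofactor_proximity_flag(StructureModel(1, [cys]), cys)
        assert not flag

    def test_distant_ligand_not_flagged(self):
        model, cys = self._model_with_ligand("ZN", 6.0)
        assert cofactor_proximity_flag(model, cys)[0] is False
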