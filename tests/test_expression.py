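"""Expression pipeline: probe filtering/selection, sample restriction, SRS,
differential stability, top-DS gene retention."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from imgtx.expression import (
    differential_stability,
    filter_probes_intensity,
    restrict_samples,
    select_probes_by_rnaseq,
    select_top_ds,
    srs_normalize,
)
from imgtx.images import ActivityMap


def _tables(flags_rows):
    n = len(flags_rows[0])
    samples = [f"s{i}" for i in range(n)]
    probes = [f"p{i}" for i in range(len(flags_rows))]
    expr = pd.DataFrame(np.ones((len(probes), n)), index=probes, columns=samples)
    flags = pd.DataFrame(flags_rows, index=probes, columns=samples, dtype=bool)
    return expr, flags


class TestIntensityFilter:
    def test_always_above_background_retained(self):
        expr, flags = _tables([[True] * 10])
        assert list(filter_probes_intensity(expr, flags)) == ["p0"]

    def test_below_half_removed(self):
        expr, flags = _tables([[True] * 49 + [False] * 51])
        assert len(filter_probes_intensity(expr, flags)) == 0

    def test_exactly_half_retained_inclusive(self):
        expr, flags = _tables([[True] * 5 + [False] * 5])
        assert list(filter_probes_intensity(expr, flags)) == ["p0"]


def _selection_setup(probe_rs):
    """Probes for one gene whose (donor, structure) profiles have known
    correlation structure against a reference profile."""
    rng = np.random.default_rng(7)
    structures = [f"S{i}" for i in range(8)]
    samples = pd.DataFrame(
        {
            "donor": ["D1"] * 8 + ["D2"] * 8,
            "structure": structures + structures,
        },
        index=[f"s{i}" for i in range(16)],
    )
    ref = rng.standard_normal(16)
    rows = {}
    for i, r in enumerate(probe_rs):
        noise = rng.standard_normal(16)
        noise -= noise.mean()
        ref_c = ref - ref.mean()
        noise -= (noise @ ref_c) / (ref_c @ ref_c) * ref_c  # orthogonalize
        x = r * ref_c / ref_c.std() + np.sqrt(max(0, 1 - r**2)) * noise / noise.std()
        rows[f"p{i}"] = x
    expr = pd.DataFrame(rows).T
    expr.columns = samples.index
    probes = pd.DataFrame({"gene": ["G1"] * len(probe_rs)}, index=expr.index)
    key = samples["donor"] + "|" + samples["structure"]
    ref_prof = pd.Series(ref, index=samples.index).groupby(key.to_numpy()).mean()
    rnaseq = pd.DataFrame([ref_prof], index=pd.Index(["G1"], name="gene"))
    return probes, expr, rnaseq, samples


class TestProbeSelection:
    def test_single_good_probe_selected(self):
        probes, expr, rnaseq, samples = _selection_setup([0.9])
        sel = select_probes_by_rnaseq(probes, expr, rnaseq, samples)
        assert sel["G1"] == "p0"

    def test_gene_dropped_when_all_probes_below_cut(self):
        probes, expr, rnaseq, samples = _selection_setup([0.15, 0.19])
        sel = select_probes_by_rnaseq(probes, expr, rnaseq, samples)
        assert "G1" not in sel.index

    def test_highest_correlation_probe_wins(self):
        probes, expr, rnaseq, samples = _selection_setup([0.3, 0.6])
        sel = select_probes_by_rnaseq(probes, expr, rnaseq, samples)
        # brute-force check: compute each probe's pooled correlation directly
        key = (samples["donor"] + "|" + samples["structure"]).to_numpy()
        prof = expr.T.groupby(key).mean().T
        ref = rnaseq.loc["G1", prof.columns].to_numpy(float)
        r0 = np.corrcoef(prof.loc["p0"], ref)[0, 1]
        r1 = np.corrcoef(prof.loc["p1"], ref)[0, 1]
        assert r1 > r0 >= 0.2
        assert sel["G1"] == "p1"

    def test_zero_variance_probe_treated_as_failing(self):
        probes, expr, rnaseq, samples = _selection_setup([0.9])
        expr.loc["p0"] = 1.0  # constant probe
        sel = select_probes_by_rnaseq(probes, expr, rnaseq, samples)
        assert "G1" not in sel.index

    def test_gene_absent_from_rnaseq_excluded(self):
        probes, expr, rnaseq, samples = _selection_setup([0.9])
        sel = select_probes_by_rnaseq(
            probes, expr, rnaseq.rename(index={"G1": "OTHER"}), samples
        )
        assert len(sel) == 0


class TestSampleRestriction:
    def _annotations(self):
        return pd.DataFrame(
            {
                "donor": ["D1"] * 4,
                "mni_x": [-6.0, 6.0, -6.0, -6.0],
                "mni_y": [0.0, 0.0, 0.0, 200.0],
                "mni_z": [0.0, 0.0, 0.0, 0.0],
                "hemisphere": ["L", "R", "L", "L"],
                "tissue_class": ["cortex", "cortex", "subcortex", "cortex"],
                "structure": ["A", "A", "SUB", "A"],
            },
            index=["left_ctx", "right_ctx", "left_sub", "outside"],
        )

    def test_restriction_rules(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = -7.5
        mask = ActivityMap(np.ones((6, 6, 6)), affine)
        kept = restrict_samples(self._annotations(), mask)
        assert list(kept) == ["left_ctx"]

    def test_no_mask_keeps_all_left_cortex(self):
        kept = restrict_samples(self._annotations(), None)
        assert list(kept) == ["left_ctx", "outside"]

    def test_in_mask_value_required(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = -7.5
        mask = ActivityMap(np.zeros((6, 6, 6)), affine)
        assert len(restrict_samples(self._annotations(), mask)) == 0


class TestSrsNormalize:
    def test_median_maps_to_half_before_rescale(self):
        # odd-length vector: the median element sits at sigmoid value 0.5,
        # hence at (0.5 - lo) / (hi - lo) after rescale; check via formula
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        med, iqr = np.median(x), np.percentile(x, 75) - np.percentile(x, 25)
        s = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        expected = (s - s.min()) / (s.max() - s.min())
        out = srs_normalize(pd.DataFrame({"g": x}), axis=0)["g"].to_numpy()
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_output_in_unit_interval_and_rank_preserving(self, rng):
        frame = pd.DataFrame(rng.standard_normal((30, 5)) * 10)
        out = srs_normalize(frame, axis=0)
        assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1
        for c in frame.columns:
            assert (
                frame[c].rank().to_numpy() == out[c].rank().to_numpy()
            ).all()

    def test_outlier_compressed_relative_to_minmax(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        out = srs_normalize(pd.DataFrame({"g": x}), axis=0)["g"].to_numpy()
        minmax = (x - x.min()) / np.ptp(x)
        gap_srs = out[4] - out[3]
        gap_minmax = minmax[4] - minmax[3]
        assert gap_srs < gap_minmax

    def test_zero_iqr_gives_constant_half(self):
        x = np.array([2.0, 2.0, 2.0, 2.0])
        out = srs_normalize(pd.DataFrame({"g": x}), axis=0)["g"].to_numpy()
        np.testing.assert_array_equal(out, 0.5)


class TestDifferentialStability:
    def _donor(self, profiles, structures):
        """One sample per structure with the given per-gene profile values."""
        frame = pd.DataFrame(profiles, index=structures)
        frame.index = [f"s_{s}" for s in structures]
        labels = pd.Series(structures, index=frame.index)
        return frame, labels

    def test_identical_profiles_give_one(self):
        profile = {"g1": [0.1, 0.5, 0.9, 0.3], "g2": [1.0, 0.0, 0.5, 0.2]}
        structures = ["A", "B", "C", "D"]
        m1, s1 = self._donor(profile, structures)
        m2, s2 = self._donor(profile, structures)
        ds = differential_stability({"D1": m1, "D2": m2}, {"D1": s1, "D2": s2})
        np.testing.assert_allclose(ds.to_numpy(), 1.0)

    def test_independent_profiles_near_zero_on_average(self, rng):
        structures = ["A", "B", "C", "D", "E", "F"]
        matrices, labels = {}, {}
        n_genes = 300
        for d in range(4):
            prof = {f"g{i}": rng.standard_normal(6) for i in range(n_genes)}
            matrices[f"D{d}"], labels[f"D{d}"] = self._donor(prof, structures)
        ds = differential_stability(matrices, labels)
        assert abs(ds.mean()) < 0.05

    def test_three_donor_hand_profiles_match_pairwise_spearman(self):
        structures = ["A", "B", "C", "D"]
        profs = [
            {"g1": [1.0, 2.0, 3.0, 4.0]},
            {"g1": [2.0, 1.0, 4.0, 3.0]},
            {"g1": [1.0, 3.0, 2.0, 4.0]},
        ]
        matrices, labels = {}, {}
        for i, p in enumerate(profs):
            matrices[f"D{i}"], labels[f"D{i}"] = self._donor(p, structures)
        ds = differential_stability(matrices, labels)
        rhos = [
            spearmanr(profs[i]["g1"], profs[j]["g1"]).statistic
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert ds["g1"] == pytest.approx(np.mean(rhos))

    def test_pairs_with_few_shared_structures_skipped(self):
        m1, s1 = self._donor({"g1": [1.0, 2.0, 3.0, 4.0]}, ["A", "B", "C", "D"])
        m2, s2 = self._donor({"g1": [1.0, 2.0]}, ["X", "Y"])
        with pytest.raises(ValueError):
            differential_stability({"D1": m1, "D2": m2}, {"D1": s1, "D2": s2})


class TestTopDsSelection:
    def test_distinct_values_keep_exact_half(self):
        ds = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        kept = select_top_ds(ds, 0.5)
        assert set(kept) == {f"g{i}" for i in range(5, 10)}

    def test_all_ties_all_retained(self):
        ds = pd.Series(1.0, index=[f"g{i}" for i in range(8)])
        assert len(select_top_ds(ds, 0.5)) == 8

    def test_matches_sort_and_slice_oracle(self, rng):
        for _ in range(20):
            ds = pd.Series(rng.standard_normal(17), index=[f"g{i}" for i in range(17)])
            kept = set(select_top_ds(ds, 0.5))
            cut = np.quantile(ds.to_numpy(), 0.5)
            expected = {g for g, v in ds.items() if v >= cut}
            assert kept == expected
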