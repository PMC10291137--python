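"""Somatic filter rules, Jaccard distances, conservation classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdxplore.variants import (
    FilterThresholds,
    classify_conservation,
    classify_origin,
    filter_variants,
    jaccard_distance,
    mutation_gain_ratio,
    oncoprint_table,
    pairwise_jaccard_matrix,
    variant_key_sets,
)


def _call(**kwargs):
    base = dict(
        sample="S1", patient="P1", timepoint="diagnosis", chrom="chr1", pos=100,
        ref="A", alt="T", gene="G0001", alt_reads=20, depth=60, vaf=0.33,
        popaf_1000g=0.0, popaf_kaviar=0.0,
    )
    base.update(kwargs)
    return base


class TestFilterVariants:
    def test_fewer_than_five_supporting_reads_removed(self):
        kept, log = filter_variants(pd.DataFrame([_call(alt_reads=4, vaf=0.30)]))
        assert kept.empty and log["failed_rules"].iloc[0] == "support"

    def test_exactly_five_reads_kept(self):
        kept, _ = filter_variants(pd.DataFrame([_call(alt_reads=5)]))
        assert len(kept) == 1

    def test_population_frequency_above_one_percent_removed(self):
        kept, log = filter_variants(pd.DataFrame([_call(popaf_1000g=0.02)]))
        assert kept.empty and log["failed_rules"].iloc[0] == "population"

    def test_population_frequency_boundary_kept(self):
        kept, _ = filter_variants(pd.DataFrame([_call(popaf_1000g=0.01, popaf_kaviar=0.01)]))
        assert len(kept) == 1

    def test_vaf_boundary(self):
        kept, _ = filter_variants(pd.DataFrame([_call(vaf=0.05), _call(pos=101, vaf=0.049)]))
        assert list(kept["pos"]) == [100]

    def test_both_population_databases_checked(self):
        kept, log = filter_variants(pd.DataFrame([_call(popaf_kaviar=0.05)]))
        assert kept.empty

    def test_missing_evidence_rejected_as_incomplete(self):
        kept, log = filter_variants(pd.DataFrame([_call(vaf=np.nan)]))
        assert kept.empty and log["failed_rules"].iloc[0] == "incomplete"

    def test_missing_popaf_treated_as_zero_unless_strict(self):
        df = pd.DataFrame([_call(popaf_kaviar=np.nan)])
        kept, _ = filter_variants(df)
        assert len(kept) == 1
        kept, log = filter_variants(df, FilterThresholds(strict_popaf=True))
        assert kept.empty and log["failed_rules"].iloc[0] == "incomplete"

    def test_multiple_failed_rules_all_logged(self):
        _, log = filter_variants(pd.DataFrame([_call(alt_reads=2, vaf=0.01, depth=200)]))
        assert set(log["failed_rules"].iloc[0].split(",")) == {"support", "vaf"}

    def test_random_calls_match_brute_force_predicates(self, rng):
        # independent oracle: re-evaluate the three predicates row by row
        n = 1000
        df = pd.DataFrame(
            [
                _call(
                    pos=i,
                    alt_reads=int(rng.integers(0, 12)),
                    depth=200,
                    vaf=float(rng.choice([0.01, 0.049, 0.05, 0.3])),
                    popaf_1000g=float(rng.choice([0.0, 0.005, 0.01, 0.02])),
                    popaf_kaviar=float(rng.choice([0.0, 0.01, 0.011])),
                )
                for i in range(n)
            ]
        )
        kept, _ = filter_variants(df)
        expected = {
            row.pos
            for row in df.itertuples()
            if row.alt_reads >= 5 and row.vaf >= 0.05
            and row.popaf_1000g <= 0.01 and row.popaf_kaviar <= 0.01
        }
        assert set(kept["pos"]) == expected

    def test_filter_is_idempotent(self, variant_cohort):
        calls, _ = variant_cohort
        kept, _ = filter_variants(calls)
        kept2, log2 = filter_variants(kept)
        assert log2.empty
        pd.testing.assert_frame_equal(kept.reset_index(drop=True), kept2.reset_index(drop=True))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_vaf=0.0)


class TestJaccard:
    def test_identity_and_disjoint(self):
        assert jaccard_distance({1, 2}, {1, 2}) == 0.0
        assert jaccard_distance({1}, {2}) == 1.0
        assert jaccard_distance(set(), set()) == 0.0

    def test_worked_example(self):
        assert jaccard_distance({"v1", "v2", "v3"}, {"v2", "v3", "v4"}) == 0.5

    def test_matrix_equals_elementwise_calls(self, rng):
        sets = {f"s{i}": set(rng.choice(30, size=rng.integers(0, 15), replace=False))
                for i in range(8)}
        mat = pairwise_jaccard_matrix(sets)
        for a in sets:
            for b in sets:
                assert mat.loc[a, b] == pytest.approx(jaccard_distance(sets[a], sets[b]))
        assert np.allclose(mat.values, mat.values.T) and np.allclose(np.diag(mat), 0)

    def test_identical_sets_give_zero_matrix(self):
        mat = pairwise_jaccard_matrix({"a": {1, 2}, "b": {1, 2}, "c": {1, 2}})
        assert (mat.values == 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_jaccard_matrix({"a": {1}})

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.frozensets(st.integers(0, 20)),
        b=st.frozensets(st.integers(0, 20)),
        c=st.frozensets(st.integers(0, 20)),
    )
    def test_metric_properties(self, a, b, c):
        dab, dbc, dac = jaccard_distance(a, b), jaccard_distance(b, c), jaccard_distance(a, c)
        assert 0.0 <= dab <= 1.0
        assert dab == jaccard_distance(b, a)
        assert dac <= dab + dbc + 1e-12  # Jaccard distance is a metric

    def test_planted_cohort_distances_follow_set_arithmetic(self):
        from pdxplore.synthetic import CohortSpec, simulate_variant_cohort

        spec = CohortSpec(n_patients=1, n_variants_shared=10,
                          n_variants_relapse_gained=5, n_variants_pdx_private=0, seed=17)
        calls, _ = simulate_variant_cohort(spec, decoy_fraction=0.0)
        sets = variant_key_sets(calls)
        d = sets["OS-01_Pat_D"]
        r = sets["OS-01_Pat_R"]
        sc = sets["OS-01_PDX_sc"]
        # diagnosis vs relapse: 10 shared of 15 -> 1/3; relapse vs PDX identical
        assert jaccard_distance(d, r) == pytest.approx(1 - 10 / 15)
        assert jaccard_distance(r, sc) == 0.0
        assert jaccard_distance(d, r) > jaccard_distance(r, sc)


class TestConservation:
    @pytest.mark.parametrize(
        "present,expected",
        [
            ({"diagnosis", "relapse", "pdx_sc", "pdx_pt"}, "diagnosis-conserved"),
            ({"diagnosis", "pdx_pt"}, "diagnosis-conserved"),
            ({"relapse", "pdx_sc"}, "relapse-emergent"),
            ({"pdx_pt"}, "pdx-private"),
            ({"pdx_sc", "pdx_pt"}, "pdx-private"),
            ({"relapse"}, "not-conserved"),
            ({"diagnosis"}, "not-conserved"),
        ],
    )
    def test_origin_rules(self, present, expected):
        assert classify_origin(present) == expected

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError, match="unknown timepoint"):
            classify_origin({"diagnosis", "necropsy"})

    def test_each_variant_gets_exactly_one_origin(self, variant_cohort):
        calls, _ = variant_cohort
        records = classify_conservation(calls)
        assert records["origin"].isin(
            ["diagnosis-conserved", "relapse-emergent", "pdx-private", "not-conserved"]
        ).all()
        keys = records[["patient", "chrom", "pos", "ref", "alt"]]
        assert not keys.duplicated().any()

    def test_single_timepoint_patient_rejected(self):
        df = pd.DataFrame([_call()])
        with pytest.raises(ValueError, match="< 2 timepoints"):
            classify_conservation(df)


class TestGainRatio:
    def _meta(self):
        return pd.DataFrame(
            {"sample": ["d", "r"], "patient": ["P1", "P1"], "timepoint": ["diagnosis", "relapse"]}
        )

    def test_worked_ratio(self):
        out = mutation_gain_ratio({"d": set(range(10)), "r": set(range(15))}, self._meta())
        assert out["ratio"].iloc[0] == pytest.approx(1.5)

    def test_identical_sets_ratio_one(self):
        out = mutation_gain_ratio({"d": {1, 2}, "r": {1, 2}}, self._meta())
        assert out["ratio"].iloc[0] == 1.0

    def test_empty_earlier_reported_missing(self):
        out = mutation_gain_ratio({"d": set(), "r": {1}}, self._meta())
        assert np.isnan(out["ratio"].iloc[0])

    def test_planted_cohort_ratio(self):
        from pdxplore.synthetic import CohortSpec, simulate_variant_cohort

        spec = CohortSpec(n_patients=3, n_variants_shared=10,
                          n_variants_relapse_gained=5, n_variants_pdx_private=0, seed=21)
        calls, _ = simulate_variant_cohort(spec, decoy_fraction=0.0)
        meta = calls[["sample", "patient", "timepoint"]].drop_duplicates()
        out = mutation_gain_ratio(variant_key_sets(calls), meta)
        assert np.allclose(out["ratio"], 1.5)


class TestOncoprint:
    def test_empty_records_give_empty_grid(self):
        out = oncoprint_table(["TP53", "RB1"])
        assert list(out.index) == ["TP53", "RB1"] and out.shape[1] == 0

    def test_single_mutation_single_cell(self):
        muts = pd.DataFrame({"gene": ["TP53"], "sample": ["s1"]})
        out = oncoprint_table(["TP53", "RB1"], mutations=muts)
        assert out.loc["TP53", "s1"] == "mut" and (out != "").sum().sum() == 1

    def test_merged_sources_match_brute_force_join(self, rng):
        panel = [f"G{i}" for i in range(6)]
        muts = pd.DataFrame({"gene": rng.choice(panel + ["OFF"], 20), "sample": rng.choice(["a", "b"], 20)})
        cnas = pd.DataFrame({"gene": rng.choice(panel, 10), "sample": rng.choice(["a", "b"], 10),
                             "category": rng.choice(["gain", "deletion"], 10)})
        fus = pd.DataFrame({"gene5": rng.choice(panel, 5), "gene3": rng.choice(panel, 5),
                            "sample": rng.choice(["a", "b"], 5)})
        out = oncoprint_table(panel, mutations=muts, cna_calls=cnas, fusions=fus)
        # brute-force join oracle
        for gene in panel:
            for sample in out.columns:
                expected = set()
                if ((muts.gene == gene) & (muts["sample"] == sample)).any():
                    expected.add("mut")
                expected |= set(cnas.loc[(cnas.gene == gene) & (cnas["sample"] == sample), "category"])
                if (((fus.gene5 == gene) | (fus.gene3 == gene)) & (fus["sample"] == sample)).any():
                    expected.add("fusion")
                got = set(out.loc[gene, sample].split(";")) - {""}
                assert got == expected

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            oncoprint_table([])
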