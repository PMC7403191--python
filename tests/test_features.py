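"""Feature derivation: baselining, functional features, table assembly."""

import numpy as np
import pandas as pd
import pytest

import orthoimmune as oi
from orthoimmune.features import (
    PER_SEX,
    POOLED,
    FeatureTable,
    assemble_feature_table,
    compute_baseline_reference,
    derive_functional_features,
    impute_missing,
)
from orthoimmune.gating import EventTable, apply_gating
from orthoimmune.panel import FREQUENCY, PanelConfig
from orthoimmune.synthetic import (
    CohortConfig,
    EffectSpec,
    simulation_cohort_config,
)


def manual_events(panel, cells):
    """cells: list of (sample_id, sex, timepoint, pop_label, marker_values)."""
    rows = []
    labels = []
    for sid, sex, tp, pop, values in cells:
        raw = {m: panel.inverse_arcsinh(v) for m, v in values.items()}
        for m in panel.markers:
            raw.setdefault(m, 0.0)
        rows.append({"sample_id": sid, "animal_id": sid, "sex": sex,
                     "timepoint": tp, **raw})
        labels.append(pop)
    data = pd.DataFrame(rows)
    ev = EventTable(data=data, panel=panel)
    return ev, pd.Series(labels, index=data.index, name="population")


class TestBaselineReference:
    def test_single_sample_median(self, panel):
        ev, labels = manual_events(panel, [
            ("b1", "M", "BL", "NK", {"pSTAT3": 1.0}),
            ("b1", "M", "BL", "NK", {"pSTAT3": 1.2}),
            ("b1", "M", "BL", "NK", {"pSTAT3": 1.4}),
        ])
        ref = compute_baseline_reference(ev, labels)
        assert ref.loc["NK", "pSTAT3"] == pytest.approx(1.2)

    def test_pooled_policy_uses_cell_level_median(self, panel):
        # 3 male cells at 1.0 and 3 female cells at 2.0: the pooled
        # reference is the median of the concatenated cells
        cells = [("bM", "M", "BL", "NK", {"pSTAT3": 1.0})] * 3
        cells += [("bF", "F", "BL", "NK", {"pSTAT3": 2.0})] * 3
        ev, labels = manual_events(panel, cells)
        ref = compute_baseline_reference(ev, labels, policy=POOLED)
        expected = np.median([1.0] * 3 + [2.0] * 3)
        assert ref.loc["NK", "pSTAT3"] == pytest.approx(expected)
        assert 1.0 <= ref.loc["NK", "pSTAT3"] <= 2.0

    def test_per_sex_policy_gives_two_references(self, panel):
        cells = [("bM", "M", "BL", "NK", {"pSTAT3": 1.0})] * 2
        cells += [("bF", "F", "BL", "NK", {"pSTAT3": 2.0})] * 2
        ev, labels = manual_events(panel, cells)
        ref = compute_baseline_reference(ev, labels, policy=PER_SEX)
        assert ref.loc[("M", "NK"), "pSTAT3"] == pytest.approx(1.0)
        assert ref.loc[("F", "NK"), "pSTAT3"] == pytest.approx(2.0)

    def test_no_baseline_samples_raises(self, panel):
        ev, labels = manual_events(
            panel, [("s", "M", "12h", "NK", {"pSTAT3": 1.0})] * 2
        )
        with pytest.raises(ValueError, match="baseline"):
            compute_baseline_reference(ev, labels)


class TestFunctionalFeatures:
    def test_median_minus_reference(self, panel):
        cells = [("b1", "M", "BL", "NK", {"pSTAT3": 1.0})] * 3
        cells += [("s1", "M", "12h", "NK", {"pSTAT3": 1.8})] * 3
        ev, labels = manual_events(panel, cells)
        ref = compute_baseline_reference(ev, labels)
        func = derive_functional_features(ev, labels, ref, populations=["NK"])
        assert func.loc["s1", "NK|pSTAT3"] == pytest.approx(0.8)
        assert func.loc["b1", "NK|pSTAT3"] == pytest.approx(0.0)

    def test_absent_population_gives_missing(self, panel):
        cells = [("b1", "M", "BL", "NK", {"pSTAT3": 1.0})] * 3
        cells += [("s1", "M", "12h", "Tregs", {"pSTAT3": 1.5})] * 3
        ev, labels = manual_events(panel, cells)
        ref = compute_baseline_reference(ev, labels)
        func = derive_functional_features(ev, labels, ref, populations=["NK"])
        assert np.isnan(func.loc["s1", "NK|pSTAT3"])

    def test_injected_sex_effect_recovered(self, panel, sim_setup):
        config = simulation_cohort_config(
            n_per_group=24, events_per_sample=4000,
            effect_timepoints=("12h",), seed=0,
        )
        # single injected effect of interest kept; delta forced to 1.0
        effects = tuple(
            EffectSpec(e.population, e.marker, e.timepoint, e.sex_scope, 1.0)
            for e in config.effects
            if (e.population, e.marker) == ("Neutrophils", "pSTAT3")
        )
        from dataclasses import replace

        config = replace(config, effects=effects, timepoints=("BL", "12h"))
        events, _ = oi.generate_cohort(config, panel)
        labels = apply_gating(events, sim_setup)
        table = oi.derive_feature_table(events, labels, sim_setup)
        tp = table.at_timepoint("12h")
        col = tp.values["Neutrophils|pSTAT3"]
        diff = col[tp.sex() == "F"].mean() - col[tp.sex() == "M"].mean()
        assert diff == pytest.approx(1.0, abs=0.15)

    def test_baseline_features_center_near_zero(self, small_feature_table):
        bl = small_feature_table.at_timepoint("BL")
        func = bl.select_class("functional")
        assert abs(func.values.mean().mean()) < 0.05


class TestAssembly:
    def test_default_panel_yields_273_features(self, small_feature_table):
        assert small_feature_table.n_features == 273
        ann = small_feature_table.annotations
        assert (ann["feature_class"] == "frequency").sum() == 21
        assert (ann["feature_class"] == "functional").sum() == 252
        assert set(ann["compartment"]) == {"innate", "adaptive"}

    def test_column_count_formula_small_panel(self):
        samples = ["s1", "s2"]
        freqs = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0]},
                             index=pd.Index(samples, name="sample_id"))
        panel = PanelConfig(surface_markers=("CD45",),
                            functional_markers=("m1", "m2", "m3"))
        func = pd.DataFrame(
            {f"{p}|{m}": [0.1, 0.2] for p in "AB" for m in ("m1", "m2", "m3")},
            index=freqs.index,
        )
        meta = pd.DataFrame({"animal_id": samples, "sex": ["M", "F"],
                             "timepoint": "BL"}, index=freqs.index)
        table = assemble_feature_table(freqs, func, meta, panel, ["A", "B"])
        assert table.n_features == 2 * (3 + 1) == 8
        # population-major order, FREQUENCY leading each block
        assert list(table.values.columns)[:4] == [
            f"A|{FREQUENCY}", "A|m1", "A|m2", "A|m3"
        ]

    def test_mismatched_samples_raise(self):
        samples = ["s1", "s2"]
        idx = pd.Index(samples, name="sample_id")
        freqs = pd.DataFrame({"A": [1.0, 2.0]}, index=idx)
        func = pd.DataFrame({"A|m1": [0.1]},
                            index=pd.Index(["s1"], name="sample_id"))
        meta = pd.DataFrame({"animal_id": samples, "sex": ["M", "F"],
                             "timepoint": "BL"}, index=idx)
        panel = PanelConfig(surface_markers=("CD45",), functional_markers=("m1",))
        with pytest.raises(ValueError, match="different samples"):
            assemble_feature_table(freqs, func, meta, panel, ["A"])

    def test_round_trip(self, small_feature_table, tmp_path):
        vp, ap = tmp_path / "values.csv", tmp_path / "ann.csv"
        small_feature_table.write(vp, ap)
        back = FeatureTable.read(vp, ap)
        pd.testing.assert_frame_equal(back.values, small_feature_table.values)
        pd.testing.assert_frame_equal(back.meta, small_feature_table.meta)
        pd.testing.assert_frame_equal(back.annotations,
                                      small_feature_table.annotations)

    def test_imputation_fills_all_missing(self, small_cohort, scheme):
        _, events, _ = small_cohort
        labels = apply_gating(events, scheme)
        table = oi.derive_feature_table(events, labels, scheme)
        imputed, n = impute_missing(table)
        assert not imputed.values.isna().any().any()
        assert n == int(table.values.isna().to_numpy().sum())

    def test_scale_invariance(self, panel, scheme):
        config = CohortConfig(n_per_group=3, events_per_sample=300, seed=2)
        events, _ = oi.generate_cohort(config, panel)
        labels = apply_gating(events, scheme)
        t1 = oi.derive_feature_table(events, labels, scheme)
        scaled_panel = PanelConfig(arcsinh_cofactor=panel.arcsinh_cofactor * 3)
        data = events.data.copy()
        data[list(panel.markers)] *= 3.0
        scaled = EventTable(data=data, panel=scaled_panel)
        labels2 = apply_gating(scaled, scheme)
        t2 = oi.derive_feature_table(scaled, labels2, scheme)
        assert np.allclose(t1.values.to_numpy(), t2.values.to_numpy(),
                           rtol=1e-9, atol=1e-9, equal_nan=True)
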