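"""Allele indicator, residual model, contrasts, classification, cytonuclear scan."""

import math

import numpy as np
import pandas as pd
import pytest

from hapbdm.genotyping import MarkerPanel
from hapbdm.inference import (
    PairContrast,
    ResidualRecord,
    allele_indicator,
    build_residual_dataset,
    classification_summary,
    classify_pairs,
    cytonuclear_scan,
    fit_additive_model,
    fit_residual_model,
    interaction_test,
    omnibus_interaction,
    pairwise_contrasts,
)

from .conftest import make_table


class TestAlleleIndicator:
    residuals = {"A": {"I": 2.0, "II": -2.0}, "B": {"I": -1.0, "II": 1.0}}

    @pytest.mark.parametrize(
        "haplotype, expected",
        [("I.I", 1.0), ("I.II", 3.0), ("II.I", -3.0), ("II.II", -1.0)],
    )
    def test_sum_of_locus_residuals(self, haplotype, expected):
        assert allele_indicator(("A", "B"), haplotype, self.residuals) == expected

    def test_zero_residuals_give_zero_indicator(self):
        zeros = {"A": {"I": 0.0, "II": 0.0}, "B": {"I": 0.0, "II": 0.0}}
        assert all(allele_indicator(("A", "B"), h, zeros) == 0.0 for h in ("I.I", "I.II", "II.I", "II.II"))


def _records(per_pair, indicator=0.0):
    """Build records from {pair: {haplotype: residual}}."""
    out = []
    for pair, haps in per_pair.items():
        for hap, value in haps.items():
            cls = "parental" if hap in ("I.I", "II.II") else "recombinant"
            ind = indicator(pair, hap) if callable(indicator) else indicator
            out.append(ResidualRecord(pair=pair, haplotype=hap, hap_class=cls, residual=value, indicator=ind))
    return out


def _all_pairs(markers="ABCDEFGH"):
    ms = list(markers)
    return [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]


class TestResidualDataset:
    def test_complete_design_yields_4_per_pair(self, complete_groups, panel):
        recs = build_residual_dataset(
            complete_groups[("viable", "I")], complete_groups[("inviable", "I")], panel
        )
        assert len(recs) == 112  # 28 pairs x 4 haplotypes
        assert all(r.hap_class == ("parental" if r.haplotype in ("I.I", "II.II") else "recombinant") for r in recs)

    def test_zero_expected_cell_omitted(self):
        # haplotype II.I never occurs in either group -> its column total is 0,
        # the expected count is 0 and the record is dropped
        viable = make_table(
            [("v1", "viable", "I", "I", "I"), ("v2", "viable", "I", "I", "II"), ("v3", "viable", "I", "II", "II")]
        )
        inviable = make_table(
            [("i1", "inviable", "I", "I", "I"), ("i2", "inviable", "I", "I", "II"), ("i3", "inviable", "I", "II", "II")]
        )
        panel = MarkerPanel(markers=("A", "B"))
        recs = build_residual_dataset(viable, inviable, panel)
        assert len(recs) == 3
        assert {r.haplotype for r in recs} == {"I.I", "I.II", "II.II"}

    def test_single_marker_rejected(self):
        t = make_table([("s1", "viable", "I", "I")], markers=("A",))
        with pytest.raises(ValueError):
            build_residual_dataset(t, t, MarkerPanel(markers=("A",)))


class TestModelFit:
    def test_df_accounting_complete_and_one_omission(self, complete_groups, panel):
        recs = build_residual_dataset(
            complete_groups[("viable", "I")], complete_groups[("inviable", "I")], panel
        )
        fit = fit_residual_model(recs)
        assert (fit.n, fit.rank, fit.df_resid) == (112, 57, 55)
        fit54 = fit_residual_model(recs[:-1])  # one haplotype cell inestimable
        assert (fit54.n, fit54.df_resid) == (111, 54)

    def test_zero_response_gives_zero_fit(self):
        recs = _records({p: {h: 0.0 for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()})
        fit = fit_residual_model(recs)
        assert fit.rss == 0.0
        assert np.allclose(fit.coef, 0.0)

    def test_interaction_f_zero_when_reduced_equals_full(self):
        rng = np.random.default_rng(1)
        recs = _records(
            {p: {h: float(rng.normal()) for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()},
            indicator=lambda p, h: float(rng.normal()),
        )
        fit = fit_residual_model(recs)
        test = interaction_test(fit, fit)
        assert test.f_statistic == 0.0 and test.p_value == 1.0

    def test_linear_in_indicator_means_no_interaction(self):
        # residuals an exact linear function of the indicator: the indicator
        # term absorbs everything, contrasts are 0 and the interaction F is 0
        rng = np.random.default_rng(2)
        inds = {}

        def ind(p, h):
            key = (p, h)
            if key not in inds:
                inds[key] = float(rng.normal())
            return inds[key]

        recs = _records(
            {p: {h: 2.0 * ind(p, h) for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()},
            indicator=ind,
        )
        test = omnibus_interaction(recs)
        assert test.f_statistic == pytest.approx(0.0, abs=1e-8)
        contrasts = pairwise_contrasts(fit_residual_model(recs), adjust="none")
        assert all(abs(c.estimate) < 1e-8 for c in contrasts)

    def test_saturated_full_model_reports_infinite_f(self):
        # 2 records per cell but identical within cells except one pair's class
        # split; with zero noise the full model is exact while the reduced is not
        per_pair = {p: {h: 0.0 for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()}
        per_pair[("A", "B")] = {"I.I": 2.0, "II.II": 2.0, "I.II": -2.0, "II.I": -2.0}
        recs = _records(per_pair)
        test = interaction_test(fit_residual_model(recs), fit_additive_model(recs))
        assert math.isinf(test.f_statistic)


class TestContrasts:
    def test_no_class_difference_gives_zero_estimates_and_p_one(self):
        recs = _records({p: {"I.I": 1.0, "II.II": 1.0, "I.II": 1.0, "II.I": 1.0} for p in _all_pairs()})
        contrasts = pairwise_contrasts(fit_residual_model(recs), adjust="none")
        assert all(c.estimate == pytest.approx(0.0, abs=1e-10) for c in contrasts)
        assert all(c.p_value == 1.0 for c in contrasts)

    def test_injected_split_has_estimate_four(self):
        per_pair = {p: {h: 0.0 for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()}
        per_pair[("C", "F")] = {"I.I": 2.0, "II.II": 2.0, "I.II": -2.0, "II.I": -2.0}
        contrasts = {c.pair: c for c in pairwise_contrasts(fit_residual_model(_records(per_pair)), adjust="none")}
        assert contrasts[("C", "F")].estimate == pytest.approx(4.0)
        assert contrasts[("A", "B")].estimate == pytest.approx(0.0, abs=1e-10)

    def test_missing_class_reported_undefined(self):
        per_pair = {p: {h: 0.1 for h in ("I.I", "I.II", "II.I", "II.II")} for p in _all_pairs()}
        per_pair[("A", "B")] = {"I.I": 0.5, "II.II": -0.5}  # no recombinant records
        contrasts = {c.pair: c for c in pairwise_contrasts(fit_residual_model(_records(per_pair)))}
        assert math.isnan(contrasts[("A", "B")].estimate)

    def test_holm_adjustment_attached(self, complete_groups, panel):
        recs = build_residual_dataset(
            complete_groups[("viable", "I")], complete_groups[("inviable", "I")], panel
        )
        adjusted = pairwise_contrasts(fit_residual_model(recs), adjust="holm")
        raw = pairwise_contrasts(fit_residual_model(recs), adjust="none")
        assert all(a.p_adjusted >= r.p_value - 1e-15 for a, r in zip(adjusted, raw))


class TestClassification:
    @pytest.mark.parametrize(
        "estimate, p, expected",
        [(1.2, 0.01, "BDM"), (-0.8, 0.30, "none"), (-0.8, 0.01, "heterosis"), (0.5, 0.06, "none")],
    )
    def test_rule(self, estimate, p, expected):
        c = PairContrast(("A", "B"), estimate, 1.0, estimate, 10, p)
        assert classify_pairs([c])[0].label == expected

    def test_antisymmetry_under_residual_negation(self, study_groups, panel):
        # negating the viable-row residuals (= swapping the group roles)
        # swaps BDM and heterosis labels exactly
        recs = build_residual_dataset(study_groups[("viable", "I")], study_groups[("inviable", "I")], panel)
        flipped = [
            ResidualRecord(r.pair, r.haplotype, r.hap_class, -r.residual, -r.indicator) for r in recs
        ]
        labels = [c.label for c in classify_pairs(pairwise_contrasts(fit_residual_model(recs)))]
        labels_flipped = [c.label for c in classify_pairs(pairwise_contrasts(fit_residual_model(flipped)))]
        swap = {"BDM": "heterosis", "heterosis": "BDM", "none": "none"}
        assert labels_flipped == [swap[l] for l in labels]

    def test_summary_counts_partition_pairs(self, study_groups, panel):
        recs = build_residual_dataset(study_groups[("viable", "I")], study_groups[("inviable", "I")], panel)
        cls = classify_pairs(pairwise_contrasts(fit_residual_model(recs)))
        assert sum(classification_summary(cls).values()) == 28


class TestCytonuclearScan:
    @staticmethod
    def _balanced_group(pheno, cyto, n=10, markers=("A", "B")):
        rows = []
        for i in range(n):
            rows.append((f"{cyto}{i}", pheno, cyto) + tuple("I" if i < n // 2 else "II" for _ in markers))
        return make_table(rows, markers=markers)

    def test_identical_frequencies_not_flagged(self):
        g1 = self._balanced_group("viable", "I")
        g2 = self._balanced_group("viable", "II")
        scan = cytonuclear_scan(g1, g2, MarkerPanel(markers=("A", "B")))
        assert (scan.table["p_value"] == 1.0).all()
        assert not scan.table["significant"].any()

    def test_injected_locus_flagged_after_holm(self):
        markers = tuple("ABCDEFGH")

        # locus F all-I in group 1, all-II in group 2; every other locus 5/5
        def group(label, cyto, f_allele):
            rows = []
            for i in range(10):
                calls = tuple(f_allele if m == "F" else ("I" if i < 5 else "II") for m in markers)
                rows.append((f"{label}{i}", "viable", cyto) + calls)
            return make_table(rows, markers=markers)

        scan = cytonuclear_scan(group("a", "I", "I"), group("b", "II", "II"), MarkerPanel(markers=markers))
        assert scan.table.loc["F", "p_value"] == pytest.approx(2 / 184756, rel=1e-6)
        assert scan.table.loc["F", "significant"]
        assert not scan.table.drop("F")["significant"].any()
        assert scan.table.loc["F", "direction"] == "more I in viable I"

    def test_zero_call_group_reported_undefined(self):
        g1 = self._balanced_group("viable", "I")
        g2 = self._balanced_group("viable", "II")
        g2["A"] = np.nan
        scan = cytonuclear_scan(g1, g2, MarkerPanel(markers=("A", "B")))
        assert math.isnan(scan.table.loc["A", "p_value"])
        assert not scan.table.loc["A", "significant"]
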