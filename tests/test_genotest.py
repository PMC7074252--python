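"""Exact association tests against rational-arithmetic enumeration
oracles, plus the multi-breed genotype tabulation."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eclemap import genotest
from eclemap.genio import ValidationError, make_sample_table
from eclemap.genotest import (
    GenotypeCountTable,
    fisher_exact_2x2,
    tabulate_genotypes,
)
from eclemap.genotest import test_variant as run_variant_test
from oracles import fisher_2x3_oracle, fisher_oracle

# Genotype counts of the published-style association cohort: 544 genotyped
# German Shorthaired Pointers (24 cases, 520 controls), plus the related
# breeds, at the candidate missense variant.  hom-ref / het / hom-alt.
STUDY_COUNTS = [
    ("German Shorthaired Pointer", "case", 1, 0, 23),
    ("German Shorthaired Pointer", "control", 457, 63, 0),
    ("German Longhaired Pointer", "control", 50, 2, 0),
    ("German Wirehaired Pointer", "control", 210, 0, 0),
    ("Braque du Bourbonnais", "control", 7, 0, 0),
    ("Vizsla", "case", 0, 0, 1),
    ("Vizsla", "control", 51, 5, 0),
]


def study_table() -> GenotypeCountTable:
    df = pd.DataFrame(
        [
            {
                "breed": b,
                "phenotype": p,
                "n_hom_ref": hr,
                "n_het": het,
                "n_hom_alt": ha,
                "n_missing": 0,
                "n": hr + het + ha,
            }
            for b, p, hr, het, ha in STUDY_COUNTS
        ]
    )
    return GenotypeCountTable(df)


class TestFisherExact2x2:
    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_2x2(0, 7, 0, 13) == 1.0

    def test_small_table_matches_enumeration(self):
        got = fisher_exact_2x2(2, 3, 1, 4)
        assert got == pytest.approx(float(fisher_oracle(2, 3, 1, 4)), rel=1e-9)

    def test_study_scale_p_value(self):
        """Recessive collapse of the study's 544-dog cohort: hom-alt 23/1
        in cases vs 0/520 in controls rounds to p = 1.2e-39."""
        p = fisher_exact_2x2(23, 1, 0, 520)
        assert f"{p:.1e}" == "1.2e-39"

    def test_random_small_tables_match_enumeration(self):
        """A seeded sample of 2x2 tables (totals <= 60) agrees with the
        exact enumeration oracle; the exhaustive sweep lives in the
        acceptance suite."""
        rng = np.random.default_rng(99)
        for _ in range(800):
            n = int(rng.integers(1, 61))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            got = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            want = float(fisher_oracle(int(a), int(b), int(c), int(d)))
            assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_agrees_with_scipy_at_extreme_magnitudes(self):
        got = fisher_exact_2x2(23, 1, 0, 520)
        want = stats.fisher_exact([[23, 1], [0, 520]])[1]
        assert got == pytest.approx(want, rel=1e-6)

    def test_symmetry_under_row_and_column_swaps(self):
        for a, b, c, d in [(2, 3, 1, 4), (23, 1, 0, 520), (5, 0, 0, 5)]:
            p = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_one_sided_options(self):
        assert fisher_exact_2x2(5, 0, 0, 5, "greater") == pytest.approx(
            float(Fraction(1, math.comb(10, 5)))
        )
        assert fisher_exact_2x2(0, 5, 5, 0, "less") == pytest.approx(
            float(Fraction(1, math.comb(10, 5)))
        )


class TestTabulateGenotypes:
    def test_one_of_each_genotype_aggregates(self):
        samples = make_sample_table(
            ["a", "b", "c"], ["B"] * 3, ["control"] * 3
        )
        t = tabulate_genotypes(
            np.array([0, 1, 2], dtype=np.int8), ["a", "b", "c"], samples
        )
        row = t.counts.iloc[0]
        assert (
            row["n_hom_ref"],
            row["n_het"],
            row["n_hom_alt"],
            row["n"],
        ) == (1, 1, 1, 3)

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(20)]
        samples = make_sample_table(
            ids,
            ["B1"] * 10 + ["B2"] * 10,
            ["case"] * 5 + ["control"] * 15,
        )
        calls = rng.integers(-1, 3, size=20).astype(np.int8)
        base = tabulate_genotypes(calls, ids, samples).counts
        perm = rng.permutation(20)
        again = tabulate_genotypes(
            calls[perm], [ids[i] for i in perm], samples
        ).counts
        pd.testing.assert_frame_equal(base, again)

    def test_missing_calls_excluded_from_n(self):
        samples = make_sample_table(["a", "b"], ["B"] * 2, ["control"] * 2)
        t = tabulate_genotypes(
            np.array([-1, 2], dtype=np.int8), ["a", "b"], samples
        )
        row = t.counts.iloc[0]
        assert row["n"] == 1 and row["n_missing"] == 1

    def test_call_without_metadata_rejected(self):
        samples = make_sample_table(["a"], ["B"], ["control"])
        with pytest.raises(ValidationError):
            tabulate_genotypes(
                np.array([0, 1], dtype=np.int8), ["a", "ghost"], samples
            )

    def test_study_shaped_table_layout(self, tmp_path):
        """A 544+301-dog fixture shaped like the published genotype table
        round-trips through the report writer with its layout intact."""
        from eclemap import genio

        table = study_table()
        genio.write_report(table, tmp_path / "t2.tsv")
        back = genio.read_report(tmp_path / "t2.tsv")
        assert list(back.columns) == [
            "breed",
            "phenotype",
            "n_hom_ref",
            "n_het",
            "n_hom_alt",
            "n_missing",
            "n",
        ]
        assert len(back) == 7
        gsp = back[
            (back.breed == "German Shorthaired Pointer")
            & (back.phenotype == "case")
        ].iloc[0]
        assert (gsp.n_hom_alt, gsp.n_hom_ref, gsp.n) == (23, 1, 24)


class TestTestVariant:
    def test_equal_counts_give_one_under_every_coding(self):
        df = pd.DataFrame(
            [
                {
                    "breed": "B",
                    "phenotype": p,
                    "n_hom_ref": 4,
                    "n_het": 4,
                    "n_hom_alt": 4,
                    "n_missing": 0,
                    "n": 12,
                }
                for p in ("case", "control")
            ]
        )
        t = GenotypeCountTable(df)
        for coding in ("recessive", "dominant", "allelic", "genotypic"):
            assert run_variant_test(t, coding).p_value == pytest.approx(1.0)

    def test_recessive_on_study_pointer_counts(self):
        res = run_variant_test(
            study_table(),
            coding="recessive",
            breeds=["German Shorthaired Pointer"],
        )
        assert res.table.tolist() == [[23, 1], [0, 520]]
        assert f"{res.p_value:.1e}" == "1.2e-39"
        assert res.odds_ratio_corrected  # zero cell -> Haldane correction

    def test_genotypic_exact_matches_full_enumeration(self):
        t23 = np.array([[6, 3, 1], [2, 5, 8]])
        df = pd.DataFrame(
            [
                {
                    "breed": "B",
                    "phenotype": "case",
                    "n_hom_ref": 1,
                    "n_het": 3,
                    "n_hom_alt": 6,
                    "n_missing": 0,
                    "n": 10,
                },
                {
                    "breed": "B",
                    "phenotype": "control",
                    "n_hom_ref": 8,
                    "n_het": 5,
                    "n_hom_alt": 2,
                    "n_missing": 0,
                    "n": 15,
                },
            ]
        )
        res = run_variant_test(GenotypeCountTable(df), coding="genotypic")
        assert res.p_value == pytest.approx(
            float(fisher_2x3_oracle(t23)), rel=1e-9
        )

    def test_single_case_breed_never_tested_alone(self):
        with pytest.raises(ValidationError, match="margin"):
            run_variant_test(study_table(), breeds=["Vizsla"])

    def test_log_space_stability_under_row_reordering(self):
        p1 = fisher_exact_2x2(23, 1, 0, 520)
        p2 = fisher_exact_2x2(0, 520, 23, 1)
        assert p1 > 0 and np.isfinite(p1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_unknown_breed_rejected(self):
        with pytest.raises(ValidationError):
            run_variant_test(study_table(), breeds=["Beagle"])


class TestFisherProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        st.integers(0, 40),
        st.integers(0, 40),
        st.integers(0, 40),
        st.integers(0, 40),
    )
    def test_probability_mass_rule_properties(self, a, b, c, d):
        """For any table: p in (0, 1], invariant under transposition, and
        equal to the exact enumeration oracle."""
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(a, b, c, d)
        assert 0 < p <= 1
        assert fisher_exact_2x2(a, c, b, d) == pytest.approx(p, rel=1e-9)
        assert p == pytest.approx(
            float(fisher_oracle(a, b, c, d)), rel=1e-7, abs=1e-12
        )
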