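"""Context classification, catalog building, and exposure refitting:
hand-classified bins, degenerate and simulated-recovery fits, greedy vs
exhaustive subset search, and the cohort-level selection rule.
"""

import numpy as np
import pandas as pd
import pytest

from cdkres.signatures import (
    CONTEXT_LABELS,
    build_catalog,
    classify_context,
    fit_cohort,
    fit_exposures,
    select_cohort_signatures,
    synthetic_reference_signatures,
    validate_signatures,
)
from cdkres.simulate import catalog_to_variants, simulate_mutations

from oracles import exhaustive_best_subset, nnls_normalized_sse


class TestClassifyContext:
    def test_pyrimidine_reference_direct(self):
        assert CONTEXT_LABELS[classify_context("C", "A", "A", "G")] == "A[C>A]G"

    def test_purine_reference_reverse_complemented(self):
        # G>T with 5'=C, 3'=T is C>A with 5'=A, 3'=G on the pyrimidine strand
        assert CONTEXT_LABELS[classify_context("G", "T", "C", "T")] == "A[C>A]G"

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            classify_context("C", "C", "A", "A")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_context("C", "A", "N", "G")

    def test_all_96_bins_reachable(self):
        hit = set()
        for ref in "CT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for f in "ACGT":
                    for t in "ACGT":
                        hit.add(classify_context(ref, alt, f, t))
        assert hit == set(range(96))


class TestBuildCatalog:
    def test_empty_variants(self):
        df = pd.DataFrame(
            columns=["sample", "ref", "alt", "context_5p", "context_3p"]
        ).astype(str)
        df["sample"] = pd.Series(dtype=str)
        cat = build_catalog(df.assign(sample=pd.Series(dtype=str)))
        assert cat.shape == (96, 0)

    def test_sum_conservation(self, refs):
        cat = simulate_mutations(pd.Series({"S1": 1.0}), 100, refs, seed=0)
        variants = catalog_to_variants(cat, sample="A")
        rebuilt = build_catalog(variants)
        assert int(rebuilt["A"].sum()) == 100
        assert rebuilt["A"].tolist() == cat.tolist()

    def test_hand_built_bins(self):
        rows = [
            ("C", "T", "A", "A", "A[C>T]A"),
            ("G", "A", "T", "T", "A[C>T]A"),   # revcomp of the first
            ("T", "G", "C", "C", "C[T>G]C"),
            ("A", "C", "G", "G", "C[T>G]C"),   # revcomp of the third
            ("C", "G", "T", "G", "T[C>G]G"),
        ]
        df = pd.DataFrame(
            [
                {
                    "sample": "A", "ref": r, "alt": a,
                    "context_5p": f, "context_3p": t,
                }
                for r, a, f, t, _ in rows
            ]
        )
        cat = build_catalog(df)["A"]
        assert cat["A[C>T]A"] == 2
        assert cat["C[T>G]C"] == 2
        assert cat["T[C>G]G"] == 1
        assert cat.sum() == 5

    def test_indels_skipped(self):
        df = pd.DataFrame(
            [
                {"sample": "A", "ref": "C", "alt": "T", "context_5p": "A", "context_3p": "A"},
                {"sample": "A", "ref": "CT", "alt": "C", "context_5p": "A", "context_3p": "A"},
            ]
        )
        assert int(build_catalog(df)["A"].sum()) == 1


class TestFitExposures:
    def test_single_signature_exact(self, refs):
        catalog = pd.Series(np.round(refs["S5"].to_numpy() * 1e6), index=CONTEXT_LABELS)
        fit = fit_exposures(catalog, refs)
        assert fit.weights["S5"] == pytest.approx(1.0)
        assert fit.residual < 1e-9

    def test_two_signature_recovery(self, refs):
        cat = simulate_mutations(pd.Series({"S1": 0.6, "S13": 0.4}), 10_000, refs, seed=7)
        fit = fit_exposures(cat, refs)
        assert fit.weights["S1"] == pytest.approx(0.6, abs=0.05)
        assert fit.weights["S13"] == pytest.approx(0.4, abs=0.05)

    def test_small_weight_zeroed_by_cutoff(self, refs):
        mix = pd.Series({"S1": 0.57, "S13": 0.40, "S7": 0.03})
        cat = simulate_mutations(mix, 50_000, refs, seed=3)
        fit = fit_exposures(cat, refs, weight_cutoff=0.06)
        assert fit.weights["S7"] == 0.0
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_min_mutation_guard(self, refs):
        catalog = pd.Series(0, index=CONTEXT_LABELS)
        catalog.iloc[0] = 5
        with pytest.raises(ValueError, match="at least 10"):
            fit_exposures(catalog, refs)

    def test_scale_invariance(self, refs):
        cat = simulate_mutations(pd.Series({"S2": 0.5, "S9": 0.5}), 1000, refs, seed=5)
        f1 = fit_exposures(cat, refs)
        f2 = fit_exposures(cat * 7, refs)
        assert np.allclose(f1.weights, f2.weights)

    def test_greedy_sse_close_to_exhaustive(self, refs4):
        rng = np.random.default_rng(21)
        for _ in range(5):
            k = int(rng.integers(1, 4))
            names = list(rng.choice(refs4.columns, size=k, replace=False))
            w = rng.dirichlet(np.ones(k))
            mix = pd.Series(w, index=names)
            cat = simulate_mutations(mix, 5000, refs4, seed=int(rng.integers(2**31 - 1)))
            frac = cat.to_numpy(float) / cat.sum()
            fit = fit_exposures(cat, refs4, weight_cutoff=0.0)
            sse_best, best_subset = exhaustive_best_subset(frac, refs4)
            assert fit.residual <= sse_best * 1.05 + 1e-12
            selected = set(fit.nonzero().index)
            if selected == set(best_subset):
                _, sse_same = nnls_normalized_sse(
                    frac, refs4[list(fit.nonzero().index)].to_numpy(float)
                )
                assert fit.residual == pytest.approx(sse_same, abs=1e-12)

    def test_forward_selection_error_nonincreasing(self, refs):
        # the final residual never exceeds the best single-signature residual
        cat = simulate_mutations(
            pd.Series({"S3": 0.5, "S8": 0.3, "S21": 0.2}), 20_000, refs, seed=9
        )
        frac = cat.to_numpy(float) / cat.sum()
        singles = [
            nnls_normalized_sse(frac, refs[[c]].to_numpy(float))[1] for c in refs.columns
        ]
        fit = fit_exposures(cat, refs, weight_cutoff=0.0)
        assert fit.residual <= min(singles) + 1e-12


class TestCohortSelection:
    def test_rule_boundaries(self):
        exp = pd.DataFrame(
            {
                "S1": [0.25, 0.25, 0.25],     # >0.2 in 3 samples -> selected
                "S2": [0.25, 0.25, 0.0],      # in exactly 2 -> not selected
                "S3": [0.15, 0.15, 0.15],     # never above threshold
                "residual": [0.01, 0.01, 0.01],
            },
            index=["a", "b", "c"],
        )
        assert select_cohort_signatures(exp) == ["S1"]

    def test_threshold_strictness(self):
        exp = pd.DataFrame({"S1": [0.2, 0.2, 0.2, 0.2]})
        assert select_cohort_signatures(exp) == []


class TestReferenceValidation:
    def test_synthetic_matrix_valid(self, refs):
        validate_signatures(refs)
        assert refs.shape == (96, 30)

    def test_bad_columns_rejected(self, refs):
        bad = refs.copy()
        bad["S1"] = bad["S1"] * 2
        with pytest.raises(ValueError, match="sum to 1"):
            validate_signatures(bad)


def test_cohort_fit_shapes(refs):
    cats = pd.DataFrame(
        {
            "a": simulate_mutations(pd.Series({"S1": 1.0}), 500, refs, seed=1),
            "b": simulate_mutations(pd.Series({"S3": 1.0}), 500, refs, seed=2),
        }
    )
    out = fit_cohort(cats, refs)
    assert list(out.index) == ["a", "b"]
    assert out.loc["a", "S1"] > 0.9
    assert out.loc["b", "S3"] > 0.9


def test_simulate_mutations_contracts(refs):
    with pytest.raises(ValueError):
        simulate_mutations(pd.Series({"S1": 0.5}), 100, refs, seed=0)
    with pytest.raises(ValueError):
        simulate_mutations(pd.Series({"S1": 1.0}), 0, refs, seed=0)
    cat = simulate_mutations(pd.Series({"S1": 1.0}), 1000, refs, seed=0)
    assert int(cat.sum()) == 1000


class TestContextRenormalization:
    def test_uniform_weights_change_nothing(self, refs):
        from cdkres.signatures import CONTEXT_LABELS, trinucleotide_of
        cat = simulate_mutations(pd.Series({"S1": 0.6, "S13": 0.4}), 5000, refs, seed=2)
        tris = sorted({trinucleotide_of(lab) for lab in CONTEXT_LABELS})
        w = pd.Series(2.0, index=tris)  # uniform scaling cancels in the fractions
        a = fit_exposures(cat, refs)
        b = fit_exposures(cat, refs, context_weights=w)
        assert np.allclose(a.weights, b.weights)

    def test_incomplete_table_rejected(self, refs):
        cat = simulate_mutations(pd.Series({"S1": 1.0}), 1000, refs, seed=0)
        with pytest.raises(ValueError, match="32 trinucleotides"):
            fit_exposures(cat, refs, context_weights=pd.Series({"ACA": 1.0}))

    def test_equivalent_to_manually_scaled_catalog(self, refs):
        from cdkres.signatures import CONTEXT_LABELS, trinucleotide_of
        cat = simulate_mutations(pd.Series({"S2": 0.5, "S9": 0.5}), 4000, refs, seed=6)
        tris = sorted({trinucleotide_of(lab) for lab in CONTEXT_LABELS})
        rng = np.random.default_rng(0)
        w = pd.Series(rng.uniform(0.5, 2.0, size=len(tris)), index=tris)
        via_option = fit_exposures(cat, refs, context_weights=w)
        scaled = cat.astype(float) * cat.index.map(lambda lab: w[trinucleotide_of(lab)])
        via_scaling = fit_exposures(scaled, refs)
        assert np.allclose(via_option.weights, via_scaling.weights)
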