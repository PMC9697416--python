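"""Genotype QC pipeline: filters, segregation test, window correction,
bin projection, numeric coding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxemap import genotypes as gt
from gxemap import simulate as sim
from oracles import marker_filter_oracle, window_correct_oracle


def _geno_from_calls(calls, chrom=None, pos=None, families=None, parents=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({
        "marker": [f"m{k}" for k in range(m)],
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
    })
    return gt.GenotypeMatrix(
        lines=[f"L{i}" for i in range(n)],
        families=np.array(families if families is not None else ["fam"] * n),
        markers=markers,
        calls=calls,
        parents=parents or {},
    )


class TestFilterVariants:
    def test_maf_thresholds_boundary_kept(self):
        # MAF {0.00, 0.04, 0.05, 0.30, 0.50} over 100 lines, no missing/het
        n = 100
        cols = []
        for maf in (0.0, 0.04, 0.05, 0.30, 0.50):
            k = int(round(maf * n))
            cols.append(np.array([gt.HOM_ALT] * k + [gt.HOM_REF] * (n - k)))
        geno = _geno_from_calls(np.column_stack(cols))
        out = gt.filter_variants(geno)
        assert list(out.markers["marker"]) == ["m2", "m3", "m4"]

    def test_missing_over_threshold_removed(self):
        n = 100
        col = np.full(n, gt.HOM_REF)
        col[:31] = gt.MISSING
        col2 = np.array([gt.HOM_ALT] * 50 + [gt.HOM_REF] * 50)
        geno = _geno_from_calls(np.column_stack([col, col2]))
        out = gt.filter_variants(geno, maf_min=0.0)
        assert list(out.markers["marker"]) == ["m1"]

    def test_random_matrix_matches_oracle(self):
        rng = np.random.default_rng(21)
        calls = rng.choice([-1, 0, 1, 2], size=(200, 500), p=[0.1, 0.4, 0.1, 0.4])
        geno = _geno_from_calls(calls)
        out = gt.filter_variants(geno)
        keep = marker_filter_oracle(calls, 0.05, 0.3, 0.3)
        assert list(out.markers["marker"]) == [f"m{k}" for k in np.flatnonzero(keep)]


class TestSegregationFilter:
    @staticmethod
    def _family(counts_p1, counts_p2, cross="F1DH"):
        n = counts_p1 + counts_p2
        col = np.array([gt.HOM_REF] * counts_p1 + [gt.HOM_ALT] * counts_p2)
        parents = {"fam": {"P1": np.array([gt.HOM_REF], dtype=np.int8),
                           "P2": np.array([gt.HOM_ALT], dtype=np.int8)}}
        geno = _geno_from_calls(col[:, None], families=["fam"] * n, parents=parents)
        return geno, {"fam": cross}

    def test_distorted_f1dh_removed(self):
        geno, crosses = self._family(70, 30)
        # closed-form oracle: chi2 = (70-50)^2/50 + (30-50)^2/50 = 16
        assert stats.chi2.sf(16.0, 1) < 0.005
        out = gt.segregation_filter(geno, crosses)
        assert out.n_markers == 0

    def test_exact_bc1dh_ratio_retained(self):
        geno, crosses = self._family(75, 25, cross="BC1DH")
        out = gt.segregation_filter(geno, crosses)
        assert out.n_markers == 1

    def test_balanced_f1dh_retained(self):
        geno, crosses = self._family(50, 50)
        assert gt.segregation_filter(geno, crosses).n_markers == 1

    def test_small_family_skipped_not_tested(self):
        geno, crosses = self._family(5, 0)  # wildly distorted but < 10 calls
        assert gt.segregation_filter(geno, crosses).n_markers == 1


def _origin_to_calls(origin, p1, p2):
    calls = np.where(origin == 0, p1, p2).astype(np.int8)
    calls[origin == 2] = gt.HET
    calls[origin == -1] = gt.MISSING
    return calls


def _family_geno_from_origin(origin_rows):
    origin = np.asarray(origin_rows, dtype=np.int8)
    n, m = origin.shape
    p1 = np.full(m, gt.HOM_REF, dtype=np.int8)
    p2 = np.full(m, gt.HOM_ALT, dtype=np.int8)
    calls = np.vstack([_origin_to_calls(origin[i], p1, p2) for i in range(n)])
    return _geno_from_calls(
        calls, families=["fam"] * n,
        parents={"fam": {"P1": p1, "P2": p2}},
    )


class TestWindowCorrect:
    def test_twelve_three_window_corrected_to_p1(self):
        origin = np.array([[0] * 6 + [1, 0, 1, 0, 1] + [0] * 4])
        geno = _family_geno_from_origin(origin)
        corrected, _ = gt.window_correct(geno, window=15)
        assert (corrected.calls == gt.HOM_REF).all()

    def test_eight_seven_window_left_alone(self):
        origin = np.array([[0, 1] * 7 + [0]])  # 8 P1, 7 P2 everywhere
        geno = _family_geno_from_origin(origin)
        corrected, _ = gt.window_correct(geno, window=15)
        assert (corrected.calls == geno.calls).all()

    def test_clean_crossover_single_breakpoint(self):
        origin = np.array([[0] * 60 + [1] * 60])
        geno = _family_geno_from_origin(origin)
        corrected, bins = gt.window_correct(geno, window=15)
        assert (corrected.calls == geno.calls).all()
        b = bins.bins
        assert len(b) == 2
        pos = geno.markers["pos"].to_numpy()
        assert b.iloc[0]["parent"] == "P1" and b.iloc[1]["parent"] == "P2"
        # breakpoint between the flanking markers
        assert pos[59] <= b.iloc[0]["end"] <= pos[60]

    def test_matches_bruteforce_oracle_bit_exact(self):
        rng = np.random.default_rng(31)
        for rep in range(5):
            true = np.zeros(400, dtype=np.int8)
            for bp in np.sort(rng.choice(np.arange(20, 380), 3, replace=False)):
                true[bp:] = 1 - true[bp:]
            noisy = true.copy()
            flip = rng.random(400) < 0.05
            noisy[flip] = 1 - noisy[flip]
            noisy[rng.random(400) < 0.05] = -1
            geno = _family_geno_from_origin(noisy[None, :])
            corrected, _ = gt.window_correct(geno, window=15)
            expected_origin, _ = window_correct_oracle(noisy, 15)
            got_origin = corrected.to_origin("fam")[0]
            assert (got_origin == expected_origin).all(), f"rep {rep}"

    def test_idempotent(self):
        rng = np.random.default_rng(32)
        true = np.zeros(300, dtype=np.int8)
        true[150:] = 1
        noisy = true.copy()
        noisy[rng.random(300) < 0.04] = 1
        geno = _family_geno_from_origin(noisy[None, :])
        once, bins1 = gt.window_correct(geno, window=15)
        twice, bins2 = gt.window_correct(once, window=15)
        assert (once.calls == twice.calls).all()
        pd.testing.assert_frame_equal(bins1.bins, bins2.bins)

    def test_error_free_input_unchanged(self, gmap):
        # exact equality holds on lines whose true segments are all at least
        # one window long; shorter true segments are beyond the method's
        # resolution by construction
        spec = sim.FamilySpec("F", "a", "b", "F1DH", 15)
        fam = sim.simulate_dh_family(spec, gmap, seed=44)
        corrected, _ = gt.window_correct(fam, window=15)
        chroms = fam.markers["chrom"].to_numpy()
        eligible = 0
        for i in range(fam.n_lines):
            min_seg = min(
                np.diff(np.r_[0, np.flatnonzero(np.diff(fam.origins[i][chroms == c])) + 1,
                              (chroms == c).sum()]).min()
                for c in dict.fromkeys(chroms)
            )
            if min_seg >= 15:
                eligible += 1
                assert (corrected.calls[i] == fam.calls[i]).all()
        assert eligible >= 8

    def test_small_chromosome_single_window_warning(self):
        origin = np.array([[0] * 8])
        geno = _family_geno_from_origin(origin)
        with pytest.warns(UserWarning, match="single window"):
            gt.window_correct(geno, window=15)

    def test_multifamily_input_rejected(self, population):
        with pytest.raises(ValueError, match="single-family"):
            gt.window_correct(population)


class TestBinsAndProjection:
    def test_projection_fills_bin_with_parent_allele(self):
        origin = np.array([[0] * 20])
        # monomorphic at markers 5..9 (both parents alt)
        p1 = np.full(20, gt.HOM_REF, dtype=np.int8)
        p2 = np.full(20, gt.HOM_ALT, dtype=np.int8)
        p1[5:10] = gt.HOM_ALT
        calls = _origin_to_calls(origin[0], p1, p2)[None, :]
        calls[0, 3] = gt.MISSING
        geno = _geno_from_calls(calls, families=["fam"],
                                parents={"fam": {"P1": p1, "P2": p2}})
        _, bins = gt.window_correct(geno, window=15)
        merged = gt.build_bins_and_project({"fam": bins}, {"fam": geno})
        # all markers polymorphic except 5..9 within the single family; the
        # union keeps polymorphic ones and projection fills the missing call
        assert merged.n_markers == 15
        assert (merged.calls == gt.HOM_REF).all()

    def test_monomorphic_family_recovers_shared_allele(self):
        # family A monomorphic (both parents alt) at marker 0, family B polymorphic
        pA1 = np.array([2, 0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        pA2 = np.array([2, 2, 2, 2, 2, 2, 2, 2, 2, 2], dtype=np.int8)
        pB1 = np.zeros(10, dtype=np.int8)
        pB2 = np.full(10, 2, dtype=np.int8)
        callsA = np.tile(pA1, (3, 1))
        callsB = np.tile(pB1, (3, 1))
        genoA = _geno_from_calls(callsA, families=["A"] * 3,
                                 parents={"A": {"P1": pA1, "P2": pA2}})
        genoB = _geno_from_calls(callsB, families=["B"] * 3,
                                 parents={"B": {"P1": pB1, "P2": pB2}})
        _, binsA = gt.window_correct(genoA, window=15)
        _, binsB = gt.window_correct(genoB, window=15)
        merged = gt.build_bins_and_project({"A": binsA, "B": binsB},
                                           {"A": genoA, "B": genoB})
        assert merged.n_markers == 10  # union of polymorphic loci
        col0 = merged.calls[:, 0]
        famA = merged.families == "A"
        assert (col0[famA] == gt.HOM_ALT).all()  # shared parental allele

    def test_projection_preserves_breakpoint_count(self, gmap):
        spec = sim.FamilySpec("F", "a", "b", "F1DH", 10)
        fam = sim.simulate_dh_family(spec, gmap, seed=50)
        _, bins_before = gt.window_correct(fam, window=15)
        merged = gt.build_bins_and_project({"F": bins_before}, {"F": fam})
        _, bins_after = gt.window_correct(merged, window=15)
        assert bins_before.n_breakpoints() == bins_after.n_breakpoints()


class TestEncodeNumeric:
    def test_major_allele_plus_one(self):
        col = np.array([gt.HOM_REF] * 140 + [gt.HOM_ALT] * 60)
        geno = _geno_from_calls(col[:, None])
        out = gt.encode_numeric(geno)
        assert (out.numeric[:140, 0] == 1.0).all()
        assert (out.numeric[140:, 0] == -1.0).all()

    def test_column_mean_is_one_minus_two_maf(self):
        col = np.array([gt.HOM_REF] * 150 + [gt.HOM_ALT] * 50)  # MAF 0.25
        geno = _geno_from_calls(col[:, None])
        out = gt.encode_numeric(geno)
        assert out.numeric[:, 0].mean() == pytest.approx(0.5)

    def test_tie_breaks_to_reference_allele(self):
        col = np.array([gt.HOM_REF] * 50 + [gt.HOM_ALT] * 50)
        out = gt.encode_numeric(_geno_from_calls(col[:, None]))
        assert (out.numeric[:50, 0] == 1.0).all()

    def test_missing_requires_flag(self):
        col = np.array([gt.HOM_REF, gt.MISSING, gt.HOM_ALT, gt.HOM_REF])
        geno = _geno_from_calls(col[:, None])
        with pytest.raises(ValueError, match="missing"):
            gt.encode_numeric(geno)
        out = gt.encode_numeric(geno, mean_fill=True)
        assert np.isfinite(out.numeric).all()


class TestAuxiliarySteps:
    def test_het_to_missing(self):
        col = np.array([gt.HOM_REF, gt.HET, gt.HOM_ALT])
        out = gt.set_het_missing(_geno_from_calls(col[:, None]))
        assert out.calls[1, 0] == gt.MISSING

    def test_mq_prefilter(self):
        calls = np.zeros((4, 3), dtype=np.int8)
        geno = _geno_from_calls(calls)
        geno.markers["mq"] = [60.0, 4.9, 5.0]
        out = gt.filter_by_mq(geno, min_mq=5.0)
        assert list(out.markers["marker"]) == ["m0", "m2"]
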