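"""CSP computation, classification, region segmentation, relaxation fitting."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parvmap.nmr_csp import (
    CSPRecord,
    CSPStatus,
    EpitopeSet,
    RegionScheme,
    ShiftTable,
    classify_perturbed,
    compute_csp,
    fit_exponential,
    fit_relaxation,
    read_shift_table,
    relaxation_records,
    segment_regions,
)

from conftest import make_shift_table


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadShiftTable:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "shifts.tsv"
        p.write_text("residue\taa\tdH\tdN\n1\tA\t8.1\t110.2\n2\tG\t8.5\t109.0\n3\tK\t7.9\t121.5\n")
        table = read_shift_table(p, "free")
        assert len(table.data) == 3
        assert table.shift(2) == (8.5, 109.0)

    def test_duplicate_residue_is_hard_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("residue\taa\tdH\tdN\n42\tA\t8.1\t110.2\n42\tG\t8.5\t109.0\n")
        with pytest.raises(ValueError, match="duplicate residue 42"):
            read_shift_table(p, "free")

    def test_blank_cell_row_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "blank.tsv"
        p.write_text("residue\taa\tdH\tdN\n1\tA\t8.1\t110.2\n2\tG\t\t109.0\n3\tK\t7.9\t121.5\n")
        with caplog.at_level("WARNING"):
            table = read_shift_table(p, "free")
        assert len(table.data) == 2
        assert list(table.residues) == [1, 3]
        assert any("dropping row" in r.message for r in caplog.records)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("residue\taa\tdH\tdN\n")
        with pytest.raises(ValueError):
            read_shift_table(p, "free")


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

class TestComputeCSP:
    def test_formula_and_statuses(self, free_bound_pair):
        free, bound = free_bound_pair
        records = {r.residue_number: r for r in compute_csp(free, bound)}
        assert records[1].csp == pytest.approx(0.0)
        # ΔδH = 0.10, ΔδN = 0.50 -> 0.10 + 0.1*0.50 = 0.15 ppm
        assert records[2].csp == pytest.approx(0.15)
        assert records[3].status is CSPStatus.DISAPPEARED
        assert records[3].csp is None

    def test_missing_in_free_and_both(self):
        free = make_shift_table("free", [(1, "A", 8.0, 110.0)])
        bound = make_shift_table("bound", [(1, "A", 8.0, 110.0), (2, "G", 8.2, 112.0)])
        records = {r.residue_number: r for r in compute_csp(free, bound, n_residues=3)}
        assert records[2].status is CSPStatus.MISSING_IN_FREE
        assert records[3].status is CSPStatus.MISSING_IN_BOTH

    def test_negative_weight_rejected(self, free_bound_pair):
        with pytest.raises(ValueError):
            compute_csp(*free_bound_pair, nitrogen_weight=-0.1)

    def test_self_comparison_yields_no_epitope(self, free_bound_pair):
        free, _ = free_bound_pair
        records = compute_csp(free, free)
        epitope, disappeared = classify_perturbed(records)
        assert epitope is None and disappeared == []

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(-1, 1, allow_nan=False),
        dn=st.floats(-5, 5, allow_nan=False),
    )
    def test_sign_flip_invariance(self, dh, dn):
        """CSP depends only on |ΔδH| and |ΔδN|."""
        free = make_shift_table("free", [(1, "A", 8.0, 110.0)])
        plus = make_shift_table("b", [(1, "A", 8.0 + dh, 110.0 + dn)])
        minus = make_shift_table("b", [(1, "A", 8.0 - dh, 110.0 - dn)])
        csp_plus = compute_csp(free, plus)[0].csp
        csp_minus = compute_csp(free, minus)[0].csp
        assert csp_plus == pytest.approx(csp_minus, abs=1e-12)
        assert csp_plus == pytest.approx(abs(dh) + 0.1 * abs(dn), abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(0, 1), dn=st.floats(0, 5),
        extra_h=st.floats(0, 1), extra_n=st.floats(0, 5),
    )
    def test_monotonic_in_shift_magnitudes(self, dh, dn, extra_h, extra_n):
        free = make_shift_table("free", [(1, "A", 8.0, 110.0)])
        small = make_shift_table("b", [(1, "A", 8.0 + dh, 110.0 + dn)])
        large = make_shift_table("b", [(1, "A", 8.0 + dh + extra_h, 110.0 + dn + extra_n)])
        assert compute_csp(free, large)[0].csp >= compute_csp(free, small)[0].csp - 1e-12


class TestClassifyPerturbed:
    def _records(self, csps: dict[int, float]) -> list[CSPRecord]:
        return [CSPRecord(r, v, CSPStatus.MEASURED) for r, v in csps.items()]

    def test_threshold_is_strict(self):
        records = self._records({1: 0.028, 2: 0.03, 3: 0.0279999})
        epitope, _ = classify_perturbed(records, threshold=0.028)
        assert epitope.residues == {2}

    def test_planted_set_matches_brute_force_filter(self, rng):
        csps = {r: (0.05 if r in {3, 9, 17} else 0.0) for r in range(1, 30)}
        records = self._records(csps)
        epitope, _ = classify_perturbed(records)
        brute = {r for r, v in csps.items() if v > 0.028}
        assert epitope.residues == brute == {3, 9, 17}

    def test_disappeared_not_merged(self):
        records = self._records({1: 0.5}) + [CSPRecord(7, None, CSPStatus.DISAPPEARED)]
        epitope, disappeared = classify_perturbed(records)
        assert epitope.residues == {1}
        assert disappeared == [7]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            classify_perturbed(self._records({1: 0.1}), threshold=0.0)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

class TestRegions:
    def test_counts_and_unassigned(self):
        scheme = RegionScheme(regions={"n_term": (1, 15), "c_term": (95, 109)})
        epitope = EpitopeSet("e", "csp", frozenset({2, 3, 100}))
        counts, unassigned = segment_regions(epitope, scheme)
        assert counts == {"n_term": 2, "c_term": 1}
        assert unassigned == []

    def test_uncovered_residue_listed(self):
        scheme = RegionScheme(regions={"n_term": (1, 15)})
        epitope = EpitopeSet("e", "csp", frozenset({50}))
        counts, unassigned = segment_regions(epitope, scheme)
        assert counts == {"n_term": 0} and unassigned == [50]

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionScheme(regions={"a": (1, 10), "b": (10, 20)})

    def test_region_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            RegionScheme(regions={"a": (1, 200)}, sequence_length=109)

    @settings(derandomize=True, max_examples=30)
    @given(residues=st.sets(st.integers(1, 120), min_size=1, max_size=40))
    def test_counts_plus_unassigned_partition_epitope(self, residues):
        scheme = RegionScheme()
        epitope = EpitopeSet("e", "csp", frozenset(residues))
        counts, unassigned = segment_regions(epitope, scheme)
        assert sum(counts.values()) + len(unassigned) == len(residues)


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

def grid_search_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: scan R over (0, 20] at step 1e-3; for each R the
    optimal amplitude is the closed-form least-squares solution."""
    best_r, best_sse = None, np.inf
    for r in np.arange(1e-3, 20.0 + 1e-9, 1e-3):
        basis = np.exp(-r * t)
        a = float(y @ basis / (basis @ basis))
        sse = float(np.sum((a * basis - y) ** 2))
        if sse < best_sse:
            best_r, best_sse = r, sse
    return best_r


class TestRelaxationFit:
    def test_noiseless_exact(self):
        t = np.arange(0, 0.6, 0.1)
        y = 100.0 * np.exp(-2.0 * t)
        fit = fit_exponential(t, y)
        assert fit.converged
        assert fit.rate == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)

    def test_noisy_matches_grid_search_oracle(self, rng):
        t = np.array([0.004, 0.01, 0.017, 0.026, 0.036, 0.05, 0.07, 0.095])
        true_rate = 12.5
        y = 100.0 * np.exp(-true_rate * t) + rng.normal(0, 1.0, len(t))
        fit = fit_exponential(t, y)
        oracle = grid_search_rate(t, y)
        assert fit.rate == pytest.approx(oracle, abs=2e-3)
        assert fit.rate == pytest.approx(true_rate, rel=0.05)

    def test_requires_three_points_and_positive(self):
        with pytest.raises(ValueError):
            fit_exponential([0.0, 0.1], [100.0, 80.0])
        with pytest.raises(ValueError):
            fit_exponential([0.0, 0.1, 0.2], [100.0, -5.0, 60.0])

    def test_fit_relaxation_dataframe_and_ratio(self):
        t = np.arange(0.05, 0.5, 0.05)
        rows = []
        for res, rate in [(1, 1.0), (2, 2.0)]:
            for d in t:
                rows.append({"residue": res, "delay_s": d,
                             "intensity": 100.0 * math.exp(-rate * d)})
        df = pd.DataFrame(rows)
        r1 = fit_relaxation(df, "R1")
        assert list(r1["residue"]) == [1, 2]
        assert r1["R1"].to_numpy() == pytest.approx([1.0, 2.0], rel=1e-6)

        rows2 = [{"residue": 1, "delay_s": d, "intensity": 100.0 * math.exp(-10.0 * d)}
                 for d in t]
        r2 = fit_relaxation(pd.DataFrame(rows2), "R2")
        recs = relaxation_records(r1, r2)
        assert len(recs) == 1
        assert recs[0].ratio_R2_over_R1 == pytest.approx(10.0, rel=1e-6)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            fit_relaxation({}, "R3")


# ---------------------------------------------------------------------------
# domain-type invariants
# ---------------------------------------------------------------------------

class TestDomainTypes:
    def test_shift_table_requires_increasing_residues(self):
        with pytest.raises(ValueError):
            make_shift_table("x", [(2, "A", 8.0, 110.0), (1, "G", 8.1, 111.0)])

    def test_csp_record_consistency(self):
        with pytest.raises(ValueError):
            CSPRecord(1, 0.1, CSPStatus.DISAPPEARED)
        with pytest.raises(ValueError):
            CSPRecord(1, None, CSPStatus.MEASURED)

    def test_epitope_set_validation(self):
        with pytest.raises(ValueError):
            EpitopeSet("e", "csp", frozenset())
        with pytest.raises(ValueError):
            EpitopeSet("e", "wetlab", frozenset({1}))
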