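"""Generator determinism and recoverability of the planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from parvmap.conservation import conservation_symbols
from parvmap.docking import contact_frequency, contact_residues
from parvmap.nmr_csp import classify_perturbed, compute_csp, fit_relaxation
from parvmap.simulate import (
    DEFAULT_PLANTED_EPITOPE,
    SimulationConfig,
    TruthManifest,
    cdr_definition,
    simulate_alignment,
    simulate_decay_curves,
    simulate_pose_ensemble,
    simulate_shift_tables,
    write_bundle,
)

SMALL = dict(n_poses=30)


class TestConfigValidation:
    def test_planted_residue_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SimulationConfig(n_residues=50)  # default epitope reaches residue 108

    def test_effect_must_exceed_noise(self):
        with pytest.raises(ValueError, match="recoverable"):
            SimulationConfig(csp_effect=0.005, csp_noise_sigma=0.002)

    def test_default_epitope_region_breakdown(self):
        """The default planted epitope reproduces the 5 / 16 / 5 / 3 breakdown
        (N-terminus / CD-loop proximal / around 80 / C-terminus)."""
        from parvmap.nmr_csp import RegionScheme, EpitopeSet, segment_regions

        epitope = EpitopeSet("planted", "csp", DEFAULT_PLANTED_EPITOPE)
        counts, unassigned = segment_regions(epitope, RegionScheme())
        assert counts["n_terminus"] == 5
        assert counts["ab_cd_axis"] + counts["cd_site"] == 16
        assert counts["around_80"] == 5
        assert counts["c_terminus"] == 3
        assert unassigned == []
        assert len(DEFAULT_PLANTED_EPITOPE) == 29


class TestShiftTables:
    def test_noiseless_perturbs_exactly_planted(self):
        config = SimulationConfig(
            seed=5, planted_epitope=frozenset({10, 20}),
            csp_noise_sigma=0.0, csp_effect=0.05, **SMALL,
        )
        free, points, _ = simulate_shift_tables(config)
        records = compute_csp(free, points[-1].shift_table)
        nonzero = {r.residue_number for r in records if r.csp and r.csp > 1e-12}
        assert nonzero == {10, 20}

    def test_same_seed_identical_tables(self):
        a = simulate_shift_tables(SimulationConfig(seed=7, **SMALL))
        b = simulate_shift_tables(SimulationConfig(seed=7, **SMALL))
        assert a[0].data.equals(b[0].data)
        for pa, pb in zip(a[1], b[1]):
            assert pa.shift_table.data.equals(pb.shift_table.data)

    def test_disappeared_rows_dropped(self):
        config = SimulationConfig(seed=5, disappeared=frozenset({33, 36}), **SMALL)
        free, points, manifest = simulate_shift_tables(config)
        records = compute_csp(free, points[-1].shift_table)
        _, disappeared = classify_perturbed(records)
        assert disappeared == [33, 36] == manifest.disappeared

    def test_recovery_over_many_seeds(self):
        """Gaussian noise at sigma = 0.002 ppm against a 0.05 ppm effect and a
        0.028 ppm threshold: the planted set is recovered exactly, every seed."""
        failures = 0
        for seed in range(100):
            config = SimulationConfig(seed=seed, **SMALL)
            free, points, manifest = simulate_shift_tables(config)
            records = compute_csp(free, points[-1].shift_table)
            epitope, _ = classify_perturbed(records)
            if epitope is None or epitope.sorted() != manifest.planted_epitope:
                failures += 1
        assert failures == 0

    def test_csp_nondecreasing_across_titration(self):
        """Fast-exchange generator: bound fraction grows with concentration,
        so per-residue CSP is non-decreasing across titration points."""
        config = SimulationConfig(seed=11, csp_noise_sigma=0.0, **SMALL)
        free, points, _ = simulate_shift_tables(config)
        previous = None
        for point in points:
            csps = {
                r.residue_number: r.csp
                for r in compute_csp(free, point.shift_table)
                if r.csp is not None
            }
            if previous is not None:
                assert all(csps[r] >= previous[r] - 1e-12 for r in previous)
            previous = csps


class TestPoseEnsemble:
    def test_extremes_give_binary_frequencies(self):
        config = SimulationConfig(
            seed=3, n_poses=10, p_contact_in=1.0, p_contact_out=0.0
        )
        poses, _, _ = simulate_pose_ensemble(config)
        profile = contact_frequency(poses, cdr_definition())
        for residue in range(1, config.n_residues + 1):
            expected = 1.0 if residue in config.planted_epitope else 0.0
            assert profile.frequency_of(residue) == pytest.approx(expected)

    def test_manifest_matches_contact_residues_on_every_pose(self):
        config = SimulationConfig(seed=9, n_poses=50)
        poses, _, manifest = simulate_pose_ensemble(config)
        cdr = cdr_definition()
        for pose in poses:
            assert contact_residues(pose, cdr) == set(manifest.pose_contacts[pose.pose_id])

    def test_score_filtering_enriches_planted_contacts(self):
        config = SimulationConfig(seed=13, n_poses=200)
        poses, _, _ = simulate_pose_ensemble(config)
        cdr = cdr_definition()
        unfiltered = contact_frequency(poses, cdr)
        filtered = contact_frequency(poses, cdr, score_top_fraction=0.1)
        planted = sorted(config.planted_epitope)
        mean_unf = np.mean([unfiltered.frequency_of(r) for r in planted])
        mean_fil = np.mean([filtered.frequency_of(r) for r in planted])
        assert mean_fil > mean_unf

    def test_same_seed_identical_ensembles(self):
        a_poses, a_scores, _ = simulate_pose_ensemble(SimulationConfig(seed=21, n_poses=5))
        b_poses, b_scores, _ = simulate_pose_ensemble(SimulationConfig(seed=21, n_poses=5))
        assert a_scores == b_scores
        for pa, pb in zip(a_poses, b_poses):
            for ra, rb in zip(pa.structure.chain("B"), pb.structure.chain("B")):
                assert [a.coords for a in ra.atoms] == [a.coords for a in rb.atoms]


class TestAlignment:
    def test_zero_substitution_rate_all_identical(self):
        config = SimulationConfig(seed=2, substitution_rate=0.0, gap_rate=0.0, **SMALL)
        aln, _ = simulate_alignment(config)
        assert set(conservation_symbols(aln)) == {"*"}

    def test_planted_columns_invariant(self):
        config = SimulationConfig(seed=4, substitution_rate=0.3, **SMALL)
        aln, manifest = simulate_alignment(config)
        symbols = conservation_symbols(aln)
        assert all(symbols[c - 1] == "*" for c in manifest.conserved_columns)

    def test_conservation_enriched_inside_planted_columns(self):
        """Over seeds, '*' columns are rarer outside the planted set than inside."""
        for seed in range(20):
            config = SimulationConfig(
                seed=seed, substitution_rate=0.3, n_sequences=5, **SMALL
            )
            aln, manifest = simulate_alignment(config)
            symbols = conservation_symbols(aln)
            inside = [symbols[c - 1] == "*" for c in manifest.conserved_columns]
            outside = [
                symbols[c] == "*"
                for c in range(config.n_residues)
                if (c + 1) not in set(manifest.conserved_columns)
            ]
            assert np.mean(outside) < np.mean(inside)


class TestDecays:
    def test_noiseless_recovery_to_1e6(self):
        config = SimulationConfig(seed=6, decay_noise_frac=0.0, **SMALL)
        datasets, manifest = simulate_decay_curves(config)
        fits = fit_relaxation(datasets["free_R2"], "R2")
        for _, row in fits.iterrows():
            true = manifest.relaxation_rates["free"][int(row["residue"])]["R2"]
            assert row["R2"] == pytest.approx(true, rel=1e-6)

    def test_complex_ratio_exceeds_free(self):
        config = SimulationConfig(seed=8, **SMALL)
        datasets, manifest = simulate_decay_curves(config)
        ratios = {}
        for state in ("free", "complex"):
            r1 = fit_relaxation(datasets[f"{state}_R1"], "R1").set_index("residue")["R1"]
            r2 = fit_relaxation(datasets[f"{state}_R2"], "R2").set_index("residue")["R2"]
            ratios[state] = (r2 / r1).mean()
        assert ratios["complex"] > ratios["free"]

    def test_median_error_under_noise(self):
        """1% intensity noise: median relative R2 error stays below 3%."""
        errors = []
        for seed in range(20):
            config = SimulationConfig(seed=seed, n_residues=50, decay_noise_frac=0.01,
                                      planted_epitope=frozenset({5, 10}), **SMALL)
            datasets, manifest = simulate_decay_curves(config)
            fits = fit_relaxation(datasets["free_R2"], "R2")
            for _, row in fits.iterrows():
                true = manifest.relaxation_rates["free"][int(row["residue"])]["R2"]
                errors.append(abs(row["R2"] - true) / true)
        assert np.median(errors) < 0.03


class TestBundle:
    def test_bundle_files_and_manifest_round_trip(self, tmp_path):
        config = SimulationConfig(seed=10, n_poses=8)
        out = write_bundle(config, tmp_path / "bundle")
        expected = {"free.tsv", "bound_40uM.tsv", "bound_70uM.tsv", "antigen.pdb",
                    "poses.pdb", "scores.tsv", "family.afa", "truth.json",
                    "pipeline.yaml"}
        assert expected <= {p.name for p in out.iterdir()}
        manifest = TruthManifest.from_json(out / "truth.json")
        assert manifest.planted_epitope == sorted(config.planted_epitope)
        assert len(manifest.pose_contacts) == 8

    def test_bundle_byte_identical_across_reruns(self, tmp_path):
        config = SimulationConfig(seed=10, n_poses=5)
        out1 = write_bundle(config, tmp_path / "b1")
        out2 = write_bundle(config, tmp_path / "b2")
        for p1 in sorted(out1.iterdir()):
            assert p1.read_bytes() == (out2 / p1.name).read_bytes(), p1.name
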