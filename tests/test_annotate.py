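"""Cluster detection, ppm matching, quantification and peak-list IO."""

import numpy as np
import pytest

from rnacad.annotate import (
    PeakList,
    annotate_spectrum,
    charge_summed,
    detect_clusters,
    match_fragments,
    quantify,
    read_peaklist,
)
from rnacad.fragments import FragmentSpecies, enumerate_fragments, make_fragment
from rnacad.synth import generate_spectrum, noiseless, scenario_presets


class TestPeakListIO:
    def test_sorted_and_validated(self):
        peaklist = PeakList([1100.0, 1000.0], [1.0, 2.0], {"pH": 6.8})
        assert peaklist.mz.tolist() == [1000.0, 1100.0]
        assert peaklist.intensity.tolist() == [2.0, 1.0]
        with pytest.raises(ValueError):
            PeakList([1.0], [-5.0])

    def test_text_round_trip(self, tmp_path):
        original = PeakList(
            [500.25, 800.5],
            [10.0, 20.0],
            {"precursor_charge": 4, "collision_energy_eV": 42.0, "pH": 6.8, "scans": 200},
        )
        path = tmp_path / "peaks.txt"
        original.write_text(path)
        loaded = read_peaklist(path)
        assert np.allclose(loaded.mz, original.mz)
        assert np.allclose(loaded.intensity, original.intensity)
        assert loaded.metadata["precursor_charge"] == 4
        assert loaded.metadata["pH"] == pytest.approx(6.8)

    def test_csv_form_and_comments(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("# pH: 3.0\n1000.0,5.0\n1001.0,6.0\n")
        loaded = read_peaklist(path)
        assert len(loaded) == 2
        assert loaded.metadata["pH"] == pytest.approx(3.0)


class TestDetection:
    def test_two_peaks_half_neutron_apart_read_charge_two(self):
        peaklist = PeakList([1000.0, 1000.50168], [100.0, 90.0])
        clusters = detect_clusters(peaklist, (1, 2, 3))
        assert len(clusters) == 1
        assert clusters[0].charge == 2
        assert clusters[0].mono_mz == pytest.approx(1000.0)
        assert clusters[0].intensity == pytest.approx(190.0)

    def test_isolated_peak_is_charge_undetermined(self):
        peaklist = PeakList([1000.0, 1500.0], [100.0, 50.0])
        clusters = detect_clusters(peaklist, (1, 2))
        assert len(clusters) == 2
        assert all(c.charge is None for c in clusters)

    def test_full_envelope_beats_its_sub_runs(self):
        """A 3+ envelope also lines up at charge 1 on every third peak;
        the full run must win and claim all members."""
        mono = 1200.0
        mz = [mono + k * 1.0033548 / 3 for k in range(9)]
        peaklist = PeakList(mz, np.full(9, 10.0))
        clusters = detect_clusters(peaklist, (1, 2, 3))
        assert len(clusters) == 1
        assert clusters[0].charge == 3

    def test_upward_intensity_jump_breaks_chain(self):
        """A weak stray peak one spacing below a strong monoisotopic peak
        must not swallow the envelope."""
        mz = [999.49832, 1000.0, 1000.50168, 1001.00336]
        peaklist = PeakList(mz, [0.5, 1000.0, 900.0, 500.0])
        clusters = detect_clusters(peaklist, (2,))
        by_mono = {round(c.mono_mz, 3): c for c in clusters}
        assert by_mono[1000.0].charge == 2
        assert len(by_mono[1000.0].indices) == 3

    def test_empty_peaklist(self):
        assert detect_clusters(PeakList([], []), (1, 2)) == []


class TestMatching:
    def test_exact_fragment_match(self, rna1):
        frag = make_fragment(rna1, "y", 8, charge=2)
        theory = enumerate_fragments(rna1, ("c", "y"), charge_range=(1, 2, 3))
        peaklist = PeakList(
            [frag.mz, frag.mz + 1.0033548 / 2], [100.0, 80.0]
        )
        clusters = detect_clusters(peaklist, (1, 2, 3))
        assignments = match_fragments(clusters, theory, ppm_tolerance=5.0)
        assert len(assignments) == 1
        assert assignments[0].fragment.key() == frag.key()
        assert assignments[0].ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_decoy_shift_kills_all_matches(self, rna1):
        theory = enumerate_fragments(rna1, ("c", "y"), charge_range=(1, 2, 3))
        shifted = [
            FragmentSpecies(
                sp.series, sp.site, sp.losses, sp.charge,
                sp.neutral_mass + 0.5 * sp.charge, sp.mz + 0.5, sp.composition,
            )
            for sp in theory
        ]
        peaklist, _ = generate_spectrum(noiseless(scenario_presets("RNA1", seed=2)))
        clusters = detect_clusters(peaklist, (1, 2, 3))
        assert match_fragments(clusters, shifted, ppm_tolerance=5.0) == []

    def test_tie_breaks_toward_fewer_losses(self):
        comp = None
        lean = FragmentSpecies("c", 5, (), 1, 999.0, 1000.0, comp)
        lossy = FragmentSpecies("c", 3, ("H2O",), 1, 999.0, 1000.0, comp)
        peaklist = PeakList([1000.0], [10.0])
        clusters = detect_clusters(peaklist, (1,))
        assignments = match_fragments(clusters, [lossy, lean], ppm_tolerance=5.0)
        assert len(assignments) == 1
        assert assignments[0].fragment is lean

    def test_duplicate_theoretical_rejected(self, rna1):
        frag = make_fragment(rna1, "c", 3, charge=1)
        with pytest.raises(ValueError, match="duplicates"):
            match_fragments([], [frag, frag])

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_fragments([], [], ppm_tolerance=-1.0)

    def test_shuffled_decoy_false_discovery_below_one_percent(self, rna1):
        """Random m/z values must almost never match the fragment space."""
        rng = np.random.default_rng(42)
        peaklist, _ = generate_spectrum(noiseless(scenario_presets("RNA1", seed=3)))
        decoy = PeakList(
            np.sort(rng.uniform(peaklist.mz.min(), peaklist.mz.max(), len(peaklist))),
            np.ones(len(peaklist)),
        )
        theory = enumerate_fragments(rna1, ("c", "y"), charge_range=(1, 2, 3))
        clusters = detect_clusters(decoy, (1, 2, 3))
        assignments = match_fragments(clusters, theory, ppm_tolerance=5.0)
        assert len(assignments) / len(clusters) <= 0.01


class TestQuantify:
    def test_single_assignment_recovers_cluster_intensity(self, rna1):
        """A clean complete cluster of total intensity 100 quantifies as
        abundance 100 (the envelope fit coincides with the member sum)."""
        from rnacad.isotopes import cluster_mz_grid, isotope_pattern

        frag = make_fragment(rna1, "y", 8, charge=2)
        grid = cluster_mz_grid(
            isotope_pattern(frag.composition), frag.neutral_mass, frag.charge
        )
        peaklist = PeakList([m for m, _ in grid], [100.0 * a for _, a in grid])
        annotated = annotate_spectrum(peaklist, [frag])
        assert annotated.abundances["abundance"].sum() == pytest.approx(100.0)
        cluster_sum = annotated.assignments[0].cluster.intensity
        assert cluster_sum == pytest.approx(100.0)

    def test_charge_summed_mean(self):
        table = quantify([])
        assert len(table) == 0
        import pandas as pd

        table = pd.DataFrame(
            {
                "series": ["y", "y"],
                "site": [8, 8],
                "losses": ["-", "-"],
                "charge": [2, 3],
                "abundance": [60.0, 40.0],
                "mz": [1.0, 1.0],
                "ppm_error": [0.0, 0.0],
                "score": [1.0, 1.0],
                "low_confidence": [False, False],
            }
        )
        summed = charge_summed(table)
        assert summed.loc[0, "abundance"] == pytest.approx(100.0)
        assert summed.loc[0, "mean_charge"] == pytest.approx(2.4)


class TestEndToEnd:
    def test_noiseless_round_trip_is_complete(self):
        scenario = noiseless(scenario_presets("RNA1", seed=5))
        peaklist, truth = generate_spectrum(scenario)
        theory = enumerate_fragments(scenario.sequence, charge_range=range(1, 4))
        annotated = annotate_spectrum(peaklist, theory)
        planted = set(
            map(tuple, truth.species[["series", "site", "losses", "charge"]].itertuples(index=False))
        )
        found = set(
            map(tuple, annotated.abundances[["series", "site", "losses", "charge"]].itertuples(index=False))
        )
        assert planted == found

    def test_jittered_spectrum_recall(self):
        scenario = scenario_presets("RNA1", seed=6)
        peaklist, truth = generate_spectrum(scenario)
        theory = enumerate_fragments(scenario.sequence, charge_range=range(1, 4))
        annotated = annotate_spectrum(peaklist, theory, ppm_tolerance=5.0)
        planted = set(
            map(tuple, truth.species[["series", "site", "losses", "charge"]].itertuples(index=False))
        )
        found = set(
            map(tuple, annotated.abundances[["series", "site", "losses", "charge"]].itertuples(index=False))
        )
        assert len(planted & found) / len(planted) >= 0.99
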