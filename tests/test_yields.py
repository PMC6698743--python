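"""Yield statistics: profiles, cross-RNA correlation, groups, charges."""

import numpy as np
import pandas as pd
import pytest

from rnacad.yields import (
    DEFAULT_GROUPS,
    DEFAULT_RATIOS,
    average_charge,
    compare_rnas,
    grouped_yields,
    site_yield_profile,
)


def abundance_table(rows):
    """Build an abundance table like annotate.quantify produces.

    Rows are (series, site, losses, charge, abundance); remember that y
    fragments are indexed by length, so y at cleavage site i is (y, 15-i).
    """
    frame = pd.DataFrame(
        rows, columns=["series", "site", "losses", "charge", "abundance"]
    )
    frame["mz"] = 0.0
    frame["ppm_error"] = 0.0
    frame["score"] = 1.0
    frame["low_confidence"] = False
    return frame


def uniform_table(value=1.0):
    rows = []
    for site in range(1, 15):
        rows.append(("c", site, "-", 2, value))
        rows.append(("y", 15 - site, "-", 2, value))
    return abundance_table(rows)


class TestSiteYieldProfile:
    def test_uniform_spectrum_gives_equal_yields(self):
        profile = site_yield_profile(uniform_table(), 14)
        assert np.allclose(profile.combined, 1.0 / 14)
        assert np.allclose(profile.c, profile.y)

    def test_profile_sums_to_one(self):
        rows = [("c", 7, "-", 2, 50.0), ("y", 8, "H2O", 2, 30.0), ("y", 1, "-", 1, 20.0)]
        profile = site_yield_profile(abundance_table(rows), 14)
        assert profile.combined.sum() == pytest.approx(1.0, abs=1e-9)

    def test_losses_count_toward_their_site(self):
        rows = [
            ("c", 7, "-", 2, 60.0),
            ("c", 7, "base:G", 2, 20.0),
            ("y", 8, "H2O", 2, 20.0),  # y8 also breaks site 7
        ]
        profile = site_yield_profile(abundance_table(rows), 14)
        assert profile.combined[6] == pytest.approx(1.0)

    def test_precursor_species_excluded(self):
        rows = [("c", 7, "-", 2, 50.0), ("y", 8, "-", 2, 50.0)]
        table = pd.concat(
            [
                abundance_table(rows),
                abundance_table([("precursor", None, "base:G", 3, 1000.0)]),
            ]
        )
        profile = site_yield_profile(table, 14)
        assert profile.total_intensity == pytest.approx(100.0)

    def test_zero_backbone_signal_raises(self):
        with pytest.raises(ValueError):
            site_yield_profile(abundance_table([]), 14)


class TestCompareRnas:
    def test_identical_tables(self):
        table = uniform_table(100.0)
        result = compare_rnas(table, table.copy())
        assert result.pearson == pytest.approx(1.0)
        assert result.outliers == []
        assert result.effect_factor == 1.0

    def test_global_scaling_has_no_outliers(self):
        reference = uniform_table(100.0)
        rng = np.random.default_rng(0)
        reference["abundance"] *= rng.uniform(0.5, 2.0, len(reference))
        variant = reference.copy()
        variant["abundance"] *= 0.5
        result = compare_rnas(reference, variant)
        assert result.slope == pytest.approx(0.5, abs=1e-9)
        assert result.pearson == pytest.approx(1.0, abs=1e-12)
        assert result.outliers == []

    def test_sevenfold_suppression_detected(self):
        """Dividing the site-7 pair (c7 and y8) by 7 marks exactly those
        species as outliers with effect factor 7."""
        rng = np.random.default_rng(1)
        reference = uniform_table(100.0)
        reference["abundance"] *= rng.uniform(0.8, 1.2, len(reference))
        variant = reference.copy()
        mask = ((variant["series"] == "c") & (variant["site"] == 7)) | (
            (variant["series"] == "y") & (variant["site"] == 8)
        )
        variant.loc[mask, "abundance"] /= 7.0
        result = compare_rnas(reference, variant)
        outlier_sites = {(series, site) for series, site, _, _ in result.outliers}
        assert outlier_sites == {("c", 7), ("y", 8)}
        assert result.effect_factor == pytest.approx(7.0, rel=0.05)

    def test_base_loss_identity_collapses_for_pairing(self):
        reference = abundance_table(
            [("c", 7, "-", 2, 90.0), ("y", 8, "base:A", 2, 50.0), ("y", 1, "-", 1, 10.0)]
        )
        variant = abundance_table(
            [("c", 7, "-", 2, 88.0), ("y", 8, "base:c3A", 2, 49.0), ("y", 1, "-", 1, 11.0)]
        )
        result = compare_rnas(reference, variant)
        assert len(result.pairs) == 3  # the shifted base loss still pairs

    def test_too_few_pairs(self):
        table = abundance_table([("c", 1, "-", 1, 10.0), ("y", 1, "-", 1, 10.0)])
        with pytest.raises(ValueError, match="paired species"):
            compare_rnas(table, table.copy())

    def test_swap_inverts_slope_and_effect(self):
        rng = np.random.default_rng(2)
        reference = uniform_table(100.0)
        reference["abundance"] *= rng.uniform(0.8, 1.2, len(reference))
        variant = reference.copy()
        mask = (variant["series"] == "c") & (variant["site"] == 7)
        variant.loc[mask, "abundance"] /= 7.0
        forward = compare_rnas(reference, variant)
        backward = compare_rnas(variant, reference)
        assert forward.effect_factor * backward.effect_factor == pytest.approx(1.0, rel=1e-6)
        assert forward.slope * backward.slope == pytest.approx(1.0, rel=1e-6)


class TestGroupedYields:
    def test_uniform_two_group_ratio(self):
        profile = site_yield_profile(uniform_table(), 14)
        stats = grouped_yields(
            profile,
            {"head": (1, 2), "rest": tuple(range(3, 15))},
            {"head/rest": (("head",), ("rest",))},
        )
        assert stats.ratios["head/rest"] == pytest.approx((2 / 14) / (12 / 14))

    def test_group_sums_total_one(self):
        profile = site_yield_profile(uniform_table(), 14)
        stats = grouped_yields(profile, DEFAULT_GROUPS, DEFAULT_RATIOS)
        assert sum(stats.sums.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "groups",
        [
            {"a": (1, 2), "b": (2, 3)},  # overlap
            {"a": (1, 2, 3)},  # incomplete
            {"a": tuple(range(1, 16))},  # out of range
        ],
    )
    def test_invalid_partitions_rejected(self, groups):
        profile = site_yield_profile(uniform_table(), 14)
        with pytest.raises(ValueError, match="partition"):
            grouped_yields(profile, groups)


class TestAverageCharge:
    def test_single_charge_state(self):
        table = abundance_table([("y", 8, "-", 2, 100.0)])
        assert average_charge(table, "y").loc[8] == pytest.approx(2.0)

    def test_equal_split_between_charges(self):
        table = abundance_table([("y", 8, "-", 2, 50.0), ("y", 8, "-", 3, 50.0)])
        assert average_charge(table, "y").loc[8] == pytest.approx(2.5)

    def test_absent_series_raises(self):
        table = abundance_table([("y", 8, "-", 2, 50.0)])
        with pytest.raises(ValueError, match="not observed"):
            average_charge(table, "c")
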