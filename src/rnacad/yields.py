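"""Cleavage-yield statistics: site yields, cross-RNA correlation, groups.

The central statistic is the site-specific yield Y: for each backbone
cleavage site, the summed abundance of its c and y fragments (over all
charge states, including water- and nucleobase-loss variants) divided by
the total abundance of all backbone fragments, so that yields sum to 1.
Comparing the fragment signals of a modified RNA against an unmodified
reference on a line through the origin isolates site-specific chemistry:
species suppressed (or enhanced) well off the common trend are flagged as
outliers and their geometric-mean reference/variant ratio is the
multiplicative effect size (the "A-effect" factor for the adenine
N3-protonation mechanism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotatedSpectrum

__all__ = [
    "CleavageYieldProfile",
    "CorrelationResult",
    "GroupYieldStats",
    "average_charge",
    "compare_rnas",
    "grouped_yields",
    "site_yield_profile",
]

BACKBONE_SERIES = ("a", "b", "c", "d", "w", "x", "y", "z")


def _abundance_table(data) -> pd.DataFrame:
    """Accept an AnnotatedSpectrum or a bare abundance DataFrame."""
    if isinstance(data, AnnotatedSpectrum):
        return data.abundances
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError(f"expected AnnotatedSpectrum or DataFrame, got {type(data).__name__}")


def _backbone(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["series"].isin(BACKBONE_SERIES)]


@dataclass
class CleavageYieldProfile:
    """Per-site yields for the c series, the y series and their sum.

    Arrays are indexed site-1 for sites 1..L-1; ``combined`` sums to 1
    whenever any backbone fragment was observed.
    """

    sites: np.ndarray
    c: np.ndarray
    y: np.ndarray
    combined: np.ndarray
    total_intensity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site": self.sites, "c": self.c, "y": self.y, "combined": self.combined}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def site_yield_profile(annotated, n_sites: int) -> CleavageYieldProfile:
    """Site-specific yield profile from an annotated spectrum.

    Numerator per (site, series): summed abundance over all charge states
    including H2O/base-loss variants; denominator: total backbone-fragment
    abundance.  Precursor and precursor-loss species are excluded from
    both.  Raises on zero backbone signal.

    ``n_sites`` is L-1 for an L-mer.  5'-side fragments are indexed by
    their cleavage site directly (c_i breaks site i); 3'-side fragments
    are indexed by fragment length (y_j breaks site L-j) and are mapped
    back to cleavage sites here.
    """
    table = _backbone(_abundance_table(annotated))
    total = float(table["abundance"].sum()) if len(table) else 0.0
    if total <= 0:
        raise ValueError("no backbone-fragment intensity to normalize by")
    sites = np.arange(1, n_sites + 1)
    c = np.zeros(n_sites)
    y = np.zeros(n_sites)
    for _, row in table.iterrows():
        index = int(row["site"])
        if not 1 <= index <= n_sites:
            raise ValueError(f"fragment index {index} outside 1..{n_sites}")
        if row["series"] in ("a", "b", "c", "d"):
            c[index - 1] += row["abundance"]
        else:
            site = n_sites + 1 - index  # y_j cleaves site L-j
            y[site - 1] += row["abundance"]
    return CleavageYieldProfile(
        sites=sites, c=c / total, y=y / total, combined=(c + y) / total,
        total_intensity=total,
    )


def _loss_class(losses: str) -> str:
    """Collapse base identity so species pair across modified RNAs
    (a lost A pairs with a lost c3A at the same site)."""
    if losses == "-":
        return "-"
    parts = []
    for token in losses.split("+"):
        parts.append("base" if token.startswith("base") else token)
    return "+".join(sorted(parts))


def _keyed_abundances(data) -> pd.Series:
    table = _backbone(_abundance_table(data)).copy()
    table["loss_class"] = [_loss_class(l) for l in table["losses"]]
    return table.groupby(["series", "site", "loss_class", "charge"])["abundance"].sum()


@dataclass
class CorrelationResult:
    """Origin-anchored comparison of two fragment-abundance tables.

    ``slope`` is the fit of variant against reference signals through the
    origin on non-outlier pairs (the orientation of the scatter plots);
    ``pearson`` is computed on the same pairs.  ``outliers`` lists the
    (series, site, loss_class, charge) keys whose reference/variant ratio
    departs from the fitted trend by more than the threshold factor (in
    either direction), and ``effect_factor`` is the geometric mean of the
    outliers' reference/variant ratios relative to the fitted central
    ratio (1.0 when there are none), i.e. the factor by which the outlier
    species fall below the common trend.
    """

    pairs: pd.DataFrame
    slope: float
    pearson: float
    outliers: list
    effect_factor: float
    outlier_threshold: float


def compare_rnas(reference, variant, outlier_threshold: float = 3.0) -> CorrelationResult:
    """Correlate fragment signals of a variant RNA against a reference.

    Species pair by (series, site, loss-class, charge); the loss class
    collapses nucleobase identity so mass-shifted counterparts pair.  A
    line through the origin is fit to all pairs, pairs whose
    reference/variant ratio exceeds ``outlier_threshold`` times (or falls
    below 1/threshold of) the fitted ratio are set aside, and the fit is
    repeated once without them.
    """
    if outlier_threshold <= 1:
        raise ValueError("outlier_threshold must be > 1")
    ref = _keyed_abundances(reference)
    var = _keyed_abundances(variant)
    pairs = pd.DataFrame({"reference": ref, "variant": var}).dropna()
    pairs = pairs[(pairs["reference"] > 0) & (pairs["variant"] > 0)]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired species, got {len(pairs)}")

    x = pairs["reference"].to_numpy()
    y = pairs["variant"].to_numpy()
    ratio = x / y  # reference/variant

    def _outlier_mask(inliers: np.ndarray) -> np.ndarray:
        # Fitted central ratio from the through-origin fit of ref on var.
        a = (x[inliers] * y[inliers]).sum() / (y[inliers] ** 2).sum()
        return (ratio > outlier_threshold * a) | (ratio < a / outlier_threshold)

    out = _outlier_mask(np.ones(len(pairs), dtype=bool))
    if out.all():
        raise ValueError("all pairs flagged as outliers; comparison is meaningless")
    out = _outlier_mask(~out)  # one re-fit iteration
    if out.all():
        raise ValueError("all pairs flagged as outliers; comparison is meaningless")
    inl = ~out

    slope = float((y[inl] * x[inl]).sum() / (x[inl] ** 2).sum())
    if len(np.unique(x[inl])) > 1 and len(np.unique(y[inl])) > 1:
        pearson = float(np.corrcoef(x[inl], y[inl])[0, 1])
    else:
        pearson = 1.0
    # Effect size relative to the fitted central ratio: normalizing by the
    # inlier trend makes the factor independent of overall spectrum
    # scaling (e.g. the redistribution of normalized intensity onto other
    # sites when one site's yield collapses).
    central = float((x[inl] * y[inl]).sum() / (y[inl] ** 2).sum())
    effect = (
        float(np.exp(np.log(ratio[out] / central).mean())) if out.any() else 1.0
    )
    pairs = pairs.copy()
    pairs["ratio"] = ratio
    pairs["outlier"] = out
    return CorrelationResult(
        pairs=pairs,
        slope=slope,
        pearson=pearson,
        outliers=[tuple(k) for k in pairs.index[out]],
        effect_factor=effect,
        outlier_threshold=outlier_threshold,
    )


@dataclass
class GroupYieldStats:
    """Added yields over named site groups plus requested ratios."""

    groups: dict
    sums: dict
    ratios: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.sums),
                "sites": [",".join(map(str, self.groups[g])) for g in self.sums],
                "yield_sum": list(self.sums.values()),
            }
        )


#: Site groups used for the 15-mer pH analysis: the two adenine-adjacent
#: blocks (sites 1-2 near the 5' terminus, sites 6-8 in the center) versus
#: everything else.
DEFAULT_GROUPS = {
    "1-2": (1, 2),
    "3-5": (3, 4, 5),
    "6-8": (6, 7, 8),
    "9-14": (9, 10, 11, 12, 13, 14),
}

#: Ratios of adenine-adjacent group yields to the added yields of the
#: remaining sites; ratio form damps charge-partitioning artifacts on the
#: large 3'-side fragments.
DEFAULT_RATIOS = {
    "(1-2)/(3-5+9-14)": (("1-2",), ("3-5", "9-14")),
    "(6-8)/(3-5+9-14)": (("6-8",), ("3-5", "9-14")),
}


def grouped_yields(
    profile: CleavageYieldProfile,
    groups: dict | None = None,
    ratios: dict | None = None,
) -> GroupYieldStats:
    """Added combined yields over site groups, with optional sum ratios.

    ``groups`` maps group name -> iterable of sites and must partition the
    profile's site range exactly.  ``ratios`` maps ratio name ->
    (numerator group names, denominator group names).
    """
    groups = {name: tuple(sites) for name, sites in (groups or DEFAULT_GROUPS).items()}
    covered = [s for sites in groups.values() for s in sites]
    expected = list(range(1, len(profile.sites) + 1))
    if sorted(covered) != expected:
        raise ValueError(
            f"groups must partition sites 1..{len(profile.sites)}; got {sorted(covered)}"
        )
    sums = {
        name: float(sum(profile.combined[s - 1] for s in sites))
        for name, sites in groups.items()
    }
    ratio_values = {}
    for name, (num_names, den_names) in (ratios or {}).items():
        numerator = sum(sums[g] for g in num_names)
        denominator = sum(sums[g] for g in den_names)
        if denominator <= 0:
            raise ValueError(f"zero denominator in ratio {name!r}")
        ratio_values[name] = numerator / denominator
    return GroupYieldStats(groups=groups, sums=sums, ratios=ratio_values)


def average_charge(annotated, series: str) -> pd.Series:
    """Intensity-weighted mean charge of one fragment series per index.

    Loss variants count toward their parent (series, site) since the loss
    does not change which backbone bond broke.
    """
    table = _backbone(_abundance_table(annotated))
    table = table[table["series"] == series]
    if not len(table):
        raise ValueError(f"series {series!r} not observed")
    weighted = table.groupby("site").apply(
        lambda g: (g["charge"] * g["abundance"]).sum() / g["abundance"].sum(),
        include_groups=False,
    )
    weighted.name = "mean_charge"
    return weighted
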