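"""Isotope-cluster detection and fragment assignment for centroided spectra.

The annotation pipeline is: read a centroided peak list, group peaks into
isotope clusters by their 1.0033548/z spacing (an open replacement for
vendor deisotoping), match cluster monoisotopic m/z values against a
theoretical fragment list within a ppm tolerance, and quantify each
species by a non-negative least-squares fit of its theoretical envelope
to the member-peak intensities -- identical to the member sum for clean
clusters, and an exact decomposition where species coincide in m/z.

Peak-list text format: two whitespace- or comma-separated columns (m/z,
intensity); ``#`` comment lines of the form ``# key = value`` carry
metadata (``precursor_charge``, ``collision_energy_eV``, ``pH``, ``scans``,
``source``, ``sequence``).  Centroided mzML is supported behind the same
interface when pyteomics is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fragments import FragmentSpecies
from .isotopes import NEUTRON_SPACING, cluster_mz_grid, isotope_pattern

__all__ = [
    "AnnotatedSpectrum",
    "Assignment",
    "IsotopeCluster",
    "PeakList",
    "annotate_spectrum",
    "charge_summed",
    "detect_clusters",
    "match_fragments",
    "quantify",
    "read_peaklist",
    "read_mzml",
    "resolve_envelope_overlaps",
    "write_annotation_tsv",
    "write_summary_json",
]

_METADATA_KEYS = ("precursor_charge", "collision_energy_eV", "pH", "scans", "source", "sequence")


@dataclass
class PeakList:
    """Centroided peaks (m/z ascending) plus acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def to_text(self) -> str:
        lines = [
            f"# {key} = {self.metadata[key]}"
            for key in sorted(self.metadata)
        ]
        lines += [f"{m:.6f}\t{i:.6f}" for m, i in zip(self.mz, self.intensity)]
        return "\n".join(lines) + "\n"

    def write_text(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.to_text())


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_peaklist(path) -> PeakList:
    """Read the two-column text format described in the module docstring."""
    mz, intensity, metadata = [], [], {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for sep in ("=", ":"):
                    if sep in body:
                        key, value = body.split(sep, 1)
                        metadata[key.strip()] = _coerce(value.strip())
                        break
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ValueError(f"cannot parse peak line {line!r}")
            mz.append(float(fields[0]))
            intensity.append(float(fields[1]))
    return PeakList(np.array(mz), np.array(intensity), metadata)


def read_mzml(path) -> list[PeakList]:
    """Read centroided spectra from an mzML file (requires pyteomics)."""
    from pyteomics import mzml as _mzml  # deferred optional dependency

    spectra = []
    with _mzml.read(str(path)) as reader:
        for entry in reader:
            metadata = {"source": entry.get("id", "")}
            precursors = entry.get("precursorList", {}).get("precursor", [])
            if precursors:
                ions = precursors[0].get("selectedIonList", {}).get("selectedIon", [])
                if ions and "charge state" in ions[0]:
                    metadata["precursor_charge"] = int(ions[0]["charge state"])
            spectra.append(
                PeakList(entry["m/z array"], entry["intensity array"], metadata)
            )
    return spectra


@dataclass(frozen=True)
class IsotopeCluster:
    """A run of peaks consistent with one isotopologue envelope.

    ``charge`` is None for single-peak clusters whose spacing cannot be
    read; ``mono_mz`` is the m/z of the first (lowest-mass) member and
    ``intensity`` the sum over members.
    """

    indices: tuple[int, ...]
    charge: int | None
    mono_mz: float
    intensity: float
    member_intensities: tuple[float, ...] = ()


def detect_clusters(
    peaklist: PeakList,
    charge_candidates=(1, 2, 3, 4),
    spacing_tolerance: float = 0.002,
    intensity_ratio_limit: float = 10.0,
) -> list[IsotopeCluster]:
    """Greedy longest-run-first isotope-cluster grouping.

    For every peak and every candidate charge z, the run of peaks spaced
    by 1.0033548/z (each within ``spacing_tolerance`` m/z of its expected
    position, intensity > 0, ties to the closest peak) is a candidate
    cluster.  Candidates are accepted longest run first (ties: smaller
    cumulative spacing error, then lower start m/z) and consume their
    member peaks, so a complete envelope always beats the spurious
    sub-runs it contains -- e.g. the charge-1 reading of every third peak
    of a 3+ envelope, or a chain from an overlapping neighbor extending
    into foreign peaks.  Peaks left without a partner become
    charge-undetermined singleton clusters.

    ``intensity_ratio_limit`` bounds the intensity *rise* between adjacent
    chain members: aggregate isotope envelopes climb gently (the +1 peak
    of even a large RNA fragment is at most a few times its neighbor), so
    a ~100-fold upward jump marks a foreign monoisotopic peak and ends
    the chain rather than letting one envelope swallow an overlapping
    one.  Decays are unrestricted -- envelope tails and the 2-peak
    envelopes of small fragments fall off steeply and legitimately.
    """
    import heapq

    charge_candidates = sorted(set(int(z) for z in charge_candidates))
    if not charge_candidates:
        raise ValueError("charge_candidates must not be empty")
    if intensity_ratio_limit <= 1:
        raise ValueError("intensity_ratio_limit must be > 1")
    mz = peaklist.mz
    intensity = peaklist.intensity
    n = len(mz)
    consumed = np.zeros(n, dtype=bool)
    positive = intensity > 0

    def _chain(start: int, z: int) -> tuple[list[int], float]:
        members = [start]
        error = 0.0
        current = mz[start]
        while True:
            expected = current + NEUTRON_SPACING / z
            lo = np.searchsorted(mz, expected - spacing_tolerance, side="left")
            hi = np.searchsorted(mz, expected + spacing_tolerance, side="right")
            previous = intensity[members[-1]]
            best, best_err = -1, spacing_tolerance
            for idx in range(lo, hi):
                if consumed[idx] or not positive[idx]:
                    continue
                if intensity[idx] > intensity_ratio_limit * previous:
                    continue
                err = abs(mz[idx] - expected)
                if err <= best_err:
                    best, best_err = idx, err
            if best < 0:
                return members, error
            members.append(best)
            error += best_err
            current = mz[best]

    heap: list[tuple] = []
    for start in range(n):
        if not positive[start]:
            continue
        for z in charge_candidates:
            members, error = _chain(start, z)
            heapq.heappush(heap, (-len(members), error, mz[start], start, z, members))

    clusters: list[IsotopeCluster] = []
    while heap:
        neg_len, error, _, start, z, members = heapq.heappop(heap)
        if consumed[start]:
            continue
        if any(consumed[idx] for idx in members[1:]):
            # Stale candidate: some member was claimed by a longer run.
            members, error = _chain(start, z)
            heapq.heappush(heap, (-len(members), error, mz[start], start, z, members))
            continue
        consumed[members] = True
        clusters.append(
            IsotopeCluster(
                indices=tuple(members),
                charge=z if len(members) > 1 else None,
                mono_mz=float(mz[members[0]]),
                intensity=float(intensity[members].sum()),
                member_intensities=tuple(float(v) for v in intensity[members]),
            )
        )
    clusters.sort(key=lambda c: c.mono_mz)
    return clusters


@dataclass(frozen=True)
class Assignment:
    """One accepted cluster-fragment pairing.

    ``abundance`` is the species intensity attributed to the fragment:
    by default the summed member-peak intensity of its cluster, replaced
    by the envelope least-squares estimate when overlap resolution has
    run (see :func:`resolve_envelope_overlaps`).
    """

    fragment: FragmentSpecies
    cluster: IsotopeCluster
    ppm_error: float
    score: float
    low_confidence: bool = False
    abundance: float | None = None

    @property
    def intensity(self) -> float:
        return self.cluster.intensity if self.abundance is None else self.abundance


def _pattern_score(cluster: IsotopeCluster, fragment: FragmentSpecies) -> float:
    """Cosine agreement in [0, 1] between observed member intensities and
    the theoretical isotope envelope of the fragment composition."""
    if fragment.composition is None or not cluster.member_intensities:
        return 0.0
    theory = np.asarray(isotope_pattern(fragment.composition).abundances)
    observed = np.asarray(cluster.member_intensities)
    k = max(len(theory), len(observed))
    theory = np.pad(theory, (0, k - len(theory)))
    observed = np.pad(observed, (0, k - len(observed)))
    denom = np.linalg.norm(theory) * np.linalg.norm(observed)
    if denom == 0:
        return 0.0
    return float(np.clip(theory @ observed / denom, 0.0, 1.0))


def match_fragments(
    clusters,
    theoretical,
    ppm_tolerance: float = 5.0,
) -> list[Assignment]:
    """Assign clusters to theoretical fragments by minimal |ppm error|.

    Candidates require matching charge (charge-undetermined singletons may
    match any charge, flagged low-confidence).  Ties break toward fewer
    losses, then the lower site index.  Each cluster is assigned at most
    once and each theoretical species (which carries its charge) claims at
    most one cluster.
    """
    if ppm_tolerance < 0:
        raise ValueError(f"ppm_tolerance must be >= 0, got {ppm_tolerance}")
    keys = [sp.key() for sp in theoretical]
    if len(keys) != len(set(keys)):
        raise ValueError("theoretical fragment list contains duplicates")

    candidates = []
    for ci, cluster in enumerate(clusters):
        for fi, frag in enumerate(theoretical):
            if cluster.charge is not None and cluster.charge != frag.charge:
                continue
            ppm = (cluster.mono_mz - frag.mz) / frag.mz * 1e6
            if abs(ppm) <= ppm_tolerance:
                candidates.append((abs(ppm), len(frag.losses), frag.site or 0, ci, fi, ppm))
    candidates.sort()

    assignments: list[Assignment] = []
    used_clusters: set[int] = set()
    used_fragments: set[int] = set()
    for _, _, _, ci, fi, ppm in candidates:
        if ci in used_clusters or fi in used_fragments:
            continue
        used_clusters.add(ci)
        used_fragments.add(fi)
        cluster, frag = clusters[ci], theoretical[fi]
        assignments.append(
            Assignment(
                fragment=frag,
                cluster=cluster,
                ppm_error=ppm,
                score=_pattern_score(cluster, frag),
                low_confidence=cluster.charge is None,
            )
        )
    assignments.sort(
        key=lambda a: (a.fragment.series, a.fragment.site or 0, a.fragment.losses, a.fragment.charge)
    )
    return assignments


def quantify(assignments) -> pd.DataFrame:
    """Per-species abundance table (one row per series/site/losses/charge).

    Abundance is the summed member-peak intensity of the assigned cluster.
    Use :func:`charge_summed` for the charge-aggregated view.
    """
    rows = [
        {
            "series": a.fragment.series,
            "site": a.fragment.site,
            "losses": a.fragment.loss_label,
            "charge": a.fragment.charge,
            "abundance": a.intensity,
            "mz": a.fragment.mz,
            "ppm_error": a.ppm_error,
            "score": a.score,
            "low_confidence": a.low_confidence,
        }
        for a in assignments
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "series", "site", "losses", "charge", "abundance",
            "mz", "ppm_error", "score", "low_confidence",
        ],
    )
    if len(table):
        keys = list(zip(table["series"], table["site"], table["losses"], table["charge"]))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate species keys in abundance table")
        table = table.sort_values(
            ["series", "site", "losses", "charge"], na_position="first"
        ).reset_index(drop=True)
    return table


def charge_summed(table: pd.DataFrame) -> pd.DataFrame:
    """Charge-aggregated abundances with intensity-weighted mean charge."""
    if not len(table):
        return pd.DataFrame(columns=["series", "site", "losses", "abundance", "mean_charge"])
    def _agg(group):
        total = group["abundance"].sum()
        mean_charge = (group["charge"] * group["abundance"]).sum() / total if total else np.nan
        return pd.Series({"abundance": total, "mean_charge": mean_charge})
    out = (
        table.groupby(["series", "site", "losses"], dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out


def resolve_envelope_overlaps(
    peaklist: PeakList,
    assignments: list[Assignment],
    theoretical,
    ppm_tolerance: float = 5.0,
    spacing_tolerance: float = 0.002,
) -> list[Assignment]:
    """Re-quantify assignments by least-squares isotope-envelope fits.

    Species whose m/z grids coincide cannot be separated by peak grouping
    alone: a fragment of doubled composition at doubled charge has exactly
    the m/z of its half (here the 5'-terminal GAAG repeat makes c8(2+)
    coincide with c4(1+), and c2(1+)/c4(2+)/c6(3+) share one grid), so a
    detected cluster may contain several species.  For every assigned
    cluster this step fits the member intensities as a non-negative
    combination of the theoretical envelopes of the assigned fragment and
    of any still-unassigned fragments whose monoisotopic m/z coincides
    within the ppm tolerance (at a different charge, which keeps the fit
    well conditioned).  Each species' abundance becomes its fitted total
    intensity -- identical to the member sum for a clean single-species
    cluster, and an exact decomposition for overlapped ones.  Rivals with
    positive fitted intensity gain assignments of their own.
    """
    from scipy.optimize import nnls

    used = {a.fragment.key() for a in assignments}
    refined: list[Assignment] = []
    for a in assignments:
        cluster = a.cluster
        if cluster.charge is None or a.fragment.composition is None:
            refined.append(replace(a, abundance=cluster.intensity))
            continue
        rivals = [
            f
            for f in theoretical
            if f.key() not in used
            and f.charge != cluster.charge
            and f.composition is not None
            and abs(cluster.mono_mz - f.mz) / f.mz * 1e6 <= ppm_tolerance
        ]
        candidates = [a.fragment] + rivals
        members = peaklist.mz[list(cluster.indices)]
        b = np.asarray(cluster.member_intensities, dtype=float)
        columns = []
        for frag in candidates:
            grid = cluster_mz_grid(
                isotope_pattern(frag.composition), frag.neutral_mass, frag.charge
            )
            col = np.zeros(len(members))
            for mz_k, abundance_k in grid:
                j = int(np.argmin(np.abs(members - mz_k)))
                if abs(members[j] - mz_k) <= spacing_tolerance:
                    col[j] += abundance_k
            columns.append(col)
        design = np.column_stack(columns)
        if not design[:, 0].any():
            refined.append(replace(a, abundance=cluster.intensity))
            continue
        # Trim member slots that no candidate envelope can explain (tail
        # peaks of unrelated species, baseline hits): a slot whose fit
        # residual stays well above numerical noise is contaminated, and
        # the envelope shape determines the abundance from the clean
        # slots alone.
        keep = np.ones(len(b), dtype=bool)
        for _ in range(5):
            coef, residual = nnls(design[keep], b[keep])
            slot_residual = b[keep] - design[keep] @ coef
            threshold = 1e-9 * b.sum()
            worst = int(np.argmax(slot_residual))
            if slot_residual[worst] <= threshold or keep.sum() <= 2:
                break
            keep[np.flatnonzero(keep)[worst]] = False
        norm = np.linalg.norm(b[keep])
        score = float(np.clip(1.0 - residual / norm, 0.0, 1.0)) if norm else 0.0
        refined.append(replace(a, abundance=float(coef[0]), score=score))
        for frag, value in zip(rivals, coef[1:]):
            if value > 1e-9 * max(cluster.intensity, 1e-300):
                used.add(frag.key())
                ppm = (cluster.mono_mz - frag.mz) / frag.mz * 1e6
                refined.append(
                    Assignment(
                        fragment=frag,
                        cluster=cluster,
                        ppm_error=ppm,
                        score=score,
                        low_confidence=a.low_confidence,
                        abundance=float(value),
                    )
                )
    refined.sort(
        key=lambda x: (x.fragment.series, x.fragment.site or 0, x.fragment.losses, x.fragment.charge)
    )
    return refined


@dataclass
class AnnotatedSpectrum:
    """A peak list with its cluster assignments and abundance table."""

    peaklist: PeakList
    assignments: list[Assignment]
    unassigned: list[IsotopeCluster]
    abundances: pd.DataFrame

    @property
    def charge_summed(self) -> pd.DataFrame:
        return charge_summed(self.abundances)


def annotate_spectrum(
    peaklist: PeakList,
    theoretical,
    ppm_tolerance: float = 5.0,
    charge_candidates=None,
    spacing_tolerance: float = 0.002,
) -> AnnotatedSpectrum:
    """Full annotation: detect clusters, match fragments, quantify.

    ``charge_candidates`` defaults to 1..precursor_charge from the peak
    list metadata (1..4 when absent).
    """
    if charge_candidates is None:
        n = int(peaklist.metadata.get("precursor_charge", 4))
        charge_candidates = range(1, n + 1)
    clusters = detect_clusters(
        peaklist, charge_candidates, spacing_tolerance=spacing_tolerance
    )
    assignments = match_fragments(clusters, theoretical, ppm_tolerance)
    assignments = resolve_envelope_overlaps(
        peaklist, assignments, theoretical, ppm_tolerance, spacing_tolerance
    )
    assigned = {id(a.cluster) for a in assignments}
    unassigned = [c for c in clusters if id(c) not in assigned]
    return AnnotatedSpectrum(peaklist, assignments, unassigned, quantify(assignments))


def write_annotation_tsv(annotated: AnnotatedSpectrum, path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "cluster_mz\tcharge\tintensity\tseries\tsite\tlosses\tppm_error\tscore\n"
        )
        for a in annotated.assignments:
            site = "" if a.fragment.site is None else a.fragment.site
            handle.write(
                f"{a.cluster.mono_mz:.4f}\t{a.fragment.charge}\t"
                f"{a.cluster.intensity:.4f}\t{a.fragment.series}\t{site}\t"
                f"{a.fragment.loss_label}\t{a.ppm_error:.3f}\t{a.score:.4f}\n"
            )


def write_summary_json(annotated: AnnotatedSpectrum, path) -> None:
    summary = {
        "n_peaks": len(annotated.peaklist),
        "n_clusters": len(annotated.assignments) + len(annotated.unassigned),
        "n_assigned": len(annotated.assignments),
        "n_unassigned": len(annotated.unassigned),
        "metadata": annotated.peaklist.metadata,
        "total_assigned_intensity": float(
            annotated.abundances["abundance"].sum() if len(annotated.abundances) else 0.0
        ),
    }
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
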