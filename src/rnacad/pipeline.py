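"""Run configuration and the end-to-end annotation/statistics pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import (
    annotate_spectrum,
    read_peaklist,
    write_annotation_tsv,
    write_summary_json,
)
from .fragments import enumerate_fragments
from .rna_chem import ModifiedRNASequence, read_sequences
from .yields import (
    DEFAULT_GROUPS,
    DEFAULT_RATIOS,
    compare_rnas,
    grouped_yields,
    site_yield_profile,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("rnacad")


@dataclass
class RunConfig:
    """Validated settings for a pipeline run.

    Loadable from a YAML key-value file via :meth:`from_file`; every field
    is checked on construction with an actionable message.
    """

    ppm_tolerance: float = 5.0
    series: tuple[str, ...] = ("c", "y")
    max_h2o_losses: int = 1
    allow_base_loss: bool = True
    charge_min: int = 1
    charge_max: int | None = None  # default: precursor charge - 1
    spacing_tolerance: float = 0.002
    outlier_threshold: float = 3.0
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    ratios: dict = field(default_factory=lambda: dict(DEFAULT_RATIOS))
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.ppm_tolerance < 0:
            raise ValueError("ppm_tolerance must be >= 0")
        if not self.series:
            raise ValueError("series must name at least one fragment series")
        self.series = tuple(self.series)
        if self.max_h2o_losses < 0:
            raise ValueError("max_h2o_losses must be >= 0")
        if self.charge_min < 1:
            raise ValueError("charge_min must be >= 1")
        if self.charge_max is not None and self.charge_max < self.charge_min:
            raise ValueError("charge_max must be >= charge_min")
        if self.spacing_tolerance <= 0:
            raise ValueError("spacing_tolerance must be > 0")
        if self.outlier_threshold <= 1:
            raise ValueError("outlier_threshold must be > 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys are "
                f"{sorted(cls.__dataclass_fields__)}"
            )
        return cls(**data)


def _charge_range(config: RunConfig, precursor_charge: int) -> range:
    top = config.charge_max if config.charge_max is not None else max(
        precursor_charge - 1, config.charge_min
    )
    return range(config.charge_min, top + 1)


def _pick_sequence(
    sequences: dict[str, ModifiedRNASequence], metadata: dict, fallback: str
) -> tuple[str, ModifiedRNASequence]:
    wanted = metadata.get("sequence")
    if wanted is not None:
        for name, seq in sequences.items():
            if name == wanted or seq.notation() == str(wanted).replace(" ", ""):
                return name, seq
        raise ValueError(
            f"peak list names sequence {wanted!r} but the sequence file only "
            f"defines {sorted(sequences)}"
        )
    return fallback, sequences[fallback]


def run_pipeline(config: RunConfig, sequence_file, peaklist_files) -> dict:
    """Annotate each peak list, compute yield statistics, write reports.

    Each peak list is matched to its sequence via the ``sequence`` metadata
    key (by name or notation); without it the first sequence in the file is
    used.  Multi-spectrum runs also emit a pairwise comparison of every
    later spectrum against the first, plus grouped yields per spectrum
    where the configured groups fit the site range.  Returns a summary
    dict; all outputs land under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences = read_sequences(sequence_file)
    if not sequences:
        raise ValueError(f"no sequences found in {sequence_file}")
    first_name = next(iter(sequences))

    report: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "spectra": [],
    }
    annotated_list = []
    for path in peaklist_files:
        path = Path(path)
        peaklist = read_peaklist(path)
        seq_name, seq = _pick_sequence(sequences, peaklist.metadata, first_name)
        precursor = int(peaklist.metadata.get("precursor_charge", 4))
        theoretical = enumerate_fragments(
            seq,
            series_set=config.series,
            max_h2o_losses=config.max_h2o_losses,
            allow_base_loss=config.allow_base_loss,
            charge_range=_charge_range(config, precursor),
        )
        annotated = annotate_spectrum(
            peaklist,
            theoretical,
            ppm_tolerance=config.ppm_tolerance,
            spacing_tolerance=config.spacing_tolerance,
        )
        stem = path.stem
        write_annotation_tsv(annotated, out_dir / f"{stem}.annotation.tsv")
        write_summary_json(annotated, out_dir / f"{stem}.summary.json")
        entry = {
            "peaklist": str(path),
            "sequence": seq_name,
            "n_peaks": len(peaklist),
            "n_assigned": len(annotated.assignments),
        }
        if len(annotated.abundances):
            profile = site_yield_profile(annotated, len(seq) - 1)
            profile.write_tsv(out_dir / f"{stem}.yields.tsv")
            entry["yield_sum"] = float(profile.combined.sum())
            covered = sorted(
                s for sites in config.groups.values() for s in sites
            )
            if covered == list(range(1, len(seq))):
                stats = grouped_yields(profile, config.groups, config.ratios)
                entry["group_sums"] = stats.sums
                entry["group_ratios"] = stats.ratios
        else:
            log.warning("no fragments assigned in %s", path)
            entry["yield_sum"] = 0.0
        report["spectra"].append(entry)
        annotated_list.append((stem, annotated))

    if len(annotated_list) > 1:
        reference_stem, reference = annotated_list[0]
        comparisons = []
        for stem, variant in annotated_list[1:]:
            result = compare_rnas(reference, variant, config.outlier_threshold)
            result.pairs.to_csv(
                out_dir / f"{reference_stem}_vs_{stem}.pairs.tsv", sep="\t"
            )
            comparisons.append(
                {
                    "reference": reference_stem,
                    "variant": stem,
                    "slope": result.slope,
                    "pearson": result.pearson,
                    "effect_factor": result.effect_factor,
                    "outliers": [list(map(str, key)) for key in result.outliers],
                }
            )
        report["comparisons"] = comparisons

    with open(out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=float)
        handle.write("\n")
    return report
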