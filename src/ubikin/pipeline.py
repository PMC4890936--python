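"""Orchestration of the two analysis arms from one declarative configuration.

``run_site_analysis`` takes a site table (+ optional alignment, annotations,
phospho/hotspot lists) through classification, summary and ranking;
``run_traj_analysis`` takes per-construct metric series (or coordinate
trajectories) through pooled histograms, per-simulation summaries and
construct comparisons.  Both are deterministic given inputs and seed and
emit a manifest recording every parameter and an SHA-256 digest of every
input file, sufficient to re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import domain_mapping, ensemble_stats, ptm_sites, traj_metrics

logger = logging.getLogger("ubikin")


@dataclass
class RunConfig:
    """Inputs plus the analysis constants (defaults are the study's values)."""

    # inputs
    site_table: str | None = None
    alignment: str | None = None
    alignment_format: str = "fasta"
    reference: str = "ZAP70"
    annotations: str | None = None
    series_files: dict[str, str] = field(default_factory=dict)  # construct -> path
    trajectory_files: dict[str, str] = field(default_factory=dict)
    # parameters
    mg132_comparisons: list[str] = field(default_factory=lambda: ["mg132_vs_ctrl"])
    hiv_comparison: str | None = None
    hiv_mg132_comparison: str | None = None
    alpha: float = 0.05
    fold_change: float = 2.0
    near_window: int = 4
    residue_conservation_threshold: int = 40
    modification_conservation_threshold: int = 5
    contact_cutoff: float = 10.0      # Angstrom
    contact_stride_ps: float = 100.0
    helix_range: tuple[int, int] = (380, 393)
    helical_threshold: int = 10
    n_sims: int = 32
    statistic: str = "mean"
    seed: int = 0
    out_dir: str = "ubikin_out"

    def __post_init__(self):
        for name in ("alpha", "fold_change", "contact_cutoff",
                     "contact_stride_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.helix_range = tuple(self.helix_range)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        paths = [self.site_table, self.alignment, self.annotations,
                 *self.series_files.values(), *self.trajectory_files.values()]
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(config: RunConfig, inputs: list[str]) -> dict:
    return {
        "parameters": {k: v for k, v in asdict(config).items()},
        "input_digests": {p: _digest(p) for p in inputs if p},
    }


def read_annotations_tsv(path) -> list[ptm_sites.DomainAnnotation]:
    """TSV with columns accession, start, end, kind (1-based inclusive)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("accession", "start", "end", "kind"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(row["accession"], []).append(
            (int(row["start"]), int(row["end"]), row["kind"]))
    return [ptm_sites.DomainAnnotation(acc, ranges)
            for acc, ranges in out.items()]


def run_site_analysis(config: RunConfig, sites=None, annotations=None,
                      phospho_sites=(), hotspots=frozenset(),
                      write: bool = True) -> dict:
    """Site arm: classify, summarize (composition table), rank kinases.

    ``sites``/``annotations`` may be passed in memory; otherwise they are
    read from the configured paths.  Without an alignment the conservation
    columns are skipped and logged.
    """
    t0 = time.time()
    if sites is None:
        if config.site_table is None:
            raise ValueError("no site table configured")
        sites = ptm_sites.read_site_table(config.site_table)
    if annotations is None and config.annotations:
        annotations = read_annotations_tsv(config.annotations)
    logger.info("site analysis: %d sites, %d annotated proteins",
                len(sites), len(annotations or []))

    calls = ptm_sites.classify_sites(
        sites, config.mg132_comparisons,
        hiv_comparison=config.hiv_comparison,
        hiv_mg132_comparison=config.hiv_mg132_comparison,
        alpha=config.alpha)

    conservation = mod_conservation = None
    density = None
    if config.alignment:
        aln = domain_mapping.MultipleAlignment.read(config.alignment,
                                                    config.alignment_format)
        conservation = domain_mapping.conservation_flags(
            aln, sites, threshold=config.residue_conservation_threshold)
        _, mod_conservation = domain_mapping.modification_conservation(
            aln, sites, threshold=config.modification_conservation_threshold)
    else:
        logger.info("no alignment supplied; conservation columns skipped")

    summary = ptm_sites.summarize_sites(
        sites, calls, annotations=annotations, phospho_sites=phospho_sites,
        hotspots=hotspots, conservation=conservation,
        modification_conservation=mod_conservation, window=config.near_window)
    ranking = ptm_sites.rank_kinases(sites, calls)

    bundle = {"calls": calls, "summary": summary, "ranking": ranking,
              "density": density,
              "manifest": _manifest(config, [config.site_table,
                                             config.alignment,
                                             config.annotations])}
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.as_frame().to_csv(out / "site_summary.tsv", sep="\t")
        ranking.to_csv(out / "kinase_ranking.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True, default=str)
    logger.info("site analysis done in %.2f s", time.time() - t0)
    return bundle


def run_traj_analysis(config: RunConfig, series_by_construct=None,
                      control: str | None = None, write: bool = True) -> dict:
    """Trajectory arm: pooled histograms per construct and a per-simulation
    rank-sum comparison of every construct against the control.

    ``series_by_construct`` maps construct label -> list of MetricSeries;
    when absent, the configured ``series_files`` are read and split into
    ``n_sims`` blocks each.  The first construct (or ``control``) is the
    comparison baseline.  Constructs may have unequal snapshot counts; the
    pooled statistics tolerate it.
    """
    t0 = time.time()
    if series_by_construct is None:
        if not config.series_files:
            raise ValueError("no series files configured")
        series_by_construct = {
            label: traj_metrics.read_scalar_series(path, n_sims=config.n_sims)
            for label, path in config.series_files.items()}
    labels = list(series_by_construct)
    if control is None:
        control = labels[0]
    counts = {lab: sum(len(s.values) for s in ser)
              for lab, ser in series_by_construct.items()}
    if len(set(counts.values())) > 1:
        logger.warning("constructs have mismatched snapshot counts: %s", counts)

    histograms = {lab: ensemble_stats.pooled_histogram(ser)
                  for lab, ser in series_by_construct.items()}
    comparisons = {}
    for lab in labels:
        if lab == control:
            continue
        comparisons[(control, lab)] = ensemble_stats.compare_constructs(
            series_by_construct[control], series_by_construct[lab],
            statistic=config.statistic, labels=(control, lab))

    bundle = {"histograms": histograms, "comparisons": comparisons,
              "manifest": _manifest(config, list(config.series_files.values()))}
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = {
            "histogram_medians": {lab: h.median for lab, h in histograms.items()},
            "comparisons": {
                f"{a}_vs_{b}": {"statistic": c.statistic, "p_value": c.p_value,
                                "method": c.method,
                                "per_sim_means_a": c.summaries_a.tolist(),
                                "per_sim_means_b": c.summaries_b.tolist()}
                for (a, b), c in comparisons.items()},
        }
        with open(out / "traj_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True, default=str)
    logger.info("trajectory analysis done in %.2f s", time.time() - t0)
    return bundle


def setup_logging(level: str = "INFO", logfile: str | None = None) -> None:
    """Structured logging to stderr and optionally a run log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
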