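"""Classification and summary statistics for kinase ubiquitination sites.

A ubiquitination site (diGly remnant) is called proteasome *sensitive* when
its abundance rises at least two-fold (log2 fold-change >= 1) under the
proteasome inhibitor MG-132, *insensitive* when the change is below two-fold,
*neither* when calls conflict across cell lines or conditions, and *unknown*
without MG-132 data.  Sites whose ubiquitination is itself significantly
HIV-dependent are judged from the +HIV MG-132 comparison alone, since their
ubiquitination level without HIV may be near zero.

Summaries reproduce the composition tables of the site catalogue: fractions
on the kinase domain / any folded domain, at conserved residues, at conserved
modification positions, and near phosphosites or phospho hot spots, per
sensitivity category, together with per-kinase site-count rankings and the
chi-square two-proportion comparison and randomized-lysine null expectations
used to judge enrichment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODIFICATIONS = ("ubiquitin_remnant", "phospho", "acetyl")
SENSITIVITY_CALLS = ("sensitive", "insensitive", "neither", "unknown")

#: log2 fold-change at or above which a site is proteasome sensitive.
L2FC_SENSITIVE = 1.0
#: default significance level for the HIV-dependence trigger.
HIV_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class SiteRecord:
    """One PTM site with per-condition quantification and provenance.

    ``quant`` maps a comparison name to ``(log2_fold_change, adjusted_p)``.
    ``flags`` holds per-site annotations (precomputed conservation flags,
    planted synthetic truth, etc.) that travel with the record.
    """

    protein_accession: str
    gene_name: str
    residue_index: int
    modification: str
    quant: dict[str, tuple[float, float]] = field(default_factory=dict)
    source: frozenset = frozenset({"synthetic"})
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.modification not in MODIFICATIONS:
            raise ValueError(f"unknown modification {self.modification!r}")
        for name, (l2fc, p) in self.quant.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"adjusted p {p} for {name!r} outside [0, 1]")
        self.source = frozenset(self.source)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein_accession, self.residue_index, self.modification)


@dataclass
class DomainAnnotation:
    """1-based inclusive domain ranges for one protein."""

    protein_accession: str
    ranges: list[tuple[int, int, str]]

    def __post_init__(self):
        for start, end, kind in self.ranges:
            if start > end:
                raise ValueError(f"degenerate range {start}-{end} "
                                 f"on {self.protein_accession}")

    def region_kinds(self, residue_index: int) -> set[str]:
        return {kind for start, end, kind in self.ranges
                if start <= residue_index <= end}


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_proteasome_sensitivity(
    record: SiteRecord,
    mg132_comparisons: list[str],
    hiv_comparison: str | None = None,
    hiv_mg132_comparison: str | None = None,
    alpha: float = HIV_ALPHA,
) -> str:
    """Call a site sensitive / insensitive / neither / unknown from MG-132 data.

    Each available MG-132 comparison yields sensitive iff its log2
    fold-change >= 1 (two-fold) and insensitive below; conflicting calls
    across cell lines or conditions give 'neither'; no MG-132 data gives
    'unknown'.  If the site is significantly more abundant with HIV
    (``hiv_comparison`` log2FC > 0 with adjusted p < alpha) only the
    ``hiv_mg132_comparison`` is consulted.
    """
    comparisons = list(mg132_comparisons)
    if hiv_comparison is not None and hiv_comparison in record.quant:
        l2fc, adj_p = record.quant[hiv_comparison]
        if l2fc > 0 and adj_p < alpha:
            if hiv_mg132_comparison is None:
                raise ValueError("hiv_mg132_comparison required when the HIV "
                                 "rule triggers")
            comparisons = [hiv_mg132_comparison]
    calls = set()
    for name in comparisons:
        if name in record.quant:
            l2fc, _ = record.quant[name]
            calls.add("sensitive" if l2fc >= L2FC_SENSITIVE else "insensitive")
    if not calls:
        return "unknown"
    if len(calls) > 1:
        return "neither"
    return calls.pop()


def classify_sites(records, mg132_comparisons, **kwargs) -> dict[tuple, str]:
    """Classify a collection; rejects MG-132 comparison names absent everywhere."""
    known = set()
    for r in records:
        known.update(r.quant)
    missing = [c for c in mg132_comparisons if c not in known]
    if missing and records:
        raise ValueError(f"unknown comparison name(s): {missing}")
    return {r.key: classify_proteasome_sensitivity(r, mg132_comparisons, **kwargs)
            for r in records}


def merge_site_sets(a, b) -> list[SiteRecord]:
    """Merge two site collections to one record per (protein, residue, mod).

    Sources are unioned and quantifications combined; per-site flags from
    either input are kept (the first input wins on conflicting flag keys).
    """
    merged: dict[tuple, SiteRecord] = {}
    for rec in list(a) + list(b):
        if rec.key not in merged:
            merged[rec.key] = SiteRecord(
                rec.protein_accession, rec.gene_name, rec.residue_index,
                rec.modification, dict(rec.quant), frozenset(rec.source),
                dict(rec.flags),
            )
        else:
            m = merged[rec.key]
            m.source = m.source | rec.source
            for name, val in rec.quant.items():
                m.quant.setdefault(name, val)
            for kf, vf in rec.flags.items():
                m.flags.setdefault(kf, vf)
    return list(merged.values())


def near_phospho(site: SiteRecord, phospho_sites, window: int = 4) -> bool:
    """True iff a phosphosite lies within ``window`` residues on the same protein."""
    for p in phospho_sites:
        if (p.protein_accession == site.protein_accession
                and abs(p.residue_index - site.residue_index) <= window):
            return True
    return False


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_SUMMARY_METRICS = (
    "fraction_on_kinase_domain",
    "fraction_on_folded_domain",
    "fraction_residue_conserved",
    "fraction_modification_conserved",
    "fraction_near_phospho",
    "fraction_near_hotspot",
)


@dataclass
class SiteSummary:
    """Per-category composition fractions with their denominators."""

    fractions: dict[str, dict[str, float | None]]
    denominators: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions).T
        df["n_sites"] = pd.Series(self.denominators)
        return df


def summarize_sites(
    sites,
    calls: dict[tuple, str],
    annotations=None,
    phospho_sites=(),
    hotspots: set[tuple[str, int]] = frozenset(),
    conservation: dict[tuple[str, int], bool] | None = None,
    modification_conservation: dict[tuple[str, int], bool] | None = None,
    window: int = 4,
) -> SiteSummary:
    """Composition fractions per sensitivity category (sensitive /
    insensitive / all).

    'Neither' and 'unknown' sites enter the *all* denominator but neither
    sensitivity-specific row.  Sites on proteins without a domain annotation
    are counted off-domain and logged via a warning.  Conservation flags are
    taken as precomputed per-(protein, residue) maps; ``None`` skips those
    columns (reported as absent).
    """
    ann_by_acc = {}
    if annotations:
        ann_by_acc = {a.protein_accession: a for a in annotations}
    missing_ann = sorted({s.protein_accession for s in sites
                          if s.protein_accession not in ann_by_acc})
    if annotations is not None and missing_ann:
        warnings.warn(f"{len(missing_ann)} proteins lack domain annotations; "
                      "their sites count as off-domain", stacklevel=2)

    categories = {"sensitive": [], "insensitive": [], "all": []}
    for s in sites:
        call = calls.get(s.key, "unknown")
        categories["all"].append(s)
        if call in ("sensitive", "insensitive"):
            categories[call].append(s)

    def site_metrics(s: SiteRecord) -> dict[str, bool | None]:
        kinds = set()
        if s.protein_accession in ann_by_acc:
            kinds = ann_by_acc[s.protein_accession].region_kinds(s.residue_index)
        key = (s.protein_accession, s.residue_index)
        return {
            "fraction_on_kinase_domain": "kinase_domain" in kinds,
            "fraction_on_folded_domain": bool(kinds),
            "fraction_residue_conserved": (None if conservation is None
                                           else conservation.get(key, False)),
            "fraction_modification_conserved": (
                None if modification_conservation is None
                else modification_conservation.get(key, False)),
            "fraction_near_phospho": near_phospho(s, phospho_sites, window),
            "fraction_near_hotspot": any(
                s.protein_accession == acc and abs(s.residue_index - r) <= window
                for acc, r in hotspots),
        }

    fractions: dict[str, dict[str, float | None]] = {}
    denominators: dict[str, int] = {}
    for cat, members in categories.items():
        denominators[cat] = len(members)
        row: dict[str, float | None] = {}
        if not members:
            row = {m: None for m in _SUMMARY_METRICS}
        else:
            per_site = [site_metrics(s) for s in members]
            for m in _SUMMARY_METRICS:
                vals = [p[m] for p in per_site]
                row[m] = None if vals[0] is None else float(np.mean(vals))
        fractions[cat] = row
    return SiteSummary(fractions, denominators)


def rank_kinases(sites, calls: dict[tuple, str]) -> pd.DataFrame:
    """Per-protein counts of insensitive / sensitive / unknown sites.

    'Neither' calls count toward the total but to no sensitivity column, and
    the 'unknown' column also absorbs them as sites without a usable call.
    Rows sort by insensitive count (desc), then total sites (desc), then
    accession; ties are therefore deterministic.
    """
    rows: dict[str, dict[str, int]] = {}
    for s in sites:
        acc = s.protein_accession
        r = rows.setdefault(acc, {"gene": s.gene_name, "insensitive": 0,
                                  "sensitive": 0, "unknown": 0, "total": 0})
        call = calls.get(s.key, "unknown")
        if call in ("sensitive", "insensitive"):
            r[call] += 1
        else:
            r["unknown"] += 1
        r["total"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "protein_accession"
    df = df.reset_index().sort_values(
        ["insensitive", "total", "protein_accession"],
        ascending=[False, False, True])
    return df.set_index("protein_accession")


# ---------------------------------------------------------------------------
# Two-proportion chi-square test (prop.test-compatible)
# ---------------------------------------------------------------------------

def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square test of equal proportions, Yates-corrected.

    Reproduces R's ``prop.test`` for two groups: the continuity correction is
    capped at ``|p1 - p2| / (1/n1 + 1/n2)`` so equal observed proportions give
    statistic 0 and p = 1.  Returns ``(statistic, two_sided_p)``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"success count {x} outside [0, {n}]")
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    if np.any(expected == 0):
        # a margin is empty: both proportions are 0 or 1, hence equal
        return 0.0, 1.0
    yates = 0.0
    if correction:
        delta = x1 / n1 - x2 / n2
        yates = min(0.5, abs(delta) / (1.0 / n1 + 1.0 / n2))
    statistic = float((((np.abs(obs - expected) - yates) ** 2) / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, min(1.0, p)


# ---------------------------------------------------------------------------
# Random-lysine null expectations
# ---------------------------------------------------------------------------

def random_site_null(
    kinase_sequences: dict[str, str],
    is_conserved,
    phospho_sites=(),
    hotspots: set[tuple[str, int]] = frozenset(),
    mode: str = "exact",
    n_draws: int = 10000,
    seed: int = 0,
    window: int = 4,
) -> dict[str, float]:
    """Expected fractions if ubiquitination sites were random lysines.

    Enumerates every lysine across ``kinase_sequences`` (1-based positions)
    and reports the expected fraction that (a) sits at a conserved-residue
    position per the ``is_conserved(accession, position)`` predicate, (b)
    lies within ``window`` residues of a phosphosite on the same protein,
    and (c) likewise for a phospho hot spot.  ``mode='exact'`` averages over
    the full lysine pool; ``mode='monte_carlo'`` samples ``n_draws`` lysines
    with the given seed.
    """
    pool = [(acc, i + 1) for acc, seq in kinase_sequences.items()
            for i, aa in enumerate(seq) if aa.upper() == "K"]
    if not pool:
        raise ValueError("no lysine residues in the provided sequences")
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(pool), size=n_draws)
        chosen = [pool[i] for i in idx]
    elif mode == "exact":
        chosen = pool
    else:
        raise ValueError(f"unknown mode {mode!r}")

    phospho_by_acc: dict[str, list[int]] = {}
    for p in phospho_sites:
        phospho_by_acc.setdefault(p.protein_accession, []).append(p.residue_index)

    n = len(chosen)
    conserved = near_p = near_h = 0
    for acc, pos in chosen:
        if is_conserved(acc, pos):
            conserved += 1
        if any(abs(pos - r) <= window for r in phospho_by_acc.get(acc, ())):
            near_p += 1
        if any(acc == hacc and abs(pos - r) <= window for hacc, r in hotspots):
            near_h += 1
    return {
        "conserved": conserved / n,
        "near_phospho": near_p / n,
        "near_hotspot": near_h / n,
        "n_lysines": float(len(pool)),
    }


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["accession", "gene", "residue", "modification",
                "comparison", "log2fc", "adj_p"]


def write_site_table(sites, path) -> None:
    """Long-format TSV: one row per (site, comparison); quant-less sites get
    an empty comparison row so they round-trip."""
    rows = []
    for s in sites:
        if s.quant:
            for name, (l2fc, p) in sorted(s.quant.items()):
                rows.append([s.protein_accession, s.gene_name, s.residue_index,
                             s.modification, name, l2fc, p])
        else:
            rows.append([s.protein_accession, s.gene_name, s.residue_index,
                         s.modification, "", np.nan, np.nan])
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path, source: str = "synthetic") -> list[SiteRecord]:
    """Read the long-format TSV written by :func:`write_site_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    sites: dict[tuple, SiteRecord] = {}
    for _, row in df.iterrows():
        key = (row["accession"], int(row["residue"]), row["modification"])
        if key not in sites:
            sites[key] = SiteRecord(row["accession"], str(row["gene"]),
                                    int(row["residue"]), row["modification"],
                                    {}, frozenset({source}))
        comp = row["comparison"]
        if isinstance(comp, str) and comp:
            sites[key].quant[comp] = (float(row["log2fc"]), float(row["adj_p"]))
    return list(sites.values())
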