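"""Genotype- and site-level quality filters for hemizygous X calls.

Genotype filters (applied first, failing calls become missing, not dropped):

* depth  — DP < 8 fails (strictly; DP = 8 passes),
* GQ     — genotype quality < 20 fails,
* MRR    — minor read ratio, min(ref, alt) / (ref + alt), below 20% fails
  *when minor-allele reads are present*.  A call whose reads all support the
  called allele (MRR = 0 with zero minor reads) is exactly what a clean
  hemizygous call looks like and passes; nonzero minor support below the
  threshold indicates contamination or mosaicism and fails.

Site filters, evaluated after genotype masking (so masked calls count toward
cohort missingness), in fixed report order: reference-population call rate
< 50%, non-PASS flag, decoy/low-complexity overlap, more than four alleles,
cohort missingness above 20%, span above 20 nt.  Boundary values (call rate
exactly 0.50, 4 alleles, 20% missing, 20 nt) pass; the quoted inequalities
are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GenotypeCall, GenotypeMatrix
from .errors import ConfigError, SchemaError, StructuralError

GENOTYPE_FILTERS = ("depth", "gq", "mrr", "malformed")
SITE_FILTERS = ("ref_callrate", "non_pass", "decoy", "multiallelic", "missingness", "span")

_SITE_COLUMNS = ("pop_call_rate", "pass_flag", "in_decoy", "n_alleles", "span_nt")


@dataclass(frozen=True)
class QcThresholds:
    min_depth: int = 8
    min_gq: int = 20
    min_mrr: float = 0.20
    min_ref_pop_callrate: float = 0.50
    max_cohort_missingness: float = 0.20
    max_alleles: int = 4
    max_span_nt: int = 20
    mrr_denominator: str = "informative"  # or "dp"

    def validate(self) -> None:
        for name in ("min_mrr", "min_ref_pop_callrate", "max_cohort_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("min_depth", "min_gq", "max_alleles", "max_span_nt"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mrr_denominator not in ("informative", "dp"):
            raise ConfigError("mrr_denominator must be 'informative' or 'dp'")


@dataclass
class QcReport:
    """Per-filter removal counts; removals + retained reconcile with inputs."""

    genotype_removals: dict = field(default_factory=lambda: {k: 0 for k in GENOTYPE_FILTERS})
    site_removals: dict = field(default_factory=lambda: {k: 0 for k in SITE_FILTERS})
    input_sites: int = 0
    retained_sites: int = 0
    input_genotypes: int = 0
    retained_genotypes: int = 0
    genotypes_on_removed_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("genotype", k, v) for k, v in self.genotype_removals.items()]
        rows += [("site", k, v) for k, v in self.site_removals.items()]
        rows += [
            ("total", "input_sites", self.input_sites),
            ("total", "retained_sites", self.retained_sites),
            ("total", "input_genotypes", self.input_genotypes),
            ("total", "retained_genotypes", self.retained_genotypes),
            ("total", "genotypes_on_removed_sites", self.genotypes_on_removed_sites),
        ]
        return pd.DataFrame(rows, columns=["level", "filter", "count"])


def genotype_passes(call: GenotypeCall, t: QcThresholds | None = None) -> tuple[bool, str | None]:
    """Scalar genotype filter: returns (passes, first failing reason)."""
    t = t or QcThresholds()
    if call.allele_count == -1:
        return True, None  # already missing; nothing to filter
    informative = call.ref_reads + call.alt_reads
    if informative == 0:
        return False, "malformed"
    if call.depth < t.min_depth:
        return False, "depth"
    if call.genotype_quality < t.min_gq:
        return False, "gq"
    minor = min(call.ref_reads, call.alt_reads)
    denom = call.depth if t.mrr_denominator == "dp" else informative
    if minor > 0 and minor / denom < t.min_mrr:
        return False, "mrr"
    return True, None


def genotype_fail_masks(gm: GenotypeMatrix, t: QcThresholds) -> dict[str, np.ndarray]:
    """Vectorized genotype filters; each mask flags first-reason failures only."""
    called = gm.allele_count >= 0
    informative = gm.ref_reads + gm.alt_reads
    malformed = called & (informative == 0)
    depth = called & ~malformed & (gm.depth < t.min_depth)
    gq = called & ~malformed & ~depth & (gm.gq < t.min_gq)
    minor = np.minimum(gm.ref_reads, gm.alt_reads)
    denom = gm.depth if t.mrr_denominator == "dp" else informative
    with np.errstate(divide="ignore", invalid="ignore"):
        mrr_val = np.where(denom > 0, minor / np.maximum(denom, 1), 0.0)
    mrr = called & ~malformed & ~depth & ~gq & (minor > 0) & (mrr_val < t.min_mrr)
    return {"malformed": malformed, "depth": depth, "gq": gq, "mrr": mrr}


def site_passes(
    site: pd.Series, cohort_missingness: float, t: QcThresholds | None = None
) -> tuple[bool, str | None]:
    """Scalar site filter; first failing reason in the documented order."""
    t = t or QcThresholds()
    for col in _SITE_COLUMNS:
        if col not in site or pd.isna(site[col]):
            raise SchemaError(f"site annotation missing required field {col!r}")
    if site["pop_call_rate"] < t.min_ref_pop_callrate:
        return False, "ref_callrate"
    if not site["pass_flag"]:
        return False, "non_pass"
    if site["in_decoy"]:
        return False, "decoy"
    if site["n_alleles"] > t.max_alleles:
        return False, "multiallelic"
    if cohort_missingness > t.max_cohort_missingness:
        return False, "missingness"
    if site["span_nt"] > t.max_span_nt:
        return False, "span"
    return True, None


def cohort_missingness(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site fraction of samples with a missing call."""
    if gm.n_samples == 0:
        return np.zeros(gm.n_sites)
    return (gm.allele_count == -1).mean(axis=1)


def mark_in_decoy(sites: pd.DataFrame, decoy_bed: pd.DataFrame | None) -> pd.DataFrame:
    """Recompute the in_decoy flag from BED intervals (0-based half-open)."""
    if decoy_bed is None:
        return sites
    sites = sites.copy()
    flag = np.zeros(len(sites), dtype=bool)
    for chrom, grp in decoy_bed.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], np.maximum.accumulate(ends[order])
        here = (sites["chrom"] == chrom).to_numpy()
        pos0 = sites.loc[here, "pos"].to_numpy() - 1  # BED is 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(pos0), dtype=bool)
        inside[ok] = pos0[ok] < ends[idx[ok]]
        flag[here] = inside
    sites["in_decoy"] = flag
    return sites


def apply_qc(
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    gm: GenotypeMatrix,
    decoy_bed: pd.DataFrame | None = None,
    thresholds: QcThresholds | None = None,
    site_filters_first: bool = False,
) -> tuple[pd.DataFrame, GenotypeMatrix, QcReport]:
    """Run genotype masking then site filtering (order switchable).

    Returns the retained site table, the genotype matrix with failing calls
    masked to missing and failing site rows dropped, and a reconciled report.
    """
    t = thresholds or QcThresholds()
    t.validate()
    if list(gm.sample_ids) != list(samples["sample_id"]):
        raise StructuralError("genotype matrix samples do not match the sample sheet")
    if gm.n_sites != len(sites) or not gm.site_index.equals(pd.Index(sites.index)):
        raise StructuralError("genotype matrix rows do not match the site table")
    for col in _SITE_COLUMNS:
        if col not in sites.columns:
            raise SchemaError(f"site annotation missing required field {col!r}")
        if sites[col].isna().any():
            raise SchemaError(f"site annotation has missing values in field {col!r}")

    report = QcReport(input_sites=len(sites), input_genotypes=int((gm.allele_count >= 0).sum()))
    sites = mark_in_decoy(sites, decoy_bed)
    gm = gm.copy()

    def run_site_filters(sites_in, gm_in):
        miss = cohort_missingness(gm_in)
        keep = np.ones(len(sites_in), dtype=bool)
        reasons = {k: 0 for k in SITE_FILTERS}
        checks = [
            ("ref_callrate", sites_in["pop_call_rate"].to_numpy() < t.min_ref_pop_callrate),
            ("non_pass", ~sites_in["pass_flag"].to_numpy().astype(bool)),
            ("decoy", sites_in["in_decoy"].to_numpy().astype(bool)),
            ("multiallelic", sites_in["n_alleles"].to_numpy() > t.max_alleles),
            ("missingness", miss > t.max_cohort_missingness),
            ("span", sites_in["span_nt"].to_numpy() > t.max_span_nt),
        ]
        undecided = np.ones(len(sites_in), dtype=bool)
        for name, bad in checks:
            hit = undecided & bad
            reasons[name] = int(hit.sum())
            keep &= ~hit
            undecided &= ~hit
        for k, v in reasons.items():
            report.site_removals[k] += v
        report.genotypes_on_removed_sites += int((gm_in.allele_count[~keep] >= 0).sum())
        kept_labels = sites_in.index[keep]
        return sites_in.loc[keep], gm_in.take_sites(kept_labels)

    def run_genotype_filters(gm_in):
        masks = genotype_fail_masks(gm_in, t)
        for name in GENOTYPE_FILTERS:
            report.genotype_removals[name] += int(masks[name].sum())
        fail = np.zeros_like(gm_in.allele_count, dtype=bool)
        for m in masks.values():
            fail |= m
        gm_in.allele_count[fail] = -1
        return gm_in

    if site_filters_first:
        sites, gm = run_site_filters(sites, gm)
        gm = run_genotype_filters(gm)
        # missingness-dependent site filter re-evaluated after masking
        sites, gm = run_site_filters(sites, gm)
    else:
        gm = run_genotype_filters(gm)
        sites, gm = run_site_filters(sites, gm)

    report.retained_sites = len(sites)
    report.retained_genotypes = int((gm.allele_count >= 0).sum())
    return sites, gm, report
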