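"""Synthetic male case/control cohorts with X-linked rare-variant architecture.

This module generates the inputs the burden-test pipeline consumes: a sample
sheet of hemizygous male cases and controls, a table of X-chromosome variant
sites with population-frequency and QC annotations, and noisy genotype calls
(haploid allele count plus DP/GQ/allelic read depths).  The generator emulates
the structure of a critical-pneumonia case/control exome study: 1,202 cases
(age mean 52.9 y, SD 16.4) versus 331 mildly infected controls (age mean
38.7 y, SD 17.2), discrete ancestry strata with stratum-specific common-variant
frequencies (so genotype PCA yields meaningful covariates), a per-gene
rare-variant architecture, and an optionally "planted" gene whose qualifying
variants are carried by an exact number of cases and controls.

Everything is deterministic given ``CohortSpec.seed``; independent seeded
streams are used per component so that, e.g., regenerating genotypes does not
perturb the age draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

CONSEQUENCES = ("lof_annotation", "missense", "inframe_indel", "synonymous", "other")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenotypeNoise:
    """Noise laws for simulated genotype calls.

    Depth is negative-binomial with mean ``dp_mean`` and shape
    ``dp_overdispersion`` (variance = mu + mu^2/shape); GQ is a rounded
    normal clipped to [0, 99].  With probability ``contam_prob`` a call
    receives reads from the non-called allele, with minor-allele read
    fraction drawn from Beta(*contam_beta*); otherwise all reads support
    the called allele, as expected for a clean hemizygous call.
    """

    dp_mean: float = 40.0
    dp_overdispersion: float = 8.0
    gq_mean: float = 70.0
    gq_sd: float = 18.0
    contam_prob: float = 0.03
    contam_beta: tuple[float, float] = (1.5, 6.0)


@dataclass(frozen=True)
class QcFailFractions:
    """Fractions of rare sites given deliberately QC-failing metadata."""

    non_pass: float = 0.03
    low_call_rate: float = 0.03
    decoy: float = 0.02
    multiallelic: float = 0.01
    long_span: float = 0.01


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the study conditions: cohort sizes and age laws from the
    case/control descriptors, a log-uniform rare-variant population-MAF law
    over [1e-6, 1e-2], three ancestry strata, and a planted gene carried by
    21 cases and 0 controls.  Planted case carriers are drawn younger
    (mean 34.4 y) than the cohort at large, matching the observed ages of
    the deleterious-variant patients; this is what makes age adjustment
    informative rather than neutral.
    """

    n_cases: int = 1202
    n_controls: int = 331
    age_case_mean: float = 52.9
    age_case_sd: float = 16.4
    age_control_mean: float = 38.7
    age_control_sd: float = 17.2
    age_min: float = 0.5
    n_strata: int = 3
    stratum_weights: tuple[float, ...] = (0.6, 0.25, 0.15)
    n_genes: int = 40
    variants_per_gene_rate: float = 200.0
    rare_maf_range: tuple[float, float] = (1e-6, 1e-2)
    consequence_probs: tuple[float, ...] = (0.08, 0.55, 0.04, 0.25, 0.08)
    n_common_variants: int = 200
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    planted_gene: str | None = "GENE0001"
    planted_case_carriers: int = 21
    planted_control_carriers: int = 0
    planted_case_age_mean: float = 34.4
    planted_case_age_sd: float = 16.0
    qc_fail_fractions: QcFailFractions = field(default_factory=QcFailFractions)
    genotype_noise: GenotypeNoise = field(default_factory=GenotypeNoise)
    missingness_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigError("n_cases must be >= 0")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        if self.n_strata < 1:
            raise ConfigError("n_strata must be >= 1")
        if len(self.stratum_weights) != self.n_strata:
            raise ConfigError("stratum_weights length must equal n_strata")
        if any(w < 0 for w in self.stratum_weights):
            raise ConfigError("stratum_weights must be non-negative")
        if abs(sum(self.stratum_weights) - 1.0) > 1e-12:
            raise ConfigError("stratum_weights must sum to 1 within 1e-12")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if self.variants_per_gene_rate < 0:
            raise ConfigError("variants_per_gene_rate must be >= 0")
        lo, hi = self.rare_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("rare_maf_range bounds must satisfy 0 < lo <= hi < 1")
        if len(self.consequence_probs) != len(CONSEQUENCES):
            raise ConfigError("consequence_probs must have one entry per consequence class")
        if abs(sum(self.consequence_probs) - 1.0) > 1e-9:
            raise ConfigError("consequence_probs must sum to 1")
        if self.planted_case_carriers < 0 or self.planted_case_carriers > self.n_cases:
            raise ConfigError("planted_case_carriers must be in [0, n_cases]")
        if self.planted_control_carriers < 0 or self.planted_control_carriers > self.n_controls:
            raise ConfigError("planted_control_carriers must be in [0, n_controls]")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ConfigError("missingness_rate must be in [0, 1]")


class GenotypeCall(NamedTuple):
    """One sample-by-variant hemizygous call (scalar QC-filter API)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_count: int  # 0, 1, or -1 for missing
    depth: int
    genotype_quality: int
    ref_reads: int
    alt_reads: int


@dataclass
class GenotypeMatrix:
    """Columnar store of hemizygous genotype calls (sites x samples).

    ``allele_count`` uses -1 for missing.  Rows align with the site table the
    matrix was generated against (``site_index`` holds those row labels);
    columns align with ``sample_ids``.
    """

    sample_ids: list[str]
    site_index: pd.Index
    allele_count: np.ndarray  # int8
    depth: np.ndarray  # int32
    gq: np.ndarray  # int16
    ref_reads: np.ndarray  # int32
    alt_reads: np.ndarray  # int32

    @property
    def n_sites(self) -> int:
        return self.allele_count.shape[0]

    @property
    def n_samples(self) -> int:
        return self.allele_count.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.site_index.copy(),
            self.allele_count.copy(),
            self.depth.copy(),
            self.gq.copy(),
            self.ref_reads.copy(),
            self.alt_reads.copy(),
        )

    def take_sites(self, row_labels) -> "GenotypeMatrix":
        """Subset to the site rows with the given labels, preserving order."""
        pos = self.site_index.get_indexer(row_labels)
        if (pos < 0).any():
            raise KeyError("unknown site labels in take_sites")
        return GenotypeMatrix(
            list(self.sample_ids),
            pd.Index(row_labels),
            self.allele_count[pos],
            self.depth[pos],
            self.gq[pos],
            self.ref_reads[pos],
            self.alt_reads[pos],
        )

    def call(self, i: int, j: int, sites: pd.DataFrame) -> GenotypeCall:
        """Materialize one call as a GenotypeCall record."""
        row = sites.loc[self.site_index[i]]
        return GenotypeCall(
            self.sample_ids[j],
            str(row["chrom"]),
            int(row["pos"]),
            str(row["ref"]),
            str(row["alt"]),
            int(self.allele_count[i, j]),
            int(self.depth[i, j]),
            int(self.gq[i, j]),
            int(self.ref_reads[i, j]),
            int(self.alt_reads[i, j]),
        )


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def planted_case_ids(spec: CohortSpec) -> list[str]:
    """Case sample ids planted as carriers, in seeded-shuffle order.

    Shared between :func:`generate_cohort` (which draws these samples' ages
    from the younger carrier-age law) and :func:`generate_genotypes` (which
    assigns their qualifying variants), so the two stages agree without
    passing state.
    """
    if spec.planted_gene is None or spec.planted_case_carriers == 0:
        return []
    order = _rng(spec, 10).permutation(spec.n_cases)
    return [f"CASE{i + 1:05d}" for i in order[: spec.planted_case_carriers]]


def planted_control_ids(spec: CohortSpec) -> list[str]:
    if spec.planted_gene is None or spec.planted_control_carriers == 0:
        return []
    order = _rng(spec, 11).permutation(spec.n_controls)
    return [f"CTRL{i + 1:05d}" for i in order[: spec.planted_control_carriers]]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    a = (lower - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the sample sheet: sample_id, phenotype, age, stratum.

    Ages are truncated normals (lower bound ``age_min``, 0.5 y by default, the
    youngest patient age); strata are drawn from ``stratum_weights`` and are
    independent of phenotype.  Planted case carriers get ages from the
    carrier-age law instead of the cohort-wide case law.
    """
    spec.validate()
    rng = _rng(spec, 0)
    n = spec.n_cases + spec.n_controls
    sample_id = [f"CASE{i + 1:05d}" for i in range(spec.n_cases)] + [
        f"CTRL{i + 1:05d}" for i in range(spec.n_controls)
    ]
    phenotype = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    age = np.concatenate(
        [
            _truncnorm(rng, spec.age_case_mean, spec.age_case_sd, spec.age_min, spec.n_cases),
            _truncnorm(rng, spec.age_control_mean, spec.age_control_sd, spec.age_min, spec.n_controls),
        ]
    )
    stratum = rng.choice(spec.n_strata, size=n, p=list(spec.stratum_weights))
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "phenotype": phenotype,
            "age": np.round(age, 3),
            "stratum": [f"S{k + 1}" for k in stratum],
        }
    )
    carriers = planted_case_ids(spec)
    if carriers:
        rng_age = _rng(spec, 12)
        ages = _truncnorm(
            rng_age, spec.planted_case_age_mean, spec.planted_case_age_sd, spec.age_min, len(carriers)
        )
        df.loc[df["sample_id"].isin(carriers), "age"] = np.round(ages, 3)
    return df


def _gene_names(n_genes: int) -> list[str]:
    return [f"GENE{g + 1:04d}" for g in range(n_genes)]


def generate_variant_sites(spec: CohortSpec) -> pd.DataFrame:
    """Generate the variant-site table (rare burden sites + common PCA sites).

    Rare sites: per-gene counts are Poisson(``variants_per_gene_rate``),
    population MAF is log-uniform over ``rare_maf_range``, consequence classes
    follow ``consequence_probs``, and a configurable fraction of sites gets
    QC-failing metadata (non-PASS, reference call rate < 50%, decoy overlap,
    > 4 alleles, span > 20 nt) so every site-level filter sees work.  The
    planted gene's sites are kept QC-clean so planted carrier counts survive
    filtering exactly.

    Common sites (``consequence == "other"``, MAF in ``common_maf_range``)
    carry stratum-specific allele frequencies (Balding-Nichols with the given
    Fst) in ``stratum_freq_*`` columns; they feed the ancestry PCA and never
    qualify for the burden test.
    """
    spec.validate()
    if spec.n_genes < 1:
        raise ConfigError("n_genes must be >= 1 to generate variant sites")
    rng = _rng(spec, 1)
    genes = _gene_names(spec.n_genes)
    if spec.planted_gene is not None and spec.planted_gene not in genes:
        raise ConfigError(f"planted_gene {spec.planted_gene!r} not among generated genes")

    counts = rng.poisson(spec.variants_per_gene_rate, size=spec.n_genes)
    if spec.planted_gene is not None:
        # guarantee the planted gene has qualifying (very rare, non-synonymous) sites
        counts[genes.index(spec.planted_gene)] = max(counts[genes.index(spec.planted_gene)], 6)
    rows = []
    lo, hi = spec.rare_maf_range
    for g, gene in enumerate(genes):
        m = counts[g]
        if m == 0:
            continue
        base = 1_000_000 + g * 100_000
        offsets = np.sort(rng.choice(np.arange(1, 99_000), size=m, replace=False))
        maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        cons = rng.choice(len(CONSEQUENCES), size=m, p=list(spec.consequence_probs))
        if gene == spec.planted_gene:
            # force >= 4 very rare missense sites among the gene's variants
            force = rng.choice(m, size=min(4, m), replace=False)
            maf[force] = np.exp(rng.uniform(np.log(lo), np.log(1e-4 * 0.99), size=len(force)))
            cons[force] = CONSEQUENCES.index("missense")
        for i in range(m):
            rows.append(
                {
                    "chrom": "chrX",
                    "pos": int(base + offsets[i]),
                    "gene": gene,
                    "consequence": CONSEQUENCES[cons[i]],
                    "pop_maf": float(maf[i]),
                    "is_common": False,
                }
            )
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "gene", "consequence", "pop_maf", "is_common"]
    )
    n_rare = len(sites)

    # QC-failing metadata, defaults first
    sites["pop_call_rate"] = rng.uniform(0.90, 1.0, size=n_rare)
    sites["pass_flag"] = True
    sites["n_alleles"] = 2
    sites["span_nt"] = 1
    sites["in_decoy"] = False
    ff = spec.qc_fail_fractions
    protect = (
        (sites["gene"] == spec.planted_gene).to_numpy()
        if spec.planted_gene is not None
        else np.zeros(n_rare, dtype=bool)
    )
    for frac, col, values in [
        (ff.non_pass, "pass_flag", False),
        (ff.decoy, "in_decoy", True),
    ]:
        hit = (rng.uniform(size=n_rare) < frac) & ~protect
        sites.loc[hit, col] = values
    hit = (rng.uniform(size=n_rare) < ff.low_call_rate) & ~protect
    sites.loc[hit, "pop_call_rate"] = rng.uniform(0.10, 0.499, size=int(hit.sum()))
    hit = (rng.uniform(size=n_rare) < ff.multiallelic) & ~protect
    sites.loc[hit, "n_alleles"] = rng.integers(5, 8, size=int(hit.sum()))
    hit = (rng.uniform(size=n_rare) < ff.long_span) & ~protect
    sites.loc[hit, "span_nt"] = rng.integers(21, 51, size=int(hit.sum()))

    # alleles: SNVs except long-span records, written as deletions
    ref = rng.choice(_BASES, size=n_rare)
    alt = rng.choice(_BASES, size=n_rare)
    alt = np.where(alt == ref, np.char.add("", np.where(ref == "A", "G", "A")), alt)
    refs, alts = [], []
    for i in range(n_rare):
        span = int(sites["span_nt"].iloc[i])
        if span > 1:
            tail = "".join(rng.choice(_BASES, size=span - 1))
            refs.append(str(ref[i]) + tail)
            alts.append(str(ref[i]))
        else:
            refs.append(str(ref[i]))
            alts.append(str(alt[i]))
    sites["ref"] = refs
    sites["alt"] = alts

    # common variants for ancestry PCA, spread across genes
    if spec.n_common_variants > 0:
        rng_c = _rng(spec, 2)
        lo_c, hi_c = spec.common_maf_range
        p_global = rng_c.uniform(lo_c, hi_c, size=spec.n_common_variants)
        f = spec.fst
        if f > 0:
            a = p_global * (1 - f) / f
            b = (1 - p_global) * (1 - f) / f
            p_strata = rng_c.beta(a[:, None], b[:, None], size=(spec.n_common_variants, spec.n_strata))
        else:
            p_strata = np.repeat(p_global[:, None], spec.n_strata, axis=1)
        gene_of = [genes[i % spec.n_genes] for i in range(spec.n_common_variants)]
        base_of = [1_000_000 + (i % spec.n_genes) * 100_000 for i in range(spec.n_common_variants)]
        pos_c = [base + 99_000 + 1 + i // spec.n_genes for i, base in enumerate(base_of)]
        ref_c = rng_c.choice(_BASES, size=spec.n_common_variants)
        common = pd.DataFrame(
            {
                "chrom": "chrX",
                "pos": pos_c,
                "gene": gene_of,
                "consequence": "other",
                "pop_maf": p_global,
                "is_common": True,
                "pop_call_rate": rng_c.uniform(0.95, 1.0, size=spec.n_common_variants),
                "pass_flag": True,
                "n_alleles": 2,
                "span_nt": 1,
                "in_decoy": False,
                "ref": ref_c,
                "alt": np.where(ref_c == "A", "G", "A"),
            }
        )
        for k in range(spec.n_strata):
            sites[f"stratum_freq_{k}"] = np.nan
            common[f"stratum_freq_{k}"] = p_strata[:, k]
        sites = pd.concat([sites, common], ignore_index=True)

    sites["male_maf"] = sites["pop_maf"]
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "consequence", "pop_maf", "male_maf",
        "pop_call_rate", "pass_flag", "n_alleles", "span_nt", "in_decoy", "is_common",
    ]
    cols += [c for c in sites.columns if c.startswith("stratum_freq_")]
    return sites[cols]


def qualifying_site_mask(sites: pd.DataFrame, max_pop_maf: float = 1e-4) -> np.ndarray:
    """Truth-level qualifying mask used when planting carriers."""
    nonsyn = sites["consequence"].isin(["lof_annotation", "missense", "inframe_indel"])
    return (nonsyn & (sites["pop_maf"] < max_pop_maf)).to_numpy()


def generate_genotypes(
    samples: pd.DataFrame, sites: pd.DataFrame, spec: CohortSpec
) -> GenotypeMatrix:
    """Draw hemizygous genotype calls with read-level noise.

    Background carrier status at each rare site is one Bernoulli(pop_maf) draw
    per male; common sites use the sample's stratum-specific frequency.  For
    the planted gene, background carriers at its qualifying sites are cleared
    and exactly the planted case/control carriers are assigned one qualifying
    site each (uniform choice).  DP, GQ and allelic reads follow
    ``spec.genotype_noise``; planted carrier calls are generated clean so they
    survive genotype-level QC.
    """
    spec.validate()
    if spec.planted_gene is not None and len(sites) and spec.planted_gene not in set(sites["gene"]):
        raise ConfigError(f"planted_gene {spec.planted_gene!r} absent from sites")
    n_sites, n_samples = len(sites), len(samples)
    rng = _rng(spec, 3)
    sample_ids = list(samples["sample_id"])

    ac = np.zeros((n_sites, n_samples), dtype=np.int8)
    if n_sites and n_samples:
        maf = sites["pop_maf"].to_numpy()
        u = rng.uniform(size=(n_sites, n_samples))
        ac[:] = (u < maf[:, None]).astype(np.int8)
        common = sites["is_common"].to_numpy() if "is_common" in sites else np.zeros(n_sites, bool)
        freq_cols = [c for c in sites.columns if c.startswith("stratum_freq_")]
        if common.any() and freq_cols:
            strata = pd.Categorical(samples["stratum"]).codes
            pf = sites.loc[common, freq_cols].to_numpy()  # (n_common, n_strata)
            thr = pf[:, strata]  # (n_common, n_samples)
            ac[common] = (u[common] < thr).astype(np.int8)

    planted_rows = np.zeros(0, dtype=int)
    if spec.planted_gene is not None and n_sites:
        qual = qualifying_site_mask(sites) & (sites["gene"] == spec.planted_gene).to_numpy()
        planted_rows = np.flatnonzero(qual)
        if len(planted_rows) == 0:
            raise ConfigError("planted gene has no qualifying sites")
        ac[planted_rows] = 0
        rng_p = _rng(spec, 4)
        col_of = {s: j for j, s in enumerate(sample_ids)}
        for sid in planted_case_ids(spec) + planted_control_ids(spec):
            if sid in col_of:
                ac[rng_p.choice(planted_rows), col_of[sid]] = 1

    noise = spec.genotype_noise
    r = noise.dp_overdispersion
    # common (PCA) sites are kept cleaner than the rare-site background: the
    # analysis selects call-rate > 0.99 variants, which real capture data has
    # in abundance only among well-behaved common sites
    common_rows = (
        sites["is_common"].to_numpy().astype(bool)
        if "is_common" in sites
        else np.zeros(n_sites, dtype=bool)
    )
    contam_p = np.where(common_rows, min(noise.contam_prob, 0.004), noise.contam_prob)
    miss_p = np.where(common_rows, min(spec.missingness_rate, 0.003), spec.missingness_rate)
    dp = rng.negative_binomial(r, r / (r + noise.dp_mean), size=(n_sites, n_samples)).astype(np.int32)
    gq_raw = np.rint(rng.normal(noise.gq_mean, noise.gq_sd, size=(n_sites, n_samples)))
    gq_raw[common_rows] += 15
    gq = np.clip(gq_raw, 0, 99).astype(np.int16)
    contam = rng.uniform(size=(n_sites, n_samples)) < contam_p[:, None]
    minor = np.zeros((n_sites, n_samples), dtype=np.int32)
    hit = np.nonzero(contam)
    if hit[0].size:
        frac = rng.beta(*noise.contam_beta, size=hit[0].size)
        minor[hit] = rng.binomial(dp[hit], frac)
    major = dp - minor
    alt_reads = np.where(ac == 1, major, minor).astype(np.int32)
    ref_reads = np.where(ac == 1, minor, major).astype(np.int32)

    missing = rng.uniform(size=(n_sites, n_samples)) < miss_p[:, None]

    if len(planted_rows):
        carrier_cols = np.flatnonzero(ac[planted_rows].max(axis=0) == 1)
        for j in carrier_cols:
            i = planted_rows[np.flatnonzero(ac[planted_rows, j] == 1)]
            dp[i, j] = np.maximum(dp[i, j], 20)
            gq[i, j] = np.maximum(gq[i, j], 40)
            alt_reads[i, j] = dp[i, j]
            ref_reads[i, j] = 0
            missing[i, j] = False

    ac[missing] = -1
    return GenotypeMatrix(
        sample_ids,
        pd.Index(sites.index),
        ac,
        dp,
        gq,
        ref_reads,
        alt_reads,
    )


def generate_all(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]:
    """Convenience wrapper: cohort, sites and genotypes in one call."""
    samples = generate_cohort(spec)
    sites = generate_variant_sites(spec)
    genotypes = generate_genotypes(samples, sites, spec)
    return samples, sites, genotypes


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same study conditions with no planted gene (null cohort)."""
    return replace(spec, planted_gene=None, planted_case_carriers=0, planted_control_carriers=0)
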