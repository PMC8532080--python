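"""End-to-end orchestration: simulate -> qc -> select -> pca -> burden -> summarize.

Each stage is a pure function of its inputs plus the config; a run writes the
stage outputs as TSVs together with a machine-readable JSON report, and
identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .cohort import CohortSpec, GenotypeNoise, QcFailFractions
from .errors import ConfigError, SchemaError, StructuralError
from .firth import FirthOptions, bonferroni, test_all_genes
from .pca import PcaThresholds, compute_pcs, load_pc_scores, select_pca_variants
from .qc import QcThresholds, apply_qc
from .qualify import SelectionRule, collapse_carriers, gene_test_eligibility, select_qualifying
from .summaries import cohort_summaries

log = logging.getLogger("xburden")


@dataclass
class PipelineConfig:
    # input files; leave unset to simulate a cohort from `spec`
    vcf: str | None = None
    annotation: str | None = None
    samples: str | None = None
    decoy_bed: str | None = None
    pc_scores: str | None = None  # precomputed-PC hook
    simulate: bool = True
    spec: CohortSpec = field(default_factory=CohortSpec)
    qc: QcThresholds = field(default_factory=QcThresholds)
    selection: SelectionRule = field(default_factory=SelectionRule)
    pca: PcaThresholds = field(default_factory=PcaThresholds)
    n_pcs: int = 5
    firth: FirthOptions = field(default_factory=FirthOptions)
    alpha: float = 0.05
    min_case_carriers: int = 5
    control_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_case_carriers < 0:
            raise ConfigError("min_case_carriers must be >= 0")
        if self.n_pcs < 0:
            raise ConfigError("n_pcs must be >= 0")
        self.qc.validate()
        self.selection.validate()
        self.pca.validate()
        if not self.simulate:
            for name in ("vcf", "annotation", "samples"):
                if getattr(self, name) is None:
                    raise ConfigError(f"input path {name!r} required when simulate is off")


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            sub = {}
            for k, v in value.items():
                if k not in {f.name for f in dataclasses.fields(current)}:
                    raise ConfigError(f"unknown config key {key}.{k}")
                fld = next(f for f in dataclasses.fields(current) if f.name == k)
                if isinstance(v, list):
                    v = tuple(v)
                if k == "genotype_noise" and isinstance(v, dict):
                    v = GenotypeNoise(**v)
                if k == "qc_fail_fractions" and isinstance(v, dict):
                    v = QcFailFractions(**v)
                if k == "included_consequences":
                    v = frozenset(v)
                sub[k] = v
            setattr(cfg, key, dataclasses.replace(current, **sub))
        else:
            setattr(cfg, key, value)
    return cfg


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Collect all input-schema errors without raising."""
    errors: list[str] = []
    try:
        config.validate()
    except ConfigError as e:
        errors.append(str(e))
        return errors
    if config.simulate:
        try:
            config.spec.validate()
        except ConfigError as e:
            errors.append(f"spec: {e}")
        return errors
    for name in ("vcf", "annotation", "samples", "decoy_bed"):
        p = getattr(config, name)
        if p is not None and not os.path.exists(p):
            errors.append(f"{name}: file not found: {p}")
    if errors:
        return errors

    samples = sites = gm = None
    try:
        samples = xio.read_sample_sheet(config.samples)
    except SchemaError as e:
        errors.append(str(e))
    try:
        sites = xio.read_annotation(config.annotation)
    except SchemaError as e:
        errors.append(str(e))
    try:
        vcf_sites, gm = xio.read_vcf(config.vcf)
    except Exception as e:  # cyvcf2 raises plain Exception on malformed headers
        errors.append(f"vcf: {e}")
        vcf_sites = None
    if config.decoy_bed:
        try:
            xio.read_bed(config.decoy_bed)
        except SchemaError as e:
            errors.append(str(e))

    if samples is not None and gm is not None:
        sheet_ids = set(samples["sample_id"])
        for sid in gm.sample_ids:
            if sid not in sheet_ids:
                errors.append(f"VCF sample {sid!r} absent from sample sheet")
    if sites is not None and vcf_sites is not None and len(sites) != len(vcf_sites):
        errors.append("annotation and VCF record counts differ")
    if sites is not None:
        bad = sites[(sites["pop_maf"] < 0) | (sites["pop_maf"] > 1)]
        for _, row in bad.iterrows():
            errors.append(f"annotation: pop_maf out of range at {row['chrom']}:{row['pos']}")
        bad = sites[(sites["pop_call_rate"] < 0) | (sites["pop_call_rate"] > 1)]
        for _, row in bad.iterrows():
            errors.append(f"annotation: pop_call_rate out of range at {row['chrom']}:{row['pos']}")
    if samples is not None:
        if (samples["age"] <= 0).any():
            errors.append("sample sheet: non-positive age")
        if not samples["phenotype"].isin(["case", "control"]).all():
            errors.append("sample sheet: phenotype must be case/control")
    return errors


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages; writes outputs under out_dir and returns the report."""
    t0 = time.time()
    config.validate()
    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    report: dict = {"config": _config_echo(config), "seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t": round(time.time() - t0, 2)}
        return report["stages"][name]

    rec = stage("load")
    if config.simulate:
        from .cohort import generate_all

        spec = dataclasses.replace(config.spec, seed=config.seed)
        samples, sites, gm = generate_all(spec)
        xio.write_cohort(out / "cohort", samples, sites, gm)
        decoy = xio.decoy_bed_from_sites(sites)
    else:
        errs = validate_inputs(config)
        if errs:
            raise SchemaError("; ".join(errs))
        samples, sites, gm, decoy = xio.read_cohort(
            {
                "vcf": config.vcf,
                "annotation": config.annotation,
                "samples": config.samples,
                "decoy_bed": config.decoy_bed,
            }
        )
    rec.update(n_samples=len(samples), n_sites=len(sites))

    rec = stage("qc")
    sites_f, gm_f, qc_report = apply_qc(samples, sites, gm, decoy, config.qc)
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    rec.update(retained_sites=qc_report.retained_sites, retained_genotypes=qc_report.retained_genotypes)

    rec = stage("select")
    rule = dataclasses.replace(config.selection, control_mode=config.control_mode)
    qual = select_qualifying(sites_f, rule)
    cm = collapse_carriers(gm_f, qual, samples, all_genes=sorted(sites_f["gene"].unique()))
    cm.counts.assign(
        eligible=cm.counts["gene"].isin(gene_test_eligibility(cm, config.min_case_carriers))
    ).to_csv(out / "carrier_counts.tsv", sep="\t", index=False)
    cm.indicators.to_csv(out / "carrier_matrix.tsv", sep="\t")
    rec.update(qualifying_sites=len(qual), genes=len(cm.genes))

    rec = stage("pca")
    if config.pc_scores:
        pcs = load_pc_scores(config.pc_scores)
    else:
        pca_matrix = select_pca_variants(sites_f, gm_f, config.pca)
        pcs = compute_pcs(pca_matrix, k=config.n_pcs)
    pcs.scores.round(6).to_csv(out / "pc_scores.tsv", sep="\t")
    rec.update(n_pcs=int(pcs.k))

    rec = stage("burden")
    covariates = pcs.scores.copy()
    covariates["age"] = samples.set_index("sample_id")["age"]
    results = test_all_genes(cm, covariates, samples, config.min_case_carriers, config.firth)
    threshold, results = bonferroni(results, config.alpha)
    results.to_csv(out / "burden_results.tsv", sep="\t", index=False, float_format="%.6g")
    top = results.iloc[0]
    rec.update(
        n_eligible=int(results["eligible"].sum()),
        bonferroni_threshold=threshold,
        top_gene=str(top["gene"]),
        top_p=float(top["p_value"]),
    )

    rec = stage("summarize")
    top_flags = cm.indicators.loc[top["gene"]] if len(cm.genes) else pd.Series(dtype=int)
    summary = cohort_summaries(samples, top_flags)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

    report["n_eligible"] = int(results["eligible"].sum())
    report["bonferroni_threshold"] = threshold
    report["top_genes"] = results.head(10)[
        ["gene", "case_carriers", "control_carriers", "beta_carrier", "p_value", "p_corrected"]
    ].to_dict("records")
    report["success"] = True
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return enc(config)
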