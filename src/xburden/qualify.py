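"""Qualifying-variant selection and gene-level carrier collapsing.

A variant qualifies for the primary burden analysis if it is non-synonymous
(loss-of-function annotation, missense, or in-frame indel) and very rare:
population MAF strictly below 1e-4, with variants absent from the reference
population (MAF recorded as 0, "private") qualifying.  The negative-control
analysis applies the same frequency cut to synonymous variants instead.

Collapsing is binary: a sample carries a gene's burden if it has at least one
qualifying variant allele in that gene (a carrier with two qualifying variants
counts once).  A CMC-style allele-count collapse is available via ``mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .errors import ConfigError, StructuralError

NON_SYNONYMOUS = frozenset({"lof_annotation", "missense", "inframe_indel"})


@dataclass(frozen=True)
class SelectionRule:
    max_pop_maf: float = 1e-4
    included_consequences: frozenset = field(default_factory=lambda: NON_SYNONYMOUS)
    control_mode: bool = False

    def validate(self) -> None:
        if not 0.0 < self.max_pop_maf < 1.0:
            raise ConfigError("max_pop_maf must be in (0, 1)")
        if not self.control_mode:
            if not self.included_consequences:
                raise ConfigError("included_consequences must be non-empty")
            if "synonymous" in self.included_consequences:
                raise ConfigError("synonymous consequences require control_mode")

    @property
    def consequences(self) -> frozenset:
        return frozenset({"synonymous"}) if self.control_mode else frozenset(self.included_consequences)


@dataclass
class CarrierMatrix:
    """Genes x samples binary indicators plus per-gene counts by phenotype."""

    indicators: pd.DataFrame  # index: gene, columns: sample_id, values {0,1} (or counts)
    counts: pd.DataFrame  # gene, case_carriers, control_carriers
    omitted_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.indicators.index)


def select_qualifying(sites: pd.DataFrame, rule: SelectionRule | None = None) -> pd.DataFrame:
    """Subset a QC-passed site table to the qualifying variants."""
    rule = rule or SelectionRule()
    rule.validate()
    mask = sites["consequence"].isin(rule.consequences) & (sites["pop_maf"] < rule.max_pop_maf)
    return sites.loc[mask]


def collapse_carriers(
    gm: GenotypeMatrix,
    qualifying_sites: pd.DataFrame,
    samples: pd.DataFrame,
    mode: str = "binary",
    all_genes: list[str] | None = None,
) -> CarrierMatrix:
    """Collapse qualifying variants to per-sample, per-gene carrier indicators.

    Samples whose calls at all of a gene's qualifying sites are missing get
    indicator 0 (conservative non-carrier).  Genes with zero qualifying
    variants are omitted from the matrix; pass ``all_genes`` to have them
    listed in ``CarrierMatrix.omitted_genes``.
    """
    if mode not in ("binary", "count"):
        raise ConfigError("mode must be 'binary' or 'count'")
    if list(gm.sample_ids) != list(samples["sample_id"]):
        raise StructuralError("genotype matrix samples do not match the sample sheet")
    pheno = samples["phenotype"].to_numpy()
    is_case = pheno == "case"

    labels = qualifying_sites.index
    known = gm.site_index.get_indexer(labels)
    if (known < 0).any():
        raise StructuralError("qualifying sites missing from the genotype matrix")

    genes = sorted(qualifying_sites["gene"].unique())
    rows = np.zeros((len(genes), gm.n_samples), dtype=np.int32)
    for gi, gene in enumerate(genes):
        gl = qualifying_sites.index[qualifying_sites["gene"] == gene]
        # duplicated site records collapse to one row: carrier status is a max
        gl = gl.unique()
        pos = gm.site_index.get_indexer(gl)
        calls = gm.allele_count[pos]
        carried = calls == 1
        rows[gi] = carried.sum(axis=0) if mode == "count" else carried.any(axis=0)
    if mode == "binary":
        rows = rows.astype(np.int8)
    indicators = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=gm.sample_ids)
    carrier = indicators.to_numpy() > 0
    counts = pd.DataFrame(
        {
            "gene": genes,
            "case_carriers": carrier[:, is_case].sum(axis=1),
            "control_carriers": carrier[:, ~is_case].sum(axis=1),
        }
    )
    omitted = sorted(set(all_genes) - set(genes)) if all_genes is not None else []
    return CarrierMatrix(indicators=indicators, counts=counts, omitted_genes=omitted)


def gene_test_eligibility(
    carrier_matrix: CarrierMatrix,
    min_case_carriers: int = 5,
    count_pooled: bool = False,
) -> list[str]:
    """Genes with at least ``min_case_carriers`` case carriers (the Bonferroni set).

    ``count_pooled`` switches to counting carriers in cases + controls.
    """
    c = carrier_matrix.counts
    n = c["case_carriers"] + (c["control_carriers"] if count_pooled else 0)
    return list(c.loc[n >= min_case_carriers, "gene"])
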