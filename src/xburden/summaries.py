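"""Functional allele classification and descriptive cohort summaries.

Alleles assayed in an NF-kB reporter system (activity expressed as % of the
stimulated wild type) are classified as loss-of-function (activity at or
below ``lof_max``, default 5% — indistinguishable from empty vector),
hypomorphic (above ``lof_max`` but strictly below 25% of wild type), or
neutral.  The cumulative minor allele frequency of a deleterious allele set
in males approximates the hemizygote frequency, since one allele suffices on
the male X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

STIMULATED_CONDITIONS = ("R848", "imiquimod", "CL264")
WT_ALLELE = "WT"


@dataclass(frozen=True)
class ClassificationRule:
    hypomorphic_max: float = 0.25  # fraction of WT, strict upper bound
    lof_max: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.lof_max <= self.hypomorphic_max < 1.0:
            raise ConfigError("need 0 <= lof_max <= hypomorphic_max < 1")


def classify_allele(
    records: pd.DataFrame,
    allele: str,
    rule: ClassificationRule | None = None,
) -> str:
    """Classify one allele from its reporter-activity records.

    ``records`` holds columns allele, condition, replicate, activity_pct_wt
    for at least the allele of interest and the wild type.  Replicates under
    stimulated conditions are aggregated by mean; activity is taken relative
    to the wild-type mean under the same conditions (which re-anchors 100%
    per batch, making classification invariant to raw luminescence units).
    """
    rule = rule or ClassificationRule()
    rule.validate()
    stim = records[records["condition"].isin(STIMULATED_CONDITIONS)]
    mine = stim[stim["allele"] == allele]
    wt = stim[stim["allele"] == WT_ALLELE]
    if mine.empty:
        raise ConfigError(f"no stimulated-condition records for allele {allele!r}")
    if wt.empty:
        raise ConfigError("no stimulated-condition records for the wild-type reference")
    frac = float(mine["activity_pct_wt"].mean()) / float(wt["activity_pct_wt"].mean())
    if frac <= rule.lof_max:
        return "LOF"
    if frac < rule.hypomorphic_max:
        return "hypomorphic"
    return "neutral"


def classify_all(records: pd.DataFrame, rule: ClassificationRule | None = None) -> pd.Series:
    alleles = [a for a in records["allele"].unique() if a != WT_ALLELE]
    return pd.Series(
        {a: classify_allele(records, a, rule) for a in alleles}, name="class"
    )


def cumulative_maf(alleles, freq_table: pd.DataFrame) -> float:
    """Sum of male MAFs over an allele set (hemizygote-frequency estimate).

    ``freq_table`` holds allele, male_allele_count, male_allele_number (the
    male MAF is count/number) or a precomputed male_maf column.
    """
    alleles = list(alleles)
    ft = freq_table.set_index("allele") if "allele" in freq_table.columns else freq_table
    missing = [a for a in alleles if a not in ft.index]
    if missing:
        raise ConfigError(f"alleles missing from the frequency table: {missing}")
    if not alleles:
        return 0.0
    if "male_maf" in ft.columns:
        freqs = ft.loc[alleles, "male_maf"].astype(float)
    else:
        sub = ft.loc[alleles]
        if (sub["male_allele_count"] > sub["male_allele_number"]).any():
            raise ConfigError("male_allele_count exceeds male_allele_number")
        freqs = sub["male_allele_count"] / sub["male_allele_number"]
    return float(freqs.sum())


def deleterious_alleles(classes: pd.Series, include_hypomorphic: bool = True) -> list[str]:
    """Allele set for cumulative-MAF summaries (LOF, optionally + hypomorphic)."""
    allowed = {"LOF"} | ({"hypomorphic"} if include_hypomorphic else set())
    return list(classes.index[classes.isin(allowed)])


def proportion_pct(count: int, total: int) -> float:
    """count/total as a percentage rounded to one decimal (report formatting)."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, 1)


def cohort_summaries(
    samples: pd.DataFrame,
    carrier_flags: pd.Series,
    by: str = "phenotype",
) -> pd.DataFrame:
    """Per-group carrier counts/proportions and age statistics.

    ``carrier_flags`` is indexed by sample_id.  Groups with no members report
    missing proportions.  Proportions are rounded to one decimal of percent
    (underlying counts are exact); ages are summarized by mean, SD and range.
    """
    df = samples.copy()
    df["carrier"] = df["sample_id"].map(carrier_flags).fillna(0).astype(int)
    groups = [("all", df)] + [(str(g), sub) for g, sub in df.groupby(by)]
    rows = []
    for name, sub in groups:
        n = len(sub)
        carriers = int(sub["carrier"].sum())
        ages = sub["age"]
        carrier_ages = sub.loc[sub["carrier"] == 1, "age"]
        rows.append(
            {
                "group": name,
                "n": n,
                "carriers": carriers,
                "carrier_pct": proportion_pct(carriers, n),
                "age_mean": round(float(ages.mean()), 1) if n else float("nan"),
                "age_sd": round(float(ages.std(ddof=1)), 1) if n > 1 else float("nan"),
                "age_min": float(ages.min()) if n else float("nan"),
                "age_max": float(ages.max()) if n else float("nan"),
                "carrier_age_mean": round(float(carrier_ages.mean()), 1) if carriers else float("nan"),
            }
        )
    return pd.DataFrame(rows)
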