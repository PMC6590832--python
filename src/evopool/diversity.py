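"""Per-line nucleotide diversity from pooled variant tables.

The diversity measure is expected heterozygosity at called variant sites:
pi = p (1 - p) per locus, summed over a line's variant loci after
filtering (coverage window, minimum variant count, minimum variant-allele
frequency, autosome restriction) and after excluding loci that are fixed
for the non-reference allele in every line.  Line totals are normalised
to the mean of the outbred control lines for cross-group comparison.
A pairwise two-sample Kolmogorov-Smirnov diagnostic checks that read
coverage is comparably distributed across treatment groups, which is the
precondition for comparing summed pi across groups at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiversityEstimate",
    "read_variant_tsv",
    "read_variant_vcf",
    "filter_variants",
    "remove_cross_sample_monomorphic",
    "nucleotide_diversity",
    "relative_pi",
    "diversity_table",
    "coverage_ks_diagnostic",
]

AUTOSOMES = frozenset({"2", "3", "4"})
VARIANT_COLUMNS = ["chrom", "pos", "coverage", "variant_count", "frequency"]


@dataclass
class DiversityEstimate:
    """Summed pi for one line."""

    line_id: str
    n_snps: int
    pi_sum: float
    pi_relative: float | None = None


def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-line variant table (chrom, pos, coverage, variant_count[, frequency])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "coverage", "variant_count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    # counts are authoritative; recompute frequency to avoid rounding drift
    df["frequency"] = np.where(
        df["coverage"] > 0, df["variant_count"] / df["coverage"], 0.0
    )
    return df[VARIANT_COLUMNS]


def read_variant_vcf(path: str | Path, sample: str | int = 0) -> pd.DataFrame:
    """Minimal VCF ingestion: DP as coverage, first ALT's AD as variant count."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            samp = rec.samples[sample]
            ad = samp.get("AD")
            dp = samp.get("DP")
            if dp is None and ad is not None:
                dp = int(sum(a for a in ad if a is not None))
            if ad is None or dp is None or dp == 0:
                continue
            var = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
            rows.append((rec.chrom.removeprefix("chr"), rec.pos, int(dp), var))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "coverage", "variant_count"])
    df["frequency"] = np.where(df["coverage"] > 0, df["variant_count"] / df["coverage"], 0.0)
    return df


def _validate(records: pd.DataFrame) -> None:
    bad = records.index[records["variant_count"] > records["coverage"]]
    if len(bad):
        raise ValueError(
            f"variant_count exceeds coverage at row(s) {list(bad[:5])}"
        )


def filter_variants(
    records: pd.DataFrame,
    min_cov: int = 10,
    max_cov: int = 600,
    min_count: int = 1,
    min_freq: float = 0.10,
    autosomes: Iterable[str] = AUTOSOMES,
) -> pd.DataFrame:
    """Apply the variant-calling retention rules.

    Keeps records on the listed autosomes with coverage in
    [min_cov, max_cov], at least ``min_count`` variant reads, and
    variant-allele frequency >= ``min_freq`` (the caller's convention:
    the called allele's frequency, not the folded minor-allele
    frequency).  Idempotent and order-preserving.
    """
    if min_cov < 0 or max_cov < 0 or min_count < 0 or min_freq < 0:
        raise ValueError("thresholds must be non-negative")
    if min_cov > max_cov:
        raise ValueError(f"min_cov {min_cov} > max_cov {max_cov}")
    _validate(records)
    autosomes = {str(c) for c in autosomes}
    keep = (
        records["chrom"].astype(str).isin(autosomes)
        & (records["coverage"] >= min_cov)
        & (records["coverage"] <= max_cov)
        & (records["variant_count"] >= min_count)
        & (records["frequency"] >= min_freq)
    )
    return records[keep]


def remove_cross_sample_monomorphic(
    tables: Mapping[str, pd.DataFrame], tol: float = 1e-12
) -> dict[str, pd.DataFrame]:
    """Drop loci fixed for the non-reference allele in *every* line.

    A locus (chrom, pos) is removed from all lines iff its frequency is 1
    in each line where it appears post-filter; a locus polymorphic in at
    least one line is kept everywhere.  Loci absent from some lines are
    judged on the lines where they are present.
    """
    if not tables:
        raise ValueError("need at least one line")

    def _key(df: pd.DataFrame) -> pd.Series:
        return df["chrom"].astype(str) + ":" + df["pos"].astype(str)

    frames = [
        pd.DataFrame({"key": _key(df), "fixed": df["frequency"] >= 1.0 - tol})
        for df in tables.values()
    ]
    allf = pd.concat(frames, ignore_index=True)
    fixed_everywhere = allf.groupby("key")["fixed"].all()
    drop = fixed_everywhere.index[fixed_everywhere]
    out = {}
    for line_id, df in tables.items():
        out[line_id] = df[~_key(df).isin(drop)]
    return out


def nucleotide_diversity(records: pd.DataFrame, line_id: str = "") -> DiversityEstimate:
    """Summed pi = Sigma p (1 - p) over a line's (already filtered) loci."""
    p = records["frequency"].to_numpy(dtype=float)
    return DiversityEstimate(
        line_id=line_id, n_snps=int(p.size), pi_sum=float(np.sum(p * (1.0 - p)))
    )


def relative_pi(
    estimates: Iterable[DiversityEstimate], outbred_ids: Iterable[str]
) -> list[DiversityEstimate]:
    """Fill pi_relative = pi_sum / mean pi_sum of the outbred lines."""
    estimates = list(estimates)
    outbred_ids = set(outbred_ids)
    ob = [e.pi_sum for e in estimates if e.line_id in outbred_ids]
    if not ob:
        raise ValueError("no outbred lines among the estimates")
    mean_ob = float(np.mean(ob))
    if mean_ob == 0:
        raise ValueError("outbred mean pi is zero; cannot normalise")
    for e in estimates:
        e.pi_relative = e.pi_sum / mean_ob
    return estimates


def diversity_table(
    tables: Mapping[str, pd.DataFrame],
    outbred_ids: Iterable[str],
    min_cov: int = 10,
    max_cov: int = 600,
    min_count: int = 1,
    min_freq: float = 0.10,
    autosomes: Iterable[str] = AUTOSOMES,
    drop_monomorphic_after_filter: bool = True,
) -> pd.DataFrame:
    """Full per-line pipeline: filter -> monomorphic exclusion -> pi -> normalise.

    Returns a DataFrame (line_id, n_snps, pi_sum, pi_relative).  The
    cross-sample monomorphic exclusion is applied after the per-line
    frequency filter by default (switchable).
    """
    filtered = {
        lid: filter_variants(df, min_cov, max_cov, min_count, min_freq, autosomes)
        for lid, df in tables.items()
    }
    if drop_monomorphic_after_filter:
        filtered = remove_cross_sample_monomorphic(filtered)
    else:
        pruned = remove_cross_sample_monomorphic(tables)
        filtered = {
            lid: filter_variants(df, min_cov, max_cov, min_count, min_freq, autosomes)
            for lid, df in pruned.items()
        }
    ests = [nucleotide_diversity(df, lid) for lid, df in filtered.items()]
    ests = relative_pi(ests, outbred_ids)
    out = pd.DataFrame(
        {
            "line_id": [e.line_id for e in ests],
            "n_snps": [e.n_snps for e in ests],
            "pi_sum": [e.pi_sum for e in ests],
            "pi_relative": [e.pi_relative for e in ests],
        }
    )
    # diagnostic only: all downstream analyses use the summed pi
    out["pi_per_snp"] = np.where(out["n_snps"] > 0, out["pi_sum"] / out["n_snps"], np.nan)
    return out


def coverage_ks_diagnostic(
    group_coverages: Mapping[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise two-sample K-S tests on per-group read-coverage samples.

    D = sup |ECDF_1 - ECDF_2| with the asymptotic two-sided p-value.
    Rows with p < alpha are flagged: dissimilar coverage distributions
    undermine cross-group comparison of summed pi.
    """
    for g, v in group_coverages.items():
        if len(np.asarray(v)) < 2:
            raise ValueError(f"group {g!r} needs >= 2 coverage values")
    rows = []
    for a, b in combinations(sorted(group_coverages), 2):
        res = stats.ks_2samp(group_coverages[a], group_coverages[b], method="asymp")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "d_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "flagged": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows)
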