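"""Normalization, replicate QC and aggregation of raw measurements.

The measurement design: each plasmodial cell is sampled twice per time
point (biological samples 1 and 2, picked at distant sites of the same
giant cell) and each RNA sample is measured twice by multiplex RT-PCR
(technical replicates 1 and 2).  Values are positive relative mRNA
abundances in arbitrary units.

Processing order:

1. ``normalize_sample_median`` — divide every measurement (one RT-PCR
   reaction) by the median over its 35 genes, correcting for RNA input
   and reaction efficiency.
2. ``normalize_gene_geomean`` — divide every value by the geometric
   mean of all retained values of that gene, putting genes on a common
   scale.
3. ``replicate_deviations`` / ``apply_qc_filters`` — the x-fold
   deviation of a value from its replicate-group mean; gene pairs
   deviating more than two-fold are dropped, and a plasmodium whose
   sample profile deviates more than two-fold from its sibling sample
   is excluded wholesale.
4. ``aggregate_measurements`` — mean of the surviving replicate values
   per (gene, cell, time point), one expression vector per
   cell-timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError
from .synthetic import EXPRESSION_COLUMNS

__all__ = [
    "QCReport",
    "validate_expression_table",
    "normalize_sample_median",
    "normalize_gene_geomean",
    "replicate_deviations",
    "deviation_quantiles",
    "apply_qc_filters",
    "aggregate_measurements",
]

MEASUREMENT_KEY = ["cell", "time_h", "sample", "replicate"]
DEFAULT_PROBS = (0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99)


@dataclass
class QCReport:
    """Replicate x-fold deviations and the quality flags derived from them.

    ``deviations`` holds one row per measurement with the ratio ``r``
    of the value to the arithmetic mean of its replicate group (pair or
    quad) and ``log2_r``.  For a pair (x1, x2), r1 + r2 = 2 exactly.
    """

    deviations: pd.DataFrame
    group: str  # 'pair' | 'quad'
    quantile_table: pd.DataFrame | None = None
    excluded_plasmodia: list[str] = field(default_factory=list)

    @property
    def flags(self) -> pd.Series:
        """Per-measurement pass of the two-fold rule (r within [0.5, 2])."""
        r = self.deviations["r"]
        return (r >= 0.5) & (r <= 2.0)


def validate_expression_table(table: pd.DataFrame) -> None:
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"expression table lacks columns {missing}")
    bad = table[~(table["value"] > 0)]
    if len(bad):
        keys = bad[["gene", "cell", "time_h", "sample", "replicate"]]
        raise DataError(
            f"non-positive values in {len(bad)} records, first: "
            f"{keys.iloc[0].to_dict()}"
        )
    dup = table.duplicated(subset=["gene", *MEASUREMENT_KEY])
    if dup.any():
        first = table[dup].iloc[0]
        raise DataError(
            "duplicate (gene, cell, time_h, sample, replicate) record: "
            f"{first[['gene', *MEASUREMENT_KEY]].to_dict()}"
        )


def normalize_sample_median(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each measurement's values by their median over genes.

    A measurement is one RT-PCR reaction, keyed by (cell, time_h,
    sample, replicate).  Even gene counts use the mean-of-central-pair
    median.  Ratios between genes within a measurement are preserved;
    afterwards every measurement has median exactly 1.
    """
    validate_expression_table(table)
    out = table.copy()
    medians = out.groupby(MEASUREMENT_KEY)["value"].transform("median")
    out["value"] = out["value"] / medians
    return out


def normalize_gene_geomean(table: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Divide each gene's values by the gene's overall geometric mean.

    Computed in log space.  Values at or below the detection floor are
    rejected unless ``floor`` is given, in which case they are clamped
    to it first.
    """
    validate_expression_table(table)
    out = table.copy()
    if floor is not None:
        out["value"] = out["value"].clip(lower=floor)
    logs = np.log(out["value"])
    gm = np.exp(logs.groupby(out["gene"]).transform("mean"))
    out["value"] = out["value"] / gm
    return out


def replicate_deviations(table: pd.DataFrame, group: str = "pair") -> QCReport:
    """x-fold deviation of each value from its replicate-group mean.

    ``group='pair'`` compares the two technical replicates of one
    sample (group key: gene, cell, time_h, sample; 2 members);
    ``group='quad'`` compares all four measurements of a cell-timepoint
    (group key: gene, cell, time_h; 4 members).
    """
    if group not in ("pair", "quad"):
        raise ArgumentError(f"group must be 'pair' or 'quad', got {group!r}")
    validate_expression_table(table)
    key = (
        ["gene", "cell", "time_h", "sample"]
        if group == "pair"
        else ["gene", "cell", "time_h"]
    )
    size = 2 if group == "pair" else 4
    dev = table.copy()
    counts = dev.groupby(key)["value"].transform("size")
    if (counts != size).any():
        bad = dev.loc[counts != size, key].drop_duplicates()
        raise DataError(
            f"incomplete replicate group(s) (need {size} members), first: "
            f"{bad.iloc[0].to_dict()}"
        )
    means = dev.groupby(key)["value"].transform("mean")
    dev["r"] = dev["value"] / means
    dev["log2_r"] = np.log2(dev["r"])
    return QCReport(deviations=dev, group=group)


def deviation_quantiles(
    report: QCReport, probs: tuple[float, ...] = DEFAULT_PROBS
) -> pd.DataFrame:
    """Quantile table of the deviation distribution.

    One row per probability with the quantile on the log2 scale and as
    an x-fold factor (fold = 2**log2 exactly, quantiles being monotone
    under the log transform).
    """
    if len(report.deviations) == 0:
        raise DataError("empty deviation report")
    probs = tuple(probs)
    if any(not 0 < p < 1 for p in probs):
        raise ArgumentError(f"probabilities must lie in (0, 1): {probs}")
    log2_q = np.quantile(report.deviations["log2_r"], probs)
    table = pd.DataFrame(
        {
            "prob": probs,
            "log2_quantile": log2_q,
            "fold_quantile": np.exp2(log2_q),
        }
    )
    report.quantile_table = table
    return table


def apply_qc_filters(
    table: pd.DataFrame, report: QCReport, fold_limit: float = 2.0
) -> tuple[pd.DataFrame, QCReport]:
    """Drop discordant replicate pairs, then discordant plasmodia.

    (i) Every gene's technical replicate pair in which either value
    deviates more than ``fold_limit`` from the pair mean is removed
    (both members — a discordant pair identifies neither value as the
    good one).  (ii) A plasmodium is excluded wholesale when, for any
    of its samples, the median over genes of the ratio of the sample's
    profile to the median profile of its sibling samples (same cell and
    time point, other samples) exceeds ``fold_limit`` in either
    direction.  Returns the filtered table and a report updated with
    the excluded plasmodia.
    """
    if fold_limit <= 1.0:
        raise ArgumentError(f"fold_limit must exceed 1, got {fold_limit}")
    if report.group != "pair":
        raise ArgumentError("QC filtering expects a pair-wise report")
    dev = report.deviations
    if len(dev) != len(table):
        raise DataError("report was not computed on this table")

    pair_key = ["gene", "cell", "time_h", "sample"]
    bad = (dev["r"] > fold_limit) | (dev["r"] < 1.0 / fold_limit)
    bad_pairs = dev.loc[bad, pair_key].drop_duplicates()
    merged = table.merge(bad_pairs, on=pair_key, how="left", indicator=True)
    kept = table[(merged["_merge"] == "left_only").to_numpy()]

    # plasmodium exclusion on sample profiles (replicate means per gene)
    sample_profiles = (
        kept.groupby(["cell", "time_h", "sample", "gene"])["value"]
        .mean()
        .unstack("gene")
    )
    excluded: set[str] = set()
    for (cell, time_h), block in sample_profiles.groupby(level=[0, 1]):
        if len(block) < 2:
            continue
        for idx in block.index:
            own = block.loc[idx]
            siblings = block.drop(index=idx)
            sibling_median = siblings.median(axis=0)
            ratio = (own / sibling_median).dropna()
            if len(ratio) == 0:
                continue
            score = float(ratio.median())
            if score > fold_limit or score < 1.0 / fold_limit:
                excluded.add(str(cell))
    kept = kept[~kept["cell"].astype(str).isin(excluded)]
    updated = QCReport(
        deviations=dev,
        group=report.group,
        quantile_table=report.quantile_table,
        excluded_plasmodia=sorted(excluded),
    )
    return kept.reset_index(drop=True), updated


def aggregate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of available replicate values per (cell, time_h, gene).

    Returns a wide matrix indexed by (cell, time_h) with one column per
    gene; missing combinations (all replicates removed by QC) are NaN
    and must be handled by the caller.  The number of contributing
    values is attached as ``matrix.attrs['n_values']``.
    """
    validate_expression_table(table)
    grouped = table.groupby(["cell", "time_h", "gene"])["value"]
    matrix = grouped.mean().unstack("gene")
    counts = grouped.size().unstack("gene").reindex(matrix.index).fillna(0).astype(int)
    matrix.attrs["n_values"] = counts
    return matrix
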