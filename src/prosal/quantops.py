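"""Quantitative filtering, normalization, exclusivity partitioning and
two-group differential analysis for peptide and protein LFQ tables.

Conventions (documented, applied consistently):

* Missing is NaN, never zero; a recorded zero intensity is a *valid* value
  for filtering purposes.
* The quality filter keeps rows with quality ≥ threshold (threshold read as
  the minimum acceptable score).
* Differential testing is one-way ANOVA on log2 intensities of present
  values, without multiplicity correction at the discovery stage; a
  Benjamini–Hochberg adjusted q-value column is available on request.
* Pipeline order: quality filter → valid-value filter → normalization →
  differential test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import (
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    PeptideQuantTable,
    ProteinQuantTable,
)

logger = logging.getLogger("prosal")

#: pseudocount added before log2 so recorded zero intensities stay valid
LOG_PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# Row filters
# ---------------------------------------------------------------------------

def filter_quality(table: PeptideQuantTable, threshold: float = 8.0) -> PeptideQuantTable:
    """Drop peptides whose quality score is below ``threshold``."""
    keep = table.data["quality"] >= threshold
    removed = int((~keep).sum())
    logger.info("quality filter (>= %g): removed %d of %d rows",
                threshold, removed, len(table))
    return table.with_data(table.data.loc[keep].copy())


def valid_counts(table: PeptideQuantTable) -> pd.DataFrame:
    """Per-row count of present (non-missing) values in each group."""
    counts = {}
    for group in table.groups:
        cols = table.samples_in(group)
        counts[group] = table.data[cols].notna().sum(axis=1)
    return pd.DataFrame(counts)


def filter_valid_values(table: PeptideQuantTable, min_per_group: int = 1) -> PeptideQuantTable:
    """Keep rows with at least ``min_per_group`` present values in every group."""
    counts = valid_counts(table)
    keep = (counts >= min_per_group).all(axis=1)
    logger.info("valid-value filter (>= %d per group): removed %d of %d rows",
                min_per_group, int((~keep).sum()), len(table))
    return table.with_data(table.data.loc[keep].copy())


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_intensities(table: PeptideQuantTable, method: str = "median") -> PeptideQuantTable:
    """Per-sample rescaling so the chosen statistic is equal across samples.

    ``median``: every sample's median of present values is brought to the
    across-sample mean of medians; ``total``: likewise for column sums.
    Missing cells stay missing.
    """
    if method not in ("median", "total"):
        raise ValueError(f"unknown normalization method {method!r}")
    inten = table.intensities
    if method == "median":
        stat = inten.median(axis=0, skipna=True)
    else:
        stat = inten.sum(axis=0, skipna=True)
    if stat.isna().any() or (stat <= 0).any():
        bad = list(stat.index[stat.isna() | (stat <= 0)])
        raise ValueError(f"samples without positive present values: {bad}")
    target = float(stat.mean())
    factors = target / stat
    data = table.data.copy()
    for s in table.samples:
        data[s] = data[s] * factors[s]
    logger.info("%s normalization: scale factors in [%.3g, %.3g]",
                method, factors.min(), factors.max())
    return table.with_data(data)


# ---------------------------------------------------------------------------
# Exclusivity partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusivityPartition:
    """Group-exclusive vs shared detection of features (Venn partition)."""

    exclusive_negative: tuple[str, ...]
    exclusive_positive: tuple[str, ...]
    shared: tuple[str, ...]

    @property
    def total(self) -> int:
        return (len(self.exclusive_negative) + len(self.exclusive_positive)
                + len(self.shared))

    def counts(self) -> dict[str, int]:
        return {
            "exclusive_pN0": len(self.exclusive_negative),
            "exclusive_pN+": len(self.exclusive_positive),
            "shared": len(self.shared),
            "total": self.total,
        }


def exclusivity_partition(table: PeptideQuantTable) -> ExclusivityPartition:
    """Partition features into group-exclusive and shared detections.

    A feature is exclusive to a group when it has ≥1 present value there and
    none in the other group; features with ≥1 present value in both are
    shared.  Features absent everywhere are not counted.
    """
    counts = valid_counts(table)
    neg = counts[GROUP_NEGATIVE] if GROUP_NEGATIVE in counts else None
    pos = counts[GROUP_POSITIVE] if GROUP_POSITIVE in counts else None
    if neg is None or pos is None:
        raise ValueError("exclusivity partition needs both pN0 and pN+ samples")
    excl_neg = counts.index[(neg > 0) & (pos == 0)]
    excl_pos = counts.index[(pos > 0) & (neg == 0)]
    shared = counts.index[(pos > 0) & (neg > 0)]
    return ExclusivityPartition(
        exclusive_negative=tuple(excl_neg),
        exclusive_positive=tuple(excl_pos),
        shared=tuple(shared),
    )


# ---------------------------------------------------------------------------
# Differential analysis
# ---------------------------------------------------------------------------

def differential_anova(
    table: PeptideQuantTable,
    alpha: float = 0.05,
    log_transform: bool = True,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Two-group one-way ANOVA per feature on (log2) present values.

    Returns a frame indexed like the table with columns ``mean_pN0``,
    ``mean_pN+`` (log2 scale when ``log_transform``), ``log2fc``
    (pN+ − pN0), ``p_value``, ``n_pN0``, ``n_pN+``, ``tested`` and
    ``significant``.  Rows with fewer than two present values in either
    group are reported untested.  No multiplicity correction is applied
    unless ``adjust='bh'`` (adds a ``q_value`` column; significance still
    follows the raw p-value, matching the discovery-stage convention).
    """
    neg_cols = table.samples_in(GROUP_NEGATIVE)
    pos_cols = table.samples_in(GROUP_POSITIVE)
    if len(neg_cols) < 2 or len(pos_cols) < 2:
        raise ValueError("differential test needs >= 2 samples per group")

    values = table.intensities
    if log_transform:
        values = np.log2(values + LOG_PSEUDOCOUNT)

    records = []
    for pid, row in values.iterrows():
        a = row[neg_cols].dropna().to_numpy(float)
        b = row[pos_cols].dropna().to_numpy(float)
        rec = {"n_pN0": len(a), "n_pN+": len(b)}
        if len(a) < 2 or len(b) < 2:
            rec.update(mean_pN0=np.nan, **{"mean_pN+": np.nan}, log2fc=np.nan,
                       p_value=np.nan, tested=False, degenerate=False)
        else:
            ma, mb = float(a.mean()), float(b.mean())
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and ma == mb:
                p = 1.0
                degenerate = True
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    stat = stats.f_oneway(a, b)
                p = float(stat.pvalue)
                degenerate = bool(np.isnan(p))
                if degenerate:  # zero variance, equal means up to fp noise
                    p = 1.0
            rec.update(mean_pN0=ma, **{"mean_pN+": mb}, log2fc=mb - ma,
                       p_value=p, tested=True, degenerate=degenerate)
        records.append(rec)

    out = pd.DataFrame(records, index=values.index)
    out["significant"] = out["tested"] & (out["p_value"] <= alpha)
    if adjust == "bh":
        tested = out["tested"]
        q = pd.Series(np.nan, index=out.index)
        if tested.any():
            q.loc[tested] = multipletests(out.loc[tested, "p_value"],
                                          method="fdr_bh")[1]
        out["q_value"] = q
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    logger.info("differential ANOVA: %d/%d tested, %d significant at alpha=%g",
                int(out["tested"].sum()), len(out),
                int(out["significant"].sum()), alpha)
    return out


# ---------------------------------------------------------------------------
# Protein-level helpers
# ---------------------------------------------------------------------------

def proteomics_clean(table: ProteinQuantTable) -> ProteinQuantTable:
    """Post-search cleanup: drop reverse and only-by-site protein groups."""
    keep = ~(table.data["is_reverse"] | table.data["only_by_site"])
    logger.info("proteomics cleanup: removed %d of %d protein groups",
                int((~keep).sum()), len(table))
    return table.with_data(table.data.loc[keep].copy())


def mean_log2_shift(table: ProteinQuantTable, class_tag: str) -> tuple[float, pd.Series]:
    """Average pN+ − pN0 log2 shift over proteins of one functional class.

    Per protein: mean log2 of present pN+ values minus mean log2 of present
    pN0 values; proteins lacking a present value in either group are
    skipped.  Returns (unweighted class mean, per-protein series).
    """
    sub = table.data[table.data["class_tag"] == class_tag]
    if sub.empty:
        raise ValueError(f"no proteins tagged {class_tag!r}")
    neg_cols = table.samples_in(GROUP_NEGATIVE)
    pos_cols = table.samples_in(GROUP_POSITIVE)
    shifts = {}
    for acc, row in sub.iterrows():
        a = np.log2(row[neg_cols].dropna().astype(float) + LOG_PSEUDOCOUNT)
        b = np.log2(row[pos_cols].dropna().astype(float) + LOG_PSEUDOCOUNT)
        if len(a) == 0 or len(b) == 0:
            continue
        shifts[acc] = float(b.mean() - a.mean())
    if not shifts:
        raise ValueError(f"class {class_tag!r} has no protein with values in both groups")
    series = pd.Series(shifts, name="log2fc")
    return float(series.mean()), series
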