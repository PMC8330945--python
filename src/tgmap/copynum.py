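"""Transgene copy-number and relative-expression quantification.

Two independent routes to allele counts:

* qPCR delta-delta-Ct: per-sample Ct values are referenced to a control
  locus (delta Ct), compared to a calibrator genotype group (delta-delta
  Ct), and converted to absolute allele counts as ``2 ** (-ddCt) * 2`` —
  the factor two reflecting the calibrator's two alleles.
* windowed sequencing depth: per-window ``(test / control) * 2`` ratios,
  summarised over a segment by the median with a bootstrap interval.  This
  is a deliberately simple segment estimator; full maximum-likelihood
  multi-state copy-number calling is out of scope.

RT-qPCR relative expression uses the same delta-Ct referencing with a group
fold change ``2 ** -(mean_b - mean_a)`` and Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicInterval

CT_COLUMNS = ("sample", "group", "target", "replicate", "ct")


def _check_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return table


def _replicate_means(table: pd.DataFrame, outlier_window: float) -> pd.DataFrame:
    """Mean Ct per (sample, target) after dropping replicates further than
    ``outlier_window`` cycles from the replicate median."""

    def collapse(group: pd.DataFrame) -> float:
        ct = group["ct"].to_numpy()
        med = np.median(ct)
        kept = ct[np.abs(ct - med) <= outlier_window]
        if kept.size == 0:  # pathological spread: fall back to the median
            return float(med)
        return float(kept.mean())

    rows = []
    for (sample, target), grp in table.groupby(["sample", "target"], sort=True):
        rows.append(
            {
                "sample": sample,
                "target": target,
                "group": grp["group"].iloc[0],
                "ct": collapse(grp),
            }
        )
    return pd.DataFrame(rows)


def ddct_allele_counts(
    table: pd.DataFrame,
    reference_target: str,
    calibrator_group: str,
    outlier_window: float = 0.5,
) -> pd.DataFrame:
    """Delta-delta-Ct absolute allele counts.

    Per sample and target: ``dct = Ct(target) - Ct(reference)`` (replicates
    averaged after outlier removal); ``ddct = dct - mean dct of the
    calibrator group``; ``allele_count = 2 ** (-ddct) * 2``.  The calibrator
    group therefore averages an allele count of exactly two per target.
    """
    table = _check_ct_table(table)
    means = _replicate_means(table, outlier_window)
    ref = means[means["target"] == reference_target].set_index("sample")["ct"]
    samples = means["sample"].unique()
    missing_ref = [s for s in samples if s not in ref.index]
    if missing_ref:
        raise ValueError(f"reference target missing for samples: {missing_ref}")
    rows = means[means["target"] != reference_target].copy()
    rows["dct"] = rows["ct"].to_numpy() - ref.loc[rows["sample"]].to_numpy()
    out = []
    for target, grp in rows.groupby("target", sort=True):
        calib = grp[grp["group"] == calibrator_group]
        if calib.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} empty for target {target!r}"
            )
        base = calib["dct"].mean()
        g = grp.copy()
        g["ddct"] = g["dct"] - base
        g["allele_count"] = 2.0 ** (-g["ddct"]) * 2.0
        out.append(g)
    result = pd.concat(out, ignore_index=True)
    return result[["sample", "group", "target", "dct", "ddct", "allele_count"]]


@dataclass
class DepthRatioTrack:
    """Windowed (test / control) * 2 allele-count signal."""

    window: int
    table: pd.DataFrame  # start, end, test_count, control_count, ratio, masked

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()


def depth_ratio_track(
    test_counts: Union[pd.DataFrame, Sequence[float]],
    control_counts: Optional[Sequence[float]] = None,
    window: int = 1_000,
    min_control: int = 10,
) -> DepthRatioTrack:
    """Per-window ``(test / control) * 2`` ratios.

    Accepts either a depth table (columns start, end, test_count,
    control_count — e.g. the output of the depth simulator) or two count
    arrays.  Windows whose control count falls below ``min_control`` are
    masked: too few control reads make the ratio unstable.
    """
    if isinstance(test_counts, pd.DataFrame):
        df = test_counts.copy()
        if "start" in df.columns and len(df) > 1:
            window = int(df["end"].iloc[0] - df["start"].iloc[0])
    else:
        test = np.asarray(test_counts, dtype=float)
        control = np.asarray(control_counts, dtype=float)
        if test.shape != control.shape:
            raise ValueError("test and control count arrays must match")
        starts = np.arange(len(test)) * window
        df = pd.DataFrame(
            {
                "start": starts,
                "end": starts + window,
                "test_count": test,
                "control_count": control,
            }
        )
    masked = df["control_count"].to_numpy() < min_control
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 2.0 * df["test_count"].to_numpy() / df["control_count"].to_numpy()
    ratio[masked] = np.nan
    df["ratio"] = ratio
    df["masked"] = masked
    return DepthRatioTrack(window=window, table=df.reset_index(drop=True))


@dataclass
class CopyEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n_windows: int

    def summary(self) -> str:
        return (
            f"copy number {self.estimate:.2f} "
            f"(95% bootstrap CI {self.ci_low:.2f}-{self.ci_high:.2f}, "
            f"{self.n_windows} windows)"
        )


def segment_copy_estimate(
    track: DepthRatioTrack,
    segment: Union[GenomicInterval, Tuple[int, int]],
    n_boot: int = 199,
    seed: int = 0,
) -> CopyEstimate:
    """Median window ratio over a segment with a bootstrap 95% interval."""
    if isinstance(segment, GenomicInterval):
        lo, hi = segment.start, segment.end
    else:
        lo, hi = segment
    if hi <= lo:
        raise ValueError("empty segment")
    df = track.table
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) / 2
    sel = (mids >= lo) & (mids < hi) & ~df["masked"].to_numpy()
    vals = df["ratio"].to_numpy()[sel]
    if vals.size < 3:
        raise ValueError(f"only {vals.size} unmasked windows in segment; need >= 3")
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
    )
    lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
    return CopyEstimate(
        estimate=float(np.median(vals)),
        ci_low=float(lo_ci),
        ci_high=float(hi_ci),
        n_windows=int(vals.size),
    )


@dataclass
class ExpressionResult:
    fold_change: float
    p_value: float
    mean_dct_a: float
    mean_dct_b: float
    n_a: int
    n_b: int

    def summary(self) -> str:
        return (
            f"relative expression: fold change {self.fold_change:.3f} "
            f"(group sizes {self.n_a}/{self.n_b}), Welch p = {self.p_value:.3g}"
        )


def relative_expression(
    table: pd.DataFrame,
    reference_target: str,
    group_a: str,
    group_b: str,
    target: Optional[str] = None,
    outlier_window: float = 0.5,
) -> ExpressionResult:
    """Group fold change of a target's expression referenced to a control
    locus, with Welch's unequal-variance t-test on the per-sample delta-Ct
    values.  Fold change ``2 ** -(mean_dct_b - mean_dct_a)`` is group_b
    relative to group_a.
    """
    table = _check_ct_table(table)
    means = _replicate_means(table, outlier_window)
    targets = sorted(set(means["target"]) - {reference_target})
    if target is None:
        if len(targets) != 1:
            raise ValueError(f"specify the target; candidates: {targets}")
        target = targets[0]
    ref = means[means["target"] == reference_target].set_index("sample")["ct"]
    sub = means[means["target"] == target].copy()
    sub["dct"] = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
    a = sub[sub["group"] == group_a]["dct"].to_numpy()
    b = sub[sub["group"] == group_b]["dct"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    fc = 2.0 ** (-(b.mean() - a.mean()))
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ExpressionResult(
        fold_change=float(fc),
        p_value=p,
        mean_dct_a=float(a.mean()),
        mean_dct_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )
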