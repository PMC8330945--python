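"""4C-style per-fragment contact profiles: normalisation, smoothing and
segment fold changes.

A profile holds one score per restriction fragment around a viewpoint.
Scores are normalised to the mean score of fragments within a fixed flank
(default 10 Mb) of the viewpoint, smoothed by an 11-fragment running mean,
and inter-genotype changes are quantified as per-segment shares of the host
TAD signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval


@dataclass
class FourCProfile:
    """Per-restriction-fragment contact scores around a viewpoint."""

    viewpoint: GenomicInterval
    fragments: pd.DataFrame  # columns: start, end, score
    genotype: str = ""

    def __post_init__(self) -> None:
        df = self.fragments.reset_index(drop=True)
        required = {"start", "end", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        if (df["score"] < 0).any():
            raise ValueError("fragment scores must be >= 0")
        starts, ends = df["start"].to_numpy(), df["end"].to_numpy()
        if not (np.diff(starts) > 0).all():
            raise ValueError("fragments must be sorted by start")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("fragments must not overlap")
        self.fragments = df

    @property
    def midpoints(self) -> np.ndarray:
        return (self.fragments["start"].to_numpy() + self.fragments["end"].to_numpy()) / 2

    @property
    def scores(self) -> np.ndarray:
        return self.fragments["score"].to_numpy(dtype=float)

    def with_scores(self, scores: np.ndarray) -> "FourCProfile":
        df = self.fragments.copy()
        df["score"] = scores
        return replace(self, fragments=df)

    def viewpoint_mask(self, pad_fragments: int = 1) -> np.ndarray:
        """True for fragments overlapping the viewpoint, padded by
        ``pad_fragments`` neighbours on each side."""
        starts = self.fragments["start"].to_numpy()
        ends = self.fragments["end"].to_numpy()
        hit = (starts < self.viewpoint.end) & (ends > self.viewpoint.start)
        idx = np.where(hit)[0]
        mask = hit.copy()
        if idx.size:
            lo = max(0, idx.min() - pad_fragments)
            hi = min(len(mask), idx.max() + 1 + pad_fragments)
            mask[lo:hi] = True
        return mask


def fourc_normalize(
    profile: FourCProfile, flank: int = 10_000_000, pad_fragments: int = 1
) -> FourCProfile:
    """Divide every score by the mean score of fragments within ``flank``
    of the viewpoint (viewpoint fragments +/- ``pad_fragments`` excluded
    from the mean)."""
    mids = profile.midpoints
    vp_mid = (profile.viewpoint.start + profile.viewpoint.end) / 2
    in_flank = np.abs(mids - vp_mid) <= flank
    in_flank &= ~profile.viewpoint_mask(pad_fragments)
    if not in_flank.any():
        raise ValueError("no fragments within the normalisation flank")
    mean = profile.scores[in_flank].mean()
    if mean == 0:
        raise ValueError("flank mean score is zero; cannot normalise")
    return profile.with_scores(profile.scores / mean)


def fourc_smooth(profile: FourCProfile, n: int = 11) -> FourCProfile:
    """Running mean over ``n`` consecutive fragments (``n`` odd); at the
    profile edges the window shrinks symmetrically."""
    if n % 2 == 0 or n < 1:
        raise ValueError("smoothing window must be a positive odd number")
    scores = profile.scores
    h = n // 2
    out = np.empty_like(scores, dtype=float)
    m = len(scores)
    for i in range(m):
        hi = min(h, i, m - 1 - i)
        out[i] = scores[i - hi : i + hi + 1].mean()
    return profile.with_scores(out)


def _segment_sum(
    profile: FourCProfile,
    segment: GenomicInterval,
    exclude: Sequence[GenomicInterval],
) -> float:
    mids = profile.midpoints
    sel = (mids >= segment.start) & (mids < segment.end)
    for iv in exclude:
        sel &= ~((mids >= iv.start) & (mids < iv.end))
    return float(profile.scores[sel].sum())


@dataclass
class FourCSegmentFC:
    """Per-side fold change of TAD-normalised segment signal."""

    fc_left: float
    fc_right: float
    share_left_mut: float
    share_left_wt: float
    share_right_mut: float
    share_right_wt: float

    def summary(self) -> str:
        return (
            f"4C segment fold changes: left {self.fc_left * 100:+.1f}%, "
            f"right {self.fc_right * 100:+.1f}%"
        )


def fourc_segment_fc(
    mut: FourCProfile,
    wt: FourCProfile,
    left_segment: GenomicInterval,
    right_segment: GenomicInterval,
    host_tad: GenomicInterval,
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> FourCSegmentFC:
    """Per-side contact change across an insertion.

    For each genotype, the non-smoothed segment score sums are normalised by
    the host-TAD total, and the fold change is
    ``(share_mut - share_wt) / share_wt`` per side.  Intervals in
    ``exclude`` (e.g. the insert and its target-site duplication) are left
    out of all sums.
    """
    exclude = list(exclude or [])
    shares = {}
    for name, prof in (("mut", mut), ("wt", wt)):
        tad = _segment_sum(prof, host_tad, exclude)
        if tad == 0:
            raise ValueError(f"host TAD sum is zero for {name} profile")
        shares[name, "left"] = _segment_sum(prof, left_segment, exclude) / tad
        shares[name, "right"] = _segment_sum(prof, right_segment, exclude) / tad
    for side in ("left", "right"):
        if shares["wt", side] == 0:
            raise ValueError(f"wild-type {side} segment share is zero")
    return FourCSegmentFC(
        fc_left=(shares["mut", "left"] - shares["wt", "left"]) / shares["wt", "left"],
        fc_right=(shares["mut", "right"] - shares["wt", "right"])
        / shares["wt", "right"],
        share_left_mut=shares["mut", "left"],
        share_left_wt=shares["wt", "left"],
        share_right_mut=shares["mut", "right"],
        share_right_wt=shares["wt", "right"],
    )


def read_profile_tsv(path, viewpoint: GenomicInterval, genotype: str = "") -> FourCProfile:
    df = pd.read_csv(path, sep="\t")
    return FourCProfile(viewpoint=viewpoint, fragments=df, genotype=genotype)


def write_profile_tsv(profile: FourCProfile, path) -> None:
    profile.fragments.to_csv(path, sep="\t", index=False)
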