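"""Smoothing, DMR calling and summaries for per-CpG WGBS methylation tracks.

A differentially methylated region (DMR) is a maximal run of >= 4 consecutive
CpGs whose smoothed methylation difference between resistant and parental
cells exceeds 0.4 in magnitude, with the same sign, in both cell lines.
Smoothing is a coverage-weighted running mean over a fixed window of
neighbouring CpGs; it replaces a local-likelihood smoother with a simpler,
configurable stand-in, since the calling criterion itself is threshold-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STATES = ("parental", "resistant", "P5", "P12")

TRACK_COLUMNS = ("chrom", "pos", "meth", "cov")


@dataclass
class MethylomeTrack:
    """Per-CpG methylation levels and coverages for one (line, state) sample.

    ``records`` holds columns chrom, pos (bp, 0-based), meth (fraction in
    [0, 1]) and cov (reads).  Positions are strictly increasing within a
    chromosome; record order is canonicalised on construction so downstream
    calls are invariant to input permutation.
    """

    line_id: str
    state: str
    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track is missing columns {missing}")
        df = df.loc[:, list(TRACK_COLUMNS)].copy()
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if ((df["meth"] < 0) | (df["meth"] > 1)).any():
            raise ValueError("methylation level outside [0, 1]")
        if (df["cov"] < 0).any():
            raise ValueError("negative coverage")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate CpG position in track")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.records.groupby("chrom", sort=True)


@dataclass
class DMRCallParams:
    min_cpgs: int = 4
    min_delta: float = 0.4
    smoothing_window: int = 5
    min_coverage: int = 1
    # "per_cpg": the delta threshold must hold at every smoothed CpG;
    # "region_mean": runs are seeded per-CpG but the threshold is applied to
    # the run-mean difference instead.
    delta_mode: str = "per_cpg"

    def __post_init__(self):
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not 0 < self.min_delta <= 1:
            raise ValueError("min_delta must be in (0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.delta_mode not in ("per_cpg", "region_mean"):
            raise ValueError("delta_mode must be 'per_cpg' or 'region_mean'")


@dataclass
class DMR:
    """A called differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    direction: str  # "hyper" or "hypo" in the resistant state
    mean_methylation: dict[tuple[str, str], float] = field(default_factory=dict)
    reversion_score: float | None = None
    reverting: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def smooth_methylation(track: MethylomeTrack, window: int = 5) -> MethylomeTrack:
    """Coverage-weighted running mean over a window of neighbouring CpGs.

    The window is counted in CpGs (not bp), centred, truncated at chromosome
    ends.  ``window=1`` returns the track unchanged.  Windows with zero total
    coverage fall back to the unweighted mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1 or len(track) == 0:
        return MethylomeTrack(track.line_id, track.state, track.records.copy())
    half = window // 2
    out = []
    for chrom, df in track.by_chrom():
        m = df["meth"].to_numpy(dtype=float)
        c = df["cov"].to_numpy(dtype=float)
        n = len(m)
        # cumulative sums with a leading zero give O(1) truncated-window sums
        cw = np.concatenate([[0.0], np.cumsum(m * c)])
        cc = np.concatenate([[0.0], np.cumsum(c)])
        cm = np.concatenate([[0.0], np.cumsum(m)])
        i = np.arange(n)
        lo = np.maximum(i - half, 0)
        hi = np.minimum(i + half + 1, n)
        wsum = cw[hi] - cw[lo]
        csum = cc[hi] - cc[lo]
        msum = cm[hi] - cm[lo]
        smoothed = np.where(csum > 0, wsum / np.maximum(csum, 1e-300), msum / (hi - lo))
        new = df.copy()
        new["meth"] = np.clip(smoothed, 0.0, 1.0)
        out.append(new)
    return MethylomeTrack(track.line_id, track.state, pd.concat(out, ignore_index=True))


def _joined_frame(
    tracks: Mapping[tuple[str, str], MethylomeTrack],
    lines: list[str],
    min_coverage: int,
) -> pd.DataFrame:
    """Inner-join parental/resistant levels of both lines on CpG position."""
    needed = [(ln, st) for ln in lines for st in ("parental", "resistant")]
    for key in needed:
        if key not in tracks:
            raise ValueError(f"missing track for (line, state) = {key}")
    chrom_sets = {key: set(tracks[key].records["chrom"].unique()) for key in needed}
    ref = chrom_sets[needed[0]]
    for key, cs in chrom_sets.items():
        off = cs.symmetric_difference(ref)
        if off:
            raise ValueError(
                f"chromosome sets differ between samples: {sorted(off)} "
                f"(offending sample {key})"
            )
    merged: pd.DataFrame | None = None
    for ln, st in needed:
        df = tracks[(ln, st)].records.rename(
            columns={"meth": f"meth_{ln}_{st}", "cov": f"cov_{ln}_{st}"}
        )
        merged = df if merged is None else merged.merge(df, on=["chrom", "pos"], how="inner")
    cov_cols = [c for c in merged.columns if c.startswith("cov_")]
    keep = (merged[cov_cols] >= min_coverage).all(axis=1)
    return merged.loc[keep].reset_index(drop=True)


def call_dmrs(
    tracks: Mapping[tuple[str, str], MethylomeTrack],
    params: DMRCallParams | None = None,
    extra_state_tracks: Mapping[tuple[str, str], MethylomeTrack] | None = None,
) -> list[DMR]:
    """Call DMRs common to both cell lines from smoothed tracks.

    ``tracks`` maps (line_id, state) to a MethylomeTrack and must contain
    parental and resistant tracks for exactly two lines; CpGs are
    inner-joined on position.  A DMR is a maximal run of consecutive joined
    CpGs where, in BOTH lines, the smoothed difference resistant - parental
    has the same sign and magnitude >= ``min_delta``, with at least
    ``min_cpgs`` CpGs.  Qualifying runs separated by a non-qualifying CpG
    are not merged.  Per-(line, state) raw mean methylation over the region
    is attached for every track supplied in ``tracks`` and
    ``extra_state_tracks`` (e.g. P5/P12).
    """
    params = params or DMRCallParams()
    lines = sorted({ln for ln, _ in tracks})
    if len(lines) != 2:
        raise ValueError(f"expected exactly two cell lines, got {lines}")

    smoothed = {
        key: smooth_methylation(tr, params.smoothing_window)
        for key, tr in tracks.items()
        if key[1] in ("parental", "resistant")
    }
    joined = _joined_frame(smoothed, lines, params.min_coverage)

    d = {
        ln: (
            joined[f"meth_{ln}_resistant"].to_numpy()
            - joined[f"meth_{ln}_parental"].to_numpy()
        )
        for ln in lines
    }
    la, lb = lines
    sign = np.sign(d[la])
    agree = (sign != 0) & (np.sign(d[lb]) == sign)
    if params.delta_mode == "per_cpg":
        qual = (
            agree
            & (np.abs(d[la]) >= params.min_delta)
            & (np.abs(d[lb]) >= params.min_delta)
        )
    else:
        qual = agree  # threshold re-checked on the run mean below

    dmrs: list[DMR] = []
    chroms = joined["chrom"].to_numpy()
    pos = joined["pos"].to_numpy()
    n = len(joined)
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and qual[j + 1]
            and chroms[j + 1] == chroms[i]
            and sign[j + 1] == sign[i]
        ):
            j += 1
        run = slice(i, j + 1)
        n_cpgs = j - i + 1
        ok = n_cpgs >= params.min_cpgs
        if ok and params.delta_mode == "region_mean":
            ok = all(np.abs(d[ln][run].mean()) >= params.min_delta for ln in lines)
        if ok:
            end = int(pos[j]) + 2  # cover the CpG dinucleotide ...
            if j + 1 < n and chroms[j + 1] == chroms[i]:
                end = min(end, int(pos[j + 1]))  # ... without swallowing the next CpG
            dmrs.append(
                DMR(
                    chrom=str(chroms[i]),
                    start=int(pos[i]),
                    end=end,
                    n_cpgs=n_cpgs,
                    direction="hyper" if sign[i] > 0 else "hypo",
                )
            )
        i = j + 1

    all_tracks = dict(tracks)
    if extra_state_tracks:
        all_tracks.update(extra_state_tracks)
    attach_state_means(dmrs, all_tracks)
    return dmrs


def attach_state_means(
    dmrs: list[DMR], tracks: Mapping[tuple[str, str], MethylomeTrack]
) -> list[DMR]:
    """Attach per-(line, state) raw mean methylation over each DMR."""
    for key, tr in tracks.items():
        df = tr.records
        by_chrom = {c: g for c, g in df.groupby("chrom", sort=False)}
        for dmr in dmrs:
            g = by_chrom.get(dmr.chrom)
            if g is None:
                continue
            p = g["pos"].to_numpy()
            lo, hi = np.searchsorted(p, [dmr.start, dmr.end])
            if hi > lo:
                dmr.mean_methylation[key] = float(
                    g["meth"].to_numpy()[lo:hi].mean()
                )
    return dmrs


def summarize_dmrs(dmrs: list[DMR]) -> dict:
    """Count, hyper fraction and CpG-content / length statistics of a DMR set."""
    if not dmrs:
        return {
            "empty": True,
            "count": 0,
            "hyper_fraction": 0.0,
            "mean_cpgs": 0.0,
            "min_cpgs": 0,
            "max_cpgs": 0,
            "mean_length": 0.0,
            "min_length": 0,
            "max_length": 0,
        }
    ncpg = np.array([d.n_cpgs for d in dmrs])
    lengths = np.array([d.length for d in dmrs])
    hyper = np.array([d.direction == "hyper" for d in dmrs])
    return {
        "empty": False,
        "count": len(dmrs),
        "hyper_fraction": float(hyper.mean()),
        "mean_cpgs": float(ncpg.mean()),
        "min_cpgs": int(ncpg.min()),
        "max_cpgs": int(ncpg.max()),
        "mean_length": float(lengths.mean()),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
    }


def validate_amplicon(
    mean_parental: float,
    mean_resistant: float,
    min_diff: float = 0.2,
    wgbs_direction: str | None = None,
) -> bool:
    """Amplicon-level validation of a DMR at a minimum methylation difference.

    True iff |resistant - parental| >= ``min_diff`` and, when the WGBS call
    direction is given, the amplicon difference has the matching sign.
    """
    for v in (mean_parental, mean_resistant):
        if not 0 <= v <= 1:
            raise ValueError("mean methylation outside [0, 1]")
    delta = mean_resistant - mean_parental
    if abs(delta) < min_diff - 1e-12:  # tolerate float representation of 0.2
        return False
    if wgbs_direction is not None:
        if wgbs_direction not in ("hyper", "hypo"):
            raise ValueError("wgbs_direction must be 'hyper' or 'hypo'")
        return delta > 0 if wgbs_direction == "hyper" else delta < 0
    return True


def metaprofile(
    regions,
    track: MethylomeTrack,
    flank: int = 2000,
    n_bins: int = 30,
) -> np.ndarray:
    """Mean methylation profile over scaled region bodies and absolute flanks.

    ``n_bins`` is split into three parts: ``n_bins // 3`` bins for each flank
    (absolute bp, ``flank`` bp wide) and the remainder for the region body
    (scaled to a fixed bin count regardless of region length).  Returns the
    per-bin mean over all regions; bins with no CpGs in any region are NaN.
    Flanks running off a chromosome end are simply empty, not an error.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    k = n_bins // 3
    body_bins = n_bins - 2 * k
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    by_chrom = {c: g for c, g in track.records.groupby("chrom", sort=False)}
    for chrom, start, end in regions:
        g = by_chrom.get(chrom)
        if g is None:
            continue
        p = g["pos"].to_numpy()
        m = g["meth"].to_numpy()

        def _accumulate(lo: float, hi: float, first_bin: int, nb: int):
            if hi <= lo:
                return
            edges = np.linspace(lo, hi, nb + 1)
            il, ih = np.searchsorted(p, [lo, hi])
            if ih <= il:
                return
            idx = np.clip(np.searchsorted(edges, p[il:ih], side="right") - 1, 0, nb - 1)
            np.add.at(sums, first_bin + idx, m[il:ih])
            np.add.at(counts, first_bin + idx, 1)

        _accumulate(start - flank, start, 0, k)
        _accumulate(start, end, k, body_bins)
        _accumulate(end, end + flank, k + body_bins, k)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile
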