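"""Monte-Carlo feature enrichment against length- and CpG-matched random regions.

Each observed region (e.g. a DMR) is matched, per iteration, with a random
genomic region of similar length and CpG count; the number of regions
overlapping a feature track is compared between the observed set and each
random replicate set.  A feature is enriched at level 0.05 / 0.01 / 0.001 if
the observed overlap count exceeds the random one in at least 95% / 99% /
99.9% of iterations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import intervals as ivl
from .context import GenomeAnnotation

Region = tuple[str, int, int]


class MatchingFailureError(RuntimeError):
    """No random region matching a template was found within the attempt budget."""


@dataclass
class EnrichmentParams:
    n_iterations: int = 10_000
    length_tolerance: float = 0.10  # fractional slack on region length
    cpg_tolerance: float = 0.10  # fractional slack on CpG count, floored at 1
    seed: int = 0
    significance_levels: tuple[float, ...] = (0.05, 0.01, 0.001)
    max_attempt_batches: int = 200  # rejection-sampling budget per template
    exclude_originals: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.length_tolerance < 0 or self.cpg_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class EnrichmentResult:
    feature: str
    n_regions: int
    observed: int  # regions overlapping >= 1 feature interval
    null_mean: float  # mean overlap count over random replicates
    exceed_fraction: float  # fraction of iterations with observed > random
    significance: float | None  # strictest level reached, or None

    def __post_init__(self):
        assert 0 <= self.observed <= self.n_regions
        assert 0.0 <= self.exceed_fraction <= 1.0


def _cpg_slack(n_cpgs: int, tol: float) -> int:
    return max(1, int(np.ceil(tol * n_cpgs)))


def _sample_batch(
    length: int,
    genome: GenomeAnnotation,
    rng: np.random.Generator,
    size: int,
    chrom_names: list[str],
    chrom_probs: np.ndarray,
):
    """Draw `size` uniform placements of a fixed-length window over the genome."""
    ci = rng.choice(len(chrom_names), size=size, p=chrom_probs)
    lens = np.array([genome.chromosomes[chrom_names[i]] for i in ci])
    starts = (rng.random(size) * np.maximum(lens - length, 1)).astype(np.int64)
    return ci, starts


def _matched_starts(
    template: Region,
    genome: GenomeAnnotation,
    rng: np.random.Generator,
    n: int,
    params: EnrichmentParams,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised rejection sampling of `n` matched placements for one template.

    Returns (chrom indices, starts, sampled length).  The sampled length
    equals the template length, which trivially satisfies the length
    tolerance; matching is on CpG count within the configured slack.
    """
    chrom, start, end = template
    length = end - start
    target = genome.cpg_count(chrom, start, end)
    slack = _cpg_slack(target, params.cpg_tolerance)
    eligible = [c for c, clen in genome.chromosomes.items() if clen >= length]
    if not eligible:
        raise MatchingFailureError(
            f"template {chrom}:{start}-{end} is longer than every chromosome"
        )
    lens = np.array([genome.chromosomes[c] for c in eligible], dtype=float)
    probs = lens / lens.sum()
    got_ci: list[np.ndarray] = []
    got_st: list[np.ndarray] = []
    n_got = 0
    batch = min(max(4 * n, 256), 100_000)
    attempts = 0
    for _ in range(params.max_attempt_batches):
        projected = attempts * n / max(n_got, 1)
        if attempts >= 2 * batch and projected > params.max_attempt_batches * batch:
            # rejection sampling will not finish within budget for this
            # (typically short, CpG-dense) template; enumerate the qualifying
            # windows exactly and draw uniformly from them instead
            ci, starts = _enumerate_matches(
                length, target, slack, genome, eligible, params, template, rng, n
            )
            return ci, starts, length
        ci, starts = _sample_batch(length, genome, rng, batch, eligible, probs)
        counts = np.empty(batch, dtype=np.int64)
        for k, c in enumerate(eligible):
            mask = ci == k
            if not mask.any():
                continue
            pos = genome.cpg_positions.get(c, np.empty(0, dtype=np.int64))
            s = starts[mask]
            counts[mask] = np.searchsorted(pos, s + length) - np.searchsorted(pos, s)
        ok = np.abs(counts - target) <= slack
        if params.exclude_originals:
            same = np.array([eligible[i] == chrom for i in ci])
            ok &= ~(same & (starts < end) & (starts + length > start))
        attempts += batch
        if ok.any():
            got_ci.append(ci[ok])
            got_st.append(starts[ok])
            n_got += int(ok.sum())
        if n_got >= n:
            all_ci = np.concatenate(got_ci)[:n]
            all_st = np.concatenate(got_st)[:n]
            return all_ci, all_st, length
    raise MatchingFailureError(
        f"no random region with {target}±{slack} CpGs and length {length} found "
        f"for template {chrom}:{start}-{end} within the attempt budget"
    )


def _enumerate_matches(
    length: int,
    target: int,
    slack: int,
    genome: GenomeAnnotation,
    eligible: list[str],
    params: EnrichmentParams,
    template: Region,
    rng: np.random.Generator,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact sliding-window enumeration of every qualifying placement."""
    chrom, t_start, t_end = template
    all_ci: list[np.ndarray] = []
    all_st: list[np.ndarray] = []
    for k, c in enumerate(eligible):
        clen = genome.chromosomes[c]
        pos = genome.cpg_positions.get(c, np.empty(0, dtype=np.int64))
        starts = np.arange(max(clen - length, 1), dtype=np.int64)
        counts = np.searchsorted(pos, starts + length) - np.searchsorted(pos, starts)
        ok = np.abs(counts - target) <= slack
        if params.exclude_originals and c == chrom:
            ok &= ~((starts < t_end) & (starts + length > t_start))
        hit = starts[ok]
        if len(hit):
            all_ci.append(np.full(len(hit), k, dtype=np.int64))
            all_st.append(hit)
    if not all_ci:
        raise MatchingFailureError(
            f"no genomic window matches {target}±{slack} CpGs at length {length} "
            f"for template {chrom}:{t_start}-{t_end}"
        )
    pool_ci = np.concatenate(all_ci)
    pool_st = np.concatenate(all_st)
    idx = rng.integers(0, len(pool_ci), size=n)
    return pool_ci[idx], pool_st[idx]


def sample_matched_region(
    template: Region,
    genome: GenomeAnnotation,
    rng: np.random.Generator,
    params: EnrichmentParams | None = None,
) -> Region:
    """One random region matching a template in length and CpG count."""
    params = params or EnrichmentParams()
    eligible = [c for c, clen in genome.chromosomes.items() if clen >= template[2] - template[1]]
    ci, starts, length = _matched_starts(template, genome, rng, 1, params)
    return (eligible[int(ci[0])], int(starts[0]), int(starts[0]) + length)


def enrichment_test(
    regions: Sequence[Region],
    feature_track: Mapping[str, np.ndarray],
    genome: GenomeAnnotation,
    params: EnrichmentParams | None = None,
    feature_name: str = "feature",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Paired matched-random-region enrichment test for one feature track.

    Per iteration, every observed region is replaced by one matched random
    region and the count of regions overlapping the feature is recomputed;
    ``exceed_fraction`` is the fraction of iterations in which the observed
    count strictly exceeds the random one.  Deterministic given the seed.
    """
    params = params or EnrichmentParams()
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one region")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    track = {c: ivl.merge(iv) for c, iv in feature_track.items()}

    starts = np.array([r[1] for r in regions])
    ends = np.array([r[2] for r in regions])
    observed = 0
    for (chrom, s, e) in regions:
        iv = track.get(chrom, np.empty((0, 2), dtype=np.int64))
        observed += int(ivl.overlaps_any([s], [e], iv)[0])

    n_it = params.n_iterations
    random_counts = np.zeros(n_it, dtype=np.int64)
    for region in regions:
        ci, st, length = _matched_starts(region, genome, rng, n_it, params)
        eligible = [
            c for c, clen in genome.chromosomes.items() if clen >= region[2] - region[1]
        ]
        hits = np.zeros(n_it, dtype=bool)
        for k, c in enumerate(eligible):
            mask = ci == k
            if not mask.any():
                continue
            iv = track.get(c, np.empty((0, 2), dtype=np.int64))
            hits[mask] = ivl.overlaps_any(st[mask], st[mask] + length, iv)
        random_counts += hits

    exceed = float(np.mean(observed > random_counts))
    sig = None
    for level in sorted(params.significance_levels, reverse=True):
        if exceed >= 1 - level:
            sig = level
    return EnrichmentResult(
        feature=feature_name,
        n_regions=len(regions),
        observed=observed,
        null_mean=float(random_counts.mean()),
        exceed_fraction=exceed,
        significance=sig,
    )


def enrichment_panel(
    regions: Sequence[Region],
    feature_tracks: Mapping[str, Mapping[str, np.ndarray]],
    genome: GenomeAnnotation,
    params: EnrichmentParams | None = None,
) -> list[EnrichmentResult]:
    """Enrichment test per track with a per-track random stream.

    Each track's random stream is seeded from (seed, crc32(track name)), so
    results are independent of the order in which tracks are supplied.
    """
    params = params or EnrichmentParams()
    names = list(feature_tracks)
    if len(set(names)) != len(names):
        raise ValueError("duplicate track names")
    results = []
    for name in names:
        child = np.random.default_rng(
            [params.seed & 0x7FFFFFFF, zlib.crc32(name.encode())]
        )
        results.append(
            enrichment_test(
                regions,
                feature_tracks[name],
                genome,
                params,
                feature_name=name,
                rng=child,
            )
        )
    return results
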