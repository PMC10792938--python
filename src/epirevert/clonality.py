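"""VAF-trajectory variant classification and clonal-structure analysis.

Variants are grouped by their change in variant allele fraction (VAF)
between parental and resistant samples: present-in-parental (VpP, VAF drops
to 0), present-in-resistant (VpR, parental VAF 0 and resistant VAF > 0.1),
or present in both (VpPR).  Kernel density estimation of VpR VAFs reveals
clonal structure: a single expanded clone carrying each variant on one of
``ploidy`` haplotypes produces a VAF mode at 1/ploidy (0.25 in a
near-tetraploid population).  Bisulfite data can validate variant
persistence only for A>T / T>A substitutions at sufficient coverage, since
bisulfite conversion confounds every class involving C or G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

VCLASSES = ("VpP", "VpR", "VpPR", "unclassified")

#: columns of the canonical variant table
VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf_parental",
    "vaf_resistant",
)


@dataclass
class ClonalityParams:
    vpr_min_vaf: float = 0.1  # resistant VAF above which a parental-0 variant is VpR
    wgbs_min_coverage: int = 15  # strict > when filtering for bisulfite validation
    kde_bandwidth: float | None = None  # absolute VAF units; None = Silverman clipped
    ploidy: int = 4
    zero_epsilon: float = 0.0  # VAFs <= epsilon count as "0" in the class rules

    def __post_init__(self):
        if not 0 < self.vpr_min_vaf < 1:
            raise ValueError("vpr_min_vaf must be in (0, 1)")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


def classify_variants(vaf_parental, vaf_resistant, params: ClonalityParams | None = None):
    """Classify variants by their parental-to-resistant VAF trajectory.

    VpP: parental VAF > 0 and resistant VAF = 0.  VpR: parental VAF = 0 and
    resistant VAF > ``vpr_min_vaf``.  VpPR: both VAFs > 0.  Everything else
    (notably parental 0 with 0 < resistant <= vpr_min_vaf, and double zero)
    is unclassified.  Accepts scalars or arrays.
    """
    params = params or ClonalityParams()
    p = np.asarray(vaf_parental, dtype=float)
    r = np.asarray(vaf_resistant, dtype=float)
    if np.any((p < 0) | (p > 1) | (r < 0) | (r > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    eps = params.zero_epsilon
    p_zero = p <= eps
    r_zero = r <= eps
    out = np.full(np.broadcast(p, r).shape, "unclassified", dtype=object)
    out[~p_zero & r_zero] = "VpP"
    out[p_zero & (r > params.vpr_min_vaf)] = "VpR"
    out[~p_zero & ~r_zero] = "VpPR"
    if out.ndim == 0:
        return str(out[()])
    return out


def classify_table(
    variants: pd.DataFrame, params: ClonalityParams | None = None
) -> pd.DataFrame:
    """Add a ``vclass`` column to a variant table."""
    out = variants.copy()
    out["vclass"] = classify_variants(
        out["vaf_parental"].to_numpy(), out["vaf_resistant"].to_numpy(), params
    )
    return out


def vaf_density(
    vafs,
    bandwidth: float | None = None,
    grid_size: int = 1001,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Gaussian-kernel VAF density on [0, 1] with its modes.

    The bandwidth is in absolute VAF units; the default is Silverman's rule
    clipped to [0.01, 0.1].  Modes are local maxima of the density above 10%
    of the global maximum, sorted by height (highest first).  Returns
    (grid, density, modes).
    """
    v = np.asarray(vafs, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 VAF values for a density estimate")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    if bandwidth is None:
        sd = v.std(ddof=1)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        if spread == 0:
            bandwidth = 0.01
        else:
            bandwidth = float(np.clip(0.9 * spread * len(v) ** (-0.2), 0.01, 0.1))
        # fixed-depth VAFs live on a k/depth lattice; Silverman's rule then
        # undersmooths and the mode jumps between adjacent lattice points, so
        # never let the bandwidth drop below the lattice spacing
        uniq = np.unique(v)
        if len(uniq) > 1:
            spacing = float(np.min(np.diff(uniq)))
            bandwidth = max(bandwidth, min(spacing, 0.1))
    grid = np.linspace(0.0, 1.0, grid_size)
    # direct evaluation keeps the bandwidth in absolute units even for
    # degenerate (zero-variance) samples, where gaussian_kde fails
    dens = np.exp(
        -0.5 * ((grid[:, None] - v[None, :]) / bandwidth) ** 2
    ).sum(axis=1) / (len(v) * bandwidth * np.sqrt(2 * np.pi))
    peaks, _ = signal.find_peaks(dens, height=0.1 * dens.max())
    # interior plateaus and boundary maxima: fall back to argmax if no peak
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    order = np.argsort(dens[peaks])[::-1]
    modes = [float(grid[p]) for p in peaks[order]]
    return grid, dens, modes


def expected_clonal_vaf(
    ploidy: int, variant_copies: int = 1, purity: float = 1.0
) -> float:
    """Expected VAF of a clonal variant on ``variant_copies`` of ``ploidy`` alleles.

    With tumour purity < 1 the remaining cell fraction is assumed diploid and
    variant-free: VAF = purity * copies / (purity * ploidy + (1 - purity) * 2).
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 1 <= variant_copies <= ploidy:
        raise ValueError("variant_copies must lie in [1, ploidy]")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    return purity * variant_copies / (purity * ploidy + (1 - purity) * 2)


def per_chromosome_vaf(
    variants: pd.DataFrame,
    vaf_column: str = "vaf_resistant",
    bandwidth: float | None = None,
    min_support: int = 10,
) -> pd.DataFrame:
    """Per-chromosome VAF summary with the primary KDE mode.

    Chromosomes with fewer than ``min_support`` variants are flagged
    low-support; chromosomes with fewer than 2 variants report a NaN mode.
    Chromosomes with no variants are absent from the table.
    """
    rows = []
    for chrom, g in variants.groupby("chrom", sort=True):
        v = g[vaf_column].to_numpy(dtype=float)
        if len(v) >= 2:
            _, _, modes = vaf_density(v, bandwidth)
            mode = modes[0]
        else:
            mode = np.nan
        rows.append(
            {
                "chrom": chrom,
                "n_variants": len(v),
                "mean_vaf": float(v.mean()),
                "primary_mode": mode,
                "low_support": len(v) < min_support,
            }
        )
    return pd.DataFrame(rows)


_BISULFITE_SAFE = {("A", "T"), ("T", "A")}


def wgbs_validation_filter(
    variants: pd.DataFrame,
    params: ClonalityParams | None = None,
    coverage_column: str = "cov_wgbs",
) -> pd.DataFrame:
    """Keep only variants assessable in bisulfite data.

    Bisulfite conversion turns unmethylated C to T, so any substitution
    involving C or G is confounded; only A>T and T>A SNVs covered strictly
    above ``wgbs_min_coverage`` reads in the validating sample are kept.
    """
    params = params or ClonalityParams()
    ref = variants["ref"].astype(str).str.upper()
    alt = variants["alt"].astype(str).str.upper()
    safe = pd.Series(
        [(r, a) in _BISULFITE_SAFE for r, a in zip(ref, alt)], index=variants.index
    )
    covered = variants[coverage_column] > params.wgbs_min_coverage
    return variants.loc[safe & covered].copy()


def persistence_check(
    vprs: pd.DataFrame,
    vpps: pd.DataFrame,
    p12_column: str = "vaf_P12",
) -> dict:
    """Persistence of resistant-clone variants after drug withdrawal.

    A variant is present in P12 iff its P12 VAF is > 0.  Returns the
    fraction of VpRs present and the fraction of VpPs absent in P12, the
    per-variant tables, and counts of variants excluded for lacking a P12
    measurement.
    """

    def _split(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        if p12_column not in df.columns:
            return df.iloc[0:0], len(df)
        missing = df[p12_column].isna()
        return df.loc[~missing].copy(), int(missing.sum())

    vprs_ok, vprs_missing = _split(vprs)
    vpps_ok, vpps_missing = _split(vpps)
    vprs_ok["present_in_P12"] = vprs_ok[p12_column] > 0 if len(vprs_ok) else []
    vpps_ok["present_in_P12"] = vpps_ok[p12_column] > 0 if len(vpps_ok) else []
    return {
        "vpr_present_fraction": (
            float(vprs_ok["present_in_P12"].mean()) if len(vprs_ok) else np.nan
        ),
        "vpp_absent_fraction": (
            float((~vpps_ok["present_in_P12"]).mean()) if len(vpps_ok) else np.nan
        ),
        "vprs": vprs_ok,
        "vpps": vpps_ok,
        "vprs_missing_p12": vprs_missing,
        "vpps_missing_p12": vpps_missing,
    }
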