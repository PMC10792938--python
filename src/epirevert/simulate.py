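"""Synthetic genomes, methylomes, variant tables and dose-response surfaces.

Every generator plants a known ground truth (recorded in a TruthTable) so the
downstream DMR caller, reversion scorer, enrichment test, clonality analysis
and synergy fit can be validated without external data.  The defaults emulate
the study design the package targets: two cell lines observed in four states
(parental, MEK-inhibitor resistant, and P5/P12 after drug withdrawal), WGBS
methylation with beta-binomial noise at ~30x, a near-tetraploid clonal
structure with variant allele fractions centred on 1/ploidy at ~40x WGS
depth, predominantly hypermethylated planted DMRs (96%) of which ~10%
revert, and three-parameter log-logistic viability curves with a low-nM
IC50 for the MEK inhibitor.

All coordinates are 0-based half-open; identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .context import GenomeAnnotation
from .methylome import STATES, MethylomeTrack
from .pharmacology import DoseResponseCurve, loewe_expected


class GenerationError(RuntimeError):
    """A generator could not satisfy its configuration (e.g. overfull genome)."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_cpg_islands: int = 20
    background_cpg_rate: float = 0.01  # CpGs per bp outside islands
    island_cpg_rate: float = 0.10  # CpGs per bp inside islands
    island_length_range: tuple[int, int] = (500, 2000)
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    # methylome
    n_planted_dmrs: int = 50
    dmr_cpg_range: tuple[int, int] = (4, 30)
    dmr_delta: float = 0.5
    frac_hyper: float = 0.96
    frac_reverting: float = 0.10
    coverage_mean: float = 30.0
    bb_precision: float = 100.0  # beta-binomial precision (higher = less dispersed)
    bg_meth_alpha: float = 8.0  # background (non-island) methylation ~ Beta(8, 2)
    bg_meth_beta: float = 2.0
    island_meth_alpha: float = 2.0  # island CpGs are mostly unmethylated
    island_meth_beta: float = 8.0
    noiseless: bool = False
    lines: tuple[str, ...] = ("L1", "L2")
    # variants
    ploidy: int = 4
    n_vpr: int = 3000
    n_vpp: int = 500
    n_vppr: int = 1000
    wgs_depth: int = 40
    # features
    feature_enrichment_factor: float = 10.0
    # pharmacology
    ic50_true: float = 12.70  # nM, MEK inhibitor
    ic50_true_b: float = 500.0  # nM, the second (DNMT-inhibitor-like) drug
    hill_top: float = 100.0
    hill_bottom: float = 0.0
    dr_noise_sd: float = 2.0  # viability %
    planted_synergy: float = 0.0  # viability offset at saturating dose pairs

    def __post_init__(self):
        counts = (
            self.n_chroms,
            self.n_cpg_islands,
            self.n_genes,
            self.n_planted_dmrs,
            self.n_vpr,
            self.n_vpp,
            self.n_vppr,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.background_cpg_rate <= 0 or self.island_cpg_rate <= 0:
            raise ValueError("CpG rates must be > 0")
        if not 0 < self.dmr_delta <= 1:
            raise ValueError("dmr_delta must be in (0, 1]")
        for f in (self.frac_hyper, self.frac_reverting):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if len(self.lines) < 2:
            raise ValueError("need at least two cell lines")

    def to_yaml_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dmr_cpg_range"] = list(self.dmr_cpg_range)
        d["island_length_range"] = list(self.island_length_range)
        d["gene_length_range"] = list(self.gene_length_range)
        d["lines"] = list(self.lines)
        return d


@dataclass
class TruthTable:
    """Ground truth of one simulation run, for recovery checks."""

    planted_dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_feature_overlaps: dict[str, list[int]] = field(default_factory=dict)
    planted_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    ic50_true: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
                "planted_variants": self.planted_variants.to_dict(orient="records"),
                "planted_feature_overlaps": self.planted_feature_overlaps,
                "planted_genes": self.planted_genes.to_dict(orient="records"),
                "ic50_true": self.ic50_true,
            },
            indent=1,
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so products are individually stable
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Simulate chromosomes, CpG coordinates, islands and gene models.

    Background CpGs follow a homogeneous Poisson process; islands add CpGs at
    a denser rate.  Genes are non-overlapping spans with alternating
    exon/intron structure; the TSS sits at the strand-aware 5' end.
    """
    rng = _rng(config, 1)
    mean_island = sum(config.island_length_range) / 2
    per_chrom_islands = int(np.ceil(config.n_cpg_islands / max(config.n_chroms, 1)))
    if per_chrom_islands * mean_island > 0.5 * config.chrom_length:
        raise GenerationError(
            "island count x mean island size exceeds half the chromosome length"
        )

    chromosomes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    cpgs: dict[str, np.ndarray] = {}
    islands: dict[str, np.ndarray] = {}

    chrom_names = list(chromosomes)
    island_chroms = [chrom_names[i % len(chrom_names)] for i in range(config.n_cpg_islands)]
    for chrom, length in chromosomes.items():
        n_here = island_chroms.count(chrom)
        placed: list[tuple[int, int]] = []
        for _ in range(n_here):
            for _attempt in range(1000):
                ilen = int(rng.integers(*config.island_length_range, endpoint=True))
                s = int(rng.integers(0, length - ilen))
                if all(s + ilen <= ps or s >= pe for ps, pe in placed):
                    placed.append((s, s + ilen))
                    break
            else:
                raise GenerationError(f"could not place islands on {chrom}")
        placed.sort()
        islands[chrom] = (
            np.asarray(placed, dtype=np.int64)
            if placed
            else np.empty((0, 2), dtype=np.int64)
        )

        n_bg = rng.poisson(config.background_cpg_rate * length)
        pos = rng.integers(0, length, size=n_bg)
        extra = []
        for s, e in placed:
            n_isl = rng.poisson(config.island_cpg_rate * (e - s))
            extra.append(rng.integers(s, e, size=n_isl))
        if extra:
            pos = np.concatenate([pos] + extra)
        cpgs[chrom] = np.unique(pos).astype(np.int64)

    gene_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        length = chromosomes[chrom]
        for _attempt in range(1000):
            glen = int(rng.integers(*config.gene_length_range, endpoint=True))
            s = int(rng.integers(0, length - glen))
            if all(s + glen <= ps or s >= pe for ps, pe in occupied[chrom]):
                occupied[chrom].append((s, s + glen))
                break
        else:
            raise GenerationError(f"could not place genes on {chrom}")
        e = s + glen
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 7))
        # 2*n_ex - 2 interior cuts give alternating exon/intron segments that
        # start and end with an exon
        cuts = np.sort(rng.choice(np.arange(s + 1, e), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[s], cuts, [e]])
        exons = [
            (int(bounds[k]), int(bounds[k + 1])) for k in range(0, 2 * n_ex - 1, 2)
        ]
        gene_rows.append(
            {
                "gene_id": f"gene{gi + 1:04d}",
                "chrom": chrom,
                "strand": strand,
                "tss": s if strand == "+" else e - 1,
                "start": s,
                "end": e,
                "exons": exons,
            }
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end", "exons"]
    )
    return GenomeAnnotation(
        chromosomes=chromosomes,
        cpg_positions=cpgs,
        islands=islands,
        genes=genes,
        feature_tracks={},
    )


def _beta_binomial_level(
    rng: np.random.Generator, true: np.ndarray, cov: np.ndarray, precision: float
) -> np.ndarray:
    p = np.clip(true, 1e-6, 1 - 1e-6)
    latent = rng.beta(p * precision, (1 - p) * precision)
    k = rng.binomial(cov, latent)
    return k / np.maximum(cov, 1)


def generate_methylomes(
    genome: GenomeAnnotation, config: SimulationConfig
) -> tuple[dict[tuple[str, str], MethylomeTrack], TruthTable]:
    """Simulate per-CpG methylation for every (line, state) with planted DMRs.

    Non-DMR CpGs share one per-(line, CpG) baseline across all four states.
    Planted DMRs shift the resistant level by +/- dmr_delta in BOTH lines;
    reverting DMRs return to the parental level at P12 with the P5 level
    strictly between resistant and P12, non-reverting DMRs stay at the
    resistant level.  Observed levels are beta-binomial draws at
    Poisson(coverage_mean) coverage unless ``noiseless`` is set.
    """
    rng = _rng(config, 2)
    delta = config.dmr_delta

    # --- choose planted DMR CpG runs (non-overlapping, >= 1 CpG gap) -------
    chrom_names = [c for c in genome.chromosomes if len(genome.cpg_positions[c]) > 0]
    weights = np.array([len(genome.cpg_positions[c]) for c in chrom_names], dtype=float)
    weights /= weights.sum()
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    truth_rows = []
    for di in range(config.n_planted_dmrs):
        n_cpg = int(rng.integers(*config.dmr_cpg_range, endpoint=True))
        for _attempt in range(2000):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            pos = genome.cpg_positions[chrom]
            if len(pos) < n_cpg + 2:
                continue
            i0 = int(rng.integers(1, len(pos) - n_cpg - 1))
            i1 = i0 + n_cpg - 1
            # keep a >= 1 CpG buffer between planted runs
            if all(i1 + 1 < lo or i0 - 1 > hi for lo, hi in used[chrom]):
                used[chrom].append((i0, i1))
                break
        else:
            raise GenerationError(
                "could not place non-overlapping planted DMRs; genome too dense"
            )
        hyper = rng.random() < config.frac_hyper
        reverting = rng.random() < config.frac_reverting
        end = int(pos[i1]) + 2
        if i1 + 1 < len(pos):
            end = min(end, int(pos[i1 + 1]))  # never cover the next CpG
        truth_rows.append(
            {
                "dmr_id": f"dmr{di + 1:04d}",
                "chrom": chrom,
                "start": int(pos[i0]),
                "end": end,
                "cpg_lo": i0,
                "cpg_hi": i1,
                "n_cpgs": n_cpg,
                "direction": "hyper" if hyper else "hypo",
                "reverting": bool(reverting),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "dmr_id", "chrom", "start", "end", "cpg_lo", "cpg_hi",
            "n_cpgs", "direction", "reverting",
        ],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- true methylation levels per (line, state, CpG) ---------------------
    from . import intervals as ivl

    tracks: dict[tuple[str, str], MethylomeTrack] = {}
    true_levels: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for line in config.lines:
        per_state: dict[str, dict[str, np.ndarray]] = {st: {} for st in STATES}
        for chrom in genome.chromosomes:
            pos = genome.cpg_positions[chrom]
            in_island = ivl.overlaps_point_set(pos, genome.islands.get(chrom, []))
            base = np.where(
                in_island,
                rng.beta(config.island_meth_alpha, config.island_meth_beta, len(pos)),
                rng.beta(config.bg_meth_alpha, config.bg_meth_beta, len(pos)),
            )
            lev = {st: base.copy() for st in STATES}
            for row in truth.itertuples():
                if row.chrom != chrom:
                    continue
                sl = slice(row.cpg_lo, row.cpg_hi + 1)
                n = row.cpg_hi - row.cpg_lo + 1
                if row.direction == "hyper":
                    m_p = rng.uniform(0.02, 0.98 - delta, n)
                    m_r = m_p + delta
                else:
                    m_p = rng.uniform(0.02 + delta, 0.98, n)
                    m_r = m_p - delta
                lev["parental"][sl] = m_p
                lev["resistant"][sl] = m_r
                if row.reverting:
                    m_p12 = m_p
                    u = rng.uniform(0.3, 0.7, n)
                    m_p5 = m_r + u * (m_p12 - m_r)
                else:
                    m_p12 = m_r
                    m_p5 = m_r
                lev["P5"][sl] = m_p5
                lev["P12"][sl] = m_p12
            for st in STATES:
                per_state[st][chrom] = lev[st]
        for st in STATES:
            true_levels[(line, st)] = per_state[st]

    # --- observation noise ---------------------------------------------------
    for (line, st), per_chrom in true_levels.items():
        frames = []
        for chrom in genome.chromosomes:
            pos = genome.cpg_positions[chrom]
            true = per_chrom[chrom]
            if config.noiseless:
                cov = np.full(len(pos), int(round(config.coverage_mean)))
                meth = true
            else:
                cov = np.maximum(rng.poisson(config.coverage_mean, len(pos)), 1)
                meth = _beta_binomial_level(rng, true, cov, config.bb_precision)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "meth": meth, "cov": cov}
                )
            )
        tracks[(line, st)] = MethylomeTrack(
            line_id=line, state=st, records=pd.concat(frames, ignore_index=True)
        )
    return tracks, TruthTable(planted_dmrs=truth)


SNV_CLASSES = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
]  # all 12 substitution classes


def generate_variants(
    genome: GenomeAnnotation, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate clonal SNVs with VAF trajectories over the four cell states.

    VpRs sit on 1 of ``ploidy`` haplotypes of the resistant clone (true VAF
    1/ploidy in resistant and P12, 0 in parental); VpPs mirror this in the
    parental state only; VpPRs carry 1..ploidy copies in every state.
    Observed VAFs are Binomial(wgs_depth, true VAF) / wgs_depth; the WGBS
    validation coverage is Poisson(coverage_mean).
    """
    if config.wgs_depth < 1:
        raise GenerationError("wgs_depth must be >= 1")
    rng = _rng(config, 3)
    n_total = config.n_vpr + config.n_vpp + config.n_vppr
    classes = (
        ["VpR"] * config.n_vpr + ["VpP"] * config.n_vpp + ["VpPR"] * config.n_vppr
    )
    chrom_names = list(genome.chromosomes)
    lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    ci = rng.choice(len(chrom_names), size=n_total, p=lens / lens.sum())
    pos = (rng.random(n_total) * lens[ci]).astype(np.int64)
    sub = rng.integers(0, len(SNV_CLASSES), size=n_total)

    clonal = 1.0 / config.ploidy
    true_p = np.zeros(n_total)
    true_r = np.zeros(n_total)
    true_12 = np.zeros(n_total)
    copies = np.ones(n_total, dtype=int)
    for i, cl in enumerate(classes):
        if cl == "VpR":
            true_r[i] = true_12[i] = clonal
        elif cl == "VpP":
            true_p[i] = clonal
        else:
            copies[i] = int(rng.integers(1, config.ploidy + 1))
            true_p[i] = true_r[i] = true_12[i] = copies[i] / config.ploidy

    depth = config.wgs_depth
    cov_wgbs = np.maximum(rng.poisson(config.coverage_mean, n_total), 0)
    full = pd.DataFrame(
        {
            "chrom": [chrom_names[i] for i in ci],
            "pos": pos,
            "ref": [SNV_CLASSES[s][0] for s in sub],
            "alt": [SNV_CLASSES[s][1] for s in sub],
            "vaf_parental": rng.binomial(depth, true_p) / depth,
            "vaf_resistant": rng.binomial(depth, true_r) / depth,
            "vaf_P12": rng.binomial(depth, true_12) / depth,
            "cov_parental": depth,
            "cov_resistant": depth,
            "cov_P12": depth,
            "cov_wgbs": cov_wgbs,
            "vclass": classes,
            "copies": copies,
            "true_vaf_resistant": true_r,
        }
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    truth = full[["chrom", "pos", "vclass", "copies", "true_vaf_resistant"]].copy()
    variants = full.drop(columns=["vclass", "copies", "true_vaf_resistant"])
    return variants, TruthTable(planted_variants=truth)


def generate_feature_tracks(
    genome: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    track_names: tuple[str, ...] = ("TFBS", "ATAC", "H3K27ac"),
    background_density: float = 0.02,
    feature_length: int = 300,
) -> dict[str, dict[str, np.ndarray]]:
    """Feature interval tracks with controllable enrichment in planted DMRs.

    Each track covers roughly ``background_density`` of the genome at random
    and additionally drops a feature onto a planted DMR with probability
    min(1, background_density * feature_enrichment_factor); truth overlaps
    are recorded per track.
    """
    from . import intervals as ivl

    rng = _rng(config, 4)
    p_hit = min(1.0, background_density * config.feature_enrichment_factor)
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for name in track_names:
        per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
        for chrom, length in genome.chromosomes.items():
            n_bg = rng.poisson(background_density * length / feature_length)
            starts = rng.integers(0, max(length - feature_length, 1), size=n_bg)
            per_chrom[chrom].extend((int(s), int(s) + feature_length) for s in starts)
        hit_ids = []
        for row in truth.planted_dmrs.itertuples():
            if rng.random() < p_hit:
                mid = (row.start + row.end) // 2
                s = max(0, mid - feature_length // 2)
                per_chrom[row.chrom].append((s, s + feature_length))
                hit_ids.append(row.Index)
        tracks[name] = {
            c: ivl.merge(v) if v else np.empty((0, 2), dtype=np.int64)
            for c, v in per_chrom.items()
        }
        truth.planted_feature_overlaps[name] = hit_ids
    return tracks


def generate_expression(
    config: SimulationConfig, frac_de: float = 0.3
) -> tuple[pd.DataFrame, TruthTable]:
    """Gene-level log2 fold-change table with planted reverting transcripts.

    ``frac_de`` of genes are differentially expressed between parental and
    resistant (|log2FC| in [1.5, 4]); of those, ``frac_reverting`` revert
    (log2FC(P12, R) matches log2FC(P, R)) while the rest stay resistant-like
    (log2FC(P12, R) near 0).  Null genes have |log2FC| < 1 in both columns.
    """
    rng = _rng(config, 5)
    n = config.n_genes
    n_de = int(round(frac_de * n))
    n_rev = int(round(config.frac_reverting * n_de))
    noise = 0.0 if config.noiseless else 0.05
    rows = []
    for gi in range(n):
        gid = f"gene{gi + 1:04d}"
        if gi < n_rev:
            label = "reverting"
            l1 = rng.uniform(1.5, 4.0) * (1 if rng.random() < 0.5 else -1)
            l2 = l1 + rng.normal(0, noise)
        elif gi < n_de:
            label = "non_reverting"
            l1 = rng.uniform(1.5, 4.0) * (1 if rng.random() < 0.5 else -1)
            l2 = rng.normal(0, noise)
        else:
            label = "null"
            l1 = rng.uniform(-0.9, 0.9)
            l2 = rng.uniform(-0.9, 0.9)
        rows.append(
            {
                "gene_id": gid,
                "log2fc_P_vs_R": l1 + rng.normal(0, noise),
                "log2fc_P12_vs_R": l2,
                "truth": label,
            }
        )
    table = pd.DataFrame(rows)
    truth = TruthTable(planted_genes=table[["gene_id", "truth"]].copy())
    return table, truth


@dataclass
class DoseResponseData:
    """Single-agent responses and a combination surface for two drugs."""

    doses_a: np.ndarray
    responses_a: np.ndarray
    doses_b: np.ndarray
    responses_b: np.ndarray
    surface: np.ndarray  # viability %, shape (len(doses_a), len(doses_b))
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve


def generate_dose_response(
    config: SimulationConfig,
    doses_a: np.ndarray | None = None,
    doses_b: np.ndarray | None = None,
) -> tuple[DoseResponseData, TruthTable]:
    """Simulate viability under two drugs and their Loewe-additive combination.

    Single-drug responses follow the three-parameter log-logistic model
    (Hill slope 1) at the configured IC50/top/bottom plus Gaussian noise;
    the combination surface is the Loewe expectation plus the planted
    synergy offset scaled by joint receptor occupancy (zero on the margins).
    """
    rng = _rng(config, 6)

    def _default_grid(ic50: float) -> np.ndarray:
        return np.concatenate([[0.0], np.geomspace(ic50 / 64, ic50 * 64, 9)])

    if doses_a is None:
        doses_a = _default_grid(config.ic50_true)
    if doses_b is None:
        doses_b = _default_grid(config.ic50_true_b)
    for grid in (doses_a, doses_b):
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise GenerationError("dose grid must be strictly increasing")
        if np.any(grid < 0):
            raise GenerationError("doses must be >= 0")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)

    curve_a = DoseResponseCurve(
        "drugA", config.ic50_true, config.hill_top, config.hill_bottom
    )
    curve_b = DoseResponseCurve(
        "drugB", config.ic50_true_b, config.hill_top, config.hill_bottom
    )
    sd = 0.0 if config.noiseless else config.dr_noise_sd
    resp_a = curve_a(doses_a) + rng.normal(0, sd, len(doses_a))
    resp_b = curve_b(doses_b) + rng.normal(0, sd, len(doses_b))

    surface = np.empty((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            base = loewe_expected(curve_a, curve_b, da, db)
            occ = (da / (da + curve_a.ic50)) * (db / (db + curve_b.ic50))
            surface[i, j] = base + config.planted_synergy * occ + rng.normal(0, sd)
    truth = TruthTable(
        ic50_true={"drugA": config.ic50_true, "drugB": config.ic50_true_b}
    )
    return (
        DoseResponseData(doses_a, resp_a, doses_b, resp_b, surface, curve_a, curve_b),
        truth,
    )
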