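"""End-to-end driver: simulate, call DMRs, score reversion, annotate, enrich,
classify variants, and write per-stage outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__, io as eio
from .clonality import ClonalityParams, classify_table
from .context import (
    build_cpg_context,
    build_gene_context,
    composition_chisq,
    genome_composition,
    regions_composition,
)
from .enrichment import EnrichmentParams, enrichment_panel
from .methylome import DMRCallParams, call_dmrs, summarize_dmrs
from .reversion import ReversionParams, classify_reverting_dmrs
from .simulate import (
    SimulationConfig,
    generate_feature_tracks,
    generate_genome,
    generate_methylomes,
    generate_variants,
)

log = logging.getLogger("epirevert")

DEFAULT_STAGES = ("simulate", "call_dmrs", "reversion", "annotate", "enrich", "clonality")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "epirevert_run",
    stages: tuple[str, ...] = DEFAULT_STAGES,
) -> dict:
    """Run the synthetic pipeline end to end and write a run manifest.

    ``config`` may contain blocks ``simulation``, ``dmr``, ``reversion``,
    ``enrichment`` and ``clonality`` whose keys override the corresponding
    parameter defaults, plus a global ``seed``.  Each stage writes its
    outputs under ``outdir``; a failure halts with the stage name while
    earlier outputs remain on disk.  The manifest records parameters, seed,
    package version and content checksums, which suffice to reproduce the
    run bit for bit.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    sim_kwargs = dict(config.get("simulation", {}))
    sim_kwargs.setdefault("seed", seed)
    for key in ("dmr_cpg_range", "island_length_range", "gene_length_range", "lines"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim = SimulationConfig(**sim_kwargs)
    dmr_params = DMRCallParams(**config.get("dmr", {}))
    rev_params = ReversionParams(**config.get("reversion", {}))
    enr_kwargs = dict(config.get("enrichment", {}))
    enr_kwargs.setdefault("seed", seed)
    enr_params = EnrichmentParams(**enr_kwargs)
    clo_params = ClonalityParams(**config.get("clonality", {}))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "parameters": {
            "simulation": sim.to_yaml_dict(),
            "dmr": dataclasses.asdict(dmr_params),
            "reversion": dataclasses.asdict(rev_params),
            "enrichment": dataclasses.asdict(enr_params),
            "clonality": dataclasses.asdict(clo_params),
        },
        "outputs": {},
        "results": {},
    }
    results: dict = {"manifest": manifest}

    def _record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": eio.file_checksum(path),
        }

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.time()
            log.info("stage %s: start", stage)
            if stage == "simulate":
                genome = generate_genome(sim)
                tracks, truth = generate_methylomes(genome, sim)
                features = generate_feature_tracks(genome, truth, sim)
                variants, vtruth = generate_variants(genome, sim)
                state.update(
                    genome=genome,
                    tracks=tracks,
                    truth=truth,
                    features=features,
                    variants=variants,
                    vtruth=vtruth,
                )
                eio.write_genome_bed(
                    genome, outdir / "islands.bed", outdir / "genes.bed"
                )
                for (ln, st), tr in tracks.items():
                    p = outdir / f"methylation_{ln}_{st}.bedgraph"
                    eio.write_methylation_table(tr, p)
                eio.write_vcf(variants, outdir / "variants.vcf")
                (outdir / "truth.json").write_text(truth.to_json())
                with open(outdir / "config.yaml", "w") as fh:
                    yaml.safe_dump(sim.to_yaml_dict(), fh)
                for name in ("islands.bed", "genes.bed", "variants.vcf", "truth.json"):
                    _record(name, outdir / name)
            elif stage == "call_dmrs":
                dmrs = call_dmrs(state["tracks"], dmr_params)
                state["dmrs"] = dmrs
                manifest["results"]["dmr_summary"] = summarize_dmrs(dmrs)
                eio.write_dmrs(dmrs, outdir / "dmrs.tsv")
                _record("dmrs.tsv", outdir / "dmrs.tsv")
            elif stage == "reversion":
                dmrs, cutoff = classify_reverting_dmrs(state["dmrs"], rev_params)
                manifest["results"]["reversion_cutoff"] = cutoff
                manifest["results"]["n_reverting"] = sum(d.reverting for d in dmrs)
                eio.write_dmrs(dmrs, outdir / "dmrs_scored.tsv")
                _record("dmrs_scored.tsv", outdir / "dmrs_scored.tsv")
            elif stage == "annotate":
                genome = state["genome"]
                part = build_cpg_context(genome.islands, genome.chromosomes)
                gpart = build_gene_context(genome.genes, genome.chromosomes)
                regions = [d.region for d in state["dmrs"]]
                obs = regions_composition(regions, part)
                bg = genome_composition(part)
                stat, p = composition_chisq(obs, bg)
                manifest["results"]["cpg_context"] = obs.fractions
                manifest["results"]["cpg_context_chisq"] = {"stat": stat, "p": p}
                gobs = regions_composition(regions, gpart)
                manifest["results"]["gene_context"] = gobs.fractions
            elif stage == "enrich":
                regions = [d.region for d in state["dmrs"]]
                if regions:
                    panel = enrichment_panel(
                        regions, state["features"], state["genome"], enr_params
                    )
                    manifest["results"]["enrichment"] = [
                        dataclasses.asdict(r) for r in panel
                    ]
            elif stage == "clonality":
                classified = classify_table(state["variants"], clo_params)
                counts = classified["vclass"].value_counts().to_dict()
                manifest["results"]["variant_classes"] = {
                    k: int(v) for k, v in counts.items()
                }
                classified.to_csv(outdir / "variants_classified.tsv", sep="\t", index=False)
                _record("variants_classified.tsv", outdir / "variants_classified.tsv")
            else:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results.update(state)
    return results
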