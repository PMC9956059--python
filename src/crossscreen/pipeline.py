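"""End-to-end orchestration: simulate → screen → annotate → narrow → enrich → qc.

A run is driven by one YAML config and one seed.  Outputs are plain text
(VCF/TSV/FASTA/JSON) under the output directory, and a run manifest records
the package version, a hash of the fully-resolved config, the seed, per-stage
tallies (sites in, screen passes, exonic, missense — the synthetic analog of
a narrowing chain) and a checksum of every output file.  No timestamps are
written, so re-running an identical config reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, effect_annotation, enrichment, formats_io, qc_metrics
from .errors import ConfigError, CrossScreenError, StageError
from .mendelian_screen import ScreenPolicy, screen_all
from .synthetic_cross import SimConfig, emit_dataset, simulate_dataset

log = logging.getLogger("crossscreen")

STAGES = ("simulate", "screen", "annotate", "narrow", "enrich", "qc")


@dataclass(frozen=True)
class EnrichmentConfig:
    """Synthetic annotation layer for the demo enrichment stage."""

    n_terms: int = 8
    n_extra_genes: int = 40
    mean_term_size: int = 10


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "crossscreen_out"
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.sim.validate()

    def resolved(self) -> "RunConfig":
        """Propagate the run seed into the simulator configuration."""
        return replace(self, sim=replace(self.sim, seed=self.seed))


def load_run_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Build a RunConfig from YAML; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return build_run_config(raw, **overrides)


def build_run_config(raw: dict, **overrides: Any) -> RunConfig:
    try:
        sim = SimConfig(**raw.get("sim", {}))
        policy = ScreenPolicy(**raw.get("policy", {}))
        enrich_cfg = EnrichmentConfig(**raw.get("enrichment", {}))
        cfg = RunConfig(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "crossscreen_out")),
            stages=tuple(raw.get("stages", STAGES)),
            sim=sim, policy=policy, enrichment=enrich_cfg,
        )
        for key, value in overrides.items():
            if value is not None:
                cfg = replace(cfg, **{key: value})
        cfg.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid run config: {exc}") from exc
    return cfg


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_annotations(
    gene_ids: list[str], cfg: EnrichmentConfig, seed: int
) -> tuple[list[enrichment.TermAnnotation], set[str]]:
    """A seeded, made-up term layer over the simulated genes plus padding genes."""
    rng = np.random.default_rng(seed % (2**31))
    universe = list(gene_ids) + [f"pad_gene_{i + 1}" for i in range(cfg.n_extra_genes)]
    annotations = []
    for t in range(cfg.n_terms):
        size = min(len(universe), max(2, int(rng.poisson(cfg.mean_term_size))))
        genes = rng.choice(universe, size=size, replace=False)
        annotations.append(enrichment.TermAnnotation(
            term_id=f"TERM:{t + 1:04d}", term_name=f"synthetic term {t + 1}",
            genes=frozenset(genes.tolist()),
        ))
    return annotations, set(universe)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run manifest."""
    config.validate()
    config = config.resolved()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "crossscreen",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": [],
        "tallies": {},
        "outputs": {},
    }
    state: dict[str, Any] = {}

    def _run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        log.info("stage %s: starting", name)
        try:
            fn()
        except CrossScreenError as exc:
            raise StageError(f"stage {name}: {exc}") from exc
        manifest["stages"].append(name)
        log.info("stage %s: done", name)

    def _simulate() -> None:
        ds = simulate_dataset(config.sim)
        state["paths"] = emit_dataset(ds, outdir / "data")
        state["dataset"] = ds
        manifest["tallies"]["sites"] = config.sim.n_sites

    def _screen() -> None:
        sites, _ = formats_io.read_vcf(state["paths"]["vcf"])
        sample_groups = formats_io.read_manifest(state["paths"]["manifest"])
        decisions, tallies = screen_all(sites, sample_groups, config.policy)
        formats_io.write_decisions(decisions, outdir / "decisions.tsv")
        state["sites"] = sites
        state["decisions"] = decisions
        manifest["tallies"]["screen_pass"] = tallies.get("PASS", 0)
        manifest["tallies"]["screen_reasons"] = dict(sorted(tallies.items()))

    def _annotate() -> None:
        models = effect_annotation.read_gene_models(state["paths"]["gene_models"])
        reference = formats_io.read_fasta(state["paths"]["reference"])
        effects = effect_annotation.annotate_all(state["sites"], models, reference)
        effect_annotation.write_effects(effects, outdir / "effects.tsv")
        state["effects"] = effects
        state["models"] = models

    def _narrow() -> None:
        result = effect_annotation.narrow_candidates(state["decisions"],
                                                     state["effects"])
        state["narrow"] = result
        effect_by_key = {e.key: e for e in state["effects"]}
        records = [
            formats_io.CandidateRecord(
                snp_id=f"SNP {i + 1}", chrom=k[0], pos=k[1],
                gene_id=effect_by_key[k].gene_id or ".",
                transcript_id=effect_by_key[k].transcript_id or ".",
                coding_change=effect_by_key[k].coding_change or ".",
                protein_change=effect_by_key[k].protein_change or ".",
            )
            for i, k in enumerate(result.stage_missense)
        ]
        formats_io.write_candidates(records, outdir / "candidates.tsv")
        with (outdir / "narrow_report.json").open("w") as fh:
            json.dump({
                "per_chromosome": dict(sorted(result.per_chromosome.items())),
                "effect_tally": dict(sorted(result.effect_tally.items())),
            }, fh, indent=2, sort_keys=True)
        manifest["tallies"]["exonic"] = len(result.stage_cds)
        manifest["tallies"]["missense"] = len(result.stage_missense)

    def _enrich() -> None:
        result = state["narrow"]
        effect_by_key = {e.key: e for e in state["effects"]}
        candidate_genes = {effect_by_key[k].gene_id for k in result.stage_cds
                           if effect_by_key[k].gene_id}
        gene_ids = sorted({m.gene_id for m in state["models"]})
        annotations, universe = _synthetic_annotations(
            gene_ids, config.enrichment, config.seed + 11)
        enrichment.write_annotations(annotations, outdir / "annotations.tsv")
        results = enrichment.enrich_terms(candidate_genes, annotations, universe)
        enrichment.write_results(results, outdir / "enrichment.tsv")
        manifest["tallies"]["terms_tested"] = len(results)

    def _qc() -> None:
        rows = qc_metrics.qc_report(formats_io.load_table2_fixture())
        import pandas as pd
        pd.DataFrame(rows).to_csv(outdir / "qc.tsv", sep="\t", index=False)
        manifest["tallies"]["qc_pass"] = sum(r["qc_pass"] for r in rows)

    _run_stage("simulate", _simulate)
    _run_stage("screen", _screen)
    _run_stage("annotate", _annotate)
    _run_stage("narrow", _narrow)
    _run_stage("enrich", _enrich)
    _run_stage("qc", _qc)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _file_sha256(path)
    with (outdir / "run_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
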