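"""End-to-end orchestration: ingest → annotate → popgen → enrichment.

Every stage writes its TSV with a provenance header (package version +
config hash) and the run ends with a single summary mapping.  Stage
outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, enrichment, formats_io, popgen
from .model import RegionClass

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and record context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (defaults match the analysis design)."""

    vcf: str = ""
    gff3: str = ""
    panel: str = ""
    known_sites: str | None = None
    evidence: str | None = None
    go: str | None = None
    disease: str | None = None
    out_dir: str = "results"

    q95: float = 0.95
    q99: float = 0.99
    alpha: float = 0.05
    r_threshold: float = -0.5
    min_datasets: int = 2
    psma_high_freq: float = 0.5
    B_target: int = 2000
    B_process: int = 2000
    B_disease: int = 10000
    seed: int = 0
    obs_set_size: int = 8
    africa_label: str = "Africa"
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.q95 < 1 or not 0 < self.q99 < 1:
            raise ValueError("percentile thresholds must lie in (0, 1)")
        if self.q99 < self.q95:
            raise ValueError("q99 must be >= q95")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")
        for b in ("B_target", "B_process", "B_disease"):
            if getattr(self, b) < 1:
                raise ValueError(f"{b} must be >= 1")
        if self.run_enrichment and (self.evidence is None) != (self.go is None):
            raise ValueError(
                "enrichment needs both evidence and GO tables (or neither)"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the summary mapping (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    # hash covers analysis parameters only, not the output location
    hashed = {k: v for k, v in config.to_mapping().items() if k != "out_dir"}
    meta = {"config_hash": formats_io.config_hash(hashed), "seed": config.seed}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    # ---- ingest ----------------------------------------------------------
    try:
        panel = formats_io.read_panel(config.panel)
        catalog = formats_io.read_mirna_gff(config.gff3)
        known = (
            formats_io.read_known_sites(config.known_sites)
            if config.known_sites else None
        )
        raw = formats_io.read_vcf(config.vcf, panel, known)
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        raise PipelineError("ingest", str(exc)) from exc

    # ---- annotate --------------------------------------------------------
    try:
        annotated = annotate.annotate_variants(raw, catalog)
        in_hairpin = annotated.subset(
            np.array([v.region is not RegionClass.NONE for v in annotated.variants])
        )
        filtered, n_singletons = annotate.drop_singletons(in_hairpin)
        counts = annotate.region_counts(filtered, deduplicate=True)
        counts_per_mirna = annotate.region_counts(filtered, deduplicate=False)
        density = annotate.region_density(filtered, catalog, deduplicate=True)
        formats_io.write_tsv(filtered.to_frame(), out("variants_annotated.tsv"), meta=meta)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc

    unique_keys = {v.key for v in filtered.variants}
    unique_variants = [
        v for i, v in enumerate(filtered.variants)
        if v.key not in {filtered.variants[j].key for j in range(i)}
    ]
    n_snp = sum(1 for v in unique_variants if v.variant_type == "SNP")
    n_novel = sum(1 for v in unique_variants if not v.known)

    # ---- popgen ----------------------------------------------------------
    try:
        thetas = popgen.watterson_by_class(filtered, panel, catalog, "population")
        theta_frame = pd.DataFrame(
            [dataclasses.asdict(t) for t in thetas]
        )
        formats_io.write_tsv(theta_frame, out("theta.tsv"), meta=meta)

        psma, psma_density = popgen.detect_psma(
            filtered, panel, high_freq_threshold=config.psma_high_freq
        )
        formats_io.write_tsv(
            pd.DataFrame([dataclasses.asdict(r) for r in psma]),
            out("psma.tsv"), meta=meta,
        )

        records = popgen.fst_scan(filtered, panel)
        pooled = [r for r in records if r.kind == "pooled" and r.defined]
        if pooled:
            values = [r.theta_reported for r in pooled]
            q95 = popgen.percentile_threshold(values, config.q95)
            q99 = popgen.percentile_threshold(values, config.q99)
            pd_classes = popgen.classify_pd(pooled, q95, q99, config.alpha)
            mirna_labels = popgen.mirna_pd_labels(pd_classes, filtered)
        else:
            q95 = q99 = float("nan")
            pd_classes, mirna_labels = [], {}
        fst_frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
        label_by_key = {c.variant_key: c.label for c in pd_classes}
        if not fst_frame.empty:
            fst_frame["label"] = [
                label_by_key.get(k, "") if kind == "pooled" else ""
                for k, kind in zip(fst_frame["variant_key"], fst_frame["kind"])
            ]
        formats_io.write_tsv(
            fst_frame, out("fst.tsv"), meta={**meta, "q95": q95, "q99": q99}
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("popgen", str(exc)) from exc

    pd_mirnas = sorted(m for m, lab in mirna_labels.items() if lab in ("PD", "HPD"))
    hpd_mirnas = sorted(m for m, lab in mirna_labels.items() if lab == "HPD")

    summary: dict = {
        "n_variants": len(unique_keys),
        "n_snp": n_snp,
        "n_indel": len(unique_keys) - n_snp,
        "n_novel": n_novel,
        "n_singletons_removed": n_singletons,
        "region_counts": {rc.value: counts[rc] for rc in RegionClass},
        "region_counts_per_mirna": {
            rc.value: counts_per_mirna[rc] for rc in RegionClass
        },
        "region_density": {
            rc.value: density[rc] for rc in density
        },
        "n_psma": len(psma),
        "n_psma_high_freq": sum(1 for r in psma if r.high_frequency),
        "psma_density": psma_density,
        "fst_q95": q95,
        "fst_q99": q99,
        "pd_mirnas": pd_mirnas,
        "hpd_mirnas": hpd_mirnas,
    }

    # ---- enrichment ------------------------------------------------------
    if config.run_enrichment and config.evidence and config.go:
        try:
            evidence = formats_io.read_evidence(config.evidence)
            go = formats_io.read_go(config.go)
            target_map = enrichment.filter_evidence(
                evidence,
                r_threshold=config.r_threshold,
                min_datasets=config.min_datasets,
            )
            catalog_ids = catalog.mirna_ids
            obs = hpd_mirnas[: config.obs_set_size]
            if len(obs) < config.obs_set_size:
                extra = [m for m in pd_mirnas if m not in obs]
                obs = (obs + extra)[: config.obs_set_size]
            summary["enrichment_obs_set"] = obs
            if obs:
                gene_res = enrichment.bootstrap_target_enrichment(
                    obs, catalog_ids, target_map,
                    B=config.B_target, seed=config.seed, alpha=config.alpha,
                )
                proc_res = enrichment.bootstrap_process_enrichment(
                    obs, catalog_ids, target_map, go,
                    B=config.B_process, seed=config.seed + 1, alpha=config.alpha,
                )
                obs_genes = sorted(
                    g for g in target_map.genes_of(obs) if g in go.background
                )
                hyper = enrichment.genomic_go_enrichment(obs_genes, go) if obs_genes else []
                formats_io.write_tsv(
                    pd.DataFrame([dataclasses.asdict(r) for r in gene_res]),
                    out("enrichment_targets.tsv"), meta=meta,
                )
                formats_io.write_tsv(
                    pd.DataFrame([dataclasses.asdict(r) for r in proc_res]),
                    out("enrichment_processes.tsv"), meta=meta,
                )
                formats_io.write_tsv(
                    pd.DataFrame([dataclasses.asdict(r) for r in hyper]),
                    out("enrichment_go_hypergeometric.tsv"),
                    meta={**meta, "note": "hypergeometric+BH approximation"},
                )
                summary["n_enriched_targets"] = sum(r.enriched for r in gene_res)
                summary["n_enriched_processes"] = sum(r.enriched for r in proc_res)
            if config.disease and pd_mirnas:
                disease = formats_io.read_disease(config.disease)
                dz = enrichment.disease_bootstrap(
                    pd_mirnas, disease, catalog_ids,
                    B=config.B_disease, seed=config.seed + 2,
                )
                formats_io.write_tsv(
                    pd.DataFrame([dataclasses.asdict(dz)]),
                    out("disease_bootstrap.tsv"), meta=meta,
                )
                summary["disease_bootstrap"] = dataclasses.asdict(dz)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", str(exc)) from exc

    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
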