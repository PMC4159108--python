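"""Self-contained simulated fixture worlds with known ground truth.

Genotypes follow the Balding–Nichols model: an ancestral frequency
p ~ Uniform(0.05, 0.95), per-population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), and diploid genotypes Binomial(2, p_pop).
Loci are independent (no linkage).  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval
from .model import (
    DiseaseAssociationTable,
    GenomePanel,
    GoAnnotationTable,
    MatureArm,
    MirnaCatalog,
    MirnaRecord,
    TargetEvidenceTable,
    Variant,
    VariantTable,
)

_DEFAULT_REGIONS = ("Africa", "Europe", "Asia")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def simulate_catalog(
    n_mirna: int,
    hairpin_len: int = 100,
    seed: int = 0,
    *,
    per_contig: int = 50,
    spacing: int = 200,
) -> MirnaCatalog:
    """Non-overlapping hairpins on synthetic contigs, two mature arms each.

    Every hairpin carries a 5' and a 3' mature arm of 20–23 nt with derived
    seeds; strands alternate between consecutive hairpins.
    """
    if hairpin_len < 50:
        raise ValueError(
            f"hairpin_len={hairpin_len} cannot accommodate two mature arms"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_mirna):
        contig = f"chrS{i // per_contig + 1}"
        offset = (i % per_contig) * (hairpin_len + spacing) + spacing
        strand = "+" if i % 2 == 0 else "-"
        mid = f"sim-mir-{i + 1}"
        hairpin = Interval(offset, offset + hairpin_len)
        len5, len3 = rng.integers(20, 24, size=2)
        arm5 = Interval(hairpin.start, hairpin.start + int(len5))
        arm3 = Interval(hairpin.end - int(len3), hairpin.end)
        if arm5.overlaps(arm3):
            raise ValueError(f"cannot place non-overlapping arms in {mid}")
        records.append(
            MirnaRecord(
                mirna_id=mid, chrom=contig, hairpin=hairpin, strand=strand,
                mature_arms=(
                    MatureArm(f"{mid}-5p", arm5, strand),
                    MatureArm(f"{mid}-3p", arm3, strand),
                ),
            )
        )
    return MirnaCatalog(records)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the genotype simulator.

    ``sample_sizes`` maps population → diploid count; ``fst`` is the
    Balding–Nichols drift parameter, global or per population.  The three
    ``fraction_*`` knobs place loci inside catalog regions (their
    remainder to 1 falls outside every hairpin).
    """

    sample_sizes: dict[str, int]
    fst: float | dict[str, float] = 0.2
    n_loci: int = 100
    fraction_seed: float = 0.1
    fraction_mature: float = 0.2
    fraction_stem: float = 0.5
    regions: dict[str, str] | None = None
    hunter_gatherer: frozenset[str] = field(default_factory=frozenset)
    admixed: frozenset[str] = field(default_factory=frozenset)
    n_planted_pd: int = 0
    pd_gap: float = 0.6
    n_private_per_population: int = 0
    known_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_sizes:
            raise ValueError("need at least one population")
        for pop, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"population {pop} needs >= 2 diploids, got {n}")
        for f in self.fst_by_population().values():
            if not 0 < f < 1:
                raise ValueError(f"drift parameter F must lie in (0, 1), got {f}")
        total = self.fraction_seed + self.fraction_mature + self.fraction_stem
        if total > 1 + 1e-9:
            raise ValueError(f"region fractions sum to {total} > 1")
        n_planted = self.n_planted_pd + self.n_private_per_population * len(
            self.sample_sizes
        )
        if n_planted > self.n_loci:
            raise ValueError(
                f"{n_planted} planted loci exceed n_loci={self.n_loci}"
            )

    def fst_by_population(self) -> dict[str, float]:
        if isinstance(self.fst, dict):
            return dict(self.fst)
        return {p: float(self.fst) for p in self.sample_sizes}

    def region_by_population(self) -> dict[str, str]:
        if self.regions is not None:
            return dict(self.regions)
        out = {}
        for i, pop in enumerate(sorted(self.sample_sizes)):
            if pop in self.admixed:
                out[pop] = "Admixed"
            else:
                out[pop] = _DEFAULT_REGIONS[i % len(_DEFAULT_REGIONS)]
        return out


def build_panel(config: SimConfig) -> GenomePanel:
    regions = config.region_by_population()
    rows = []
    for pop in sorted(config.sample_sizes):
        for j in range(config.sample_sizes[pop]):
            rows.append(
                {
                    "sample_id": f"{pop}_{j + 1:03d}",
                    "population": pop,
                    "region": regions[pop],
                    "hunter_gatherer": pop in config.hunter_gatherer,
                    "admixed": pop in config.admixed,
                }
            )
    return GenomePanel(pd.DataFrame(rows))


def _catalog_positions(catalog: MirnaCatalog) -> dict[str, list[tuple[str, int]]]:
    """Candidate (chrom, pos) per region class, plus inter-hairpin 'none'."""
    from .annotate import _region_of_span  # per-base oracle labeling

    by_class: dict[str, list[tuple[str, int]]] = {
        "seed": [], "mature": [], "stem-loop": [], "none": [],
    }
    for rec in catalog:
        for pos in range(rec.hairpin.start, rec.hairpin.end):
            label = _region_of_span(Interval(pos, pos + 1), rec).value
            by_class[label].append((rec.chrom, pos))
        # a strip of inter-hairpin sequence immediately downstream
        for pos in range(rec.hairpin.end + 5, rec.hairpin.end + 55):
            by_class["none"].append((rec.chrom, pos))
    return by_class


def simulate_genotypes(
    config: SimConfig, catalog: MirnaCatalog
) -> tuple[VariantTable, GenomePanel, dict]:
    """Simulate a variant table + panel with planted structure.

    Returns ``(table, panel, truth)`` where ``truth`` records the planted
    PD loci, private alleles, per-class locus counts, and design
    frequencies.
    """
    rng = np.random.default_rng(config.seed)
    panel = build_panel(config)
    pops = sorted(config.sample_sizes)
    fst = config.fst_by_population()
    regions = config.region_by_population()

    # --- locus placement -------------------------------------------------
    candidates = _catalog_positions(catalog)
    fractions = {
        "seed": config.fraction_seed,
        "mature": config.fraction_mature,
        "stem-loop": config.fraction_stem,
    }
    fractions["none"] = max(0.0, 1.0 - sum(fractions.values()))
    wanted = {}
    assigned = 0
    for cls in ("seed", "mature", "stem-loop"):
        wanted[cls] = int(round(fractions[cls] * config.n_loci))
        assigned += wanted[cls]
    wanted["none"] = config.n_loci - assigned
    positions: list[tuple[str, int, str]] = []
    for cls, count in wanted.items():
        pool = candidates[cls]
        if count > len(pool):
            raise ValueError(
                f"cannot place {count} loci in {len(pool)} available {cls} bases"
            )
        picks = rng.choice(len(pool), size=count, replace=False)
        positions.extend((pool[i][0], pool[i][1], cls) for i in picks)
    positions.sort()

    # --- planted structure assignment ------------------------------------
    n_loci = len(positions)
    locus_idx = rng.permutation(n_loci)
    cursor = 0
    pd_loci = list(locus_idx[cursor : cursor + config.n_planted_pd])
    cursor += config.n_planted_pd
    private_loci: dict[int, str] = {}
    for pop in pops:
        for _ in range(config.n_private_per_population):
            private_loci[int(locus_idx[cursor])] = pop
            cursor += 1

    afr_pops = [p for p in pops if regions[p] == "Africa" and p not in config.admixed]
    non_pops = [
        p for p in pops
        if regions[p] not in ("Africa", "Admixed") and p not in config.admixed
    ]
    if config.n_planted_pd and (not afr_pops or not non_pops):
        raise ValueError("planted PD loci need both an African and a non-African pool")

    # --- frequencies and genotypes ---------------------------------------
    pop_slices: dict[str, np.ndarray] = {
        p: panel.sample_indices(population=p) for p in pops
    }
    n_samples = panel.n_samples
    genotypes = np.zeros((n_loci, n_samples), dtype=np.int8)
    variants: list[Variant] = []
    truth_pd: list[str] = []
    truth_private: dict[str, list[str]] = {p: [] for p in pops}
    rs_counter = 1

    for i, (chrom, pos, cls) in enumerate(positions):
        if i in private_loci:
            pop_freq = {p: 0.0 for p in pops}
            owner = private_loci[i]
            pop_freq[owner] = float(rng.uniform(0.2, 0.6))
        elif i in pd_loci:
            lo = float(rng.uniform(0.05, (1 - config.pd_gap) / 2))
            hi = lo + config.pd_gap + float(
                rng.uniform(0, 1 - config.pd_gap - 2 * lo)
            )
            pop_freq = {}
            for p in pops:
                if p in afr_pops:
                    pop_freq[p] = lo
                elif p in non_pops:
                    pop_freq[p] = hi
                else:
                    pop_freq[p] = (lo + hi) / 2
        else:
            anc = float(rng.uniform(0.05, 0.95))
            pop_freq = {}
            for p in pops:
                F = fst[p]
                alpha = anc * (1 - F) / F
                beta = (1 - anc) * (1 - F) / F
                pop_freq[p] = float(rng.beta(alpha, beta))

        for p in pops:
            idx = pop_slices[p]
            genotypes[i, idx] = rng.binomial(2, pop_freq[p], size=len(idx))

        if i in private_loci:
            owner = private_loci[i]
            idx = pop_slices[owner]
            if not (genotypes[i, idx] > 0).any():
                genotypes[i, idx[rng.integers(len(idx))]] = 1
            others = np.setdiff1d(np.arange(n_samples), idx)
            genotypes[i, others] = 0

        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        known = bool(rng.random() < config.known_fraction)
        known_id = None
        if known:
            known_id = f"rs{900000 + rs_counter}"
            rs_counter += 1
        v = Variant(
            chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
            known=known, known_id=known_id,
        )
        variants.append(v)
        if i in pd_loci:
            truth_pd.append(v.key)
        if i in private_loci:
            truth_private[private_loci[i]].append(v.key)

    table = VariantTable(variants, genotypes, panel.samples)
    truth = {
        "n_loci": n_loci,
        "loci_per_class": {
            cls: sum(1 for _, _, c in positions if c == cls) for cls in wanted
        },
        "planted_pd": truth_pd,
        "planted_private": truth_private,
        "fst": fst,
        "seed": config.seed,
    }
    return table, panel, truth


# ---------------------------------------------------------------------------
# enrichment world
# ---------------------------------------------------------------------------

def simulate_enrichment_world(
    catalog: MirnaCatalog,
    n_genes: int,
    n_processes: int,
    planted_set,
    effect: float,
    seed: int = 0,
    *,
    planted_block_size: int = 30,
    background_rate: float = 0.05,
    qc_pass_rate: float = 0.5,
    disease_rate: float = 0.1,
    disease_effect: float = 0.0,
) -> tuple[TargetEvidenceTable, GoAnnotationTable, DiseaseAssociationTable, dict]:
    """Evidence/GO/disease tables with a planted enriched miRNA set.

    Background miRNA→gene targeting happens at ``background_rate``; a
    targeted pair's evidence passes the downstream QC filter with
    probability ``qc_pass_rate``.  Members of ``planted_set`` additionally
    target a designated gene block with probability
    ``background_rate + effect`` (always with passing evidence), a
    designated process annotates exactly that block, and planted members
    carry disease flags at ``disease_rate + disease_effect``.
    """
    rng = np.random.default_rng(seed)
    planted = list(planted_set)
    mirnas = catalog.mirna_ids
    unknown = set(planted) - set(mirnas)
    if unknown:
        raise ValueError(f"planted miRNA(s) not in catalog: {sorted(unknown)}")
    genes = [f"g{j + 1:05d}" for j in range(n_genes)]
    block = genes[:planted_block_size]
    processes = [f"BP{j + 1:04d}" for j in range(n_processes)]

    ev_rows = []

    def add_pair(m: str, g: str, passing: bool) -> None:
        if passing:
            for d in (1, 2):
                ev_rows.append(
                    (m, g, f"DS{d}", float(rng.uniform(-0.95, -0.55)))
                )
        else:
            if rng.random() < 0.5:
                # strong correlation in only one dataset
                ev_rows.append((m, g, "DS1", float(rng.uniform(-0.95, -0.55))))
            else:
                # weak correlation in two datasets
                for d in (1, 2):
                    ev_rows.append(
                        (m, g, f"DS{d}", float(rng.uniform(-0.45, 0.45)))
                    )

    n_background_pairs = 0
    n_passing_pairs = 0
    planted_rate = min(1.0, background_rate + effect)
    for m in mirnas:
        for j, g in enumerate(genes):
            in_block = j < planted_block_size
            if m in planted and in_block:
                if rng.random() < planted_rate:
                    add_pair(m, g, passing=True)
                continue
            if rng.random() < background_rate:
                n_background_pairs += 1
                passing = bool(rng.random() < qc_pass_rate)
                n_passing_pairs += passing
                add_pair(m, g, passing)

    evidence = TargetEvidenceTable(
        pd.DataFrame(ev_rows, columns=["mirna_id", "gene_id", "dataset_id", "r"])
    )

    go_rows = []
    planted_process = processes[0]
    for g in block:
        go_rows.append((g, planted_process))
    for g in genes:
        k = int(rng.integers(1, 4))
        for p in rng.choice(processes[1:], size=k, replace=False):
            go_rows.append((g, str(p)))
    go = GoAnnotationTable(
        pd.DataFrame(go_rows, columns=["gene_id", "process_id"]).drop_duplicates(),
        frozenset(genes),
    )

    dz_rows = []
    planted_dz = min(1.0, disease_rate + disease_effect)
    for m in mirnas:
        rate = planted_dz if m in planted else disease_rate
        if rng.random() < rate:
            direction = str(rng.choice(["up", "down", "both", "unknown"]))
            dz_rows.append((m, "simulated-disease", direction))
    disease = DiseaseAssociationTable(
        pd.DataFrame(dz_rows, columns=["mirna_id", "disease", "direction"])
    )

    truth = {
        "planted_set": planted,
        "planted_genes": block,
        "planted_process": planted_process,
        "background_rate": background_rate,
        "qc_pass_rate": qc_pass_rate,
        "n_background_pairs": n_background_pairs,
        "n_passing_pairs": n_passing_pairs,
        "disease_rate": disease_rate,
        "seed": seed,
    }
    return evidence, go, disease, truth


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def write_fixture(
    out_dir: str | os.PathLike,
    config: SimConfig,
    *,
    n_mirna: int = 20,
    hairpin_len: int = 100,
    n_genes: int = 200,
    n_processes: int = 50,
    planted_set_size: int = 8,
    effect: float = 0.8,
) -> dict:
    """Write a complete fixture directory (VCF, GFF3, manifest, tables,
    truth JSON) and return the truth mapping."""
    from . import formats_io

    os.makedirs(out_dir, exist_ok=True)
    catalog = simulate_catalog(n_mirna, hairpin_len, config.seed)
    table, panel, truth = simulate_genotypes(config, catalog)
    planted_set = catalog.mirna_ids[:planted_set_size]
    evidence, go, disease, etruth = simulate_enrichment_world(
        catalog, n_genes, n_processes, planted_set, effect, config.seed + 1
    )
    out = os.fspath(out_dir)
    formats_io.write_mirna_gff(catalog, os.path.join(out, "mirna.gff3"))
    formats_io.write_vcf(table, os.path.join(out, "variants.vcf"))
    formats_io.write_panel(panel, os.path.join(out, "panel.tsv"))
    evidence.frame.to_csv(os.path.join(out, "evidence.tsv"), sep="\t", index=False)
    go.frame.to_csv(os.path.join(out, "go.tsv"), sep="\t", index=False)
    disease.frame.to_csv(os.path.join(out, "disease.tsv"), sep="\t", index=False)
    truth_all = {"genotypes": truth, "enrichment": etruth}
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(truth_all, fh, indent=2)
    return truth_all
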