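"""Evidence QC and the three resampling enrichment analyses.

All empirical p-values use the add-one rule (1 + #{null >= observed}) /
(B + 1), so p is never exactly zero, and all nulls are one-sided
(over-representation only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DiseaseAssociationTable, GoAnnotationTable, TargetEvidenceTable


@dataclass(frozen=True)
class ValidatedTargetMap:
    """miRNA → validated target genes after evidence QC.

    Every retained (miRNA, gene) pair is supported by a correlation
    stricter than ``r_threshold`` in at least ``min_datasets`` distinct
    datasets.
    """

    targets: dict[str, frozenset[str]]
    support: pd.DataFrame  # per retained pair: mirna_id, gene_id, n_datasets, min_r
    r_threshold: float
    min_datasets: int

    def genes_of(self, mirna_ids) -> frozenset[str]:
        out: set[str] = set()
        for m in mirna_ids:
            out |= self.targets.get(m, frozenset())
        return frozenset(out)

    @property
    def target_counts(self) -> dict[str, int]:
        return {m: len(g) for m, g in self.targets.items()}


def filter_evidence(
    evidence: TargetEvidenceTable,
    *,
    r_threshold: float = -0.5,
    min_datasets: int = 2,
) -> ValidatedTargetMap:
    """Retain (miRNA, gene) pairs with r < r_threshold in >= min_datasets
    distinct datasets (strict inequality on r)."""
    frame = evidence.frame
    passing = frame[frame["r"] < r_threshold]
    grouped = (
        passing.groupby(["mirna_id", "gene_id"])
        .agg(n_datasets=("dataset_id", "nunique"), min_r=("r", "min"))
        .reset_index()
    )
    kept = grouped[grouped["n_datasets"] >= min_datasets].reset_index(drop=True)
    targets: dict[str, frozenset[str]] = {
        m: frozenset(sub["gene_id"])
        for m, sub in kept.groupby("mirna_id")
    }
    return ValidatedTargetMap(targets, kept, r_threshold, min_datasets)


def high_confidence_ids(target_map: ValidatedTargetMap) -> set[str]:
    """miRNAs with >= 1 validated target (the catalog's confidence flag)."""
    return {m for m, genes in target_map.targets.items() if genes}


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    observed: int
    B: int
    null_exceed: int
    p_emp: float
    enriched: bool
    seed: int


def _empirical_p(null_exceed: int, B: int) -> float:
    return (1 + null_exceed) / (B + 1)


def _target_matrix(
    catalog_ids: list[str], target_map: ValidatedTargetMap, genes: list[str]
) -> np.ndarray:
    """Boolean (miRNA × gene) targeting matrix over the candidate pool."""
    gene_col = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(catalog_ids), len(genes)), dtype=bool)
    for i, m in enumerate(catalog_ids):
        for g in target_map.targets.get(m, ()):
            if g in gene_col:
                mat[i, gene_col[g]] = True
    return mat


def _check_obs_set(obs_set, catalog_ids) -> list[str]:
    obs = list(obs_set)
    missing = [m for m in obs if m not in set(catalog_ids)]
    if missing:
        raise ValueError(f"observed miRNA(s) not in candidate pool: {missing}")
    return obs


def bootstrap_target_enrichment(
    obs_set,
    catalog_ids,
    target_map: ValidatedTargetMap,
    *,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    replace: bool = False,
) -> list[EnrichmentResult]:
    """Per-gene enrichment of the observed miRNA set vs random same-size sets.

    The statistic for a gene is the number of set members targeting it.
    Each of the B replicates draws ``len(obs_set)`` miRNAs from the
    candidate pool (without replacement by default) and recomputes it.
    """
    if B < 1:
        raise ValueError(f"need B >= 1 replicates, got {B}")
    catalog_ids = list(catalog_ids)
    obs = _check_obs_set(obs_set, catalog_ids)
    genes = sorted(target_map.genes_of(catalog_ids))
    mat = _target_matrix(catalog_ids, target_map, genes)
    row_of = {m: i for i, m in enumerate(catalog_ids)}
    observed = mat[[row_of[m] for m in obs]].sum(axis=0)

    rng = np.random.default_rng(seed)
    k = len(obs)
    null_exceed = np.zeros(len(genes), dtype=np.int64)
    for _ in range(B):
        if replace:
            idx = rng.integers(0, len(catalog_ids), size=k)
        else:
            idx = rng.choice(len(catalog_ids), size=k, replace=False)
        null = mat[idx].sum(axis=0)
        null_exceed += null >= observed
    return [
        EnrichmentResult(
            g, int(observed[j]), B, int(null_exceed[j]),
            _empirical_p(int(null_exceed[j]), B),
            _empirical_p(int(null_exceed[j]), B) < alpha, seed,
        )
        for j, g in enumerate(genes)
    ]


def bootstrap_process_enrichment(
    obs_set,
    catalog_ids,
    target_map: ValidatedTargetMap,
    go: GoAnnotationTable,
    *,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "count",
    replace: bool = False,
) -> list[EnrichmentResult]:
    """Per-process enrichment via the same resampling null.

    With ``statistic="count"`` the observed statistic for a process is the
    number of validated target genes of the set annotated to it;
    ``"presence"`` reduces it to 0/1 (process reached at all).
    """
    if B < 1:
        raise ValueError(f"need B >= 1 replicates, got {B}")
    if statistic not in ("count", "presence"):
        raise ValueError(f"statistic must be count|presence, got {statistic!r}")
    catalog_ids = list(catalog_ids)
    obs = _check_obs_set(obs_set, catalog_ids)
    genes = sorted(set(go.frame["gene_id"]) | target_map.genes_of(catalog_ids))
    processes = go.processes
    mat = _target_matrix(catalog_ids, target_map, genes)
    gene_col = {g: j for j, g in enumerate(genes)}
    proc_col = {p: j for j, p in enumerate(processes)}
    g2p = np.zeros((len(genes), len(processes)), dtype=np.int32)
    for _, row in go.frame.iterrows():
        g2p[gene_col[row["gene_id"]], proc_col[row["process_id"]]] = 1

    row_of = {m: i for i, m in enumerate(catalog_ids)}

    def proc_stat(mirna_rows: np.ndarray) -> np.ndarray:
        gene_hit = mat[mirna_rows].any(axis=0).astype(np.int32)
        counts = gene_hit @ g2p
        if statistic == "presence":
            return (counts > 0).astype(np.int32)
        return counts

    observed = proc_stat(np.array([row_of[m] for m in obs]))
    rng = np.random.default_rng(seed)
    k = len(obs)
    null_exceed = np.zeros(len(processes), dtype=np.int64)
    for _ in range(B):
        if replace:
            idx = rng.integers(0, len(catalog_ids), size=k)
        else:
            idx = rng.choice(len(catalog_ids), size=k, replace=False)
        null_exceed += proc_stat(idx) >= observed
    return [
        EnrichmentResult(
            p, int(observed[j]), B, int(null_exceed[j]),
            _empirical_p(int(null_exceed[j]), B),
            _empirical_p(int(null_exceed[j]), B) < alpha, seed,
        )
        for j, p in enumerate(processes)
    ]


@dataclass(frozen=True)
class GoTermResult:
    process_id: str
    n_background: int
    n_annotated: int
    n_targets: int
    overlap: int
    p: float
    q: float


def genomic_go_enrichment(
    target_genes,
    go: GoAnnotationTable,
) -> list[GoTermResult]:
    """Upper-tail hypergeometric over-representation per GO process with
    Benjamini–Hochberg adjustment across processes.

    This replaces an external genome-wide enrichment tool with a plain
    hypergeometric test; outputs are flagged as an approximation.
    Terms annotating zero genes are skipped; an empty target set is an
    error.
    """
    targets = set(target_genes)
    if not targets:
        raise ValueError("empty target gene set")
    background = set(go.background)
    stray = targets - background
    if stray:
        raise ValueError(
            f"target gene(s) outside the background universe: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(targets)
    by_proc = go.frame.groupby("process_id")["gene_id"].apply(set)
    rows = []
    for proc, annotated in by_proc.items():
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((proc, N, K, n, k, p))
    if not rows:
        return []
    pvals = np.array([r[5] for r in rows])
    order = np.argsort(pvals)
    m = len(pvals)
    q = np.empty(m)
    # Benjamini–Hochberg step-up
    ranked = pvals[order] * m / (np.arange(m) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    return [
        GoTermResult(proc, N, K, n, k, p, float(q[i]))
        for i, (proc, N, K, n, k, p) in enumerate(rows)
    ]


@dataclass(frozen=True)
class DiseaseBootstrapResult:
    observed_count: int
    set_size: int
    B: int
    expectation: float
    ci95: tuple[float, float]
    null_exceed: int
    p_emp: float
    seed: int


def disease_bootstrap(
    pd_set,
    disease_db: DiseaseAssociationTable,
    catalog_ids,
    *,
    B: int = 10_000,
    seed: int = 0,
    replace: bool = True,
) -> DiseaseBootstrapResult:
    """Bootstrap null for the number of disease-associated miRNAs in a set.

    The observed count is the number of set members with >= 1 disease
    association.  Each replicate draws ``len(pd_set)`` miRNAs from the
    candidate pool (with replacement by default) and counts associated
    draws.  Returns the null mean, 2.5/97.5 percentile interval, and the
    add-one empirical p.
    """
    if B < 1:
        raise ValueError(f"need B >= 1 replicates, got {B}")
    catalog_ids = list(catalog_ids)
    pd_set = list(pd_set)
    k = len(pd_set)
    if not replace and k > len(catalog_ids):
        raise ValueError(
            f"cannot draw {k} distinct miRNAs from a pool of {len(catalog_ids)}"
        )
    associated = disease_db.associated_mirnas()
    observed = sum(1 for m in pd_set if m in associated)
    is_assoc = np.array([m in associated for m in catalog_ids], dtype=bool)
    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.integers(0, len(catalog_ids), size=(B, k))
    else:
        draws = np.stack(
            [rng.choice(len(catalog_ids), size=k, replace=False) for _ in range(B)]
        )
    null = is_assoc[draws].sum(axis=1)
    null_exceed = int((null >= observed).sum())
    lo, hi = np.percentile(null, [2.5, 97.5])
    return DiseaseBootstrapResult(
        observed, k, B, float(null.mean()), (float(lo), float(hi)),
        null_exceed, _empirical_p(null_exceed, B), seed,
    )
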