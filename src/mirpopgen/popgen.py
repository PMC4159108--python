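"""Diversity and differentiation statistics.

Weir–Cockerham theta-hat is implemented in its allele-frequency
(haploid-sample) form: the 2N called chromosomes of each group are the
sample and the observed-heterozygosity component is omitted, the standard
choice for frequency-only data from unphased genotypes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import region_base_counts
from .model import MISSING, GenomePanel, MirnaCatalog, RegionClass, VariantTable

# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyTable:
    """Alt-allele frequency and called-chromosome count per group × variant."""

    freq: pd.DataFrame     # index: group label, columns: variant key
    n_chrom: pd.DataFrame  # same shape, integer chromosome counts


def _group_freq(genotypes: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt frequency, called chromosomes) over one sample-index group."""
    sub = genotypes[:, idx]
    called = sub != MISSING
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom


def allele_frequencies(
    table: VariantTable, panel: GenomePanel, grouping: str = "population"
) -> FrequencyTable:
    """Per-group alt-allele frequencies.

    ``grouping`` is one of ``population``, ``region``, or ``pooled``
    (African vs non-African pools, admixed samples in neither).  Missing
    genotypes are excluded from the denominator; a group with zero called
    chromosomes gets a missing frequency.
    """
    if grouping == "population":
        groups = {p: panel.sample_indices(population=p) for p in panel.populations}
    elif grouping == "region":
        groups = {r: panel.sample_indices(region=r) for r in panel.regions}
    elif grouping == "pooled":
        afr, non = panel.pool_indices()
        groups = {"Africa-pool": afr, "nonAfrica-pool": non}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    keys = [v.key for v in table.variants]
    freq_rows, n_rows = {}, {}
    for label, idx in groups.items():
        p, n = _group_freq(table.genotypes, idx)
        freq_rows[label], n_rows[label] = p, n
    return FrequencyTable(
        freq=pd.DataFrame(freq_rows, index=keys).T,
        n_chrom=pd.DataFrame(n_rows, index=keys).T,
    )


# ---------------------------------------------------------------------------
# Watterson's theta
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThetaEstimate:
    group: str
    sequence_class: str
    S: int
    n: int
    L: float
    a_n: float
    theta_per_site: float


def harmonic_number(k: int) -> float:
    """H_k = sum_{i=1}^{k} 1/i (H_0 = 0)."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def watterson_theta(
    S: int, n: int, L: float, *, group: str = "", sequence_class: str = ""
) -> ThetaEstimate:
    """Watterson's estimator per site: theta = S / (a_n * L), a_n = H_{n-1}."""
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got n={n}")
    if L <= 0:
        raise ValueError(f"surveyed length must be positive, got L={L}")
    if S < 0:
        raise ValueError(f"segregating-site count must be >= 0, got S={S}")
    a_n = harmonic_number(n - 1)
    return ThetaEstimate(group, sequence_class, S, n, L, a_n, S / (a_n * L))


def watterson_by_class(
    table: VariantTable,
    panel: GenomePanel,
    catalog: MirnaCatalog,
    grouping: str = "population",
) -> list[ThetaEstimate]:
    """Watterson's theta per group for each hairpin sequence class.

    S counts distinct variant records segregating within the group (alt
    and ref both present among called chromosomes); n is the group's
    sampled chromosome count; L is the class's total bases in the catalog.
    The ``hairpin`` class pools the three sub-regions.
    """
    bases = region_base_counts(catalog)
    class_bases = {rc.value: float(b) for rc, b in bases.items()}
    class_bases["hairpin"] = float(sum(bases.values()))

    if grouping == "population":
        groups = {p: panel.sample_indices(population=p) for p in panel.populations}
    elif grouping == "region":
        groups = {r: panel.sample_indices(region=r) for r in panel.regions}
    elif grouping == "pooled":
        afr, non = panel.pool_indices()
        groups = {"Africa-pool": afr, "nonAfrica-pool": non}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    # deduplicate variants spanning overlapping hairpins, keep top class
    best: dict[str, tuple[RegionClass, int]] = {}
    for i, v in enumerate(table.variants):
        cur = best.get(v.key)
        if cur is None or v.region.precedence < cur[0].precedence:
            best[v.key] = (v.region, i)

    out = []
    for label, idx in groups.items():
        n = 2 * len(idx)
        if n < 2:
            continue
        seg_count = {rc: 0 for rc in RegionClass}
        for region, i in best.values():
            sub = table.genotypes[i, idx]
            called = sub != MISSING
            n_called = 2 * int(called.sum())
            alt = int(np.where(called, sub, 0).sum())
            if 0 < alt < n_called:
                seg_count[region] += 1
        for cls in ("seed", "mature", "stem-loop", "hairpin"):
            if cls == "hairpin":
                S = sum(
                    seg_count[rc]
                    for rc in (RegionClass.SEED, RegionClass.MATURE, RegionClass.STEM_LOOP)
                )
            else:
                S = seg_count[RegionClass(cls)]
            L = class_bases[cls]
            if L > 0:
                out.append(
                    watterson_theta(S, n, L, group=label, sequence_class=cls)
                )
    return out


# ---------------------------------------------------------------------------
# population-specific alleles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsmaRecord:
    variant_key: str
    population: str
    frequency: float
    high_frequency: bool


def detect_psma(
    table: VariantTable,
    panel: GenomePanel,
    *,
    high_freq_threshold: float = 0.5,
) -> tuple[list[PsmaRecord], dict[str, float]]:
    """Population-specific alleles: alt frequency > 0 in exactly one population.

    Returns the PSMA records and the per-population density (PSMA count
    divided by genomes sampled for that population).  Variants duplicated
    across overlapping hairpins count once.
    """
    freqs = allele_frequencies(table, panel, "population")
    pops = list(freqs.freq.index)
    seen: set[str] = set()
    records: list[PsmaRecord] = []
    for key in freqs.freq.columns:
        if key in seen:
            continue
        seen.add(key)
        col = freqs.freq[key]
        present = [p for p in pops if not np.isnan(col[p]) and col[p] > 0]
        if len(present) == 1:
            pop = present[0]
            f = float(col[pop])
            records.append(
                PsmaRecord(key, pop, f, f >= high_freq_threshold)
            )
    n_genomes = panel.n_genomes_per_population
    counts = {p: 0 for p in pops}
    for rec in records:
        counts[rec.population] += 1
    density = {p: counts[p] / n_genomes[p] for p in pops}
    return records, density


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstComponents:
    """Variance components of the two-group Weir–Cockerham estimator."""

    a: float            # among-population component
    w: float            # within-population component
    theta_hat: float    # raw a/(a+w); nan when undefined
    theta_reported: float  # max(theta_hat, 0); nan when undefined
    defined: bool


def wc_fst(p1: float, n1: int, p2: float, n2: int) -> FstComponents:
    """Two-group Weir–Cockerham theta-hat from allele frequencies.

    ``n1``/``n2`` are called chromosome counts (>= 2 each).  Both groups
    monomorphic for the same allele leaves the ratio 0/0: the estimate is
    undefined (``defined=False``), not an exception.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 chromosomes per group, got n1={n1}, n2={n2}")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError(f"frequencies must lie in [0, 1], got p1={p1}, p2={p2}")
    r = 2
    n_tot = n1 + n2
    n_bar = n_tot / r
    n_c = (n_tot - (n1 * n1 + n2 * n2) / n_tot) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2)
    )
    w = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2)
    denom = a + w
    if denom == 0:
        return FstComponents(a, w, math.nan, math.nan, defined=False)
    theta = a / denom
    return FstComponents(a, w, theta, max(theta, 0.0), defined=True)


# ---------------------------------------------------------------------------
# Welch two-sided t-test on per-individual dosages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> WelchResult:
    """Welch–Satterthwaite two-sided t-test on per-individual alt dosages.

    Dosages are alt alleles / ploidy per diploid individual (0, 0.5, 1);
    missing individuals must already be excluded.  Two zero-variance
    groups give (t=0, p=1) when the means agree and a degenerate p=0
    otherwise.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 individuals, got {a.size} and {b.size}"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0 and vb == 0:
        if ma == mb:
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(math.inf if ma > mb else -math.inf, math.nan, 0.0, True)
    se2a, se2b = va / a.size, vb / b.size
    t = (ma - mb) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


# ---------------------------------------------------------------------------
# hierarchical F_ST scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """One pairwise comparison: two labeled sample-index groups."""

    kind: str  # {population, region, pooled}
    group_a: str
    group_b: str
    idx_a: np.ndarray = field(repr=False, compare=False, default=None)
    idx_b: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def name(self) -> str:
        return f"{self.group_a}|{self.group_b}"


@dataclass(frozen=True)
class FstRecord:
    variant_key: str
    contrast: str
    kind: str
    p1: float
    p2: float
    n1: int
    n2: int
    a: float
    w: float
    theta_hat: float
    theta_reported: float
    defined: bool
    t: float | None = None
    df: float | None = None
    p_welch: float | None = None


def build_contrasts(panel: GenomePanel, africa_label: str = "Africa") -> list[Contrast]:
    """All population pairs, all region pairs, and the pooled contrast.

    The pooled African/non-African contrast excludes admixed populations
    from both pools.
    """
    contrasts: list[Contrast] = []
    for a, b in itertools.combinations(panel.populations, 2):
        contrasts.append(
            Contrast("population", a, b,
                     panel.sample_indices(population=a),
                     panel.sample_indices(population=b))
        )
    for a, b in itertools.combinations(panel.regions, 2):
        contrasts.append(
            Contrast("region", a, b,
                     panel.sample_indices(region=a),
                     panel.sample_indices(region=b))
        )
    afr, non = panel.pool_indices(africa_label)
    contrasts.append(Contrast("pooled", f"{africa_label}-pool", "nonAfrica-pool", afr, non))
    return contrasts


def fst_scan(
    table: VariantTable,
    panel: GenomePanel,
    contrasts: Iterable[Contrast] | None = None,
) -> list[FstRecord]:
    """One :class:`FstRecord` per (deduplicated) variant per contrast.

    The Welch test on per-individual dosages is attached for pooled
    contrasts only, mirroring the outlier-calling stage downstream.
    """
    if contrasts is None:
        contrasts = build_contrasts(panel)
    contrasts = list(contrasts)
    for c in contrasts:
        if len(c.idx_a) == 0 or len(c.idx_b) == 0:
            raise ValueError(f"contrast {c.name} has an empty group")

    # deduplicate: one record per variant key
    seen: set[str] = set()
    rows: list[int] = []
    for i, v in enumerate(table.variants):
        if v.key not in seen:
            seen.add(v.key)
            rows.append(i)

    records: list[FstRecord] = []
    for c in contrasts:
        p_a, n_a = _group_freq(table.genotypes, c.idx_a)
        p_b, n_b = _group_freq(table.genotypes, c.idx_b)
        for i in rows:
            key = table.variants[i].key
            n1, n2 = int(n_a[i]), int(n_b[i])
            if n1 < 2 or n2 < 2:
                continue
            comp = wc_fst(float(p_a[i]), n1, float(p_b[i]), n2)
            t = df = p_welch = None
            if c.kind == "pooled":
                ga = table.genotypes[i, c.idx_a]
                gb = table.genotypes[i, c.idx_b]
                res = welch_test(ga[ga != MISSING] / 2.0, gb[gb != MISSING] / 2.0)
                t, df, p_welch = res.t, res.df, res.p
            records.append(
                FstRecord(
                    key, c.name, c.kind,
                    float(p_a[i]), float(p_b[i]), n1, n2,
                    comp.a, comp.w, comp.theta_hat, comp.theta_reported,
                    comp.defined, t, df, p_welch,
                )
            )
    return records


def multilocus_fst(records: Iterable[FstRecord]) -> float:
    """Weighted multi-locus theta-hat: sum(a) / sum(a + w) over defined loci.

    This is the weighted combination across loci; the unweighted mean of
    per-locus ratios is biased downward and does not recover the
    simulation's drift parameter.
    """
    a = w = 0.0
    n = 0
    for rec in records:
        if rec.defined:
            a += rec.a
            w += rec.w
            n += 1
    if n == 0 or a + w == 0:
        raise ValueError("no defined loci to combine")
    return a / (a + w)


# ---------------------------------------------------------------------------
# empirical percentile outliers / PD classification
# ---------------------------------------------------------------------------


def percentile_threshold(values: Sequence[float], q: float) -> float:
    """Empirical q-quantile, linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    if not 0 < q < 1:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    if np.isnan(values).any():
        raise ValueError("percentile input contains undefined values")
    return float(np.quantile(values, q, method="linear"))


@dataclass(frozen=True)
class PdClassification:
    variant_key: str
    theta: float
    q95: float
    q99: float
    p_welch: float | None
    label: str  # {none, PD, HPD}


def classify_pd(
    records: Iterable[FstRecord],
    q95: float,
    q99: float,
    alpha: float = 0.05,
) -> list[PdClassification]:
    """Label pooled-contrast records: PD at >= q95, HPD at >= q99 (both with
    Welch p < alpha; thresholds inclusive)."""
    out = []
    for rec in records:
        label = "none"
        if rec.defined and rec.p_welch is not None and rec.p_welch < alpha:
            if rec.theta_reported >= q99:
                label = "HPD"
            elif rec.theta_reported >= q95:
                label = "PD"
        out.append(
            PdClassification(
                rec.variant_key, rec.theta_reported, q95, q99, rec.p_welch, label
            )
        )
    return out


def mirna_pd_labels(
    classifications: Iterable[PdClassification], table: VariantTable
) -> dict[str, str]:
    """miRNA-level label = strongest label over the miRNA's variants."""
    by_key: dict[str, str] = {c.variant_key: c.label for c in classifications}
    rank = {"none": 0, "PD": 1, "HPD": 2}
    out: dict[str, str] = {}
    for v in table.variants:
        if v.mirna_id is None:
            continue
        label = by_key.get(v.key, "none")
        if rank[label] >= rank[out.get(v.mirna_id, "none")] or v.mirna_id not in out:
            out[v.mirna_id] = label
    return out
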