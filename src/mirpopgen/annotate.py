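"""Region classification, novelty flagging, singleton filtering, density.

Hairpin bases partition into three mutually exclusive classes: seed
(bases 2–8 from the 5' end of a mature arm), mature (remaining mature-arm
bases), and stem-loop (hairpin bases in neither).  For multi-base
variants the higher-precedence class wins (seed > mature > stem-loop).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .intervals import Interval
from .model import MirnaCatalog, MirnaRecord, RegionClass, Variant, VariantTable

logger = logging.getLogger(__name__)


def seed_interval(mature: Interval, strand: str) -> Interval:
    """Seed = bases 2–8 of the mature arm counted from its 5' end.

    On the + strand the 5' end is the lower genomic coordinate; on the −
    strand it is the higher one, so counting walks downward.
    """
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    if len(mature) < 8:
        raise ValueError(f"mature arm of length {len(mature)} is too short (< 8 nt)")
    if strand == "+":
        return Interval(mature.start + 1, mature.start + 8)
    return Interval(mature.end - 8, mature.end - 1)


def _region_of_span(span: Interval, record: MirnaRecord) -> RegionClass:
    """Class of a variant span within one hairpin, with precedence."""
    if any(span.overlaps(s) for s in record.seed_intervals):
        return RegionClass.SEED
    if any(span.overlaps(a.interval) for a in record.mature_arms):
        return RegionClass.MATURE
    if span.overlaps(record.hairpin):
        return RegionClass.STEM_LOOP
    return RegionClass.NONE


def classify_variant(
    variant: Variant, catalog: MirnaCatalog
) -> list[tuple[str, RegionClass]]:
    """Classify a variant against every hairpin it overlaps.

    Returns one ``(mirna_id, region)`` pair per overlapping hairpin
    (miRBase contains overlapping annotations); an empty list means the
    variant falls in no hairpin.
    """
    hits = []
    for rec in catalog.overlapping(variant.chrom, variant.span):
        region = _region_of_span(variant.span, rec)
        if region is not RegionClass.NONE:
            hits.append((rec.mirna_id, region))
    return hits


def annotate_variants(table: VariantTable, catalog: MirnaCatalog) -> VariantTable:
    """Attach region class and miRNA id to every variant.

    A variant overlapping two hairpins is duplicated, once per hairpin,
    with its genotype row copied.  Variants outside every hairpin keep
    region ``none`` and a null mirna_id.
    """
    out_variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for i, v in enumerate(table.variants):
        hits = classify_variant(v, catalog)
        if not hits:
            out_variants.append(replace(v, region=RegionClass.NONE, mirna_id=None))
            rows.append(table.genotypes[i])
            continue
        for mirna_id, region in hits:
            out_variants.append(replace(v, region=region, mirna_id=mirna_id))
            rows.append(table.genotypes[i])
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(table.samples)), dtype=np.int8)
    )
    return VariantTable(out_variants, genotypes, table.samples)


def flag_novel(variant: Variant) -> bool:
    """True iff the variant is absent from the known-sites information."""
    return not variant.known


def drop_singletons(table: VariantTable) -> tuple[VariantTable, int]:
    """Remove novel variants carried by exactly one individual.

    Known variants are never removed; a single homozygous carrier still
    counts as one individual.  Returns the filtered table and the number
    of distinct variant records removed.  Idempotent.
    """
    carriers = table.n_carriers()
    singleton = np.array(
        [flag_novel(v) and carriers[i] == 1 for i, v in enumerate(table.variants)]
    )
    n_removed = len({table.variants[i].key for i in np.flatnonzero(singleton)})
    if n_removed:
        logger.info("removed %d novel singleton variant(s)", n_removed)
    return table.subset(~singleton), n_removed


def region_base_counts(catalog: MirnaCatalog) -> dict[RegionClass, int]:
    """Total bases per region class, summed over hairpins.

    Computed by per-base labeling inside each hairpin so that the three
    classes always partition the hairpin exactly, whatever the arm layout.
    """
    totals = {RegionClass.SEED: 0, RegionClass.MATURE: 0, RegionClass.STEM_LOOP: 0}
    for rec in catalog:
        for pos in range(rec.hairpin.start, rec.hairpin.end):
            totals[_region_of_span(Interval(pos, pos + 1), rec)] += 1
    return totals


def region_counts(
    table: VariantTable, *, deduplicate: bool = False
) -> dict[RegionClass, int]:
    """Variant count per region class.

    With ``deduplicate=True`` a variant duplicated across overlapping
    hairpins counts once, under its highest-precedence class.
    """
    if deduplicate:
        best: dict[str, RegionClass] = {}
        for v in table.variants:
            cur = best.get(v.key)
            if cur is None or v.region.precedence < cur.precedence:
                best[v.key] = v.region
        classes = best.values()
    else:
        classes = [v.region for v in table.variants]
    counts = {rc: 0 for rc in RegionClass}
    for rc in classes:
        counts[rc] += 1
    return counts


def region_density(
    table: VariantTable, catalog: MirnaCatalog, *, deduplicate: bool = False
) -> dict[RegionClass, float | None]:
    """Variants per base for each hairpin region class.

    A class with zero total bases in the catalog has undefined density and
    is reported as ``None``.
    """
    bases = region_base_counts(catalog)
    counts = region_counts(table, deduplicate=deduplicate)
    out: dict[RegionClass, float | None] = {}
    for rc, total in bases.items():
        out[rc] = counts[rc] / total if total > 0 else None
    return out
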