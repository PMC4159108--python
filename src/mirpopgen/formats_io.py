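"""Readers and writers for the external formats the pipeline touches.

GFF3 (miRBase dialect), VCF v4.x, and headered TSV manifests all use
1-based inclusive coordinates on disk; everything is converted to the
internal half-open 0-based convention on the way in.
"""

from __future__ import annotations

import hashlib
import logging
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

from . import __version__
from .intervals import Interval
from .model import (
    MISSING,
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

logger = logging.getLogger(__name__)

_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# panel manifest
# ---------------------------------------------------------------------------

def read_panel(path: str | os.PathLike) -> GenomePanel:
    """Read a sample manifest TSV into a :class:`GenomePanel`.

    Required columns: ``sample_id``, ``population``, ``region``,
    ``hunter_gatherer``, ``admixed``.  Duplicate sample ids are a hard
    error.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(
        frame, ["sample_id", "population", "region", "hunter_gatherer", "admixed"],
        "panel manifest",
    )
    frame["hunter_gatherer"] = frame["hunter_gatherer"].map(_parse_bool)
    frame["admixed"] = frame["admixed"].map(_parse_bool)
    return GenomePanel(frame)


def write_panel(panel: GenomePanel, path: str | os.PathLike) -> None:
    panel.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRBase-dialect GFF3
# ---------------------------------------------------------------------------

def read_mirna_gff(path: str | os.PathLike) -> MirnaCatalog:
    """Read a miRBase-dialect GFF3 into a :class:`MirnaCatalog`.

    Hairpins are ``miRNA_primary_transcript`` features; mature arms are
    ``miRNA`` features linked to their hairpin via ``Derives_from``.
    A mature feature without a resolvable parent, or an arm shorter than
    8 nt, is a hard error naming the offending feature.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    hairpins: dict[str, gffutils.Feature] = {}
    arms: dict[str, list[gffutils.Feature]] = {}
    for feat in db.all_features():
        if feat.featuretype == "miRNA_primary_transcript":
            hairpins[feat.id] = feat
        elif feat.featuretype == "miRNA":
            parent = feat.attributes.get("Derives_from", [None])[0]
            if parent is None:
                raise ValueError(
                    f"mature miRNA feature {feat.id!r} has no Derives_from parent"
                )
            arms.setdefault(parent, []).append(feat)

    orphans = set(arms) - set(hairpins)
    if orphans:
        raise ValueError(
            "mature miRNA feature(s) reference unknown hairpin(s): "
            + ", ".join(sorted(orphans))
        )

    records = []
    for hid, hp in hairpins.items():
        name = hp.attributes.get("Name", [hid])[0]
        confidence = hp.attributes.get("confidence", ["low"])[0]
        mature = tuple(
            MatureArm(
                arm_id=a.attributes.get("Name", [a.id])[0],
                interval=Interval.from_1based(a.start, a.end),
                strand=a.strand,
            )
            for a in sorted(arms.get(hid, []), key=lambda a: a.start)
        )
        records.append(
            MirnaRecord(
                mirna_id=name,
                chrom=hp.seqid,
                hairpin=Interval.from_1based(hp.start, hp.end),
                strand=hp.strand,
                mature_arms=mature,
                confidence=confidence,
            )
        )
    return MirnaCatalog(records)


def write_mirna_gff(catalog: MirnaCatalog, path: str | os.PathLike) -> None:
    """Write a catalog back to miRBase-dialect GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in catalog:
            start, end = rec.hairpin.to_1based()
            fh.write(
                f"{rec.chrom}\t.\tmiRNA_primary_transcript\t{start}\t{end}\t.\t"
                f"{rec.strand}\t.\tID={rec.mirna_id};Name={rec.mirna_id};"
                f"confidence={rec.confidence}\n"
            )
            for arm in rec.mature_arms:
                astart, aend = arm.interval.to_1based()
                fh.write(
                    f"{rec.chrom}\t.\tmiRNA\t{astart}\t{aend}\t.\t{arm.strand}\t.\t"
                    f"ID={arm.arm_id};Name={arm.arm_id};Derives_from={rec.mirna_id}\n"
                )


# ---------------------------------------------------------------------------
# known-sites list
# ---------------------------------------------------------------------------

class KnownSites:
    """dbSNP-style known-site membership.

    Entries are allele-aware ``(chrom, pos, ref, alt)`` tuples when alleles
    are given, or position-only ``(chrom, pos)`` otherwise.  Positions are
    1-based on disk.
    """

    def __init__(self, allelic: Iterable[tuple] = (), positional: Iterable[tuple] = ()):
        self._allelic = set(allelic)
        self._positional = set(positional)

    def __contains__(self, variant: Variant) -> bool:
        pos1 = variant.pos + 1
        return (
            (variant.chrom, pos1, variant.ref, variant.alt) in self._allelic
            or (variant.chrom, pos1) in self._positional
        )

    def __len__(self) -> int:
        return len(self._allelic) + len(self._positional)


def read_known_sites(path: str | os.PathLike) -> KnownSites:
    """Read a known-sites TSV with columns chrom, pos[, ref, alt]."""
    allelic, positional = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 4:
                allelic.append((fields[0], int(fields[1]), fields[2], fields[3]))
            elif len(fields) >= 2:
                positional.append((fields[0], int(fields[1])))
            else:
                raise ValueError(f"malformed known-sites line: {line!r}")
    return KnownSites(allelic, positional)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def _is_clean_allele(allele: str) -> bool:
    return bool(allele) and set(allele.upper()) <= _ACGT


def read_vcf(
    path: str | os.PathLike,
    panel: GenomePanel,
    known_sites: KnownSites | None = None,
) -> VariantTable:
    """Read a VCF into a :class:`VariantTable` aligned to the panel order.

    Multi-allelic sites are split into biallelic records; for each split
    record, sample alleles equal to the record's alt count as alt, any
    other called allele counts as ref, and ``./.`` is missing.  Records
    whose alleles are not plain ACGT strings are skipped with a warning.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    absent = [s for s in panel.samples if s not in vcf_samples]
    if absent:
        raise ValueError(f"panel sample(s) absent from VCF: {absent}")
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    order = [col_of[s] for s in panel.samples]

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        alts = rec.alts or ()
        if not _is_clean_allele(rec.ref) or not all(_is_clean_allele(a) for a in alts):
            logger.warning(
                "skipping record %s:%d with non-ACGT allele(s) %s>%s",
                rec.chrom, rec.pos, rec.ref, ",".join(alts) or ".",
            )
            continue
        gts = []
        for sample in vcf_samples:
            gts.append(rec.samples[sample].get("GT", (None, None)))
        for alt_idx, alt in enumerate(alts, start=1):
            row = np.full(len(vcf_samples), MISSING, dtype=np.int8)
            for col, gt in enumerate(gts):
                if gt is None or all(a is None for a in gt):
                    continue
                called = [a for a in gt if a is not None]
                row[col] = sum(1 for a in called if a == alt_idx)
            rec_id = rec.id if rec.id not in (None, ".") else None
            variant = Variant(
                chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alt=alt,
                known=rec_id is not None, known_id=rec_id,
            )
            if known_sites is not None and variant in known_sites:
                variant = Variant(
                    chrom=variant.chrom, pos=variant.pos, ref=variant.ref,
                    alt=variant.alt, known=True, known_id=variant.known_id,
                )
            variants.append(variant)
            rows.append(row[order])
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, panel.n_samples), dtype=np.int8)
    )
    return VariantTable(variants, genotypes, panel.samples)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str | os.PathLike, *, source: str = "mirpopgen") -> None:
    """Write a minimal text VCF v4.2 (one biallelic record per variant)."""
    contigs = sorted({v.chrom for v in table.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source} {__version__}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples) + "\n"
        )
        idx = sorted(
            range(len(table.variants)),
            key=lambda i: (table.variants[i].chrom, table.variants[i].pos,
                           table.variants[i].alt),
        )
        for i in idx:
            v = table.variants[i]
            gts = "\t".join(_GT_STRING[int(g)] for g in table.genotypes[i])
            vid = v.known_id if v.known_id else "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# evidence / GO / disease tables
# ---------------------------------------------------------------------------

def read_evidence(path: str | os.PathLike) -> TargetEvidenceTable:
    """Read a miRNA→gene target-evidence TSV.

    Columns: ``mirna_id``, ``gene_id``, ``dataset_id``, ``r``.  Correlations
    outside [−1, 1] are a hard error; duplicate (mirna, gene, dataset)
    triples are collapsed to their first row with a warning.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(frame, ["mirna_id", "gene_id", "dataset_id", "r"], "evidence table")
    frame["r"] = frame["r"].astype(float)
    bad = frame[(frame["r"] < -1) | (frame["r"] > 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"correlation out of [-1, 1] for ({row.mirna_id}, {row.gene_id}, "
            f"{row.dataset_id}): r={row.r}"
        )
    key = ["mirna_id", "gene_id", "dataset_id"]
    n_dupes = int(frame.duplicated(key).sum())
    if n_dupes:
        logger.warning("collapsing %d duplicate evidence row(s)", n_dupes)
        frame = frame.drop_duplicates(key, keep="first")
    return TargetEvidenceTable(frame.reset_index(drop=True))


def read_go(
    path: str | os.PathLike, background: Iterable[str] | None = None
) -> GoAnnotationTable:
    """Read a gene→process annotation TSV (columns gene_id, process_id).

    The background universe defaults to the set of annotated genes and may
    be extended with an explicit iterable of gene ids.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(frame, ["gene_id", "process_id"], "GO annotation table")
    frame = frame.drop_duplicates(["gene_id", "process_id"]).reset_index(drop=True)
    universe = set(frame["gene_id"])
    if background is not None:
        universe |= set(background)
    return GoAnnotationTable(frame, frozenset(universe))


def read_disease(path: str | os.PathLike) -> DiseaseAssociationTable:
    """Read a miRNA→disease association TSV (mirna_id, disease, direction)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(frame, ["mirna_id", "disease", "direction"], "disease table")
    allowed = {"up", "down", "both", "unknown"}
    bad = set(frame["direction"]) - allowed if len(frame) else set()
    if bad:
        raise ValueError(f"unknown regulation direction(s): {sorted(bad)}")
    n_dupes = int(frame.duplicated(["mirna_id", "disease"]).sum())
    if n_dupes:
        logger.warning("collapsing %d duplicate disease association(s)", n_dupes)
        frame = frame.drop_duplicates(["mirna_id", "disease"], keep="first")
    return DiseaseAssociationTable(frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# plain variant-list / frequency tables
# ---------------------------------------------------------------------------

def read_variant_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a plain variant-list TSV (chrom, pos, ref, alt[, ...]).

    Positions are 1-based on disk; duplicate (chrom, pos, ref, alt)
    records are collapsed with a warning.  Extra columns pass through.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    _require_columns(frame, ["chrom", "pos", "ref", "alt"], "variant list")
    frame["pos"] = frame["pos"].astype(int)
    key = ["chrom", "pos", "ref", "alt"]
    n_dupes = int(frame.duplicated(key).sum())
    if n_dupes:
        logger.warning("collapsing %d duplicate variant record(s)", n_dupes)
        frame = frame.drop_duplicates(key)
    return frame.reset_index(drop=True)


def read_frequency_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-population allele-frequency TSV.

    Columns: ``population``, ``frequency`` (a fraction in [0, 1]),
    ``n_chrom`` (chromosomes sampled).
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(frame, ["population", "frequency", "n_chrom"], "frequency table")
    frame["frequency"] = frame["frequency"].astype(float)
    bad = frame[(frame["frequency"] < 0) | (frame["frequency"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"frequency out of [0, 1] for population {bad.iloc[0].population}"
        )
    if frame["population"].duplicated().any():
        raise ValueError("duplicate population rows in frequency table")
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV output with provenance header
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping for output provenance."""
    canon = repr(sorted((str(k), repr(v)) for k, v in config.items()))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_tsv(
    frame: pd.DataFrame, path: str | os.PathLike, *, meta: Mapping | None = None
) -> None:
    """Write a TSV with a ``#`` comment header recording version + config hash."""
    with open(path, "w") as fh:
        fh.write(f"# mirpopgen {__version__}\n")
        if meta:
            for k, v in sorted(meta.items()):
                fh.write(f"# {k}={v}\n")
        frame.to_csv(fh, sep="\t", index=False)
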