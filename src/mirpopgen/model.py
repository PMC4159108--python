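"""Shared domain types for the pipeline.

The readers in :mod:`mirpopgen.formats_io` produce these; every analysis
stage consumes them.  Coordinates are internal half-open 0-based
(:class:`mirpopgen.intervals.Interval`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval

MISSING = -1  # genotype code for ./.


class RegionClass(enum.Enum):
    """Mutually exclusive hairpin sub-regions, in precedence order."""

    SEED = "seed"
    MATURE = "mature"
    STEM_LOOP = "stem-loop"
    NONE = "none"

    @property
    def precedence(self) -> int:
        return {"seed": 0, "mature": 1, "stem-loop": 2, "none": 3}[self.value]


@dataclass(frozen=True)
class MatureArm:
    arm_id: str
    interval: Interval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for arm {self.arm_id}")
        if len(self.interval) < 8:
            raise ValueError(
                f"mature arm {self.arm_id} is {len(self.interval)} nt; minimum is 8"
            )


@dataclass(frozen=True)
class MirnaRecord:
    """One hairpin with its mature arms and derived seed intervals."""

    mirna_id: str
    chrom: str
    hairpin: Interval
    strand: str
    mature_arms: tuple[MatureArm, ...] = ()
    confidence: str = "low"  # {high, low}

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.mirna_id}")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be high/low, got {self.confidence!r}")
        for arm in self.mature_arms:
            if not self.hairpin.contains(arm.interval):
                raise ValueError(
                    f"mature arm {arm.arm_id} extends outside hairpin {self.mirna_id}"
                )

    @property
    def seed_intervals(self) -> tuple[Interval, ...]:
        from .annotate import seed_interval  # deferred: annotate imports this module

        return tuple(seed_interval(a.interval, a.strand) for a in self.mature_arms)


class MirnaCatalog:
    """Ordered collection of hairpin records with per-chromosome lookup."""

    def __init__(self, records: Sequence[MirnaRecord]):
        self.records: list[MirnaRecord] = sorted(
            records, key=lambda r: (r.chrom, r.hairpin.start, r.mirna_id)
        )
        self._by_chrom: dict[str, list[MirnaRecord]] = {}
        for rec in self.records:
            self._by_chrom.setdefault(rec.chrom, []).append(rec)
        ids = [r.mirna_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate miRNA ids in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MirnaRecord]:
        return iter(self.records)

    def __getitem__(self, mirna_id: str) -> MirnaRecord:
        for rec in self.records:
            if rec.mirna_id == mirna_id:
                return rec
        raise KeyError(mirna_id)

    @property
    def mirna_ids(self) -> list[str]:
        return [r.mirna_id for r in self.records]

    def overlapping(self, chrom: str, interval: Interval) -> list[MirnaRecord]:
        return [
            r for r in self._by_chrom.get(chrom, []) if r.hairpin.overlaps(interval)
        ]

    def with_confidence(self, high_ids: set[str]) -> "MirnaCatalog":
        """Return a copy with ``confidence`` set from a high-confidence id set."""
        return MirnaCatalog(
            [
                replace(r, confidence="high" if r.mirna_id in high_ids else "low")
                for r in self.records
            ]
        )


PANEL_COLUMNS = ["sample_id", "population", "region", "hunter_gatherer", "admixed"]


class GenomePanel:
    """Sample manifest: population / region / hunter-gatherer / admixed labels."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"panel manifest missing required column(s): {missing}")
        frame = frame[PANEL_COLUMNS].reset_index(drop=True)
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in panel: {dupes}")
        regions_per_pop = frame.groupby("population")["region"].nunique()
        bad = regions_per_pop[regions_per_pop > 1]
        if not bad.empty:
            raise ValueError(
                f"population(s) mapped to more than one region: {list(bad.index)}"
            )
        self.frame = frame

    @property
    def samples(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    @property
    def n_genomes_per_population(self) -> dict[str, int]:
        return self.frame.groupby("population").size().to_dict()

    def region_of(self, population: str) -> str:
        sub = self.frame.loc[self.frame["population"] == population, "region"]
        if sub.empty:
            raise KeyError(population)
        return sub.iloc[0]

    def sample_indices(
        self, *, population: str | None = None, region: str | None = None,
        exclude_admixed: bool = False,
    ) -> np.ndarray:
        mask = np.ones(len(self.frame), dtype=bool)
        if population is not None:
            mask &= (self.frame["population"] == population).to_numpy()
        if region is not None:
            mask &= (self.frame["region"] == region).to_numpy()
        if exclude_admixed:
            mask &= ~self.frame["admixed"].to_numpy(dtype=bool)
        return np.flatnonzero(mask)

    def pool_indices(self, africa_label: str = "Africa") -> tuple[np.ndarray, np.ndarray]:
        """African / non-African pools; admixed samples join neither pool."""
        not_admixed = ~self.frame["admixed"].to_numpy(dtype=bool)
        is_africa = (self.frame["region"] == africa_label).to_numpy()
        return (
            np.flatnonzero(is_africa & not_admixed),
            np.flatnonzero(~is_africa & not_admixed),
        )


@dataclass(frozen=True)
class Variant:
    """One biallelic variant record (post multi-allelic split)."""

    chrom: str
    pos: int  # 0-based position of the first REF base
    ref: str
    alt: str
    known: bool = False
    known_id: str | None = None
    region: RegionClass = RegionClass.NONE
    mirna_id: str | None = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt == ref at {self.chrom}:{self.pos + 1}")

    @property
    def variant_type(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"

    @property
    def span(self) -> Interval:
        # Deletions cover their REF bases; insertions anchor at the REF base.
        return Interval(self.pos, self.pos + max(1, len(self.ref)))


class VariantTable:
    """Biallelic variants plus an aligned (variants × samples) genotype matrix.

    Genotypes are alt-allele counts per diploid sample: 0, 1, 2, or
    :data:`MISSING` (-1) for no-calls.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        genotypes: np.ndarray,
        samples: Sequence[str],
    ):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(variants), len(samples)):
            raise ValueError(
                f"genotype matrix {genotypes.shape} does not match "
                f"({len(variants)} variants, {len(samples)} samples)"
            )
        valid = np.isin(genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.variants = list(variants)
        self.genotypes = genotypes
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def n_carriers(self) -> np.ndarray:
        """Number of samples carrying ≥1 alt allele, per variant."""
        return (self.genotypes > 0).sum(axis=1)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(
            [self.variants[i] for i in idx], self.genotypes[idx], self.samples
        )

    def replace_variants(self, variants: Sequence[Variant], genotypes=None) -> "VariantTable":
        return VariantTable(
            variants,
            self.genotypes if genotypes is None else genotypes,
            self.samples,
        )

    def to_frame(self) -> pd.DataFrame:
        carriers = self.n_carriers()
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos + 1 for v in self.variants],  # 1-based out
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "type": [v.variant_type for v in self.variants],
                "mirna_id": [v.mirna_id for v in self.variants],
                "region": [v.region.value for v in self.variants],
                "novel": [not v.known for v in self.variants],
                "n_carriers": carriers,
            }
        )


@dataclass(frozen=True)
class TargetEvidenceTable:
    """(mirna, gene, dataset, r) rows; one row per triple."""

    frame: pd.DataFrame  # columns: mirna_id, gene_id, dataset_id, r

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class GoAnnotationTable:
    """gene → biological-process annotation plus the background universe."""

    frame: pd.DataFrame  # columns: gene_id, process_id
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        annotated = set(self.frame["gene_id"])
        if not annotated <= set(self.background):
            raise ValueError("background universe must contain all annotated genes")

    @property
    def processes(self) -> list[str]:
        return sorted(self.frame["process_id"].unique())


@dataclass(frozen=True)
class DiseaseAssociationTable:
    """miRNA → disease associations with regulation direction."""

    frame: pd.DataFrame  # columns: mirna_id, disease, direction

    def associated_mirnas(self) -> frozenset[str]:
        return frozenset(self.frame["mirna_id"])
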