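import numpy as np
import pandas as pd
import pytest

from mirpopgen.intervals import Interval
from mirpopgen.model import (
    GenomePanel,
    MatureArm,
    MirnaCatalog,
    MirnaRecord,
    Variant,
    VariantTable,
)

# Study design from the source cohort: 14 populations, 69 samples,
# African pool n=32, non-African pool n=25, 12 admixed samples.
COHORT = [
    # (population, region, n, hunter_gatherer, admixed)
    ("Py", "Africa", 5, True, False),
    ("Hz", "Africa", 5, True, False),
    ("Sw", "Africa", 5, True, False),
    ("YRI", "Africa", 9, False, False),
    ("MKK", "Africa", 4, False, False),
    ("LWK", "Africa", 4, False, False),
    ("CEPH", "Europe", 9, False, False),
    ("TSI", "Europe", 4, False, False),
    ("JPT", "Asia", 4, False, False),
    ("CHB", "Asia", 4, False, False),
    ("GIH", "Asia", 4, False, False),
    ("MEX", "Admixed", 5, False, True),
    ("ASW", "Admixed", 5, False, True),
    ("PUR", "Admixed", 2, False, True),
]


def make_cohort_panel() -> GenomePanel:
    rows = []
    for pop, region, n, hg, adm in COHORT:
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"{pop}_{j + 1}",
                    "population": pop,
                    "region": region,
                    "hunter_gatherer": hg,
                    "admixed": adm,
                }
            )
    return GenomePanel(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def cohort_panel() -> GenomePanel:
    return make_cohort_panel()


@pytest.fixture()
def tiny_panel() -> GenomePanel:
    rows = []
    for pop, region, n in [("AF1", "Africa", 3), ("AF2", "Africa", 3),
                           ("EU1", "Europe", 3), ("AS1", "Asia", 3),
                           ("ADM", "Admixed", 2)]:
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"{pop}_{j + 1}",
                    "population": pop,
                    "region": region,
                    "hunter_gatherer": False,
                    "admixed": pop == "ADM",
                }
            )
    return GenomePanel(pd.DataFrame(rows))


@pytest.fixture()
def one_hairpin_catalog() -> MirnaCatalog:
    """One + strand hairpin chr1:1000-1084 (0-based [999, 1084)) with 2 arms."""
    hairpin = Interval.from_1based(1000, 1084)
    arm5 = Interval.from_1based(1000, 1021)  # 21 nt
    arm3 = Interval.from_1based(1062, 1084)  # 22 nt
    rec = MirnaRecord(
        mirna_id="mir-1", chrom="chr1", hairpin=hairpin, strand="+",
        mature_arms=(
            MatureArm("mir-1-5p", arm5, "+"),
            MatureArm("mir-1-3p", arm3, "+"),
        ),
    )
    return MirnaCatalog([rec])


def make_variant_table(
    specs, panel: GenomePanel, genotypes=None
) -> VariantTable:
    """specs: list of (chrom, pos1, ref, alt, known) tuples; genotypes
    defaults to all hom-ref."""
    variants = [
        Variant(chrom=c, pos=p - 1, ref=r, alt=a, known=k,
                known_id="rs1" if k else None)
        for c, p, r, a, k in specs
    ]
    if genotypes is None:
        genotypes = np.zeros((len(variants), panel.n_samples), dtype=np.int8)
    return VariantTable(variants, np.asarray(genotypes, dtype=np.int8), panel.samples)
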