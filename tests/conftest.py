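from pathlib import Path

import pytest

from strscreen import LocusRecord, MotifEntry, load_catalog

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def catalog_path() -> Path:
    return DATA / "catalog_mini.json"


@pytest.fixture(scope="session")
def catalog(catalog_path):
    return load_catalog(catalog_path)


@pytest.fixture(scope="session")
def loci_by_id(catalog):
    return {rec.locus_id: rec for rec in catalog}


def make_locus(**overrides) -> LocusRecord:
    """An HTT-like AD CAG locus, overridable field by field."""
    base = dict(
        locus_id="HTT_HD",
        gene="HTT",
        chrom="chr4",
        start_by_build={"hg38": 3074876},
        end_by_build={"hg38": 3074933},
        strand="+",
        motif_len=3,
        reference_motif="CAG",
        motifs=[
            MotifEntry(motif="CAG", orientation="reference", motif_class="pathogenic"),
            MotifEntry(motif="CAA", orientation="reference", motif_class="benign"),
        ],
        inheritance="AD",
        benign_max=26,
        intermediate_min=27,
        intermediate_max=35,
        pathogenic_min=40,
        independent_observations=10,
    )
    base.update(overrides)
    return LocusRecord(**base)
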