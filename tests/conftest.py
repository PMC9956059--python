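from __future__ import annotations

import pytest

from crossscreen.formats_io import Genotype, VariantSite
from crossscreen.synthetic_cross import SimConfig, simulate_dataset

GT = {
    "AA": Genotype(0, 0),
    "AB": Genotype(0, 1),
    "BB": Genotype(1, 1),
    "..": Genotype.missing(),
}


def make_site(founders, f2, f3, ref="A", alts=("G",), chrom="chr1", pos=100):
    """Build a site + manifest from genotype mnemonics like 'AA', 'AB', '..'.

    'A' denotes the REF allele and 'B' the first ALT; the screen itself never
    relies on that labelling.
    """
    genotypes = {}
    manifest = {}
    for group, prefix, calls in (("founder", "C", founders),
                                 ("F2", "B", f2), ("F3", "O", f3)):
        for i, call in enumerate(calls):
            sample = f"{prefix}{i + 1}"
            genotypes[sample] = GT[call] if isinstance(call, str) else call
            manifest[sample] = group
    return VariantSite(chrom, pos, ref, tuple(alts), genotypes), manifest


@pytest.fixture(scope="session")
def small_dataset():
    """A shared noise-free synthetic cross (1,500 sites, 40 planted)."""
    return simulate_dataset(SimConfig(n_sites=1500, n_candidate_sites=40, seed=7))


@pytest.fixture(scope="session")
def table3_records():
    from crossscreen.formats_io import load_table3_fixture

    return load_table3_fixture()


@pytest.fixture(scope="session")
def table2_records():
    from crossscreen.formats_io import load_table2_fixture

    return load_table2_fixture()
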