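import pytest

import locuskit as lk


@pytest.fixture(scope="session")
def preset_locus():
    """The inverted-repeat-allele preset locus, built once per session."""
    return lk.build_locus(lk.i_i_allele_config(seed=7))


@pytest.fixture(scope="session")
def nahr_mutant(preset_locus):
    """Donor→acceptor NAHR mutant with the junction at template position 600."""
    return lk.apply_nahr(preset_locus, "CHS5", "CHS1", junction=600)


@pytest.fixture(scope="session")
def chs_pair():
    """Synthetic CHS5/CHS1-like paralog pair: (seq_a, seq_b, regions)."""
    return lk.synthetic_chs_pair()


@pytest.fixture(scope="session")
def chs_alignment(chs_pair):
    seq_a, seq_b, regions = chs_pair
    aln = lk.align_paralogs(seq_a, seq_b)
    sites = lk.enumerate_discriminating_sites(aln, regions)
    return aln, sites
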