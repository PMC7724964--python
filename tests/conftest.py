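import pytest

import prmprofiler as pp


@pytest.fixture(scope="session")
def default_spec():
    return pp.SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def peptides_and_truth(default_spec):
    return pp.gen_peptide_set(default_spec)


@pytest.fixture(scope="session")
def recovered_profile(peptides_and_truth):
    ps, _ = peptides_and_truth
    return pp.build_profile(ps)


@pytest.fixture(scope="session")
def toy_complex(default_spec):
    return pp.gen_toy_complex(default_spec)


def make_alignment(rows, prm_id="TEST"):
    """Gap-free alignment from already-padded equal-length rows."""
    records = [pp.PeptideRecord(r.strip("-"), prm_id) for r in rows]
    starts = [len(r) - len(r.lstrip("-")) for r in rows]
    smax = max(starts)
    offsets = [smax - s for s in starts]
    return pp.GapFreeAlignment(prm_id, list(rows), offsets, records)
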