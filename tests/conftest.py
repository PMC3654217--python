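import pandas as pd
import pytest

from thermocomm.simulate import default_community, write_community

ROOT_SEED = 7


@pytest.fixture(scope="session")
def community_dir(tmp_path_factory):
    """The packaged study community, generated once per session."""
    out = tmp_path_factory.mktemp("community") / "comm"
    sites, pops, viral, arrays, fam = default_community()
    write_community(sites, pops, viral, out, ROOT_SEED, arrays, fam)
    return out


@pytest.fixture(scope="session")
def community_specs():
    sites, pops, viral, arrays, fam = default_community()
    return dict(sites=sites, populations=pops, viral=viral, arrays=arrays,
                family_map=fam)


@pytest.fixture(scope="session")
def siteA_arrays(community_dir):
    """Detected CRISPR arrays on the siteA assembly, computed once."""
    from Bio import SeqIO

    from thermocomm.crispr import find_crispr_arrays

    arrays = []
    for rec in SeqIO.parse(str(community_dir / "siteA_contigs.fasta"), "fasta"):
        arrays += find_crispr_arrays(rec, sample="siteA")
    return arrays


@pytest.fixture(scope="session")
def truth(community_dir):
    return {
        name: pd.read_csv(community_dir / f"truth_{name}.tsv", sep="\t")
        for name in ("reads", "contigs", "arrays", "spacer_links", "viral", "genes")
    }
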