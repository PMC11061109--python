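import pytest

from facoloc import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def gff_file(tmp_path):
    """Hand-written GFF3: 5 gene rows on 2 contigs, one with end < start."""
    text = "\n".join([
        "##gff-version 3",
        "# comment line",
        "ctg1\ttest\tgene\t100\t400\t.\t+\t.\tID=g1",
        "ctg1\ttest\tgene\t1000\t1800\t.\t-\t.\tID=g2",
        "ctg1\ttest\tgene\t5000\t4000\t.\t+\t.\tID=bad",   # malformed: end < start
        "ctg2\ttest\tgene\t50\t950\t.\t+\t.\tID=g3",
        "ctg2\ttest\tgene\t2000\t2600\t.\t-\t.\tID=g4",
        "ctg1\ttest\texon\t100\t200\t.\t+\t.\tID=e1",       # wrong feature type
        "",
    ])
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
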