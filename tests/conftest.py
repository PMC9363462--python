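import pytest

from tgprofile.library_design import LibraryDesign, load_preset


@pytest.fixture(scope="session")
def lib4() -> LibraryDesign:
    return load_preset("Lib4")


@pytest.fixture(scope="session")
def libq() -> LibraryDesign:
    return load_preset("LibQ")


@pytest.fixture()
def tiny_design() -> LibraryDesign:
    """A minimal 5-mer design with short anchors for hand-built reads."""
    return LibraryDesign(
        name="tiny",
        backbone_peptide="HQSYV",
        reactive_index=1,
        randomized_indices=frozenset({0, 2, 3, 4}),
        upstream_anchor="GGAGGTTCTAGT",
        downstream_anchor="GGCAGCGGTTCT",
    )


def write_fastq(path, records):
    """records: iterable of (name, seq, qual) triples."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path
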