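import pytest

import seqaudit as sa


@pytest.fixture(scope="session")
def schemes():
    """The three study alphabets, loaded from the bundled YAML files."""
    return {name: sa.load_scheme(name) for name in ("aac", "sez-table", "dav")}


@pytest.fixture(scope="session")
def easy_synthetic():
    """Easy preset: 7 Class-C-proportioned classes, 10 planted mislabels."""
    cfg = sa.easy_preset(seed=42)
    dataset, truth = sa.generate_synthetic(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def easy_audit(easy_synthetic, tmp_path_factory):
    """Full three-scheme audit of the easy preset (500 trees, seed 42)."""
    cfg, dataset, truth = easy_synthetic
    out = tmp_path_factory.mktemp("easy")
    fasta, labels = out / "s.fasta", out / "s.tsv"
    sa.write_fasta(dataset.records, fasta)
    sa.write_labels(dataset.records, labels)
    run = sa.RunConfig(fasta=str(fasta), labels=str(labels), seed=42)
    report = sa.run_full_audit(run, dataset=dataset)
    return dataset, truth, report


@pytest.fixture(scope="session")
def tables():
    """Bundled case-study tables (checksum-verified on load)."""
    return sa.reference_tables()


@pytest.fixture()
def toy_files(tmp_path):
    """A 3-class, 6-record toy FASTA + label TSV on disk."""
    fasta = tmp_path / "toy.fasta"
    labels = tmp_path / "toy.tsv"
    fasta.write_text(
        ">s1\nACDEFGHIKLMNPQRSTVWY\n"
        ">s2\nAAAACCCCDDDD\n"
        ">s3\nWYWYWYWYWY\n"
        ">s4\nMNPQRSTVMNPQ\n"
        ">s5\nacdefghik\n"          # lower case on purpose
        ">s6\nKLMNPQRSTV\n"
    )
    labels.write_text(
        "id\tlabel\n"
        "s1\tA\ns2\tA\ns3\tB\ns4\tB\ns5\tC\ns6\tC\n"
    )
    return fasta, labels
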