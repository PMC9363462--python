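"""QC statistics, trimming, Q25 filter, demultiplexing, anchor extraction,
design filters, and the full counting pipeline on hand-built fixtures."""

import pytest

from tgprofile.library_design import reverse_complement, translate
from tgprofile.read_processing import (
    FastqParseError,
    accept_peptide,
    assess_quality,
    count_peptides,
    demultiplex,
    extract_coding_dna,
    pass_quality,
    trim_adapter,
)

from conftest import write_fastq


def q(phred: int, n: int) -> str:
    return chr(phred + 33) * n


class TestAssessQuality:
    def test_all_high_quality(self, tmp_path):
        path = write_fastq(tmp_path / "a.fastq", [("r1", "ACGTACGTAC", q(40, 10))])
        rep = assess_quality(path)
        assert rep.q20_pct == 100.0
        assert rep.q30_pct == 100.0

    def test_hand_counted_split(self, tmp_path):
        path = write_fastq(
            tmp_path / "a.fastq",
            [("r1", "ACGTACGTAC", q(35, 10)), ("r2", "ACGTACGTAC", q(25, 10))],
        )
        rep = assess_quality(path)
        assert rep.q30_pct == 50.0
        assert rep.q20_pct == 100.0
        assert rep.n_pass_quality == 2  # both means >= 25

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.raises(FastqParseError):
            assess_quality(path)

    def test_malformed_record(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIII\n")  # qual shorter than seq
        with pytest.raises(FastqParseError):
            assess_quality(path)


class TestPassQuality:
    def test_boundary_inclusive(self):
        assert pass_quality(q(25, 20), 25.0)

    def test_mean_below_threshold(self):
        assert not pass_quality(q(20, 10) + q(28, 10), 25.0)  # mean 24

    def test_high_quality(self):
        assert pass_quality(q(40, 10), 25.0)

    def test_monotone_in_threshold(self):
        qual = q(20, 5) + q(30, 5)
        passing = [pass_quality(qual, t) for t in (10, 20, 25, 26, 30)]
        # once it fails, it keeps failing as the threshold rises
        assert passing == sorted(passing, reverse=True)


ADAPTER = "AGATCGGAAGAGC"


class TestTrimAdapter:
    def test_exact_adapter_removed(self):
        read = "ACGTACGT" + ADAPTER
        seq, qual = trim_adapter(read, q(30, len(read)), [ADAPTER])
        assert seq == "ACGTACGT"
        assert len(qual) == len(seq)

    def test_no_adapter_unchanged(self):
        read = "ACGTACGTACGTACGTACGT"
        assert trim_adapter(read, q(30, 20), [ADAPTER]) == (read, q(30, 20))

    def test_partial_overlap_with_mismatch(self):
        # read ends with first 6 nt of adapter, one substitution
        tail = "AGATCG"
        tail = tail[:2] + "T" + tail[3:]
        read = "ACGTACGTAC" + tail
        seq, _ = trim_adapter(
            read, q(30, len(read)), [ADAPTER], min_overlap=5, max_mismatch_rate=0.2
        )
        assert seq == "ACGTACGTAC"


class TestDemultiplex:
    TAGS = {"before": "ACGTACGTAC", "after": "TGCATGCATG"}

    def test_exact(self):
        assert demultiplex("ACGTACGTAC" + "GGG", self.TAGS) == "before"

    def test_one_mismatch(self):
        assert demultiplex("ACGTACGTAA" + "GGG", self.TAGS, 1) == "before"

    def test_too_many_mismatches(self):
        assert demultiplex("ACGTACCCCC" + "GGG", self.TAGS, 1) == "unassigned"

    def test_tie_is_unassigned(self):
        tags = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"}
        # read head differs from both by exactly 1
        assert demultiplex("AAAAAAAAAG", tags, 1) == "unassigned"

    def test_short_read(self):
        assert demultiplex("ACGT", self.TAGS) == "unassigned"


class TestExtractCodingDNA:
    def construct(self, design, dna):
        return design.upstream_anchor + dna + design.downstream_anchor

    def test_clean_read(self, tiny_design):
        coding = "CATCAGTCTTACGTT"
        read1 = self.construct(tiny_design, coding)
        dna, reason = extract_coding_dna(read1, None, tiny_design)
        assert reason is None
        assert dna == coding

    def test_anchor_missing(self, tiny_design):
        dna, reason = extract_coding_dna("T" * 50, None, tiny_design)
        assert dna is None
        assert reason == "no_anchor"

    def test_anchor_with_one_mismatch(self, tiny_design):
        coding = "CATCAGTCTTACGTT"
        up = tiny_design.upstream_anchor
        read1 = up[:3] + "A" + up[4:] if up[3] != "A" else up[:3] + "C" + up[4:]
        read1 += coding + tiny_design.downstream_anchor
        dna, reason = extract_coding_dna(read1, None, tiny_design, 1)
        assert reason is None
        assert dna == coding

    def test_fallback_to_read2(self, tiny_design):
        coding = "CATCAGTCTTACGTT"
        read2 = reverse_complement(self.construct(tiny_design, coding))
        dna, reason = extract_coding_dna("T" * 40, read2, tiny_design)
        assert reason is None
        assert dna == coding

    def test_frame_failure(self, tiny_design):
        coding = "CATCAGTCTTACGT"  # 14 nt, not 3 * 5
        read1 = self.construct(tiny_design, coding)
        dna, reason = extract_coding_dna(read1, None, tiny_design)
        assert dna is None
        assert reason == "frame_fail"


class TestAcceptPeptide:
    def test_reactive_gln_required_when_fixed(self, lib4):
        assert accept_peptide("HASYVDPWMLDH", lib4) == "no_reactive_gln"  # Q2A
        assert accept_peptide("HNSYVDPWMLDH", lib4) == "no_reactive_gln"  # Q2N
        assert accept_peptide("HQSYVDPWMLDH", lib4) is None

    def test_stop_codon_rejected(self, lib4):
        assert accept_peptide("HQSYVDPWMLD*", lib4) == "stop_codon"

    def test_backbone_variants_retained(self, lib4):
        # non-randomized backbone differing from the template is kept
        assert accept_peptide("HQSYVDPWMLDY", lib4) is None

    def test_gln_filter_skipped_when_reactive_randomized(self, libq):
        assert accept_peptide("HASYVDPWMLDH", libq) is None
        assert accept_peptide("HQSYVDPWMLD*", libq) == "stop_codon"


def build_pair(design, coding, phred=38, tag=""):
    construct = tag + design.upstream_anchor + coding + design.downstream_anchor
    return construct, reverse_complement(construct), q(phred, len(construct))


class TestCountPeptides:
    def test_hand_built_truth_table(self, tiny_design, tmp_path):
        """12 read pairs with a hand-computed outcome: 8 accepted over 3
        peptides, 2 low-quality, 1 without anchors, 1 stop-containing."""
        d = tiny_design
        pep = {
            "p1": "CATCAGTCTTACGTT",  # HQSYV
            "p2": "TGTCAGTCTTACGTT",  # CQSYV
            "p3": "AAGCAGTCTTACGTT",  # KQSYV
            "stop": "CATCAGTAGTACGTT",  # HQ*YV
        }
        r1, r2 = [], []

        def add(coding, phred=38, scramble=False):
            c1, c2, qq = build_pair(d, coding, phred)
            if scramble:
                c1 = "T" * len(c1)
                c2 = "A" * len(c2)
            r1.append((f"r{len(r1)}", c1, qq))
            r2.append((f"r{len(r2)}", c2, qq))

        for _ in range(4):
            add(pep["p1"])
        for _ in range(3):
            add(pep["p2"])
        add(pep["p3"])
        add(pep["p1"], phred=20)  # low quality
        add(pep["p2"], phred=10)  # low quality
        add(pep["p1"], scramble=True)  # no anchors anywhere
        add(pep["stop"])

        f1 = write_fastq(tmp_path / "r1.fastq", r1)
        f2 = write_fastq(tmp_path / "r2.fastq", r2)
        counts, qc = count_peptides(f1, f2, d, sample_label="s")
        assert counts.n_pairs == 12
        assert counts.counts["s"] == {"HQSYV": 4, "CQSYV": 3, "KQSYV": 1}
        assert dict(counts.rejections) == {
            "low_quality": 2,
            "no_anchor": 1,
            "stop_codon": 1,
        }
        assert counts.n_accepted + sum(counts.rejections.values()) == 12

    def test_tagged_demultiplexing_and_no_tag(self, tmp_path, libq):
        d = libq
        coding = d.backbone_dna
        r1, r2 = [], []
        for tag_label, n in (("before", 3), ("after", 2)):
            for _ in range(n):
                c1, c2, qq = build_pair(d, coding, tag=d.tags[tag_label])
                r1.append((f"r{len(r1)}", c1, qq))
                r2.append((f"r{len(r2)}", c2, qq))
        c1, c2, qq = build_pair(d, coding, tag="GGGGGGGGGG")
        r1.append(("untagged", c1, qq))
        r2.append(("untagged", c2, qq))
        f1 = write_fastq(tmp_path / "r1.fastq", r1)
        f2 = write_fastq(tmp_path / "r2.fastq", r2)
        counts, _ = count_peptides(f1, f2, d)
        assert counts.counts["before"] == {d.backbone_peptide: 3}
        assert counts.counts["after"] == {d.backbone_peptide: 2}
        assert counts.rejections["no_tag"] == 1

    def test_empty_input(self, tiny_design, tmp_path):
        f1 = tmp_path / "r1.fastq"
        f2 = tmp_path / "r2.fastq"
        f1.write_text("")
        f2.write_text("")
        counts, qc = count_peptides(f1, f2, tiny_design, sample_label="s")
        assert counts.n_pairs == 0
        assert counts.n_accepted == 0
        assert qc.n_reads == 0

    def test_accounting_with_sequencing_noise(self, lib4, tmp_path):
        """accepted + sum(rejections) == pairs under heavy noise."""
        from tgprofile.simulate import (
            SequencingModel,
            default_selection_model,
            simulate_experiment,
        )

        sim = simulate_experiment(
            lib4,
            default_selection_model(),
            SequencingModel(reads_per_sample=2000, per_base_error=0.05),
            2000,
            tmp_path,
            seed=5,
        )
        counts, _ = count_peptides(
            *sim.fastq_paths["before"], lib4, sample_label="before"
        )
        assert counts.n_pairs == 2000
        assert counts.n_accepted + sum(counts.rejections.values()) == 2000

    def test_quality_threshold_monotonicity(self, tiny_design, tmp_path):
        d = tiny_design
        records1, records2 = [], []
        for i, phred in enumerate(range(18, 40, 2)):
            c1, c2, qq = build_pair(d, "CATCAGTCTTACGTT", phred)
            records1.append((f"r{i}", c1, qq))
            records2.append((f"r{i}", c2, qq))
        f1 = write_fastq(tmp_path / "r1.fastq", records1)
        f2 = write_fastq(tmp_path / "r2.fastq", records2)
        accepted = []
        for t in (0, 20, 25, 30, 39):
            counts, _ = count_peptides(
                f1, f2, d, quality_threshold=t, sample_label="s"
            )
            accepted.append(counts.n_accepted)
        assert accepted == sorted(accepted, reverse=True)


def test_translate_consistency_on_extraction(tiny_design):
    coding = "CATCAGTCTTACGTT"
    read1 = tiny_design.upstream_anchor + coding + tiny_design.downstream_anchor
    dna, _ = extract_coding_dna(read1, None, tiny_design)
    assert translate(dna) == "HQSYV"
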