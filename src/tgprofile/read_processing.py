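"""From raw paired-end FASTQ to filtered peptide count tables.

The processing chain per read pair is: adapter trim -> mean-quality filter
(Q25 by default, both mates must pass) -> in-read tag demultiplex (when the
design defines tags) -> anchor-based extraction of the peptide-coding DNA
(read 1 authoritative, reverse-complemented read 2 as fallback) ->
translation -> design filters (reactive Gln present where the design fixes
it; no stop codon anywhere in the peptide).

Every rejected pair is tallied under exactly one reason, so that
``accepted + sum(rejections) == input pairs`` on every input.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_design import (
    CODON_TABLE,
    LibraryDesign,
    reverse_complement,
)

__all__ = [
    "REJECTION_REASONS",
    "ProcessedCounts",
    "QCReport",
    "accept_peptide",
    "assess_quality",
    "count_peptides",
    "demultiplex",
    "extract_coding_dna",
    "pass_quality",
    "trim_adapter",
]

REJECTION_REASONS = (
    "adapter_only",
    "low_quality",
    "no_tag",
    "no_anchor",
    "frame_fail",
    "no_reactive_gln",
    "stop_codon",
)


class FastqParseError(ValueError):
    pass


@dataclass
class QCReport:
    """Base-level quality summary of a FASTQ file (or a pair)."""

    n_reads: int = 0
    n_bases: int = 0
    n_q20: int = 0
    n_q30: int = 0
    n_pass_quality: int = 0

    @property
    def q20_pct(self) -> float:
        return 100.0 * self.n_q20 / self.n_bases if self.n_bases else 0.0

    @property
    def q30_pct(self) -> float:
        return 100.0 * self.n_q30 / self.n_bases if self.n_bases else 0.0

    @property
    def pass_pct(self) -> float:
        return 100.0 * self.n_pass_quality / self.n_reads if self.n_reads else 0.0

    def add_read(self, qual: str, threshold: float) -> None:
        q = np.frombuffer(qual.encode(), np.uint8)
        self.n_reads += 1
        self.n_bases += q.size
        self.n_q20 += int((q >= 53).sum())  # Phred 20 + 33
        self.n_q30 += int((q >= 63).sum())
        if q.size and q.mean() - 33.0 >= threshold:
            self.n_pass_quality += 1

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_bases": self.n_bases,
            "q20_pct": self.q20_pct,
            "q30_pct": self.q30_pct,
            "n_pass_quality": self.n_pass_quality,
            "pass_pct": self.pass_pct,
        }


@dataclass
class ProcessedCounts:
    """Accepted peptide counts per sample plus rejection accounting."""

    counts: dict[str, Counter] = field(default_factory=dict)
    rejections: Counter = field(default_factory=Counter)
    n_pairs: int = 0

    @property
    def n_accepted(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def write_tsv(self, counts_path, rejections_path=None) -> None:
        with open(counts_path, "w") as fh:
            fh.write("sample\tpeptide\tcount\n")
            for sample in sorted(self.counts):
                for pep, n in sorted(self.counts[sample].items()):
                    fh.write(f"{sample}\t{pep}\t{n}\n")
        if rejections_path is not None:
            with open(rejections_path, "w") as fh:
                fh.write("reason\tcount\n")
                for reason in REJECTION_REASONS:
                    fh.write(f"{reason}\t{self.rejections.get(reason, 0)}\n")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, "rt")
    return open(path)


def assess_quality(fastq_path, threshold: float = 25.0) -> QCReport:
    """Base-level Q20/Q30 percentages and mean-quality pass counts."""
    report = QCReport()
    with _open_text(fastq_path) as fh:
        try:
            for _title, _seq, qual in FastqGeneralIterator(fh):
                report.add_read(qual, threshold)
        except ValueError as exc:
            raise FastqParseError(
                f"{fastq_path}: malformed record after "
                f"{report.n_reads} reads: {exc}"
            ) from exc
    if report.n_reads == 0:
        raise FastqParseError(f"{fastq_path}: no FASTQ records")
    return report


def pass_quality(qual: str, threshold: float = 25.0) -> bool:
    """True iff the read's mean Phred score is >= threshold (inclusive)."""
    if not qual:
        return False
    return sum(qual.encode()) / len(qual) - 33.0 >= threshold


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    seq: str,
    qual: str,
    adapters,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.2,
) -> tuple[str, str]:
    """Remove 3' adapter read-through.

    The longest read suffix matching an adapter prefix (length >=
    ``min_overlap``, mismatch rate <= ``max_mismatch_rate``) is removed along
    with its qualities; no-op when nothing matches.
    """
    best = 0
    for adapter in adapters:
        max_o = min(len(seq), len(adapter))
        for o in range(max_o, min_overlap - 1, -1):
            if o <= best:
                break
            if _hamming(seq[-o:], adapter[:o]) <= max_mismatch_rate * o:
                best = o
                break
    if best:
        return seq[:-best], qual[:-best]
    return seq, qual


def demultiplex(seq: str, tags: dict[str, str], max_mismatch: int = 1) -> str:
    """Assign a read to the sample whose 10-nt tag matches its leading bases.

    Returns ``"unassigned"`` when no tag is within ``max_mismatch``
    substitutions or two tags tie at the minimum distance.
    """
    head = seq[:10]
    if len(head) < 10:
        return "unassigned"
    best_label, best_d, tie = "unassigned", max_mismatch + 1, False
    for label, tag in tags.items():
        d = _hamming(head, tag)
        if d < best_d:
            best_label, best_d, tie = label, d, False
        elif d == best_d:
            tie = True
    return "unassigned" if tie else best_label


def _approx_find(hay: str, needle: str, max_mm: int, start: int = 0) -> int:
    """First occurrence of ``needle`` in ``hay`` with <= max_mm substitutions."""
    i = hay.find(needle, start)
    if i >= 0 or max_mm == 0:
        return i
    n = len(needle)
    for i in range(start, len(hay) - n + 1):
        mm = 0
        for a, b in zip(hay[i : i + n], needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return i
    return -1


def extract_coding_dna(
    read1: str,
    read2: str | None,
    design: LibraryDesign,
    max_anchor_mismatch: int = 1,
) -> tuple[str | None, str | None]:
    """Locate the peptide-coding DNA between the design's anchors.

    Searches read 1 first, then the reverse complement of read 2.  Returns
    ``(dna, None)`` on success or ``(None, reason)`` with reason
    ``"no_anchor"`` (anchors not found) or ``"frame_fail"`` (the DNA between
    the anchors is not exactly 3L nt).
    """
    up, down = design.upstream_anchor, design.downstream_anchor
    want = 3 * design.length
    saw_anchors = False
    candidates = [read1]
    if read2:
        candidates.append(reverse_complement(read2))
    for seq in candidates:
        i = _approx_find(seq, up, max_anchor_mismatch)
        if i < 0:
            continue
        j = _approx_find(seq, down, max_anchor_mismatch, i + len(up))
        if j < 0:
            continue
        saw_anchors = True
        dna = seq[i + len(up) : j]
        if len(dna) == want:
            return dna, None
    return None, "frame_fail" if saw_anchors else "no_anchor"


def accept_peptide(peptide: str, design: LibraryDesign) -> str | None:
    """Apply the design filters; return a rejection reason or None.

    The reactive-Gln filter applies only where the design fixes that
    position (it is skipped when the reactive position is itself
    randomized).  Stop codons are rejected anywhere.  Peptides whose
    non-randomized backbone differs from the template are retained.
    """
    if design.reactive_is_fixed and peptide[design.reactive_index] != "Q":
        return "no_reactive_gln"
    if "*" in peptide:
        return "stop_codon"
    return None


def _translate_lenient(dna: str) -> str | None:
    """Codon-wise translation; None when a codon is not pure ACGT."""
    out = []
    for i in range(0, len(dna), 3):
        aa = CODON_TABLE.get(dna[i : i + 3])
        if aa is None:
            return None
        out.append(aa)
    return "".join(out)


def count_peptides(
    r1_path,
    r2_path,
    design: LibraryDesign,
    quality_threshold: float = 25.0,
    tag_mismatch: int = 1,
    anchor_mismatch: int = 1,
    adapters=(),
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.2,
    sample_label: str = "sample",
) -> tuple[ProcessedCounts, QCReport]:
    """Stream a FASTQ pair through the full filter chain and count peptides.

    When the design defines tags, reads are demultiplexed into per-tag
    samples; otherwise everything accepted lands in ``sample_label``.
    The QC report covers all input reads of both mates, before trimming.
    """
    result = ProcessedCounts()
    qc = QCReport()
    if design.tags:
        for label in design.tags:
            result.counts[label] = Counter()
    else:
        result.counts[sample_label] = Counter()

    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (_t1, s1, q1), (_t2, s2, q2) in zip(it1, it2):
            result.n_pairs += 1
            qc.add_read(q1, quality_threshold)
            qc.add_read(q2, quality_threshold)
            if adapters:
                s1, q1 = trim_adapter(
                    s1, q1, adapters, min_overlap, max_mismatch_rate
                )
                s2, q2 = trim_adapter(
                    s2, q2, adapters, min_overlap, max_mismatch_rate
                )
            if not s1 or not s2:
                result.rejections["adapter_only"] += 1
                continue
            if not (
                pass_quality(q1, quality_threshold)
                and pass_quality(q2, quality_threshold)
            ):
                result.rejections["low_quality"] += 1
                continue
            if design.tags:
                label = demultiplex(s1, design.tags, tag_mismatch)
                if label == "unassigned":
                    result.rejections["no_tag"] += 1
                    continue
                s1_body = s1[10:]
            else:
                label = sample_label
                s1_body = s1
            dna, reason = extract_coding_dna(
                s1_body, s2, design, anchor_mismatch
            )
            if dna is None:
                result.rejections[reason] += 1
                continue
            peptide = _translate_lenient(dna)
            if peptide is None:
                result.rejections["frame_fail"] += 1
                continue
            reason = accept_peptide(peptide, design)
            if reason is not None:
                result.rejections[reason] += 1
                continue
            result.counts[label][peptide] += 1
    return result, qc


def write_qc_json(qc: QCReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
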