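"""Selection-experiment simulator with known ground truth.

Emulates one round of an activity-based display selection: a degenerate NNK
library is sampled, each displayed peptide is captured with a probability
given by a logistic-additive reactivity model (plus a nonspecific
background), and both the original and the captured pool are sequenced as
paired-end FASTQ with per-base substitution errors and Phred qualities.

The capture model for a peptide x with residues x(rel) at the randomized
Gln-relative positions is::

    p(x) = beta + (1 - beta) * sigmoid(b0 + sum_rel W[rel, x(rel)])

applied only when the reactive position carries Gln (when required); peptides
failing that, or carrying a stop at a scored position, are captured at the
background rate beta alone.  An optional artifact rule adds capture
probability to peptides containing a motif (modelling streptavidin-binding
His/Trp false positives), clamped to [0, 1].

Everything is reproducible from an integer seed; identical seeds give
byte-identical FASTQ files.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import (
    AMINO_ACIDS,
    CODON_TABLE,
    NNK_CODONS,
    LibraryDesign,
    nnk_residue_counts,
    rel_to_abs,
    reverse_complement,
)

__all__ = [
    "SelectionModel",
    "SequencingModel",
    "SimulatedExperiment",
    "capture_probability",
    "capture_probabilities",
    "default_selection_model",
    "emit_fastq",
    "sample_library",
    "simulate_experiment",
    "simulate_selection",
    "true_position_ef",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SelectionModel:
    """Ground truth for one selection round.

    ``weights`` maps Gln-relative position -> residue -> log-odds
    contribution; unlisted residues contribute 0.  ``baseline`` is the
    log-odds intercept, ``background_rate`` the nonspecific capture
    probability, and ``artifact_boost`` an optional ``(motif, delta)`` rule
    adding ``delta`` capture probability to peptides containing ``motif``.
    """

    weights: dict[int, dict[str, float]] = field(default_factory=dict)
    baseline: float = -2.0
    background_rate: float = 0.002
    artifact_boost: tuple[str, float] | None = None
    requires_reactive_gln: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must be in [0, 1)")
        for rel, row in self.weights.items():
            for aa, w in row.items():
                if not math.isfinite(w):
                    raise ValueError(f"weight W[{rel},{aa}] is not finite")

    def weight(self, rel: int, residue: str) -> float:
        return self.weights.get(rel, {}).get(residue, 0.0)


def default_selection_model() -> SelectionModel:
    """The default planted model used for parameter-recovery exercises.

    Gln at -1 strongly favoured, Ile/Val at +3 moderately favoured, Phe at +2
    disfavoured — qualitatively the substrate preference the pipeline is
    meant to recover.
    """
    return SelectionModel(
        weights={-1: {"Q": 2.0}, 3: {"I": 1.0, "V": 1.0}, 2: {"F": -1.5}},
        baseline=-2.0,
        background_rate=0.002,
    )


@dataclass(frozen=True)
class SequencingModel:
    """Paired-end sequencing parameters (substitution errors only)."""

    reads_per_sample: int = 100_000
    read_length: int | None = None  # None: exactly cover the construct
    per_base_error: float = 0.0
    mean_quality: float = 35.0
    quality_sd: float = 3.0
    paired: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


def sample_library(
    design: LibraryDesign, n_molecules: int, seed: int
) -> pd.DataFrame:
    """Draw a library pool: uniform over the 32 NNK codons at each
    randomized position, backbone codons fixed.

    Returns a DataFrame with columns ``dna`` (coding region only),
    ``peptide`` and ``count``, one row per distinct molecule.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    positions = sorted(design.randomized_indices)
    draws = rng.integers(0, 32, size=(n_molecules, len(positions)))
    uniq, counts = np.unique(draws, axis=0, return_counts=True)

    codons = design.backbone_codons()
    residues = design.backbone_peptide
    dnas, peptides = [], []
    for row in uniq:
        cod = list(codons)
        pep = list(residues)
        for pos, ci in zip(positions, row):
            cod[pos] = NNK_CODONS[ci]
            pep[pos] = CODON_TABLE[NNK_CODONS[ci]]
        dnas.append("".join(cod))
        peptides.append("".join(pep))
    return pd.DataFrame({"dna": dnas, "peptide": peptides, "count": counts})


def _scores(peptides: list[str], model: SelectionModel, design: LibraryDesign):
    """Vectorized (p, specific-allowed) over a list of equal-length peptides."""
    n = len(peptides)
    L = design.length
    arr = np.frombuffer("".join(peptides).encode(), np.uint8).reshape(n, L)
    score = np.full(n, model.baseline)
    ok = np.ones(n, dtype=bool)
    for rel in design.randomized_rel:
        col = arr[:, rel_to_abs(design, rel)]
        ok &= col != ord("*")
        table = np.zeros(256)
        for aa, w in model.weights.get(rel, {}).items():
            table[ord(aa)] = w
        score += table[col]
    # weights at non-randomized positions (fixed backbone) are constant
    # offsets; apply them too so the model composes for any design
    for rel, row in model.weights.items():
        idx = design.reactive_index + rel
        if 0 <= idx < L and idx not in design.randomized_indices:
            table = np.zeros(256)
            for aa, w in row.items():
                table[ord(aa)] = w
            score += table[arr[:, idx]]
    if model.requires_reactive_gln:
        ok &= arr[:, design.reactive_index] == ord("Q")
    beta = model.background_rate
    p = np.where(ok, beta + (1 - beta) / (1 + np.exp(-score)), beta)
    if model.artifact_boost is not None:
        motif, delta = model.artifact_boost
        hit = np.fromiter(
            (motif in pep for pep in peptides), dtype=bool, count=n
        )
        p = np.clip(p + delta * hit, 0.0, 1.0)
    return p


def capture_probabilities(
    peptides, model: SelectionModel, design: LibraryDesign
) -> np.ndarray:
    """Capture probability for each peptide in a sequence of peptides."""
    peptides = list(peptides)
    if not peptides:
        return np.empty(0)
    for pep in peptides:
        if len(pep) != design.length:
            raise ValueError(
                f"peptide {pep!r} length != design length {design.length}"
            )
    return _scores(peptides, model, design)


def capture_probability(
    peptide: str, model: SelectionModel, design: LibraryDesign
) -> float:
    """Capture probability of a single peptide under the selection model."""
    return float(capture_probabilities([peptide], model, design)[0])


def simulate_selection(
    pool: pd.DataFrame,
    model: SelectionModel,
    design: LibraryDesign,
    seed: int,
) -> pd.DataFrame:
    """One selection round: Binomial(count, p) capture per molecule species.

    Returns the pool with columns ``count_before``, ``p`` (the ground-truth
    capture probability) and ``count_after`` added.
    """
    if pool.empty:
        raise ValueError("pool is empty")
    rng = np.random.default_rng(seed)
    out = pool.rename(columns={"count": "count_before"}).copy()
    out["p"] = capture_probabilities(out["peptide"].tolist(), model, design)
    out["count_after"] = rng.binomial(out["count_before"], out["p"])
    return out


def _phred_to_bytes(q: np.ndarray) -> np.ndarray:
    return (q + 33).astype(np.uint8)


def _open_out(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        # fixed mtime keeps gzip output byte-identical across runs
        return gzip.GzipFile(path, mode + "b", mtime=0)
    return open(path, mode + "b")


def emit_fastq(
    counts: pd.DataFrame,
    design: LibraryDesign,
    seq_model: SequencingModel,
    seed: int,
    out_r1,
    out_r2=None,
    tag_label: str | None = None,
    append: bool = False,
    id_prefix: str = "read",
) -> pd.DataFrame:
    """Sequence a pool: sample reads multinomially and write FASTQ.

    ``counts`` needs columns ``dna`` and ``count`` (a ``count_after`` or
    ``count_before`` column may be renamed by the caller).  Each read is
    ``[tag] + upstream_anchor + dna + downstream_anchor``, padded with ``A``
    to ``read_length``; read 2 is the reverse complement with independent
    errors.  Returns the per-molecule read allocation (columns ``dna``,
    ``n_reads``).
    """
    if counts.empty or counts["count"].sum() == 0:
        raise ValueError("counts are empty")
    tag = design.tags[tag_label] if tag_label is not None else ""
    constructs = (
        tag + design.upstream_anchor
        + counts["dna"]
        + design.downstream_anchor
    ).to_numpy()
    clen = len(constructs[0])
    read_length = seq_model.read_length or clen
    if read_length < clen:
        raise ValueError(
            f"read_length {read_length} shorter than construct ({clen} nt)"
        )
    pad = "A" * (read_length - clen)

    rng = np.random.default_rng(seed)
    weights = counts["count"].to_numpy()
    alloc = rng.multinomial(seq_model.reads_per_sample, weights / weights.sum())

    # forward and reverse-complement construct matrices (uint8 ASCII)
    fwd = np.frombuffer(
        "".join(c + pad for c in constructs).encode(), np.uint8
    ).reshape(len(constructs), read_length)
    rev = np.frombuffer(
        "".join(reverse_complement(c + pad) for c in constructs).encode(),
        np.uint8,
    ).reshape(len(constructs), read_length)

    rows = np.repeat(np.arange(len(constructs)), alloc)
    mates = [fwd[rows]]
    if seq_model.paired:
        mates.append(rev[rows])

    base_to_idx = np.zeros(256, np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_to_idx[b] = i
    idx_to_base = np.frombuffer(b"ACGT", np.uint8)

    handles = [_open_out(out_r1, "a" if append else "w")]
    if seq_model.paired:
        if out_r2 is None:
            raise ValueError("paired sequencing requires out_r2")
        handles.append(_open_out(out_r2, "a" if append else "w"))

    try:
        for mate, fh in zip(mates, handles):
            seqs = mate.copy()
            if seq_model.per_base_error > 0:
                err = rng.random(seqs.shape) < seq_model.per_base_error
                shift = rng.integers(1, 4, size=int(err.sum()))
                orig = base_to_idx[seqs[err]]
                seqs[err] = idx_to_base[(orig + shift) % 4]
            quals = _phred_to_bytes(
                np.clip(
                    np.rint(
                        rng.normal(
                            seq_model.mean_quality,
                            seq_model.quality_sd,
                            size=seqs.shape,
                        )
                    ),
                    2,
                    40,
                ).astype(np.int64)
            )
            chunk: list[bytes] = []
            for i in range(seqs.shape[0]):
                chunk.append(
                    b"@%s_%d\n%s\n+\n%s\n"
                    % (
                        id_prefix.encode(),
                        i,
                        seqs[i].tobytes(),
                        quals[i].tobytes(),
                    )
                )
                if len(chunk) == 50_000:
                    fh.write(b"".join(chunk))
                    chunk = []
            fh.write(b"".join(chunk))
    finally:
        for fh in handles:
            fh.close()

    return pd.DataFrame({"dna": counts["dna"].to_numpy(), "n_reads": alloc})


def true_position_ef(
    model: SelectionModel,
    design: LibraryDesign,
    condition_on_accepted: bool = True,
) -> pd.DataFrame:
    """Analytic expected position EF matrix under the selection model.

    For each randomized Gln-relative position and residue a::

        EF(rel, a) = E[p | a at rel] / E[p]

    computed by exact enumeration over the NNK-induced residue distribution
    at the randomized sites (weighted by NNK codon multiplicities).  With
    ``condition_on_accepted`` (default) the distribution is conditioned on
    the read-processing filters — no stop codon at any randomized site —
    matching what the empirical matrix estimates.

    Returns a 20-residue x positions DataFrame (columns = relative
    positions, ascending).
    """
    rels = design.randomized_rel
    k = len(rels)
    counts = nnk_residue_counts()
    if condition_on_accepted:
        residues = AMINO_ACIDS
        m = np.array([counts[a] for a in residues], float) / 31.0
    else:
        residues = AMINO_ACIDS + "*"
        m = np.array([counts[a] for a in residues], float) / 32.0

    grids = np.meshgrid(*([np.arange(len(residues))] * k), indexing="ij")
    combo = np.stack([g.ravel() for g in grids])  # (k, n_combos)
    weight = m[combo].prod(axis=0)

    base = model.baseline
    # weights at fixed backbone positions are constant offsets
    for rel, row in model.weights.items():
        idx = design.reactive_index + rel
        if rel not in rels and 0 <= idx < design.length:
            base += row.get(design.backbone_peptide[idx], 0.0)
    score = np.full(combo.shape[1], base)
    ok = np.ones(combo.shape[1], dtype=bool)
    for j, rel in enumerate(rels):
        res_j = combo[j]
        ok &= res_j < 20  # stop at a scored position -> background only
        wvec = np.array(
            [model.weight(rel, a) if a != "*" else 0.0 for a in residues]
        )
        score += wvec[res_j]
    if model.requires_reactive_gln:
        if design.reactive_is_fixed:
            if design.backbone_peptide[design.reactive_index] != "Q":
                ok &= False
        else:
            j = rels.index(0)
            ok &= combo[j] == _AA_INDEX["Q"]
    beta = model.background_rate
    p = np.where(ok, beta + (1 - beta) / (1 + np.exp(-score)), beta)
    if model.artifact_boost is not None:
        motif, delta = model.artifact_boost
        # enumerate peptides only when the artifact rule is active
        backbone = list(design.backbone_peptide)
        hits = np.empty(combo.shape[1], dtype=bool)
        abs_pos = [rel_to_abs(design, r) for r in rels]
        for i in range(combo.shape[1]):
            pep = list(backbone)
            for j, pos in enumerate(abs_pos):
                pep[pos] = residues[combo[j, i]]
            hits[i] = motif in "".join(pep)
        p = np.clip(p + delta * hits, 0.0, 1.0)

    overall = float(np.sum(weight * p) / np.sum(weight))
    mat = np.empty((20, k))
    for j in range(k):
        for ai in range(20):
            sel = combo[j] == ai
            w = weight[sel]
            mat[ai, j] = float(np.sum(w * p[sel]) / np.sum(w)) / overall
    return pd.DataFrame(mat, index=list(AMINO_ACIDS), columns=list(rels))


@dataclass
class SimulatedExperiment:
    """A fully simulated selection with its ground truth and outputs."""

    design: LibraryDesign
    model: SelectionModel
    seq_model: SequencingModel
    pool: pd.DataFrame  # dna, peptide, count_before, p, count_after
    fastq_paths: dict[str, tuple[str, str | None]]
    allocations: dict[str, pd.DataFrame]  # sample -> dna, peptide, n_reads

    @property
    def counts_before(self) -> pd.Series:
        return self.pool.groupby("peptide")["count_before"].sum()

    @property
    def counts_after(self) -> pd.Series:
        return self.pool.groupby("peptide")["count_after"].sum()

    def truth_table(self) -> pd.DataFrame:
        return self.pool[
            ["peptide", "dna", "p", "count_before", "count_after"]
        ].copy()

    def read_allocation(self, sample: str) -> pd.Series:
        """Reads actually emitted per peptide for one sample."""
        alloc = self.allocations[sample]
        return alloc.groupby("peptide")["n_reads"].sum()


def simulate_experiment(
    design: LibraryDesign,
    model: SelectionModel,
    seq_model: SequencingModel,
    n_molecules: int,
    out_dir,
    seed: int,
    gzip_output: bool = False,
) -> SimulatedExperiment:
    """Sample a library, select, and sequence both samples to FASTQ.

    With in-read tags defined on the design, both samples go into one file
    pair (tagged reads); otherwise each sample gets its own pair.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31, size=4)

    pool = sample_library(design, n_molecules, int(sub[0]))
    pool = simulate_selection(pool, model, design, int(sub[1]))

    ext = ".fastq.gz" if gzip_output else ".fastq"
    samples = {
        "before": pool.rename(columns={"count_before": "count"})[
            ["dna", "peptide", "count"]
        ],
        "after": pool.loc[
            pool["count_after"] > 0, ["dna", "peptide", "count_after"]
        ].rename(columns={"count_after": "count"}),
    }
    fastq_paths: dict[str, tuple[str, str | None]] = {}
    allocations: dict[str, pd.DataFrame] = {}
    tagged = bool(design.tags)
    if tagged:
        r1 = out_dir / f"reads_R1{ext}"
        r2 = out_dir / f"reads_R2{ext}"
    for i, (sample, counts) in enumerate(samples.items()):
        if tagged:
            paths = (str(r1), str(r2) if seq_model.paired else None)
            alloc = emit_fastq(
                counts,
                design,
                seq_model,
                int(sub[2 + i]),
                r1,
                r2 if seq_model.paired else None,
                tag_label=sample,
                append=i > 0,
                id_prefix=sample,
            )
        else:
            p1 = out_dir / f"{sample}_R1{ext}"
            p2 = out_dir / f"{sample}_R2{ext}"
            paths = (str(p1), str(p2) if seq_model.paired else None)
            alloc = emit_fastq(
                counts,
                design,
                seq_model,
                int(sub[2 + i]),
                p1,
                p2 if seq_model.paired else None,
                id_prefix=sample,
            )
        alloc = alloc.merge(counts[["dna", "peptide"]], on="dna")
        fastq_paths[sample] = paths
        allocations[sample] = alloc

    return SimulatedExperiment(
        design=design,
        model=model,
        seq_model=seq_model,
        pool=pool,
        fastq_paths=fastq_paths,
        allocations=allocations,
    )
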