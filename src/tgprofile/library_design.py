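"""Display-library designs and degenerate-codon / coordinate logic.

A :class:`LibraryDesign` describes one peptide display library: the backbone
peptide, which positions carry degenerate NNK codons, where the reactive
glutamine sits, and the flanking anchor DNA used to locate the coding region
inside a sequencing read.  Positions are 0-based internally; the field
convention of counting relative to the reactive Gln (-1, +1, +2, +3) is
exposed through :func:`rel_to_abs`.

NNK codons (N = any base, K = G/T) are the 32 codons whose third base is G or
T; they encode all 20 amino acids and a single stop (the amber codon TAG).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AMINO_ACIDS",
    "CODON_TABLE",
    "NNK_CODONS",
    "CoordinateError",
    "FrameError",
    "InvalidSequenceError",
    "LibraryDesign",
    "enumerate_nnk",
    "load_design",
    "load_preset",
    "rel_to_abs",
    "reverse_complement",
    "translate",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: codon -> one-letter residue, with stops in-band as '*' (64 entries)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

#: the 32 NNK codons, lexicographic
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# one fixed synonymous codon per residue, used when a design does not supply
# explicit backbone DNA (alphabetically first codon; the choice is arbitrary
# and nothing downstream depends on it)
_CANONICAL_CODON: dict[str, str] = {}
for _codon in sorted(CODON_TABLE):
    _CANONICAL_CODON.setdefault(CODON_TABLE[_codon], _codon)


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside its expected alphabet."""


class FrameError(ValueError):
    """A coding sequence is not a whole number of codons."""


class CoordinateError(IndexError):
    """A Gln-relative coordinate falls outside the peptide."""


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate frame-aligned DNA with the standard genetic code.

    Stop codons are rendered in-band as ``'*'`` so downstream filters can act
    on the translated string.

    Raises
    ------
    InvalidSequenceError
        If a character outside ``{A,C,G,T}`` occurs (the message names the
        0-based offset of the first offender).
    FrameError
        If ``len(dna)`` is not divisible by 3.
    """
    for i, ch in enumerate(dna):
        if ch not in "ACGT":
            raise InvalidSequenceError(
                f"non-ACGT character {ch!r} at offset {i}"
            )
    if len(dna) % 3:
        raise FrameError(f"length {len(dna)} is not divisible by 3")
    return "".join(CODON_TABLE[dna[i : i + 3]] for i in range(0, len(dna), 3))


def enumerate_nnk() -> list[tuple[str, str]]:
    """All 32 (NNK codon, residue-or-stop) pairs, in codon order."""
    return [(c, CODON_TABLE[c]) for c in NNK_CODONS]


def nnk_residue_counts() -> dict[str, int]:
    """Residue -> number of NNK codons encoding it ('*' included)."""
    counts: dict[str, int] = {}
    for _, aa in enumerate_nnk():
        counts[aa] = counts.get(aa, 0) + 1
    return counts


@dataclass(frozen=True)
class LibraryDesign:
    """One display-library design and its coordinate system.

    Parameters
    ----------
    name : str
        Library label (e.g. ``"Lib4"``).
    backbone_peptide : str
        Template peptide, one-letter codes, length L.
    reactive_index : int
        0-based index of the reactive (acyl-donor) glutamine.
    randomized_indices : frozenset[int]
        0-based indices carrying NNK codons.
    upstream_anchor, downstream_anchor : str
        DNA immediately 5'/3' of the peptide-coding region, used to locate it
        in reads.
    tags : dict[str, str]
        Optional sample label -> 10-nt in-read DNA tag (empty when samples are
        sequenced separately).
    min_count_after : int
        Default after-selection count threshold for ranking.
    backbone_dna : str
        Coding DNA of the backbone (3L nt); if omitted, a fixed synonymous
        encoding is generated.
    """

    name: str
    backbone_peptide: str
    reactive_index: int
    randomized_indices: frozenset[int]
    upstream_anchor: str
    downstream_anchor: str
    tags: dict[str, str] = field(default_factory=dict)
    min_count_after: int = 100
    backbone_dna: str = ""

    def __post_init__(self) -> None:
        L = len(self.backbone_peptide)
        if L == 0:
            raise ValueError("backbone_peptide is empty")
        object.__setattr__(
            self, "randomized_indices", frozenset(self.randomized_indices)
        )
        if not 0 <= self.reactive_index < L:
            raise ValueError(
                f"reactive_index {self.reactive_index} outside [0, {L})"
            )
        bad = [i for i in self.randomized_indices if not 0 <= i < L]
        if bad:
            raise ValueError(f"randomized_indices outside [0, {L}): {bad}")
        for label, anchor in (
            ("upstream_anchor", self.upstream_anchor),
            ("downstream_anchor", self.downstream_anchor),
        ):
            if not anchor or any(c not in "ACGT" for c in anchor):
                raise InvalidSequenceError(f"{label} must be nonempty ACGT DNA")
        for label, tag in self.tags.items():
            if len(tag) != 10 or any(c not in "ACGT" for c in tag):
                raise ValueError(f"tag {label!r} must be a 10-nt ACGT string")
        if len(set(self.tags.values())) != len(self.tags):
            raise ValueError("tags must be pairwise distinct")
        if not self.backbone_dna:
            object.__setattr__(
                self,
                "backbone_dna",
                "".join(_CANONICAL_CODON[a] for a in self.backbone_peptide),
            )
        if len(self.backbone_dna) != 3 * L:
            raise ValueError("backbone_dna length must be 3 * len(peptide)")
        if translate(self.backbone_dna) != self.backbone_peptide:
            raise ValueError("backbone_dna does not encode backbone_peptide")

    @property
    def length(self) -> int:
        return len(self.backbone_peptide)

    @property
    def tag_length(self) -> int:
        return 10 if self.tags else 0

    @property
    def randomized_rel(self) -> tuple[int, ...]:
        """Randomized positions in Gln-relative coordinates, ascending."""
        return tuple(
            sorted(i - self.reactive_index for i in self.randomized_indices)
        )

    @property
    def reactive_is_fixed(self) -> bool:
        """True when the design fixes Gln at the reactive position."""
        return self.reactive_index not in self.randomized_indices

    def backbone_codons(self) -> list[str]:
        dna = self.backbone_dna
        return [dna[3 * i : 3 * i + 3] for i in range(self.length)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "backbone_peptide": self.backbone_peptide,
            "reactive_index": self.reactive_index,
            "randomized_indices": sorted(self.randomized_indices),
            "upstream_anchor": self.upstream_anchor,
            "downstream_anchor": self.downstream_anchor,
            "tags": dict(self.tags),
            "min_count_after": self.min_count_after,
            "backbone_dna": self.backbone_dna,
        }


def rel_to_abs(design: LibraryDesign, rel: int) -> int:
    """Map a Gln-relative coordinate (0 = reactive Gln) to a 0-based index."""
    idx = design.reactive_index + rel
    if not 0 <= idx < design.length:
        raise CoordinateError(
            f"relative position {rel:+d} maps to index {idx}, "
            f"outside [0, {design.length})"
        )
    return idx


def _design_from_mapping(doc: dict) -> LibraryDesign:
    known = {
        "name",
        "backbone_peptide",
        "reactive_index",
        "randomized_indices",
        "upstream_anchor",
        "downstream_anchor",
        "tags",
        "min_count_after",
        "backbone_dna",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    doc = dict(doc)
    doc["randomized_indices"] = frozenset(doc.get("randomized_indices", ()))
    doc.setdefault("tags", {})
    doc["tags"] = doc["tags"] or {}
    return LibraryDesign(**doc)


def load_design(path) -> LibraryDesign:
    """Load a design from a YAML/JSON document mirroring the field names."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: design document must be a mapping")
    return _design_from_mapping(doc)


def load_preset(name: str) -> LibraryDesign:
    """Load a shipped preset design ("LibQ" or "Lib4")."""
    fname = f"{name.lower()}.yaml"
    ref = importlib.resources.files("tgprofile.presets").joinpath(fname)
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}") from None
    return _design_from_mapping(yaml.safe_load(text))
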