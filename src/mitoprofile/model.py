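"""Domain types for circular annotated mitochondrial genomes.

Coordinates are 1-based inclusive throughout (the GenBank convention); the
single conversion to Python slices happens inside the accessors here. Strands
are labelled J (majority) and N (minority); ``+``/``-`` are accepted as input
synonyms at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


class MitoError(ValueError):
    """Base error for malformed genomes, features, or files."""


@dataclass
class Genome:
    """A (usually circular) DNA molecule."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitoError(f"genome {self.id!r}: invalid symbols {sorted(bad)}")
        if not self.sequence:
            raise MitoError(f"genome {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Genome-strand sequence from start to end (1-based inclusive).

        start > end denotes a wrap-around span on a circular genome.
        """
        n = self.length
        if not (1 <= start <= n and 1 <= end <= n):
            raise MitoError(f"coordinates {start}-{end} out of range 1-{n}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise MitoError(f"wrap-around span {start}-{end} on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass
class Feature:
    """One annotated gene or the control region.

    ``anticodon`` / ``anticodon_pos`` are set only for tRNAs. ``anticodon_pos``
    is kept as the raw "start-end" text because published tables occasionally
    garble it; ``anticodon_flag`` records whether it parsed cleanly.
    """

    name: str
    cls: str
    start: int
    end: int
    strand: str = "J"
    anticodon: str | None = None
    anticodon_pos: str | None = None
    anticodon_flag: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise MitoError(f"{self.name}: unknown feature class {self.cls!r}")
        if self.strand in ("+",):
            self.strand = "J"
        elif self.strand in ("-",):
            self.strand = "N"
        if self.strand not in ("J", "N"):
            raise MitoError(f"{self.name}: unknown strand {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise MitoError(f"{self.name}: non-positive coordinates")
        if self.anticodon is not None and self.cls != "tRNA":
            raise MitoError(f"{self.name}: anticodon on non-tRNA feature")
        if self.anticodon_pos is not None:
            self.anticodon_flag = _check_anticodon_pos(self)

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def size(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def coding_sequence(self, genome: Genome) -> str:
        """The feature's own-strand (5'→3') sequence."""
        s = genome.slice(self.start, self.end)
        return revcomp(s) if self.strand == "N" else s


def _check_anticodon_pos(f: Feature) -> str | None:
    try:
        a, b = (int(x) for x in f.anticodon_pos.split("-"))
    except (ValueError, AttributeError):
        return "unparseable"
    if a > b:
        return "descending"
    if b - a != 2:
        return "not-a-triplet"
    lo, hi = (f.end, f.start) if f.wraps else (f.start, f.end)
    if not (lo <= a and b <= hi) and not f.wraps:
        return "outside-feature"
    return None


@dataclass
class FeatureTable:
    """Ordered, stranded annotations on one genome."""

    genome_id: str
    features: list[Feature]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise MitoError(f"duplicate feature names: {sorted(dup)}")
        for f in self.features:
            if f.end > self.genome_length or f.start > self.genome_length:
                raise MitoError(
                    f"{f.name}: {f.start}-{f.end} outside genome of "
                    f"length {self.genome_length}"
                )
            if f.wraps and not self.circular:
                raise MitoError(f"{f.name}: wrap-around span on a linear genome")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, cls: str) -> list[Feature]:
        return [f for f in self.features if f.cls == cls]

    def is_sorted(self) -> bool:
        starts = [f.start for f in self.features]
        # the first feature may wrap on a circular genome
        return all(a <= b for a, b in zip(starts[1:], starts[2:])) and (
            len(starts) < 2 or starts[0] <= starts[1] or self.features[0].wraps
        )


@dataclass
class GeneticCode:
    """A codon→amino-acid map plus the synonymous-family partition.

    Families group codons by encoded amino acid, so under the invertebrate
    mitochondrial code (NCBI table 5) Leu has 6 codons and Ser has 8
    (TCN + AGN, since AGA/AGG code for Ser).
    """

    table_id: int
    forward: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.families:
            fam: dict[str, set[str]] = {}
            for codon, aa in self.forward.items():
                fam.setdefault(aa, set()).add(codon)
            self.families = {aa: frozenset(c) for aa, c in fam.items()}
        n = len(self.forward) + len(self.stop_codons)
        if n != 64:
            raise MitoError(f"genetic code covers {n} codons, expected 64")

    def family_of(self, codon: str) -> frozenset[str]:
        return self.families[self.forward[codon]]

    def translate(self, codon: str) -> str:
        return "*" if codon in self.stop_codons else self.forward[codon]


def genetic_code(table_id: int = 5) -> GeneticCode:
    """Build a :class:`GeneticCode` from the NCBI tables (default: invertebrate
    mitochondrial, table 5)."""
    t = CodonTable.unambiguous_dna_by_id[table_id]
    return GeneticCode(
        table_id=table_id,
        forward=dict(t.forward_table),
        stop_codons=frozenset(t.stop_codons),
    )
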