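"""Multiple-sequence-alignment container with per-gene partition provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MitoError

ALIGN_ALPHABET = set("ACGTN-")


@dataclass
class Alignment:
    """Taxon→sequence map over {A,C,G,T,-,N} with equal row lengths.

    ``partitions`` maps a gene name to its half-open column interval
    (0-based) in a concatenated supermatrix.
    """

    sequences: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MitoError("empty alignment")
        clean = {}
        lengths = set()
        for name, seq in self.sequences.items():
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - ALIGN_ALPHABET
            if bad:
                raise MitoError(f"alignment row {name!r}: invalid symbols {sorted(bad)}")
            clean[name] = seq
            lengths.add(len(seq))
        if len(lengths) != 1:
            raise MitoError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.sequences = clean

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]

    def __len__(self) -> int:
        return len(self.sequences)


def concatenate(gene_alignments: dict[str, Alignment]) -> Alignment:
    """Column-wise concatenation of per-gene alignments into a supermatrix.

    The taxon set is the union over genes; a taxon absent from a gene gets
    that gene gap-filled. An empty intersection of taxa is an error (no row
    would tie the genes together).
    """
    if not gene_alignments:
        raise MitoError("no gene alignments supplied")
    taxa: list[str] = []
    for aln in gene_alignments.values():
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    common = set(taxa)
    for aln in gene_alignments.values():
        common &= set(aln.taxa)
    if not common:
        raise MitoError("gene alignments share no taxa")
    rows = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene, aln in gene_alignments.items():
        for t in taxa:
            rows[t].append(aln.sequences.get(t, "-" * aln.length))
        partitions[gene] = (offset, offset + aln.length)
        offset += aln.length
    return Alignment({t: "".join(parts) for t, parts in rows.items()}, partitions)
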