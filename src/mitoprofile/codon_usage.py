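"""Codon counts and relative synonymous codon usage (RSCU) for the
concatenated protein-coding genes, under the invertebrate mitochondrial
genetic code (NCBI table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp).

RSCU of codon c in a synonymous family f of size k is
``count(c) * k / sum(count(c') for c' in f)`` — 1.0 for every codon of a
family used uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import GeneticCode, MitoError, genetic_code


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    code: GeneticCode
    rscu: dict[str, float] = field(default_factory=dict)
    excluded_ambiguous: int = 0
    unused_families: list[str] = field(default_factory=list)

    def total(self) -> int:
        return sum(self.counts.values())

    def top_codons(self, n: int = 5) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]

    def rows(self) -> list[dict]:
        out = []
        for codon in sorted(self.code.forward) + sorted(self.code.stop_codons):
            out.append(
                {
                    "codon": codon,
                    "aa": self.code.translate(codon),
                    "count": self.counts.get(codon, 0),
                    "rscu": self.rscu.get(codon, 0.0),
                }
            )
        return out


def extract_codons(cds: str, code: GeneticCode | None = None) -> tuple[list[str], int]:
    """Non-overlapping triplets of a coding-strand CDS.

    A trailing incomplete codon (1–2 nt, the incomplete stop) is dropped, as
    is a terminal complete stop codon. Codons containing N are excluded;
    their number is returned alongside.
    """
    code = code or genetic_code()
    cds = cds.upper()
    if len(cds) < 3:
        raise MitoError("CDS shorter than one codon")
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if codons and codons[-1] in code.stop_codons:
        codons.pop()
    kept = [c for c in codons if "N" not in c]
    return kept, len(codons) - len(kept)


def count_codons(genes: list[str], code: GeneticCode | None = None) -> CodonUsageTable:
    code = code or genetic_code()
    counts: dict[str, int] = {}
    excluded = 0
    for cds in genes:
        codons, n_amb = extract_codons(cds, code)
        excluded += n_amb
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
    return CodonUsageTable(counts, code, excluded_ambiguous=excluded)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill per-codon RSCU from counts; families with zero total usage are
    flagged and their codons set to 0 by convention."""
    code = table.code
    values: dict[str, float] = {}
    unused: list[str] = []
    for aa, family in code.families.items():
        k = len(family)
        fam_total = sum(table.counts.get(c, 0) for c in family)
        if fam_total == 0:
            unused.append(aa)
            for c in family:
                values[c] = 0.0
            continue
        for c in family:
            values[c] = table.counts.get(c, 0) * k / fam_total
    table.rscu = values
    table.unused_families = sorted(unused)
    return table


def usage_report(genes: list[str], code: GeneticCode | None = None) -> CodonUsageTable:
    """Aggregated codon counts + RSCU over the supplied coding-strand PCGs.

    The canonical mitogenome has 13; fewer proceeds with a warning.
    """
    if len(genes) < 13:
        warnings.warn(f"only {len(genes)} PCGs supplied (expected 13)", stacklevel=2)
    return rscu(count_codons(genes, code))


def rscu_from_counts(counts: dict[str, int], code: GeneticCode | None = None) -> CodonUsageTable:
    """RSCU directly from a published codon-count table (stop codons, printed
    as zero counts, are dropped)."""
    code = code or genetic_code()
    counts = {c: n for c, n in counts.items() if c not in code.stop_codons}
    return rscu(CodonUsageTable(counts, code))
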