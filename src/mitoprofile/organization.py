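"""Gene-organization statistics on a circular annotated mitogenome.

Derived quantities of the classic mitogenome organization table: feature
sizes, signed intergenic nucleotides (IGN) per junction (negative = overlap),
and start/stop-codon classification including the incomplete stops (T-, TA-)
completed to TAA by post-transcriptional polyadenylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import Feature, FeatureTable, MitoError

START_CLASSES = ("ATN", "GTG", "TTG", "other")
STOP_CLASSES = ("TAA", "TAG", "T-", "TA-", "other")


def feature_size(f: Feature, genome_length: int) -> int:
    """Length in bp of a (possibly origin-wrapping) feature."""
    size = f.size(genome_length)
    if size <= 0:
        raise MitoError(f"{f.name}: computed non-positive size {size}")
    return size


@dataclass
class Junction:
    upstream: str
    downstream: str
    ign: int
    closing: bool = False  # the last-feature → first-feature junction


@dataclass
class JunctionReport:
    junctions: list[Junction]
    genome_length: int

    def _gene_junctions(self) -> list[Junction]:
        return [j for j in self.junctions if not j.closing]

    @property
    def spacer_total(self) -> int:
        return sum(j.ign for j in self._gene_junctions() if j.ign > 0)

    @property
    def spacer_count(self) -> int:
        return sum(1 for j in self._gene_junctions() if j.ign > 0)

    @property
    def overlap_total(self) -> int:
        return sum(-j.ign for j in self._gene_junctions() if j.ign < 0)

    @property
    def overlap_count(self) -> int:
        return sum(1 for j in self._gene_junctions() if j.ign < 0)

    @property
    def longest_overlap(self) -> int:
        overlaps = [-j.ign for j in self._gene_junctions() if j.ign < 0]
        return max(overlaps, default=0)

    def ign_of(self, downstream_name: str) -> int:
        for j in self.junctions:
            if j.downstream == downstream_name:
                return j.ign
        raise KeyError(downstream_name)


def junction_gaps(table: FeatureTable) -> JunctionReport:
    """Signed IGN for every adjacent feature pair, plus the circular closing
    junction (reported, but excluded from the gene-to-gene totals)."""
    if not table.is_sorted():
        raise MitoError("feature table is not sorted in genome order")
    feats = table.features
    n = table.genome_length
    junctions = []
    for up, down in zip(feats, feats[1:]):
        up_end = up.end if not up.wraps else up.end  # wrap only allowed first
        ign = down.start - up_end - 1
        size_up = up.size(n)
        size_down = down.size(n)
        if ign < -min(size_up, size_down):
            warnings.warn(
                f"junction {up.name}/{down.name}: overlap {-ign} bp exceeds the "
                f"smaller feature ({min(size_up, size_down)} bp)",
                stacklevel=2,
            )
        junctions.append(Junction(up.name, down.name, ign))
    last, first = feats[-1], feats[0]
    # across the origin: gap measured on the linearized circle
    closing_ign = (first.start - last.end - 1) % n
    if closing_ign > n // 2:  # interpret as overlap, not a near-full-circle gap
        closing_ign -= n
    junctions.append(Junction(last.name, first.name, closing_ign, closing=True))
    return JunctionReport(junctions, n)


def check_circle_conservation(table: FeatureTable) -> int:
    """Σ sizes + Σ signed IGN (all junctions) − genome length; 0 when the
    features and gaps tile the circle exactly."""
    report = junction_gaps(table)
    total = sum(feature_size(f, table.genome_length) for f in table)
    total += sum(j.ign for j in report.junctions)
    return total - table.genome_length


@dataclass
class CodonAssignment:
    gene: str
    start_codon: str | None = None
    start_class: str | None = None
    stop_codon: str | None = None


def classify_start_codon(cds: str) -> tuple[str, str]:
    """(codon, class) for the first triplet of a coding-strand CDS."""
    cds = cds.upper()
    if len(cds) < 3:
        raise MitoError("CDS shorter than one codon")
    codon = cds[:3]
    if codon[:2] == "AT":
        return codon, "ATN"
    if codon in ("GTG", "TTG"):
        return codon, codon
    return codon, "other"


def classify_stop_codon(cds: str, stop_set: frozenset[str] = frozenset({"TAA", "TAG"})) -> str:
    """Terminal signal of a coding-strand CDS: TAA/TAG, incomplete T- or TA-,
    else "other". Total for any CDS of length ≥ 3."""
    cds = cds.upper()
    if len(cds) < 3:
        raise MitoError("CDS shorter than one codon")
    r = len(cds) % 3
    if r == 0:
        last = cds[-3:]
        return last if last in stop_set else "other"
    if r == 1:
        return "T-" if cds[-1] == "T" else "other"
    return "TA-" if cds[-2:] == "TA" else "other"


def codon_assignments(genome, table: FeatureTable) -> list[CodonAssignment]:
    out = []
    for f in table.by_class("PCG"):
        cds = f.coding_sequence(genome)
        codon, cls = classify_start_codon(cds)
        out.append(CodonAssignment(f.name, codon, cls, classify_stop_codon(cds)))
    return out


def organization_table(table: FeatureTable, genome=None) -> list[dict]:
    """Rows of the organization report (one per feature, genome order):
    direction, coordinates, size, signed IGN, and — when the sequence is
    available — start/stop codons for PCGs."""
    report = junction_gaps(table)
    codons = {}
    if genome is not None:
        codons = {c.gene: c for c in codon_assignments(genome, table)}
    rows = []
    for f in table:
        row = {
            "gene": f.name,
            "class": f.cls,
            "direction": f.strand if f.cls != "CR" else "",
            "start": f.start,
            "end": f.end,
            "size": feature_size(f, table.genome_length),
            "ign": report.ign_of(f.name),
            "anticodon": f.anticodon or "",
        }
        c = codons.get(f.name)
        row["start_codon"] = c.start_codon if c else ""
        row["stop_codon"] = c.stop_codon if c else ""
        rows.append(row)
    return rows
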