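"""Nucleotide composition and strand-asymmetry (AT/GC skew) profiles.

Skews follow the standard definitions AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C), computed on percentages (equivalently counts).
Ambiguous bases (N) are excluded from both numerator and denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .model import FeatureTable, Genome, MitoError, revcomp

#: Row labels of the standard per-class composition report.
CLASS_ROWS = (
    "whole",
    "PCGs",
    "PCGs-J",
    "PCGs-N",
    "tRNAs",
    "tRNAs-J",
    "tRNAs-N",
    "rRNAs",
    "lrRNA",
    "srRNA",
    "CR",
)


@dataclass
class CompositionProfile:
    label: str
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    n_bases: int

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def at_skew(self) -> float:
        return skews(self.pct_A, self.pct_T, self.pct_G, self.pct_C)[0]

    @property
    def gc_skew(self) -> float:
        return skews(self.pct_A, self.pct_T, self.pct_G, self.pct_C)[1]

    def rounded(self) -> dict:
        """Report-precision view: percentages to 1 decimal, skews to 3."""
        at, gc = self.at_skew, self.gc_skew
        return {
            "label": self.label,
            "pct_T": round(self.pct_T, 1),
            "pct_C": round(self.pct_C, 1),
            "pct_A": round(self.pct_A, 1),
            "pct_G": round(self.pct_G, 1),
            "at_content": round(self.at_content, 1),
            "at_skew": round(at, 3) if not math.isnan(at) else float("nan"),
            "gc_skew": round(gc, 3) if not math.isnan(gc) else float("nan"),
        }


def base_composition(seq: str, label: str = "") -> CompositionProfile:
    """Percent A/C/G/T of a sequence, N excluded from the denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "TCAG"}
    total = sum(counts.values())
    if total == 0:
        raise MitoError(f"{label or 'sequence'}: empty or all-N")
    pct = {b: 100.0 * c / total for b, c in counts.items()}
    return CompositionProfile(label, pct["T"], pct["C"], pct["A"], pct["G"], total)


def skews(pct_A: float, pct_T: float, pct_G: float, pct_C: float) -> tuple[float, float]:
    """(AT-skew, GC-skew); a zero denominator yields NaN, never a crash."""
    at = (pct_A - pct_T) / (pct_A + pct_T) if pct_A + pct_T > 0 else float("nan")
    gc = (pct_G - pct_C) / (pct_G + pct_C) if pct_G + pct_C > 0 else float("nan")
    return at, gc


def _class_sequence(genome: Genome, feats, strand: str | None, own_strand: bool) -> str:
    """Concatenated sequence of the given features.

    Strand-split rows use each gene's own coding strand when ``own_strand``
    (the default convention here); with ``own_strand=False`` every feature
    contributes its majority(J)-strand reading instead.
    """
    parts = []
    for f in feats:
        if strand is not None and f.strand != strand:
            continue
        seq = genome.slice(f.start, f.end)
        if own_strand and f.strand == "N":
            seq = revcomp(seq)
        parts.append(seq)
    return "".join(parts)


def class_profiles(
    genome: Genome, table: FeatureTable, own_strand: bool = True
) -> list[CompositionProfile]:
    """One composition profile per standard row label (whole genome, PCGs and
    their strand splits, tRNAs and splits, rRNAs, lrRNA, srRNA, CR).

    Classes with no features are omitted with a warning.
    """
    pcg = table.by_class("PCG")
    trna = table.by_class("tRNA")
    rrna = table.by_class("rRNA")
    cr = table.by_class("CR")
    lr = [f for f in rrna if "l" in f.name.lower().split("rrna")[0] or f.name.lower().startswith("16")]
    sr = [f for f in rrna if f not in lr]
    spec = {
        "whole": (None, [None]),
        "PCGs": (pcg, [None]),
        "PCGs-J": (pcg, ["J"]),
        "PCGs-N": (pcg, ["N"]),
        "tRNAs": (trna, [None]),
        "tRNAs-J": (trna, ["J"]),
        "tRNAs-N": (trna, ["N"]),
        "rRNAs": (rrna, [None]),
        "lrRNA": (lr, [None]),
        "srRNA": (sr, [None]),
        "CR": (cr, [None]),
    }
    out = []
    for label in CLASS_ROWS:
        feats, (strand,) = spec[label]
        if feats is None:
            seq = genome.sequence
        else:
            seq = _class_sequence(genome, feats, strand, own_strand)
        if not seq:
            warnings.warn(f"composition row {label!r}: no features, omitted", stacklevel=2)
            continue
        out.append(base_composition(seq, label))
    return out
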