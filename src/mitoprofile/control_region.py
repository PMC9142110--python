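"""Detection of control-region structural elements: tandem-repeat arrays,
microsatellites, poly-N runs, and stem-loop (hairpin) structures with the
3' flanking "G(A)nT" motif check, plus the five-part partition report.

All scanners take ``origin`` — the 1-based genome coordinate of the first
base of the scanned sequence — and report 1-based inclusive coordinates in
that frame, so they are position-shift equivariant by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import MitoError

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class CrElement:
    kind: str  # tandem_repeat | microsatellite | poly_run | stem_loop
    start: int  # 1-based inclusive, in the caller's origin frame
    end: int
    details: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_poly_runs(seq: str, min_len: int = 7, origin: int = 1) -> list[CrElement]:
    """Maximal single-base runs of length >= min_len, in coordinate order."""
    if min_len < 2:
        raise MitoError("min_len must be >= 2")
    seq = seq.upper()
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            out.append(
                CrElement(
                    "poly_run",
                    origin + i,
                    origin + j - 1,
                    {"base": seq[i], "run_length": j - i},
                )
            )
        i = j
    return out


def _primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def find_microsatellites(
    seq: str,
    max_unit: int = 6,
    min_copies: int = 5,
    origin: int = 1,
    include_homopolymers: bool = False,
) -> list[CrElement]:
    """Maximal perfect short tandem repeats (units 1–6 bp, >= min_copies
    complete copies). Runs are reported under their smallest period — an
    (AT)8 is not also an (ATAT)4 — and period-1 runs are left to
    :func:`find_poly_runs` unless ``include_homopolymers`` is set.
    """
    if max_unit < 1 or min_copies < 2:
        raise MitoError("thresholds must be positive (min_copies >= 2)")
    seq = seq.upper()
    n = len(seq)
    out: list[CrElement] = []
    min_p = 1 if include_homopolymers else 2
    for p in range(min_p, max_unit + 1):
        i = 0
        while i + 2 * p <= n:
            # extend the perfect period-p run starting at i
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            copies = (j - i) // p
            unit = seq[i : i + p]
            if copies >= min_copies and _primitive(unit) and "N" not in unit:
                end = i + copies * p  # complete copies only
                out.append(
                    CrElement(
                        "microsatellite",
                        origin + i,
                        origin + end - 1,
                        {"unit": unit, "copies": copies},
                    )
                )
                i = j
            else:
                i += 1
    # irredundancy: drop any element contained in another with smaller period
    out.sort(key=lambda e: (e.start, len(e.details["unit"])))
    kept: list[CrElement] = []
    for e in out:
        if any(
            k.start <= e.start and e.end <= k.end and len(k.details["unit"]) < len(e.details["unit"])
            for k in out
            if k is not e
        ):
            continue
        kept.append(e)
    return kept


def find_tandem_repeats(
    seq: str,
    min_unit: int = 7,
    max_unit: int = 200,
    min_copies: float = 2.0,
    min_identity: float = 0.85,
    min_array: int = 30,
    origin: int = 1,
) -> list[CrElement]:
    """Tandem-repeat arrays by period enumeration with per-copy Hamming
    identity (each copy compared to the previous one).

    Copy number is fractional: (array length) / (unit length), including a
    trailing partial copy. Overlapping calls are resolved greedily by
    copies × mean identity, ties to the smaller unit. ``min_array`` (total
    bp) is a specificity floor: two near-identical copies of a very short
    unit arise constantly by chance in random sequence.
    """
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    candidates: list[CrElement] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        match = (arr[u:] == arr[:-u]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(match)])  # cs[k] = matches in match[:k]

        def ident(a: int, b: int) -> float:  # identity of seq[a:b] vs seq[a-u:b-u]
            return (cs[b - u] - cs[a - u]) / (b - a)

        # quick vector screen: first adjacent copy must clear the threshold
        starts = np.arange(0, n - 2 * u + 1)
        first = (cs[starts + u] - cs[starts]) / u
        for i in starts[first >= min_identity]:
            i = int(i)
            if not match[i]:
                continue  # array boundaries anchored on matching positions
            c = 1  # adjacent full copies confirmed beyond the initial unit
            while (
                i + (c + 2) * u <= n
                and match[i + (c + 2) * u - 1 - u]
                and ident(i + (c + 1) * u, i + (c + 2) * u) >= min_identity
            ):
                c += 1
            # trailing partial copy: longest prefix still clearing the threshold
            tail_start = i + (c + 1) * u
            best_ell = 0
            for ell in range(1, min(u - 1, n - tail_start) + 1):
                if match[tail_start + ell - 1 - u] and ident(tail_start, tail_start + ell) >= min_identity:
                    best_ell = ell
            total = (c + 1) * u + best_ell
            copies = total / u
            if copies < min_copies or total < min_array:
                continue
            ids = [ident(i + (m + 1) * u, i + (m + 2) * u) for m in range(c)]
            if best_ell:
                ids.append(ident(tail_start, tail_start + best_ell))
            mean_id = float(np.mean(ids))
            consensus = _consensus(seq[i : i + total], u)
            if _near_periodic(consensus):
                continue  # microsatellite/poly-run territory, not a repeat array
            candidates.append(
                CrElement(
                    "tandem_repeat",
                    origin + i,
                    origin + i + total - 1,
                    {
                        "unit_length": u,
                        "consensus": consensus,
                        "copies": round(copies, 4),
                        "identity": round(mean_id, 4),
                    },
                )
            )
    return _resolve_overlaps(candidates)


def _near_periodic(unit: str, max_d: int = 6, min_id: float = 0.8) -> bool:
    """True when the unit is (close to) a repetition of a period <= max_d —
    such arrays belong to the microsatellite / poly-run scanners."""
    p = len(unit)
    for d in range(1, min(max_d, p - 1) + 1):
        tiled = (unit[:d] * (p // d + 1))[:p]
        matches = sum(a == b for a, b in zip(unit, tiled))
        if matches / p >= min_id:
            return True
    return False


def _consensus(region: str, u: int) -> str:
    cols = [[] for _ in range(u)]
    for i, b in enumerate(region):
        cols[i % u].append(b)
    return "".join(max(set(c), key=c.count) for c in cols)


def _resolve_overlaps(candidates: list[CrElement]) -> list[CrElement]:
    def score(e: CrElement) -> tuple:
        return (
            -(e.details["copies"] * e.details["identity"]),
            e.details["unit_length"],
            e.start,
        )

    kept: list[CrElement] = []
    for e in sorted(candidates, key=score):
        if all(e.end < k.start or k.end < e.start for k in kept):
            kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


def _paired(a: str, b: str) -> bool:
    return (a, b) in _PAIRS or (a, b) in _WOBBLE


def find_stem_loops(
    seq: str,
    min_stem: int = 10,
    max_mismatch: int = 2,
    loop_range: tuple[int, int] = (3, 30),
    origin: int = 1,
    flank_window: int = 12,
) -> list[CrElement]:
    """Inverted repeats (DNA hairpins): stems of >= min_stem pairs
    (Watson–Crick or G-T wobble) with <= max_mismatch internal mismatches
    around a loop of loop_range nt. The 3' flank is scanned for the
    replication-associated "G(A)nT" motif and classified exact / modified
    ("GTA") / absent.
    """
    seq = seq.upper()
    n = len(seq)
    lo, hi = loop_range
    candidates: list[CrElement] = []
    for l in range(lo, hi + 1):
        for a in range(1, n - l):  # loop occupies [a, a+l)
            b = a + l
            stem = 0
            mism = 0
            best = None
            k = 0
            while a - 1 - k >= 0 and b + k < n and mism <= max_mismatch:
                if _paired(seq[a - 1 - k], seq[b + k]):
                    stem = k + 1
                    if stem >= min_stem:
                        best = (stem, mism)
                else:
                    mism += 1
                k += 1
            if best is None:
                continue
            stem, mism = best
            s0 = a - stem  # includes internal mismatched positions
            e0 = b + stem - 1
            flank = seq[e0 + 1 : e0 + 1 + flank_window]
            if re.match(r"GA+T", flank):
                motif = "exact"
            elif "GTA" in flank:
                motif = "modified"
            else:
                motif = "absent"
            candidates.append(
                CrElement(
                    "stem_loop",
                    origin + s0,
                    origin + e0,
                    {
                        "stem_length": stem,
                        "loop_length": l,
                        "mismatches": mism,
                        "flank_motif": motif,
                    },
                )
            )
    def score(e: CrElement) -> tuple:
        d = e.details
        # net pairs first; prefer clean stems over mismatch-padded variants
        return (-(d["stem_length"] - d["mismatches"]), d["mismatches"], d["loop_length"], e.start)

    kept: list[CrElement] = []
    for e in sorted(candidates, key=score):
        if all(e.end < k.start or k.end < e.start for k in kept):
            kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


@dataclass
class CrPartition:
    segments: list[tuple[str, int, int]]  # (label, start, end) 1-based inclusive

    @property
    def lengths(self) -> list[int]:
        return [e - s + 1 for _, s, e in self.segments]


def partition_cr(cr_seq: str, elements: list[CrElement]) -> CrPartition:
    """Partition a control region into lead / repeat blocks / spacers / tail,
    induced by merging adjacent tandem-repeat arrays into blocks.

    Elements must be in CR-local coordinates (origin 1). Segment lengths sum
    to the CR length by construction.
    """
    n = len(cr_seq)
    if n == 0:
        raise MitoError("zero-length control region")
    arrays = sorted(
        (e for e in elements if e.kind == "tandem_repeat"), key=lambda e: e.start
    )
    blocks: list[list[int]] = []
    for e in arrays:
        if blocks and e.start <= blocks[-1][1] + 1:
            blocks[-1][1] = max(blocks[-1][1], e.end)
        else:
            blocks.append([e.start, e.end])
    if not blocks:
        return CrPartition([("whole", 1, n)])
    segments: list[tuple[str, int, int]] = []
    pos = 1
    for bi, (s, e) in enumerate(blocks, start=1):
        if s > pos:
            label = "lead" if bi == 1 else f"spacer_{bi - 1}"
            segments.append((label, pos, s - 1))
        segments.append((f"repeat_block_{bi}", s, e))
        pos = e + 1
    if pos <= n:
        segments.append(("tail", pos, n))
    return CrPartition(segments)
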