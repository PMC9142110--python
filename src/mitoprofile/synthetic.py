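"""Synthetic annotated mitogenomes and tree-evolved alignments with known
ground truth.

The genome generator tiles a circular genome with the canonical insect
arrangement (13 PCGs, 22 tRNAs, 2 rRNAs, control region — the ancestral
*Drosophila yakuba* order), honoring planted gene overlaps including the
7-nt ATGNTAA start/stop overlap motif, building tRNAs from a cloverleaf
template with planted G-U/mismatch pairs, and assembling the control region
from an explicit plan (lead with hairpin, tandem-repeat blocks, spacer,
microsatellite, poly-N runs, tail). Every planted property is recorded in a
truth dictionary so downstream scanners can be tested for exact recovery.

Filler sequence is drawn from per-class base distributions defaulting to the
published *M. flexura* composition (A+T-rich), with homopolymer runs >= 7
broken outside planted elements so planted poly-N runs stay unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import io as mio
from .control_region import _near_periodic
from .model import Feature, FeatureTable, Genome, MitoError, revcomp
from .phylogeny import PhyloModel, simulate
from .rna_structure import CloverleafStructure, _scan_stem
from .tree import from_newick

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PAIR_KINDS = {
    "GU": ("G", "T"),
    "U-U": ("T", "T"),
    "A-G": ("A", "G"),
    "U-C": ("T", "C"),
    "A-C": ("A", "C"),
}

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RepeatBlockPlan:
    unit_length: int
    full_copies: int
    partial_len: int = 0

    @property
    def length(self) -> int:
        return self.unit_length * self.full_copies + self.partial_len

    @property
    def copies(self) -> float:
        return self.length / self.unit_length


@dataclass
class HairpinPlan:
    stem: int = 18
    loop: int = 8
    offset: int = 150  # 0-based within the lead segment
    flank: str = "GTA"  # 3' flanking motif text ("GAAT"-style = exact)

    @property
    def length(self) -> int:
        return 2 * self.stem + self.loop


@dataclass
class MicrosatPlan:
    unit: str = "AT"
    copies: int = 8
    offset: int = 100  # 0-based within the tail segment

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies


@dataclass
class PolyRunPlan:
    base: str
    length: int
    offset: int  # 0-based within the tail segment


@dataclass
class CrPlan:
    """Five-part control region: lead (with hairpin), repeat block 1,
    spacer, repeat block 2, tail (with microsatellite and poly runs)."""

    lead_len: int = 360
    blocks: tuple[RepeatBlockPlan, ...] = (
        RepeatBlockPlan(19, 3, 18),
        RepeatBlockPlan(16, 2, 12),
    )
    spacer_len: int = 23
    tail_len: int = 233
    hairpin: HairpinPlan | None = field(default_factory=HairpinPlan)
    microsat: MicrosatPlan | None = field(default_factory=MicrosatPlan)
    poly_runs: tuple[PolyRunPlan, ...] = (
        PolyRunPlan("A", 9, 62),
        PolyRunPlan("T", 9, 156),
    )

    @property
    def total(self) -> int:
        return self.lead_len + sum(b.length for b in self.blocks) + self.spacer_len + self.tail_len


#: default planted tRNA pairs: {tRNA name: [(arm, pair index, kind)]}
DEFAULT_TRNA_PAIR_PLAN: dict[str, list[tuple[str, int, str]]] = {
    "tRNA-Met": [("dhu", 1, "GU")],
    "tRNA-Trp": [("anticodon", 0, "GU"), ("tpsic", 2, "GU")],
    "tRNA-Lys": [("dhu", 2, "U-U")],
    "tRNA-His": [("anticodon", 3, "A-G")],
    "tRNA-Thr": [("tpsic", 1, "U-C")],
    "tRNA-Val": [("dhu", 0, "A-C")],
    "tRNA-Ile": [("tpsic", 0, "GU")],
}


def config_from_yaml(path, seed: int | None = None) -> "GenomeConfig":
    """Build a GenomeConfig from a YAML file; explicit ``seed`` wins over
    the file. Recognized keys: seed, cr_plan (lead_len, spacer_len,
    tail_len, blocks, hairpin, microsat, poly_runs), trna_pairs,
    motif_junctions."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "cr_plan" in raw:
        cp = dict(raw["cr_plan"])
        if "blocks" in cp:
            cp["blocks"] = tuple(RepeatBlockPlan(**b) for b in cp["blocks"])
        if cp.get("hairpin") is not None:
            cp["hairpin"] = HairpinPlan(**cp["hairpin"])
        if cp.get("microsat") is not None:
            cp["microsat"] = MicrosatPlan(**cp["microsat"])
        if "poly_runs" in cp:
            cp["poly_runs"] = tuple(PolyRunPlan(**p) for p in cp["poly_runs"])
        kwargs["cr_plan"] = CrPlan(**cp)
    if "trna_pairs" in raw:
        kwargs["trna_pairs"] = {
            k: [tuple(x) for x in v] for k, v in raw["trna_pairs"].items()
        }
    if "motif_junctions" in raw:
        kwargs["motif_junctions"] = tuple(tuple(j) for j in raw["motif_junctions"])
    kwargs["seed"] = seed if seed is not None else raw.get("seed", 0)
    return GenomeConfig(**kwargs)


@dataclass
class GenomeConfig:
    seed: int = 0
    cr_plan: CrPlan = field(default_factory=CrPlan)
    trna_pairs: dict[str, list[tuple[str, int, str]]] = field(
        default_factory=lambda: dict(DEFAULT_TRNA_PAIR_PLAN)
    )
    #: junction pairs expected to carry the 7-nt ATGNTAA overlap motif
    motif_junctions: tuple[tuple[str, str], ...] = (("ATP8", "ATP6"), ("ND4", "ND4L"))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _dist_from_row(row: dict) -> np.ndarray:
    p = np.array([row["pct_A"], row["pct_C"], row["pct_G"], row["pct_T"]], dtype=float)
    return p / p.sum()


def _class_dists() -> dict[str, np.ndarray]:
    rows = {r["label"]: r for r in mio.load_reference_composition()}
    return {
        "whole": _dist_from_row(rows["whole"]),
        "tRNA": _dist_from_row(rows["tRNAs"]),
        "lrRNA": _dist_from_row(rows["lrRNA"]),
        "srRNA": _dist_from_row(rows["srRNA"]),
        "CR": _dist_from_row(rows["CR"]),
    }


_BASES = np.array(list("ACGT"))


def _draw(rng, dist: np.ndarray, n: int) -> list[str]:
    return list(_BASES[rng.choice(4, size=n, p=dist)])


def _filler(rng, dist: np.ndarray, n: int, max_run: int = 6) -> list[str]:
    """Random filler with homopolymer runs capped at ``max_run``."""
    out = _draw(rng, dist, n)
    run = 1
    for i in range(1, n):
        run = run + 1 if out[i] == out[i - 1] else 1
        if run > max_run:
            others = [b for b in "ACGT" if b != out[i]]
            out[i] = others[int(rng.integers(3))]
            run = 1
    return out


# ---------------------------------------------------------------------------
# tRNA template
# ---------------------------------------------------------------------------


def _alloc_arms(L: int) -> tuple[int, int, int]:
    extra = L - 63
    if extra < 0 or extra > 11:
        raise MitoError(f"tRNA template supports 63-74 nt, got {L}")
    dv = min(extra, 4)
    extra -= dv
    dt = min(extra, 2)
    extra -= dt
    return 4 + extra, 4 + dt, 3 + dv  # dhu loop, t loop, variable loop


def trna_template_arms(L: int, dhu: bool = True) -> tuple[dict, tuple[int, int]]:
    """Arm pair indices (0-based) of the template cloverleaf for a tRNA gene
    of length L, plus the anticodon span."""
    dl, tl, v = _alloc_arms(L)
    arms: dict[str, list[tuple[int, int]]] = {
        "acceptor": [(k, L - 2 - k) for k in range(7)],
        "anticodon": [(17 + dl + k, 33 + dl - k) for k in range(5)],
    }
    if dhu:
        arms["dhu"] = [(8 + k, 15 + dl - k) for k in range(4)]
    s = 34 + dl + v
    arms["tpsic"] = [(s + k, s + 9 + tl - k) for k in range(5)]
    assert s + 9 + tl == L - 9
    return arms, (24 + dl, 26 + dl)


def _build_trna(
    name: str,
    L: int,
    anticodon: str,
    forced: dict[int, str],
    plant: list[tuple[str, int, str]],
    rng,
    dist: np.ndarray,
) -> tuple[str, CloverleafStructure]:
    dhu = "Ser(AGN)" not in name
    arms, ac_span = trna_template_arms(L, dhu=dhu)
    arr: list[str | None] = [None] * L
    for i, b in forced.items():
        arr[i] = b
    for off, b in enumerate(anticodon):
        i = ac_span[0] + off
        if arr[i] is not None and arr[i] != b:
            raise MitoError(f"{name}: anticodon conflicts with an overlap constraint")
        arr[i] = b
    plant_map = {(arm, k): kind for arm, k, kind in plant}
    for arm, pairs in arms.items():
        for k, (i, j) in enumerate(pairs):
            kind = plant_map.get((arm, k))
            if kind is not None:
                bi, bj = _PAIR_KINDS[kind]
                for idx, b in ((i, bi), (j, bj)):
                    if arr[idx] is not None and arr[idx] != b:
                        raise MitoError(f"{name}: planted pair {arm}[{k}] conflicts")
                    arr[idx] = b
            elif arr[i] is not None and arr[j] is not None:
                pass  # both ends constrained by overlaps; pair is whatever results
            elif arr[i] is not None:
                arr[j] = _COMP[arr[i]]
            elif arr[j] is not None:
                arr[i] = _COMP[arr[j]]
            else:
                arr[i] = str(_BASES[rng.choice(4, p=dist)])
                arr[j] = _COMP[arr[i]]
    free = [i for i in range(L) if arr[i] is None]
    fill = _draw(rng, dist, len(free))
    for i, b in zip(free, fill):
        arr[i] = b
    # keep the TΨC loop ends from pairing, which would shift the arm call
    ts, te = arms["tpsic"][0]
    loop_lo, loop_hi = ts + 5, te - 5
    if loop_lo in free or loop_hi in free:
        tgt = loop_hi if loop_hi in free else loop_lo
        other = loop_lo if tgt == loop_hi else loop_hi
        arr[tgt] = _nonpairing(arr[other], rng)
    seq = "".join(arr)
    if not dhu:
        # a DHU-less loop must not fold: resample its free bases until no
        # stem candidate survives in the DHU search window
        dl = _alloc_arms(L)[0]
        lo, hi = 8, ac_span[0] - 7
        loop_free = [i for i in range(8, 16 + dl) if i in free]
        for _ in range(200):
            if _scan_stem(seq, lo, hi, sizes=(4, 3), loops=range(3, 12)) is None:
                break
            for i, b in zip(loop_free, _draw(rng, dist, len(loop_free))):
                arr[i] = b
            seq = "".join(arr)
        else:
            raise MitoError(f"{name}: could not build a stem-free DHU loop")
    structure = CloverleafStructure(name=name, arms=arms, dhu_present=dhu, anticodon_span=ac_span)
    return seq, structure


# ---------------------------------------------------------------------------
# control region
# ---------------------------------------------------------------------------


def _nonpairing(base: str, rng) -> str:
    """A base that neither Watson–Crick- nor wobble-pairs with ``base``
    (pairs with G: C and T; with T: A and G; with A: T; with C: G)."""
    safe = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}[base]
    return safe[int(rng.integers(len(safe)))]


def _build_cr(plan: CrPlan, rng, dist: np.ndarray) -> tuple[str, list[dict]]:
    """Assemble the CR locally (1-based local coordinates in the truth)."""
    arr: list[str] = []
    elements: list[dict] = []

    def guard_against(unit_next: str) -> str:
        b = [x for x in "ACGT" if x != unit_next]
        return b[int(rng.integers(3))]

    # lead with hairpin
    lead = _filler(rng, dist, plan.lead_len)
    if plan.hairpin is not None:
        h = plan.hairpin
        if h.offset + h.length + len(h.flank) + 3 > plan.lead_len or h.offset < 3:
            raise MitoError("hairpin does not fit inside the CR lead")
        left = _filler(rng, dist, h.stem)
        loop = _filler(rng, dist, h.loop)
        # keep the loop from pairing inward (which would shift the call)
        for a, b in ((0, h.loop - 1), (1, h.loop - 2), (2, h.loop - 3)):
            if a < b:
                loop[b] = _nonpairing(loop[a], rng)
        right = [_COMP[b] for b in reversed(left)]
        hp = left + loop + right
        s = h.offset
        lead[s : s + h.length] = hp
        for i, b in enumerate(h.flank):
            lead[s + h.length + i] = b
        # guards: 3 bases either side must not extend the stem
        for k in range(3):
            lead[s - 1 - k] = _nonpairing(lead[s + h.length + k], rng)
        elements.append(
            {
                "kind": "stem_loop",
                "local_start": s + 1,
                "local_end": s + h.length,
                "stem_length": h.stem,
                "loop_length": h.loop,
                "mismatches": 0,
                "flank_motif": "modified" if h.flank == "GTA" else "exact",
            }
        )
    arr.extend(lead)

    # repeat blocks separated by the spacer
    for bi, block in enumerate(plan.blocks):
        if bi == 1:
            spacer = _filler(rng, dist, plan.spacer_len)
            prev = plan.blocks[0]
            # guard the spacer head against extending block 1's partial copy
            for t in range(min(5, plan.spacer_len)):
                nxt = elements[-1]["unit"][(prev.partial_len + t) % prev.unit_length]
                spacer[t] = guard_against(nxt)
            arr.extend(spacer)
        for _ in range(100):
            unit = _filler(rng, dist, block.unit_length)
            if _has_short_period(unit) or _max_run("".join(unit * 2)) >= 7:
                continue
            break
        else:
            raise MitoError("could not draw a clean repeat unit")
        unit_s = "".join(unit)
        # anchor the array start: a candidate shifted left by j is rejected
        # by the scanner's boundary-match rule when seq[s-j] != unit[-j]
        for j in range(1, min(3, len(arr)) + 1):
            arr[-j] = guard_against(unit_s[-j])
        region = unit_s * block.full_copies + unit_s[: block.partial_len]
        elements.append(
            {
                "kind": "tandem_repeat",
                "local_start": len(arr) + 1,
                "local_end": len(arr) + len(region),
                "unit_length": block.unit_length,
                "unit": unit_s,
                "copies": round(len(region) / block.unit_length, 4),
            }
        )
        arr.extend(region)

    # tail with microsatellite and poly runs
    tail = _filler(rng, dist, plan.tail_len)
    last = plan.blocks[-1]
    for t in range(min(5, plan.tail_len)):
        nxt = elements[-1]["unit"][(last.partial_len + t) % last.unit_length]
        tail[t] = guard_against(nxt)
    planted_spans = []
    if plan.microsat is not None:
        m = plan.microsat
        ms = m.unit * m.copies
        tail[m.offset : m.offset + len(ms)] = list(ms)
        tail[m.offset - 1] = guard_against(m.unit[-1])
        tail[m.offset + len(ms)] = guard_against(m.unit[0])
        planted_spans.append((m.offset, m.offset + len(ms)))
        elements.append(
            {
                "kind": "microsatellite",
                "local_start": plan.total - plan.tail_len + m.offset + 1,
                "local_end": plan.total - plan.tail_len + m.offset + len(ms),
                "unit": m.unit,
                "copies": m.copies,
            }
        )
    for pr in plan.poly_runs:
        tail[pr.offset : pr.offset + pr.length] = [pr.base] * pr.length
        tail[pr.offset - 1] = guard_against(pr.base)
        tail[pr.offset + pr.length] = guard_against(pr.base)
        planted_spans.append((pr.offset, pr.offset + pr.length))
        elements.append(
            {
                "kind": "poly_run",
                "local_start": plan.total - plan.tail_len + pr.offset + 1,
                "local_end": plan.total - plan.tail_len + pr.offset + pr.length,
                "base": pr.base,
                "run_length": pr.length,
            }
        )
    for a, b in planted_spans:
        for c, d in planted_spans:
            if (a, b) != (c, d) and a < d + 1 and c < b + 1:
                raise MitoError("planted tail elements overlap")
    arr.extend(tail)
    if len(arr) != plan.total:
        raise MitoError("CR plan lengths do not tile the control region")
    elements.sort(key=lambda e: e["local_start"])
    return "".join(arr), elements


def _has_short_period(unit: list[str]) -> bool:
    # same criterion the tandem-repeat scanner uses to cede an array to the
    # microsatellite scanner; planted units must stay clear of it
    return _near_periodic("".join(unit))


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


class _Canvas:
    def __init__(self, length: int):
        self.arr: list[str | None] = [None] * length
        self.length = length

    def fill(self, pos: int, base: str, what: str) -> None:
        cur = self.arr[pos - 1]
        if cur is not None and cur != base:
            raise MitoError(f"conflicting constraints at position {pos} ({what}: {base} vs {cur})")
        self.arr[pos - 1] = base

    def get(self, pos: int) -> str | None:
        return self.arr[pos - 1]


def _coding_to_genome(f: Feature, i: int) -> int:
    return f.start + i if f.strand == "J" else f.end - i


def _forced_map(canvas: _Canvas, f: Feature, L: int) -> dict[int, str]:
    forced = {}
    for i in range(L):
        g = canvas.get(_coding_to_genome(f, i))
        if g is not None:
            forced[i] = g if f.strand == "J" else _COMP[g]
    return forced


def _write_coding(canvas: _Canvas, f: Feature, seq: str) -> None:
    for i, b in enumerate(seq):
        g = _coding_to_genome(f, i)
        canvas.fill(g, b if f.strand == "J" else _COMP[b], f.name)


def _build_pcg(
    f: Feature,
    L: int,
    start_codon: str,
    stop_codon: str,
    forced: dict[int, str],
    rng,
    codons: list[str],
    weights: np.ndarray,
) -> str:
    tail = {"TAA": "TAA", "TAG": "TAG", "T-": "T", "TA-": "TA"}[stop_codon]
    if (L - len(tail)) % 3 != 0:
        raise MitoError(f"{f.name}: length {L} incompatible with stop {stop_codon}")
    arr: list[str | None] = [None] * L
    for i, b in forced.items():
        arr[i] = b
    for i, b in enumerate(start_codon):
        if arr[i] is not None and arr[i] != b:
            raise MitoError(f"{f.name}: start codon conflicts with overlap constraint")
        arr[i] = b
    for off, b in enumerate(tail):
        i = L - len(tail) + off
        if arr[i] is not None and arr[i] != b:
            raise MitoError(f"{f.name}: stop codon conflicts with overlap constraint")
        arr[i] = b
    n_codons = (L - len(tail)) // 3
    for ci in range(1, n_codons):
        idx = [3 * ci, 3 * ci + 1, 3 * ci + 2]
        free = [i for i in idx if arr[i] is None]
        for _ in range(50):
            draw = codons[int(rng.choice(len(codons), p=weights))]
            trial = [arr[i] if arr[i] is not None else draw[j] for j, i in enumerate(idx)]
            if "".join(trial) not in ("TAA", "TAG"):
                break
        for j, i in enumerate(idx):
            if arr[i] is None:
                arr[i] = trial[j]
        if not free and "".join(trial) in ("TAA", "TAG"):
            pass  # fully constrained by overlaps; accept as-is
    return "".join(arr)


def generate_mitogenome(config: GenomeConfig | None = None):
    """Generate (Genome, FeatureTable, truth) for the configured layout.

    Deterministic for a fixed seed. The truth dictionary records every
    planted feature: coordinates, start/stop codons, overlap motifs, CR
    elements (local and genome coordinates), tRNA structures with planted
    pair kinds, realized per-class compositions, and realized codon counts.
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng(config.seed)
    layout = mio.load_reference_features()
    printed = mio.load_reference_printed()
    dists = _class_dists()
    L = layout.genome_length

    cr_feats = layout.by_class("CR")
    if len(cr_feats) != 1:
        raise MitoError("layout must contain exactly one control region")
    cr = cr_feats[0]
    if config.cr_plan.total != cr.size(L):
        raise MitoError(
            f"CR plan tiles {config.cr_plan.total} bp but the CR spans {cr.size(L)} bp"
        )
    for up_name, down_name in config.motif_junctions:
        up, down = layout[up_name], layout[down_name]
        if up.end - down.start + 1 != 7:
            raise MitoError(f"{up_name}/{down_name}: motif junction must overlap 7 nt")

    canvas = _Canvas(L)
    # constraint pre-pass: every PCG start codon and stop tail
    for f in layout.by_class("PCG"):
        size = f.size(L)
        start_codon = printed[f.name]["start_codon"]
        stop = printed[f.name]["stop_codon"]
        tail = {"TAA": "TAA", "TAG": "TAG", "T-": "T", "TA-": "TA"}[stop]
        for i, b in enumerate(start_codon):
            g = _coding_to_genome(f, i)
            canvas.fill(g, b if f.strand == "J" else _COMP[b], f.name)
        for off, b in enumerate(tail):
            i = size - len(tail) + off
            g = _coding_to_genome(f, i)
            canvas.fill(g, b if f.strand == "J" else _COMP[b], f.name)

    codon_counts = mio.load_reference_codon_counts()
    codons = [c for c, n in codon_counts.items() if n > 0 and c not in ("TAA", "TAG")]
    weights = np.array([codon_counts[c] for c in codons], dtype=float)
    weights /= weights.sum()

    truth: dict = {
        "seed": config.seed,
        "genome_length": L,
        "features": [],
        "trna_structures": {},
        "trna_planted_pairs": dict(config.trna_pairs),
        "cr_elements": [],
        "motif_junctions": [],
    }
    features: list[Feature] = []
    for f in layout:
        size = f.size(L)
        new = replace(f)
        if f.cls == "PCG":
            forced = _forced_map(canvas, f, size)
            seq = _build_pcg(
                f, size, printed[f.name]["start_codon"], printed[f.name]["stop_codon"],
                forced, rng, codons, weights,
            )
            _write_coding(canvas, f, seq)
        elif f.cls == "tRNA":
            forced = _forced_map(canvas, f, size)
            seq, structure = _build_trna(
                f.name, size, f.anticodon, forced,
                config.trna_pairs.get(f.name, []), rng, dists["tRNA"],
            )
            _write_coding(canvas, f, seq)
            truth["trna_structures"][f.name] = structure
            a0 = structure.anticodon_span[0]
            ga = _coding_to_genome(f, a0)
            gb = _coding_to_genome(f, a0 + 2)
            new = replace(f, anticodon_pos=f"{min(ga, gb)}-{max(ga, gb)}")
        elif f.cls == "rRNA":
            forced = _forced_map(canvas, f, size)
            seq = _filler(rng, dists[f.name if f.name in dists else "whole"], size)
            for i, b in forced.items():
                seq[i] = b
            _write_coding(canvas, f, "".join(seq))
        else:  # CR
            cr_seq, cr_elements = _build_cr(config.cr_plan, rng, dists["CR"])
            _write_coding(canvas, f, cr_seq)
            for e in cr_elements:
                e = dict(e)
                e["start"] = f.start + e["local_start"] - 1
                e["end"] = f.start + e["local_end"] - 1
                truth["cr_elements"].append(e)
        features.append(new)
        truth["features"].append(
            {
                "name": f.name,
                "class": f.cls,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "size": size,
                "start_codon": printed[f.name]["start_codon"],
                "stop_codon": printed[f.name]["stop_codon"],
            }
        )

    # intergenic filler
    gaps = [i + 1 for i in range(L) if canvas.arr[i] is None]
    fill = _filler(rng, dists["whole"], len(gaps))
    for pos, b in zip(gaps, fill):
        canvas.fill(pos, b, "intergenic")
    sequence = "".join(canvas.arr)
    genome = Genome(f"synthetic-mitogenome-seed{config.seed}", sequence, circular=True)
    table = FeatureTable(genome.id, features, L, circular=True)

    # verify + record motif junctions on the realized sequence
    for up_name, down_name in config.motif_junctions:
        up, down = layout[up_name], layout[down_name]
        span = genome.slice(down.start, up.end)
        if up.strand == "N":
            span = revcomp(span)
        ok = span[:3] == "ATG" and span[4:] == "TAA"
        truth["motif_junctions"].append(
            {"upstream": up_name, "downstream": down_name, "motif": span, "matches_ATGNTAA": ok}
        )
        if not ok:
            raise MitoError(f"{up_name}/{down_name}: motif {span} != ATGNTAA")

    # realized per-class composition and codon counts (simple direct counting)
    truth["composition"] = _realized_composition(genome, table)
    truth["codon_counts"] = _realized_codon_counts(genome, table)
    truth["codon_total"] = sum(truth["codon_counts"].values())
    return genome, table, truth


def _realized_composition(genome: Genome, table: FeatureTable) -> dict[str, dict[str, float]]:
    def pct(seq: str) -> dict[str, float]:
        n = sum(seq.count(b) for b in "ACGT")
        return {b: 100.0 * seq.count(b) / n for b in "ACGT"}

    def concat(feats) -> str:
        return "".join(f.coding_sequence(genome) for f in feats)

    out = {"whole": pct(genome.sequence)}
    for cls, label in (("PCG", "PCGs"), ("tRNA", "tRNAs"), ("rRNA", "rRNAs"), ("CR", "CR")):
        out[label] = pct(concat(table.by_class(cls)))
    return out


def _realized_codon_counts(genome: Genome, table: FeatureTable) -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in table.by_class("PCG"):
        cds = f.coding_sequence(genome)
        triplets = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        if triplets and triplets[-1] in ("TAA", "TAG"):
            triplets.pop()
        for c in triplets:
            counts[c] = counts.get(c, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# tree-evolved alignments
# ---------------------------------------------------------------------------

#: published sizes of the 13 PCGs, used as default per-gene alignment lengths
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 1035, "COI": 1545, "COII": 688, "ATP8": 159, "ATP6": 678,
    "COIII": 789, "ND3": 354, "ND5": 1735, "ND4": 1341, "ND4L": 297,
    "ND6": 525, "CytB": 1137, "ND1": 951,
}

#: 14-taxon Amphinemurinae-shaped truth topology with moderate branch lengths
DEFAULT_TREE_NEWICK = (
    "((Amphinemura_longispina:0.10,Amphinemura_yao:0.12):0.08,"
    "(Malenka_flexura:0.16,((Protonemura_datongensis:0.09,"
    "(Protonemura_kohnoae:0.07,Protonemura_orbiculata:0.08):0.04):0.07,"
    "((Indonemoura_auriformis:0.10,(Indonemoura_jacobsoni:0.08,"
    "Indonemoura_nohirae:0.07):0.05):0.06,((Sphaeronemoura_acutispina:0.09,"
    "(Sphaeronemoura_elephas:0.08,Sphaeronemoura_grandicauda:0.07):0.04):0.05,"
    "(Mesonemoura_metafiligera:0.08,Mesonemoura_tritaenia:0.09):0.06):0.04):0.03):0.05):0.06);"
)


def default_truth_model() -> PhyloModel:
    """A mitochondrial-PCG-flavored GTR+I+G truth: AT-rich frequencies,
    transition-heavy exchangeabilities, strong rate heterogeneity."""
    return PhyloModel(
        freqs=np.array([0.273, 0.171, 0.163, 0.393]),
        exch=np.array([1.5, 10.0, 2.0, 1.2, 12.0, 1.0]),
        p_inv=0.2,
        alpha=0.5,
        k=4,
    )


@dataclass
class SimConfig:
    tree_newick: str = DEFAULT_TREE_NEWICK
    model: PhyloModel = field(default_factory=default_truth_model)
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    seed: int = 0


def evolve_alignment(config: SimConfig | None = None):
    """Evolve the 13 per-gene alignments along the truth tree; returns
    ({gene: Alignment}, truth) where truth carries the tree, the model and
    the partition boundaries of the concatenated supermatrix."""
    config = config or SimConfig()
    if any(n <= 0 for n in config.gene_lengths.values()):
        raise MitoError("gene lengths must be positive")
    tree = from_newick(config.tree_newick)
    rng = np.random.default_rng(config.seed)
    alignments = {}
    partitions = {}
    offset = 0
    for gene, n in config.gene_lengths.items():
        alignments[gene] = simulate(tree, config.model, n, rng)
        partitions[gene] = (offset, offset + n)
        offset += n
    truth = {
        "tree_newick": config.tree_newick,
        "splits": from_newick(config.tree_newick).splits(),
        "model": config.model,
        "partitions": partitions,
        "seed": config.seed,
    }
    return alignments, truth
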