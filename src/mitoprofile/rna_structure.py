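"""tRNA cloverleaf pairing statistics.

A :class:`CloverleafStructure` lists the paired positions of the four arms
(acceptor, DHU, anticodon, TΨC) on the tRNA gene sequence (DNA alphabet; U
is mapped to T at I/O). :func:`pair_stats` classifies every pair as
Watson–Crick, weak G-U, or a typed mismatch — the accounting behind
"unmatched base pair" tallies. :func:`fold_cloverleaf` is a constraint-based
heuristic folder for template-like metazoan mitochondrial tRNAs; structures
from external annotation tools can be supplied instead.

Folding constraints (version 1): acceptor stem 7 pairs with a single 3'
discriminator base; anticodon stem 5 pairs around a 7-nt loop centered on
the anticodon; TΨC stem 4–5 pairs (loop 3–9) abutting the acceptor 3' arm;
DHU stem 3–4 pairs (loop 3–11) between acceptor and anticodon arms. An arm
candidate is accepted when at most one of its positions fails to pair
(WC or G-T), with a floor of 3 true pairs; if no DHU candidate passes, the
DHU arm is declared absent — the tRNA-Ser(AGN) situation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MitoError

ARMS = ("acceptor", "dhu", "anticodon", "tpsic")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}
# canonical mismatch naming order (RNA letters), matching the field's usage
_ORDER = {"A": 0, "U": 1, "G": 2, "C": 3}


@dataclass
class CloverleafStructure:
    name: str
    arms: dict[str, list[tuple[int, int]]]  # arm -> [(i, j)] 0-based, i < j
    dhu_present: bool = True
    anticodon_span: tuple[int, int] | None = None  # 0-based inclusive

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for arm, pairs in self.arms.items():
            if arm not in ARMS:
                raise MitoError(f"{self.name}: unknown arm {arm!r}")
            for i, j in pairs:
                if i >= j:
                    raise MitoError(f"{self.name}: pair ({i},{j}) not i<j")
                if i in seen or j in seen:
                    raise MitoError(f"{self.name}: position paired twice")
                seen.update((i, j))
        if len(self.arms.get("acceptor", [])) > 7:
            raise MitoError(f"{self.name}: acceptor stem exceeds 7 pairs")

    def all_pairs(self) -> list[tuple[str, int, int]]:
        return [(arm, i, j) for arm in ARMS for i, j in self.arms.get(arm, [])]


@dataclass
class PairStats:
    per_arm: dict[str, dict] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return sum(a["wc"] + a["gu"] + sum(a["mismatch"].values()) for a in self.per_arm.values())

    @property
    def total_wc(self) -> int:
        return sum(a["wc"] for a in self.per_arm.values())

    @property
    def total_gu(self) -> int:
        return sum(a["gu"] for a in self.per_arm.values())

    @property
    def total_mismatch(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.per_arm.values():
            for t, n in a["mismatch"].items():
                out[t] = out.get(t, 0) + n
        return out

    @property
    def total_nonwc(self) -> int:
        """The "unmatched" tally: G-U wobbles plus true mismatches."""
        return self.total_gu + sum(self.total_mismatch.values())

    def add(self, other: "PairStats") -> "PairStats":
        merged = PairStats({k: {**v, "mismatch": dict(v["mismatch"])} for k, v in self.per_arm.items()})
        for arm, a in other.per_arm.items():
            tgt = merged.per_arm.setdefault(arm, {"wc": 0, "gu": 0, "mismatch": {}})
            tgt["wc"] += a["wc"]
            tgt["gu"] += a["gu"]
            for t, n in a["mismatch"].items():
                tgt["mismatch"][t] = tgt["mismatch"].get(t, 0) + n
        return merged


def classify_pair(a: str, b: str) -> str:
    """'WC', 'GU', or the canonical mismatch type (e.g. 'U-C', 'A-G')."""
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    ra, rb = a.replace("T", "U"), b.replace("T", "U")
    x, y = sorted((ra, rb), key=_ORDER.get)
    return f"{x}-{y}"


def pair_stats(seq: str, structure: CloverleafStructure) -> PairStats:
    """Classify every structural pair of one tRNA."""
    seq = seq.upper().replace("U", "T")
    stats = PairStats()
    for arm, i, j in structure.all_pairs():
        if not (0 <= i < len(seq) and 0 <= j < len(seq)):
            raise MitoError(f"{structure.name}: pair index ({i},{j}) out of bounds")
        a = stats.per_arm.setdefault(arm, {"wc": 0, "gu": 0, "mismatch": {}})
        kind = classify_pair(seq[i], seq[j])
        if kind == "WC":
            a["wc"] += 1
        elif kind == "GU":
            a["gu"] += 1
        else:
            a["mismatch"][kind] = a["mismatch"].get(kind, 0) + 1
    return stats


class FoldFailure(MitoError):
    """No structure satisfying the acceptor + anticodon constraints."""


def _ok(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _GU


def _arm_score(seq: str, pairs: list[tuple[int, int]]) -> int:
    return sum(_ok(seq[i], seq[j]) for i, j in pairs)


def _accept(score: int, size: int) -> bool:
    return score >= max(3, size - 1)


def _scan_stem(seq, lo, hi, sizes, loops, anchor_right=False):
    """Best stem candidate inside seq[lo:hi]: pairs ((s+k, e-k)) around a
    loop. Returns (pairs, score) or None. Preference: higher score, larger
    stem, then right-most (anchor_right) / left-most placement."""
    best = None
    for m in sizes:
        for loop in loops:
            span = 2 * m + loop
            for s in range(lo, hi - span + 1):
                e = s + span - 1
                pairs = [(s + k, e - k) for k in range(m)]
                score = _arm_score(seq, pairs)
                if not _accept(score, m):
                    continue
                pos_pref = s if anchor_right else -s
                key = (score, m, pos_pref)
                if best is None or key > best[0]:
                    best = (key, pairs, score)
    if best is None:
        return None
    return best[1], best[2]


def fold_cloverleaf(seq: str, anticodon: str, name: str = "tRNA") -> CloverleafStructure:
    """Heuristic cloverleaf fold of a mitochondrial tRNA gene sequence."""
    seq = seq.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    L = len(seq)
    if not 55 <= L <= 80:
        raise MitoError(f"{name}: length {L} outside the 55-80 nt tRNA range")
    acc_pairs = [(k, L - 2 - k) for k in range(7)]
    if not _accept(_arm_score(seq, acc_pairs), 7):
        raise FoldFailure(f"{name}: no acceptor stem")
    best_ac = None
    p = seq.find(anticodon)
    while p != -1:
        if p - 8 >= 8 and p + 10 <= L - 8:
            ac_pairs = [(p - 3 - k, p + 5 + k) for k in range(5)]
            score = _arm_score(seq, ac_pairs)
            if _accept(score, 5) and (best_ac is None or score > best_ac[1]):
                best_ac = (p, score, ac_pairs)
        p = seq.find(anticodon, p + 1)
    if best_ac is None:
        raise FoldFailure(f"{name}: no anticodon stem around {anticodon}")
    p, _, ac_pairs = best_ac
    arms = {"acceptor": acc_pairs, "anticodon": sorted(ac_pairs)}
    t = _scan_stem(seq, p + 10, L - 8, sizes=(5, 4), loops=range(3, 10), anchor_right=True)
    if t is not None:
        arms["tpsic"] = t[0]
    # DHU window ends before the anticodon 5' arm (those bases are taken)
    d = _scan_stem(seq, 8, p - 7, sizes=(4, 3), loops=range(3, 12))
    dhu_present = d is not None
    if dhu_present:
        arms["dhu"] = d[0]
    return CloverleafStructure(
        name=name, arms=arms, dhu_present=dhu_present, anticodon_span=(p, p + 2)
    )


# -- dot-bracket + arm-span sidecar I/O -------------------------------------


def to_dot_bracket(length: int, structure: CloverleafStructure) -> str:
    db = ["."] * length
    for _, i, j in structure.all_pairs():
        db[i], db[j] = "(", ")"
    return "".join(db)


def write_structures(path, items: list[tuple[str, CloverleafStructure]]) -> None:
    """TSV: name, dot-bracket, dhu_present, then one 'arm i-j,i-j' column per arm."""
    with open(path, "w") as fh:
        fh.write("name\tdot_bracket\tdhu_present\tarm_pairs\n")
        for seq, s in items:
            spans = ";".join(
                f"{arm}:" + ",".join(f"{i}-{j}" for i, j in s.arms.get(arm, []))
                for arm in ARMS
                if s.arms.get(arm)
            )
            fh.write(f"{s.name}\t{to_dot_bracket(len(seq), s)}\t{int(s.dhu_present)}\t{spans}\n")


def read_structures(path) -> list[CloverleafStructure]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            name, _db, dhu, spans = line.rstrip("\n").split("\t")
            arms: dict[str, list[tuple[int, int]]] = {}
            for part in filter(None, spans.split(";")):
                arm, pairs = part.split(":")
                arms[arm] = [tuple(map(int, p.split("-"))) for p in filter(None, pairs.split(","))]
            out.append(CloverleafStructure(name=name, arms=arms, dhu_present=bool(int(dhu))))
    return out
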