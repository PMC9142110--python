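"""Readers/writers for the standard formats the pipeline touches.

TSV feature tables (columns: gene, class, strand, start, end, anticodon,
anticodon_pos) and FASTA round-trip bit-faithfully. GenBank flat files are
read through Biopython and mapped once, at this boundary, to the internal
1-based-inclusive J/N convention; ``join()`` across the origin becomes a
single wrap-around feature.
"""

from __future__ import annotations

import warnings
from importlib import resources

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .align import Alignment
from .model import Feature, FeatureTable, Genome, MitoError
from .tree import read_newick, write_newick  # noqa: F401  (re-exported)

FT_COLUMNS = ["gene", "class", "strand", "start", "end", "anticodon", "anticodon_pos"]


def _parse_coord(token: str, row: int, col: str) -> int:
    token = token.replace(",", "").strip()
    if not token.isdigit() or int(token) <= 0:
        raise MitoError(f"row {row}: malformed {col} coordinate {token!r}")
    return int(token)


def read_feature_table(path, genome_length: int | None = None, circular: bool = True) -> FeatureTable:
    """Read a TSV feature table.

    Thousands separators in coordinates are tolerated (tables transcribed from
    publications often keep them). If ``genome_length`` is omitted it defaults
    to the largest end coordinate seen.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MitoError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    if header[:5] != FT_COLUMNS[:5]:
        raise MitoError(f"{path}: unexpected header {header[:5]} (want {FT_COLUMNS[:5]})")
    feats = []
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        cells += [""] * (len(FT_COLUMNS) - len(cells))
        gene, cls, strand, start, end, anticodon, acpos = cells[: len(FT_COLUMNS)]
        f = Feature(
            name=gene,
            cls=cls,
            strand=strand or "J",
            start=_parse_coord(start, i, "start"),
            end=_parse_coord(end, i, "end"),
            anticodon=anticodon.replace(",", "") or None,
            anticodon_pos=acpos.replace(",", "") or None,
        )
        if f.anticodon_flag:
            warnings.warn(
                f"{gene}: suspicious anticodon position {acpos!r} ({f.anticodon_flag})",
                stacklevel=2,
            )
        feats.append(f)
    glen = genome_length if genome_length is not None else max(f.end for f in feats)
    for f in feats:
        if f.wraps and not circular:
            raise MitoError(f"{f.name}: wrap-around row in a non-circular table")
    return FeatureTable("", feats, glen, circular=circular)


def write_feature_table(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FT_COLUMNS) + "\n")
        for f in table:
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.cls,
                        f.strand,
                        str(f.start),
                        str(f.end),
                        f.anticodon or "",
                        f.anticodon_pos or "",
                    ]
                ).rstrip("\t")
                + "\n"
            )


# -- GenBank ----------------------------------------------------------------

_GB_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def _gb_name(feat) -> str:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return feat.type


def read_genbank(path) -> tuple[Genome, FeatureTable]:
    """Read one GenBank record into (Genome, FeatureTable)."""
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises plain ValueError on bad grammar
        raise MitoError(f"{path}: cannot parse GenBank record ({exc})") from None
    try:
        seq = str(record.seq)
    except Exception:  # Bio.Seq.UndefinedSequenceError and friends
        raise MitoError(f"{path}: record has no ORIGIN sequence") from None
    if not seq or set(seq) == {"N"}:
        raise MitoError(f"{path}: record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    genome = Genome(record.id or record.name, seq, circular=circular)
    feats = []
    for gb in record.features:
        cls = _GB_CLASS.get(gb.type)
        if cls is None and gb.type == "misc_feature":
            note = " ".join(gb.qualifiers.get("note", [])).lower()
            if "control region" in note:
                cls = "CR"
        if cls is None:
            continue
        loc = gb.location
        strand = "N" if loc.strand == -1 else "J"
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            tail, head = parts[-1], parts[0]
            if int(tail.end) == genome.length and int(head.start) == 0:
                start, end = int(tail.start) + 1, int(head.end)  # wraps the origin
            else:
                raise MitoError(
                    f"{path}: location {loc} not understood (non-origin join)"
                )
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        name = _gb_name(gb)
        if any(f.name == name for f in feats):
            name = f"{name}.{sum(f.name.startswith(name) for f in feats) + 1}"
        feats.append(Feature(name=name, cls=cls, start=start, end=end, strand=strand))
    return genome, FeatureTable(genome.id, feats, genome.length, circular=circular)


# -- FASTA ------------------------------------------------------------------


def read_fasta(path, circular: bool = True) -> Genome:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise MitoError(f"{path}: no FASTA records")
    r = records[0]
    return Genome(r.id, str(r.seq), circular=circular)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise MitoError(f"{path}: no FASTA records")
    return Alignment({r.id: str(r.seq) for r in records})


def write_alignment(aln: Alignment, path) -> None:
    write_fasta(aln.sequences, path)


# -- packaged reference data ------------------------------------------------


def _data_path(name: str):
    return resources.files("mitoprofile.data").joinpath(name)


def load_reference_features() -> FeatureTable:
    """The published *Malenka flexura* mitogenome annotation (GenBank
    ON411527), transcribed to the internal TSV layout."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known printed anticodon typos
        return read_feature_table(_data_path("mflexura_features.tsv"), genome_length=15744)


def load_reference_printed() -> dict[str, dict]:
    """Printed size/IGN/start/stop columns of the published annotation,
    kept separate from coordinates so they can serve as independent checks."""
    out: dict[str, dict] = {}
    with open(_data_path("mflexura_printed_columns.tsv")) as fh:
        next(fh)
        for line in fh:
            cells = (line.rstrip("\n") + "\t\t\t").split("\t")
            gene, size, ign = cells[0], int(cells[1]), int(cells[2])
            out[gene] = {
                "size": size,
                "ign": ign,
                "start_codon": cells[3] or None,
                "stop_codon": cells[4] or None,
            }
    return out


def load_reference_composition() -> list[dict]:
    rows = []
    with open(_data_path("mflexura_composition.tsv")) as fh:
        header = next(fh).split()
        for line in fh:
            cells = line.split()
            row = {"label": cells[0]}
            row.update({k: float(v) for k, v in zip(header[1:], cells[1:])})
            rows.append(row)
    return rows


def load_reference_codon_counts() -> dict[str, int]:
    counts = {}
    with open(_data_path("mflexura_codon_counts.tsv")) as fh:
        next(fh)
        for line in fh:
            codon, _aa, n = line.split()
            counts[codon] = int(n)
    return counts
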