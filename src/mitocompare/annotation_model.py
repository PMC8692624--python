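"""Data model and I/O for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome annotation tables.  A feature that wraps the origin of
the circle is represented with ``end < start`` together with the genome's
``circular`` flag; all arithmetic on such features is done modulo the genome
length.  Conversion to 0-based half-open coordinates happens only at file
format boundaries (BED export).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitocompare")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations or unreadable files."""


@dataclass
class GeneFeature:
    """One annotated gene (or the control region) on a mitogenome.

    ``start``/``end`` are 1-based inclusive.  ``strand`` is 'H' (heavy) or
    'L' (light); light-strand features are read as the reverse complement of
    the heavy-strand coordinates.  ``start_codon``/``stop_codon`` carry the
    annotated codons for protein-coding genes when known ("T-"/"TA-" mark
    incomplete stops completed by polyadenylation).
    """

    name: str
    ftype: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise AnnotationError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.strand not in ("H", "L"):
            raise AnnotationError(f"{self.name}: strand must be 'H' or 'L'")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates are 1-based, got "
                                  f"{self.start}..{self.end}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: Optional[int] = None) -> int:
        """Feature length in nucleotides, recomputed from coordinates."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise AnnotationError(
                f"{self.name}: wrapping feature needs the genome length")
        return (genome_length - self.start + 1) + self.end

    def positions(self, genome_length: int) -> list[int]:
        """All 1-based positions covered, walking 5'->3' on the H strand."""
        if not self.wraps:
            return list(range(self.start, self.end + 1))
        return list(range(self.start, genome_length + 1)) + list(range(1, self.end + 1))


@dataclass
class MitoGenome:
    """A circular mitochondrial genome: sequence plus ordered feature table."""

    accession: str
    length: int
    circular: bool = True
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"{self.accession}: length {self.length} != sequence "
                f"length {len(self.sequence)}")
        for f in self.features:
            if f.end > self.length or f.start > self.length:
                raise AnnotationError(
                    f"{self.accession}/{f.name}: feature {f.start}..{f.end} "
                    f"exceeds genome length {self.length}")
            if f.wraps and not self.circular:
                raise AnnotationError(
                    f"{self.accession}/{f.name}: wrapping feature on a "
                    f"non-circular genome")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]


@dataclass
class LayoutReport:
    """Adjacency arithmetic over an ordered feature table.

    ``gaps`` holds one signed entry per adjacent pair (negative = overlap),
    computed as ``next.start - prev.end - 1``; for circular genomes the
    last-vs-first pair closes the circle.
    """

    gaps: list[tuple[str, str, int]]
    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    total_overlap_bp: int
    total_spacer_bp: int
    max_overlap: Optional[tuple[str, str, int]]
    counts_by_type: dict[str, int]
    length_range_by_type: dict[str, tuple[int, int]]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CANONICAL_NAMES = {
    "D-loop": "CR", "D_loop": "CR", "control region": "CR",
    # common GenBank gene/product spellings -> the names used throughout
    "COX1": "COI", "COX2": "COII", "COX3": "COIII", "CO1": "COI",
    "CO2": "COII", "CO3": "COIII", "COXI": "COI", "COXII": "COII",
    "COXIII": "COIII", "CYTB": "Cytb", "cytb": "Cytb", "COB": "Cytb",
    "ATPase8": "ATP8", "ATPase6": "ATP6", "ATPase 8": "ATP8",
    "ATPase 6": "ATP6", "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3",
    "NAD4": "ND4", "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "12S ribosomal RNA": "12S rRNA", "16S ribosomal RNA": "16S rRNA",
    "s-rRNA": "12S rRNA", "l-rRNA": "16S rRNA", "rrnS": "12S rRNA",
    "rrnL": "16S rRNA", "small subunit ribosomal RNA": "12S rRNA",
    "large subunit ribosomal RNA": "16S rRNA",
    "tRNA-Leu(UUR)": "tRNA-Leu2", "tRNA-Leu(CUN)": "tRNA-Leu1",
    "tRNA-Ser(UCN)": "tRNA-Ser2", "tRNA-Ser(AGY)": "tRNA-Ser1",
}


def canonical_gene_name(name: str) -> str:
    return _CANONICAL_NAMES.get(name, name)

_GB_TYPE_MAP = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}
_GB_TYPE_INV = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def _gb_feature_name(feat: SeqFeature) -> Optional[str]:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "CR"
    return None


def read_genbank(path) -> MitoGenome:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features become :class:`GeneFeature` rows with
    canonical names (D-loop -> CR); complement-strand features get strand 'L'.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc
    circular = record.annotations.get("topology", "linear") == "circular"
    length = len(record.seq)
    feats: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GB_TYPE_MAP:
            continue
        name = _gb_feature_name(feat)
        if name is None:
            continue
        name = canonical_gene_name(name)
        loc = feat.location
        parts = getattr(loc, "parts", [loc])
        if len(parts) > 1:
            # origin-spanning feature: tail of the circle then head
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        if end > length or start > length:
            raise AnnotationError(
                f"{path}: feature {name} at {start}..{end} exceeds sequence "
                f"length {length}")
        strand = "L" if loc.strand == -1 else "H"
        anticodon = None
        if "anticodon" in feat.qualifiers:
            anticodon = str(feat.qualifiers["anticodon"][0]).upper()
        feats.append(GeneFeature(name=name, ftype=_GB_TYPE_MAP[feat.type],
                                 strand=strand, start=start, end=end,
                                 anticodon=anticodon))
    return MitoGenome(accession=record.id, length=length, circular=circular,
                      sequence=str(record.seq).upper(), features=feats)


def write_genbank(genome: MitoGenome, path) -> None:
    """Minimal GenBank writer (fixture/round-trip quality, not submission)."""
    if genome.sequence is None:
        raise AnnotationError("cannot write GenBank without a sequence")
    record = SeqRecord(Seq(genome.sequence), id=genome.accession,
                       name=genome.accession[:16].replace(".", "_"),
                       description="mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in genome.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, genome.length, strand),
                SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_GB_TYPE_INV[f.ftype],
                                          qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


TABLE_COLUMNS = ["name", "ftype", "strand", "start", "end", "anticodon",
                 "start_codon", "stop_codon"]


def read_annotation_table(path, genome_length: Optional[int] = None,
                          circular: bool = True,
                          accession: str = "annotation") -> MitoGenome:
    """Read a tab-separated annotation table (no sequence).

    Expected columns: name, ftype, strand, start, end and optionally
    anticodon, start_codon, stop_codon ('.' = missing).  The genome length
    defaults to the maximum feature end.
    """
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = row["name"].strip()
            if name in seen:
                raise AnnotationError(f"duplicate feature name {name!r}")
            seen.add(name)

            def opt(key):
                v = (row.get(key) or ".").strip()
                return None if v in (".", "", "-") else v

            start, end = int(row["start"]), int(row["end"])
            if end < start and not circular:
                raise AnnotationError(
                    f"{name}: end {end} < start {start} on a linear genome")
            feats.append(GeneFeature(
                name=name, ftype=row["ftype"].strip(), strand=row["strand"].strip(),
                start=start, end=end, anticodon=opt("anticodon"),
                start_codon=opt("start_codon"), stop_codon=opt("stop_codon")))
    if not feats:
        raise AnnotationError(f"no features in {path}")
    length = genome_length or max(f.end for f in feats)
    return MitoGenome(accession=accession, length=length, circular=circular,
                      features=feats)


def write_annotation_table(genome: MitoGenome, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for f in genome.features:
            writer.writerow([f.name, f.ftype, f.strand, f.start, f.end,
                             f.anticodon or ".", f.start_codon or ".",
                             f.stop_codon or "."])


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(genome: MitoGenome, path) -> None:
    """BED export (0-based half-open); wrapping features emit two blocks."""
    with open(path, "w") as fh:
        for f in genome.features:
            strand = "-" if f.strand == "L" else "+"
            if f.wraps:
                fh.write(f"{genome.accession}\t{f.start - 1}\t{genome.length}"
                         f"\t{f.name}\t0\t{strand}\n")
                fh.write(f"{genome.accession}\t0\t{f.end}\t{f.name}\t0\t{strand}\n")
            else:
                fh.write(f"{genome.accession}\t{f.start - 1}\t{f.end}"
                         f"\t{f.name}\t0\t{strand}\n")


def load_reference_annotation() -> MitoGenome:
    """The packaged Baer's pochard (A. baeri, 16,623 bp) annotation table."""
    path = resources.files("mitocompare.data") / "aythya_baeri_annotation.tsv"
    with resources.as_file(path) as p:
        return read_annotation_table(p, accession="MT129533")


# ---------------------------------------------------------------------------
# sequence extraction and layout arithmetic
# ---------------------------------------------------------------------------

def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand-oriented sequence of a feature.

    H-strand features are the plain substring; L-strand features are the
    reverse complement.  Wrapping features concatenate the tail and head of
    the circle before orientation is applied.
    """
    if genome.sequence is None:
        raise AnnotationError(f"{genome.accession}: no sequence loaded")
    if feature.wraps:
        raw = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        raw = genome.sequence[feature.start - 1:feature.end]
    return reverse_complement(raw) if feature.strand == "L" else raw


def splice_feature_sequence(genome_seq: str, feature: GeneFeature,
                            new_seq: str) -> str:
    """Write a coding-strand-oriented sequence back into the H-strand genome."""
    raw = reverse_complement(new_seq) if feature.strand == "L" else new_seq
    if feature.wraps:
        # raw runs start..L then 1..end on the H strand
        tail = len(genome_seq) - (feature.start - 1)
        return (raw[tail:] + genome_seq[feature.end:feature.start - 1] +
                raw[:tail])
    return genome_seq[:feature.start - 1] + raw + genome_seq[feature.end:]


def layout_report(genome: MitoGenome) -> LayoutReport:
    """Overlap/spacer arithmetic over adjacent features in table order.

    The signed gap after feature *i* is ``next.start - prev.end - 1``; for a
    circular genome the pair (last, first) is included with the first
    feature's start lifted by one genome length.
    """
    feats = genome.features
    if not feats:
        raise AnnotationError("layout_report needs at least one feature")
    gaps: list[tuple[str, str, int]] = []
    if len(feats) > 1:
        for prev, nxt in zip(feats, feats[1:]):
            gaps.append((prev.name, nxt.name, nxt.start - prev.end - 1))
        if genome.circular:
            last, first = feats[-1], feats[0]
            gaps.append((last.name, first.name,
                         first.start + genome.length - last.end - 1))
    overlaps = [(a, b, -g) for a, b, g in gaps if g < 0]
    spacers = [(a, b, g) for a, b, g in gaps if g > 0]
    counts: dict[str, int] = {}
    ranges: dict[str, tuple[int, int]] = {}
    for f in feats:
        counts[f.ftype] = counts.get(f.ftype, 0) + 1
        n = f.length(genome.length)
        lo, hi = ranges.get(f.ftype, (n, n))
        ranges[f.ftype] = (min(lo, n), max(hi, n))
    return LayoutReport(
        gaps=gaps, overlaps=overlaps, spacers=spacers,
        total_overlap_bp=sum(o for _, _, o in overlaps),
        total_spacer_bp=sum(s for _, _, s in spacers),
        max_overlap=max(overlaps, key=lambda t: t[2]) if overlaps else None,
        counts_by_type=counts, length_range_by_type=ranges)
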