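"""Annotated phage genome I/O and coordinate-safe views.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention is converted at the parsing boundary (Biopython already
stores locations 0-based).  The format-agnostic alternative input is a FASTA
nucleotide sequence plus a TSV annotation table with columns
``locus_id  kind  start  end  strand  product`` (0-based half-open).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import AfterPosition, BeforePosition, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

TRANSLATION_TABLE_ID = 11
_TABLE = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE_ID]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CoordinateError(ValueError):
    pass


@dataclass
class Feature:
    kind: str  # CDS | tRNA | other
    start: int
    end: int
    strand: str  # '+' | '-'
    locus_id: str
    product: str = ""
    translation: str | None = None
    truncated: bool = False  # fuzzy GenBank boundary (< or >)
    pseudo: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"feature {self.locus_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    genome_id: str
    display_name: str
    sequence: str
    topology: str = "linear"  # linear | circular-permuted
    features: list[Feature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.genome_id}: empty sequence")
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.end > len(self.sequence):
                raise CoordinateError(
                    f"{self.genome_id}:{f.locus_id} extends to {f.end}, "
                    f"beyond sequence end {len(self.sequence)}"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_id))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_locus(self, locus_id: str) -> Feature:
        for f in self.features:
            if f.locus_id == locus_id:
                return f
        raise KeyError(f"{self.genome_id}: no feature with locus_id {locus_id!r}")

    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def trna_counts(self) -> tuple[int, int]:
        """(functional tRNAs, pseudo tRNAs) — bookkept separately."""
        trnas = [f for f in self.features if f.kind == "tRNA"]
        pseudo = sum(1 for f in trnas if f.pseudo)
        return len(trnas) - pseudo, pseudo


@dataclass
class ProteinRecord:
    protein_id: str
    genome_id: str
    aa_sequence: str
    genome_coords: tuple[int, int, str]
    truncated: bool = False
    flagged: bool = False  # internal stop observed during translation

    def __post_init__(self):
        if not self.aa_sequence:
            raise ValueError(f"{self.protein_id}: empty translation")

    @property
    def length(self) -> int:
        return len(self.aa_sequence)

    @property
    def locus_id(self) -> str:
        return self.protein_id.split(":", 1)[1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(nt: str) -> tuple[str, bool]:
    """Translate a coding sequence with the bacterial table (11).

    Returns (protein, internal_stop_seen).  The terminal stop is trimmed,
    ambiguous or incomplete codons yield X, and internal stops are emitted as
    X and reported via the flag.
    """
    aa = []
    internal_stop = False
    codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
    for idx, codon in enumerate(codons):
        if codon in _TABLE.stop_codons:
            if idx == len(codons) - 1:
                break
            internal_stop = True
            aa.append("X")
        else:
            aa.append(_TABLE.forward_table.get(codon, "X"))
    return "".join(aa), internal_stop


# ---------------------------------------------------------------------------
# reading


def _parse_genbank(handle, genome_id: str | None) -> GenomeRecord:
    try:
        rec = SeqIO.read(handle, "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record: {exc}") from exc
    features = []
    counters: dict[str, int] = {}
    for feat in rec.features:
        if feat.type == "CDS":
            kind = "CDS"
        elif feat.type == "tRNA":
            kind = "tRNA"
        elif feat.type == "source":
            continue
        else:
            kind = "other"
        loc = feat.location
        fuzzy = isinstance(loc.start, BeforePosition) or isinstance(loc.end, AfterPosition)
        counters[kind] = counters.get(kind, 0) + 1
        locus = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("protein_id", [None])[0]
            or f"{kind}_{counters[kind]}"
        )
        translation = feat.qualifiers.get("translation", [None])[0]
        features.append(
            Feature(
                kind=kind,
                start=int(loc.start),
                end=int(loc.end),
                strand="-" if loc.strand == -1 else "+",
                locus_id=locus,
                product=feat.qualifiers.get("product", [""])[0],
                translation=translation,
                truncated=fuzzy,
                pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
            )
        )
    return GenomeRecord(
        genome_id=genome_id or rec.id or rec.name,
        display_name=rec.description or rec.name,
        sequence=str(rec.seq),
        features=features,
        source="file",
    )


def read_annotation_table(path_or_text) -> list[Feature]:
    text = Path(path_or_text).read_text() if _is_path(path_or_text) else path_or_text
    features = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("locus_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"annotation table line {ln}: expected >=5 tab-separated fields")
        locus, kind, start, end, strand = parts[:5]
        product = parts[5] if len(parts) > 5 else ""
        features.append(Feature(kind, int(start), int(end), strand, locus, product))
    return features


def _is_path(obj) -> bool:
    if isinstance(obj, Path):
        return True
    return isinstance(obj, str) and "\n" not in obj and len(obj) < 4096 and Path(obj).exists()


def read_genome_record(
    path_or_text,
    format: str = "genbank",
    annotation_table=None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read one annotated genome from GenBank, or FASTA plus annotation table."""
    if format == "genbank":
        if _is_path(path_or_text):
            with open(path_or_text) as fh:
                return _parse_genbank(fh, genome_id)
        return _parse_genbank(io.StringIO(path_or_text), genome_id)
    if format == "fasta+table":
        handle = open(path_or_text) if _is_path(path_or_text) else io.StringIO(path_or_text)
        with handle:
            rec = SeqIO.read(handle, "fasta")
        features = read_annotation_table(annotation_table) if annotation_table is not None else []
        return GenomeRecord(
            genome_id=genome_id or rec.id,
            display_name=rec.description,
            sequence=str(rec.seq),
            features=features,
            source="file",
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# writing


def write_fasta(records, path, wrap: int = 70) -> None:
    """Write sequences (GenomeRecords or (name, seq) pairs) as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeRecord):
                name, seq = rec.genome_id, rec.sequence
            elif isinstance(rec, ProteinRecord):
                name, seq = rec.protein_id, rec.aa_sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_annotation_table(genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tkind\tstart\tend\tstrand\tproduct\n")
        for f in genome.features:
            fh.write(f"{f.locus_id}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t{f.product}\n")


def to_seqrecord(genome: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description=genome.display_name,
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for f in genome.features:
        qualifiers = {"locus_tag": [f.locus_id]}
        if f.product:
            qualifiers["product"] = [f.product]
        if f.translation:
            qualifiers["translation"] = [f.translation]
        if f.pseudo:
            qualifiers["pseudo"] = [""]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type=f.kind if f.kind != "other" else "misc_feature",
                qualifiers=qualifiers,
            )
        )
    return rec


def write_genbank(genome: GenomeRecord, path) -> None:
    SeqIO.write(to_seqrecord(genome), path, "genbank")


# ---------------------------------------------------------------------------
# views


def extract_proteome(genome: GenomeRecord) -> list[ProteinRecord]:
    """All CDS products of a genome, using stored translations when present."""
    proteome = []
    for f in genome.features:
        if f.kind != "CDS" or f.pseudo:
            continue
        if f.translation:
            aa, internal_stop = f.translation.rstrip("*"), False
        else:
            nt = genome.sequence[f.start : f.end]
            if f.strand == "-":
                nt = reverse_complement(nt)
            aa, internal_stop = translate_cds(nt)
        if internal_stop:
            warnings.warn(
                f"{genome.genome_id}:{f.locus_id}: internal stop codon; record flagged",
                stacklevel=2,
            )
        proteome.append(
            ProteinRecord(
                protein_id=f"{genome.genome_id}:{f.locus_id}",
                genome_id=genome.genome_id,
                aa_sequence=aa,
                genome_coords=(f.start, f.end, f.strand),
                truncated=f.truncated,
                flagged=internal_stop,
            )
        )
    return proteome


def extract_intergenic(genome: GenomeRecord, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Maximal regions not covered by any CDS/tRNA feature, length >= min_len."""
    covered = [
        (f.start, f.end) for f in genome.features if f.kind in ("CDS", "tRNA")
    ]
    covered.sort()
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    regions = []
    prev = 0
    for s, e in merged + [[len(genome), len(genome)]]:
        if s - prev >= min_len:
            regions.append((prev, s, genome.sequence[prev:s]))
        prev = max(prev, e)
    return regions


def rotate_to_anchor(genome: GenomeRecord, anchor_locus: str) -> GenomeRecord:
    """Rotate a genome so the anchor feature starts at position 0.

    Used to present maps with an arbitrary origin at the large terminase
    subunit ORF.  The rotation point must not fall inside a feature.
    """
    anchor = genome.feature_by_locus(anchor_locus)
    off = anchor.start
    if off == 0:
        return genome
    n = len(genome)
    for f in genome.features:
        if f.start < off < f.end:
            raise CoordinateError(
                f"rotation point {off} falls inside feature {f.locus_id}"
            )
    new_features = [
        replace(f, start=(f.start - off) % n, end=(f.end - off - 1) % n + 1)
        for f in genome.features
    ]
    return GenomeRecord(
        genome_id=genome.genome_id,
        display_name=genome.display_name,
        sequence=genome.sequence[off:] + genome.sequence[:off],
        topology=genome.topology,
        features=new_features,
        source=genome.source,
    )
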