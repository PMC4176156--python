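"""Transcript-space annotation and footprint-alignment I/O.

Everything downstream of alignment works in *transcript* coordinate space:
each mRNA is its own reference sequence, coordinates are 0-based half-open,
and the genomic strand survives only as metadata.  This removes strand and
exon bookkeeping from every analysis while losing nothing that a
start-codon-anchored analysis needs.

Supported formats
-----------------
* annotations: BED12 (native 0-based half-open) and GFF3 (1-based inclusive,
  converted at the boundary).  In BED12 the chrom column is the transcript id
  and the name column optionally carries upstream ORFs as ``uorf:100-130,...``.
  In GFF3, ``uORF`` features are children of the transcript feature.
* alignments: BED6 (native) and SAM (POS - 1, reference span from the CIGAR,
  via pysam).  The read class rides in the read name as a ``|tag`` suffix,
  e.g. ``read37|rRNA_18S``; an absent tag means a regular footprint.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: Controlled vocabulary for read classes (library composition QC).
READ_CLASSES = ("footprint", "rRNA_18S", "rRNA_25S", "other")

#: Footprint lengths a real RNase-protection assay can produce, generously.
MIN_FOOTPRINT_LEN = 20
MAX_FOOTPRINT_LEN = 45


class ParseError(ValueError):
    """A record could not be parsed under the named standard."""


class ValidationError(ValueError):
    """Parsed records violate the transcript-space data model."""


@dataclass(frozen=True)
class Transcript:
    """One annotated mRNA in transcript coordinates.

    ``cds_start``/``cds_end`` bound the main ORF (0-based half-open, so the
    first nucleotide of the start codon is ``cds_start``).  ``uorfs`` are
    half-open intervals entirely within the 5'UTR, each a multiple of 3 and
    at least 6 nt (start codon + stop codon).
    """

    id: str
    length: int
    cds_start: int
    cds_end: int
    exon_count: int = 1
    uorfs: tuple[tuple[int, int], ...] = ()
    strand_on_genome: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "uorfs", tuple((int(s), int(e)) for s, e in self.uorfs))
        if self.length <= 0:
            raise ValidationError(f"{self.id}: transcript length must be positive")
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValidationError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside [0,{self.length}]"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValidationError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} not divisible by 3"
            )
        if self.exon_count < 1:
            raise ValidationError(f"{self.id}: exon_count must be >= 1")
        if self.strand_on_genome not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be + or -")
        for s, e in self.uorfs:
            if not (0 <= s < e <= self.cds_start):
                raise ValidationError(f"{self.id}: uORF [{s},{e}) not within 5'UTR")
            if (e - s) % 3 or (e - s) < 6:
                raise ValidationError(
                    f"{self.id}: uORF [{s},{e}) must be a multiple of 3 and >= 6 nt"
                )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_codons(self) -> int:
        return self.cds_length // 3

    @property
    def utr5_length(self) -> int:
        return self.cds_start


@dataclass(frozen=True)
class FootprintAlignment:
    """One mapped footprint: transcript id, half-open interval, read class."""

    transcript_id: str
    start: int
    end: int
    read_class: str = "footprint"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"{self.transcript_id}: bad interval [{self.start},{self.end})"
            )
        n = self.end - self.start
        if not (MIN_FOOTPRINT_LEN <= n <= MAX_FOOTPRINT_LEN):
            raise ValidationError(
                f"{self.transcript_id}: footprint length {n} outside "
                f"[{MIN_FOOTPRINT_LEN},{MAX_FOOTPRINT_LEN}]"
            )
        if self.read_class not in READ_CLASSES:
            raise ValidationError(f"unknown read class {self.read_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class TranscriptSet(Mapping):
    """Immutable id -> Transcript mapping with unique ids."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self._by_id: dict[str, Transcript] = {}
        for tx in transcripts:
            if tx.id in self._by_id:
                raise ValidationError(f"duplicate transcript id {tx.id!r}")
            self._by_id[tx.id] = tx

    def __getitem__(self, key: str) -> Transcript:
        return self._by_id[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def sorted_ids(self) -> list[str]:
        return sorted(self._by_id)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TranscriptSet({len(self)} transcripts)"


# ---------------------------------------------------------------------------
# annotation reading
# ---------------------------------------------------------------------------


def _parse_uorf_tag(tag: str, line_no: int) -> tuple[tuple[int, int], ...]:
    """Parse ``uorf:100-130,200-230`` from a BED12 name column."""
    if not tag.startswith("uorf:"):
        raise ParseError(f"line {line_no}: unrecognized name field {tag!r}")
    out = []
    for chunk in tag[5:].split(","):
        try:
            s, e = chunk.split("-")
            out.append((int(s), int(e)))
        except ValueError as exc:
            raise ParseError(f"line {line_no}: bad uORF interval {chunk!r}") from exc
    return tuple(out)


def _read_bed12(path: Path) -> TranscriptSet:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ParseError(
                    f"line {line_no}: expected 12 BED12 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-numeric BED12 field") from exc
            if chrom_start != 0:
                raise ParseError(
                    f"line {line_no}: transcript-space BED12 must start at 0"
                )
            uorfs = () if name in (".", "", chrom) else _parse_uorf_tag(name, line_no)
            rows.append(
                dict(
                    line_no=line_no,
                    id=chrom,
                    length=chrom_end,
                    cds_start=thick_start,
                    cds_end=thick_end,
                    exon_count=block_count,
                    uorfs=uorfs,
                    strand=strand if strand in "+-" else "+",
                )
            )
    return _build_transcript_set(rows)


def _build_transcript_set(rows: list[dict]) -> TranscriptSet:
    bad_cds = [r["id"] for r in rows if (r["cds_end"] - r["cds_start"]) % 3]
    if bad_cds:
        raise ValidationError(
            "CDS length not divisible by 3 for: " + ", ".join(sorted(bad_cds))
        )
    transcripts = [
        Transcript(
            id=r["id"],
            length=r["length"],
            cds_start=r["cds_start"],
            cds_end=r["cds_end"],
            exon_count=r["exon_count"],
            uorfs=r["uorfs"],
            strand_on_genome=r["strand"],
        )
        for r in rows
    ]
    return TranscriptSet(transcripts)


def _read_gff3(path: Path) -> TranscriptSet:
    import gffutils

    # Light pre-scan so malformed records fail with a line number, which
    # gffutils does not report.
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ParseError(f"line {line_no}: GFF3 record does not have 9 columns")
    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:  # gffutils raises various concrete types
        raise ParseError(f"could not parse GFF3 {path}: {exc}") from exc

    rows = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        exons = list(db.children(feat, featuretype="exon"))
        cds = sorted(db.children(feat, featuretype="CDS"), key=lambda c: c.start)
        if not cds:
            raise ValidationError(f"{feat.id}: transcript has no CDS feature")
        cds_start = cds[0].start - 1
        cds_end = max(c.end for c in cds)
        # honour an explicit phase on the first CDS segment
        if cds[0].frame in ("1", "2"):
            cds_start += int(cds[0].frame)
        uorfs = tuple(
            (u.start - 1, u.end) for u in db.children(feat, featuretype="uORF")
        )
        if feat.start != 1:
            raise ValidationError(f"{feat.id}: transcript-space feature must start at 1")
        rows.append(
            dict(
                id=feat.id,
                length=feat.end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_count=len(exons) or 1,
                uorfs=uorfs,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return _build_transcript_set(rows)


def read_annotation(path: str | Path, format: str | None = None) -> TranscriptSet:
    """Read a transcript annotation in BED12 or GFF3.

    ``format`` is ``"bed12"`` or ``"gff3"``; if omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed12"
    if format == "bed12":
        return _read_bed12(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation(
    txs: TranscriptSet, path: str | Path, format: str = "bed12"
) -> None:
    """Write a TranscriptSet as BED12 or GFF3 (round-trips with read_annotation)."""
    path = Path(path)
    if format == "bed12":
        with open(path, "w") as fh:
            for tid in txs.sorted_ids():
                tx = txs[tid]
                name = (
                    "uorf:" + ",".join(f"{s}-{e}" for s, e in tx.uorfs)
                    if tx.uorfs
                    else "."
                )
                # split the transcript into exon_count contiguous blocks
                bounds = [
                    round(i * tx.length / tx.exon_count)
                    for i in range(tx.exon_count + 1)
                ]
                sizes = ",".join(
                    str(bounds[i + 1] - bounds[i]) for i in range(tx.exon_count)
                )
                starts = ",".join(str(b) for b in bounds[:-1])
                fh.write(
                    "\t".join(
                        [
                            tx.id,
                            "0",
                            str(tx.length),
                            name,
                            "0",
                            tx.strand_on_genome,
                            str(tx.cds_start),
                            str(tx.cds_end),
                            "0,0,0",
                            str(tx.exon_count),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for tid in txs.sorted_ids():
                tx = txs[tid]
                s = tx.strand_on_genome
                fh.write(
                    f"{tid}\tribodrift\tmRNA\t1\t{tx.length}\t.\t{s}\t.\tID={tid}\n"
                )
                bounds = [
                    round(i * tx.length / tx.exon_count)
                    for i in range(tx.exon_count + 1)
                ]
                for i in range(tx.exon_count):
                    fh.write(
                        f"{tid}\tribodrift\texon\t{bounds[i] + 1}\t{bounds[i + 1]}\t.\t{s}\t."
                        f"\tID={tid}.exon{i + 1};Parent={tid}\n"
                    )
                fh.write(
                    f"{tid}\tribodrift\tCDS\t{tx.cds_start + 1}\t{tx.cds_end}\t.\t{s}\t0"
                    f"\tID={tid}.cds;Parent={tid}\n"
                )
                for j, (us, ue) in enumerate(tx.uorfs):
                    fh.write(
                        f"{tid}\tribodrift\tuORF\t{us + 1}\t{ue}\t.\t{s}\t."
                        f"\tID={tid}.uorf{j + 1};Parent={tid}\n"
                    )
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# alignment reading / writing
# ---------------------------------------------------------------------------


def _class_from_name(name: str) -> str:
    if "|" in name:
        tag = name.rsplit("|", 1)[1]
        if tag in READ_CLASSES:
            return tag
    return "footprint"


def _read_bed6(path: Path) -> list[FootprintAlignment]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"line {line_no}: expected 6 BED6 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-numeric BED6 coordinate") from exc
            try:
                out.append(
                    FootprintAlignment(
                        transcript_id=fields[0],
                        start=start,
                        end=end,
                        read_class=_class_from_name(fields[3]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
    return out


def _read_sam(path: Path) -> list[FootprintAlignment]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            out.append(
                FootprintAlignment(
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    read_class=_class_from_name(rec.query_name or ""),
                )
            )
    return out


def read_alignments(
    path: str | Path,
    format: str | None = None,
    transcripts: TranscriptSet | None = None,
) -> list[FootprintAlignment]:
    """Read footprint alignments from BED6 or SAM.

    When ``transcripts`` is given, footprint-class reads are validated against
    it: their reference must be an annotated transcript and the interval must
    lie within it.  Contamination classes (rRNA, other) are exempt because
    their references (rRNA genes) sit outside the mRNA annotation by design.
    """
    path = Path(path)
    if format is None:
        format = "sam" if path.suffix.lower() == ".sam" else "bed6"
    if format == "bed6":
        alignments = _read_bed6(path)
    elif format == "sam":
        alignments = _read_sam(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if transcripts is not None:
        validate_alignments(alignments, transcripts)
    return alignments


def validate_alignments(
    alignments: Iterable[FootprintAlignment], transcripts: TranscriptSet
) -> None:
    """Check footprint-class reads against the annotation; raise on violations."""
    unknown: set[str] = set()
    for aln in alignments:
        if aln.read_class != "footprint":
            continue
        tx = transcripts.get(aln.transcript_id)
        if tx is None:
            unknown.add(aln.transcript_id)
            continue
        if aln.end > tx.length:
            raise ValidationError(
                f"{aln.transcript_id}: interval [{aln.start},{aln.end}) beyond "
                f"transcript end {tx.length}"
            )
    if unknown:
        raise ValidationError(
            "unknown transcript ids: " + ", ".join(sorted(unknown))
        )


def write_alignments(
    alignments: Iterable[FootprintAlignment],
    path: str | Path,
    format: str = "bed6",
) -> None:
    """Write alignments as BED6; read_alignments round-trips bit-exactly."""
    if format != "bed6":
        raise ValueError(f"unknown alignment format {format!r}")
    with open(path, "w") as fh:
        for i, aln in enumerate(alignments):
            name = f"read{i}" if aln.read_class == "footprint" else f"read{i}|{aln.read_class}"
            fh.write(
                f"{aln.transcript_id}\t{aln.start}\t{aln.end}\t{name}\t0\t+\n"
            )
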