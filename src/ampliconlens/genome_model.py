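"""Gene/transcript/domain data model, GTF I/O, and bundled gene fixtures.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive)
is converted at the I/O boundary.  Exons are kept in transcription order,
so for a minus-strand transcript exon 1 has the greatest genomic
coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "GenomicInterval",
    "Transcript",
    "ProteinDomain",
    "GeneFixture",
    "ExonLocation",
    "GtfParseError",
    "GeneNotFoundError",
    "load_gtf",
    "write_gtf",
    "exon_index_of",
    "map_genomic_to_cds",
    "load_fixture",
    "domain_exon_span",
]


class GtfParseError(ValueError):
    """A GTF line could not be parsed; carries the 1-based line number."""


class GeneNotFoundError(KeyError):
    """A requested gene/transcript is absent from the annotation."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ProteinDomain:
    """A named domain on the canonical protein, 1-based inclusive aa coords."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"domain {self.name}: need 1 <= aa_start <= aa_end, "
                f"got [{self.aa_start}, {self.aa_end}]"
            )


@dataclass
class Transcript:
    """A transcript model with exons in transcription order.

    ``cds_start`` and ``cds_end`` are the genomic positions (0-based) of the
    first and last coding base *in transcript orientation*: for a
    minus-strand transcript ``cds_start`` therefore lies at a higher genomic
    coordinate than ``cds_end``.  ``cds_sequence`` is the spliced coding
    sequence (mRNA sense, including the stop codon) and is only required by
    start-codon scanning.
    """

    gene: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons: {a} and {b}")
        expected = by_start if self.strand == "+" else by_start[::-1]
        if [e.start for e in self.exons] != [e.start for e in expected]:
            raise ValueError("exons are not in transcription order")
        if self.cds_start is not None and self.genomic_to_tx(self.cds_start) is None:
            raise ValueError("cds_start does not fall inside an exon")

    # -- basic geometry -------------------------------------------------

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """0-based offset of ``pos`` in the spliced transcript, or None."""
        off = 0
        for exon in self.exons:
            if exon.contains(pos):
                if self.strand == "+":
                    return off + (pos - exon.start)
                return off + (exon.end - 1 - pos)
            off += len(exon)
        return None

    def tx_to_genomic(self, tx_off: int) -> int:
        """Inverse of :meth:`genomic_to_tx` (raises if out of range)."""
        off = tx_off
        for exon in self.exons:
            if off < len(exon):
                if self.strand == "+":
                    return exon.start + off
                return exon.end - 1 - off
            off -= len(exon)
        raise IndexError(f"transcript offset {tx_off} out of range")

    @property
    def cds_tx_start(self) -> int:
        if self.cds_start is None:
            raise ValueError(f"{self.gene}: transcript has no CDS annotation")
        off = self.genomic_to_tx(self.cds_start)
        assert off is not None
        return off

    @property
    def cds_tx_end(self) -> int:
        """Transcript offset one past the last coding base."""
        if self.cds_end is None:
            raise ValueError(f"{self.gene}: transcript has no CDS annotation")
        off = self.genomic_to_tx(self.cds_end)
        if off is None:
            raise ValueError("cds_end does not fall inside an exon")
        return off + 1


@dataclass
class GeneFixture:
    """A packaged annotation snapshot: transcript + domains + TSS."""

    transcript: Transcript
    domains: list[ProteinDomain] = field(default_factory=list)
    tss: int = -1

    def __post_init__(self) -> None:
        if self.tss < 0:
            self.tss = self.transcript.tss
        if self.tss != self.transcript.tss:
            raise ValueError(
                f"fixture tss {self.tss} disagrees with exon-1 start "
                f"{self.transcript.tss}"
            )

    def domain(self, name: str) -> ProteinDomain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)


# -- position classification -----------------------------------------------


@dataclass(frozen=True)
class ExonLocation:
    """Where a genomic position falls relative to a transcript.

    kind is one of ``exon`` (with ``exon``), ``intron`` (between
    ``exon`` and ``exon + 1`` in transcription order) or ``outside``
    (with ``side`` 5prime/3prime in transcript orientation).
    """

    kind: str
    exon: Optional[int] = None
    side: Optional[str] = None

    def __str__(self) -> str:
        if self.kind == "exon":
            return f"exon {self.exon}"
        if self.kind == "intron":
            return f"intron {self.exon}/{self.exon + 1}"
        return f"outside {'5′' if self.side == '5prime' else '3′'}"


def exon_index_of(transcript: Transcript, pos: int) -> ExonLocation:
    """Locate ``pos`` relative to the exon structure (1-based numbering)."""
    span = transcript.span
    if pos < span.start or pos >= span.end:
        if transcript.strand == "+":
            side = "5prime" if pos < span.start else "3prime"
        else:
            side = "5prime" if pos >= span.end else "3prime"
        return ExonLocation("outside", side=side)
    for i, exon in enumerate(transcript.exons, start=1):
        if exon.contains(pos):
            return ExonLocation("exon", exon=i)
    # intronic: find flanking exons in transcription order
    for i, (a, b) in enumerate(zip(transcript.exons, transcript.exons[1:]), start=1):
        lo = min(a.end, b.end)
        hi = max(a.start, b.start)
        if lo <= pos < hi:
            return ExonLocation("intron", exon=i)
    raise AssertionError("unreachable: position inside span but unlocated")


def map_genomic_to_cds(transcript: Transcript, pos: int) -> Optional[int]:
    """0-based offset of ``pos`` in the spliced CDS; None for noncoding."""
    tx = transcript.genomic_to_tx(pos)
    if tx is None:
        return None
    start = transcript.cds_tx_start
    end = transcript.cds_tx_end
    if not (start <= tx < end):
        return None
    return tx - start


def domain_exon_span(fixture: GeneFixture, domain: ProteinDomain) -> tuple[int, int]:
    """Project a protein domain to its (first, last) exon numbers via CDS
    arithmetic (1-based, transcription order)."""
    tr = fixture.transcript
    start_tx = tr.cds_tx_start + (domain.aa_start - 1) * 3
    end_tx = tr.cds_tx_start + domain.aa_end * 3 - 1
    first = exon_index_of(tr, tr.tx_to_genomic(start_tx))
    last = exon_index_of(tr, tr.tx_to_genomic(end_tx))
    assert first.kind == "exon" and last.kind == "exon"
    return first.exon, last.exon


# -- GTF I/O ----------------------------------------------------------------


def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gtf(
    path,
    gene_names: Optional[Iterable[str]] = None,
    cds_sequences: Optional[dict[str, str]] = None,
) -> list[Transcript]:
    """Read transcripts from a 9-column GTF file.

    ``gene_names`` restricts the result to the given gene names; every
    requested gene must be present.  ``cds_sequences`` optionally maps gene
    name to the spliced CDS sequence.
    """
    wanted = set(gene_names) if gene_names is not None else None
    exons: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    cds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _, feature, start, end, _, strand, _, attr_raw = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i = int(start)
                end_i = int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: bad coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise GtfParseError(
                    f"line {lineno}: invalid 1-based interval ({start}, {end})"
                )
            attrs = _parse_attributes(attr_raw)
            gene = attrs.get("gene_name") or attrs.get("gene_id")
            if gene is None:
                raise GtfParseError(f"line {lineno}: no gene_name/gene_id attribute")
            if wanted is not None and gene not in wanted:
                continue
            key = (gene, chrom)
            # GTF 1-based inclusive -> 0-based half-open
            rec = (start_i - 1, end_i, strand, chrom)
            if feature == "exon":
                exons.setdefault(key, []).append(rec)
            else:
                cds.setdefault(key, []).append((start_i - 1, end_i))

    transcripts = []
    for (gene, chrom), recs in exons.items():
        strand = recs[0][2]
        ivals = sorted(
            (GenomicInterval(chrom, s, e, strand) for s, e, _, _ in recs),
            key=lambda iv: iv.start,
        )
        if strand == "-":
            ivals = ivals[::-1]
        cds_start = cds_end = None
        if (gene, chrom) in cds:
            blocks = sorted(cds[(gene, chrom)])
            lo, hi = blocks[0][0], blocks[-1][1]
            if strand == "+":
                cds_start, cds_end = lo, hi - 1
            else:
                cds_start, cds_end = hi - 1, lo
        seq = cds_sequences.get(gene) if cds_sequences else None
        transcripts.append(
            Transcript(gene, chrom, strand, ivals, cds_start, cds_end, seq)
        )

    if wanted is not None:
        found = {t.gene for t in transcripts}
        missing = wanted - found
        if missing:
            raise GeneNotFoundError(
                f"gene(s) not found in {path}: {', '.join(sorted(missing))}"
            )
    return transcripts


def write_gtf(transcripts: Iterable[Transcript], path) -> None:
    """Write transcripts back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for tr in transcripts:
            attrs = f'gene_id "{tr.gene}"; gene_name "{tr.gene}"; transcript_id "{tr.gene}.t1";'
            for exon in sorted(tr.exons, key=lambda e: e.start):
                fh.write(
                    "\t".join(
                        [
                            tr.chrom,
                            "ampliconlens",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            tr.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            if tr.cds_start is not None and tr.cds_end is not None:
                lo = min(tr.cds_start, tr.cds_end)
                hi = max(tr.cds_start, tr.cds_end)
                for exon in sorted(tr.exons, key=lambda e: e.start):
                    s = max(exon.start, lo)
                    e = min(exon.end, hi + 1)
                    if s < e:
                        fh.write(
                            "\t".join(
                                [
                                    tr.chrom,
                                    "ampliconlens",
                                    "CDS",
                                    str(s + 1),
                                    str(e),
                                    ".",
                                    tr.strand,
                                    ".",
                                    attrs,
                                ]
                            )
                            + "\n"
                        )


# -- bundled fixtures -------------------------------------------------------


def _read_fasta_resource(name: str) -> str:
    ref = importlib.resources.files("ampliconlens.data") / name
    seq = []
    for line in ref.read_text().splitlines():
        if not line.startswith(">"):
            seq.append(line.strip())
    return "".join(seq)


def load_fixture(gene: str) -> GeneFixture:
    """Load one of the packaged gene snapshots (``FGFR1`` or ``NSD3``).

    These are desk-scale stand-ins for the hg19 8p11-p12 gene models: exon
    counts, strand, domain layout and locus coordinates follow the published
    annotation, while the CDS nucleotide sequences are synthetic (engineered
    so that in-frame ATGs occur at the documented positions).
    """
    ref = importlib.resources.files("ampliconlens.data") / "gene_fixtures.tsv"
    rows = [
        line.split("\t")
        for line in ref.read_text().splitlines()[1:]
        if line.strip()
    ]
    rows = [r for r in rows if r[0] == gene]
    if not rows:
        raise GeneNotFoundError(f"no bundled fixture for gene {gene!r}")
    strand = next(r[5] for r in rows if r[1] == "gene")
    chrom = "chr8"
    exon_rows = sorted(
        (r for r in rows if r[1] == "exon"), key=lambda r: int(r[2])
    )
    exons = [GenomicInterval(chrom, int(r[3]), int(r[4]), strand) for r in exon_rows]
    cds_row = next(r for r in rows if r[1] == "cds")
    cds_start, cds_end = int(cds_row[3]), int(cds_row[4])
    domains = [
        ProteinDomain(r[2], int(r[3]), int(r[4]))
        for r in rows
        if r[1] == "domain"
    ]
    tss = next(int(r[3]) for r in rows if r[1] == "tss")
    seq_file = {"FGFR1": "fgfr1_cds.fasta", "NSD3": "nsd3_cds.fasta"}[gene]
    transcript = Transcript(
        gene, chrom, strand, exons, cds_start, cds_end,
        _read_fasta_resource(seq_file),
    )
    return GeneFixture(transcript=transcript, domains=domains, tss=tss)
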