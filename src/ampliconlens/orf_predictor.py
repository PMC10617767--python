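"""Truncated open-reading-frame prediction for intragenic rearrangements.

Given a junction with a breakend inside a gene, determine the exons
retained on the derivative, find the first surviving in-frame ATG (the
canonical start when it is untouched), and report which protein domains
are lost and whether the kinase domain survives.  All scanning is done on
the transcript (mRNA-sense) spliced CDS; only ATGs congruent to the
canonical reading frame are considered, with no start-context scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_model import (
    GeneFixture,
    Transcript,
    exon_index_of,
)
from .rearrangements import Junction

__all__ = [
    "NotIntragenicError",
    "RetainedExons",
    "StartCodon",
    "TruncationCall",
    "retained_exons",
    "next_inframe_start",
    "predict_variant",
]


class NotIntragenicError(ValueError):
    """The junction has no breakend inside the transcript."""


@dataclass(frozen=True)
class RetainedExons:
    """Exons surviving on the derivative, in transcription order.

    ``partial`` names the exon truncated by an intra-exonic breakend (or
    None).  ``tx_range`` is the retained half-open interval in spliced
    transcript coordinates; retention is always a transcript prefix
    (3'-truncating) or suffix (5'-truncating).
    """

    exons: tuple[int, ...]
    partial: Optional[int]
    tx_range: tuple[int, int]

    @property
    def is_suffix(self) -> bool:
        return self.tx_range[0] > 0


def _retained_tx_range(tr: Transcript, pos: int, retained_side: str) -> tuple[int, int]:
    """Retained spliced-transcript interval for one breakend."""
    L = tr.spliced_length
    loc = exon_index_of(tr, pos)
    if loc.kind == "exon":
        t = tr.genomic_to_tx(pos)
        assert t is not None
        if tr.strand == "-":
            # transcript runs high -> low genomic coordinates
            return (t, L) if retained_side == "left" else (0, t + 1)
        return (0, t + 1) if retained_side == "left" else (t, L)
    if loc.kind == "intron":
        k = loc.exon  # between exon k and k+1 in transcription order
        boundary = sum(len(e) for e in tr.exons[:k])
        genomic_left_is_5prime = tr.strand == "+"
        if (retained_side == "left") == genomic_left_is_5prime:
            return (0, boundary)  # keep exons 1..k
        return (boundary, L)  # keep exons k+1..n
    raise NotIntragenicError(f"position {pos} is outside the transcript")


def retained_exons(transcript: Transcript, j: Junction) -> RetainedExons:
    """Exons entirely on the retained derivative (1-based, transcription
    order); a breakend inside an exon marks that exon partial."""
    span = transcript.span
    inside = [
        be
        for be in j.breakends()
        if be.chrom == span.chrom and span.contains(be.pos)
    ]
    if not inside:
        # a junction fully 5' of the transcript leaves everything intact
        if any(be.chrom == span.chrom for be in j.breakends()):
            raise NotIntragenicError(
                "junction does not intersect the transcript"
            )
        raise NotIntragenicError("junction is on a different chromosome")
    lo, hi = 0, transcript.spliced_length
    for be in inside:
        r_lo, r_hi = _retained_tx_range(transcript, be.pos, be.retained_side)
        lo, hi = max(lo, r_lo), min(hi, r_hi)
    if lo >= hi:
        raise NotIntragenicError("breakends retain no transcript sequence")
    exons: list[int] = []
    partial = None
    off = 0
    for i, exon in enumerate(transcript.exons, start=1):
        e_lo, e_hi = off, off + len(exon)
        keep_lo, keep_hi = max(e_lo, lo), min(e_hi, hi)
        if keep_lo < keep_hi:
            exons.append(i)
            if keep_hi - keep_lo < len(exon):
                partial = i
        off = e_hi
    return RetainedExons(tuple(exons), partial, (lo, hi))


@dataclass(frozen=True)
class StartCodon:
    exon: int
    cds_offset: int
    canonical: bool


def next_inframe_start(
    transcript: Transcript, retained: RetainedExons
) -> Optional[StartCodon]:
    """First surviving in-frame ATG on the retained spliced sequence.

    Returns the canonical start when its codon is fully retained,
    otherwise the first downstream ATG whose CDS offset is a multiple of
    three; None when no in-frame ATG survives.
    """
    if transcript.cds_sequence is None:
        raise ValueError(f"{transcript.gene}: cds_sequence required for start scanning")
    cds = transcript.cds_sequence.upper()
    cds_lo = transcript.cds_tx_start
    lo, hi = retained.tx_range
    if lo <= cds_lo and cds_lo + 3 <= hi:
        return StartCodon(
            exon=_exon_of_cds_offset(transcript, 0), cds_offset=0, canonical=True
        )
    # first candidate CDS offset fully inside the retained region, in frame
    first = max(0, lo - cds_lo)
    first += (-first) % 3
    last = min(len(cds), hi - cds_lo)
    for off in range(first, last - 2, 3):
        if cds[off : off + 3] == "ATG":
            return StartCodon(
                exon=_exon_of_cds_offset(transcript, off),
                cds_offset=off,
                canonical=False,
            )
    return None


def _exon_of_cds_offset(transcript: Transcript, cds_offset: int) -> int:
    pos = transcript.tx_to_genomic(transcript.cds_tx_start + cds_offset)
    loc = exon_index_of(transcript, pos)
    assert loc.kind == "exon"
    return loc.exon


@dataclass
class TruncationCall:
    """Predicted consequence of an intragenic rearrangement."""

    gene: str
    breakend_pos: int
    retained_exons: tuple[int, ...]
    partial_exon: Optional[int]
    start_codon: Optional[StartCodon]
    lost_domains: list[str] = field(default_factory=list)
    partial_domains: list[str] = field(default_factory=list)
    kinase_retained: bool = False
    protein_start_aa: Optional[int] = None
    no_orf: bool = False

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "breakend_pos": self.breakend_pos,
            "retained_exons": list(self.retained_exons),
            "partial_exon": self.partial_exon,
            "start_codon": (
                None
                if self.start_codon is None
                else {
                    "exon": self.start_codon.exon,
                    "cds_offset": self.start_codon.cds_offset,
                    "canonical": self.start_codon.canonical,
                }
            ),
            "lost_domains": self.lost_domains,
            "partial_domains": self.partial_domains,
            "kinase_retained": self.kinase_retained,
            "protein_start_aa": self.protein_start_aa,
            "no_orf": self.no_orf,
        }


def predict_variant(fixture: GeneFixture, j: Junction) -> TruncationCall:
    """Compose retained-exon analysis and start-codon scanning into a
    truncation call with domain-level consequences."""
    tr = fixture.transcript
    retained = retained_exons(tr, j)
    span = tr.span
    inside = [
        be for be in j.breakends() if be.chrom == span.chrom and span.contains(be.pos)
    ]
    breakend_pos = inside[0].pos if inside else -1

    start = next_inframe_start(tr, retained)
    n_aa = (len(tr.cds_sequence) // 3) - 1 if tr.cds_sequence else 0

    if start is None:
        return TruncationCall(
            gene=tr.gene,
            breakend_pos=breakend_pos,
            retained_exons=retained.exons,
            partial_exon=retained.partial,
            start_codon=None,
            lost_domains=[d.name for d in fixture.domains],
            kinase_retained=False,
            no_orf=True,
        )

    start_aa = start.cds_offset // 3 + 1
    # last amino acid whose codon is fully retained
    cds_lo = tr.cds_tx_start
    retained_cds_hi = min(n_aa * 3, retained.tx_range[1] - cds_lo)
    last_aa = max(0, retained_cds_hi // 3)

    lost, partial = [], []
    for d in fixture.domains:
        if d.aa_end < start_aa or d.aa_start > last_aa:
            lost.append(d.name)
        elif d.aa_start < start_aa or d.aa_end > last_aa:
            partial.append(d.name)

    kinase_retained = False
    try:
        kin = fixture.domain("kinase")
        kinase_retained = start_aa <= kin.aa_start and kin.aa_end <= last_aa
    except KeyError:
        pass

    return TruncationCall(
        gene=tr.gene,
        breakend_pos=breakend_pos,
        retained_exons=retained.exons,
        partial_exon=retained.partial,
        start_codon=start,
        lost_domains=lost,
        partial_domains=partial,
        kinase_retained=kinase_retained,
        protein_start_aa=start_aa,
    )
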