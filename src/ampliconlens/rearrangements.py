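"""Rearrangement-junction I/O, orientation classification and locus rules.

Orientation nomenclature (documented because it is used inconsistently in
the wild): "tail" is the high-coordinate flank of a breakend.  A
tail-to-tail junction joins the two *left* reference flanks (BEDPE strands
"+/+"), a head-to-head junction the two *right* flanks ("-/-").  A
tail-to-tail junction inside a minus-strand gene therefore deletes its 5'
exons, which sit at the higher genomic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .genome_model import GeneFixture, domain_exon_span, exon_index_of

__all__ = [
    "Breakend",
    "Junction",
    "FoldBack",
    "NSD3Evidence",
    "read_bedpe",
    "write_junction_tsv",
    "read_vcf_bnd",
    "classify_junction",
    "detect_foldbacks",
    "assign_fgfr1_window",
    "call_nsd3_disruption",
    "DEFAULT_FOLDBACK_PROXIMITY_BP",
    "DEFAULT_UPSTREAM_WINDOW_BP",
    "DEFAULT_MIN_SUPPORT",
]

DEFAULT_FOLDBACK_PROXIMITY_BP = 100_000
DEFAULT_UPSTREAM_WINDOW_BP = 400_000
DEFAULT_MIN_SUPPORT = 2

TAIL_TO_TAIL = "tail_to_tail"
HEAD_TO_HEAD = "head_to_head"
DELETION_TYPE = "deletion_type"
DUPLICATION_TYPE = "duplication_type"
INTERCHROMOSOMAL = "interchromosomal"


@dataclass(frozen=True)
class Breakend:
    """One side of a junction.

    ``retained_side`` names the reference flank joined into the derivative
    chromosome: ``left`` (BEDPE strand "+") keeps the sequence at lower
    coordinates, ``right`` ("-") the sequence at higher coordinates.
    """

    chrom: str
    pos: int
    retained_side: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"breakend position must be >= 0, got {self.pos}")
        if self.retained_side not in ("left", "right"):
            raise ValueError(
                f"retained_side must be left/right, got {self.retained_side!r}"
            )


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass(frozen=True)
class Junction:
    """A pair of oriented breakends in canonical order (a <= b)."""

    a: Breakend
    b: Breakend
    support: int = 0
    name: str = "."

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be >= 0")
        side_rank = {"left": 0, "right": 1}
        ka = (_chrom_key(self.a.chrom), self.a.pos, side_rank[self.a.retained_side])
        kb = (_chrom_key(self.b.chrom), self.b.pos, side_rank[self.b.retained_side])
        if ka > kb:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def orientation_class(self) -> str:
        return classify_junction(self)

    @property
    def span(self) -> Optional[int]:
        """|pos_b - pos_a| for same-chromosome junctions, else None."""
        if self.a.chrom != self.b.chrom:
            return None
        return abs(self.b.pos - self.a.pos)

    @property
    def low_confidence(self) -> bool:
        return self.support < DEFAULT_MIN_SUPPORT

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.a, self.b)


def classify_junction(j: Junction) -> str:
    """Orientation class from the two retained sides.

    Same chromosome: (left, left) -> tail_to_tail; (right, right) ->
    head_to_head; (left, right) -> deletion_type; (right, left) ->
    duplication_type.  Different chromosomes -> interchromosomal.
    """
    if j.a.chrom != j.b.chrom:
        return INTERCHROMOSOMAL
    sides = (j.a.retained_side, j.b.retained_side)
    return {
        ("left", "left"): TAIL_TO_TAIL,
        ("right", "right"): HEAD_TO_HEAD,
        ("left", "right"): DELETION_TYPE,
        ("right", "left"): DUPLICATION_TYPE,
    }[sides]


@dataclass(frozen=True)
class FoldBack:
    """A same-chromosome inverted junction with nearby breakends."""

    junction: Junction

    def __post_init__(self) -> None:
        if self.junction.a.chrom != self.junction.b.chrom:
            raise ValueError("fold-back breakends must share a chromosome")
        if classify_junction(self.junction) not in (TAIL_TO_TAIL, HEAD_TO_HEAD):
            raise ValueError("fold-back must be tail-to-tail or head-to-head")

    @property
    def span(self) -> int:
        return self.junction.span  # type: ignore[return-value]


def detect_foldbacks(
    junctions: Iterable[Junction],
    proximity_bp: int = DEFAULT_FOLDBACK_PROXIMITY_BP,
) -> list[FoldBack]:
    """All same-chromosome inverted junctions with span <= proximity_bp."""
    if proximity_bp <= 0:
        raise ValueError("proximity_bp must be > 0")
    out = []
    for j in junctions:
        if j.a.chrom != j.b.chrom:
            continue
        if classify_junction(j) in (TAIL_TO_TAIL, HEAD_TO_HEAD) and j.span <= proximity_bp:
            out.append(FoldBack(j))
    return out


# -- BEDPE / VCF I/O --------------------------------------------------------

_STRAND_TO_SIDE = {"+": "left", "-": "right"}


def read_bedpe(path) -> list[Junction]:
    """Read a standard 10-column BEDPE file.

    Strand columns encode retained sides: "+" -> left, "-" -> right.  The
    breakend position used is the BEDPE end coordinate minus one for "+"
    records (last retained base) and the start for "-" records; for the
    single-base intervals produced by most SV callers both collapse to the
    interval start.
    """
    junctions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(
                    f"{path}: line {lineno}: BEDPE needs 10 columns, got {len(f)}"
                )
            c1, s1, e1, c2, s2, e2, name, score, st1, st2 = f[:10]
            try:
                s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if min(s1, s2) < 0:
                raise ValueError(f"{path}: line {lineno}: negative coordinates")
            if st1 not in _STRAND_TO_SIDE or st2 not in _STRAND_TO_SIDE:
                raise ValueError(
                    f"{path}: line {lineno}: strands must be +/- "
                    f"(got {st1!r}, {st2!r})"
                )
            support = int(score) if score not in (".", "") else 0
            a = Breakend(c1, e1 - 1 if st1 == "+" else s1, _STRAND_TO_SIDE[st1])
            b = Breakend(c2, e2 - 1 if st2 == "+" else s2, _STRAND_TO_SIDE[st2])
            junctions.append(Junction(a, b, support=support, name=name))
    return junctions


def write_bedpe(junctions: Iterable[Junction], path) -> None:
    side_to_strand = {"left": "+", "right": "-"}
    with open(path, "w") as fh:
        for j in junctions:
            row = [
                j.a.chrom,
                str(j.a.pos),
                str(j.a.pos + 1),
                j.b.chrom,
                str(j.b.pos),
                str(j.b.pos + 1),
                j.name,
                str(j.support),
                side_to_strand[j.a.retained_side],
                side_to_strand[j.b.retained_side],
            ]
            fh.write("\t".join(row) + "\n")


def _decode_bnd_alt(alt: str) -> tuple[str, int, str, str]:
    """Decode a VCF BND ALT into (mate_chrom, mate_pos0, local_side, mate_side).

    ``t]p]``  -> local left,  mate left   (tail-to-tail partner)
    ``[p[t``  -> local right, mate right  (head-to-head partner)
    ``t[p[``  -> local left,  mate right
    ``]p]t``  -> local right, mate left
    """
    bracket = "]" if "]" in alt else "[" if "[" in alt else None
    if bracket is None or alt.count(bracket) != 2:
        raise ValueError(f"malformed BND ALT: {alt!r}")
    first, locus, last = alt.split(bracket)
    if ":" not in locus:
        raise ValueError(f"malformed BND ALT locus: {alt!r}")
    mate_chrom, mate_pos = locus.rsplit(":", 1)
    mate_pos0 = int(mate_pos) - 1
    t_first = first != ""  # replacement sequence precedes the bracket
    if t_first and bracket == "]":
        local_side, mate_side = "left", "left"
    elif not t_first and bracket == "[":
        local_side, mate_side = "right", "right"
    elif t_first and bracket == "[":
        local_side, mate_side = "left", "right"
    else:  # ]p]t
        local_side, mate_side = "right", "left"
    return mate_chrom, mate_pos0, local_side, mate_side


def read_vcf_bnd(path) -> list[Junction]:
    """Read BND-style breakend records from a VCF and pair mates.

    Mates are matched via MATEID when present, otherwise by reciprocal
    coordinates.  Unmated records produce a warning and are skipped.
    """
    from cyvcf2 import VCF

    records = {}
    order = []
    for var in VCF(str(path)):
        if var.INFO.get("SVTYPE") not in (None, "BND"):
            continue
        alt = var.ALT[0] if var.ALT else ""
        if "[" not in alt and "]" not in alt:
            continue
        rid = var.ID or f"{var.CHROM}:{var.POS}"
        mateid = var.INFO.get("MATEID")
        records[rid] = (var.CHROM, var.POS - 1, alt, mateid, var.INFO.get("SUPPORT"))
        order.append(rid)

    junctions = []
    seen = set()
    for rid in order:
        if rid in seen:
            continue
        chrom, pos, alt, mateid, support = records[rid]
        mate_chrom, mate_pos, local_side, mate_side = _decode_bnd_alt(alt)
        mate_rid = None
        if mateid is not None:
            if mateid in records:
                mate_rid = mateid
            else:
                warnings.warn(f"unmatched MATEID {mateid!r} for record {rid}; skipped")
                seen.add(rid)
                continue
        else:
            for other, (oc, op, *_rest) in records.items():
                if other != rid and other not in seen and oc == mate_chrom and op == mate_pos:
                    mate_rid = other
                    break
        if mate_rid is not None:
            seen.add(mate_rid)
        seen.add(rid)
        a = Breakend(chrom, pos, local_side)
        b = Breakend(mate_chrom, mate_pos, mate_side)
        junctions.append(
            Junction(a, b, support=int(support) if support else 0, name=rid)
        )
    return junctions


# -- FGFR1 window rule ------------------------------------------------------

INTRAGENIC = "intragenic"
UPSTREAM_WINDOW = "upstream_window"
OUTSIDE = "outside"


def assign_fgfr1_window(
    j: Junction,
    fixture: GeneFixture,
    window_bp: int = DEFAULT_UPSTREAM_WINDOW_BP,
) -> str:
    """Classify a junction relative to the FGFR1 gene body and its
    strand-aware upstream window.

    Gene-body overlap takes precedence; the upstream window is the
    half-open genomic interval (TSS, TSS + window_bp] for the minus-strand
    gene (upstream = higher coordinates), mirrored for plus strand.
    """
    tr = fixture.transcript
    span = tr.span
    tss = fixture.tss
    for be in j.breakends():
        if be.chrom == span.chrom and span.contains(be.pos):
            return INTRAGENIC
    for be in j.breakends():
        if be.chrom != span.chrom:
            continue
        if tr.strand == "-":
            if tss < be.pos <= tss + window_bp:
                return UPSTREAM_WINDOW
        else:
            if tss - window_bp <= be.pos < tss:
                return UPSTREAM_WINDOW
    return OUTSIDE


# -- NSD3 disruption --------------------------------------------------------


@dataclass
class NSD3Evidence:
    """Evidence backing an NSD3-disruption call."""

    disrupted: bool
    junctions: list[Junction] = field(default_factory=list)
    affected_exons: Optional[tuple[int, int]] = None
    reason: str = "no junction affects the NSD3 ORF"


def call_nsd3_disruption(
    junctions: Iterable[Junction],
    fixture: GeneFixture,
) -> NSD3Evidence:
    """Call NSD3 destroyed when a junction separates or deletes the
    SET-domain-encoding exons from the promoter-proximal exons.

    Triggers: (i) an intragenic junction whose affected exon range
    intersects the SET exons or whose breakend lies in the ORF 5' of the
    SET-domain end; (ii) a junction with exactly one breakend inside the
    ORF upstream of the SET-domain end (fusion/translocation separating
    the downstream exons).
    """
    tr = fixture.transcript
    span = tr.span
    set_first, set_last = domain_exon_span(fixture, fixture.domain("SET"))

    def tx_exon(pos: int) -> Optional[float]:
        """Transcript-order exon coordinate (intron k/k+1 -> k + 0.5)."""
        loc = exon_index_of(tr, pos)
        if loc.kind == "exon":
            return float(loc.exon)
        if loc.kind == "intron":
            return loc.exon + 0.5
        return None

    hits = []
    affected: Optional[tuple[int, int]] = None
    for j in junctions:
        inside = [
            be for be in j.breakends()
            if be.chrom == span.chrom and span.contains(be.pos)
        ]
        if not inside:
            continue
        if len(inside) == 2:
            e1, e2 = tx_exon(inside[0].pos), tx_exon(inside[1].pos)
            if e1 is None or e2 is None:
                continue
            lo, hi = sorted((e1, e2))
            # exons strictly inside the bracket are removed/rearranged
            first_aff = int(lo) + 1 if lo == int(lo) else int(lo + 0.5) + 1
            last_aff = int(hi) - 1 if hi == int(hi) else int(hi + 0.5)
            if first_aff <= last_aff and not (
                last_aff < set_first or first_aff > set_last
            ):
                hits.append(j)
                affected = (first_aff, last_aff)
            elif lo <= set_last:  # breakend 5' of SET end separates SET
                hits.append(j)
                affected = (first_aff, tr.n_exons)
        else:
            e = tx_exon(inside[0].pos)
            if e is None:
                continue
            if e <= set_last:
                hits.append(j)
                affected = (
                    int(e) if e == int(e) else int(e + 0.5),
                    tr.n_exons,
                )
    if hits:
        return NSD3Evidence(
            disrupted=True,
            junctions=hits,
            affected_exons=affected,
            reason=(
                f"junction(s) separate SET-domain exons {set_first}-{set_last} "
                "from the promoter-proximal exons"
            ),
        )
    return NSD3Evidence(disrupted=False)


# -- annotated output -------------------------------------------------------


def write_junction_tsv(
    junctions: Iterable[Junction],
    fixture_fgfr1: Optional[GeneFixture],
    path,
    window_bp: int = DEFAULT_UPSTREAM_WINDOW_BP,
    foldback_bp: int = DEFAULT_FOLDBACK_PROXIMITY_BP,
) -> None:
    """Write an annotated junction table."""
    junctions = list(junctions)
    foldback_set = {fb.junction for fb in detect_foldbacks(junctions, foldback_bp)}
    with open(path, "w") as fh:
        fh.write(
            "name\tchrom_a\tpos_a\tside_a\tchrom_b\tpos_b\tside_b\tsupport\t"
            "orientation_class\tfoldback\tfgfr1_window\tlow_confidence\n"
        )
        for j in junctions:
            window = (
                assign_fgfr1_window(j, fixture_fgfr1, window_bp)
                if fixture_fgfr1
                else "."
            )
            fh.write(
                "\t".join(
                    [
                        j.name,
                        j.a.chrom,
                        str(j.a.pos),
                        j.a.retained_side,
                        j.b.chrom,
                        str(j.b.pos),
                        j.b.retained_side,
                        str(j.support),
                        classify_junction(j),
                        str(j in foldback_set).lower(),
                        window,
                        str(j.low_confidence).lower(),
                    ]
                )
                + "\n"
            )
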