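"""Seeded synthetic-cohort generator.

Builds deterministic gene models on a synthetic chromosome arm plus
per-sample copy-number segments and junction lists exhibiting the
structural features the pipeline detects: BFB-stepped amplification with
fold-back junctions, planted intragenic or upstream tail-to-tail
rearrangements, kinase-deleting head-to-head events, NSD3-style
disruptions, and responder/nonresponder labels.

All randomness flows from one integer seed through a spawned generator
hierarchy (cohort -> sample -> event).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bfb import simulate_bfb
from .genome_model import GeneFixture, GenomicInterval, ProteinDomain, Transcript
from .rearrangements import Breakend, Junction, write_bedpe
from .robocop import CNSegment, write_seg

__all__ = [
    "ScenarioSpec",
    "SampleTruth",
    "make_gene_models",
    "simulate_sample",
    "simulate_cohort",
    "SYNTHETIC_CHROM",
]

SYNTHETIC_CHROM = "chrS"
_ARM_FGFR1_MID = 20_000_000

SCENARIOS = (
    "deltaEC_FGFR1",
    "FGFR1_centered",
    "non_centered",
    "FGFR1_inactivated",
)

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA_NO_MET = "ALSGVTKRPEDNQHFYWCI"


@dataclass
class ScenarioSpec:
    """Parameters for one scenario group of a synthetic cohort."""

    scenario: str
    n_samples: int
    n_segments: int = 8
    min_cycles: int = 2
    max_cycles: int = 4
    nsd3_disruption_prob: float = 0.0
    jitter_bp: int = 0
    p_responder_dependent: float = 1.0
    p_responder_other: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for p in (self.nsd3_disruption_prob, self.p_responder_dependent,
                  self.p_responder_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.min_cycles <= self.max_cycles:
            raise ValueError("need 0 <= min_cycles <= max_cycles")


@dataclass
class SampleTruth:
    """Ground-truth record for one simulated sample."""

    sample_id: str
    category: str
    response: str
    planted_junction: Optional[tuple[int, int]]
    nsd3_disrupted: bool
    bfb_string: list[int]
    bfb_cycles: int
    telomeric_loss: bool


def _back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def _synth_protein(rng: np.random.Generator, n_aa: int, met_positions: set[int]) -> str:
    out = []
    for i in range(1, n_aa + 1):
        if i in met_positions:
            out.append("M")
        else:
            out.append(_AA_NO_MET[int(rng.integers(0, len(_AA_NO_MET)))])
    return "".join(out)


def _build_transcript(
    gene: str,
    strand: str,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    utr5: int,
    utr3: int,
    cds: str,
    anchor: int,
) -> Transcript:
    """Lay a transcript onto the synthetic arm.

    ``exon_lengths`` are CDS-only lengths in transcription order for the
    coding exons; a UTR-only exon 1 and UTR tails are added.  ``anchor``
    is the genomic start (plus strand) or end (minus strand) of the gene.
    """
    tx_exon_lengths = [utr5] + list(exon_lengths)
    tx_exon_lengths[-1] += utr3
    if strand == "+":
        exons = []
        cur = anchor
        for i, L in enumerate(tx_exon_lengths):
            exons.append(GenomicInterval(SYNTHETIC_CHROM, cur, cur + L, strand))
            cur += L + (intron_lengths[i] if i < len(intron_lengths) else 0)
        cds_start = exons[1].start
    else:
        exons = []
        cur = anchor
        for i, L in enumerate(tx_exon_lengths):
            exons.append(GenomicInterval(SYNTHETIC_CHROM, cur - L, cur, strand))
            cur -= L + (intron_lengths[i] if i < len(intron_lengths) else 0)
        cds_start = exons[1].end - 1
    tr = Transcript(gene, SYNTHETIC_CHROM, strand, exons, cds_start=cds_start,
                    cds_sequence=cds)
    # locate the last coding base by walking the spliced transcript
    cds_tx_start = tr.genomic_to_tx(cds_start)
    assert cds_tx_start is not None
    tr.cds_end = tr.tx_to_genomic(cds_tx_start + len(cds) - 1)
    return tr


def make_gene_models(seed: int) -> dict[str, GeneFixture]:
    """Deterministic synthetic FGFR1-like and NSD3-like gene fixtures.

    The FGFR1-like gene is minus strand with 18 exons, an ectodomain /
    TM / kinase domain table, and an in-frame ATG at the first codon of
    each of exons 4-10 so ectodomain-truncating breaks always find a
    downstream start.  The NSD3-like gene is plus strand with 24 exons
    and a SET domain projecting to exons 19-22.
    """
    rng = np.random.default_rng(seed)

    # FGFR1-like: 17 coding exons, 800 aa, in-frame ATG at the first codon
    # of each of exons 4..10 (aa 91, 141, ..., 391)
    exon_cds = [120] + [150] * 15 + [33]
    protein = _synth_protein(rng, 800, {1, 91, 141, 191, 241, 291, 341, 391})
    cds = _back_translate(protein)
    introns = [int(rng.integers(5_000, 10_000)) for _ in range(17)]
    fgfr1_tr = _build_transcript(
        "FGFR1S", "-", exon_cds, introns, utr5=300, utr3=800, cds=cds,
        anchor=_ARM_FGFR1_MID + int(rng.integers(-50_000, 50_000)),
    )
    fgfr1 = GeneFixture(
        transcript=fgfr1_tr,
        domains=[
            ProteinDomain("IG-I", 30, 120),
            ProteinDomain("acid box", 130, 142),
            ProteinDomain("IG-II", 160, 250),
            ProteinDomain("IG-III", 260, 350),
            ProteinDomain("TM", 395, 415),
            ProteinDomain("kinase", 420, 740),
        ],
    )

    # NSD3-like: 23 coding exons, 1400 aa, plus strand, ~4 Mb centromeric
    exon_cds = [150] + [180] * 21 + [273]
    protein = _synth_protein(rng, 1400, {1})
    cds = _back_translate(protein)
    introns = [int(rng.integers(8_000, 15_000)) for _ in range(23)]
    nsd3_tr = _build_transcript(
        "NSD3S", "+", exon_cds, introns, utr5=250, utr3=900, cds=cds,
        anchor=fgfr1_tr.span.start - 4_000_000 - int(rng.integers(0, 100_000)),
    )
    nsd3 = GeneFixture(
        transcript=nsd3_tr,
        domains=[
            ProteinDomain("PWWP", 270, 330),
            ProteinDomain("SET", 1020, 1240),
        ],
    )
    return {"FGFR1": fgfr1, "NSD3": nsd3}


def _fit_boundaries(
    rng: np.random.Generator,
    counts: Sequence[int],
    fixtures: dict[str, GeneFixture],
    centered: bool,
    window_bp: int = 400_000,
    margin: int = 50_000,
) -> list[int]:
    """Segment boundaries placing the maximal-count segment either
    narrowly over the FGFR1-like gene (centered) or as a broad plateau
    spanning it without a distinct center (non-centered).

    Fold-back junctions occur only at segment boundaries, so boundaries
    are kept out of the gene body (centered case) or out of the gene body
    plus its upstream window (non-centered case) and always out of the
    NSD3-like gene; otherwise simulated fold-backs would masquerade as
    planted rearrangements.
    """
    k = len(counts)
    m = int(np.argmax(counts))
    span = fixtures["FGFR1"].transcript.span
    tss = fixtures["FGFR1"].tss
    nspan = fixtures["NSD3"].transcript.span
    forbidden = [(nspan.start - margin, nspan.end + margin)]
    mid = (span.start + span.end) // 2
    if centered:
        w = int(rng.integers(400_000, 600_000))
        lo = mid - w // 2
        hi = lo + w
    else:
        lo = span.start - int(rng.integers(200_000, 800_000))
        w = int(rng.integers(1_500_000, 2_500_000))
        hi = max(lo + w, tss + window_bp + margin)
        forbidden.append((span.start - margin, tss + window_bp + margin))

    def push_down(b: int) -> int:
        for zs, ze in forbidden:
            if zs <= b <= ze:
                return zs - 1
        return b

    def push_up(b: int) -> int:
        for zs, ze in forbidden:
            if zs <= b <= ze:
                return ze + 1
        return b

    bounds = [lo, hi]
    for _ in range(m):
        bounds.insert(0, push_down(bounds[0] - int(rng.integers(200_000, 800_000))))
    for _ in range(k - m - 1):
        bounds.append(push_up(bounds[-1] + int(rng.integers(200_000, 800_000))))
    if bounds[0] < 0:
        shift = -bounds[0]
        bounds = [b + shift for b in bounds]
    return bounds


def _jitter(rng: np.random.Generator, pos: int, jitter_bp: int) -> int:
    if jitter_bp <= 0:
        return pos
    return max(0, pos + int(rng.integers(-jitter_bp, jitter_bp + 1)))


def simulate_sample(
    spec: ScenarioSpec,
    fixtures: dict[str, GeneFixture],
    seed: int,
    sample_id: str = "S0",
) -> tuple[list[CNSegment], list[Junction], SampleTruth]:
    """Simulate one sample for a scenario.

    BFB cycles produce stepped copy-number segments (cn = 1 homolog copy
    + per-segment BFB count) and fold-back junctions; the scenario's
    defining junction and optional NSD3-style disruption are planted on
    top, and the response label is drawn from the spec's label rule.
    """
    rng = np.random.default_rng(seed)
    fgfr1 = fixtures["FGFR1"]
    nsd3 = fixtures["NSD3"]
    tr = fgfr1.transcript

    n_cycles = int(rng.integers(spec.min_cycles, spec.max_cycles + 1))
    sim_seed = int(rng.integers(0, 2**31 - 1))
    first = simulate_bfb(spec.n_segments, n_cycles, seed=sim_seed)
    centered = spec.scenario in ("deltaEC_FGFR1", "FGFR1_centered")
    boundaries = _fit_boundaries(rng, first.count_vector.counts, fixtures, centered)
    sim = simulate_bfb(
        spec.n_segments,
        n_cycles,
        breaks=first.string.break_positions,
        boundaries=boundaries,
        chrom=SYNTHETIC_CHROM,
    )

    segments = [
        CNSegment(
            GenomicInterval(SYNTHETIC_CHROM, boundaries[i], boundaries[i + 1]),
            1.0 + sim.count_vector.counts[i],
        )
        for i in range(spec.n_segments)
    ]
    junctions = []
    for fb in sim.foldbacks:
        j = fb.junction
        if spec.jitter_bp > 0:
            pos = _jitter(rng, j.a.pos, spec.jitter_bp)
            j = Junction(
                Breakend(j.a.chrom, pos, j.a.retained_side),
                Breakend(j.b.chrom, pos, j.b.retained_side),
                support=j.support,
                name=j.name,
            )
        junctions.append(j)

    planted: Optional[tuple[int, int]] = None
    if spec.scenario == "deltaEC_FGFR1":
        # tail-to-tail with a breakend in a random intron among introns 1..9
        j_intron = int(rng.integers(1, 10))
        a_ex, b_ex = tr.exons[j_intron], tr.exons[j_intron - 1]
        pos = int((a_ex.end + b_ex.start) // 2)
        partner = tr.span.end - 1 + int(rng.integers(20_000, 300_000))
        planted = (pos, partner)
        junctions.append(
            Junction(
                Breakend(SYNTHETIC_CHROM, _jitter(rng, pos, spec.jitter_bp), "left"),
                Breakend(SYNTHETIC_CHROM, _jitter(rng, partner, spec.jitter_bp), "left"),
                support=int(rng.integers(10, 200)),
                name="planted_tt_intragenic",
            )
        )
    elif spec.scenario == "FGFR1_centered":
        tss = fgfr1.tss
        pos = tss + 1 + int(rng.integers(0, 380_000))
        partner = pos + int(rng.integers(10_000, 100_000))
        planted = (pos, partner)
        junctions.append(
            Junction(
                Breakend(SYNTHETIC_CHROM, _jitter(rng, pos, spec.jitter_bp), "left"),
                Breakend(SYNTHETIC_CHROM, _jitter(rng, partner, spec.jitter_bp), "left"),
                support=int(rng.integers(10, 200)),
                name="planted_tt_upstream",
            )
        )
    elif spec.scenario == "FGFR1_inactivated":
        # head-to-head deleting the kinase-encoding 3' exons: breakend in
        # intron 5/6, high-coordinate flanks retained on the minus strand
        a_ex, b_ex = tr.exons[5], tr.exons[4]
        pos = int((a_ex.end + b_ex.start) // 2)
        partner = tr.span.start - int(rng.integers(100_000, 500_000))
        planted = (pos, partner)
        junctions.append(
            Junction(
                Breakend(SYNTHETIC_CHROM, _jitter(rng, pos, spec.jitter_bp), "right"),
                Breakend(SYNTHETIC_CHROM, max(0, _jitter(rng, partner, spec.jitter_bp)), "right"),
                support=int(rng.integers(10, 200)),
                name="planted_hh_kinase_del",
            )
        )

    nsd3_disrupted = False
    if rng.random() < spec.nsd3_disruption_prob:
        nsd3_disrupted = True
        ntr = nsd3.transcript
        intron_pos = int((ntr.exons[14].end + ntr.exons[15].start) // 2)
        junctions.append(
            Junction(
                Breakend(SYNTHETIC_CHROM, _jitter(rng, intron_pos, spec.jitter_bp), "left"),
                Breakend(SYNTHETIC_CHROM, _jitter(rng, ntr.span.end + 5_000, spec.jitter_bp), "right"),
                support=int(rng.integers(10, 100)),
                name="planted_nsd3_del",
            )
        )

    dependent = spec.scenario in ("deltaEC_FGFR1", "FGFR1_centered")
    p_resp = spec.p_responder_dependent if dependent else spec.p_responder_other
    response = "responder" if rng.random() < p_resp else "nonresponder"

    truth = SampleTruth(
        sample_id=sample_id,
        category=spec.scenario,
        response=response,
        planted_junction=planted,
        nsd3_disrupted=nsd3_disrupted,
        bfb_string=list(sim.string.symbols),
        bfb_cycles=n_cycles,
        telomeric_loss=sim.telomeric_loss,
    )
    return segments, junctions, truth


def simulate_cohort(
    specs: Sequence[ScenarioSpec],
    seed: int,
    out_dir,
    fixtures: Optional[dict[str, GeneFixture]] = None,
) -> dict:
    """Simulate a cohort and write SEG TSV, BEDPE, labels TSV and truth
    JSON under ``out_dir``.  Deterministic for a given (specs, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fixtures is None:
        fixtures = make_gene_models(seed)
    ss = np.random.SeedSequence(seed)
    seg_by_sample: dict[str, list[CNSegment]] = {}
    all_junctions: list[Junction] = []
    labels: list[tuple[str, str]] = []
    truths: list[SampleTruth] = []
    idx = 0
    for spec in specs:
        child_seeds = ss.spawn(1)[0].generate_state(max(spec.n_samples, 1))
        for i in range(spec.n_samples):
            sid = f"SYN{idx:03d}"
            idx += 1
            segs, juncs, truth = simulate_sample(
                spec, fixtures, int(child_seeds[i]), sample_id=sid
            )
            seg_by_sample[sid] = segs
            for j in juncs:
                all_junctions.append(
                    Junction(j.a, j.b, support=j.support, name=f"{sid}:{j.name}")
                )
            labels.append((sid, truth.response))
            truths.append(truth)

    write_seg(seg_by_sample, out / "segments.seg.tsv")
    write_bedpe(all_junctions, out / "junctions.bedpe")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("sample\tresponse\n")
        for sid, resp in labels:
            fh.write(f"{sid}\t{resp}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1, default=list)
    return {
        "n_samples": idx,
        "segments": seg_by_sample,
        "junctions": all_junctions,
        "labels": dict(labels),
        "truth": truths,
    }
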