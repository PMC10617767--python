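"""Per-sample integration and cohort-level association testing.

``call_sample`` folds junction and copy-number evidence into one of four
amplicon categories with a predicted FGFR-dependency flag;
``cohort_association`` runs the two-sided Fisher's exact test of a
rearrangement flag against responder status.  The bundled pooled-cohort
fixture (21 models: 9 responders, 12 nonresponders) reproduces the
published pooled analysis.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy import stats

from . import bfb as bfb_mod
from .genome_model import GeneFixture, load_fixture
from .orf_predictor import NotIntragenicError, predict_variant
from .rearrangements import (
    DEFAULT_UPSTREAM_WINDOW_BP,
    INTRAGENIC,
    TAIL_TO_TAIL,
    UPSTREAM_WINDOW,
    Breakend,
    Junction,
    assign_fgfr1_window,
    call_nsd3_disruption,
    detect_foldbacks,
)
from .robocop import CNSegment

logger = logging.getLogger(__name__)

__all__ = [
    "SampleCall",
    "ContingencyTable2x2",
    "call_sample",
    "fisher_exact_2x2",
    "cohort_association",
    "load_pooled_cohort",
    "CATEGORY_DELTA_EC",
    "CATEGORY_CENTERED",
    "CATEGORY_NON_CENTERED",
    "CATEGORY_INACTIVATED",
]

CATEGORY_DELTA_EC = "deltaEC_FGFR1"
CATEGORY_CENTERED = "FGFR1_centered"
CATEGORY_NON_CENTERED = "non_centered"
CATEGORY_INACTIVATED = "FGFR1_inactivated"

DEPENDENT_CATEGORIES = {CATEGORY_DELTA_EC, CATEGORY_CENTERED}


@dataclass
class SampleCall:
    """Integrated per-sample call."""

    sample_id: str
    response: str = "unknown"
    has_intragenic_TT: bool = False
    has_upstream_TT: bool = False
    nsd3_disrupted: bool = False
    fgfr1_kinase_deleted: bool = False
    bfb_confidence: Optional[str] = None
    category: str = CATEGORY_NON_CENTERED
    predicted_dependency: bool = False
    no_amplicon: bool = False
    no_evidence: bool = False

    def flag(self, name: str) -> bool:
        if name == "tt_in_or_near_fgfr1":
            return self.has_intragenic_TT or self.has_upstream_TT
        return bool(getattr(self, name))

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "response": self.response,
            "has_intragenic_TT": self.has_intragenic_TT,
            "has_upstream_TT": self.has_upstream_TT,
            "nsd3_disrupted": self.nsd3_disrupted,
            "fgfr1_kinase_deleted": self.fgfr1_kinase_deleted,
            "bfb_confidence": self.bfb_confidence,
            "category": self.category,
            "predicted_dependency": self.predicted_dependency,
            "no_amplicon": self.no_amplicon,
            "no_evidence": self.no_evidence,
        }


def call_sample(
    junctions: Sequence[Junction],
    segments: Optional[Sequence[CNSegment]],
    fixtures: dict[str, GeneFixture],
    sample_id: str = ".",
    response: str = "unknown",
    window_bp: int = DEFAULT_UPSTREAM_WINDOW_BP,
    bfb_baseline: float = bfb_mod.DEFAULT_HOMOLOG_BASELINE,
    bfb_max_cycles: int = 8,
) -> SampleCall:
    """Integrate junctions and copy-number segments into a sample call.

    Category precedence: intragenic tail-to-tail with retained kinase ->
    deltaEC_FGFR1; kinase-deleting rearrangement -> FGFR1_inactivated;
    upstream-window tail-to-tail -> FGFR1_centered; otherwise
    non_centered.  NSD3 disruption and BFB confidence are annotations.
    """
    fgfr1 = fixtures["FGFR1"]
    call = SampleCall(sample_id=sample_id, response=response)
    if not junctions:
        call.no_evidence = True

    delta_ec = False
    for j in junctions:
        window = assign_fgfr1_window(j, fgfr1, window_bp)
        is_tt = j.orientation_class == TAIL_TO_TAIL
        if window == INTRAGENIC:
            try:
                variant = predict_variant(fgfr1, j)
            except NotIntragenicError:
                variant = None
            if variant is not None and not variant.kinase_retained:
                call.fgfr1_kinase_deleted = True
            if is_tt:
                call.has_intragenic_TT = True
                if variant is not None and variant.kinase_retained:
                    delta_ec = True
        elif window == UPSTREAM_WINDOW and is_tt:
            call.has_upstream_TT = True

    if "NSD3" in fixtures:
        call.nsd3_disrupted = call_nsd3_disruption(junctions, fixtures["NSD3"]).disrupted

    if segments:
        chrom = fgfr1.transcript.chrom
        chr_segs = sorted(
            (s for s in segments if s.interval.chrom == chrom),
            key=lambda s: s.interval.start,
        )
        if chr_segs:
            observed = [s.cn for s in chr_segs]
            foldback_support = bool(detect_foldbacks(junctions))
            adj = [max(0.0, x - bfb_baseline) for x in observed]
            rounded = tuple(int(round(x)) for x in adj)
            telomeric_loss = bool(rounded) and rounded[-1] == 0
            decision = bfb_mod.is_bfb_count_vector(rounded, max_cycles=bfb_max_cycles)
            if decision is True:
                bcall = bfb_mod.BFBCall(
                    observed=tuple(observed),
                    approximation=bfb_mod.CountVector(rounded),
                    log_poisson_likelihood=sum(
                        bfb_mod._log_poisson(x, lam) for x, lam in zip(adj, rounded)
                    ),
                    n_segments_in_approximation=len(rounded),
                    foldback_support=foldback_support,
                    telomeric_loss=telomeric_loss,
                )
                call.bfb_confidence = bfb_mod.bfb_confidence(bcall)
            elif decision is False:
                call.bfb_confidence = "excluded"
            else:
                call.bfb_confidence = "ambiguous"
        else:
            call.no_amplicon = True
    elif segments is not None:
        call.no_amplicon = True

    if delta_ec:
        call.category = CATEGORY_DELTA_EC
    elif call.fgfr1_kinase_deleted:
        call.category = CATEGORY_INACTIVATED
    elif call.has_upstream_TT:
        call.category = CATEGORY_CENTERED
    else:
        call.category = CATEGORY_NON_CENTERED
    call.predicted_dependency = call.category in DEPENDENT_CATEGORIES
    return call


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = response (responder / nonresponder), columns = flag (+ / -)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value (minimum-likelihood convention:
    the sum of hypergeometric probabilities of all same-margin tables no
    more probable than the observed one)."""
    if (t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0):
        return 1.0
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


@dataclass
class AssociationResult:
    table: ContingencyTable2x2
    p_value: Optional[float]
    responder_fraction: float
    nonresponder_fraction: float
    n_excluded_unknown: int = 0


def cohort_association(
    calls: Iterable[SampleCall],
    flag: str = "tt_in_or_near_fgfr1",
) -> AssociationResult:
    """Association of a rearrangement flag with responder status."""
    calls = list(calls)
    known = [c for c in calls if c.response in ("responder", "nonresponder")]
    n_unknown = len(calls) - len(known)
    if n_unknown:
        logger.info("excluding %d samples with unknown response", n_unknown)
    resp = [c for c in known if c.response == "responder"]
    nonresp = [c for c in known if c.response == "nonresponder"]
    a = sum(c.flag(flag) for c in resp)
    b = len(resp) - a
    c_ = sum(c.flag(flag) for c in nonresp)
    d = len(nonresp) - c_
    table = ContingencyTable2x2(a, b, c_, d)
    p: Optional[float]
    if len(resp) < 2 or len(nonresp) < 2:
        logger.warning("fewer than 2 samples per response group; p undefined")
        p = None
    else:
        p = fisher_exact_2x2(table)
    return AssociationResult(
        table=table,
        p_value=p,
        responder_fraction=a / len(resp) if resp else math.nan,
        nonresponder_fraction=c_ / len(nonresp) if nonresp else math.nan,
        n_excluded_unknown=n_unknown,
    )


# -- bundled pooled cohort --------------------------------------------------


def load_pooled_cohort() -> tuple[dict[str, list[Junction]], dict[str, str]]:
    """The bundled 21-model pooled cohort: junction lists and response
    labels keyed by sample ID."""
    data = importlib.resources.files("ampliconlens.data")
    labels: dict[str, str] = {}
    for line in (data / "pooled_cohort_labels.tsv").read_text().splitlines()[1:]:
        if line.strip():
            sample, response = line.split("\t")
            labels[sample] = response
    junctions: dict[str, list[Junction]] = {s: [] for s in labels}
    for line in (data / "pooled_cohort_junctions.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        (sample, name, ca, pa, sa, cb, pb, sb, support, _prov) = line.split("\t")
        junctions[sample].append(
            Junction(
                Breakend(ca, int(pa), sa),
                Breakend(cb, int(pb), sb),
                support=int(support),
                name=name,
            )
        )
    return junctions, labels


def pooled_cohort_calls() -> list[SampleCall]:
    """Run call_sample over the bundled pooled cohort."""
    fixtures = {"FGFR1": load_fixture("FGFR1"), "NSD3": load_fixture("NSD3")}
    junctions, labels = load_pooled_cohort()
    return [
        call_sample(junctions[s], None, fixtures, sample_id=s, response=labels[s])
        for s in labels
    ]
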