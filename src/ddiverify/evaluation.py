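"""Evaluation against known complexes and GO molecular-function annotation.

Predicted complexes rarely match a known complex exactly, so matching uses
the Bader overlap criterion

    V(P, K) = |Np ∩ Nk|^2 / (|Np| * |Nk|)

with a prediction counted as matched when its best V over the known catalog
is strictly greater than the threshold (default 0.25). Precision is the
fraction of predictions that match some known complex; recall is the
fraction of known complexes matched by at least one prediction — several
predictions may match the same known complex.

Functional coherence is measured as the fraction of within-complex protein
pairs sharing at least one molecular-function GO term; proteins that are
unannotated or carry only the "molecular function unknown" placeholders
(GO:0003674 / GO:0005554) are excluded from the denominator. The same
annotation drives function suggestions for uncharacterized proteins and the
accounting of false negatives attributable to the exclusivity assumption.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ComplexCatalog, DDICatalog, DomainAnnotation, GOAnnotation

logger = logging.getLogger(__name__)

DEFAULT_V_THRESHOLD = 0.25


def _members(prediction) -> frozenset[str]:
    """Accept VerifiedComplex, CandidateComplex, or a bare protein set."""
    m = getattr(prediction, "members", prediction)
    return frozenset(m)


def overlap_score(predicted: Iterable[str], known: Iterable[str]) -> float:
    """Bader overlap V = |Np ∩ Nk|^2 / (|Np| |Nk|), in [0, 1]."""
    np_, nk = frozenset(predicted), frozenset(known)
    if not np_ or not nk:
        raise ValueError("overlap_score requires two non-empty sets")
    return len(np_ & nk) ** 2 / (len(np_) * len(nk))


@dataclass(frozen=True)
class EvaluationReport:
    predicted: int
    known: int
    matched_predicted: int
    matched_known: int
    precision: float
    recall: float
    #: per-prediction (best-matching known complex id or None, best V)
    best_matches: tuple[tuple[str | None, float], ...] = ()

    def summary(self) -> str:
        return (
            f"predicted\t{self.predicted}\n"
            f"known\t{self.known}\n"
            f"matched_predicted\t{self.matched_predicted}\n"
            f"matched_known\t{self.matched_known}\n"
            f"precision\t{self.precision:.4f}\n"
            f"recall\t{self.recall:.4f}"
        )


def precision_recall(
    predicted: Sequence,
    known: ComplexCatalog,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> EvaluationReport:
    """Precision/recall of predictions against the known-complex catalog."""
    if not predicted:
        logger.warning("precision_recall: empty prediction list")
    best: list[tuple[str | None, float]] = []
    matched_known: set[str] = set()
    n_matched_pred = 0
    for pred in predicted:
        members = _members(pred)
        best_id, best_v = None, 0.0
        hits: list[str] = []
        for cid, kmembers in known:
            v = overlap_score(members, kmembers) if members else 0.0
            if v > best_v:
                best_id, best_v = cid, v
            if v > threshold:
                hits.append(cid)
        if best_v <= threshold:
            best_id = None
        best.append((best_id, best_v))
        if hits:
            n_matched_pred += 1
            matched_known.update(hits)
    n_pred, n_known = len(predicted), len(known)
    return EvaluationReport(
        predicted=n_pred,
        known=n_known,
        matched_predicted=n_matched_pred,
        matched_known=len(matched_known),
        precision=n_matched_pred / n_pred if n_pred else 0.0,
        recall=len(matched_known) / n_known if n_known else 0.0,
        best_matches=tuple(best),
    )


def same_function_ratio(complexes: Sequence, go: GOAnnotation) -> float | None:
    """Fraction of eligible within-complex pairs sharing a function term.

    A pair is eligible when both proteins carry at least one known
    molecular-function term; unannotated and unknown-function proteins do
    not enter the denominator. Returns None when no pair is eligible.
    """
    eligible = sharing = 0
    for cpx in complexes:
        members = sorted(_members(cpx))
        for a, b in itertools.combinations(members, 2):
            ta, tb = go.known_terms_of(a), go.known_terms_of(b)
            if not ta or not tb:
                continue
            eligible += 1
            if ta & tb:
                sharing += 1
    if eligible == 0:
        return None
    return sharing / eligible


@dataclass(frozen=True)
class FalseNegativeReport:
    """Accounting of known complexes missed because of exclusivity.

    ``beta`` counts known complexes recovered by the unverified step-1
    predictions (true positives of the existing method); ``alpha`` counts
    those that verification then lost even though their members carry
    cognate DDI annotation — the net cost of the one-interface-one-partner
    assumption. Complexes with no DDI annotation at all are subtracted,
    since no verification scheme could keep them.
    """

    fn_ours: int
    fn_existing: int
    net_fn: int
    no_ddi_excluded: int
    alpha: int
    beta: int

    @property
    def ratio(self) -> float:
        return self.alpha / self.beta if self.beta else 0.0

    def summary(self) -> str:
        return (
            f"fn_ours\t{self.fn_ours}\n"
            f"fn_existing\t{self.fn_existing}\n"
            f"net_fn\t{self.net_fn}\n"
            f"no_ddi_excluded\t{self.no_ddi_excluded}\n"
            f"alpha\t{self.alpha}\n"
            f"beta\t{self.beta}\n"
            f"ratio\t{self.ratio:.4f}"
        )


def _has_ddi_annotation(
    members: frozenset[str], domains: DomainAnnotation, ddis: DDICatalog
) -> bool:
    """True when any member pair carries a cataloged domain-type pair."""
    for a, b in itertools.combinations(sorted(members), 2):
        for ia in domains.domains_of(a):
            for ib in domains.domains_of(b):
                if ddis.allows(ia.domain_type, ib.domain_type):
                    return True
    return False


def false_negative_report(
    existing_predictions: Sequence,
    our_predictions: Sequence,
    known: ComplexCatalog,
    domains: DomainAnnotation,
    ddis: DDICatalog,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> FalseNegativeReport:
    """Estimate net false negatives caused by the exclusivity assumption.

    ``our_predictions`` are assumed to be the verified subset of
    ``existing_predictions``.
    """

    def matched_ids(predictions: Sequence) -> set[str]:
        hit: set[str] = set()
        for pred in predictions:
            members = _members(pred)
            for cid, kmembers in known:
                if overlap_score(members, kmembers) > threshold:
                    hit.add(cid)
        return hit

    by_existing = matched_ids(existing_predictions)
    by_ours = matched_ids(our_predictions)
    all_ids = {cid for cid, _ in known}
    net = by_existing - by_ours
    no_ddi = {
        cid
        for cid in net
        if not _has_ddi_annotation(dict(known)[cid], domains, ddis)
    }
    return FalseNegativeReport(
        fn_ours=len(all_ids - by_ours),
        fn_existing=len(all_ids - by_existing),
        net_fn=len(net),
        no_ddi_excluded=len(no_ddi),
        alpha=len(net) - len(no_ddi),
        beta=len(by_existing),
    )


def suggest_functions(
    complexes: Sequence, go: GOAnnotation
) -> list[tuple[frozenset[str], str, frozenset[str]]]:
    """Propose functions for uncharacterized proteins by complex membership.

    For each complex containing exactly one unknown-function protein whose
    remaining members are all characterized and share at least one common
    molecular-function term, emit (complex members, protein, shared terms).
    """
    out: list[tuple[frozenset[str], str, frozenset[str]]] = []
    for cpx in complexes:
        members = _members(cpx)
        unknown = sorted(p for p in members if go.is_uncharacterized(p))
        if len(unknown) != 1:
            continue
        others = sorted(members - {unknown[0]})
        if not others:
            continue
        term_sets = [go.known_terms_of(p) for p in others]
        if any(not t for t in term_sets):
            continue
        shared = frozenset(frozenset.intersection(*term_sets))
        if shared:
            out.append((members, unknown[0], shared))
    return out
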