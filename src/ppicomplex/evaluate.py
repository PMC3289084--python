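"""Benchmarking predicted complexes against a reference complex set.

A prediction A matches a reference complex B when their overlap score

    OS(A, B) = |V_A ∩ V_B|^2 / (|V_A| * |V_B|)

exceeds a threshold (default 0.20, strict inequality).  Predictions matching
at least one reference complex are *matched clusters*; reference complexes
matched by at least one prediction are *matched complexes*.  Then

    precision = M_cluster / P_cluster        (over retained predictions)
    recall    = M_complexes / T_complexes    (over retained references)
    f         = 2 P R / (P + R)

Clusters and complexes with fewer than four members are excluded before
counting: small sets match too easily by chance to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .network import ComplexSet

__all__ = ["EvalReport", "overlap_score", "f_measure", "score_predictions"]


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """MCODE-style overlap score |A∩B|²/(|A|·|B|); 1 iff the sets are equal."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Counts and rates of a benchmark comparison."""

    overlap_threshold: float
    min_size: int
    matched_clusters: int
    predicted_clusters: int
    matched_complexes: int
    true_complexes: int
    precision: float
    recall: float
    f_measure: float
    match_table: list[tuple[frozenset, Optional[str], float]] = field(
        default_factory=list
    )

    def summary(self) -> str:
        return (
            f"predicted clusters (size >= {self.min_size}): {self.predicted_clusters}\n"
            f"matched clusters:  {self.matched_clusters}\n"
            f"reference complexes: {self.true_complexes}\n"
            f"matched complexes: {self.matched_complexes}\n"
            f"precision: {self.precision:.3f}\n"
            f"recall:    {self.recall:.3f}\n"
            f"f-measure: {self.f_measure:.3f}"
        )


def score_predictions(
    predicted: Sequence[Iterable[str]],
    benchmark: ComplexSet,
    overlap_threshold: float = 0.20,
    min_size: int = 4,
) -> EvalReport:
    """Compare predictions to the benchmark via the overlap score.

    A prediction may match several complexes and vice versa; counts are of
    matched entities, not matched pairs.  The match table records, for each
    retained prediction, its best-matching complex and that overlap score.
    """
    preds = [frozenset(p) for p in predicted if len(frozenset(p)) >= min_size]
    refs = [(n, m) for n, m in benchmark if len(m) >= min_size]

    matched_refs: set[int] = set()
    matched_preds = 0
    table: list[tuple[frozenset, Optional[str], float]] = []
    for p in preds:
        best_name: Optional[str] = None
        best_os = 0.0
        hit = False
        for ref_idx, (name, members) in enumerate(refs):
            os_ = overlap_score(p, members)
            if os_ > best_os or best_name is None:
                best_name, best_os = name, os_
            if os_ > overlap_threshold:
                hit = True
                matched_refs.add(ref_idx)
        if hit:
            matched_preds += 1
        table.append((p, best_name, best_os))

    p_cluster = len(preds)
    t_complexes = len(refs)
    precision = matched_preds / p_cluster if p_cluster else 0.0
    recall = len(matched_refs) / t_complexes if t_complexes else 0.0
    return EvalReport(
        overlap_threshold=overlap_threshold,
        min_size=min_size,
        matched_clusters=matched_preds,
        predicted_clusters=p_cluster,
        matched_complexes=len(matched_refs),
        true_complexes=t_complexes,
        precision=precision,
        recall=recall,
        f_measure=f_measure(precision, recall),
        match_table=table,
    )
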