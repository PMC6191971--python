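"""Iterative multiple-model extraction.

Iteration 1 learns on the full matrix. Every accepted model (cross-validated
F-measure at or above the gate) contributes its genes to the cumulative
feature set; elimination combinations derived from those genes are queued,
and each later iteration removes one combination's columns before learning
again. The walk stops at the first satisfied criterion: the iteration cap,
sub-threshold results with nothing left to try, or an exhausted queue.

``strict`` mode keeps a single pending combination — the cumulative union of
all accepted genes — so iterations are linear and accepted models pairwise
disjoint in genes. ``loose`` mode explores the combination lattice
breadth-first (worst-case exponential) and therefore surfaces more
alternative models.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional

from camur.expression_io import ExpressionMatrix, validate_matrix
from camur.ripper import (
    LearnerParams,
    Metrics,
    RuleModel,
    cross_validate,
    evaluate_model,
    learn_model,
    resolve_positive_class,
)

STOP_MAX_ITERATIONS = "max_iterations"
STOP_F_BELOW_THRESHOLD = "f_below_threshold"
STOP_COMBINATIONS_EXHAUSTED = "combinations_exhausted"
CONTINUE = "continue"

EXHAUSTED = object()  # sentinel returned by next_elimination


@dataclass(frozen=True)
class EngineConfig:
    mode: str = "loose"
    max_iterations: int = 100
    min_f_measure: float = 0.8
    learner: LearnerParams = field(default_factory=LearnerParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("loose", "strict"):
            raise ValueError(f"mode must be 'loose' or 'strict', got {self.mode!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 <= self.min_f_measure <= 1.0):
            raise ValueError("min_f_measure must be in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "max_iterations": self.max_iterations,
            "min_f_measure": self.min_f_measure,
            "seed": self.seed,
            "learner": {
                "positive_class": self.learner.positive_class,
                "grow_fraction": self.learner.grow_fraction,
                "mdl_slack_bits": self.learner.mdl_slack_bits,
                "optimization_passes": self.learner.optimization_passes,
                "cv_folds": self.learner.cv_folds,
                "seed": self.learner.seed,
            },
        }


class EliminationState:
    """Pending / processed elimination combinations plus the cumulative
    accepted-gene set S."""

    def __init__(self) -> None:
        self.pending: deque[frozenset[str]] = deque([frozenset()])
        self.processed: set[frozenset[str]] = set()
        self.cumulative: set[str] = set()

    def pop(self) -> frozenset[str]:
        combo = self.pending.popleft()
        self.processed.add(combo)
        return combo

    def _enqueue(self, combo: frozenset[str]) -> bool:
        if combo in self.processed or combo in self.pending:
            return False
        self.pending.append(combo)
        return True


@dataclass
class IterationRecord:
    index: int  # 1-based; one learner invocation per record
    eliminated: tuple[str, ...]  # sorted gene ids removed before learning
    model: RuleModel
    cv_metrics: Metrics
    train_metrics: Metrics
    accepted: bool

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "eliminated": list(self.eliminated),
            "rule_text": self.model.text,
            "positive_class": self.model.positive_class,
            "default_class": self.model.default_class,
            "cv_metrics": self.cv_metrics.as_dict(),
            "train_metrics": self.train_metrics.as_dict(),
            "accepted": self.accepted,
        }


@dataclass
class RunResult:
    config: EngineConfig
    records: list[IterationRecord]
    stop_reason: str

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def accepted_records(self) -> list[IterationRecord]:
        return [r for r in self.records if r.accepted]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_records)

    def distinct_genes(self) -> set[str]:
        out: set[str] = set()
        for rec in self.accepted_records:
            out |= rec.model.genes()
        return out

    def to_manifest(self) -> dict:
        return {
            "config": self.config.as_dict(),
            "stop_reason": self.stop_reason,
            "totals": {
                "iterations": self.n_iterations,
                "accepted_models": self.n_accepted,
                "distinct_genes": sorted(self.distinct_genes()),
            },
            "records": [rec.as_dict() for rec in self.records],
        }

    def manifest_json(self) -> str:
        return json.dumps(self.to_manifest(), sort_keys=True, indent=2)


def extend_queue(state: EliminationState, mode: str, last: IterationRecord) -> int:
    """Queue the follow-up combinations implied by the last record.

    Returns the number of newly enqueued combinations. Rejected records
    contribute nothing (their genes are not considered).
    """
    if not last.accepted:
        return 0
    features = last.model.genes()
    state.cumulative |= features
    added = 0
    if mode == "strict":
        # one pending combination: everything accepted so far
        state.pending.clear()
        if state._enqueue(frozenset(state.cumulative)):
            added += 1
    else:
        base = frozenset(last.eliminated)
        for gene in sorted(features - set(base)):
            if state._enqueue(base | {gene}):
                added += 1
    return added


def next_elimination(state: EliminationState, mode: str,
                     last: Optional[IterationRecord] = None):
    """Advance the elimination walk: queue follow-ups of ``last`` and pop
    the next combination; EXHAUSTED when nothing is pending."""
    if last is not None:
        extend_queue(state, mode, last)
    if not state.pending:
        return EXHAUSTED
    return state.pop()


def stopping_check(state: EliminationState, records: list[IterationRecord],
                   cfg: EngineConfig) -> str:
    """First applicable stop reason, or CONTINUE.

    Checked in order: iteration cap; empty queue. An empty queue means
    sub-threshold results ended the walk when no model was ever accepted or
    the latest run fell below the gate; otherwise every combination was
    genuinely used up.
    """
    if not records:
        raise ValueError("stopping_check requires at least one record")
    if len(records) >= cfg.max_iterations:
        return STOP_MAX_ITERATIONS
    if not state.pending:
        if any(r.accepted for r in records) and records[-1].accepted:
            return STOP_COMBINATIONS_EXHAUSTED
        if any(r.accepted for r in records):
            return STOP_F_BELOW_THRESHOLD
        return STOP_F_BELOW_THRESHOLD
    return CONTINUE


def run_camur(m: ExpressionMatrix, cfg: EngineConfig = EngineConfig()) -> RunResult:
    """Run the learn / gate / eliminate loop until a stopping criterion fires."""
    report = validate_matrix(m)
    if not report.ok:
        codes = sorted({issue.code for issue in report.issues})
        raise ValueError(f"invalid matrix: {', '.join(codes)}")

    # resolve the positive class once on the full matrix so every iteration
    # and CV fold targets the same class
    pos, _ = resolve_positive_class(m, cfg.learner.positive_class)
    params = replace(cfg.learner, positive_class=pos,
                     seed=cfg.learner.seed if cfg.learner.seed else cfg.seed)

    state = EliminationState()
    records: list[IterationRecord] = []
    all_genes = set(m.gene_ids)

    combo = state.pop()  # iteration 1: the empty combination
    while True:
        view = m.drop_genes(combo) if combo else m
        model = learn_model(view, params)
        cv = cross_validate(view, params)
        train = evaluate_model(model, view)
        accepted = bool(model.conjunctions) and cv.f_measure >= cfg.min_f_measure
        record = IterationRecord(
            index=len(records) + 1,
            eliminated=tuple(sorted(combo)),
            model=model,
            cv_metrics=cv,
            train_metrics=train,
            accepted=accepted,
        )
        records.append(record)
        extend_queue(state, cfg.mode, record)

        # skip queued combinations that would leave no gene columns
        while state.pending and not (all_genes - state.pending[0]):
            state.pop()

        reason = stopping_check(state, records, cfg)
        if reason != CONTINUE:
            return RunResult(config=cfg, records=records, stop_reason=reason)
        combo = state.pop()
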