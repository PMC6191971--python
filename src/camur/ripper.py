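"""RIPPER-style induction of threshold-rule models on expression matrices.

A model is a disjunction of conjunctions of literals ``gene < t`` /
``gene >= t`` predicting one positive class; any uncovered sample gets the
default class. Learning follows the incremental reduced-error-pruning
scheme: a stratified grow/prune split, FOIL-gain greedy literal growth,
``(p - n) / (p + n)`` reduced-error pruning, a description-length budget on
ruleset growth, and optimization passes that try to replace or revise each
conjunction. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.model_selection import StratifiedKFold

from camur.expression_io import ExpressionMatrix

NEG_INF = float("-inf")

OP_LT = "<"
OP_GE = ">="
_OP_RANK = {OP_LT: 0, OP_GE: 1}


def _fmt_threshold(t: float) -> str:
    return format(float(t), ".6g")


@dataclass(frozen=True)
class Literal:
    """One threshold condition on one gene."""

    gene: str
    op: str  # '<' (strict) or '>=' (closed)
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OP_RANK:
            raise ValueError(f"unsupported operator {self.op!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        return value < self.threshold if self.op == OP_LT else value >= self.threshold

    def covers(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values < self.threshold if self.op == OP_LT else values >= self.threshold

    @property
    def text(self) -> str:
        return f"({self.gene} {self.op} {_fmt_threshold(self.threshold)})"


@dataclass(frozen=True)
class Conjunction:
    """AND of literals; covers a sample when every literal holds."""

    literals: tuple[Literal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "literals", tuple(self.literals))
        seen = set()
        for lit in self.literals:
            key = (lit.gene, lit.op)
            if key in seen:
                raise ValueError(f"duplicate literal on {key} in conjunction")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.literals)

    def genes(self) -> set[str]:
        return {lit.gene for lit in self.literals}

    def covers_matrix(self, m: ExpressionMatrix) -> np.ndarray:
        mask = np.ones(m.n_samples, dtype=bool)
        for lit in self.literals:
            mask &= lit.covers(m.column(lit.gene))
        return mask

    def covers_sample(self, sample: Mapping[str, float]) -> bool:
        for lit in self.literals:
            if lit.gene not in sample:
                raise KeyError(f"sample is missing gene {lit.gene!r}")
            if not lit.holds(sample[lit.gene]):
                return False
        return True

    @property
    def text(self) -> str:
        if len(self.literals) == 1:
            return self.literals[0].text
        return "(" + " AND ".join(lit.text for lit in self.literals) + ")"


@dataclass(frozen=True)
class RuleModel:
    """Disjunction of conjunctions predicting ``positive_class``."""

    positive_class: str
    default_class: str
    conjunctions: tuple[Conjunction, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "conjunctions", tuple(self.conjunctions))
        if self.positive_class.casefold() == self.default_class.casefold():
            raise ValueError("positive and default class must differ")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for conj in self.conjunctions:
            out |= conj.genes()
        return out

    def covers_matrix(self, m: ExpressionMatrix) -> np.ndarray:
        mask = np.zeros(m.n_samples, dtype=bool)
        for conj in self.conjunctions:
            mask |= conj.covers_matrix(m)
        return mask

    @property
    def text(self) -> str:
        if not self.conjunctions:
            return f"() => {self.positive_class}"
        body = " OR ".join(conj.text for conj in self.conjunctions)
        return f"{body} => {self.positive_class}"


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived scores for one positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def accuracy(self) -> float:
        d = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / d if d else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f_measure": self.f_measure, "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class LearnerParams:
    positive_class: str = "auto"
    grow_fraction: float = 2.0 / 3.0
    mdl_slack_bits: float = 64.0
    optimization_passes: int = 2
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.grow_fraction < 1.0):
            raise ValueError("grow_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


# --------------------------------------------------------------------------
# primitive operations

def candidate_thresholds(values: Sequence[float], labels: Sequence[bool]) -> list[float]:
    """Midpoints between consecutive distinct values whose label sets differ.

    ``labels[i]`` is True for positive samples. Only boundaries where the
    set of labels present changes can affect any coverage-based score, so
    only those midpoints are candidates.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError(f"{values.size} values but {labels.size} labels")
    if values.size == 0:
        return []
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    uniq, start = np.unique(v, return_index=True)
    if uniq.size < 2:
        return []
    bounds = np.append(start, v.size)
    out: list[float] = []
    prev_set = None
    for k in range(uniq.size):
        seg = y[bounds[k]:bounds[k + 1]]
        label_set = (bool(seg.any()), bool((~seg).any()))
        if prev_set is not None and label_set != prev_set:
            out.append((uniq[k - 1] + uniq[k]) / 2.0)
        prev_set = label_set
    return out


def foil_gain(p0: int, n0: int, p1: int, n1: int) -> float:
    """FOIL information gain of refining a rule from (p0, n0) to (p1, n1).

    Returns ``p1 * (log2(p1/(p1+n1)) - log2(p0/(p0+n0)))``; -inf when the
    refined rule covers no positives.
    """
    if min(p0, n0, p1, n1) < 0 or p1 > p0:
        raise ValueError("counts must be >= 0 with p1 <= p0")
    if p1 == 0:
        return NEG_INF
    return p1 * (math.log2(p1 / (p1 + n1)) - math.log2(p0 / (p0 + n0)))


def _counts(mask: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    return int(np.count_nonzero(mask & y)), int(np.count_nonzero(mask & ~y))


# --------------------------------------------------------------------------
# internal learner working on raw arrays

class _Data:
    """Array view of a matrix with a boolean positive-class vector."""

    def __init__(self, m: ExpressionMatrix, positive_class: str):
        self.matrix = m
        self.X = m.values
        key = positive_class.casefold()
        self.y = np.array([lab.casefold() == key for lab in m.labels], dtype=bool)
        self.genes = m.gene_ids

    def subset(self, idx: np.ndarray) -> "_SubData":
        return _SubData(self, idx)


class _SubData:
    def __init__(self, data: _Data, idx: np.ndarray):
        self.genes = data.genes
        self.X = data.X[idx]
        self.y = data.y[idx]


def _conj_mask(conj: Conjunction, X: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    col = {g: j for j, g in enumerate(genes)}
    mask = np.ones(X.shape[0], dtype=bool)
    for lit in conj.literals:
        mask &= lit.covers(X[:, col[lit.gene]])
    return mask


def _ruleset_mask(rules: Iterable[Conjunction], X: np.ndarray,
                  genes: Sequence[str]) -> np.ndarray:
    mask = np.zeros(X.shape[0], dtype=bool)
    for conj in rules:
        mask |= _conj_mask(conj, X, genes)
    return mask


def _best_literal(X: np.ndarray, y: np.ndarray, genes: Sequence[str],
                  covered: np.ndarray, used: set[tuple[str, str]]):
    """Highest-FOIL-gain literal over the currently covered samples.

    Ties broken by (lower column index, '<' before '>=', smaller threshold)
    so the search is a total order and the learner deterministic.
    """
    p0 = int(np.count_nonzero(y[covered]))
    n0 = int(np.count_nonzero(~y[covered]))
    if p0 == 0:
        return None
    base = math.log2(p0 / (p0 + n0))
    best = None  # (gain, col, op_rank, threshold, Literal)
    Xc, yc = X[covered], y[covered]
    for j, gene in enumerate(genes):
        v = Xc[:, j]
        thresholds = candidate_thresholds(v, yc)
        if not thresholds:
            continue
        order = np.argsort(v, kind="stable")
        sv, sy = v[order], yc[order]
        cum_pos = np.cumsum(sy)
        ts = np.asarray(thresholds)
        k = np.searchsorted(sv, ts, side="left")  # samples with value < t
        p_lt = np.where(k > 0, cum_pos[np.maximum(k - 1, 0)], 0).astype(float)
        n_lt = k - p_lt
        for op, p1s, n1s in (
            (OP_LT, p_lt, n_lt),
            (OP_GE, p0 - p_lt, (n0 - n_lt)),
        ):
            if (gene, op) in used:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                gains = np.where(
                    p1s > 0,
                    p1s * (np.log2(np.maximum(p1s, 1e-300) / np.maximum(p1s + n1s, 1e-300)) - base),
                    NEG_INF,
                )
            i = _argbest(gains, ts, op)
            if i is None:
                continue
            cand = (gains[i], -j, -_OP_RANK[op], -ts[i])
            if best is None or cand > best[0]:
                best = (cand, Literal(gene, op, float(ts[i])))
    if best is None:
        return None
    return best[1], best[0][0]


def _argbest(gains: np.ndarray, ts: np.ndarray, op: str):
    """Index of max gain; among equal gains prefer the smaller threshold."""
    finite = gains > NEG_INF
    if not finite.any():
        return None
    gmax = gains[finite].max()
    if gmax <= 0 and not math.isinf(gmax):
        # still return it; caller decides whether non-positive gain stops
        pass
    tie = np.nonzero(gains == gmax)[0]
    return int(tie[np.argmin(ts[tie])])


def grow_conjunction(grow: ExpressionMatrix | _SubData, positive_class: str | None = None,
                     params: LearnerParams | None = None) -> Conjunction:
    """Greedily append max-FOIL-gain literals until no negative is covered
    or no literal has positive gain."""
    if isinstance(grow, ExpressionMatrix):
        if positive_class is None:
            raise ValueError("positive_class required")
        data = _Data(grow, positive_class)
        X, y, genes = data.X, data.y, data.genes
    else:
        X, y, genes = grow.X, grow.y, grow.genes
    if not y.any():
        raise ValueError("grow set has no positive samples")

    covered = np.ones(X.shape[0], dtype=bool)
    literals: list[Literal] = []
    used: set[tuple[str, str]] = set()
    while np.count_nonzero(covered & ~y) > 0:
        found = _best_literal(X, y, genes, covered, used)
        if found is None:
            break
        lit, gain = found
        if gain <= 0:
            break
        literals.append(lit)
        used.add((lit.gene, lit.op))
        covered &= lit.covers(X[:, list(genes).index(lit.gene)])
    if not literals:
        # fall back to the single best literal even at non-positive gain is
        # not allowed; an empty conjunction signals "nothing grown"
        return Conjunction(())
    return Conjunction(tuple(literals))


def _prune_value(p: int, n: int) -> float:
    return (p - n) / (p + n) if (p + n) else -1.0


def prune_conjunction(conj: Conjunction, prune: ExpressionMatrix | _SubData,
                      positive_class: str | None = None) -> Conjunction:
    """Drop trailing literals while the prune-set value (p-n)/(p+n) does not
    decrease; ties prefer the shorter conjunction."""
    if isinstance(prune, ExpressionMatrix):
        if positive_class is None:
            raise ValueError("positive_class required")
        data = _Data(prune, positive_class)
        X, y, genes = data.X, data.y, data.genes
    else:
        X, y, genes = prune.X, prune.y, prune.genes
    if len(conj) == 0:
        return conj
    literals = list(conj.literals)
    current = _prune_value(*_counts(_conj_mask(Conjunction(tuple(literals)), X, genes), y))
    while len(literals) > 1:
        shorter = Conjunction(tuple(literals[:-1]))
        val = _prune_value(*_counts(_conj_mask(shorter, X, genes), y))
        if val >= current:
            literals.pop()
            current = val
        else:
            break
    return Conjunction(tuple(literals))


# --------------------------------------------------------------------------
# description length (only relative comparisons matter)

def _log2_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / math.log(2.0)


def _ruleset_dl(rules: Sequence[Conjunction], X: np.ndarray, y: np.ndarray,
                genes: Sequence[str]) -> float:
    """Bits to transmit the ruleset plus its exceptions on (X, y)."""
    n = X.shape[0]
    n_conditions = max(2, 2 * len(genes) * max(n - 1, 1))
    theory = 0.0
    for conj in rules:
        k = len(conj)
        theory += 0.5 * (math.log2(k + 1) + k * math.log2(n_conditions))
    mask = _ruleset_mask(rules, X, genes)
    cov = int(np.count_nonzero(mask))
    unc = n - cov
    fp = int(np.count_nonzero(mask & ~y))
    fn = int(np.count_nonzero(~mask & y))
    exceptions = (
        math.log2(cov + 1) + _log2_comb(cov, fp)
        + math.log2(unc + 1) + _log2_comb(unc, fn)
    )
    return theory + exceptions


# --------------------------------------------------------------------------
# model-level operations

def resolve_positive_class(m: ExpressionMatrix, positive_class: str = "auto") -> tuple[str, str]:
    """Return (positive, default) display labels; 'auto' = minority class."""
    labels = m.distinct_labels()
    if len(labels) < 2:
        raise ValueError("matrix has a single class; cannot learn")
    counts = {lab: 0 for lab in labels}
    fold = {lab.casefold(): lab for lab in labels}
    for lab in m.labels:
        counts[fold[lab.casefold()]] += 1
    if positive_class == "auto":
        pos = min(labels, key=lambda lab: (counts[lab], lab.casefold()))
    else:
        key = positive_class.casefold()
        if key not in fold:
            raise ValueError(f"positive class {positive_class!r} absent from labels")
        pos = fold[key]
    others = [lab for lab in labels if lab.casefold() != pos.casefold()]
    default = max(others, key=lambda lab: (counts[lab], lab.casefold()))
    return pos, default


def _stratified_split(y: np.ndarray, grow_fraction: float, rng: np.random.Generator):
    grow_idx: list[int] = []
    prune_idx: list[int] = []
    for cls in (True, False):
        members = np.nonzero(y == cls)[0]
        if members.size == 0:
            continue
        perm = rng.permutation(members)
        n_grow = max(1, int(math.ceil(grow_fraction * members.size)))
        grow_idx.extend(perm[:n_grow].tolist())
        prune_idx.extend(perm[n_grow:].tolist())
    grow_idx.sort()
    prune_idx.sort()
    if not prune_idx:  # too small to split: prune on the grow set
        prune_idx = list(grow_idx)
    return np.array(grow_idx, dtype=int), np.array(prune_idx, dtype=int)


def _grow_prune_once(data: _Data, idx: np.ndarray, params: LearnerParams,
                     rng: np.random.Generator) -> Conjunction | None:
    y_rem = data.y[idx]
    if not y_rem.any():
        return None
    gi, pi = _stratified_split(y_rem, params.grow_fraction, rng)
    grow_view = data.subset(idx[gi])
    conj = grow_conjunction(grow_view)
    if len(conj) == 0:
        return None
    prune_view = data.subset(idx[pi])
    conj = prune_conjunction(conj, prune_view)
    # reduced-error sanity: reject rules no better than the empty rule on
    # the prune split
    p, n = _counts(_conj_mask(conj, prune_view.X, data.genes), prune_view.y)
    p_all = int(np.count_nonzero(prune_view.y))
    n_all = prune_view.y.size - p_all
    if p == 0 or _prune_value(p, n) < _prune_value(p_all, n_all):
        return None
    return conj


def _best_single_literal_rule(data: _Data) -> tuple[Conjunction | None, float]:
    """Exhaustive best 1-literal conjunction by training F-measure."""
    X, y, genes = data.X, data.y, data.genes
    best = None  # (f, -col, -op_rank, -threshold) maximized
    best_conj = None
    for j, gene in enumerate(genes):
        v = X[:, j]
        ts = candidate_thresholds(v, y)
        ts = list(ts) + [float(v.max()) + 1.0]  # allow the cover-all literal
        for t in ts:
            for op in (OP_LT, OP_GE):
                lit = Literal(gene, op, float(t))
                tp, fp = _counts(lit.covers(v), y)
                fn = int(np.count_nonzero(y)) - tp
                prec = tp / (tp + fp) if (tp + fp) else 0.0
                rec = tp / (tp + fn) if (tp + fn) else 0.0
                f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
                key = (f, -j, -_OP_RANK[op], -t)
                if best is None or key > best:
                    best = key
                    best_conj = Conjunction((lit,))
    return best_conj, (best[0] if best else 0.0)


def _training_f(rules: Sequence[Conjunction], data: _Data) -> float:
    mask = _ruleset_mask(rules, data.X, data.genes)
    tp, fp = _counts(mask, data.y)
    fn = int(np.count_nonzero(data.y)) - tp
    tn = data.y.size - tp - fp - fn
    return Metrics(tp, fp, fn, tn).f_measure


def learn_model(train: ExpressionMatrix, params: LearnerParams = LearnerParams()) -> RuleModel:
    """Learn a rule model for the positive class.

    Sequential covering with grow/prune splits and a description-length
    budget, followed by optimization passes that may replace or revise each
    conjunction, a DL-based deletion sweep, and a depth-1 safeguard: the
    returned model's training F-measure is never below the best exhaustive
    single-literal model's.
    """
    pos, default = resolve_positive_class(train, params.positive_class)
    data = _Data(train, pos)
    rng = np.random.default_rng(params.seed)

    rules: list[Conjunction] = []
    remaining = np.arange(train.n_samples)
    dl_min = _ruleset_dl([], data.X, data.y, data.genes)
    while data.y[remaining].any():
        conj = _grow_prune_once(data, remaining, params, rng)
        if conj is None:
            break
        candidate = rules + [conj]
        dl = _ruleset_dl(candidate, data.X, data.y, data.genes)
        if dl > dl_min + params.mdl_slack_bits:
            break
        rules = candidate
        dl_min = min(dl_min, dl)
        covered = _conj_mask(conj, data.X[remaining], data.genes)
        remaining = remaining[~covered]

    for _ in range(params.optimization_passes):
        rules = _optimize_pass(rules, data, params, rng)

    # deletion sweep: drop any conjunction whose removal lowers DL
    changed = True
    while changed and rules:
        changed = False
        dl_now = _ruleset_dl(rules, data.X, data.y, data.genes)
        for i in range(len(rules)):
            trial = rules[:i] + rules[i + 1:]
            if _ruleset_dl(trial, data.X, data.y, data.genes) < dl_now:
                rules = trial
                changed = True
                break

    # depth-1 safeguard
    single, f_single = _best_single_literal_rule(data)
    if single is not None and _training_f(rules, data) < f_single:
        rules = [single]

    # soundness: every stored conjunction covers >=1 positive training sample
    rules = [c for c in rules
             if _counts(_conj_mask(c, data.X, data.genes), data.y)[0] > 0]
    return RuleModel(positive_class=pos, default_class=default,
                     conjunctions=tuple(rules))


def _optimize_pass(rules: list[Conjunction], data: _Data, params: LearnerParams,
                   rng: np.random.Generator) -> list[Conjunction]:
    out = list(rules)
    for i in range(len(out)):
        others = out[:i] + out[i + 1:]
        uncovered_by_others = ~_ruleset_mask(others, data.X, data.genes)
        idx = np.nonzero(uncovered_by_others)[0]
        variants: list[list[Conjunction]] = [out]
        if idx.size and data.y[idx].any():
            replacement = _grow_prune_once(data, idx, params, rng)
            if replacement is not None:
                variants.append(out[:i] + [replacement] + out[i + 1:])
        # revision: re-prune the existing conjunction on a fresh split
        gi, pi = _stratified_split(data.y, params.grow_fraction, rng)
        revised = prune_conjunction(out[i], data.subset(np.sort(pi)))
        if len(revised):
            variants.append(out[:i] + [revised] + out[i + 1:])
        best = min(
            variants,
            key=lambda rs: (_ruleset_dl(rs, data.X, data.y, data.genes),
                            variants.index(rs)),
        )
        out = best
    return out


def predict(model: RuleModel, sample: Mapping[str, float]) -> str:
    """Classify one sample given a gene -> value mapping."""
    for conj in model.conjunctions:
        if conj.covers_sample(sample):
            return model.positive_class
    return model.default_class


def evaluate_model(model: RuleModel, m: ExpressionMatrix) -> Metrics:
    """Confusion counts of the model against the matrix labels."""
    covered = model.covers_matrix(m)
    key = model.positive_class.casefold()
    y = np.array([lab.casefold() == key for lab in m.labels], dtype=bool)
    tp = int(np.count_nonzero(covered & y))
    fp = int(np.count_nonzero(covered & ~y))
    fn = int(np.count_nonzero(~covered & y))
    tn = int(np.count_nonzero(~covered & ~y))
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn)


def cross_validate(m: ExpressionMatrix, params: LearnerParams = LearnerParams()) -> Metrics:
    """Stratified k-fold cross-validation, confusion counts pooled over folds."""
    pos, _ = resolve_positive_class(m, params.positive_class)
    key = pos.casefold()
    y = np.array([lab.casefold() == key for lab in m.labels], dtype=bool)
    n_pos = int(np.count_nonzero(y))
    n_neg = y.size - n_pos
    if min(n_pos, n_neg) < params.cv_folds:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} samples; "
            f"cannot run {params.cv_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=params.cv_folds, shuffle=True,
                          random_state=params.seed)
    fold_params = replace(params, positive_class=pos)
    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(np.zeros(y.size), y):
        model = learn_model(m.take_samples(train_idx), fold_params)
        fold = evaluate_model(model, m.take_samples(test_idx))
        tp += fold.tp
        fp += fold.fp
        fn += fold.fn
        tn += fold.tn
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn)


# --------------------------------------------------------------------------
# rule text grammar:  conj (" OR " conj)* " => " class
#   conj    := literal | "(" literal (" AND " literal)* ")"
#   literal := "(" gene op number ")"

_LITERAL_RE = re.compile(r"^\(\s*(?P<gene>\S+)\s+(?P<op><|>=)\s+(?P<num>[-+0-9.eE]+)\s*\)$")


def _split_top(text: str, sep: str) -> list[str]:
    parts: list[str] = []
    depth = 0
    start = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0 and text.startswith(sep, i):
            parts.append(text[start:i])
            i += len(sep)
            start = i
            continue
        i += 1
    parts.append(text[start:])
    return parts


def _parse_literal(text: str) -> Literal:
    match = _LITERAL_RE.match(text.strip())
    if not match:
        raise ValueError(f"malformed literal {text!r}")
    return Literal(match["gene"], match["op"], float(match["num"]))


def _parse_conjunction(text: str) -> Conjunction:
    text = text.strip()
    if not text.startswith("(") or not text.endswith(")"):
        raise ValueError(f"malformed conjunction {text!r}")
    inner = text[1:-1].strip()
    if inner.startswith("("):  # multi-literal: outer parens wrap an AND list
        parts = _split_top(inner, " AND ")
        return Conjunction(tuple(_parse_literal(p) for p in parts))
    return Conjunction((_parse_literal(text),))


def parse_rule(text: str, default_class: str = "other") -> RuleModel:
    """Parse the exported rule grammar back into a :class:`RuleModel`."""
    if " => " not in text:
        raise ValueError(f"rule text missing '=>': {text!r}")
    body, positive = text.rsplit(" => ", 1)
    positive = positive.strip()
    body = body.strip()
    default = default_class if default_class.casefold() != positive.casefold() \
        else default_class + "_other"
    if body == "()":
        return RuleModel(positive_class=positive, default_class=default)
    conjs = tuple(_parse_conjunction(p) for p in _split_top(body, " OR "))
    return RuleModel(positive_class=positive, default_class=default,
                     conjunctions=conjs)
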