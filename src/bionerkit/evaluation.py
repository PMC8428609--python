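"""Mention-level scoring under two span-matching protocols.

``exact_tolerant`` requires type equality and each span boundary to lie
within a configurable character tolerance (default 1, accounting for
divergent handling of special characters at span edges); ``overlap``
counts any same-type span intersection as a match.  Counts are aggregated
micro (pooled) and macro (unweighted mean of per-type F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_types import EntityMention

__all__ = ["MatchProtocol", "TypeCounts", "EvalReport", "is_match", "match_and_count", "report"]


@dataclass(frozen=True)
class MatchProtocol:
    """A named span-matching rule.

    mode: ``exact_tolerant`` or ``overlap``.
    tolerance: max character offset per boundary (exact_tolerant only).
    whole_span_shift: if set, the tolerance applies to a rigid shift of the
        whole span (both boundaries moved by the same amount) instead of to
        each boundary independently.
    """

    mode: str = "exact_tolerant"
    tolerance: int = 1
    whole_span_shift: bool = False

    def __post_init__(self):
        if self.mode not in ("exact_tolerant", "overlap"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


EXACT = MatchProtocol("exact_tolerant", tolerance=0)
EXACT_TOLERANT = MatchProtocol("exact_tolerant", tolerance=1)
OVERLAP = MatchProtocol("overlap")


def is_match(gold: EntityMention, pred: EntityMention, protocol: MatchProtocol) -> bool:
    if gold.type != pred.type:
        return False
    if protocol.mode == "overlap":
        return max(gold.start, pred.start) < min(gold.end, pred.end)
    t = protocol.tolerance
    ds, de = pred.start - gold.start, pred.end - gold.end
    if protocol.whole_span_shift:
        return ds == de and abs(ds) <= t
    return abs(ds) <= t and abs(de) <= t


@dataclass
class TypeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __iadd__(self, other: "TypeCounts"):
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def match_and_count(
    gold,
    pred,
    protocol: MatchProtocol,
    maximum_matching: bool = False,
) -> dict[str, TypeCounts]:
    """One-to-one match gold vs predicted mentions; count per type.

    Default matching is greedy over candidate pairs sorted by
    ``(gold.start, pred.start)`` with each mention consumed at most once —
    deterministic and adequate in practice.  ``maximum_matching=True``
    switches to optimal bipartite matching for sensitivity checks.
    """
    types = sorted({m.type for m in gold} | {m.type for m in pred})
    out: dict[str, TypeCounts] = {}
    for etype in types:
        g = sorted((m for m in gold if m.type == etype), key=lambda m: (m.start, m.end))
        p = sorted((m for m in pred if m.type == etype), key=lambda m: (m.start, m.end))
        pairs = [
            (gm.start, pm.start, i, j)
            for i, gm in enumerate(g)
            for j, pm in enumerate(p)
            if is_match(gm, pm, protocol)
        ]
        if maximum_matching:
            tp = _max_bipartite(len(g), len(p), [(i, j) for _, _, i, j in pairs])
        else:
            pairs.sort()
            used_g: set[int] = set()
            used_p: set[int] = set()
            tp = 0
            for _, _, i, j in pairs:
                if i not in used_g and j not in used_p:
                    used_g.add(i)
                    used_p.add(j)
                    tp += 1
        out[etype] = TypeCounts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)
    return out


def _max_bipartite(n_left: int, n_right: int, edges) -> int:
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
    match_right = {}

    def augment(i, visited):
        for j in adj.get(i, []):
            if j in visited:
                continue
            visited.add(j)
            if j not in match_right or augment(match_right[j], visited):
                match_right[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(n_left))


@dataclass
class EvalReport:
    """Per-type and aggregate precision/recall/F1 (fractions in [0,1])."""

    protocol: MatchProtocol
    per_type: dict[str, TypeCounts] = field(default_factory=dict)

    @property
    def micro(self) -> TypeCounts:
        total = TypeCounts()
        for c in self.per_type.values():
            total += c
        return total

    @property
    def micro_f1(self) -> float:
        return self.micro.f1

    @property
    def macro_f1(self) -> float:
        if not self.per_type:
            return 0.0
        return sum(c.f1 for c in self.per_type.values()) / len(self.per_type)

    def add(self, counts: dict[str, TypeCounts]):
        for etype, c in counts.items():
            self.per_type.setdefault(etype, TypeCounts()).__iadd__(c)
        return self

    def as_dict(self) -> dict:
        def row(c: TypeCounts):
            return {
                "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "precision": round(100 * c.precision, 2),
                "recall": round(100 * c.recall, 2),
                "f1": round(100 * c.f1, 2),
            }

        return {
            "protocol": {
                "mode": self.protocol.mode,
                "tolerance": self.protocol.tolerance,
            },
            "per_type": {t: row(c) for t, c in sorted(self.per_type.items())},
            "micro": row(self.micro),
            "macro_f1": round(100 * self.macro_f1, 2),
        }

    def format_table(self) -> str:
        lines = [f"{'type':<12}{'tp':>6}{'fp':>6}{'fn':>6}{'P%':>9}{'R%':>9}{'F1%':>9}"]
        for etype, c in sorted(self.per_type.items()):
            lines.append(
                f"{etype:<12}{c.tp:>6}{c.fp:>6}{c.fn:>6}"
                f"{100 * c.precision:>9.2f}{100 * c.recall:>9.2f}{100 * c.f1:>9.2f}"
            )
        m = self.micro
        lines.append(
            f"{'micro':<12}{m.tp:>6}{m.fp:>6}{m.fn:>6}"
            f"{100 * m.precision:>9.2f}{100 * m.recall:>9.2f}{100 * m.f1:>9.2f}"
        )
        lines.append(f"macro-F1: {100 * self.macro_f1:.2f}")
        return "\n".join(lines)


def report(counts_per_type: dict[str, TypeCounts], protocol: MatchProtocol = EXACT_TOLERANT) -> EvalReport:
    rep = EvalReport(protocol=protocol)
    rep.add(counts_per_type)
    return rep


def evaluate_examples(gold_examples, pred_examples, protocol: MatchProtocol) -> EvalReport:
    """Score aligned lists of (sentence, mentions) examples."""
    if len(gold_examples) != len(pred_examples):
        raise ValueError("gold and prediction example counts differ")
    rep = EvalReport(protocol=protocol)
    for g, p in zip(gold_examples, pred_examples):
        rep.add(match_and_count(g.mentions, p.mentions, protocol))
    return rep
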