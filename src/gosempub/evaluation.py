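"""Retrieval evaluation: precision, relative recall, F-score, agreement.

Absolute recall is unknowable without reading every candidate article, so
recall is *relative*: the gold standard is the union of the relevant
articles returned by any of the compared tools, as judged by two blinded
reviewers whose individual selections are also unioned.  Inter-rater
agreement is summarised by Cohen's kappa on the 2x2 judgment table.

Metrics are computed unrounded; printed reports round half-up to 3 decimals
(2 for kappa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Optional

from .errors import UndefinedKappaError


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.3125 -> 0.313 at 3 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RelevanceJudgments:
    """Binary relevance calls by exactly two reviewers on one pmid universe."""

    reviewers: tuple[str, str]
    calls: dict[str, dict[int, bool]]

    def __post_init__(self) -> None:
        if len(self.reviewers) != 2 or len(set(self.reviewers)) != 2:
            raise ValueError("exactly two distinct reviewers are required")
        universes = [set(self.calls.get(r, {})) for r in self.reviewers]
        if universes[0] != universes[1]:
            raise ValueError("both reviewers must judge the same pmid universe")

    @classmethod
    def from_tsv(cls, stream) -> "RelevanceJudgments":
        """Rows: ``pmid <tab> reviewer_id <tab> 0/1``."""
        text = stream if isinstance(stream, str) else stream.read()
        calls: dict[str, dict[int, bool]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            pmid, reviewer, verdict = line.rstrip("\n").split("\t")
            calls.setdefault(reviewer, {})[int(pmid)] = verdict.strip() == "1"
        reviewers = tuple(sorted(calls))
        return cls(reviewers=reviewers, calls=calls)

    def agreement_table(self) -> "AgreementTable":
        r1, r2 = self.reviewers
        a = b = c = d = 0
        for pmid, v1 in self.calls[r1].items():
            v2 = self.calls[r2][pmid]
            if v1 and v2:
                a += 1
            elif v1:
                b += 1
            elif v2:
                c += 1
            else:
                d += 1
        return AgreementTable(a, b, c, d)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 contingency counts for two raters on a binary call."""

    both_positive: int
    only_first: int
    only_second: int
    both_negative: int

    def __post_init__(self) -> None:
        if min(self.both_positive, self.only_first,
               self.only_second, self.both_negative) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("agreement table is empty")

    @property
    def total(self) -> int:
        return (self.both_positive + self.only_first
                + self.only_second + self.both_negative)


@dataclass(frozen=True)
class ToolRun:
    name: str
    returned: frozenset[int]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("tool name must be non-empty")


def gold_standard(judgments: RelevanceJudgments) -> set[int]:
    """Union of the two reviewers' relevant selections."""
    r1, r2 = judgments.reviewers
    return (
        {p for p, v in judgments.calls[r1].items() if v}
        | {p for p, v in judgments.calls[r2].items() if v}
    )


def score_tool(run: ToolRun, gold: set[int]) -> tuple[float, float, float]:
    """(precision, relative recall, F-score) of one tool against the pool.

    F is the harmonic mean 2PR/(P+R).  Empty denominators yield 0.
    Values are unrounded.
    """
    hit = len(run.returned & gold)
    precision = hit / len(run.returned) if run.returned else 0.0
    recall = hit / len(gold) if gold else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected two-rater agreement; unrounded.

    po is the observed agreement rate; pe the agreement expected from the
    raters' marginal rates.  kappa = (po - pe) / (1 - pe).
    """
    a, b, c, d = (table.both_positive, table.only_first,
                  table.only_second, table.both_negative)
    n = table.total
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        raise UndefinedKappaError(
            "both raters are constant and identical; kappa is undefined"
        )
    return (po - pe) / (1 - pe)


@dataclass
class ToolScore:
    returned: int
    relevant_returned: int
    precision: float
    relative_recall: float
    f_score: float

    def __post_init__(self) -> None:
        if self.relevant_returned > self.returned:
            raise ValueError("relevant-returned exceeds returned")


@dataclass
class EvalReport:
    """Per-tool metrics for one query against a shared relevant pool."""

    pool: int  # total relevant count (gold standard size)
    tools: dict[str, ToolScore] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]], pool: int) -> "EvalReport":
        """Build a report from printed (returned, relevant) pairs per tool."""
        report = cls(pool=pool)
        for name, (returned, relevant) in counts.items():
            precision = relevant / returned if returned else 0.0
            recall = relevant / pool if pool else 0.0
            f = (2 * precision * recall / (precision + recall)
                 if precision + recall else 0.0)
            report.tools[name] = ToolScore(returned, relevant, precision, recall, f)
        return report

    @classmethod
    def from_runs(cls, runs: list[ToolRun], gold: set[int]) -> "EvalReport":
        report = cls(pool=len(gold))
        for run in runs:
            p, r, f = score_tool(run, gold)
            report.tools[run.name] = ToolScore(
                len(run.returned), len(run.returned & gold), p, r, f
            )
        return report

    def formatted(self) -> str:
        """Aligned text table with the canonical row labels."""
        names = list(self.tools)
        rows = [
            ("", names),
            ("(a) Number of results", [str(self.tools[n].returned) for n in names]),
            ("(b) Relevant among (a)", [str(self.tools[n].relevant_returned) for n in names]),
            ("Precision", [f"{round_half_up(self.tools[n].precision, 3):.3f}" for n in names]),
            ("Relative Recall", [f"{round_half_up(self.tools[n].relative_recall, 3):.3f}" for n in names]),
            ("F-score", [f"{round_half_up(self.tools[n].f_score, 3):.3f}" for n in names]),
        ]
        label_w = max(len(r[0]) for r in rows)
        col_w = max(max(len(v) for v in r[1]) for r in rows)
        return "\n".join(
            label.ljust(label_w) + "  " + "  ".join(v.rjust(col_w) for v in vals)
            for label, vals in rows
        )


@dataclass
class OverlapPartition:
    """Counts of pmids returned by exactly each non-empty subset of tools."""

    regions: dict[frozenset[str], int]
    relevant_regions: Optional[dict[frozenset[str], int]] = None


def overlap_partition(
    runs: list[ToolRun], gold: Optional[set[int]] = None
) -> OverlapPartition:
    """Exact-subset membership tally over the union of all runs."""
    if len(runs) < 2:
        raise ValueError("need at least two tool runs")
    names = [r.name for r in runs]
    subsets = [
        frozenset(c)
        for k in range(1, len(names) + 1)
        for c in combinations(names, k)
    ]
    regions = {s: 0 for s in subsets}
    relevant = {s: 0 for s in subsets} if gold is not None else None
    for pmid in set().union(*(r.returned for r in runs)):
        signature = frozenset(r.name for r in runs if pmid in r.returned)
        regions[signature] += 1
        if relevant is not None and pmid in gold:
            relevant[signature] += 1
    return OverlapPartition(regions=regions, relevant_regions=relevant)


def aggregate_report(
    reports: list[EvalReport],
) -> tuple[dict[str, int], dict[str, float]]:
    """Cross-query aggregates: pooled recall (%) and mean returned per tool.

    Pooled recall sums relevant-returned and pool sizes over the queries
    before dividing, then rounds to the nearest percent; mean returned is
    rounded to 2 decimals.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    names = list(reports[0].tools)
    for rep in reports:
        if list(rep.tools) != names:
            raise ValueError("all reports must cover the same tool set")
    pooled: dict[str, int] = {}
    means: dict[str, float] = {}
    total_pool = sum(rep.pool for rep in reports)
    for name in names:
        hits = sum(rep.tools[name].relevant_returned for rep in reports)
        pooled[name] = int(round_half_up(100 * hits / total_pool, 0))
        means[name] = round_half_up(
            sum(rep.tools[name].returned for rep in reports) / len(reports), 2
        )
    return pooled, means
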