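"""End-to-end comparison of the advanced pipeline against the naive baseline.

Wires the synthetic world, both retrieval front ends and the evaluation
statistics into one experiment: index the laymen corpus, answer every
case with both systems, score per-case precision against the merged
gold standard, and test whether the advanced system's mean precision
exceeds the baseline's.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expansion import ExpansionParams
from .fixtures import Benchmark, FixtureSpec, generate_benchmark
from .retrieval import (Audience, build_index, recommend_advanced,
                        recommend_naive)
from .stats import (PrecisionReport, TTestResult, merge_judgments,
                    paired_one_sided_t, precision_rho)

__all__ = ["ComparisonResult", "run_comparison", "run_benchmark"]

#: recommendations shown per case, mirroring a short top-k result list
DEFAULT_TOPK = 4


@dataclass
class ComparisonResult:
    report: PrecisionReport
    ttest: TTestResult

    @property
    def delta_rho(self) -> float:
        return self.report.rho_h - self.report.rho_v


def run_comparison(bench: Benchmark, topk: int = DEFAULT_TOPK,
                   params: ExpansionParams = ExpansionParams(),
                   alpha: float = 0.05) -> ComparisonResult:
    """Advanced vs naive retrieval over one benchmark world.

    Only laymen artifacts are recommendable (the item set is a laymen
    information corpus); expert documents exist for classifier training
    and as distractors, not as retrieval targets.
    """
    laymen = [a for a in bench.corpus if a.audience == Audience.LAYMEN]
    idx = build_index(laymen)
    gold = merge_judgments(bench.gold)
    results_h: dict[str, set[str]] = {}
    results_v: dict[str, set[str]] = {}
    for case_id, text in bench.cases:
        results_h[case_id] = set(
            recommend_advanced(text, bench.graph, idx, params, topk).ids())
        results_v[case_id] = set(recommend_naive(text, idx, topk).ids())
    per_h = precision_rho(results_h, gold)
    per_v = precision_rho(results_v, gold)
    order = sorted(per_h)
    report = PrecisionReport(per_case_h=per_h, per_case_v=per_v)
    ttest = paired_one_sided_t([per_h[c] for c in order],
                               [per_v[c] for c in order], alpha=alpha)
    return ComparisonResult(report=report, ttest=ttest)


def run_benchmark(spec: FixtureSpec = FixtureSpec(), topk: int = DEFAULT_TOPK,
                  params: ExpansionParams = ExpansionParams()
                  ) -> ComparisonResult:
    """Generate the world for ``spec`` and run the comparison on it."""
    return run_comparison(generate_benchmark(spec), topk=topk, params=params)
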