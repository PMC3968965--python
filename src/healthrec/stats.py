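"""Evaluation statistics for the recommender comparison study.

Implements the planned controlled experiment's machinery: merging
multi-judge gold standards, per-case retrieval precision and its mean
over cases (rho), the one-sided dependent t-test of "advanced beats
naive", and a-priori power analysis — how many clinical cases (n_c) and
expert judges (n_p) a study needs to detect a given standardized
precision improvement.

The sample-size formula is the normal approximation with Guenther's
small-sample correction for a one-sided paired t-test,

    n = ceil( ((z_{1-alpha} + z_{power}) / d)^2 + z_{1-alpha}^2 / 2 ),

with d the standardized mean difference of paired per-case precisions.
An iterative noncentral-t solution is provided alongside for
cross-checking; the two agree to within one case in the ranges used
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

__all__ = ["GoldStandard", "PrecisionReport", "PowerSpec", "TTestResult",
           "merge_judgments", "precision_rho", "paired_one_sided_t",
           "required_cases", "required_cases_nct", "required_physicians",
           "load_gold_standard", "save_gold_standard"]


@dataclass
class GoldStandard:
    """Per-case expert selections: case id -> judge id -> artifact ids.

    ``j`` is the interjudge agreement factor — the number of independent
    experts who assess each case.
    """

    cases: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    j: int = 2

    def add(self, case_id: str, judge_id: str, artifact_id: str) -> None:
        self.cases.setdefault(case_id, {}).setdefault(judge_id, set()).add(
            artifact_id)


@dataclass
class PrecisionReport:
    """Per-case precisions and their means for the two competing systems."""

    per_case_h: dict[str, float]
    per_case_v: dict[str, float]

    @property
    def rho_h(self) -> float:
        return float(np.mean(list(self.per_case_h.values())))

    @property
    def rho_v(self) -> float:
        return float(np.mean(list(self.per_case_v.values())))


@dataclass(frozen=True)
class PowerSpec:
    """Parameters of the a-priori power analysis."""

    omega0: float = 0.1      # standardized expected precision improvement
    alpha: float = 0.05      # one-sided significance level
    power: float = 0.8       # target power 1 - beta
    j: int = 2               # judges per case
    c_p: int = 50            # cases assessed per participant

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be > 0")
        if self.j < 1 or self.c_p < 1:
            raise ValueError("j and c_p must be >= 1")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    reject: bool
    degenerate: bool = False


def merge_judgments(gs: GoldStandard, rule: str = "majority"
                    ) -> dict[str, set[str]]:
    """Merge per-judge selections into one relevant set per case.

    ``majority``: an artifact is relevant iff selected by at least
    ceil(j/2) judges (with j = 2 this is the union).  ``union`` and
    ``intersection`` are available as alternatives.
    """
    merged: dict[str, set[str]] = {}
    for case_id, judges in gs.cases.items():
        if not judges:
            raise ValueError(f"case {case_id!r} has no judges")
        sels = list(judges.values())
        if rule == "union":
            merged[case_id] = set().union(*sels)
        elif rule == "intersection":
            out = set(sels[0])
            for s in sels[1:]:
                out &= s
            merged[case_id] = out
        elif rule == "majority":
            threshold = math.ceil(gs.j / 2)
            votes: dict[str, int] = {}
            for s in sels:
                for a in s:
                    votes[a] = votes.get(a, 0) + 1
            merged[case_id] = {a for a, v in votes.items() if v >= threshold}
        else:
            raise ValueError(f"unknown merge rule {rule!r}")
    return merged


def precision_rho(results: dict[str, set[str]], gold: dict[str, set[str]]
                  ) -> dict[str, float]:
    """Per-case precision |retrieved & relevant| / |retrieved|.

    A case with an empty retrieved set scores 0 — returning nothing when
    relevant documents exist is a retrieval failure, not a skip.
    """
    out: dict[str, float] = {}
    for case_id, retrieved in results.items():
        if case_id not in gold:
            raise KeyError(f"no gold standard for case {case_id!r}")
        if not retrieved:
            out[case_id] = 0.0
        else:
            out[case_id] = len(retrieved & gold[case_id]) / len(retrieved)
    return out


def paired_one_sided_t(per_case_h: list[float], per_case_v: list[float],
                       alpha: float = 0.05) -> TTestResult:
    """One-sided dependent t-test of H_a: mean(H - V) > 0.

    Pairs the per-case precisions, tests the mean difference against
    zero with df = n - 1, upper tail.  Zero-variance differences are
    degenerate: p is 1 when the mean is non-positive and 0 when it is
    positive (flagged).
    """
    h = np.asarray(per_case_h, dtype=float)
    v = np.asarray(per_case_v, dtype=float)
    if h.shape != v.shape:
        raise ValueError("paired samples must have equal length")
    n = h.size
    if n < 2:
        raise ValueError("need at least 2 paired cases")
    d = h - v
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean > 0:
            return TTestResult(math.inf, df, 0.0, True, degenerate=True)
        return TTestResult(0.0 if mean == 0 else -math.inf, df, 1.0, False,
                           degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = float(sps.t.sf(t, df))
    return TTestResult(float(t), df, p, p < alpha)


def required_cases(spec: PowerSpec) -> int:
    """Cases needed for the one-sided paired t-test at the given power.

    Guenther-corrected normal approximation (see module docstring) with
    the standardized effect size ``omega0``.
    """
    za = sps.norm.ppf(1.0 - spec.alpha)
    zb = sps.norm.ppf(spec.power)
    n = ((za + zb) / spec.omega0) ** 2 + za ** 2 / 2.0
    return math.ceil(n)


def required_cases_nct(spec: PowerSpec) -> int:
    """Cross-check: smallest n whose noncentral-t power reaches the target.

    Iterates n upward; power(n) = P(T' > t_{1-alpha, n-1}) with T'
    noncentral t at noncentrality sqrt(n) * omega0.
    """
    n = 2
    while n < 10_000_000:
        df = n - 1
        tcrit = sps.t.ppf(1.0 - spec.alpha, df)
        power = sps.nct.sf(tcrit, df, math.sqrt(n) * spec.omega0)
        if power >= spec.power:
            return n
        n += 1
    raise RuntimeError("sample size search did not converge")


def required_physicians(n_c: int, j: int, c_p: int) -> int:
    """Experts to recruit: ceil(n_c * j / c_p)."""
    if n_c < 1 or j < 1 or c_p < 1:
        raise ValueError("n_c, j and c_p must be >= 1")
    return math.ceil(n_c * j / c_p)


# ----------------------------------------------------------------------
# gold-standard file format


def load_gold_standard(path: str | Path, j: int = 2) -> GoldStandard:
    """Read selections from TSV: ``case_id<TAB>judge_id<TAB>artifact_id``."""
    gs = GoldStandard(j=j)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            gs.add(*parts)
    return gs


def save_gold_standard(gs: GoldStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# case_id\tjudge_id\tartifact_id\n")
        for case_id in sorted(gs.cases):
            for judge_id in sorted(gs.cases[case_id]):
                for artifact_id in sorted(gs.cases[case_id][judge_id]):
                    fh.write(f"{case_id}\t{judge_id}\t{artifact_id}\n")
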