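"""Self-validation benchmarks: planted-truth recovery and method oracles.

These helpers exercise the full pipeline against the simulator's ground
truth (recovery metrics) and against independent brute-force oracles of the
core primitives (exhaustive hit filtering, transitive-closure clustering,
hypergeometric enumeration).  They are used by the package's own acceptance
checks and are convenient for regression testing after changes.
"""

from __future__ import annotations

import math
import random
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .config import Parameters
from .detection import collapse_orthologs, FusionCall
from .expression import tissue_contingency
from .homology import AlignmentHit, assort_hits
from .pipeline import run_pipeline
from .simulate import (
    PlantedFusion,
    SimulationPlan,
    default_plan,
    default_tree,
    simulate_bundle,
)

__all__ = [
    "RecoveryReport",
    "planted_recovery",
    "null_control_calls",
    "greedy_oracle_agreement",
    "collapse_oracle_agreement",
    "fisher_oracle_max_diff",
    "fixation_recovery",
]


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline output compared against the generator's ground truth."""

    n_expected: int
    n_called: int
    precision: float
    recall: float
    round_accuracy: float
    type_accuracy: float
    subpattern_accuracy: float
    retro_accuracy: float
    expression_accuracy: float
    fixation_max_abs_err: float


def planted_recovery(
    seed: int = 0, n_background_genes: int = 60, work_dir: str | Path | None = None
) -> RecoveryReport:
    """Run the full pipeline on a planted bundle and score it against truth."""
    plan = default_plan(seed=seed, n_background_genes=n_background_genes)
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(work_dir) if work_dir is not None else Path(tmp)
        bundle = simulate_bundle(plan, base / "bundle")
        _manifest, ctx = run_pipeline(bundle.config, base / "out")
        truth = bundle.truth

        expected: dict[tuple[str, str], int] = {}
        for focus in plan.focus_species:
            for query, rnd in truth.expected_calls(focus).items():
                expected[(focus, query)] = rnd
        called: dict[tuple[str, str], FusionCall] = {}
        for focus in plan.focus_species:
            for call in ctx.calls[focus]:
                called[(focus, call.query_id)] = call
        tp = set(expected) & set(called)
        precision = len(tp) / len(called) if called else 1.0
        recall = len(tp) / len(expected) if expected else 1.0
        round_ok = sum(
            1 for key in tp if called[key].origination_round == expected[key]
        )

        type_ok = sub_ok = retro_ok = expr_ok = 0
        n_class = n_retro = n_expr = 0
        fix_err = 0.0
        for entry in truth.entries:
            for focus in plan.focus_species:
                if focus not in entry.carriers:
                    continue
                if entry.expected_round.get(focus) is None:
                    continue
                query = entry.fusion_ids[focus]
                oc = ctx.classes.get((focus, query))
                n_class += 1
                if oc is not None and oc.type == entry.expected_type[focus]:
                    type_ok += 1
                if oc is not None and oc.subpattern == entry.expected_subpattern[focus]:
                    sub_ok += 1
                flags = ctx.retro.get((focus, query), [])
                n_retro += 1
                # a retro structure is recoverable only where a parent model
                # exists in the focus annotation
                if any(f.is_retro for f in flags) == (
                    entry.retro and bool(entry.parent_ids[focus])
                ):
                    retro_ok += 1
                expect_expr = entry.expected_expression.get(focus)
                got_expr = ctx.expression_classes.get((focus, query))
                n_expr += 1
                if got_expr == expect_expr or (expect_expr is None and got_expr is None):
                    expr_ok += 1
                if focus in entry.fixation_freq:
                    result = ctx.fixation.get((focus, query))
                    if result is None:
                        fix_err = max(fix_err, 1.0)
                    else:
                        fix_err = max(
                            fix_err,
                            abs(result.frequency - entry.fixation_freq[focus]),
                        )
        return RecoveryReport(
            n_expected=len(expected),
            n_called=len(called),
            precision=precision,
            recall=recall,
            round_accuracy=round_ok / len(tp) if tp else 1.0,
            type_accuracy=type_ok / n_class if n_class else 1.0,
            subpattern_accuracy=sub_ok / n_class if n_class else 1.0,
            retro_accuracy=retro_ok / n_retro if n_retro else 1.0,
            expression_accuracy=expr_ok / n_expr if n_expr else 1.0,
            fixation_max_abs_err=fix_err,
        )


def null_control_calls(seeds, n_background_genes: int = 40) -> int:
    """Total fusion calls over pure-speciation simulations (no events)."""
    total = 0
    for seed in seeds:
        plan = default_plan(
            seed=int(seed),
            n_background_genes=n_background_genes,
            events=[],
            write_genomes="none",
        )
        with tempfile.TemporaryDirectory() as tmp:
            bundle = simulate_bundle(plan, Path(tmp) / "bundle")
            _m, ctx = run_pipeline(
                bundle.config, Path(tmp) / "out", ["groups", "detect"]
            )
            total += sum(len(calls) for calls in ctx.calls.values())
    return total


# ---------------------------------------------------------------------------
# Primitive oracles


def _exhaustive_filter(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Fixed-point simulation of "drop any hit overlapped by a longer kept
    hit", with the documented tie order; independent of the greedy code."""
    order = sorted(
        hits, key=lambda h: (-h.span, -h.bit_score, h.subject_id, h.q_start, h.q_end)
    )
    alive = list(order)
    changed = True
    while changed:
        changed = False
        for h in list(alive):
            for g in alive:
                if g is not h and h.overlaps(g) and order.index(g) < order.index(h):
                    alive.remove(h)
                    changed = True
                    break
            if changed:
                break
    return sorted(alive, key=lambda h: h.q_start)


def greedy_oracle_agreement(
    n_cases: int = 1000, seed: int = 1234, query_len: int = 100
) -> float:
    """Fraction of random hit sets (≤8 hits) where greedy assortment equals
    the exhaustive filter."""
    rng = random.Random(seed)
    params = Parameters()
    agree = 0
    for _ in range(n_cases):
        hits = []
        for _i in range(rng.randint(1, 8)):
            a = rng.randint(0, query_len - 2)
            b = rng.randint(a + 1, query_len)
            hits.append(
                AlignmentHit(
                    "q", f"s{rng.randint(1, 4)}", 90.0, b - a, a, b, 0, b - a,
                    1e-50, float(rng.randint(20, 200)), "sp",
                )
            )
        call = assort_hits("q", "sp", query_len, hits, params)
        remaining = [h for h in hits if h.coverage(query_len) <= params.long_cov]
        expect = [
            h
            for h in _exhaustive_filter(remaining)
            if h.coverage(query_len) > params.short_min_cov
        ]
        if list(call.short_hits) == expect:
            agree += 1
    return agree / n_cases


def collapse_oracle_agreement(n_cases: int = 100, seed: int = 7) -> float:
    """Fraction of random candidate graphs where connected-component
    clustering equals brute-force transitive closure (Floyd–Warshall)."""
    rng = random.Random(seed)
    params = Parameters()
    agree = 0
    for _ in range(n_cases):
        n = rng.randint(2, 12)
        calls = [FusionCall(f"n{i}", f"S{i}", "L100&S111", 1, None) for i in range(n)]
        reach = [[i == j for j in range(n)] for i in range(n)]
        hits = []
        for _e in range(rng.randint(0, 2 * n)):
            i, j = rng.randint(0, n - 1), rng.randint(0, n - 1)
            if i != j:
                hits.append(
                    AlignmentHit(
                        f"n{i}", f"n{j}", 95.0, 200, 0, 200, 0, 200, 1e-90, 300.0,
                    )
                )
                reach[i][j] = reach[j][i] = True
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    reach[i][j] = reach[i][j] or (reach[i][k] and reach[k][j])
        expected = {
            frozenset(f"n{j}" for j in range(n) if reach[i][j]) for i in range(n)
        }
        fset = collapse_orthologs(calls, hits, params, [f"S{i}" for i in range(n)])
        got = {frozenset(c.query_id for c in cl.members) for cl in fset.clusters}
        if got == expected:
            agree += 1
    return agree / n_cases


def _fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    n, r1, c1 = a + b + c + d, a + b, a + c

    def pmf(k: int) -> float:
        return math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-13))


def fisher_oracle_max_diff(n_cases: int = 300, seed: int = 99, n_max: int = 200) -> float:
    """Largest |p_implementation − p_enumeration| over random 2×2 tables."""
    rng = random.Random(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = rng.randint(2, n_max)
        kx, ky = rng.randint(0, n), rng.randint(0, n)
        p = tissue_contingency({"x": kx, "y": ky}, n)[("x", "y")]
        worst = max(worst, abs(p - _fisher_enumeration(kx, n - kx, ky, n - ky)))
    return worst


def fixation_recovery(
    disruption_prob: float, n_individuals: int = 200, seed: int = 5
) -> tuple[float, bool]:
    """Measured fixation frequency (and fixed flag) of one planted gene in a
    simulated population, recomputed through the variant pipeline."""
    plan = SimulationPlan(
        newick=default_tree(),
        focus_species=("A1",),
        outgroup_species=("O1", "O2", "O3"),
        n_background_genes=6,
        events=(PlantedFusion("e", frozenset({"A1"}), 0, 1),),
        n_individuals=n_individuals,
        disruption_prob=disruption_prob,
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as tmp:
        bundle = simulate_bundle(plan, Path(tmp) / "bundle")
        _m, ctx = run_pipeline(
            bundle.config, Path(tmp) / "out", ["groups", "detect", "fixation"]
        )
        (result,) = ctx.fixation.values()
        return result.frequency, result.fixed_in_species
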