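"""Image-number / image-timing sensitivity study.

Classification models degrade as the acquisition series is thinned; this
module trains and evaluates trees on standard subsets of the available
times — the full series, two evenly spaced triplets, two evenly spaced
pairs, and every single acquisition — and tabulates per-class percent
correct (resubstitution, observed-row basis), overall accuracy and the
cross-validated risk for each subset.
"""

from __future__ import annotations

from dataclasses import dataclass

from cropclass.cart import (
    RiskEstimate,
    TreeParams,
    cross_validate,
    grow_tree,
    predict_matrix,
)
from cropclass.evaluation import accuracy_stats, confusion
from cropclass.features import MatrixData


@dataclass
class ScenarioResult:
    label: str
    times: list[str]
    per_class: dict[str, float]  # resubstitution % correct per observed class
    oa: float
    risk: RiskEstimate  # cross-validated


def scenario_label(times: list[str], all_times: list[str]) -> str:
    if list(times) == list(all_times) and len(times) > 2:
        return f"{times[0]}-{times[-1]}"
    return ",".join(times)


def default_scenarios(times: list[str]) -> list[list[str]]:
    """The standard subset battery for a series of acquisitions.

    For a seven-image series: the full set, the triplets {T1,T3,T5} and
    {T2,T4,T6}, the pairs {T2,T5} and {T3,T6}, and each singleton — 12
    scenarios. Shorter series keep whichever subsets fit (a two-image
    series yields the full set plus two singletons); the analogous
    stride-2 triplets and stride-3 pairs are taken from the first six
    times of longer series.
    """
    if not times:
        raise ValueError("empty time series")
    times = list(times)
    scenarios: list[list[str]] = [times]
    if len(times) >= 6:
        scenarios.append([times[0], times[2], times[4]])
        scenarios.append([times[1], times[3], times[5]])
        scenarios.append([times[1], times[4]])
        scenarios.append([times[2], times[5]])
    for t in times:
        scenarios.append([t])
    unique: list[list[str]] = []
    for s in scenarios:
        if s not in unique:
            unique.append(s)
    return unique


def run_scenarios(
    matrix: MatrixData,
    scenarios: list[list[str]] | None = None,
    params: TreeParams | None = None,
) -> list[ScenarioResult]:
    """Train and evaluate one tree per time subset; deterministic per seed."""
    params = params or TreeParams()
    labeled = matrix.labeled()
    if len(labeled) == 0:
        raise ValueError("matrix has no labeled rows")
    all_times = labeled.times
    scenarios = scenarios if scenarios is not None else default_scenarios(all_times)
    results: list[ScenarioResult] = []
    for times in scenarios:
        if not times:
            raise ValueError("scenario with no times")
        sub = labeled.restrict(times)
        tree = grow_tree(sub, params)
        pred = predict_matrix(tree, sub)
        cm = confusion(sub.labels.tolist(), list(pred),
                       classes=sorted(set(sub.labels) | set(pred)))
        ua, _, oa = accuracy_stats(cm)
        observed = set(sub.labels)
        per_class = {c: ua[c] for c in cm.classes if c in observed}
        risk = cross_validate(sub, params)
        results.append(
            ScenarioResult(scenario_label(times, all_times), list(times),
                           per_class, oa, risk)
        )
    return results


def scenario_table(results: list[ScenarioResult]) -> str:
    """Classes x scenarios report: % correct per class, OA and CV risk."""
    classes = sorted({c for r in results for c in r.per_class})
    header = ["class"] + [r.label for r in results]
    lines = ["\t".join(header)]
    for c in classes:
        cells = [c] + [
            f"{r.per_class[c]:.0f}" if c in r.per_class else "-" for r in results
        ]
        lines.append("\t".join(cells))
    lines.append("\t".join(["OA"] + [f"{r.oa:.1f}" for r in results]))
    lines.append("\t".join(
        ["risk"] + [f"{r.risk.risk:.2f}±{r.risk.se:.3f}" for r in results]
    ))
    return "\n".join(lines) + "\n"
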