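"""Terminal-node rule models: SQL-style predicates, files, and classification.

Every leaf of a grown tree corresponds to one rule — the conjunction of
the split conditions on its root-to-leaf path, collapsed to the tightest
interval per variable — carrying the leaf's class and probability. The
rules of one tree partition the feature space, so applying a rule set to a
record reproduces the tree's prediction exactly.

Rule files use a line-oriented SQL-like dialect:

    -- model_name: crops
    -- model_type: Crop
    -- times_used: T1,T2,T3,T4,T5,T6,T7
    WHEN T4NDVI <= 0.35 AND T1Stu > 1.2 THEN 'WHT' PROB 0.89
    WHEN TRUE THEN 'OLV' PROB 0.6

Thresholds are printed with full 17-significant-digit precision so that a
write -> parse round trip is lossless; a JSON sidecar with the same content
is written alongside for machine use.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from cropclass.cart import Tree
from cropclass.features import VARIABLES, SBVIRecord, _parse_column

MODEL_TYPES = ("NonVeg-Veg", "CropSys", "Crop")


class RuleFormatError(ValueError):
    """Raised for unparsable or inconsistent rule files."""


@dataclass
class Predicate:
    variable: str
    operator: str  # "<=" or ">"
    threshold: float

    def matches(self, value: float) -> bool:
        return value <= self.threshold if self.operator == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.variable} {self.operator} {self.threshold!r}"


@dataclass
class Rule:
    """Conjunction of interval predicates -> (class, probability)."""

    predicates: list[Predicate]
    class_label: str
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 < self.probability <= 1.0):
            raise RuleFormatError(
                f"rule probability {self.probability} outside (0, 1]"
            )
        lower: dict[str, float] = {}
        upper: dict[str, float] = {}
        for p in self.predicates:
            if p.operator == ">":
                lower[p.variable] = max(lower.get(p.variable, -float("inf")), p.threshold)
            else:
                upper[p.variable] = min(upper.get(p.variable, float("inf")), p.threshold)
        for var in set(lower) & set(upper):
            if lower[var] >= upper[var]:
                raise RuleFormatError(
                    f"rule has empty interval for {var}: "
                    f"> {lower[var]} and <= {upper[var]}"
                )

    def matches(self, record: Mapping[str, float]) -> bool:
        for p in self.predicates:
            if p.variable not in record:
                raise KeyError(f"record lacks variable {p.variable!r}")
            if not p.matches(record[p.variable]):
                return False
        return True


@dataclass
class RuleSet:
    """All leaf rules of one tree, plus provenance metadata."""

    model_name: str
    model_type: str
    times_used: list[str]
    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise RuleFormatError(
                f"model_type {self.model_type!r} not in {MODEL_TYPES}"
            )
        always_true = [r for r in self.rules if not r.predicates]
        if len(always_true) > 1:
            raise RuleFormatError("multiple always-true rules overlap")
        if len(always_true) == 1 and len(self.rules) > 1:
            raise RuleFormatError("always-true rule overlaps other rules")

    def apply(self, record: Mapping[str, float]) -> tuple[str, float]:
        """Class and probability of the (unique) matching rule."""
        for rule in self.rules:
            if rule.matches(record):
                return rule.class_label, rule.probability
        raise RuleFormatError(
            f"model {self.model_name!r}: no rule matches the record "
            "(corrupted rule file?)"
        )


@dataclass
class ClassificationOutput:
    """Per-parcel predictions of one or more rule models, in input order."""

    model_names: list[str]
    rows: list[dict]  # parcel_id + per-model (class, probability)

    def to_table(self) -> str:
        header = ["parcel"]
        for m in self.model_names:
            header += [f"{m}_class", f"{m}_probability"]
        lines = ["\t".join(header)]
        for row in self.rows:
            cells = [row["parcel"]]
            for m in self.model_names:
                cls, prob = row[m]
                cells += [cls, f"{prob:.2f}"]
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_table())


# ---------------------------------------------------------------------------


def _times_of(feature_names: Sequence[str]) -> list[str]:
    seen: list[str] = []
    for name in feature_names:
        t = _parse_column(name)[0]
        if t not in seen:
            seen.append(t)
    return seen


def tree_to_rules(tree: Tree, model_name: str, model_type: str,
                  times_used: list[str] | None = None) -> RuleSet:
    """One rule per leaf; redundant bounds collapsed to tightest interval."""
    var_order = {v: i for i, v in enumerate(tree.feature_names)}
    rules: list[Rule] = []

    def walk(node, lower: dict[str, float], upper: dict[str, float]) -> None:
        if node.split is None:
            preds: list[Predicate] = []
            for var in sorted(set(lower) | set(upper), key=var_order.get):
                if var in lower:
                    preds.append(Predicate(var, ">", lower[var]))
                if var in upper:
                    preds.append(Predicate(var, "<=", upper[var]))
            rules.append(Rule(preds, node.terminal_class, node.terminal_probability))
            return
        var, thr = node.split.variable, node.split.threshold
        lo, up = dict(lower), dict(upper)
        up[var] = min(up.get(var, float("inf")), thr)
        walk(node.left, lower, up)
        lo[var] = max(lo.get(var, -float("inf")), thr)
        walk(node.right, lo, upper)

    walk(tree.root, {}, {})
    return RuleSet(
        model_name=model_name,
        model_type=model_type,
        times_used=times_used or _times_of(tree.feature_names),
        rules=rules,
    )


# ---------------------------------------------------------------------------
# SQL dialect I/O

_RULE_RE = re.compile(
    r"^\s*(?:WHEN|WHERE)\s+(?P<body>.+?)\s+THEN\s+'(?P<cls>[^']+)'\s+PROB\s+"
    r"(?P<prob>[0-9.eE+-]+)\s*$"
)
_COND_RE = re.compile(r"^(?P<var>\S+)\s*(?P<op><=|>)\s*(?P<thr>[0-9.eE+-]+)$")
_HEADER_RE = re.compile(r"^--\s*(?P<key>model_name|model_type|times_used)\s*:\s*(?P<val>.+?)\s*$")


def _validate_variable(var: str, lineno: int, col: int) -> str:
    try:
        t, v = _parse_column(var)
    except Exception:
        raise RuleFormatError(
            f"line {lineno}, col {col}: unknown variable {var!r}"
        ) from None
    if v not in VARIABLES:
        raise RuleFormatError(f"line {lineno}, col {col}: unknown variable {var!r}")
    return f"{t}{v}"


def write_sql(ruleset: RuleSet, path: str | Path, sidecar: bool = True) -> None:
    """Write a ``.sqlmodel`` file (and a ``.json`` sidecar by default)."""
    path = Path(path)
    lines = [
        "-- cropclass rule model",
        f"-- model_name: {ruleset.model_name}",
        f"-- model_type: {ruleset.model_type}",
        f"-- times_used: {','.join(ruleset.times_used)}",
    ]
    for rule in ruleset.rules:
        body = " AND ".join(str(p) for p in rule.predicates) or "TRUE"
        lines.append(f"WHEN {body} THEN '{rule.class_label}' PROB {rule.probability!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if sidecar:
        doc = {
            "model_name": ruleset.model_name,
            "model_type": ruleset.model_type,
            "times_used": ruleset.times_used,
            "rules": [
                {
                    "predicates": [
                        {"variable": p.variable, "operator": p.operator,
                         "threshold": p.threshold}
                        for p in r.predicates
                    ],
                    "class": r.class_label,
                    "probability": r.probability,
                }
                for r in ruleset.rules
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(doc, indent=1),
                                             encoding="utf-8")


def parse_sql(path: str | Path) -> RuleSet:
    """Parse a ``.sqlmodel`` file back into a :class:`RuleSet`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rules: list[Rule] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("--"):
            m = _HEADER_RE.match(line)
            if m:
                meta[m.group("key")] = m.group("val")
            continue
        m = _RULE_RE.match(line)
        if not m:
            col = len(raw) - len(raw.lstrip()) + 1
            raise RuleFormatError(f"line {lineno}, col {col}: unparsable rule {line!r}")
        body = m.group("body").strip()
        preds: list[Predicate] = []
        if body != "TRUE":
            offset = raw.find(body)
            for cond in body.split(" AND "):
                cm = _COND_RE.match(cond.strip())
                col = raw.find(cond.strip(), offset) + 1
                if not cm:
                    raise RuleFormatError(
                        f"line {lineno}, col {col}: unparsable condition {cond!r}"
                    )
                var = _validate_variable(cm.group("var"), lineno, col)
                preds.append(Predicate(var, cm.group("op"), float(cm.group("thr"))))
        try:
            prob = float(m.group("prob"))
        except ValueError as exc:
            raise RuleFormatError(f"line {lineno}: bad probability") from exc
        rules.append(Rule(preds, m.group("cls"), prob))
    missing = [k for k in ("model_name", "model_type", "times_used") if k not in meta]
    if missing:
        raise RuleFormatError(f"{path}: missing header field(s) {missing}")
    return RuleSet(
        model_name=meta["model_name"],
        model_type=meta["model_type"],
        times_used=[t.strip() for t in meta["times_used"].split(",") if t.strip()],
        rules=rules,
    )


# ---------------------------------------------------------------------------


def classify(
    rulesets: list[RuleSet],
    records: list[SBVIRecord] | list[Mapping[str, float]],
) -> ClassificationOutput:
    """Apply each rule model to each record; output rows in input order."""
    names = [rs.model_name for rs in rulesets]
    rows = []
    for rec in records:
        if isinstance(rec, SBVIRecord):
            parcel, feats = rec.parcel_id, rec.features()
        else:
            feats = dict(rec)
            parcel = str(feats.pop("parcel", feats.pop("parcel_id", "?")))
        row: dict = {"parcel": parcel}
        for rs in rulesets:
            row[rs.model_name] = rs.apply(feats)
        rows.append(row)
    return ClassificationOutput(model_names=names, rows=rows)
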