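"""MAP rule extraction: decode trained units into human-readable logic.

Each trained unit's MAP structure (two input positions and an operator) is
paired with its readout weight and rendered as a proposition such as

    (x0 in bin 2) XOR (x1 in bin 4) => dlogit = +1.20

Rules are ranked by absolute weight and annotated with coverage (fraction
of test points on which the unit fires) and precision (agreement between
the label and the sign of the weight among firing points).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from lpbn import core
from lpbn.core import LPBNModel

__all__ = ["Rule", "extract_rules", "rule_coverage", "rule_precision",
           "render_rule", "parse_rendered_rule", "rules_to_tsv"]


@dataclass
class Rule:
    """One unit's decoded MAP structure with its readout weight."""

    unit: int
    a_index: int  # substrate position of input A
    b_index: int
    operator: str
    weight: float
    coverage: float = None
    precision: float = None
    a_label: str = ""
    b_label: str = ""


def _position_label(model: LPBNModel, idx: int) -> str:
    scheme = model.scheme
    if scheme is None:
        return f"z{idx}"
    if scheme.const_bits and idx == scheme.const0_index:
        return "CONST0"
    if scheme.const_bits and idx == scheme.const1_index:
        return "CONST1"
    feat, b = divmod(idx, scheme.B)
    return f"(x{feat} in bin {b})"


def render_rule(rule: Rule) -> str:
    a = rule.a_label or f"z{rule.a_index}"
    b = rule.b_label or f"z{rule.b_index}"
    return f"{a} {rule.operator} {b} => dlogit = {rule.weight:+.4g}"


_RENDER_RE = re.compile(
    r"^(?P<a>\(x\d+ in bin \d+\)|CONST[01]|z\d+) (?P<op>[A-Z]+) "
    r"(?P<b>\(x\d+ in bin \d+\)|CONST[01]|z\d+) => dlogit = (?P<w>[-+0-9.eE]+)$"
)


def parse_rendered_rule(text: str) -> dict:
    """Round-trip parser for rendered rule strings."""
    m = _RENDER_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable rule text: {text!r}")
    return {
        "a": m.group("a"),
        "operator": m.group("op"),
        "b": m.group("b"),
        "weight": float(m.group("w")),
    }


def extract_rules(model: LPBNModel) -> list:
    """One rule per unit from the MAP structure, sorted by |weight| desc."""
    if model.head.variant not in ("logistic", "softmax"):
        raise ValueError("rule extraction is defined for classifier heads")
    struct = core.map_structure(model.policy)
    if model.head.weights.ndim == 1:
        weights = model.head.weights
    else:  # softmax: take each unit's dominant class column entry
        W = model.head.weights
        weights = W[np.abs(W).argmax(axis=0), np.arange(model.policy.N)]
    rules = []
    for n in range(model.policy.N):
        rules.append(
            Rule(
                unit=n,
                a_index=int(struct.A[n]),
                b_index=int(struct.B[n]),
                operator=model.operators.labels[int(struct.O[n])],
                weight=float(weights[n]),
                a_label=_position_label(model, int(struct.A[n])),
                b_label=_position_label(model, int(struct.B[n])),
            )
        )
    return sorted(rules, key=lambda r: -abs(r.weight))


def _fires(rule: Rule, Z: np.ndarray) -> np.ndarray:
    return core.apply_operator(
        rule.operator, Z[:, rule.a_index], Z[:, rule.b_index]
    ).astype(bool)


def rule_coverage(rule: Rule, substrate_data: np.ndarray) -> float:
    """Fraction of rows on which the unit's antecedent fires (h_n = 1)."""
    Z = np.asarray(substrate_data, dtype=np.uint8)
    if Z.shape[0] == 0:
        raise ValueError("coverage undefined on empty data")
    return float(_fires(rule, Z).mean())


def rule_precision(rule: Rule, substrate_data: np.ndarray, labels) -> float:
    """Among firing rows, fraction whose label matches sign(weight).

    Positive weight votes for class 1, negative for class 0.
    """
    Z = np.asarray(substrate_data, dtype=np.uint8)
    y = np.asarray(labels)
    firing = _fires(rule, Z)
    if not firing.any():
        raise ValueError("precision undefined: rule never fires")
    predicted = 1 if rule.weight > 0 else 0
    return float((y[firing] == predicted).mean())


def rules_to_tsv(rules: list) -> str:
    """TSV export: rank, rule text, weight, coverage, precision."""
    lines = ["rank\trule\tweight\tcoverage\tprecision"]
    for rank, r in enumerate(rules, start=1):
        cov = "" if r.coverage is None else f"{r.coverage:.4f}"
        prec = "" if r.precision is None else f"{r.precision:.4f}"
        lines.append(f"{rank}\t{render_rule(r)}\t{r.weight:.6g}\t{cov}\t{prec}")
    return "\n".join(lines) + "\n"
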