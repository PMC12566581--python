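"""Phase-I biotransformation rules as elemental-formula deltas.

A rule is a small signed composition change (mono-hydroxylation = +O,
dehydrogenation = -H2, desulphuration = -S+O, ...).  Chains of rules model
multi-step metabolism; because only the net composition change matters for
m/z matching, chains are unordered multisets.  The shipped rule table is a
reconstruction of the common phase-I reaction set (oxidations, reductions,
hydrolyses) and is a user-editable delimited resource.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    ElementalFormula,
    FormulaError,
    M_PLUS_H,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_difference,
)

__all__ = [
    "TransformationRule",
    "RuleChain",
    "PredictedMetabolite",
    "InfeasibleRule",
    "parse_delta",
    "load_rule_table",
    "default_rule_table",
    "apply_rule",
    "predict_candidates",
    "match_predictions",
]

_GROUP = re.compile(r"([+-])([A-Za-z0-9]+)")


class InfeasibleRule(Exception):
    """Applying the rule would drive an element count negative; the chain
    is chemically impossible for this parent and must be pruned."""


def parse_delta(text: str) -> Dict[str, int]:
    """Parse a signed delta string like ``"-S+O"`` or ``"+H2O"`` into a
    signed element->count map."""
    text = text.strip()
    if not text:
        raise ValueError("empty delta string")
    pos = 0
    delta: Dict[str, int] = {}
    for match in _GROUP.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed delta string {text!r}")
        sign = 1 if match.group(1) == "+" else -1
        group = parse_formula(match.group(2))
        for el, n in group.counts.items():
            delta[el] = delta.get(el, 0) + sign * n
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed delta string {text!r}")
    return {el: n for el, n in delta.items() if n != 0}


def render_delta(delta: Dict[str, int]) -> str:
    gains = {el: n for el, n in delta.items() if n > 0}
    losses = {el: -n for el, n in delta.items() if n < 0}
    out = ""
    if gains:
        out += "+" + ElementalFormula(gains).hill()
    if losses:
        out += "-" + ElementalFormula(losses).hill()
    return out


@dataclass(frozen=True)
class TransformationRule:
    """One phase-I reaction expressed as a signed composition change."""

    name: str
    delta: Tuple[Tuple[str, int], ...]
    reaction_class: str = "other"
    enabled: bool = True

    @classmethod
    def from_delta_string(
        cls, name: str, delta: str, reaction_class: str = "other", enabled: bool = True
    ) -> "TransformationRule":
        parsed = parse_delta(delta)
        return cls(name, tuple(sorted(parsed.items())), reaction_class, enabled)

    @property
    def delta_map(self) -> Dict[str, int]:
        return dict(self.delta)

    @property
    def mass_delta(self) -> float:
        """Signed monoisotopic mass of the delta, recomputed from the
        element counts (never stored independently)."""
        return monoisotopic_mass(self.delta_map)


@dataclass(frozen=True)
class RuleChain:
    """An unordered multiset of rules applied to one parent."""

    rules: Tuple[TransformationRule, ...]

    @property
    def depth(self) -> int:
        return len(self.rules)

    @property
    def net_delta(self) -> Dict[str, int]:
        net: Dict[str, int] = {}
        for rule in self.rules:
            for el, n in rule.delta:
                net[el] = net.get(el, 0) + n
        return {el: n for el, n in net.items() if n != 0}

    @property
    def mass_delta(self) -> float:
        return monoisotopic_mass(self.net_delta)

    def provenance(self, parent_name: str) -> str:
        """Naming-style provenance string, e.g.
        ``"Molinate_Oxidation_Mono-hydroxylation/oxidation"``."""
        classes = sorted({r.reaction_class.capitalize() for r in self.rules})
        names = " + ".join(r.name for r in self.rules)
        return f"{parent_name}_{'/'.join(classes)}_{names}"


@dataclass(frozen=True)
class PredictedMetabolite:
    """A candidate metabolite: parent plus a rule chain.

    ``formula`` is present when the parent formula is known (formula mode);
    ``mz`` is always present ([M+H]+ of the formula, or parent m/z plus the
    chain's net mass delta in m/z-only mode).  The two modes agree to
    < 1e-4 Da whenever both apply.
    """

    parent_id: str
    chain: RuleChain
    mz: float
    formula: Optional[ElementalFormula] = None


def load_rule_table(path: Optional[Path] = None) -> List[TransformationRule]:
    """Load a rule table from a tab-delimited file
    (columns: name, delta, reaction_class, enabled)."""
    if path is None:
        text = (
            resources.files("phasemet.data").joinpath("phase1_rules.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    rules: List[TransformationRule] = []
    seen = set()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, delta, reaction_class, enabled = line.rstrip("\n").split("\t")
        if name in seen:
            raise ValueError(f"duplicate rule name {name!r}")
        seen.add(name)
        rules.append(
            TransformationRule.from_delta_string(
                name, delta, reaction_class, enabled=enabled.strip() not in ("0", "")
            )
        )
    return rules


def default_rule_table(include_disabled: bool = False) -> List[TransformationRule]:
    """The shipped phase-I reaction set (enabled rules only by default)."""
    rules = load_rule_table()
    if include_disabled:
        return rules
    return [r for r in rules if r.enabled]


def apply_rule(formula: ElementalFormula, rule: TransformationRule) -> ElementalFormula:
    """Apply one rule to a neutral formula.

    Raises InfeasibleRule when the delta would drive any element count
    negative — the chain is pruned, not surfaced as a user error.
    """
    try:
        return formula.apply_delta(rule.delta_map)
    except FormulaError as exc:
        raise InfeasibleRule(
            f"rule {rule.name!r} infeasible for {formula.hill()}"
        ) from exc


def predict_candidates(
    parent: ElementalFormula | float,
    rules: Sequence[TransformationRule] | None = None,
    max_depth: int = 1,
    parent_id: str = "parent",
) -> List[PredictedMetabolite]:
    """Enumerate predicted metabolites for all feasible rule chains up to
    ``max_depth``.

    ``parent`` is either a neutral formula (formula mode) or an observed
    [M+H]+ m/z (m/z-only mode).  Chains are unordered multisets; candidates
    with identical net composition change are collapsed to one (the
    shallowest chain wins), and net-zero chains (which would re-predict the
    parent itself) are dropped.  In formula mode a chain is feasible iff the
    net delta leaves every element count non-negative.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if rules is None:
        rules = default_rule_table()
    if not rules:
        raise ValueError("empty rule table")

    formula_mode = isinstance(parent, ElementalFormula)
    if formula_mode:
        parent_mz = adduct_mz(parent)
    else:
        parent_mz = float(parent)

    by_net: Dict[Tuple[Tuple[str, int], ...], RuleChain] = {}
    for depth in range(1, max_depth + 1):
        for combo in itertools.combinations_with_replacement(rules, depth):
            chain = RuleChain(tuple(combo))
            net = tuple(sorted(chain.net_delta.items()))
            if not net:
                continue
            if net in by_net:
                continue
            if formula_mode:
                try:
                    parent.apply_delta(chain.net_delta)
                except FormulaError:
                    continue
            by_net[net] = chain

    out: List[PredictedMetabolite] = []
    for net, chain in by_net.items():
        if formula_mode:
            product = parent.apply_delta(chain.net_delta)
            out.append(
                PredictedMetabolite(parent_id, chain, adduct_mz(product), product)
            )
        else:
            out.append(PredictedMetabolite(parent_id, chain, parent_mz + chain.mass_delta))
    out.sort(key=lambda c: c.mz)
    return out


def match_predictions(
    features: Sequence[Tuple[str, float]] | Sequence[float],
    candidates: Sequence[PredictedMetabolite],
    tol_ppm: float = 10.0,
) -> List[Tuple[str, PredictedMetabolite, float]]:
    """Match observed feature m/z values to predicted metabolites.

    ``features`` is a sequence of (id, m/z) pairs or bare m/z values.  Every
    (feature, candidate) pair with |ppm error| <= tol_ppm (closed interval)
    is reported; a feature may match several candidates.  Output is sorted
    by feature id then |ppm error|.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    pairs: List[Tuple[str, float]] = []
    for item in features:
        if isinstance(item, (int, float)):
            pairs.append((f"{float(item):.4f}", float(item)))
        else:
            fid, mz = item
            pairs.append((str(fid), float(mz)))
    hits: List[Tuple[str, PredictedMetabolite, float]] = []
    for fid, mz in pairs:
        for cand in candidates:
            err = ppm_difference(mz, cand.mz)
            # closed interval, with a guard for floating-point round-off at
            # the exact boundary
            if abs(err) <= tol_ppm * (1 + 1e-12) + 1e-9:
                hits.append((fid, cand, err))
    hits.sort(key=lambda h: (h[0], abs(h[2])))
    return hits
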