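"""Data-driven induction of the 20-rule Mamdani rule base.

One rule is created for every (sampling time, irrigation level) anchor
pair — 4 DAT sets x 5 level sets = 20 rules — and each rule carries one
consequent per response variable, found by classifying the cell mean into
the ten percentile-anchored output sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MissingCellError
from .partitions import FuzzyPartition
from .simulate import IRRIGATION_LEVELS, RESPONSE_VARIABLES, SAMPLING_DAYS

#: display names used when rendering rules in the "If ... then ..." style
DISPLAY_NAMES = {"ln": "LN", "fsb": "FSB", "frb": "FRB",
                 "dsb": "DSB", "drb": "DRB"}


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedent (P-set, L-set) with one C-set consequent per variable."""

    dat_index: int  # 1..4, set P{dat_index}
    il_index: int   # 1..5, set L{il_index}
    consequents: dict  # variable -> 1..10, set C{index}

    def render(self) -> str:
        parts = ", ".join(
            f'{DISPLAY_NAMES.get(v, v)} is "C{c}"'
            for v, c in self.consequents.items()
        )
        return (f'If (DAT is "P{self.dat_index}") and '
                f'(irrigation level is "L{self.il_index}"), '
                f"then ({parts})")

    def to_dict(self) -> dict:
        return {"dat_index": self.dat_index, "il_index": self.il_index,
                "consequents": dict(self.consequents)}

    @classmethod
    def from_dict(cls, payload: dict) -> "FuzzyRule":
        return cls(dat_index=payload["dat_index"],
                   il_index=payload["il_index"],
                   consequents={v: int(c)
                                for v, c in payload["consequents"].items()})


def classify_output(value: float, partition: FuzzyPartition) -> int:
    """Map a crisp value to the 1-based index of its output set.

    Values on a plateau take that set; values in a transition band take
    the set with the greater membership, ties resolved to the lower
    index; values at or below the first plateau map to set 1 and values
    at or beyond the last plateau to the highest set (the clamping form
    of the percentile rule list).
    """
    value = float(value)
    if not np.isfinite(value):
        raise ValueError("cannot classify a non-finite value")
    sets = partition.sets
    n = len(sets)
    if value <= sets[0].c:
        return 1
    if value >= sets[-1].b:
        return n
    for m in range(1, n):  # set m's plateau, then its transition to m+1
        plateau_hi, foot = sets[m - 1].c, sets[m - 1].d
        if value <= plateau_hi:
            return m
        if value <= foot:
            # complementary ramps: membership of set m exceeds set m+1's
            # exactly up to the interval midpoint; ties go to the lower index
            return m if value <= 0.5 * (plateau_hi + foot) else m + 1
    return n


def build_rule_base(cell_means_by_variable: dict,
                    output_partitions: dict) -> list[FuzzyRule]:
    """Induce the 20 rules for one (water, cycle) slice.

    ``cell_means_by_variable`` maps variable -> {(dat, il): mean} and must
    cover all 20 design cells for each of the five variables;
    ``output_partitions`` maps variable -> its ten-set partition.
    """
    for var in RESPONSE_VARIABLES:
        if var not in cell_means_by_variable:
            raise MissingCellError(f"no cell means supplied for {var!r}")
        if var not in output_partitions:
            raise MissingCellError(f"no output partition supplied for {var!r}")
    rules = []
    for p_index, dat in enumerate(SAMPLING_DAYS, start=1):
        for l_index, il in enumerate(IRRIGATION_LEVELS, start=1):
            consequents = {}
            for var in RESPONSE_VARIABLES:
                means = cell_means_by_variable[var]
                if (dat, il) not in means:
                    raise MissingCellError(
                        f"missing cell mean for {var!r} at "
                        f"dat={dat}, irrigation_level={il}"
                    )
                consequents[var] = classify_output(
                    means[(dat, il)], output_partitions[var]
                )
            rules.append(FuzzyRule(dat_index=p_index, il_index=l_index,
                                   consequents=consequents))
    return rules


def render_rule_base(rules: list[FuzzyRule]) -> str:
    """Pretty-print the rule base, one textual rule per line."""
    return "\n".join(rule.render() for rule in rules)
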