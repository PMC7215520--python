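"""Consensus merging of binding-site residue predictions.

Independent binding-site predictors (e.g. a grid-based pocket finder and a
protein–protein interface meta-predictor) each emit a list of residues.
Residues found by every predictor — or by at least ``k`` of them under the
majority rule — form the consensus binding site. Set identity is by residue
number (predictor lists rarely carry chain IDs); conflicting residue names
at the same number raise a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from importlib import resources

from .trajectory import ResidueLabel, ResidueSet, TrajectoryError, parse_residue_set

__all__ = [
    "ResidueSet",
    "ConsensusResult",
    "consensus",
    "annotate",
    "union",
    "bundled_binding_site_groups",
]


@dataclass
class ConsensusResult:
    """A consensus residue set plus the bookkeeping behind it."""

    consensus: ResidueSet
    source_counts: dict[str, int]
    intersection_size: int
    union_size: int
    rule: str
    annotations: dict[int, set[str]] = field(default_factory=dict)
    tag_membership: dict[str, list[ResidueLabel]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.consensus)


def _number_index(sets: list[ResidueSet]) -> tuple[dict[int, list[str]], dict[int, ResidueLabel]]:
    """Per residue number: which sets contain it, and a representative label."""
    containing: dict[int, list[str]] = {}
    representative: dict[int, ResidueLabel] = {}
    names_seen: dict[int, set[str]] = {}
    for s in sets:
        for member in s.members:
            num = member.residue_number
            containing.setdefault(num, []).append(s.name)
            representative.setdefault(num, member)
            names_seen.setdefault(num, set()).add(member.residue_name)
    for num, names in names_seen.items():
        if len(names) > 1:
            warnings.warn(
                f"residue {num} carries conflicting names across sets: {sorted(names)}",
                RuntimeWarning,
                stacklevel=3,
            )
    return containing, representative


def consensus(sets: list[ResidueSet], rule: str | int = "intersection") -> ConsensusResult:
    """Merge predictor residue sets into a consensus.

    ``rule="intersection"`` keeps residues present in every set (the strict
    two-predictor consensus); ``rule="union"`` keeps all; an integer ``k``
    applies the majority rule (present in at least ``k`` sets, so
    ``k=1`` is the union and ``k=len(sets)`` the intersection).
    """
    if not sets:
        raise TrajectoryError("consensus needs at least one residue set")
    if rule == "intersection":
        k = len(sets)
        rule_name = "intersection"
    elif rule == "union":
        k = 1
        rule_name = "union"
    elif isinstance(rule, int):
        if not 1 <= rule <= len(sets):
            raise TrajectoryError(f"majority threshold {rule} outside 1..{len(sets)}")
        k = rule
        rule_name = f"majority({rule})"
    else:
        raise TrajectoryError(f"unknown consensus rule {rule!r}")

    containing, representative = _number_index(sets)
    chosen = sorted(num for num, srcs in containing.items() if len(set(srcs)) >= k)
    all_nums = set(containing)
    inter = {num for num, srcs in containing.items() if len(set(srcs)) == len(sets)}
    members = frozenset(representative[num] for num in chosen)
    return ConsensusResult(
        consensus=ResidueSet(name="consensus", members=members),
        source_counts={s.name: len(s) for s in sets},
        intersection_size=len(inter),
        union_size=len(all_nums),
        rule=rule_name,
    )


def annotate(
    result: ConsensusResult, annotations: list[tuple[str, ResidueSet]]
) -> ConsensusResult:
    """Tag consensus residues with annotation sets (variant positions,
    stability residues, terminal groups, ...) and report per-tag membership."""
    tag_map = {num: set(tags) for num, tags in result.annotations.items()}
    membership = {tag: list(labels) for tag, labels in result.tag_membership.items()}
    consensus_numbers = result.consensus.numbers()
    for tag, rset in annotations:
        hits = sorted(
            (m for m in rset.members if m.residue_number in consensus_numbers),
            key=lambda m: m.residue_number,
        )
        membership[tag] = hits
        for m in hits:
            tag_map.setdefault(m.residue_number, set()).add(tag)
    return ConsensusResult(
        consensus=result.consensus,
        source_counts=dict(result.source_counts),
        intersection_size=result.intersection_size,
        union_size=result.union_size,
        rule=result.rule,
        annotations=tag_map,
        tag_membership=membership,
    )


def union(sets: list[ResidueSet], name: str = "union") -> ResidueSet:
    """Union of residue sets (identity by residue number)."""
    merged = consensus(sets, rule="union")
    return ResidueSet(name=name, members=merged.consensus.members)


def bundled_binding_site_groups() -> list[ResidueSet]:
    """The published carbonic anhydrase VIII consensus binding site, as its
    three positional groups (N-terminal, central, C-terminal); their union
    is the 38-residue consensus."""
    groups = []
    root = resources.files("resdyn").joinpath("data", "binding_site")
    for stem in ("nterminal", "central", "cterminal"):
        text = root.joinpath(f"{stem}.txt").read_text(encoding="utf-8")
        groups.append(parse_residue_set(text, name=stem))
    return groups
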