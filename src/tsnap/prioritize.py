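"""Band-based selection of synthesis targets from candidate groups.

Compounds sharing one macrocycle backbone (same thf, enoate and alkene
geometry) form a candidate group — six members in a full library (three
side chains x two carbinol epimers).  A group is selected when at least
one member's C_s^max falls inside a closed band (default [0.55, 0.70]):
high enough to stay natural-product-like, low enough to exclude
near-replicas of the reference set.  Every member of a selected group
becomes a synthesis target, so selection always promotes whole groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from tsnap.blocks import LibraryManifest, VirtualCompound


@dataclass(frozen=True)
class SelectionConfig:
    """Closed C_s band for prioritization."""

    low: float = 0.55
    high: float = 0.70

    def __post_init__(self):
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError("band must satisfy 0 <= low <= high <= 1")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass
class CandidateGroup:
    """Compounds sharing one macrocycle backbone, with their C_s^max values."""

    backbone_key: tuple[str, str, str]
    members: list[VirtualCompound]
    cs_max: dict[str, float]  # compound id -> C_s^max
    expected_size: int = 6

    @property
    def complete(self) -> bool:
        return len(self.members) == self.expected_size

    def triggering_members(self, config: SelectionConfig) -> list[str]:
        return [c.id for c in self.members if config.contains(self.cs_max[c.id])]


@dataclass
class SelectionResult:
    selected_groups: list[CandidateGroup]
    rejected_groups: list[CandidateGroup]
    config: SelectionConfig

    @property
    def targets(self) -> list[VirtualCompound]:
        return [c for g in self.selected_groups for c in g.members]

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "backbone_key", "cs_max", "triggering"])
            for g in self.selected_groups:
                trig = set(g.triggering_members(self.config))
                for c in g.members:
                    w.writerow([c.id, "|".join(g.backbone_key),
                                f"{g.cs_max[c.id]:.4f}", int(c.id in trig)])


def group_candidates(manifest: LibraryManifest,
                     profiles: dict[str, float]) -> list[CandidateGroup]:
    """Group manifest compounds by backbone; ``profiles`` maps id -> C_s^max.

    Partial groups (toy or filtered libraries) are allowed and flagged
    via :attr:`CandidateGroup.complete`.
    """
    missing = [c.id for c in manifest.compounds if c.id not in profiles]
    if missing:
        raise KeyError(f"no C_s profile for compounds: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    groups: dict[tuple[str, str, str], list[VirtualCompound]] = {}
    for c in manifest.compounds:
        groups.setdefault(c.backbone_key, []).append(c)
    return [
        CandidateGroup(key, members, {c.id: profiles[c.id] for c in members})
        for key, members in sorted(groups.items())
    ]


def select_targets(groups: list[CandidateGroup],
                   config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Apply the band rule: any member inside the band selects the whole group."""
    selected, rejected = [], []
    for g in groups:
        (selected if g.triggering_members(config) else rejected).append(g)
    return SelectionResult(selected, rejected, config)


def coverage_report(selection: SelectionResult) -> dict[str, dict[str, int]]:
    """Building-block usage across targets: role -> block id -> target count."""
    usage: dict[str, dict[str, int]] = {"thf": {}, "enoate": {}, "sidechain": {}}
    for c in selection.targets:
        usage["thf"][c.thf_id] = usage["thf"].get(c.thf_id, 0) + 1
        usage["enoate"][c.enoate_id] = usage["enoate"].get(c.enoate_id, 0) + 1
        usage["sidechain"][c.sidechain_id] = usage["sidechain"].get(c.sidechain_id, 0) + 1
    return usage
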