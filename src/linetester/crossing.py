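"""Lines, testers, heterotic groups, and the line × tester crossing plan.

A line-by-tester plan crosses each candidate inbred line to a small set of
testers from the *opposite* heterotic group.  The plan is a bipartite graph
(lines vs testers, edges = realized crosses); joint estimability of GCA
contrasts requires that graph to be connected, so connectivity is enforced
as a hard invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "InbredLine",
    "Tester",
    "CrossingPlan",
    "DesignError",
    "build_crossing_plan",
    "design_summary",
    "plan_from_tables",
]

HETEROTIC_GROUPS = ("A", "B")


class DesignError(ValueError):
    """Raised for invalid crossing plans (wrong groups, disconnection, ...)."""


@dataclass(frozen=True)
class InbredLine:
    line_id: str
    heterotic_group: str
    pedigree: str | None = None

    def __post_init__(self):
        if self.heterotic_group not in HETEROTIC_GROUPS:
            raise DesignError(f"unknown heterotic group {self.heterotic_group!r}")


@dataclass(frozen=True)
class Tester:
    """A genetically fixed crossing partner; here always a single-cross hybrid."""

    tester_id: str
    heterotic_group: str
    type: str = "single-cross"

    def __post_init__(self):
        if self.heterotic_group not in HETEROTIC_GROUPS:
            raise DesignError(f"unknown heterotic group {self.heterotic_group!r}")


@dataclass
class CrossingPlan:
    lines: list[InbredLine]
    testers: list[Tester]
    crosses: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.validate()

    @property
    def line_ids(self) -> list[str]:
        return [l.line_id for l in self.lines]

    @property
    def tester_ids(self) -> list[str]:
        return [t.tester_id for t in self.testers]

    def graph(self) -> nx.Graph:
        """Bipartite line–tester graph with crosses as edges."""
        g = nx.Graph()
        g.add_nodes_from((("L", l) for l in self.line_ids), bipartite=0)
        g.add_nodes_from((("T", t) for t in self.tester_ids), bipartite=1)
        g.add_edges_from((("L", l), ("T", t)) for l, t in self.crosses)
        return g

    def is_connected(self) -> bool:
        """True when each heterotic sub-design is internally connected.

        Crosses only join lines to opposite-group testers, so the full
        line–tester graph naturally splits into (at most) two sub-designs:
        group-A lines with group-B testers, and vice versa.  GCA contrasts
        are jointly estimable within a sub-design only if its bipartite
        graph is connected; between sub-designs only the shared trial mean
        links the scales, which is what the constraint system assumes.
        """
        lgroup = {l.line_id: l.heterotic_group for l in self.lines}
        for grp in HETEROTIC_GROUPS:
            edges = [(("L", l), ("T", t)) for l, t in self.crosses if lgroup[l] == grp]
            if not edges:
                continue
            g = nx.Graph(edges)
            if not nx.is_connected(g):
                return False
        return True

    def validate(self) -> None:
        ids = self.line_ids
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate line_id in plan")
        tids = self.tester_ids
        if len(set(tids)) != len(tids):
            raise DesignError("duplicate tester_id in plan")
        lgroup = {l.line_id: l.heterotic_group for l in self.lines}
        tgroup = {t.tester_id: t.heterotic_group for t in self.testers}
        for lid, tid in self.crosses:
            if lid not in lgroup or tid not in tgroup:
                raise DesignError(f"cross ({lid}, {tid}) references unknown parents")
            if lgroup[lid] == tgroup[tid]:
                raise DesignError(
                    f"cross ({lid}, {tid}) pairs parents from the same heterotic group")
        if self.crosses:
            crossed_lines = {l for l, _ in self.crosses}
            uncrossed = set(ids) - crossed_lines
            if uncrossed:
                raise DesignError(f"lines with no crosses: {sorted(uncrossed)[:10]}")
            if not self.is_connected():
                raise DesignError(
                    "crossing plan is disconnected: GCA contrasts are not jointly estimable")


def build_crossing_plan(
    lines: Iterable[InbredLine],
    testers: Iterable[Tester],
    testers_per_line: int = 3,
) -> CrossingPlan:
    """Cross every line to ``testers_per_line`` opposite-group testers.

    When a group has exactly ``testers_per_line`` opposite testers, each of
    its lines is crossed to all of them; with more available, assignment is
    deterministic by sorted tester label (a reproducible stand-in for the
    field's actual assignment sheet).

    Raises
    ------
    DesignError
        If some group lacks enough opposite-group testers, or the resulting
        plan is disconnected.
    """
    lines = list(lines)
    testers = list(testers)
    by_group: dict[str, list[str]] = {g: [] for g in HETEROTIC_GROUPS}
    for t in testers:
        by_group[t.heterotic_group].append(t.tester_id)
    for g in by_group:
        by_group[g].sort()

    crosses: set[tuple[str, str]] = set()
    for line in lines:
        opposite = "B" if line.heterotic_group == "A" else "A"
        avail = by_group[opposite]
        if len(avail) < testers_per_line:
            raise DesignError(
                f"line {line.line_id} (group {line.heterotic_group}) needs "
                f"{testers_per_line} opposite-group testers, only {len(avail)} available")
        for tid in avail[:testers_per_line]:
            crosses.add((line.line_id, tid))
    return CrossingPlan(lines, testers, crosses)


def design_summary(plan: CrossingPlan) -> dict:
    """Counts table: lines per group, crosses per tester, total crosses."""
    line_groups: dict[str, int] = {}
    for l in plan.lines:
        line_groups[l.heterotic_group] = line_groups.get(l.heterotic_group, 0) + 1
    per_tester = {t: 0 for t in plan.tester_ids}
    for _, tid in plan.crosses:
        per_tester[tid] += 1
    return {
        "n_lines": len(plan.lines),
        "n_testers": len(plan.testers),
        "line_groups": line_groups,
        "crosses_per_tester": per_tester,
        "total_crosses": len(plan.crosses),
    }


def plan_from_tables(
    lines_df: pd.DataFrame,
    testers_df: pd.DataFrame,
    crosses_df: pd.DataFrame | None = None,
    testers_per_line: int = 3,
) -> CrossingPlan:
    """Build a plan from pedigree/plan tables.

    ``lines_df`` needs columns ``line_id, heterotic_group``; ``testers_df``
    needs ``tester_id, heterotic_group``.  With an explicit ``crosses_df``
    (``line_id, tester_id``) those crosses are used verbatim; otherwise the
    deterministic assignment of :func:`build_crossing_plan` applies.
    """
    lines = [InbredLine(str(r.line_id), str(r.heterotic_group))
             for r in lines_df.itertuples(index=False)]
    testers = [Tester(str(r.tester_id), str(r.heterotic_group))
               for r in testers_df.itertuples(index=False)]
    if crosses_df is None:
        return build_crossing_plan(lines, testers, testers_per_line)
    crosses = {(str(r.line_id), str(r.tester_id)) for r in crosses_df.itertuples(index=False)}
    return CrossingPlan(lines, testers, crosses)
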