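"""Lineage assignment from diagnostic alignment positions.

A column is diagnostic between groups when, ignoring missing characters
(N, ?, -), each focal group is monomorphic and the groups' states
differ.  A partial query consensus is scored by counting, over the
columns where it has a call, how many diagnostic states it shares with
each group; the verdict is the group with a strict majority of
agreements.  The same machinery runs at any label level ("lineage" or
"phylogroup"), which is what lets a query agree with one lineage overall
while sitting outside a particular phylogroup.

Uncorrected p-distances (pairwise deletion) complement the site-based
assignment with the group divergence ranges used in diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .core import IUPAC_CODES, MISSING, ReferencePanel
from .consensus import ConsensusResult

__all__ = [
    "DiagnosticSite",
    "AssignmentReport",
    "find_diagnostic_sites",
    "score_query",
    "p_distance",
    "group_distance_range",
]


@dataclass
class DiagnosticSite:
    """An alignment column fixed within and different between groups."""

    column: int
    level: str
    state_by_group: dict[str, str]
    groups_compared: tuple[str, ...]


@dataclass
class AssignmentReport:
    """Agreement of a partial query with each focal group."""

    level: str
    groups: tuple[str, ...]
    agreement: dict[str, int]
    agreeing_columns: dict[str, list[int]]
    weak_columns: dict[str, list[int]] = field(default_factory=dict)
    off_pattern_columns: list[int] = field(default_factory=list)
    n_sites_total: int = 0
    n_sites_query_informative: int = 0
    verdict: str = "ambiguous"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "groups": list(self.groups),
            "agreement": dict(self.agreement),
            "agreeing_columns": {k: list(v) for k, v in self.agreeing_columns.items()},
            "weak_columns": {k: list(v) for k, v in self.weak_columns.items()},
            "off_pattern_columns": list(self.off_pattern_columns),
            "n_sites_total": self.n_sites_total,
            "n_sites_query_informative": self.n_sites_query_informative,
            "verdict": self.verdict,
        }


def find_diagnostic_sites(
    panel: ReferencePanel,
    locus: str,
    level: str = "lineage",
    focal_groups: list[str] | None = None,
) -> list[DiagnosticSite]:
    """All columns of a locus alignment diagnostic between focal groups.

    Missing characters are ignored when testing monomorphism; a column
    where any focal group has no non-missing member is skipped.
    """
    groups = panel.groups(locus, level)
    if focal_groups is None:
        focal_groups = sorted(groups)
    for g in focal_groups:
        if g not in groups:
            raise ValueError(f"unknown {level} label {g!r}")
    members = {g: [s.residues for s in groups[g]] for g in focal_groups}
    length = panel.alignment_length(locus)

    sites = []
    for col in range(length):
        state_by_group: dict[str, str] = {}
        ok = True
        for g in focal_groups:
            states = {seq[col] for seq in members[g]} - MISSING
            if len(states) != 1:
                ok = False  # polymorphic or entirely missing
                break
            state_by_group[g] = states.pop()
        if ok and len(set(state_by_group.values())) == len(focal_groups):
            sites.append(
                DiagnosticSite(
                    column=col,
                    level=level,
                    state_by_group=state_by_group,
                    groups_compared=tuple(focal_groups),
                )
            )
    return sites


def score_query(
    query: ConsensusResult | str,
    sites: list[DiagnosticSite],
    alignment_length: int | None = None,
) -> AssignmentReport:
    """Score a partial query at each diagnostic site.

    At every site where the query has a call, the group whose state the
    query matches is credited; a query call matching no focal group's
    state is recorded as off-pattern.  An IUPAC-ambiguous query call
    matches a group iff the group's state is in its ambiguity set; such
    matches are flagged weak.  Verdict is the strict-majority group,
    else "ambiguous".
    """
    seq = query.called if isinstance(query, ConsensusResult) else query.upper()
    if alignment_length is not None and len(seq) != alignment_length:
        raise ValueError(
            f"query length {len(seq)} != alignment length {alignment_length}"
        )
    if sites:
        needed = max(s.column for s in sites) + 1
        if len(seq) < needed:
            raise ValueError(
                f"query length {len(seq)} shorter than site column {needed - 1}"
            )
        groups = sites[0].groups_compared
        level = sites[0].level
    else:
        groups, level = (), ""

    agreement = {g: 0 for g in groups}
    agreeing: dict[str, list[int]] = {g: [] for g in groups}
    weak: dict[str, list[int]] = {g: [] for g in groups}
    off_pattern: list[int] = []
    informative = 0
    for site in sites:
        call = seq[site.column]
        if call in MISSING:
            continue
        informative += 1
        call_set = set(IUPAC_CODES.get(call, call))
        exact = [g for g, st in site.state_by_group.items() if st == call]
        if exact:
            for g in exact:
                agreement[g] += 1
                agreeing[g].append(site.column)
            continue
        compatible = [
            g for g, st in site.state_by_group.items() if st in call_set
        ]
        if len(call_set) > 1 and compatible:
            for g in compatible:
                agreement[g] += 1
                agreeing[g].append(site.column)
                weak[g].append(site.column)
        else:
            off_pattern.append(site.column)

    verdict = "ambiguous"
    if agreement:
        ranked = sorted(agreement.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] > 0 and (
            len(ranked) == 1 or ranked[0][1] > ranked[1][1]
        ):
            verdict = ranked[0][0]
    return AssignmentReport(
        level=level,
        groups=tuple(groups),
        agreement=agreement,
        agreeing_columns=agreeing,
        weak_columns=weak,
        off_pattern_columns=off_pattern,
        n_sites_total=len(sites),
        n_sites_query_informative=informative,
        verdict=verdict,
    )


def p_distance(a: str, b: str) -> float:
    """Uncorrected pairwise distance with pairwise deletion.

    Columns where either sequence has a missing character (N, ?, -) are
    excluded; the distance is differing / compared columns.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    compared = differing = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return differing / compared


def group_distance_range(
    panel: ReferencePanel, locus: str, group_a: str, group_b: str,
    level: str = "lineage",
) -> tuple[float, float]:
    """(min, max) uncorrected p-distance over all cross-group pairs."""
    groups = panel.groups(locus, level)
    for g in (group_a, group_b):
        if not groups.get(g):
            raise ValueError(f"empty or unknown group {g!r}")
    dists = [
        p_distance(x.residues, y.residues)
        for x, y in product(groups[group_a], groups[group_b])
    ]
    return min(dists), max(dists)
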