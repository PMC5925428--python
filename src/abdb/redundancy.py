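"""Redundancy detection across processed antibody sets.

Two antibodies are redundant when, at every numbered position label observed
in both structures (over all chains of the antibody), the amino acids agree;
positions missing from either structure — unmodelled loops, shorter termini —
are ignored.  Redundancy so defined is not transitive, and clusters are its
single-linkage transitive closure.  A cluster's representative is chosen by
discarding the shorter structures and then taking the one with the best
(numerically smallest) resolution; structures without a resolution (NMR,
some EM) rank last.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LabeledSequence:
    """Observed residues per chain role: {role: {position label: amino acid}}."""
    form: str  # complete | light_only | heavy_only
    chains: tuple  # ((role, ((label, aa), ...)), ...) frozen for hashability

    @classmethod
    def from_dict(cls, form: str, chains: dict) -> "LabeledSequence":
        return cls(form, tuple(sorted(
            (role, tuple(sorted(positions.items()))) for role, positions in chains.items())))

    def as_dict(self) -> dict:
        return {role: dict(pos) for role, pos in self.chains}

    @property
    def length(self) -> int:
        return sum(len(pos) for _, pos in self.chains)


def redundant_pair(a: LabeledSequence, b: LabeledSequence) -> bool:
    """True iff every position label present in both antibodies agrees.

    Antibodies of different forms are never compared; with no shared labels
    at all the pair is not redundant.
    """
    if a.form != b.form:
        raise ValueError("redundancy is only defined within one antibody form")
    da, db = a.as_dict(), b.as_dict()
    shared = 0
    for role in set(da) & set(db):
        for label in da[role].keys() & db[role].keys():
            if da[role][label] != db[role][label]:
                return False
            shared += 1
    return shared > 0


@dataclass
class RedundancyCluster:
    members: list  # sorted set_ids
    representative: str = ""

    def __post_init__(self):
        self.members = sorted(self.members)
        if self.representative and self.representative not in self.members:
            raise ValueError("representative must be a member")


def cluster(labeled: dict) -> list:
    """Single-linkage clusters over {set_id: LabeledSequence}.

    Returns clusters partitioning the input, each with members sorted and
    clusters ordered by their smallest set_id.
    """
    ids = sorted(labeled)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if redundant_pair(labeled[a], labeled[b]):
                parent[find(a)] = find(b)
    groups: dict = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return [RedundancyCluster(members=m) for m in
            sorted(groups.values(), key=lambda m: min(m))]


def select_representative(clust: RedundancyCluster, metadata: dict) -> str:
    """Pick the cluster representative.

    ``metadata`` maps set_id to (observed residue count, resolution-or-None).
    Longest structures are kept; among them the best resolution wins, with
    resolution-less members ranked after all resolved ones and remaining ties
    broken by the lexicographically smallest set_id.
    """
    missing = [m for m in clust.members if m not in metadata]
    if missing:
        raise KeyError(f"metadata missing for {missing}")
    max_len = max(metadata[m][0] for m in clust.members)
    longest = [m for m in clust.members if metadata[m][0] == max_len]

    def key(m):
        res = metadata[m][1]
        return (res is None, res if res is not None else 0.0, m)

    rep = min(longest, key=key)
    clust.representative = rep
    return rep


def emit_redundancy_list(clusters: list) -> str:
    """Tab-separated cluster list: set_id, cluster ordinal, representative flag."""
    lines = ["#set_id\tcluster\trepresentative"]
    for ordinal, c in enumerate(clusters, start=1):
        for m in c.members:
            flag = "1" if m == c.representative else "0"
            lines.append(f"{m}\t{ordinal}\t{flag}")
    return "\n".join(lines) + "\n"


def free_complexed_pairs(clusters: list, status: dict) -> list:
    """Clusters whose members occur both free and complexed.

    ``status`` maps set_id to its complex class.  Returns rows
    (free members, complexed members) for each such cluster.
    """
    rows = []
    for c in clusters:
        free = [m for m in c.members if status[m] == "free"]
        bound = [m for m in c.members if status[m] != "free"]
        if free and bound:
            rows.append((free, bound))
    return rows


def emit_free_complexed_list(rows: list) -> str:
    lines = ["#free_set_ids\tcomplexed_set_ids"]
    for free, bound in rows:
        lines.append(",".join(free) + "\t" + ",".join(bound))
    return "\n".join(lines) + "\n"
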