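"""Weighted clade-representation statistics over ortholog-cluster
presence/absence, core-gene selection, tree-candidate selection, and
exclusively-shared-gene screening.

Representation is weight-based and uses presence only (count >= 1); the
exclusivity index is count-based and includes paralogs.  The asymmetry is
deliberate and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from arcogkit.genome_weighting import GenomeWeightTable, clade_weight_totals
from arcogkit.tree_io import CladeMap, MembershipTable

PSEUDOCOUNT = 1e-4

#: R_E tier boundaries for contribution units: (upper bound of tier 1,
#: upper bound of tier 2); anything above scores 3.  With the 1e-4
#: pseudocount, strictly exclusive single-copy clusters land at ~1e4+, so the
#: top tier isolates strict exclusivity.
DEFAULT_UNIT_BOUNDS = (100.0, 1e4)


@dataclass
class PhyleticMatrix:
    """cluster_id -> {genome_id -> member count}; absent genomes count 0."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_membership(cls, membership: MembershipTable) -> "PhyleticMatrix":
        counts: dict[str, dict[str, int]] = {}
        for genome, _gene, cluster in membership.records:
            row = counts.setdefault(cluster, {})
            row[genome] = row.get(genome, 0) + 1
        return cls(counts)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.counts)

    def count(self, cluster: str, genome: str) -> int:
        return self.counts.get(cluster, {}).get(genome, 0)

    def clade_member_counts(
        self, cluster: str, clades: CladeMap
    ) -> dict[str, int]:
        """C_i: number of members (genes, counting paralogs) of each clade in
        the cluster; every clade of the map appears, absent ones at 0."""
        out = {clade: 0 for clade in clades.clades}
        for genome, n in self.counts.get(cluster, {}).items():
            clade = clades.get(genome)
            if clade is not None:
                out[clade] += n
        return out


# RepresentationProfile: {cluster_id: {clade_id: representation in [0, 1]}}
RepresentationProfile = dict[str, dict[str, float]]


def clade_representation(
    matrix: PhyleticMatrix,
    weights: GenomeWeightTable,
    clades: CladeMap,
) -> RepresentationProfile:
    """Per cluster and clade: (sum of weights of the clade's genomes with at
    least one member) / (sum of weights of all the clade's genomes)."""
    totals = clade_weight_totals(weights, clades)
    zero = [c for c, t in totals.items() if t <= 0]
    if zero:
        raise ValueError(f"clade(s) with zero total weight: {sorted(zero)}")
    profile: RepresentationProfile = {}
    for cluster, row in matrix.counts.items():
        present: dict[str, float] = {}
        for genome, n in row.items():
            if n < 1:
                continue
            clade = clades.get(genome)
            if clade is None or genome not in weights:
                continue
            present[clade] = present.get(clade, 0.0) + weights[genome]
        profile[cluster] = {
            clade: present.get(clade, 0.0) / totals[clade] for clade in totals
        }
    return profile


def select_core(
    profile: RepresentationProfile,
    excluded_clades: set[str] = frozenset(),
    threshold: float = 0.75,
) -> set[str]:
    """Clusters represented at >= threshold in every non-excluded clade."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    selected: set[str] = set()
    for cluster, reps in profile.items():
        considered = {c: r for c, r in reps.items() if c not in excluded_clades}
        if not considered:
            raise ValueError("all clades excluded from core selection")
        if all(r >= threshold for r in considered.values()):
            selected.add(cluster)
    return selected


def select_tree_candidates(
    profile: RepresentationProfile,
    min_clades: int = 4,
    threshold: float = 0.5,
) -> set[str]:
    """Clusters with at least ``min_clades`` clades represented strictly above
    ``threshold`` (candidates for per-cluster tree inference)."""
    if min_clades < 2:
        raise ValueError(f"min_clades must be >= 2, got {min_clades}")
    return {
        cluster
        for cluster, reps in profile.items()
        if sum(1 for r in reps.values() if r > threshold) >= min_clades
    }


def exclusivity_index(
    matrix: PhyleticMatrix,
    clades: CladeMap,
    in_set: set[str],
    pseudocount: float = PSEUDOCOUNT,
) -> dict[str, float]:
    """R_E = (min in-set clade member count + eps) / (max out-set clade member
    count + eps), per cluster.  Counts include paralogs; weights play no role.
    """
    in_set = set(in_set)
    all_clades = clades.clades
    if not in_set:
        raise ValueError("in_set must be non-empty")
    if not in_set < all_clades:
        raise ValueError(
            "in_set must be a proper subset of the clade map's clades"
        )
    out_set = all_clades - in_set
    index: dict[str, float] = {}
    for cluster in matrix.counts:
        counts = matrix.clade_member_counts(cluster, clades)
        c_min = min(counts[c] for c in in_set)
        c_max = max(counts[c] for c in out_set)
        index[cluster] = (c_min + pseudocount) / (c_max + pseudocount)
    return index


def exclusive_screen(
    matrix: PhyleticMatrix,
    clades: CladeMap,
    in_set: set[str],
    cutoff: float = 10.0,
) -> list[tuple[str, float]]:
    """Clusters with R_E strictly above ``cutoff``, sorted by descending R_E
    (ties broken by cluster id)."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    index = exclusivity_index(matrix, clades, in_set)
    hits = [(c, r) for c, r in index.items() if r > cutoff]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return hits


def contribution_units(
    r_e: float,
    cutoff: float = 10.0,
    bounds: tuple[float, float] = DEFAULT_UNIT_BOUNDS,
) -> int:
    """Tier score in {1, 2, 3} for a screened cluster, monotone in R_E."""
    if not r_e > cutoff:
        raise ValueError(
            f"R_E={r_e} did not pass the exclusivity screen (cutoff {cutoff})"
        )
    lo, hi = bounds
    if r_e <= lo:
        return 1
    if r_e <= hi:
        return 2
    return 3


def representation_frame(profile: RepresentationProfile) -> pd.DataFrame:
    """Long-format (cluster_id, clade_id, representation) frame, sorted."""
    rows = [
        (cluster, clade, rep)
        for cluster, reps in profile.items()
        for clade, rep in reps.items()
    ]
    df = pd.DataFrame(rows, columns=["cluster_id", "clade_id", "representation"])
    return df.sort_values(["cluster_id", "clade_id"]).reset_index(drop=True)
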