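"""Alignment cleaning ahead of tree inference: gappy / heterogeneous site
removal, fragmented-row removal, and post-filter clade re-qualification.

Column homogeneity is the mean pairwise residue similarity over the non-gap
residues of a column, under BLOSUM62 affinely rescaled so the matrix's
maximal diagonal entry maps to 1 and its minimum entry to 0.  Columns with
fewer than two non-gap residues score 0 by convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Align import substitution_matrices

from arcogkit.genome_weighting import GenomeWeightTable, clade_weight_totals
from arcogkit.tree_io import GAP_CHARS, Alignment, CladeMap, genome_of

DEFAULT_MAX_GAP = 0.5
DEFAULT_MIN_HOM = 0.1
DEFAULT_MAX_ROW_GAP = 2.0 / 3.0


def _rescaled_blosum() -> tuple[dict[tuple[str, str], float], frozenset]:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = [a for a in m.alphabet if a != "*"]
    s_min = min(m[a][b] for a in m.alphabet for b in m.alphabet)
    s_max = max(m[a][a] for a in alphabet)
    span = s_max - s_min
    scores = {
        (a, b): (m[a][b] - s_min) / span for a in alphabet for b in alphabet
    }
    return scores, frozenset(alphabet)


_PAIR_SCORE, _ALPHABET = _rescaled_blosum()


def _canon(residue: str) -> str:
    r = residue.upper()
    return r if r in _ALPHABET else "X"


def column_homogeneity(column: str) -> float:
    """Mean rescaled pairwise similarity over all unordered non-gap residue
    pairs of a column; 0.0 when fewer than two residues remain."""
    residues = [_canon(c) for c in column if c not in GAP_CHARS]
    n = len(residues)
    if n < 2:
        return 0.0
    counts = Counter(residues)
    items = sorted(counts.items())
    total = 0.0
    for i, (a, na) in enumerate(items):
        total += _PAIR_SCORE[(a, a)] * na * (na - 1) / 2
        for b, nb in items[i + 1 :]:
            total += _PAIR_SCORE[(a, b)] * na * nb
    return total / (n * (n - 1) / 2)


def gap_fraction(column: str) -> float:
    if not column:
        return 0.0
    return sum(1 for c in column if c in GAP_CHARS) / len(column)


@dataclass
class SiteStats:
    """Per-column gap fraction, homogeneity, and filtering outcome."""

    frame: pd.DataFrame  # columns: site, gap_fraction, homogeneity, removed, reason

    @property
    def n_removed(self) -> int:
        return int(self.frame["removed"].sum())

    @property
    def kept_sites(self) -> list[int]:
        return self.frame.loc[~self.frame["removed"], "site"].tolist()


def site_stats(
    alignment: Alignment,
    max_gap: float = DEFAULT_MAX_GAP,
    min_hom: float = DEFAULT_MIN_HOM,
) -> SiteStats:
    rows = []
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        gf = gap_fraction(col)
        hom = column_homogeneity(col)
        reasons = []
        if gf > max_gap:
            reasons.append(f"gap_fraction {gf:.4g} > {max_gap:g}")
        if hom < min_hom:
            reasons.append(f"homogeneity {hom:.4g} < {min_hom:g}")
        rows.append((j, gf, hom, bool(reasons), "; ".join(reasons)))
    return SiteStats(
        pd.DataFrame(
            rows,
            columns=["site", "gap_fraction", "homogeneity", "removed", "reason"],
        )
    )


def filter_sites(
    alignment: Alignment,
    max_gap: float = DEFAULT_MAX_GAP,
    min_hom: float = DEFAULT_MIN_HOM,
) -> tuple[Alignment, SiteStats]:
    """Remove columns whose gap fraction exceeds ``max_gap`` or whose
    homogeneity falls below ``min_hom``; surviving column order preserved."""
    stats = site_stats(alignment, max_gap=max_gap, min_hom=min_hom)
    kept = stats.kept_sites
    if not kept:
        raise ValueError(
            f"all {alignment.n_cols} columns removed "
            f"(max_gap={max_gap}, min_hom={min_hom})"
        )
    return alignment.take_columns(kept), stats


def drop_fragmented(
    alignment: Alignment, max_row_gap: float = DEFAULT_MAX_ROW_GAP
) -> Alignment:
    """Remove rows whose gap fraction over the retained columns exceeds
    ``max_row_gap``."""
    kept = [
        i
        for i, row in enumerate(alignment.rows)
        if gap_fraction(row) <= max_row_gap
    ]
    if not kept:
        raise ValueError(f"all rows removed (max_row_gap={max_row_gap})")
    return alignment.take_rows(kept)


def requalify_clades(
    alignment: Alignment,
    clades: CladeMap,
    weights: GenomeWeightTable,
    threshold: float = 0.5,
) -> tuple[Alignment, set[str]]:
    """Drop rows of clades whose weighted representation among the alignment's
    genomes is strictly below ``threshold``; return the trimmed alignment and
    the surviving clade set.  Callers re-test any minimum-clade condition."""
    totals = clade_weight_totals(weights, clades)
    present: dict[str, float] = {}
    seen: set[str] = set()
    for label in alignment.labels:
        genome = genome_of(label)
        if genome in seen:
            continue
        seen.add(genome)
        clade = clades.get(genome)
        if clade is not None and genome in weights:
            present[clade] = present.get(clade, 0.0) + weights[genome]
    surviving = {
        clade
        for clade, total in totals.items()
        if present.get(clade, 0.0) / total >= threshold
    }
    kept = [
        i
        for i, label in enumerate(alignment.labels)
        if clades.get(genome_of(label)) in surviving
    ]
    if kept:
        trimmed = alignment.take_rows(kept)
    else:
        trimmed = Alignment([], [])
    return trimmed, surviving
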