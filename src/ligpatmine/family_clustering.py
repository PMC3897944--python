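"""Protein-family clustering of receptor sequences.

The "Family" statistic of a pattern counts how many distinct protein
families its supporting contacts come from; a family is a single-linkage
cluster of receptor amino-acid sequences linked whenever a pair shares
at least 25% sequence identity with at least 50% alignment coverage.

Pairwise alignment uses a global Needleman–Wunsch alignment with BLOSUM62
scores and affine gaps (open −11, extend −1); identity is counted over
aligned (non-gap) columns and coverage relative to the shorter sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class FamilyAssignment:
    families: dict[str, str]                 # sequence id -> family id
    parameters: tuple[float, float]          # (identity_min, coverage_min)

    def family_of(self, seq_id: str) -> str:
        return self.families[seq_id]

    def n_families(self) -> int:
        return len(set(self.families.values()))


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _clean(seq: str, which: str) -> str:
    seq = seq.upper().strip()
    if not seq:
        raise ValueError(f"empty sequence {which}")
    bad = set(seq) - VALID_LETTERS
    if bad:
        # map unexpected letters (B, Z, U, ...) onto X rather than failing
        seq = "".join(c if c in VALID_LETTERS else "X" for c in seq)
    return seq


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, coverage) of the best global alignment of two sequences.

    identity = identical aligned pairs / aligned (non-gap) columns;
    coverage = aligned residues of the shorter sequence / its length.
    A zero-column alignment yields identity 0.
    """
    seq_a = _clean(seq_a, "a")
    seq_b = _clean(seq_b, "b")
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    identity = counts.identities / aligned if aligned else 0.0
    coverage = aligned / min(len(seq_a), len(seq_b))
    return float(identity), float(min(coverage, 1.0))


def build_families(sequences: dict[str, str], identity_min: float = 0.25,
                   coverage_min: float = 0.50) -> FamilyAssignment:
    """Single-linkage families: link a pair iff identity ≥ identity_min and
    coverage ≥ coverage_min; families are the connected components.

    Family ids are the lexicographically smallest member id of each
    component, so the output is independent of input order.
    """
    ids = sorted(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # identical sequences always share a family (degenerate shortcut)
    by_seq: dict[str, str] = {}
    for i in ids:
        s = sequences[i]
        if s in by_seq:
            union(i, by_seq[s])
        else:
            by_seq[s] = i

    for a, b in itertools.combinations(ids, 2):
        if find(a) == find(b):
            continue
        identity, coverage = pairwise_identity(sequences[a], sequences[b])
        if identity >= identity_min and coverage >= coverage_min:
            union(a, b)

    members: dict[str, list[str]] = {}
    for i in ids:
        members.setdefault(find(i), []).append(i)
    families = {i: min(group) for root, group in members.items() for i in group}
    return FamilyAssignment(families=families,
                            parameters=(identity_min, coverage_min))
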