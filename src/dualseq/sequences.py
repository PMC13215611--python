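"""Cross-task operation-sequence taxonomy.

Six operations — E1, C1, R1 for Task 1 and E2, C2, R2 for Task 2 — can be
interleaved in C(6,3) = 20 ways that preserve each task's internal
E → C → R order.  Restricting to interleavings that begin with E1 and end
with R2 (Task 1 is always presented and finished first/last respectively in
the paradigm) leaves exactly six sequences, labelled A–F.  A is the fully
serial sequence; in B–F some Task 2 processing starts before Task 1 ends.
"""

from __future__ import annotations

from itertools import combinations

SEQUENCE_LABELS = ("A", "B", "C", "D", "E", "F")

SEQUENCE_ORDERS = {
    "A": ("E1", "C1", "R1", "E2", "C2", "R2"),
    "B": ("E1", "C1", "E2", "R1", "C2", "R2"),
    "C": ("E1", "E2", "C1", "R1", "C2", "R2"),
    "D": ("E1", "C1", "E2", "C2", "R1", "R2"),
    "E": ("E1", "E2", "C1", "C2", "R1", "R2"),
    "F": ("E1", "E2", "C2", "C1", "R1", "R2"),
}

_TASK1 = ("E1", "C1", "R1")
_TASK2 = ("E2", "C2", "R2")


def enumerate_valid_sequences():
    """Brute-force the taxonomy from first principles.

    Returns (all_interleavings, constrained) where ``all_interleavings`` is
    every order-preserving interleaving of the two tasks' operations and
    ``constrained`` the subset beginning with E1 and ending with R2.
    """
    all_seqs = []
    for pos1 in combinations(range(6), 3):
        seq = [None] * 6
        for p, op in zip(pos1, _TASK1):
            seq[p] = op
        rest = [i for i in range(6) if i not in pos1]
        for p, op in zip(rest, _TASK2):
            seq[p] = op
        all_seqs.append(tuple(seq))
    constrained = [s for s in all_seqs if s[0] == "E1" and s[-1] == "R2"]
    return all_seqs, constrained
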