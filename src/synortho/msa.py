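"""Progressive multiple alignment, column conservation, and residue mapping.

Family members (typically their coiled-coil fragments) are aligned with a
deterministic guide-tree progressive aligner: pairwise global identities give
distances, a UPGMA guide tree fixes the merge order, and profiles are merged
by affine-gap profile-profile alignment with sum-of-pairs BLOSUM62 scoring
("once a gap, always a gap"). Determinism does not depend on input order —
all internal orderings are by sequence id.

Conservation distinguishes strict identity from equivalence under the
{I, L, V} class: branched/aliphatic residues the family tolerates
interchangeably at its coiled-coil core positions. Every other residue forms
a singleton class, so an all-identical column is always equivalent-in-all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import (
    ALPHABET,
    BLOSUM62,
    GAP,
    GLOBAL_GAP_EXTEND,
    GLOBAL_GAP_OPEN,
    encode,
    global_align,
)

GAP_RESULT = "GAP"

DEFAULT_EQUIVALENCE = frozenset("ILV")

CLASS_IDENTICAL_ALL = "identical-in-all"
CLASS_EQUIV_ALL = "ILV-equivalent-in-all"
CLASS_IDENTICAL_GROUP = "identical-in-group"
CLASS_EQUIV_GROUP = "ILV-equivalent-in-group"
CLASS_NOT_CONSERVED = "not-conserved"


class MSA:
    """A multiple sequence alignment with column/residue coordinate maps."""

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("empty alignment")
        width = len(rows[0][1])
        if any(len(aln) != width for _, aln in rows):
            raise ValueError("aligned strings differ in length")
        for col in range(width):
            if all(aln[col] == GAP for _, aln in rows):
                raise ValueError(f"all-gap column at {col + 1}")
        self.rows = rows
        self.width = width
        self._index = {rid: i for i, (rid, _) in enumerate(rows)}
        if len(self._index) != len(rows):
            raise ValueError("duplicate row ids")
        # per-row maps between 1-based residue numbers and 1-based columns
        self._res_to_col: dict[str, list[int]] = {}
        self._col_to_res: dict[str, list[int | None]] = {}
        for rid, aln in rows:
            r2c: list[int] = []
            c2r: list[int | None] = []
            res = 0
            for col, ch in enumerate(aln, start=1):
                if ch == GAP:
                    c2r.append(None)
                else:
                    res += 1
                    r2c.append(col)
                    c2r.append(res)
            self._res_to_col[rid] = r2c
            self._col_to_res[rid] = c2r

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def aligned(self, row_id: str) -> str:
        return self.rows[self._index[row_id]][1]

    def sequence(self, row_id: str) -> str:
        return self.aligned(row_id).replace(GAP, "")

    def column(self, col: int) -> list[str]:
        """Residues (or gaps) of a 1-based column, in row order."""
        return [aln[col - 1] for _, aln in self.rows]

    def column_of(self, row_id: str, residue_number: int) -> int:
        r2c = self._res_to_col[row_id]
        if not 1 <= residue_number <= len(r2c):
            raise ValueError(f"{row_id}: residue {residue_number} out of range (1..{len(r2c)})")
        return r2c[residue_number - 1]

    def residue_at(self, row_id: str, col: int) -> int | None:
        return self._col_to_res[row_id][col - 1]


# ---------------------------------------------------------------------------
# progressive alignment


def _pairwise_distances(seqs: list[tuple[str, str]], matrix, gap_open, gap_extend) -> dict[tuple[str, str], float]:
    d: dict[tuple[str, str], float] = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a_id, a = seqs[i]
            b_id, b = seqs[j]
            aln = global_align(a, b, matrix, gap_open, gap_extend)
            dist = 1.0 - aln.percent_identity / 100.0
            d[(a_id, b_id)] = d[(b_id, a_id)] = dist
    return d


def _upgma_order(ids: list[str], dist: dict[tuple[str, str], float]) -> list[tuple[frozenset, frozenset]]:
    """UPGMA merge schedule: lowest distance first, ties by smallest ids."""
    clusters: dict[frozenset, tuple[str, int]] = {
        frozenset([i]): (i, 1) for i in ids
    }  # cluster -> (min id, size)
    d = {
        (frozenset([a]), frozenset([b])): dist[(a, b)]
        for a in ids
        for b in ids
        if a != b
    }
    merges: list[tuple[frozenset, frozenset]] = []
    while len(clusters) > 1:
        best = None
        for ci in clusters:
            for cj in clusters:
                if ci is cj or clusters[ci][0] >= clusters[cj][0]:
                    continue
                key = (d[(ci, cj)], clusters[ci][0], clusters[cj][0])
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        assert best is not None
        _, ci, cj = best
        merges.append((ci, cj))
        new = ci | cj
        (mi, ni), (mj, nj) = clusters[ci], clusters[cj]
        del clusters[ci], clusters[cj]
        for ck in clusters:
            dn = (ni * d[(ci, ck)] + nj * d[(cj, ck)]) / (ni + nj)
            d[(new, ck)] = d[(ck, new)] = dn
        clusters[new] = (min(mi, mj), ni + nj)
    return merges


def _profile_counts(profile: list[tuple[str, str]]) -> np.ndarray:
    """(width, 21) residue counts per column; gaps are not counted."""
    width = len(profile[0][1])
    counts = np.zeros((width, len(ALPHABET)))
    for _, aln in profile:
        mask = np.frombuffer(aln.encode("ascii"), dtype=np.uint8) != ord(GAP)
        cols = np.nonzero(mask)[0]
        if cols.size:
            enc = encode(aln.replace(GAP, ""))
            np.add.at(counts, cols, np.eye(len(ALPHABET))[enc])
    return counts


def _align_profiles(
    prof_a: list[tuple[str, str]],
    prof_b: list[tuple[str, str]],
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    """Affine-gap global alignment of two profiles (sum-of-pairs scoring).

    Gap penalties are scaled by the product of profile depths so their weight
    tracks the sum-of-pairs substitution scores.
    """
    ca = _profile_counts(prof_a)
    cb = _profile_counts(prof_b)
    sub21 = matrix[: len(ALPHABET), : len(ALPHABET)]
    S = ca @ sub21 @ cb.T
    m, n = S.shape
    scale = len(prof_a) * len(prof_b)
    go, ge = gap_open * scale, gap_extend * scale
    NEG = -1e30
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = H[0, j] = -(go + ge * j)
    for i in range(1, m + 1):
        F[i, 0] = H[i, 0] = -(go + ge * i)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            F[i, j] = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            H[i, j] = max(H[i - 1, j - 1] + S[i - 1, j - 1], E[i, j], F[i, j])
    # traceback, diagonal > up > left
    ops: list[str] = []
    i, j = m, n
    state = "H"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
                ops.append("D")
                i, j = i - 1, j - 1
            elif i > 0 and abs(H[i, j] - F[i, j]) < eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("U")
            if abs(F[i, j] - (H[i - 1, j] - go - ge)) < eps:
                state = "H"
            i -= 1
        else:
            ops.append("L")
            if abs(E[i, j] - (H[i, j - 1] - go - ge)) < eps:
                state = "H"
            j -= 1
    ops.reverse()
    out_a = {rid: [] for rid, _ in prof_a}
    out_b = {rid: [] for rid, _ in prof_b}
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for rid, aln in prof_a:
                out_a[rid].append(aln[ia])
            ia += 1
        else:
            for rid in out_a:
                out_a[rid].append(GAP)
        if op in ("D", "L"):
            for rid, aln in prof_b:
                out_b[rid].append(aln[ib])
            ib += 1
        else:
            for rid in out_b:
                out_b[rid].append(GAP)
    merged = [(rid, "".join(out_a[rid])) for rid, _ in prof_a]
    merged += [(rid, "".join(out_b[rid])) for rid, _ in prof_b]
    return merged


def align_family(
    sequences: list[tuple[str, str]],
    matrix: np.ndarray | None = None,
    gap_open: float = GLOBAL_GAP_OPEN,
    gap_extend: float = GLOBAL_GAP_EXTEND,
) -> MSA:
    """Progressively align a family of protein sequences.

    Pairwise global-alignment identities give distances (d = 1 - identity),
    a UPGMA guide tree (ties broken by lexicographic id) fixes the merge
    order, and profiles are merged by profile-profile alignment. The result
    is independent of input order; rows appear in input order.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    ids = [rid for rid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if any(not s for _, s in sequences):
        raise ValueError("cannot align an empty sequence")
    matrix = BLOSUM62 if matrix is None else matrix
    canonical = sorted(sequences, key=lambda p: p[0])
    dist = _pairwise_distances(canonical, matrix, gap_open, gap_extend)
    merges = _upgma_order([rid for rid, _ in canonical], dist)
    profiles: dict[frozenset, list[tuple[str, str]]] = {
        frozenset([rid]): [(rid, seq)] for rid, seq in canonical
    }
    for ci, cj in merges:
        merged = _align_profiles(profiles.pop(ci), profiles.pop(cj), matrix, gap_open, gap_extend)
        profiles[ci | cj] = merged
    (final,) = profiles.values()
    by_id = dict(final)
    return MSA([(rid, by_id[rid]) for rid in ids])


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ColumnConservation:
    column: int  # 1-based alignment column
    gap_free: bool
    residues: tuple[str, ...]  # in row order
    reference_residue: int | None  # 1-based residue number in the reference row
    conservation_class: str
    in_equivalence_set: bool  # every residue belongs to the {I,L,V} class
    per_group: dict[str, str] = field(default_factory=dict)


@dataclass
class ConservationReport:
    reference: str
    equivalence: frozenset[str]
    columns: list[ColumnConservation]

    def columns_with_class(self, *classes: str) -> list[ColumnConservation]:
        return [c for c in self.columns if c.conservation_class in classes]

    def equivalent_all_columns(self) -> list[ColumnConservation]:
        """Gap-free columns whose residues all lie in the equivalence set."""
        return [c for c in self.columns if c.gap_free and c.in_equivalence_set]


def _class_of(residues: list[str], equivalence: frozenset[str]) -> tuple[bool, bool]:
    """(identical, equivalent) for a gap-free residue list.

    Equivalence classes are the configured set plus a singleton class per
    other residue, so identity always implies equivalence.
    """
    identical = len(set(residues)) == 1
    equivalent = identical or all(r in equivalence for r in residues)
    return identical, equivalent


def conserved_columns(
    msa: MSA,
    groups: dict[str, str] | None = None,
    equivalence: frozenset[str] = DEFAULT_EQUIVALENCE,
    reference: str | None = None,
) -> ConservationReport:
    """Classify every alignment column's conservation.

    Only gap-free columns are classified (a gap vetoes conservation). The
    strictest satisfied class is reported: identical in all rows, equivalent
    in all rows, identical within the reference row's taxon group, equivalent
    within it, else not conserved. Per-group classes are attached for every
    group in ``groups``.
    """
    reference = reference if reference is not None else msa.ids[0]
    if reference not in msa.ids:
        raise ValueError(f"reference row {reference!r} not in alignment")
    groups = groups or {}
    ref_group = groups.get(reference)
    report = ConservationReport(reference=reference, equivalence=equivalence, columns=[])
    group_rows: dict[str, list[int]] = {}
    for idx, rid in enumerate(msa.ids):
        group_rows.setdefault(groups.get(rid, "unassigned"), []).append(idx)
    for col in range(1, msa.width + 1):
        residues = msa.column(col)
        gap_free = GAP not in residues
        ref_res = msa.residue_at(reference, col)
        if not gap_free:
            report.columns.append(
                ColumnConservation(col, False, tuple(residues), ref_res, CLASS_NOT_CONSERVED, False)
            )
            continue
        identical, equivalent = _class_of(residues, equivalence)
        per_group: dict[str, str] = {}
        for gname, idxs in group_rows.items():
            g_res = [residues[i] for i in idxs]
            g_id, g_eq = _class_of(g_res, equivalence)
            per_group[gname] = (
                CLASS_IDENTICAL_GROUP if g_id else CLASS_EQUIV_GROUP if g_eq else CLASS_NOT_CONSERVED
            )
        if identical:
            cls = CLASS_IDENTICAL_ALL
        elif equivalent:
            cls = CLASS_EQUIV_ALL
        elif ref_group is not None and per_group.get(ref_group) == CLASS_IDENTICAL_GROUP:
            cls = CLASS_IDENTICAL_GROUP
        elif ref_group is not None and per_group.get(ref_group) == CLASS_EQUIV_GROUP:
            cls = CLASS_EQUIV_GROUP
        else:
            cls = CLASS_NOT_CONSERVED
        in_equiv = all(r in equivalence for r in residues)
        report.columns.append(
            ColumnConservation(col, True, tuple(residues), ref_res, cls, in_equiv, per_group)
        )
    return report


def map_residue(msa: MSA, from_gene: str, residue_number: int, to_gene: str) -> int | str:
    """Map a residue number between two rows through their shared column.

    Returns the 1-based residue number in ``to_gene``, or ``"GAP"`` when the
    target row is gapped in that column. Out-of-range residues raise.
    """
    col = msa.column_of(from_gene, residue_number)
    res = msa.residue_at(to_gene, col)
    return GAP_RESULT if res is None else res
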