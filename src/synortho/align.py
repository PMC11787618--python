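"""Exact affine-gap pairwise protein alignment.

Local (Smith-Waterman) and global (Needleman-Wunsch) alignment under the
Gotoh three-state recurrence with BLOSUM62 scoring. The local aligner is the
similarity engine used for anchor detection and reciprocal-best-hit searches;
the global aligner reproduces EMBOSS-Needle-style percent identity.

Gap cost convention: a gap of length L costs ``gap_open + gap_extend * L``
(the first gap residue costs open+extend, each further residue extend).

Traceback is deterministic: at a tie the preference order is
diagonal > up (gap in subject) > left (gap in query); in local mode the
optimum cell with the lexicographically smallest (end_query, end_subject)
coordinate is used and traceback stops at the first zero cell.

Unknown residues (``X``) score 0 against everything, including ``X`` itself,
and an X/X column is never counted as identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"

#: residue order used for integer encoding; index 20 is X, index 21 is padding
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_PAD = len(ALPHABET)  # 21

# BLASTP-style defaults for the local search engine
LOCAL_GAP_OPEN = 11.0
LOCAL_GAP_EXTEND = 1.0
# EMBOSS Needle defaults for the global identity calculation
GLOBAL_GAP_OPEN = 10.0
GLOBAL_GAP_EXTEND = 0.5

_NEG = -1e30


def load_blosum62() -> np.ndarray:
    """Return the NCBI BLOSUM62 matrix as a (22, 22) float array.

    Rows/columns follow :data:`ALPHABET`; the X row and column are zeroed
    (X scores 0 against everything) and the final padding row/column holds a
    large negative sentinel so padded batch cells can never win.
    """
    b62 = substitution_matrices.load("BLOSUM62")
    mat = np.full((_PAD + 1, _PAD + 1), _NEG, dtype=float)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0.0
            else:
                mat[i, j] = float(b62[a][b])
    return mat


BLOSUM62 = load_blosum62()

_ENCODER = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODER[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a protein string to integer indices; unknowns map to X."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    enc = _ENCODER[arr]
    enc = np.where(enc < 0, ALPHABET.index("X"), enc).astype(np.int64)
    return enc


@dataclass
class AlignmentResult:
    """A pairwise alignment with score, aligned strings and identity.

    Spans are 1-based inclusive residue intervals of the input sequences
    covered by the alignment; they are ``None`` for an empty local alignment.
    """

    query_id: str
    subject_id: str
    mode: str  # "local" | "global"
    score: float
    aligned_query: str
    aligned_subject: str
    query_span: tuple[int, int] | None
    subject_span: tuple[int, int] | None
    n_identical: int = field(default=0)
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")
        self.alignment_length = len(self.aligned_query)
        self.n_identical = sum(
            1
            for x, y in zip(self.aligned_query, self.aligned_subject)
            if x == y and x != GAP and x != "X"
        )

    @property
    def percent_identity(self) -> float:
        return percent_identity(self)


def percent_identity(result: AlignmentResult) -> float:
    """Needle-convention identity: identical columns / all columns x 100.

    Gap columns count toward the denominator; X/X columns are not identical.
    Raises ``ValueError`` on a zero-length alignment, where identity is
    undefined.
    """
    if result.alignment_length == 0:
        raise ValueError("percent identity undefined for a zero-length alignment")
    return 100.0 * result.n_identical / result.alignment_length


def _dp_matrices(
    a: np.ndarray,
    b: np.ndarray,
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
):
    """Fill the Gotoh H/E/F matrices row by row.

    E holds alignments ending in a gap in the query (left move, consumes the
    subject); F holds alignments ending in a gap in the subject (up move).
    The E row is computed with a running-maximum formulation, which is exact
    because two abutting same-row gaps always merge into one cheaper gap.
    """
    m, n = len(a), len(b)
    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    js = np.arange(1, n + 1, dtype=float)
    if local:
        H[0, :] = 0.0
        H[:, 0] = 0.0
    else:
        H[0, 0] = 0.0
        H[0, 1:] = -(gap_open + gap_extend * js)
        H[1:, 0] = -(gap_open + gap_extend * np.arange(1, m + 1, dtype=float))
        E[0, 1:] = H[0, 1:]
        F[1:, 0] = H[1:, 0]
    ext_ramp = gap_extend * np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:], H[i - 1, 1:] - gap_open) - gap_extend
        diag = H[i - 1, :-1] + sub[a[i - 1]][b]
        h_no_e = np.maximum(diag, F[i, 1:])
        if local:
            h_no_e = np.maximum(h_no_e, 0.0)
        base = np.empty(n + 1)
        base[0] = H[i, 0]
        base[1:] = h_no_e
        run = np.maximum.accumulate(base + ext_ramp)
        E[i, 1:] = run[:-1] - gap_open - gap_extend * np.arange(1, n + 1, dtype=float)
        H[i, 1:] = np.maximum(h_no_e, E[i, 1:])
    return H, E, F


def _traceback(
    a: str,
    b: str,
    a_enc: np.ndarray,
    b_enc: np.ndarray,
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
    H: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    end: tuple[int, int],
):
    i, j = end
    qa: list[str] = []
    sa: list[str] = []
    state = "H"
    eps = 1e-9
    while True:
        if state == "H":
            if local and H[i, j] <= eps:
                break
            if not local and i == 0 and j == 0:
                break
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + sub[a_enc[i - 1], b_enc[j - 1]])) < eps:
                qa.append(a[i - 1])
                sa.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and abs(H[i, j] - F[i, j]) < eps:
                state = "F"
            elif j > 0 and abs(H[i, j] - E[i, j]) < eps:
                state = "E"
            else:  # pragma: no cover - matrices are internally consistent
                raise RuntimeError("traceback failed")
        elif state == "F":
            qa.append(a[i - 1])
            sa.append(GAP)
            if abs(F[i, j] - (H[i - 1, j] - gap_open - gap_extend)) < eps:
                state = "H"
            i -= 1
        else:  # E
            qa.append(GAP)
            sa.append(b[j - 1])
            if abs(E[i, j] - (H[i, j - 1] - gap_open - gap_extend)) < eps:
                state = "H"
            j -= 1
    qa.reverse()
    sa.reverse()
    return "".join(qa), "".join(sa), (i, j)


def _align(
    a: str,
    b: str,
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
    local: bool,
    query_id: str,
    subject_id: str,
) -> AlignmentResult:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    a_enc, b_enc = encode(a), encode(b)
    H, E, F = _dp_matrices(a_enc, b_enc, matrix, gap_open, gap_extend, local)
    mode = "local" if local else "global"
    if local:
        score = float(H.max())
        if score <= 0.0:
            return AlignmentResult(query_id, subject_id, mode, 0.0, "", "", None, None)
        # optimum cell with lexicographically smallest (end_i, end_j)
        flat = np.argwhere(H >= score - 1e-9)
        end_i, end_j = min((int(r), int(c)) for r, c in flat)
        end = (end_i, end_j)
    else:
        score = float(H[-1, -1])
        end = (len(a), len(b))
    aq, asub, (si, sj) = _traceback(
        a, b, a_enc, b_enc, matrix, gap_open, gap_extend, local, H, E, F, end
    )
    q_span = (si + 1, end[0]) if end[0] > si else None
    s_span = (sj + 1, end[1]) if end[1] > sj else None
    return AlignmentResult(query_id, subject_id, mode, score, aq, asub, q_span, s_span)


def local_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment (score floored at zero)."""
    return _align(a, b, BLOSUM62 if matrix is None else matrix, gap_open, gap_extend, True, query_id, subject_id)


def global_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = GLOBAL_GAP_OPEN,
    gap_extend: float = GLOBAL_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment; end gaps are penalized."""
    return _align(a, b, BLOSUM62 if matrix is None else matrix, gap_open, gap_extend, False, query_id, subject_id)


def local_score(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
) -> float:
    """Score-only Smith-Waterman (no traceback)."""
    return float(batch_local_scores(a, [b], matrix, gap_open, gap_extend)[0])


def batch_local_scores(
    query: str,
    targets: list[str],
    matrix: np.ndarray | None = None,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
) -> np.ndarray:
    """Smith-Waterman scores of one query against many subjects at once.

    Subjects are right-padded to a common length; the padding residue scores
    a large negative value against everything and padded columns are excluded
    from the per-subject maximum, so padding cannot alter any score.
    """
    if not query:
        raise ValueError("cannot align an empty sequence")
    if not targets:
        return np.zeros(0)
    if any(not t for t in targets):
        raise ValueError("cannot align an empty sequence")
    sub = BLOSUM62 if matrix is None else matrix
    q = encode(query)
    k = len(targets)
    nmax = max(len(t) for t in targets)
    T = np.full((k, nmax), _PAD, dtype=np.int64)
    lens = np.empty(k, dtype=np.int64)
    for t_i, t in enumerate(targets):
        T[t_i, : len(t)] = encode(t)
        lens[t_i] = len(t)
    valid = np.arange(1, nmax + 1)[None, :] <= lens[:, None]
    H_prev = np.zeros((k, nmax + 1))
    F_prev = np.full((k, nmax + 1), _NEG)
    best = np.zeros(k)
    ext_ramp = gap_extend * np.arange(nmax + 1, dtype=float)
    for i in range(len(q)):
        F_row = np.maximum(F_prev[:, 1:], H_prev[:, 1:] - gap_open) - gap_extend
        diag = H_prev[:, :-1] + sub[q[i]][T]
        h_no_e = np.maximum(np.maximum(diag, F_row), 0.0)
        base = np.concatenate([np.zeros((k, 1)), h_no_e], axis=1)
        run = np.maximum.accumulate(base + ext_ramp[None, :], axis=1)
        E_row = run[:, :-1] - gap_open - ext_ramp[None, 1:]
        H_row_inner = np.maximum(h_no_e, np.maximum(E_row, 0.0))
        best = np.maximum(best, np.where(valid, H_row_inner, 0.0).max(axis=1))
        H_prev = np.concatenate([np.zeros((k, 1)), H_row_inner], axis=1)
        F_prev = np.concatenate([np.full((k, 1), _NEG), F_row], axis=1)
    return best
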