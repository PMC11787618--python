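"""Heptad-register coiled-coil prediction.

Coiled coils repeat a seven-residue pattern (positions a-g) in which the
first and fourth positions (a and d) pack the hydrophobic core. The scanner
slides a window over the protein, tries all seven register phases, and scores
each phase as the fraction of a/d positions occupied by hydrophobic residues.
Windows reaching the threshold are merged into maximal same-phase intervals.

This is a transparent, parameter-exposed simplification of profile-based
coiled-coil predictors: it encodes exactly the heptad-hydrophobicity
criterion and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_HYDROPHOBIC = frozenset("ILVMFA")
DEFAULT_WINDOW = 21
DEFAULT_THRESHOLD = 0.7

_LETTERS = "abcdefg"
_CORE = {0, 3}  # a and d within the heptad


@dataclass
class CoiledCoilAnnotation:
    """A predicted coiled-coil interval with its heptad register.

    ``register_offset`` is the absolute phase o in 0..6 such that residue
    number r (1-based) carries heptad letter ``"abcdefg"[(r - 1 + o) % 7]``;
    an ``a`` residue and the ``d`` residue three positions later form the
    "1st and 4th" hydrophobic pair. ``score`` is the fraction of a/d
    positions in the interval occupied by hydrophobic residues.
    """

    gene_id: str
    start: int  # 1-based inclusive
    end: int
    register_offset: int
    score: float
    seq_length: int

    def heptad_letter(self, residue_number: int) -> str:
        return _LETTERS[(residue_number - 1 + self.register_offset) % 7]


def _core_positions(start: int, end: int, offset: int) -> list[int]:
    """1-based residue numbers with heptad letter a or d in [start, end]."""
    return [
        r for r in range(start, end + 1) if (r - 1 + offset) % 7 in _CORE
    ]


def _interval_score(protein: str, start: int, end: int, offset: int, hydrophobic: frozenset[str]) -> float:
    core = _core_positions(start, end, offset)
    if not core:
        return 0.0
    hits = sum(1 for r in core if protein[r - 1] in hydrophobic)
    return hits / len(core)


def scan_coiled_coil(
    protein: str,
    gene_id: str = "protein",
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> list[CoiledCoilAnnotation]:
    """Predict coiled-coil intervals by sliding-window heptad scoring.

    Every window position is scored under all 7 phases; windows whose best
    phase reaches ``threshold`` are merged into maximal intervals per phase.
    Overlaps between intervals of different phases are resolved in favour of
    the higher-scoring interval (the lower-scoring one is trimmed away).
    Returns non-overlapping annotations sorted by start; a protein shorter
    than the window yields an empty list.
    """
    if window < 14 or window % 7 != 0:
        raise ValueError("window must be >= 14 and a multiple of 7")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(protein)
    if n < window:
        return []
    # accepted windows: (start, winning offset, score); ties prefer the
    # smaller offset so the result is deterministic
    accepted: list[tuple[int, int, float]] = []
    for start in range(1, n - window + 2):
        best: tuple[float, int] | None = None
        for offset in range(7):
            s = _interval_score(protein, start, start + window - 1, offset, hydrophobic)
            if best is None or s > best[0]:
                best = (s, offset)
        assert best is not None
        if best[0] >= threshold:
            accepted.append((start, best[1], best[0]))
    if not accepted:
        return []
    # each covered residue adopts the phase with the largest score-weighted
    # support among accepted windows covering it (ties: smaller offset), so a
    # single boundary-straddling window cannot steal residues from a
    # consistently supported register
    votes: dict[int, dict[int, float]] = {}
    for start, offset, score in accepted:
        for r in range(start, start + window):
            votes.setdefault(r, {})[offset] = votes.get(r, {}).get(offset, 0.0) + score
    phase_of = {
        r: min(offsets, key=lambda o: (-offsets[o], o)) for r, offsets in votes.items()
    }
    # maximal same-phase runs become annotations; runs shorter than one
    # window (possible after cross-phase competition) are discarded
    kept: list[CoiledCoilAnnotation] = []
    run_start = prev = None
    run_phase = None

    def _emit(s: int, e: int, offset: int) -> None:
        if e - s + 1 >= window:
            kept.append(
                CoiledCoilAnnotation(
                    gene_id=gene_id,
                    start=s,
                    end=e,
                    register_offset=offset,
                    score=_interval_score(protein, s, e, offset, hydrophobic),
                    seq_length=n,
                )
            )

    for r in sorted(phase_of):
        if run_start is None:
            run_start, prev, run_phase = r, r, phase_of[r]
            continue
        if r == prev + 1 and phase_of[r] == run_phase:
            prev = r
            continue
        _emit(run_start, prev, run_phase)
        run_start, prev, run_phase = r, r, phase_of[r]
    _emit(run_start, prev, run_phase)
    return kept


def is_core_position(annotation: CoiledCoilAnnotation, residue_number: int) -> str:
    """Classify a residue as heptad 'a', 'd', 'other', or 'outside' the coil."""
    if not 1 <= residue_number <= annotation.seq_length:
        raise ValueError(f"residue {residue_number} outside protein (length {annotation.seq_length})")
    if residue_number < annotation.start or residue_number > annotation.end:
        return "outside"
    letter = annotation.heptad_letter(residue_number)
    return letter if letter in ("a", "d") else "other"
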