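"""Sequence containers, pairwise global alignment, and mutation events.

Coordinates are 0-based and half-open throughout. Alignments are global
(Needleman-Wunsch for linear gap costs, Gotoh three-state for affine) with a
fixed, deterministic tie-break: diagonal over deletion (gap in the target
row) over insertion (gap in the ancestor row). Differences between an
ancestral and a target sequence are represented as :class:`MutationEvent`
records anchored in alignment-column space, so that arbitrary subsets can be
applied without coordinate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence as TypingSequence

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import AlignmentError, InvalidSequenceError, MutationError

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
GAP = "-"

#: sentinel for "this alignment column has no residue in this row"
GAP_SENTINEL = -1


def revcomp(residues: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A validated DNA sequence.

    Parameters
    ----------
    id : str
        Record label (FASTA header / element id).
    residues : str
        Uppercase DNA over {A,C,G,T}. Sequences containing undetermined
        bases (N) or other characters are rejected with
        :class:`InvalidSequenceError`.
    node_label : str, optional
        Phylogeny node this sequence is attached to, if any.
    """

    id: str
    residues: str
    node_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains invalid characters "
                f"{sorted(bad)}; alphabet is {{A,C,G,T}}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        return replace(self, residues=revcomp(self.residues))


def read_fasta(path: str | Path, drop_invalid: bool = False) -> list[Sequence]:
    """Read a (multi-)FASTA file into validated :class:`Sequence` records.

    With ``drop_invalid=True``, records failing validation (e.g. containing
    N) are discarded instead of raising, mirroring the ortholog-library
    filter that drops sequences with undetermined bases.
    """
    out: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(Sequence(id=rec.id, residues=str(rec.seq).upper()))
        except InvalidSequenceError:
            if not drop_invalid:
                raise
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


@dataclass(frozen=True)
class ScoringParams:
    """Global-alignment scoring parameters.

    ``linear`` mode charges ``gap_extend`` per gap column and requires
    ``gap_open == gap_extend``; ``affine`` mode charges
    ``gap_open + gap_extend`` for the first column of a gap and
    ``gap_extend`` for each further column.
    """

    match: float
    mismatch: float
    gap_open: float
    gap_extend: float
    mode: Literal["linear", "affine"] = "linear"

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")
        if self.mode == "linear" and self.gap_open != self.gap_extend:
            raise AlignmentError("linear mode requires gap_open == gap_extend")
        if self.mode not in ("linear", "affine"):
            raise AlignmentError(f"unknown mode {self.mode!r}")

    @property
    def open_cost(self) -> float:
        """Score contribution of the first column of a gap."""
        if self.mode == "linear":
            return self.gap_extend
        return self.gap_open + self.gap_extend


#: preset used when enumerating ancestor->extant mutations
RECONSTITUTION = ScoringParams(match=1, mismatch=-1, gap_open=-1, gap_extend=-1, mode="linear")
#: preset used when orienting orthologs against the reference
ORIENTATION = ScoringParams(match=1, mismatch=0, gap_open=-2, gap_extend=-8, mode="affine")


@dataclass(frozen=True)
class AlignmentPair:
    """A global pairwise alignment of sequence ``a`` against ``b``.

    ``column_to_a``/``column_to_b`` map each alignment column to the 0-based
    residue index in the respective sequence, or :data:`GAP_SENTINEL` where
    that row is gapped.
    """

    a: Sequence
    b: Sequence
    aligned_a: str
    aligned_b: str
    score: float
    params: ScoringParams

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("gapped rows have unequal lengths")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == GAP and cb == GAP:
                raise AlignmentError("column gapped in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def column_to_a(self) -> list[int]:
        return _row_coordinate_map(self.aligned_a)

    @property
    def column_to_b(self) -> list[int]:
        return _row_coordinate_map(self.aligned_b)


def _row_coordinate_map(row: str) -> list[int]:
    out, pos = [], 0
    for ch in row:
        if ch == GAP:
            out.append(GAP_SENTINEL)
        else:
            out.append(pos)
            pos += 1
    return out


def score_alignment(aligned_a: str, aligned_b: str, params: ScoringParams) -> float:
    """Recompute the score of a gapped alignment under ``params``."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == GAP:
            score += params.gap_extend if prev_gap_a else params.open_cost
        elif cb == GAP:
            score += params.gap_extend if prev_gap_b else params.open_cost
        else:
            score += params.match if ca == cb else params.mismatch
        prev_gap_a, prev_gap_b = ca == GAP, cb == GAP
    return score


_NEG = -1e30  # effectively -inf but safe under addition


def align_global(a: Sequence, b: Sequence, params: ScoringParams = RECONSTITUTION) -> AlignmentPair:
    """Optimal global alignment of ``a`` (ancestor row) vs ``b`` (target row).

    Three-state Gotoh dynamic program; linear gap costs are the special case
    open_cost == gap_extend. Tie-break, applied during traceback, prefers
    the diagonal move, then a gap in ``b`` (deletion), then a gap in ``a``
    (insertion), making the returned alignment deterministic.
    """
    n, m = len(a), len(b)
    sa = np.frombuffer(a.residues.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.residues.encode(), dtype=np.uint8)
    opn, ext = params.open_cost, params.gap_extend
    match, mismatch = params.match, params.mismatch

    # state matrices: M diag, X gap-in-b (consumes a), Y gap-in-a (consumes b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = opn + ext * np.arange(n)
    if m:
        Y[0, 1:] = opn + ext * np.arange(m)

    for i in range(1, n + 1):
        sub = np.where(sb == sa[i - 1], match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + opn, X[i - 1, 1:] + ext)
        # Y has an intra-row dependency; closed form via running max:
        # Y[i,j] = max( max_{k<j} Z[k] + opn + ext*(j-1-k), boundary ) with
        # Z[k] = max(M[i,k], X[i,k]) — a running maximum of Z[k] - ext*k.
        run = _NEG
        row_m, row_x, row_y = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            z = max(row_m[j - 1], row_x[j - 1])
            cand = z - ext * (j - 1)
            if cand > run:
                run = cand
            row_y[j] = run + opn + ext * (j - 1)

    # traceback, preferring M > X > Y at every decision
    finals = (M[n, m], X[n, m], Y[n, m])
    if finals[0] >= finals[1] and finals[0] >= finals[2]:
        state = 0
    elif finals[1] >= finals[2]:
        state = 1
    else:
        state = 2
    score = finals[state]
    i, j = n, m
    cols_a: list[str] = []
    cols_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M: consumed a[i-1], b[j-1]
            cols_a.append(a.residues[i - 1])
            cols_b.append(b.residues[j - 1])
            sub = match if a.residues[i - 1] == b.residues[j - 1] else mismatch
            tgt = M[i, j] - sub
            i, j = i - 1, j - 1
            if abs(M[i, j] - tgt) < eps:
                state = 0
            elif abs(X[i, j] - tgt) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:  # X: consumed a[i-1], gap in b
            cols_a.append(a.residues[i - 1])
            cols_b.append(GAP)
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + opn - val) < eps:
                state = 0
            elif abs(X[i, j] + ext - val) < eps:
                state = 1
            else:
                state = 2
        else:  # Y: gap in a, consumed b[j-1]
            cols_a.append(GAP)
            cols_b.append(b.residues[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + opn - val) < eps:
                state = 0
            elif abs(X[i, j] + opn - val) < eps:
                state = 1
            else:
                state = 2
    return AlignmentPair(
        a=a, b=b,
        aligned_a="".join(reversed(cols_a)),
        aligned_b="".join(reversed(cols_b)),
        score=float(score),
        params=params,
    )


def orient_sequence(
    query: Sequence, reference: Sequence, params: ScoringParams = ORIENTATION
) -> tuple[Sequence, str]:
    """Return ``query`` in the orientation best aligning to ``reference``.

    Both orientations are globally aligned to the reference; the one with
    the higher score is retained. Ties resolve to the forward strand.
    Returns ``(oriented_sequence, strand)`` with strand in {"+", "-"}.
    """
    fwd = align_global(query, reference, params).score
    rc = query.reverse_complement()
    rev = align_global(rc, reference, params).score
    if rev > fwd:
        return rc, "-"
    return query, "+"


@dataclass(frozen=True)
class MutationEvent:
    """A single difference between ancestor and target, anchored to
    alignment columns.

    ``column_start`` indexes the ancestor/target alignment; ``ref_pos`` is
    the 0-based coordinate on the target sequence (for a deletion, the
    target position immediately after the deleted ancestral run).
    """

    id: str
    kind: Literal["substitution", "insertion", "deletion"]
    column_start: int
    ref_pos: int
    from_allele: str
    to_allele: str

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.from_allele) != 1 or len(self.to_allele) != 1:
                raise MutationError("substitution alleles must be single bases")
        elif self.kind == "insertion":
            if self.from_allele or not self.to_allele:
                raise MutationError("insertion must have empty from_allele")
        elif self.kind == "deletion":
            if self.to_allele or not self.from_allele:
                raise MutationError("deletion must have empty to_allele")
        else:
            raise MutationError(f"unknown kind {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return max(len(self.from_allele), len(self.to_allele))

    @property
    def net_length(self) -> int:
        return len(self.to_allele) - len(self.from_allele)


@dataclass(frozen=True)
class MutationSet:
    events: tuple[MutationEvent, ...]
    ancestor_id: str
    target_id: str

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def enumerate_mutations(aln: AlignmentPair) -> MutationSet:
    """Enumerate all mismatches and indel events between the rows of ``aln``.

    Row ``a`` is the ancestor and row ``b`` the target. Maximal runs of
    adjacent gap columns of the same kind are merged into a single indel
    event; substitutions are always single-column events. Event ids are
    assigned in column order and are deterministic.
    """
    ra, rb = aln.aligned_a, aln.aligned_b
    col_b = aln.column_to_b
    events: list[MutationEvent] = []
    i = 0
    ncol = aln.n_columns
    while i < ncol:
        ca, cb = ra[i], rb[i]
        if ca == cb:
            i += 1
            continue
        if ca != GAP and cb != GAP:
            events.append(
                MutationEvent(
                    id="", kind="substitution", column_start=i,
                    ref_pos=col_b[i], from_allele=ca, to_allele=cb,
                )
            )
            i += 1
        elif ca == GAP:  # insertion relative to ancestor
            j = i
            while j < ncol and ra[j] == GAP:
                j += 1
            events.append(
                MutationEvent(
                    id="", kind="insertion", column_start=i,
                    ref_pos=col_b[i], from_allele="", to_allele=rb[i:j],
                )
            )
            i = j
        else:  # deletion: present in ancestor, absent in target
            j = i
            while j < ncol and rb[j] == GAP:
                j += 1
            # target position just after the deleted run
            ref = next((col_b[k] for k in range(j, ncol) if col_b[k] != GAP_SENTINEL),
                       len(aln.b))
            events.append(
                MutationEvent(
                    id="", kind="deletion", column_start=i,
                    ref_pos=ref, from_allele=ra[i:j], to_allele="",
                )
            )
            i = j
    numbered = tuple(
        replace(ev, id=f"ev{k:03d}") for k, ev in enumerate(events)
    )
    return MutationSet(events=numbered, ancestor_id=aln.a.id, target_id=aln.b.id)


def _check_event_in_alignment(ev: MutationEvent, aln: AlignmentPair) -> None:
    ra, rb = aln.aligned_a, aln.aligned_b
    c0, c1 = ev.column_start, ev.column_start + ev.n_columns
    if c1 > aln.n_columns:
        raise MutationError(f"event {ev.id}: columns out of range")
    if ev.kind == "substitution":
        ok = ra[c0] == ev.from_allele and rb[c0] == ev.to_allele
    elif ev.kind == "insertion":
        ok = set(ra[c0:c1]) == {GAP} and rb[c0:c1] == ev.to_allele
    else:
        ok = set(rb[c0:c1]) == {GAP} and ra[c0:c1] == ev.from_allele
    if not ok:
        raise MutationError(f"event {ev.id} does not match alignment columns")


def apply_mutations(
    ancestor: Sequence,
    aln: AlignmentPair,
    subset: Iterable[MutationEvent],
    seq_id: Optional[str] = None,
) -> Sequence:
    """Apply a subset of enumerated events to the ancestor.

    Edits operate in alignment-column space, so application order never
    shifts coordinates: any permutation of the same subset yields the same
    sequence. The empty subset returns the ancestor; the full set returns
    the target exactly.
    """
    if aln.a.residues != ancestor.residues:
        raise MutationError("ancestor does not match alignment row a")
    cols = list(aln.aligned_a)
    applied = []
    for ev in subset:
        _check_event_in_alignment(ev, aln)
        c0 = ev.column_start
        if ev.kind == "substitution":
            cols[c0] = ev.to_allele
        elif ev.kind == "insertion":
            for off, base in enumerate(ev.to_allele):
                cols[c0 + off] = base
        else:
            for off in range(len(ev.from_allele)):
                cols[c0 + off] = GAP
        applied.append(ev.id)
    residues = "".join(c for c in cols if c != GAP)
    if seq_id is None:
        seq_id = f"{ancestor.id}+{len(applied)}mut" if applied else ancestor.id
    return Sequence(id=seq_id, residues=residues)


def sequence_identity(aln: AlignmentPair, denominator: str = "columns") -> float:
    """Percent identity of an alignment.

    ``denominator="columns"`` (default) divides matched columns by all
    alignment columns, gap columns included; ``"ungapped"`` divides by
    columns where both rows have a residue.
    """
    matched = sum(
        1 for ca, cb in zip(aln.aligned_a, aln.aligned_b) if ca == cb and ca != GAP
    )
    if denominator == "columns":
        total = aln.n_columns
    elif denominator == "ungapped":
        total = sum(
            1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
            if ca != GAP and cb != GAP
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matched / total if total else 0.0


def msa_column_map(
    msa: TypingSequence[tuple[str, str]] | dict[str, str], reference_id: str
) -> tuple[dict[int, int], dict[int, int]]:
    """Bidirectional map between MSA columns and reference positions.

    ``msa`` is a mapping or sequence of ``(id, gapped_row)`` pairs. Returns
    ``(col_to_pos, pos_to_col)``; gap columns of the reference row appear in
    neither map.
    """
    rows = dict(msa)
    if reference_id not in rows:
        raise AlignmentError(f"reference {reference_id!r} not present in MSA")
    row = rows[reference_id]
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            col_to_pos[col] = pos
            pos += 1
    pos_to_col = {p: c for c, p in col_to_pos.items()}
    return col_to_pos, pos_to_col


def read_msa(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{id: gapped_row}`` mapping."""
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def length_ratio_filter(
    lengths: dict[str, int], reference_length: int,
    low: float = 0.5, high: float = 1.5,
) -> dict[str, bool]:
    """Flag ortholog interval lengths within ``[low, high]`` x reference.

    Standalone version of the ortholog-retrieval size filter (intervals
    outside 0.5-1.5x the query length are discarded upstream).
    """
    return {
        name: (low * reference_length <= n <= high * reference_length)
        for name, n in lengths.items()
    }


def mutations_to_tsv(ms: MutationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tkind\tcolumn_start\tref_pos\tfrom\tto\n")
        for ev in ms.events:
            fh.write(
                f"{ev.id}\t{ev.kind}\t{ev.column_start}\t{ev.ref_pos}\t"
                f"{ev.from_allele or '.'}\t{ev.to_allele or '.'}\n"
            )


def mutations_from_tsv(path: str | Path, ancestor_id: str = "", target_id: str = "") -> MutationSet:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise MutationError("malformed mutation TSV: missing header")
        for line in fh:
            eid, kind, col, ref, frm, to = line.rstrip("\n").split("\t")
            events.append(
                MutationEvent(
                    id=eid, kind=kind, column_start=int(col), ref_pos=int(ref),
                    from_allele="" if frm == "." else frm,
                    to_allele="" if to == "." else to,
                )
            )
    return MutationSet(events=tuple(events), ancestor_id=ancestor_id, target_id=target_id)
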