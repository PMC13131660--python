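"""Oracle-guided mutational trajectories.

Reconstitution trajectories start from an (inactive) ancestral sequence and
introduce the full set of ancestor-to-extant differences one at a time until
the extant sequence is reached — either greedily, committing at each step
the mutation whose single application the oracle predicts to most increase
accessibility, or in seeded random orders as controls. De novo tuning
trajectories instead nominate arbitrary single-base substitutions for a
fixed number of steps, maximizing (enhance) or minimizing (ablate) the
predicted score. All greedy decisions are deterministic: ties break on the
lowest alignment column, then lexicographic derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .errors import CretraceError, OracleError
from .motif import MotifModel, NormalizationReference, TFBSHit, best_affinity_in_window
from .oracle import ScoringOracle, marginal_footprint
from .phylo import LineagePath
from .seqmut import (
    ALPHABET,
    AlignmentPair,
    MutationEvent,
    MutationSet,
    RECONSTITUTION,
    Sequence,
    align_global,
    apply_mutations,
    enumerate_mutations,
    sequence_identity,
    write_fasta,
)


@dataclass(frozen=True)
class TrajectoryStep:
    """One committed step: the mutation applied (None for step 0), the
    resulting sequence, the oracle's prediction, and, when available, a
    measured activity."""

    index: int
    mutation_id: Optional[str]
    sequence: Sequence
    predicted: float
    measured: Optional[float] = None
    divergence: Optional[float] = None  # percent divergence from target


@dataclass(frozen=True)
class Trajectory:
    kind: str  # model_optimized | random | phylogeny | enhance | ablate
    start_id: str
    target_id: Optional[str]
    steps: tuple[TrajectoryStep, ...]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise CretraceError("trajectory must contain at least the start step")

    @property
    def n_steps(self) -> int:
        """Number of committed mutations (excludes the unmutated start)."""
        return len(self.steps) - 1

    @property
    def predicted(self) -> list[float]:
        return [s.predicted for s in self.steps]

    @property
    def sequences(self) -> list[Sequence]:
        return [s.sequence for s in self.steps]

    @property
    def mutation_order(self) -> list[str]:
        return [s.mutation_id for s in self.steps[1:]]


Scorer = Callable[[Sequence], float]


def make_scorer(
    oracle: ScoringOracle,
    backgrounds: Optional[TypingSequence[Sequence]] = None,
    footprint_mode: str = "ratio_of_means",
) -> Scorer:
    """Build the per-candidate scoring function used throughout a run.

    With backgrounds, candidates are scored by their marginal footprint
    ratio; without, by the raw oracle score. The same scorer is used for
    every candidate of a run so greedy comparisons are consistent.
    """
    if backgrounds:
        def scorer(seq: Sequence) -> float:
            return marginal_footprint(oracle, seq, backgrounds, footprint_mode).ratio
        return scorer
    return oracle.score


def _divergence(seq: Sequence, target: Sequence) -> float:
    return 100.0 - sequence_identity(align_global(seq, target, RECONSTITUTION))


def _tie_key(ev: MutationEvent) -> tuple[int, str]:
    return (ev.column_start, ev.to_allele)


def greedy_reconstitution(
    ancestor: Sequence,
    extant: Sequence,
    oracle: ScoringOracle,
    backgrounds: Optional[TypingSequence[Sequence]] = None,
    aln: Optional[AlignmentPair] = None,
    compute_divergence: bool = True,
) -> Trajectory:
    """Model-optimized reconstitution of ``extant`` from ``ancestor``.

    At each step every remaining mutation is applied singly to the current
    intermediate and scored; the mutation with the greatest predicted score
    is committed (ties: lowest alignment column, then lexicographic derived
    allele). The trajectory terminates exactly at the extant sequence.
    """
    if aln is None:
        aln = align_global(ancestor, extant, RECONSTITUTION)
    mset = enumerate_mutations(aln)
    scorer = make_scorer(oracle, backgrounds)
    committed: list[MutationEvent] = []
    remaining = list(mset.events)
    try:
        current = apply_mutations(ancestor, aln, committed, seq_id=f"{ancestor.id}|greedy0")
        steps = [
            TrajectoryStep(
                index=0, mutation_id=None, sequence=current,
                predicted=scorer(current),
                divergence=_divergence(current, extant) if compute_divergence else None,
            )
        ]
        k = 0
        while remaining:
            k += 1
            best_ev, best_score, best_seq = None, -np.inf, None
            for ev in sorted(remaining, key=_tie_key):
                cand = apply_mutations(
                    ancestor, aln, committed + [ev],
                    seq_id=f"{ancestor.id}|greedy{k}",
                )
                s = scorer(cand)
                if s > best_score:
                    best_ev, best_score, best_seq = ev, s, cand
            committed.append(best_ev)
            remaining.remove(best_ev)
            steps.append(
                TrajectoryStep(
                    index=k, mutation_id=best_ev.id, sequence=best_seq,
                    predicted=best_score,
                    divergence=_divergence(best_seq, extant) if compute_divergence else None,
                )
            )
    except OracleError as exc:
        raise OracleError(
            f"oracle failed while scoring candidates at step {len(committed) + 1} "
            f"of greedy reconstitution {ancestor.id}->{extant.id}: {exc}"
        ) from exc
    if steps[-1].sequence.residues != extant.residues:
        raise CretraceError("greedy reconstitution did not terminate at the extant sequence")
    return Trajectory(
        kind="model_optimized", start_id=ancestor.id, target_id=extant.id,
        steps=tuple(steps),
    )


def random_reconstitutions(
    ancestor: Sequence,
    extant: Sequence,
    oracle: ScoringOracle,
    n: int = 10,
    seed: int = 0,
    backgrounds: Optional[TypingSequence[Sequence]] = None,
    aln: Optional[AlignmentPair] = None,
    compute_divergence: bool = True,
) -> list[Trajectory]:
    """``n`` independent uniformly random orderings of the same mutation set.

    Reproducible under a fixed seed; every trajectory ends exactly at the
    extant sequence.
    """
    if n < 1:
        raise CretraceError("need n >= 1 random trajectories")
    if aln is None:
        aln = align_global(ancestor, extant, RECONSTITUTION)
    mset = enumerate_mutations(aln)
    scorer = make_scorer(oracle, backgrounds)
    rng = np.random.default_rng(seed)
    out = []
    for t in range(n):
        order = [mset.events[i] for i in rng.permutation(len(mset.events))]
        committed: list[MutationEvent] = []
        seqs = [apply_mutations(ancestor, aln, [], seq_id=f"{ancestor.id}|rand{t}.0")]
        for k, ev in enumerate(order, start=1):
            committed.append(ev)
            seqs.append(
                apply_mutations(ancestor, aln, committed, seq_id=f"{ancestor.id}|rand{t}.{k}")
            )
        steps = [
            TrajectoryStep(
                index=k,
                mutation_id=None if k == 0 else order[k - 1].id,
                sequence=s,
                predicted=scorer(s),
                divergence=_divergence(s, extant) if compute_divergence else None,
            )
            for k, s in enumerate(seqs)
        ]
        out.append(
            Trajectory(
                kind="random", start_id=ancestor.id, target_id=extant.id,
                steps=tuple(steps), seed=seed,
            )
        )
    return out


def phylogeny_trajectory(
    path: LineagePath,
    sequences: Mapping[str, Sequence],
    target: str,
    oracle: Optional[ScoringOracle] = None,
    backgrounds: Optional[TypingSequence[Sequence]] = None,
) -> Trajectory:
    """The phylogeny-inferred trajectory: ancestral orthologs in path order.

    Nodes without sequences are skipped with a warning. The divergence axis
    is percent divergence from the target ortholog.
    """
    import warnings

    if target not in sequences:
        raise CretraceError(f"target {target!r} has no sequence")
    tgt = sequences[target]
    scorer = make_scorer(oracle, backgrounds) if oracle is not None else (lambda s: float("nan"))
    steps = []
    k = 0
    for node in path:
        if node not in sequences:
            warnings.warn(f"no sequence for node {node!r}; skipped in phylogeny trajectory")
            continue
        seq = sequences[node]
        steps.append(
            TrajectoryStep(
                index=k, mutation_id=None if k == 0 else node,
                sequence=seq, predicted=scorer(seq),
                divergence=_divergence(seq, tgt),
            )
        )
        k += 1
    return Trajectory(
        kind="phylogeny", start_id=steps[0].sequence.id if steps else "",
        target_id=target, steps=tuple(steps),
    )


def _substitution_candidates(seq: Sequence) -> Iterable[tuple[int, str, str]]:
    for pos, ref in enumerate(seq.residues):
        for alt in ALPHABET:
            if alt != ref:
                yield pos, ref, alt


def denovo_tune(
    seq: Sequence,
    oracle: ScoringOracle,
    objective: str,
    steps: int = 50,
    backgrounds: Optional[TypingSequence[Sequence]] = None,
) -> Trajectory:
    """De novo enhancement or ablation by iterative single-base mutagenesis.

    Each step evaluates all 3L single-base substitutions of the current
    sequence and commits the one predicted to most increase (``enhance``)
    or decrease (``ablate``) the score. A candidate identical to the
    immediately preceding sequence is excluded (cycle guard); positions may
    be revisited. Ties: lowest position, then lexicographic base.
    """
    if objective not in ("enhance", "ablate"):
        raise CretraceError(f"objective must be enhance|ablate, got {objective!r}")
    if steps < 1:
        raise CretraceError("steps must be >= 1")
    scorer = make_scorer(oracle, backgrounds)
    sign = 1.0 if objective == "enhance" else -1.0
    current = seq
    out = [TrajectoryStep(index=0, mutation_id=None, sequence=current, predicted=scorer(current))]
    previous_residues: Optional[str] = None
    for k in range(1, steps + 1):
        best = None  # (signed_score, pos, alt, seq, raw_score)
        for pos, ref, alt in _substitution_candidates(current):
            residues = current.residues[:pos] + alt + current.residues[pos + 1:]
            if residues == previous_residues:
                continue  # cycle guard: do not recreate the previous sequence
            cand = Sequence(id=f"{seq.id}|{objective}{k}", residues=residues)
            s = scorer(cand)
            # candidates iterate by ascending position then base, so a strict
            # comparison implements the (position, allele) tie-break
            if best is None or (sign * s > best[0]):
                best = (sign * s, pos, alt, cand, s)
        _, pos, alt, cand, s = best
        previous_residues = current.residues
        out.append(
            TrajectoryStep(
                index=k,
                mutation_id=f"{current.residues[pos]}{pos}{alt}",
                sequence=cand,
                predicted=s,
            )
        )
        current = cand
    return Trajectory(kind=objective, start_id=seq.id, target_id=None, steps=tuple(out))


def steps_to_level(
    traj: Trajectory, level: float, direction: str = "ge", use: str = "auto"
) -> Optional[int]:
    """Smallest step index whose value satisfies the comparison, else None.

    ``use`` selects measured values when present (``auto``/``measured``) or
    predictions (``predicted``).
    """
    if direction not in ("ge", "le"):
        raise CretraceError("direction must be 'ge' or 'le'")
    for step in traj.steps:
        if use == "predicted":
            val = step.predicted
        elif use == "measured":
            val = step.measured
        else:
            val = step.measured if step.measured is not None else step.predicted
        if val is None:
            continue
        if (direction == "ge" and val >= level) or (direction == "le" and val <= level):
            return step.index
    return None


def reconstituted_tfbs_count(
    seq: Sequence,
    reference: Sequence,
    reference_hits: TypingSequence[TFBSHit],
    motifs: Mapping[str, MotifModel],
    normalizers: Mapping[str, NormalizationReference],
    paralog_members: Optional[Mapping[str, TypingSequence[str]]] = None,
) -> int:
    """Number of reference TFBS fully reconstituted in ``seq``.

    A reference functional site counts as reconstituted when the best
    normalized affinity in ``seq`` over the site's mapped window (for the
    site's TF, or any member of its paralog group) equals or exceeds the
    endogenous normalized affinity. Sites whose window is deleted in
    ``seq`` count as not reconstituted.
    """
    if seq.residues == reference.residues:
        return len(reference_hits)
    aln = align_global(reference, seq, RECONSTITUTION)
    ref_to_col = {p: c for c, p in enumerate(aln.column_to_a) if p >= 0}
    col_to_seq = aln.column_to_b
    count = 0
    for hit in reference_hits:
        positions = [
            col_to_seq[ref_to_col[p]]
            for p in range(hit.start, hit.end)
            if p in ref_to_col and col_to_seq[ref_to_col[p]] >= 0
        ]
        if not positions:
            continue
        window = (min(positions), max(positions) + 1)
        tfs = list(paralog_members.get(hit.tf, [hit.tf])) if paralog_members else [hit.tf]
        best = 0.0
        for tf in tfs:
            if tf not in motifs:
                continue
            best = max(
                best,
                best_affinity_in_window(seq, motifs[tf], normalizers[tf], window),
            )
        if best >= hit.norm_affinity:
            count += 1
    return count


# ---------------------------------------------------------------------------
# serialization

def trajectory_to_tsv(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tstep\tmutation_id\tsequence_id\tpredicted\tmeasured\tdivergence\n")
        for s in traj.steps:
            fh.write(
                f"{traj.kind}\t{s.index}\t{s.mutation_id or '.'}\t{s.sequence.id}\t"
                f"{s.predicted:.6g}\t"
                f"{'NA' if s.measured is None else f'{s.measured:.6g}'}\t"
                f"{'NA' if s.divergence is None else f'{s.divergence:.4f}'}\n"
            )


def trajectory_intermediates_fasta(traj: Trajectory, path: str | Path) -> None:
    write_fasta([s.sequence for s in traj.steps], path)


def trajectory_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(trajs):
        for s in t.steps:
            rows.append(
                {
                    "trajectory": i, "kind": t.kind, "step": s.index,
                    "mutation_id": s.mutation_id, "sequence_id": s.sequence.id,
                    "predicted": s.predicted, "measured": s.measured,
                    "divergence": s.divergence,
                }
            )
    return pd.DataFrame(rows)


def with_measurements(
    traj: Trajectory, measured: Mapping[int, float]
) -> Trajectory:
    """Return a copy with measured activities attached by step index."""
    steps = tuple(
        TrajectoryStep(
            index=s.index, mutation_id=s.mutation_id, sequence=s.sequence,
            predicted=s.predicted,
            measured=measured.get(s.index, s.measured),
            divergence=s.divergence,
        )
        for s in traj.steps
    )
    return Trajectory(
        kind=traj.kind, start_id=traj.start_id, target_id=traj.target_id,
        steps=steps, seed=traj.seed,
    )
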