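"""Combining single-mutation effects; order dependence; TFBS attribution.

Given per-mutation log2 effect sizes measured on a fixed background
(saturation-mutagenesis convention, background activity y0), the combined
activity of a mutation subset is predicted under two models:

- additive (linear activity scale):     y = y0 + sum_i (y_i - y0), floored at 0
- multiplicative (additive in log2):    y = y0 * prod_i (y_i / y0)

where y_i = y0 * 2**effect_i is the single-mutant activity. Both models
coincide exactly for single mutations. Observed trajectories are compared
to the per-step predictions by Spearman rank correlation. Order dependence
is quantified per mutation as the standard deviation of its per-step log2
effect across trajectory contexts, relative to the replicate-noise standard
deviation propagated to a step difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EpistasisError
from .motif import MotifModel, NormalizationReference, TFBSHit, best_affinity_in_window
from .seqmut import MutationEvent
from .trajectory import Trajectory


@dataclass(frozen=True)
class SingleEffectTable:
    """Per-mutation log2 effects on a fixed measurement background.

    The caveat travels with the data: effects are typically measured on the
    extant background while reconstitution trajectories start from the
    ancestor; combination predictions inherit that approximation.
    """

    effects: Mapping[str, float]  # mutation id -> log2 effect
    y0: float  # background activity

    def __post_init__(self) -> None:
        if self.y0 <= 0:
            raise EpistasisError("background activity y0 must be positive")
        for mid, e in self.effects.items():
            if not np.isfinite(e):
                raise EpistasisError(f"non-finite effect for mutation {mid!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, y0: float) -> "SingleEffectTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "mutation_id" not in df.columns or "log2_effect" not in df.columns:
            raise EpistasisError("effect TSV needs mutation_id and log2_effect columns")
        return cls(
            effects={str(r.mutation_id): float(r.log2_effect) for r in df.itertuples()},
            y0=y0,
        )


def predict_combination(
    effects: SingleEffectTable,
    subset: TypingSequence[str],
    model: str,
) -> float:
    """Predicted activity of a mutation subset under one model."""
    missing = [m for m in subset if m not in effects.effects]
    if missing:
        raise EpistasisError(f"mutations missing from effect table: {missing}")
    y0 = effects.y0
    singles = [y0 * 2.0 ** effects.effects[m] for m in subset]
    if model == "additive":
        return max(0.0, y0 + sum(y - y0 for y in singles))
    if model == "multiplicative":
        out = y0
        for y in singles:
            out *= y / y0
        return out
    raise EpistasisError(f"unknown model {model!r}")


@dataclass(frozen=True)
class CombinationPrediction:
    steps: tuple[int, ...]
    additive: tuple[float, ...]
    multiplicative: tuple[float, ...]


def trajectory_predictions(
    traj: Trajectory, effects: SingleEffectTable
) -> CombinationPrediction:
    """Per-step additive and multiplicative predictions along a trajectory."""
    subset: list[str] = []
    add, mul, idx = [], [], []
    for step in traj.steps:
        if step.mutation_id is not None:
            subset.append(step.mutation_id)
        add.append(predict_combination(effects, subset, "additive"))
        mul.append(predict_combination(effects, subset, "multiplicative"))
        idx.append(step.index)
    return CombinationPrediction(tuple(idx), tuple(add), tuple(mul))


def model_comparison(
    traj: Trajectory, effects: SingleEffectTable
) -> pd.DataFrame:
    """Spearman rho of each model's predictions vs measured activities.

    Requires at least 3 measured intermediates; constant measurements give
    an undefined (NaN) rho. Returns a one-row-per-model table with rho and
    per-step residuals (log2 observed/predicted) attached as columns.
    """
    pred = trajectory_predictions(traj, effects)
    measured = {s.index: s.measured for s in traj.steps if s.measured is not None}
    common = [i for i in pred.steps if i in measured]
    if len(common) < 3:
        raise EpistasisError("need >= 3 measured intermediates for model comparison")
    obs = np.array([measured[i] for i in common])
    rows = []
    for model, series in (("additive", pred.additive), ("multiplicative", pred.multiplicative)):
        p = np.array([series[pred.steps.index(i)] for i in common])
        if np.ptp(obs) == 0 or np.ptp(p) == 0:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(obs, p).statistic)
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.log2(obs / p)
        rows.append(
            {
                "model": model,
                "spearman_rho": rho,
                "n_steps": len(common),
                "mean_abs_log2_residual": float(np.nanmean(np.abs(resid))),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OrderEffectStat:
    mutation_id: str
    contexts: tuple[tuple[str, int, float], ...]  # (trajectory id, step, log2 effect)
    sd_across_contexts: float
    sd_replicate_noise: Optional[float]
    ratio: Optional[float]


def order_dependence(
    trajectories: TypingSequence[Trajectory],
    step_se: Optional[TypingSequence[Mapping[int, float]]] = None,
    min_contexts: int = 2,
) -> dict[str, OrderEffectStat]:
    """Order dependence of each mutation's measured effect.

    A mutation's per-step effect in one trajectory is log2(activity after /
    activity before) at the step that introduces it. ``sd_across_contexts``
    is the standard deviation of that effect over all trajectories
    containing the mutation. ``step_se`` optionally provides per-trajectory
    {step: standard error of log2 activity}; the replicate-noise sd of a
    step difference is then propagated as sqrt(se_before^2 + se_after^2)
    and summarized as the root-mean-square across contexts. Mutations in
    fewer than ``min_contexts`` trajectories are excluded.
    """
    contexts: dict[str, list[tuple[str, int, float, Optional[float]]]] = {}
    for t_idx, traj in enumerate(trajectories):
        tid = f"{traj.kind}{t_idx}"
        se_map = step_se[t_idx] if step_se is not None else {}
        for prev, step in zip(traj.steps[:-1], traj.steps[1:]):
            if step.mutation_id is None:
                continue
            before = prev.measured if prev.measured is not None else prev.predicted
            after = step.measured if step.measured is not None else step.predicted
            if before is None or after is None or before <= 0 or after <= 0:
                continue
            eff = float(np.log2(after / before))
            noise = None
            if step.index in se_map and prev.index in se_map:
                noise = float(np.sqrt(se_map[step.index] ** 2 + se_map[prev.index] ** 2))
            contexts.setdefault(step.mutation_id, []).append((tid, step.index, eff, noise))
    out = {}
    for mid, ctx in sorted(contexts.items()):
        if len(ctx) < min_contexts:
            warnings.warn(
                f"mutation {mid!r} appears in {len(ctx)} trajectory(ies); excluded "
                f"from order-dependence analysis"
            )
            continue
        effs = np.array([c[2] for c in ctx])
        sd_ctx = float(effs.std(ddof=1))
        noises = [c[3] for c in ctx if c[3] is not None]
        if noises:
            sd_noise = float(np.sqrt(np.mean(np.square(noises))))
            ratio = sd_ctx / sd_noise if sd_noise > 0 else None
        else:
            sd_noise, ratio = None, None
        out[mid] = OrderEffectStat(
            mutation_id=mid,
            contexts=tuple((c[0], c[1], c[2]) for c in ctx),
            sd_across_contexts=sd_ctx,
            sd_replicate_noise=sd_noise,
            ratio=ratio,
        )
    return out


def _mutation_interval(ev: MutationEvent) -> tuple[int, int]:
    """Interval of a mutation on the target (extant) coordinate system."""
    if ev.kind == "deletion":
        return (ev.ref_pos, ev.ref_pos + 1)  # point of removal
    return (ev.ref_pos, ev.ref_pos + max(1, len(ev.to_allele)))


def mutation_overlaps_tfbs(
    ev: MutationEvent, sites: TypingSequence[tuple[int, int]]
) -> bool:
    m0, m1 = _mutation_interval(ev)
    return any(min(m1, s1) > max(m0, s0) for s0, s1 in sites)


def tfbs_attribution(
    traj: Trajectory,
    events: Mapping[str, MutationEvent],
    sites: TypingSequence[tuple[int, int]],
) -> tuple[Optional[float], float]:
    """Observed vs expected share of functional recovery at TFBS mutations.

    Observed share: sum of positive per-step log2 activity gains at steps
    whose mutation overlaps a reference functional TFBS interval (extant
    coordinates), divided by the sum of all positive gains. Expected share:
    fraction of all trajectory mutations overlapping a TFBS. Both in
    percent. Observed is None when the trajectory has no positive gain.
    """
    total_gain = 0.0
    tfbs_gain = 0.0
    n_overlap = 0
    n_total = 0
    for prev, step in zip(traj.steps[:-1], traj.steps[1:]):
        if step.mutation_id is None:
            continue
        n_total += 1
        ev = events.get(step.mutation_id)
        if ev is None:
            raise EpistasisError(f"no event record for mutation {step.mutation_id!r}")
        overlaps = mutation_overlaps_tfbs(ev, sites)
        if overlaps:
            n_overlap += 1
        before = prev.measured if prev.measured is not None else prev.predicted
        after = step.measured if step.measured is not None else step.predicted
        if before is None or after is None or before <= 0 or after <= 0:
            continue
        gain = float(np.log2(after / before))
        if gain > 0:
            total_gain += gain
            if overlaps:
                tfbs_gain += gain
    expected = 100.0 * n_overlap / n_total if n_total else float("nan")
    observed = 100.0 * tfbs_gain / total_gain if total_gain > 0 else None
    return observed, expected


def classify_steps(
    traj: Trajectory,
    reference_hits: TypingSequence[TFBSHit],
    events: Mapping[str, MutationEvent],
    motifs: Mapping[str, MotifModel],
    normalizers: Mapping[str, NormalizationReference],
    site_maps: TypingSequence[Mapping[int, tuple[int, int]]],
    threshold: float = 0.05,
    paralog_members: Optional[Mapping[str, TypingSequence[str]]] = None,
) -> list[str]:
    """Classify each step as reconstituting / optimizing / background.

    ``site_maps[k][site_index]`` gives reference site ``site_index``'s
    window on the step-k intermediate. A step is *reconstituting* when it
    first raises an overlapped site's normalized affinity from <= threshold
    to > threshold, *optimizing* when it changes an already-called site's
    affinity, and *background* when its mutation overlaps no reference
    site.
    """

    def site_affinity(seq, site_idx, step_idx):
        window = site_maps[step_idx].get(site_idx)
        if window is None:
            return 0.0
        hit = reference_hits[site_idx]
        tfs = list(paralog_members.get(hit.tf, [hit.tf])) if paralog_members else [hit.tf]
        return max(
            best_affinity_in_window(seq, motifs[tf], normalizers[tf], window)
            for tf in tfs
            if tf in motifs
        )

    labels = []
    for prev, step in zip(traj.steps[:-1], traj.steps[1:]):
        ev = events.get(step.mutation_id)
        if ev is None:
            raise EpistasisError(f"no event record for mutation {step.mutation_id!r}")
        ref_sites = [(h.start, h.end) for h in reference_hits]
        overlapped = [
            i for i, iv in enumerate(ref_sites)
            if mutation_overlaps_tfbs(ev, [iv])
        ]
        if not overlapped:
            labels.append("background")
            continue
        crossed = False
        for i in overlapped:
            before = site_affinity(prev.sequence, i, prev.index)
            after = site_affinity(step.sequence, i, step.index)
            if before <= threshold < after:
                crossed = True
                break
        labels.append("reconstituting" if crossed else "optimizing")
    return labels


def order_stats_to_tsv(
    statmap: Mapping[str, OrderEffectStat], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("mutation_id\tn_contexts\tsd_across_contexts\tsd_replicate_noise\tratio\n")
        for mid in sorted(statmap):
            s = statmap[mid]
            noise = "NA" if s.sd_replicate_noise is None else f"{s.sd_replicate_noise:.6g}"
            ratio = "NA" if s.ratio is None else f"{s.ratio:.6g}"
            fh.write(
                f"{mid}\t{len(s.contexts)}\t{s.sd_across_contexts:.6g}\t{noise}\t{ratio}\n"
            )
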