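"""Synthetic data with planted ground truth.

Sequences evolve root-to-tip along a labeled phylogeny under a
Jukes-Cantor-style uniform substitution process plus short geometric
indels. Every residue carries a stable token (root coordinate or insertion
id), so the simulator can emit an exact multiple sequence alignment, an
event log that replays to each node's sequence, and per-leaf retention
flags for every event — the ground truth against which lineage tracing and
trajectory analyses are validated. Clade-restricted regulatory evolution is
modeled by *planted* events: motif-creating or motif-destroying edits
applied on named branches. Activity truth is always the surrogate oracle's
score of the node sequence; barcode-level MPRA counts are simulated on top
with lognormal DNA abundances and Poisson RNA sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence as TypingSequence, Union

import numpy as np
import pandas as pd

from .errors import CretraceError
from .motif import MotifModel, write_psams
from .mpra import BarcodeMap, CountTable
from .oracle import SurrogateConfig, SurrogateOracle
from .phylo import NodeActivity, PhyloTree
from .seqmut import ALPHABET, GAP, Sequence, write_fasta

Token = Union[int, str]  # root coordinate or insertion token "i<n>.<off>"


@dataclass(frozen=True)
class PlantedEdit:
    """A motif-creating (or destroying) edit applied on a named branch.

    ``start`` is a root coordinate; ``residues`` is written over the
    root-anchored window starting there. Windows of planted edits are
    protected from indels so the ground truth stays well-defined.
    """

    branch: str  # child-node label of the edge the edit occurs on
    start: int
    residues: str
    label: str = ""


@dataclass(frozen=True)
class EvolEvent:
    """One logged edit on one branch.

    ``tokens`` anchor the event in the global token space; insertions also
    record their anchor token (the token immediately left of the inserted
    run, None at the start of the sequence).
    """

    branch: str
    kind: str  # substitution | insertion | deletion
    tokens: tuple[Token, ...]
    from_bases: str
    to_bases: str
    anchor: Optional[Token] = None
    planted: bool = False
    label: str = ""


@dataclass
class EvolutionConfig:
    tree: PhyloTree
    root_sequence: Optional[Sequence] = None
    root_length: int = 200
    sub_rate: float = 0.05  # substitutions per site per branch-length unit
    indel_rate: float = 0.0  # indel events per site per branch-length unit
    indel_mean_length: float = 1.5  # geometric mean length
    planted: tuple[PlantedEdit, ...] = ()
    #: root-coordinate windows under purifying selection: natural
    #: substitutions and indels are rejected there (planted edits still apply)
    conserved_windows: tuple[tuple[int, int], ...] = ()
    #: motifs guarding against drift-created binding sites: a natural edit
    #: whose surrounding windows would exceed ``site_guard_max_raw`` raw
    #: affinity for any of these motifs is rejected (selection against
    #: ectopic gain), keeping regulatory gains exclusively planted
    site_guard: Optional[Mapping[str, MotifModel]] = None
    site_guard_max_raw: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sub_rate < 0 or self.indel_rate < 0:
            raise CretraceError("rates must be >= 0")
        branches = {c for _, c in self.tree.edges()}
        for p in self.planted:
            if p.branch not in branches:
                raise CretraceError(f"planted edit references unknown branch {p.branch!r}")


@dataclass
class GroundTruth:
    tree: PhyloTree
    node_sequences: dict[str, Sequence]
    node_tokens: dict[str, list[Token]]
    token_order: list[Token]
    events: list[EvolEvent]
    activities: dict[str, float] = field(default_factory=dict)

    def msa_rows(self) -> dict[str, str]:
        """Exact MSA implied by the token history (root order preserved)."""
        col_of = {t: i for i, t in enumerate(self.token_order)}
        ncol = len(self.token_order)
        rows = {}
        for label, tokens in self.node_sequences_tokens():
            row = [GAP] * ncol
            seq = self.node_sequences[label].residues
            for base, tok in zip(seq, tokens):
                row[col_of[tok]] = base
            rows[label] = "".join(row)
        return rows

    def node_sequences_tokens(self):
        for label in self.node_sequences:
            yield label, self.node_tokens[label]

    def retained_in_leaf(self, event: EvolEvent, leaf: str) -> bool:
        """Whether the derived state of ``event`` survives in ``leaf``."""
        tokens = self.node_tokens[leaf]
        pos_of = {t: i for i, t in enumerate(tokens)}
        seq = self.node_sequences[leaf].residues
        if event.kind == "deletion":
            return all(t not in pos_of for t in event.tokens)
        derived = event.to_bases
        for tok, base in zip(event.tokens, derived):
            i = pos_of.get(tok)
            if i is None or seq[i] != base:
                return False
        return True

    def events_on_branch(self, child: str) -> list[EvolEvent]:
        return [e for e in self.events if e.branch == child]

    def replay(self, node: str) -> str:
        """Reconstruct a node's sequence by replaying the event log
        root-to-node; used as a round-trip integrity check."""
        from .phylo import lineage_path

        root = self.tree.root_label
        path = lineage_path(self.tree, node) if node != root else None
        tokens = list(self.node_tokens[root])
        bases = list(self.node_sequences[root].residues)
        if path is None:
            return "".join(bases)
        for child in list(path)[1:]:
            for ev in self.events_on_branch(child):
                pos_of = {t: i for i, t in enumerate(tokens)}
                if ev.kind == "substitution":
                    for tok, b in zip(ev.tokens, ev.to_bases):
                        bases[pos_of[tok]] = b
                elif ev.kind == "deletion":
                    idx = sorted(pos_of[t] for t in ev.tokens)
                    for i in reversed(idx):
                        del tokens[i], bases[i]
                else:  # insertion
                    at = 0 if ev.anchor is None else pos_of[ev.anchor] + 1
                    tokens[at:at] = list(ev.tokens)
                    bases[at:at] = list(ev.to_bases)
        return "".join(bases)


def _random_sequence(rng: np.random.Generator, length: int, seq_id: str) -> Sequence:
    idx = rng.integers(0, 4, size=length)
    return Sequence(id=seq_id, residues="".join(ALPHABET[i] for i in idx))


def simulate_evolution(cfg: EvolutionConfig) -> GroundTruth:
    """Evolve the root sequence down the tree; return full ground truth.

    Per branch, substitution and indel event counts are Poisson with mean
    L x rate x branch_length; positions and derived bases are uniform.
    Planted edits are applied after natural events on their branch and
    logged with ``planted=True``. Indels never touch planted windows.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree
    root_label = tree.root_label
    if cfg.root_sequence is not None:
        root_seq = cfg.root_sequence.residues
    else:
        root_seq = _random_sequence(rng, cfg.root_length, root_label).residues
    L0 = len(root_seq)

    protected: set[Token] = set()  # no indels here (planted windows)
    for p in cfg.planted:
        if p.start < 0 or p.start + len(p.residues) > L0:
            raise CretraceError(f"planted edit {p.label!r} outside root coordinates")
        protected.update(range(p.start, p.start + len(p.residues)))
    conserved: set[Token] = set()  # purifying selection: no natural edits at all
    for s, e in cfg.conserved_windows:
        conserved.update(range(s, e))
    protected |= conserved

    token_order: list[Token] = list(range(L0))
    node_tokens: dict[str, list[Token]] = {root_label: list(range(L0))}
    node_bases: dict[str, list[str]] = {root_label: list(root_seq)}
    events: list[EvolEvent] = []
    ins_counter = 0
    geo_p = min(1.0, 1.0 / cfg.indel_mean_length)

    guard_motifs = list(cfg.site_guard.values()) if cfg.site_guard else []

    def creates_site(bases: list[str], lo: int, hi: int) -> bool:
        """Would any motif window overlapping [lo, hi) become a near-site?

        Only windows overlapping the edited span are scored, so intentional
        consensus sites nearby never trigger the guard.
        """
        from .motif import _encode, _scan_forward
        from .seqmut import revcomp

        for m in guard_motifs:
            w0 = max(0, lo - m.k + 1)
            w1 = min(len(bases), hi + m.k - 1)
            region = "".join(bases[w0:w1])
            if len(region) < m.k:
                continue
            if _scan_forward(_encode(region), m.weights).max() > cfg.site_guard_max_raw:
                return True
            if _scan_forward(_encode(revcomp(region)), m.weights).max() > cfg.site_guard_max_raw:
                return True
        return False

    def evolve_branch(parent: str, child: str, blen: float) -> None:
        nonlocal ins_counter
        tokens = list(node_tokens[parent])
        bases = list(node_bases[parent])
        L = len(tokens)
        # natural substitutions
        n_sub = rng.poisson(L * cfg.sub_rate * blen)
        for _ in range(n_sub):
            i = int(rng.integers(0, len(tokens)))
            if tokens[i] in conserved:
                continue  # rejected by purifying selection
            old = bases[i]
            alts = [b for b in ALPHABET if b != old]
            new = alts[int(rng.integers(0, 3))]  # uniform over the 3 alternatives
            bases[i] = new
            if creates_site(bases, i, i + 1):
                bases[i] = old  # selection against ectopic site gain
                continue
            events.append(
                EvolEvent(
                    branch=child, kind="substitution", tokens=(tokens[i],),
                    from_bases=old, to_bases=new,
                )
            )
        # natural indels (skipped where they would touch a planted window)
        n_indel = rng.poisson(L * cfg.indel_rate * blen)
        for _ in range(n_indel):
            glen = int(rng.geometric(geo_p))
            if rng.random() < 0.5 and len(tokens) > glen + 10:  # deletion
                i = int(rng.integers(0, len(tokens) - glen))
                run = tokens[i:i + glen]
                if any(t in protected for t in run):
                    continue
                if creates_site(bases[:i] + bases[i + glen:], i, i):
                    continue  # junction would form an ectopic site
                del_bases = "".join(bases[i:i + glen])
                del tokens[i:i + glen]
                del bases[i:i + glen]
                events.append(
                    EvolEvent(
                        branch=child, kind="deletion", tokens=tuple(run),
                        from_bases=del_bases, to_bases="",
                    )
                )
            else:  # insertion after position i-1 (i in [0, len])
                i = int(rng.integers(0, len(tokens) + 1))
                anchor = tokens[i - 1] if i > 0 else None
                right = tokens[i] if i < len(tokens) else None
                if anchor in protected and right in protected:
                    continue  # would split a planted window
                new_bases = "".join(
                    ALPHABET[int(b)] for b in rng.integers(0, 4, size=glen)
                )
                if creates_site(bases[:i] + list(new_bases) + bases[i:], i, i + glen):
                    continue  # inserted run would form an ectopic site
                new_toks = [f"i{ins_counter}.{o}" for o in range(glen)]
                ins_counter += 1
                # splice into the global column order after the anchor
                at = 0 if anchor is None else token_order.index(anchor) + 1
                token_order[at:at] = new_toks
                tokens[i:i] = new_toks
                bases[i:i] = list(new_bases)
                events.append(
                    EvolEvent(
                        branch=child, kind="insertion", tokens=tuple(new_toks),
                        from_bases="", to_bases=new_bases, anchor=anchor,
                    )
                )
        # planted edits for this branch, applied last
        for p in cfg.planted:
            if p.branch != child:
                continue
            pos_of = {t: i for i, t in enumerate(tokens)}
            for off, b in enumerate(p.residues):
                tok = p.start + off
                if tok not in pos_of:
                    raise CretraceError(
                        f"planted edit {p.label!r} collides with a deletion on "
                        f"branch {child!r}"
                    )
                i = pos_of[tok]
                if bases[i] != b:
                    events.append(
                        EvolEvent(
                            branch=child, kind="substitution", tokens=(tok,),
                            from_bases=bases[i], to_bases=b, planted=True,
                            label=p.label,
                        )
                    )
                    bases[i] = b
        node_tokens[child] = tokens
        node_bases[child] = bases

    for parent, child in tree.edges():
        node = tree.node(child)
        blen = node.edge.length if node.edge.length is not None else 1.0
        evolve_branch(parent, child, blen)

    node_sequences = {
        label: Sequence(id=label, residues="".join(b), node_label=label)
        for label, b in node_bases.items()
    }
    return GroundTruth(
        tree=tree,
        node_sequences=node_sequences,
        node_tokens=node_tokens,
        token_order=token_order,
        events=events,
    )


def attach_activities(truth: GroundTruth, oracle: SurrogateOracle) -> GroundTruth:
    """Score every node's sequence with the surrogate (activity truth)."""
    truth.activities = {
        label: oracle.score(seq) for label, seq in truth.node_sequences.items()
    }
    return truth


@dataclass
class MPRASimConfig:
    barcodes_per_element: int = 30
    dna_lognormal_mu: float = 0.0
    dna_lognormal_sigma: float = 0.8
    replicates: int = 3
    depth: int = 1_000_000  # total UMIs per sample (DNA and RNA alike)
    baseline_rate: float = 0.0  # additive floor on the RNA rate
    mean_assembly_reads: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.replicates < 1 or self.barcodes_per_element < 1:
            raise CretraceError("depth, replicates, barcodes_per_element must be positive")


def simulate_mpra(
    activities: Mapping[str, float], cfg: MPRASimConfig
) -> tuple[CountTable, BarcodeMap]:
    """Simulate barcode-level UMI counts for elements of known activity.

    Each element receives ``barcodes_per_element`` barcodes with lognormal
    DNA abundances fixed across replicates. Per replicate, DNA UMIs are
    Poisson around depth x abundance share, and RNA UMIs Poisson around
    depth x share proportional to activity x abundance. An element of
    activity 0 (with zero baseline rate) therefore yields zero RNA counts.
    """
    if any(a < 0 for a in activities.values()):
        raise CretraceError("activities must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    elements = sorted(activities)
    total_rate = sum(activities[e] + cfg.baseline_rate for e in elements)
    if total_rate <= 0:
        raise CretraceError("all activities and the baseline rate are zero")
    barcodes, element_of, dna_abund, rna_rate = [], [], [], []
    for el in elements:
        for b in range(cfg.barcodes_per_element):
            bc = f"{el}:bc{b:03d}"
            abund = rng.lognormal(cfg.dna_lognormal_mu, cfg.dna_lognormal_sigma)
            barcodes.append(bc)
            element_of.append(el)
            dna_abund.append(abund)
            rna_rate.append(abund * (activities[el] + cfg.baseline_rate))
    dna_share = np.array(dna_abund) / np.sum(dna_abund)
    rna_total = np.sum(rna_rate)
    rna_share = np.array(rna_rate) / rna_total if rna_total > 0 else np.zeros(len(rna_rate))
    rows = []
    for rep in range(1, cfg.replicates + 1):
        dna_counts = rng.poisson(cfg.depth * dna_share)
        rna_counts = rng.poisson(cfg.depth * rna_share)
        for bc, d, r in zip(barcodes, dna_counts, rna_counts):
            rows.append((bc, f"rep{rep}", "DNA", int(d)))
            rows.append((bc, f"rep{rep}", "RNA", int(r)))
    table = CountTable(
        pd.DataFrame(rows, columns=["barcode", "replicate", "molecule", "umi_count"])
    )
    reads = 1 + rng.poisson(cfg.mean_assembly_reads, size=len(barcodes))
    bmap = BarcodeMap(
        pd.DataFrame(
            {"barcode": barcodes, "element": element_of, "reads": reads.astype(int)}
        )
    )
    return table, bmap


# ---------------------------------------------------------------------------
# canonical motif set and fixture scenarios

def default_motifs() -> dict[str, MotifModel]:
    """Small PSAM set emulating the parietal-endoderm regulators.

    Five motifs: the heterotypic module TFs (Foxa2, Sox17, Gata4 with its
    paralog Gata6) and an AP-1-like booster (Jun_Atf3). Widths 6-7 so
    exhaustive normalization checks stay cheap; each motif has one
    degenerate position so near-consensus sites score above threshold.
    """

    def psam(consensus: str, degenerate: int, off: float = 0.04) -> np.ndarray:
        w = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            w[i, ALPHABET.index(b)] = 1.0
        # one two-fold-degenerate position
        j = (ALPHABET.index(consensus[degenerate]) + 1) % 4
        w[degenerate, j] = 0.5
        return w

    return {
        "Foxa2": MotifModel("Foxa2", psam("TGTTTA", 4)),
        "Sox17": MotifModel("Sox17", psam("CATTGT", 1)),
        "Gata4": MotifModel("Gata4", psam("AGATAA", 5), paralog_group="Gata4/6"),
        "Gata6": MotifModel("Gata6", psam("AGATAG", 5), paralog_group="Gata4/6"),
        "Jun_Atf3": MotifModel("Jun_Atf3", psam("TGACTCA", 3)),
    }


PARALOG_GROUPS = {"Gata4": "Gata4/6", "Gata6": "Gata4/6"}

MOTIF_CONSENSUS = {
    "Foxa2": "TGTTTA",
    "Sox17": "CATTGT",
    "Gata4": "AGATAA",
    "Gata6": "AGATAG",
    "Jun_Atf3": "TGACTCA",
}


def default_surrogate_config(seed: int = 0) -> SurrogateConfig:
    return SurrogateConfig(
        booster_weights={"Foxa2": 1.0, "Sox17": 1.0, "Gata4/6": 1.5, "Jun_Atf3": 2.0},
        required_modules=(("Foxa2", 0.3), ("Sox17", 0.3), ("Gata4/6", 0.3)),
        b0=0.1,
        c_max=8.0,
        threshold=0.05,
        normalizer_n=100_000,
        seed=seed,
    )


def make_surrogate(seed: int = 0) -> SurrogateOracle:
    return SurrogateOracle(
        motifs=default_motifs(),
        config=default_surrogate_config(seed),
        paralog_groups=PARALOG_GROUPS,
    )


SCENARIO_I_NEWICK = (
    "((((S1:0.08,S2:0.08)A1:0.08,S3:0.16)A2:0.08,"
    "(S4:0.12,S5:0.12)A3:0.12)A4:0.08,(S6:0.2,S7:0.2)A5:0.04)R0;"
)

SCENARIO_II_NEWICK = (
    "(((((P1:0.06,P2:0.06)B1:0.06,(P3:0.06,P4:0.06)B2:0.06)B3:0.06,"
    "((P5:0.06,P6:0.06)B4:0.06,(P7:0.06,P8:0.06)B5:0.06)B6:0.06)B7:0.06,"
    "(((P9:0.06,P10:0.06)B8:0.06,(P11:0.06,P12:0.06)B9:0.06)B10:0.06,"
    "(P13:0.09,P14:0.09)B11:0.09)B12:0.06)B13:0.06,"
    "(P15:0.2,P16:0.2)B14:0.06)R0;"
)


def _write_windows(seq: str, edits: Mapping[int, str]) -> str:
    chars = list(seq)
    for start, residues in edits.items():
        chars[start:start + len(residues)] = list(residues)
    return "".join(chars)


@dataclass
class FixtureBundle:
    name: str
    tree: PhyloTree
    newick: str
    truth: GroundTruth
    oracle: SurrogateOracle
    planted: tuple[PlantedEdit, ...]
    counts: CountTable
    barcode_map: BarcodeMap
    negatives: tuple[str, ...]
    seed: int

    @property
    def activities(self) -> dict[str, float]:
        return dict(self.truth.activities)


def _scrub_states(base: str, states: TypingSequence[Mapping[int, str]],
                  rng: np.random.Generator, max_raw: float = 0.01) -> str:
    """Scrub a background so no motif near-site exists in ANY edit state.

    Each state is a mapping start -> residues written over the base;
    together the states enumerate the window contents realized anywhere on
    the phylogeny (sites absent, planted, broken by a planted loss).
    Offending windows — raw affinity above ``max_raw`` on either strand for
    any canonical motif — are disrupted by mutating base positions not
    overwritten in that state, so intentional sites are never touched and
    junction windows (consensus flanked by background) are clean in every
    state. The default ceiling keeps background at least two specific
    substitutions away from a callable site, so drift essentially never
    creates one.
    """
    from .motif import scan as motif_scan

    def realize(chars: list[str], state: Mapping[int, str]) -> tuple[str, set[int]]:
        out = list(chars)
        written: set[int] = set()
        for s, residues in state.items():
            out[s:s + len(residues)] = list(residues)
            written.update(range(s, s + len(residues)))
        return "".join(out), written

    chars = list(base)
    motifs = default_motifs()
    for _ in range(200):
        dirty = False
        for state in states:
            realized, written = realize(chars, state)
            current = Sequence(id="bg", residues=realized)
            for m in motifs.values():
                prof = motif_scan(current, m)
                raw = np.maximum(prof.fwd, prof.rev)
                for i in np.nonzero(raw > max_raw)[0]:
                    free = [p for p in range(i, i + m.k) if p not in written]
                    if not free:
                        continue  # an intentional site
                    # random free position: a window may need several bases
                    # changed before its affinity drops below the ceiling
                    j = free[int(rng.integers(0, len(free)))]
                    alts = [b for b in ALPHABET if b != chars[j]]
                    chars[j] = alts[int(rng.integers(0, 3))]
                    dirty = True
        if not dirty:
            return "".join(chars)
    raise CretraceError("background scrub did not converge")


def make_scenario_i(seed: int = 0, length: int = 180) -> FixtureBundle:
    """Conserved-but-repurposed element.

    The root already carries two of the three required-module sites (Foxa2,
    Sox17); three TFBS-creating edits — the completing Gata4 site and two
    AP-1 boosters — are planted on the branch into the terminal clade A1.
    Activity gain is therefore confined to A1 and its leaves (S1, S2).
    """
    rng = np.random.default_rng(seed)
    tree = PhyloTree.from_newick(SCENARIO_I_NEWICK, is_path=False)
    base = _random_sequence(rng, length, "root").residues
    root_edits = {20: MOTIF_CONSENSUS["Foxa2"], 40: MOTIF_CONSENSUS["Sox17"]}
    planted_windows = {60: MOTIF_CONSENSUS["Gata4"], 90: MOTIF_CONSENSUS["Jun_Atf3"],
                       120: MOTIF_CONSENSUS["Jun_Atf3"]}
    # co-scrub the two realized states: root sites only (everywhere) and
    # root sites + planted gains (the A1 clade)
    base = _scrub_states(
        base, [dict(root_edits), {**root_edits, **planted_windows}], rng
    )
    root = _write_windows(base, root_edits)
    planted = tuple(
        PlantedEdit(branch="A1", start=s, residues=r, label=f"gain@{s}")
        for s, r in sorted(planted_windows.items())
    )
    # conserve sites plus a one-motif-width margin, emulating purifying
    # selection on the sites and freezing their junction windows
    conserved = tuple(
        (max(0, s - 7), min(length, s + len(r) + 7))
        for s, r in sorted({**root_edits, **planted_windows}.items())
    )
    cfg = EvolutionConfig(
        tree=tree,
        root_sequence=Sequence(id="R0", residues=root),
        sub_rate=0.5,
        indel_rate=0.05,
        planted=planted,
        conserved_windows=conserved,
        site_guard=default_motifs(),
        seed=seed,
    )
    truth = simulate_evolution(cfg)
    oracle = make_surrogate(seed=0)
    attach_activities(truth, oracle)
    activities = dict(truth.activities)
    negatives = tuple(f"neg{i}" for i in range(1, 5))
    for n in negatives:
        activities[n] = oracle.config.b0
    counts, bmap = simulate_mpra(
        activities, MPRASimConfig(seed=seed + 1, baseline_rate=0.0)
    )
    return FixtureBundle(
        name="scenario_i", tree=tree, newick=SCENARIO_I_NEWICK, truth=truth,
        oracle=oracle, planted=planted, counts=counts, barcode_map=bmap,
        negatives=negatives, seed=seed,
    )


def _broken_core(cons: str) -> str:
    """Two-base scramble of a consensus core (complement-shifted bases)."""
    core = len(cons) // 2
    return "".join(ALPHABET[(ALPHABET.index(c) + 2) % 4] for c in cons[core:core + 2])


def _broken_consensus(tf: str) -> str:
    cons = MOTIF_CONSENSUS[tf]
    core = len(cons) // 2
    return cons[:core] + _broken_core(cons) + cons[core + 2:]


def _destroying_edit(tf: str, start: int, label: str, branch: str) -> PlantedEdit:
    """Edit that scrambles the core of a planted consensus site."""
    cons = MOTIF_CONSENSUS[tf]
    core = len(cons) // 2
    return PlantedEdit(
        branch=branch, start=start + core, residues=_broken_core(cons), label=label
    )


def make_scenario_ii(seed: int = 0, length: int = 240) -> FixtureBundle:
    """Module-dependent element.

    The full heterotypic triplet (Foxa2-Sox17-Gata4/6) is planted on the
    branch into the large clade B13; two independent planted losses destroy
    the Sox17 site below B3 and the Gata4 site below B8, and two
    independent AP-1 booster gains arise below B5 and B11. Descendants of
    the loss branches are inactive (gate closed); booster subclades exceed
    the module-only activity.
    """
    rng = np.random.default_rng(seed + 1000)
    tree = PhyloTree.from_newick(SCENARIO_II_NEWICK, is_path=False)
    base = _random_sequence(rng, length, "root").residues
    module = {30: MOTIF_CONSENSUS["Foxa2"], 60: MOTIF_CONSENSUS["Sox17"],
              90: MOTIF_CONSENSUS["Gata4"]}
    boosters = {140: MOTIF_CONSENSUS["Jun_Atf3"], 180: MOTIF_CONSENSUS["Jun_Atf3"]}
    # co-scrub every realized window state: bare background (root and the
    # B14 outgroup), planted module+boosters, and the two broken-module
    # states downstream of the planted losses
    full = {**module, **boosters}
    root = _scrub_states(
        base,
        [
            dict(),
            full,
            {**full, 60: _broken_consensus("Sox17")},
            {**full, 90: _broken_consensus("Gata4")},
        ],
        rng,
    )
    planted = tuple(
        [
            PlantedEdit(branch="B13", start=s, residues=r, label=f"module@{s}")
            for s, r in sorted(module.items())
        ]
        + [
            _destroying_edit("Sox17", 60, "loss_sox17", branch="B3"),
            _destroying_edit("Gata4", 90, "loss_gata", branch="B8"),
            PlantedEdit(branch="B5", start=140, residues=MOTIF_CONSENSUS["Jun_Atf3"],
                        label="booster_b5"),
            PlantedEdit(branch="B11", start=180, residues=MOTIF_CONSENSUS["Jun_Atf3"],
                        label="booster_b11"),
        ]
    )
    conserved = tuple(
        (max(0, s - 7), min(length, s + len(r) + 7))
        for s, r in sorted({**module, **boosters}.items())
    )
    cfg = EvolutionConfig(
        tree=tree,
        root_sequence=Sequence(id="R0", residues=root),
        sub_rate=1.0,
        indel_rate=0.1,
        planted=planted,
        conserved_windows=conserved,
        site_guard=default_motifs(),
        seed=seed,
    )
    truth = simulate_evolution(cfg)
    oracle = make_surrogate(seed=0)
    attach_activities(truth, oracle)
    activities = dict(truth.activities)
    negatives = tuple(f"neg{i}" for i in range(1, 5))
    for n in negatives:
        activities[n] = oracle.config.b0
    counts, bmap = simulate_mpra(
        activities, MPRASimConfig(seed=seed + 1, baseline_rate=0.0)
    )
    return FixtureBundle(
        name="scenario_ii", tree=tree, newick=SCENARIO_II_NEWICK, truth=truth,
        oracle=oracle, planted=planted, counts=counts, barcode_map=bmap,
        negatives=negatives, seed=seed,
    )


def make_fixture_suite(seed: int = 0) -> dict[str, FixtureBundle]:
    """The two canonical scenarios under one seed."""
    return {"scenario_i": make_scenario_i(seed), "scenario_ii": make_scenario_ii(seed)}


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Serialize a fixture bundle as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [bundle.truth.node_sequences[l] for l in sorted(bundle.truth.node_sequences)],
        outdir / "sequences.fasta",
    )
    (outdir / "tree.nwk").write_text(bundle.newick + "\n")
    rows = bundle.truth.msa_rows()
    with open(outdir / "msa.fasta", "w") as fh:
        for label in sorted(rows):
            fh.write(f">{label}\n{rows[label]}\n")
    psam_dir = outdir / "psam"
    psam_dir.mkdir(exist_ok=True)
    write_psams(bundle.oracle.motifs.values(), psam_dir / "psams.tsv")
    bundle.counts.to_tsv(outdir / "counts.tsv")
    bundle.barcode_map.to_tsv(outdir / "barcode_map.tsv")
    bundle.oracle.config.to_yaml(outdir / "surrogate.yaml")
    act = NodeActivity(
        {l: (a, 0.0, 1) for l, a in sorted(bundle.truth.activities.items())}
    )
    act.to_tsv(outdir / "true_activities.tsv")
    truth_json = {
        "name": bundle.name,
        "seed": bundle.seed,
        "negatives": list(bundle.negatives),
        "planted": [
            {"branch": p.branch, "start": p.start, "residues": p.residues,
             "label": p.label}
            for p in bundle.planted
        ],
        "events": [
            {
                "branch": e.branch, "kind": e.kind,
                "tokens": [str(t) for t in e.tokens],
                "from": e.from_bases, "to": e.to_bases,
                "planted": e.planted, "label": e.label,
            }
            for e in bundle.truth.events
        ],
        "activities": {l: bundle.truth.activities[l]
                       for l in sorted(bundle.truth.activities)},
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
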