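"""Greedy/random reconstitution, de novo tuning, and trajectory metrics."""

import itertools

import numpy as np
import pytest

from cretrace import motif as mo
from cretrace import seqmut as sm
from cretrace import synth as sy
from cretrace import trajectory as tj
from cretrace.errors import CretraceError
from cretrace.seqmut import Sequence

from conftest import ConstantOracle, PositionWeightOracle, random_seq


@pytest.fixture(scope="module")
def recon_pair():
    """Ancestor/extant pair from the fixture scenario (28 mutations)."""
    bundle = sy.make_scenario_i(seed=0)
    return (bundle.truth.node_sequences["R0"], bundle.truth.node_sequences["S1"],
            bundle.oracle)


def additive_oracle_for(ancestor, aln, events, rng):
    """Position-weight oracle whose per-mutation gains are independent.

    Weights are attached to each event's derived base at its final
    (post-all-mutations) coordinates; with substitution-only event sets the
    coordinates never shift, so gains add exactly.
    """
    weights = {}
    gains = {}
    for ev in events:
        g = float(rng.uniform(0.1, 2.0))
        weights[(ev.ref_pos, ev.to_allele)] = g
        gains[ev.id] = g
    return PositionWeightOracle(weights), gains


def substitution_only_pair(rng, length=40, n_sub=8):
    """Pair differing by isolated substitutions only (spaced >= 2 apart)."""
    anc = random_seq(rng, length, "anc")
    chars = list(anc.residues)
    for i in rng.choice(length // 2, size=n_sub, replace=False) * 2:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return anc, Sequence("ext", "".join(chars))


def identity_alignment(anc, ext):
    """The gap-free alignment of two equal-length sequences.

    Under unit scoring a substitution can tie with a del+ins placement next
    to a repeat, so the substitution-only reading is pinned explicitly where
    a test's oracle is keyed on final coordinates.
    """
    return sm.AlignmentPair(
        a=anc, b=ext, aligned_a=anc.residues, aligned_b=ext.residues,
        score=sm.score_alignment(anc.residues, ext.residues, sm.RECONSTITUTION),
        params=sm.RECONSTITUTION,
    )


class TestGreedyReconstitution:
    def test_zero_mutations_zero_steps(self, rng):
        s = random_seq(rng, 30)
        traj = tj.greedy_reconstitution(s, s, ConstantOracle())
        assert traj.n_steps == 0
        assert traj.steps[0].sequence.residues == s.residues

    def test_terminates_exactly_at_extant(self, recon_pair):
        anc, ext, oracle = recon_pair
        traj = tj.greedy_reconstitution(anc, ext, oracle, compute_divergence=False)
        assert traj.steps[-1].sequence.residues == ext.residues
        aln = sm.align_global(anc, ext)
        assert traj.n_steps == len(sm.enumerate_mutations(aln))

    def test_additive_oracle_equals_descending_sort(self):
        rng = np.random.default_rng(4)
        anc, ext = substitution_only_pair(rng)
        aln = identity_alignment(anc, ext)
        events = sm.enumerate_mutations(aln).events
        oracle, gains = additive_oracle_for(anc, aln, events, rng)
        traj = tj.greedy_reconstitution(anc, ext, oracle, aln=aln,
                                        compute_divergence=False)
        expected = [e.id for e in sorted(events,
                                         key=lambda e: (-gains[e.id], e.column_start))]
        assert traj.mutation_order == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_local_optimality_audit(self, seed):
        """Every committed step's gain >= every uncommitted alternative's."""
        rng = np.random.default_rng(seed)
        anc, ext = substitution_only_pair(rng, length=30, n_sub=6)
        aln = sm.align_global(anc, ext)
        events = list(sm.enumerate_mutations(aln).events)
        oracle = sy.make_surrogate(seed=0)
        traj = tj.greedy_reconstitution(anc, ext, oracle, compute_divergence=False)
        committed = []
        remaining = {e.id: e for e in events}
        for step in traj.steps[1:]:
            # exhaustive audit: rescore every alternative at this state
            scores = {}
            for eid, ev in remaining.items():
                cand = sm.apply_mutations(anc, aln, committed + [ev])
                scores[eid] = oracle.score(cand)
            assert scores[step.mutation_id] == pytest.approx(max(scores.values()))
            committed.append(remaining.pop(step.mutation_id))

    def test_deterministic_without_seed(self, recon_pair):
        anc, ext, oracle = recon_pair
        t1 = tj.greedy_reconstitution(anc, ext, oracle, compute_divergence=False)
        t2 = tj.greedy_reconstitution(anc, ext, oracle, compute_divergence=False)
        assert t1.mutation_order == t2.mutation_order

    def test_divergence_axis_decreases_to_zero(self, recon_pair):
        anc, ext, oracle = recon_pair
        traj = tj.greedy_reconstitution(anc, ext, oracle)
        assert traj.steps[-1].divergence == pytest.approx(0.0)
        assert traj.steps[0].divergence > 0


class TestRandomReconstitutions:
    def test_all_share_endpoint_and_step_count(self, recon_pair):
        anc, ext, oracle = recon_pair
        trajs = tj.random_reconstitutions(anc, ext, ConstantOracle(), n=5, seed=3)
        counts = {t.n_steps for t in trajs}
        assert len(counts) == 1
        for t in trajs:
            assert t.steps[-1].sequence.residues == ext.residues

    def test_seeded_reproducibility(self, recon_pair):
        anc, ext, _ = recon_pair
        a = tj.random_reconstitutions(anc, ext, ConstantOracle(), n=3, seed=11,
                                      compute_divergence=False)
        b = tj.random_reconstitutions(anc, ext, ConstantOracle(), n=3, seed=11,
                                      compute_divergence=False)
        assert [t.mutation_order for t in a] == [t.mutation_order for t in b]

    def test_permutation_uniformity_chi_square(self):
        """Orders of a 4-event set are uniform over the 24 permutations."""
        rng = np.random.default_rng(0)
        anc, ext = substitution_only_pair(rng, length=12, n_sub=4)
        n_draws = 3000
        trajs = tj.random_reconstitutions(
            anc, ext, ConstantOracle(), n=n_draws, seed=5, compute_divergence=False
        )
        orders = {}
        for t in trajs:
            key = tuple(t.mutation_order)
            orders[key] = orders.get(key, 0) + 1
        assert len(orders) == 24
        from scipy import stats
        observed = np.array(list(orders.values()))
        chi2, p = stats.chisquare(observed)
        assert p > 0.01


class TestPhylogenyTrajectory:
    def test_single_node_path(self, scenario_i):
        from cretrace.phylo import LineagePath
        seqs = scenario_i.truth.node_sequences
        traj = tj.phylogeny_trajectory(LineagePath(("S1",)), seqs, "S1")
        assert traj.n_steps == 0
        assert traj.steps[0].divergence == pytest.approx(0.0)

    def test_lineage_divergence_matches_direct_recomputation(self, scenario_i):
        from cretrace.phylo import lineage_path
        seqs = scenario_i.truth.node_sequences
        path = lineage_path(scenario_i.tree, "S1")
        traj = tj.phylogeny_trajectory(path, seqs, "S1", scenario_i.oracle)
        assert traj.steps[-1].divergence == pytest.approx(0.0)
        for step, node in zip(traj.steps, path):
            aln = sm.align_global(seqs[node], seqs["S1"])
            expected = 100.0 - sm.sequence_identity(aln)
            assert step.divergence == pytest.approx(expected)

    def test_missing_nodes_skipped_with_warning(self, scenario_i):
        from cretrace.phylo import lineage_path
        seqs = dict(scenario_i.truth.node_sequences)
        path = lineage_path(scenario_i.tree, "S1")
        del seqs["A4"]
        with pytest.warns(UserWarning, match="A4"):
            traj = tj.phylogeny_trajectory(path, seqs, "S1")
        assert traj.n_steps == len(path) - 2


class TestDenovoTune:
    def test_step_count_and_hamming_distance(self, rng):
        seq = random_seq(rng, 25)
        traj = tj.denovo_tune(seq, ConstantOracle(), "enhance", steps=6)
        assert traj.n_steps == 6
        for prev, step in zip(traj.steps[:-1], traj.steps[1:]):
            diff = sum(
                1 for x, y in zip(prev.sequence.residues, step.sequence.residues)
                if x != y
            )
            assert diff == 1

    def test_cycle_guard_blocks_immediate_reversion(self, rng):
        seq = random_seq(rng, 20)
        traj = tj.denovo_tune(seq, ConstantOracle(), "enhance", steps=8)
        seqs = [s.sequence.residues for s in traj.steps]
        for a, b in zip(seqs[:-2], seqs[2:]):
            assert a != b

    def test_ablate_reaches_baseline_once_module_destroyed(self, scenario_i):
        oracle = scenario_i.oracle
        start = scenario_i.truth.node_sequences["S1"]
        traj = tj.denovo_tune(start, oracle, "ablate", steps=4)
        assert traj.predicted[0] > oracle.config.b0
        assert traj.predicted[-1] == oracle.config.b0
        # scores never increase under the ablate objective on this surrogate
        assert all(b <= a + 1e-12 for a, b in zip(traj.predicted[:-1],
                                                  traj.predicted[1:]))

    def test_enhance_nondecreasing_capped_and_argmax_audited(self, scenario_ii):
        oracle = scenario_ii.oracle
        start = scenario_ii.truth.node_sequences["B13"]  # module intact, below cap
        traj = tj.denovo_tune(start, oracle, "enhance", steps=5)
        preds = traj.predicted
        assert all(b >= a - 1e-12 for a, b in zip(preds[:-1], preds[1:]))
        assert all(p <= oracle.config.c_max + 1e-12 for p in preds)
        # exhaustive ISM audit of each committed step
        prev_res = None
        for prev, step in zip(traj.steps[:-1], traj.steps[1:]):
            s = prev.sequence.residues
            best = -np.inf
            for pos in range(len(s)):
                for alt in "ACGT":
                    if alt == s[pos]:
                        continue
                    cand = s[:pos] + alt + s[pos + 1:]
                    if cand == prev_res:
                        continue
                    best = max(best, oracle.score(Sequence("c", cand)))
            assert step.predicted == pytest.approx(best)
            prev_res = s

    def test_invalid_objective_rejected(self, rng):
        with pytest.raises(CretraceError):
            tj.denovo_tune(random_seq(rng, 10), ConstantOracle(), "optimize")


class TestStepsToLevel:
    def mk(self, values):
        steps = tuple(
            tj.TrajectoryStep(index=i, mutation_id=None if i == 0 else f"m{i}",
                              sequence=Sequence("s", "ACGT"), predicted=v)
            for i, v in enumerate(values)
        )
        return tj.Trajectory(kind="model_optimized", start_id="a", target_id="b",
                             steps=steps)

    def test_start_already_satisfies(self):
        assert tj.steps_to_level(self.mk([5, 1, 2]), 4.0, "ge") == 0

    def test_monotone_crossing_at_step_three(self):
        assert tj.steps_to_level(self.mk([0, 1, 2, 4, 5]), 3.5, "ge") == 3

    def test_never_reached_returns_none(self):
        assert tj.steps_to_level(self.mk([1, 2]), 10, "ge") is None

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(20):
            vals = list(rng.uniform(0, 10, size=8))
            level = float(rng.uniform(0, 10))
            traj = self.mk(vals)
            expected = next((i for i, v in enumerate(vals) if v >= level), None)
            assert tj.steps_to_level(traj, level, "ge") == expected
            expected_le = next((i for i, v in enumerate(vals) if v <= level), None)
            assert tj.steps_to_level(traj, level, "le") == expected_le


class TestReconstitutedTFBSCount:
    def reference_setup(self, scenario_i):
        oracle = scenario_i.oracle
        ref = scenario_i.truth.node_sequences["S1"]
        hits = [h for h in oracle.merged_hits(ref) if h.norm_affinity >= 0.3]
        members = {"Gata4/6": ["Gata4", "Gata6"]}
        return oracle, ref, hits, members

    def test_reference_itself_counts_all_sites(self, scenario_i):
        oracle, ref, hits, members = self.reference_setup(scenario_i)
        n = tj.reconstituted_tfbs_count(
            ref, ref, hits, oracle.motifs, oracle.normalizers, members
        )
        assert n == len(hits)

    def test_ancestor_missing_planted_sites(self, scenario_i):
        oracle, ref, hits, members = self.reference_setup(scenario_i)
        anc = scenario_i.truth.node_sequences["R0"]
        n = tj.reconstituted_tfbs_count(
            anc, ref, hits, oracle.motifs, oracle.normalizers, members
        )
        assert n < len(hits)

    def test_all_sites_scrambled_counts_zero(self, scenario_i, rng):
        oracle, ref, hits, members = self.reference_setup(scenario_i)
        chars = list(ref.residues)
        for h in hits:
            for p in range(h.start, h.end):
                alts = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alts[int(rng.integers(0, 3))]
        scrambled = Sequence("scr", "".join(chars))
        n = tj.reconstituted_tfbs_count(
            scrambled, ref, hits, oracle.motifs, oracle.normalizers, members
        )
        assert n == 0

    def test_partial_reconstitution_matches_per_site_oracle(self, scenario_i):
        oracle, ref, hits, members = self.reference_setup(scenario_i)
        anc = scenario_i.truth.node_sequences["R0"]
        n = tj.reconstituted_tfbs_count(
            anc, ref, hits, oracle.motifs, oracle.normalizers, members
        )
        # independent per-site rescore via the alignment map
        aln = sm.align_global(ref, anc)
        ref2col = {p: c for c, p in enumerate(aln.column_to_a) if p >= 0}
        col2anc = aln.column_to_b
        expected = 0
        for h in hits:
            pos = [col2anc[ref2col[p]] for p in range(h.start, h.end)
                   if p in ref2col and col2anc[ref2col[p]] >= 0]
            if not pos:
                continue
            window = (min(pos), max(pos) + 1)
            best = max(
                mo.best_affinity_in_window(anc, oracle.motifs[tf],
                                           oracle.normalizers[tf], window)
                for tf in members.get(h.tf, [h.tf])
            )
            if best >= h.norm_affinity:
                expected += 1
        assert n == expected


def test_trajectory_tsv_serialization(tmp_path, rng):
    seq = random_seq(rng, 15)
    traj = tj.denovo_tune(seq, ConstantOracle(), "enhance", steps=2)
    p = tmp_path / "traj.tsv"
    tj.trajectory_to_tsv(traj, p)
    lines = p.read_text().splitlines()
    assert lines[0].startswith("kind\tstep")
    assert len(lines) == 4
    tj.trajectory_intermediates_fasta(traj, tmp_path / "ints.fasta")
    seqs = sm.read_fasta(tmp_path / "ints.fasta")
    assert len(seqs) == 3


def test_with_measurements_attaches_by_step(rng):
    seq = random_seq(rng, 12)
    traj = tj.denovo_tune(seq, ConstantOracle(), "enhance", steps=2)
    withm = tj.with_measurements(traj, {0: 1.5, 2: 2.5})
    assert withm.steps[0].measured == 1.5
    assert withm.steps[1].measured is None
    assert withm.steps[2].measured == 2.5
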