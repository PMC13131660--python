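"""Sequence-to-accessibility scoring: oracle contract, surrogate, footprint.

Any object with a ``score(Sequence) -> float`` method and a ``name`` acts as
a scoring oracle. Production deployments plug in a trained accessibility
model through the batch file contract (:class:`ExternalOracle`: FASTA in,
two-column TSV out); tests and simulations use :class:`SurrogateOracle`, a
deterministic motif-gated activity function with a required heterotypic
module (AND gate) and saturating booster terms:

    score(s) = b0                                   if any required site absent
             = min(c_max, b0 + sum_h w_tf * a_h)    otherwise,

where the sum runs over called TFBS hits h with normalized affinity a_h and
per-TF booster weight w_tf. The marginal footprint embeds a candidate at the
center of background sequences and reports the mean embedded score
normalized by the background-only (null) score.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence as TypingSequence, runtime_checkable

import numpy as np
import yaml

from .errors import OracleError
from .motif import (
    MotifModel,
    NormalizationReference,
    TFBSHit,
    call_hits,
    compute_normalizer,
    merge_paralogs,
    scan,
)
from .seqmut import ALPHABET, Sequence, read_fasta, write_fasta


@runtime_checkable
class ScoringOracle(Protocol):
    """Contract: pure, deterministic sequence -> nonnegative score."""

    name: str

    def score(self, seq: Sequence) -> float: ...


@dataclass(frozen=True)
class SurrogateConfig:
    """Configuration of the motif-gated surrogate.

    ``required_modules`` lists (tf_label, min_norm_affinity) pairs that must
    ALL be satisfied by at least one called hit (post paralog merge) before
    any booster contributes — the heterotypic-module AND gate.
    ``booster_weights`` maps tf_label -> weight of each called hit's
    normalized affinity in the score sum.
    """

    booster_weights: Mapping[str, float]
    required_modules: tuple[tuple[str, float], ...] = ()
    b0: float = 0.1
    c_max: float = 8.0
    threshold: float = 0.05
    normalizer_n: int = 100_000
    normalizer_quantile: float = 0.9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise OracleError("baseline b0 must be >= 0")
        if self.c_max <= self.b0:
            raise OracleError("ceiling c_max must exceed baseline b0")
        if any(w < 0 for w in self.booster_weights.values()):
            raise OracleError("booster weights must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "booster_weights": dict(self.booster_weights),
            "required_modules": [list(t) for t in self.required_modules],
            "b0": self.b0,
            "c_max": self.c_max,
            "threshold": self.threshold,
            "normalizer_n": self.normalizer_n,
            "normalizer_quantile": self.normalizer_quantile,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurrogateConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["required_modules"] = tuple(
            (str(tf), float(a)) for tf, a in data.get("required_modules", [])
        )
        return cls(**data)


class SurrogateOracle:
    """Deterministic motif-gated accessibility surrogate.

    Normalization references for each motif are computed once at
    construction (seeded); scoring is then pure. ``paralog_groups`` maps
    tf_name -> merged label; gate and booster labels refer to post-merge
    labels.
    """

    def __init__(
        self,
        motifs: Mapping[str, MotifModel],
        config: SurrogateConfig,
        paralog_groups: Optional[Mapping[str, str]] = None,
        normalizers: Optional[Mapping[str, NormalizationReference]] = None,
    ):
        self.motifs = dict(motifs)
        self.config = config
        self.paralog_groups = dict(paralog_groups or {})
        if normalizers is None:
            normalizers = {
                tf: compute_normalizer(
                    m,
                    n=config.normalizer_n,
                    quantile=config.normalizer_quantile,
                    seed=config.seed,
                )
                for tf, m in self.motifs.items()
            }
        self.normalizers = dict(normalizers)
        self.name = "surrogate"

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "booster_weights": dict(self.config.booster_weights),
                "required_modules": list(self.config.required_modules),
                "b0": self.config.b0,
                "c_max": self.config.c_max,
                "threshold": self.config.threshold,
                "normalizers": {t: r.normalizer for t, r in sorted(self.normalizers.items())},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def merged_hits(self, seq: Sequence) -> list[TFBSHit]:
        """Called TFBS on ``seq`` after paralog merging."""
        per_tf = {
            tf: call_hits(scan(seq, m), self.normalizers[tf], self.config.threshold)
            for tf, m in self.motifs.items()
        }
        return merge_paralogs(per_tf, self.paralog_groups)

    def gate_open(self, hits: TypingSequence[TFBSHit]) -> bool:
        for tf, min_aff in self.config.required_modules:
            if not any(h.tf == tf and h.norm_affinity >= min_aff for h in hits):
                return False
        return True

    def score(self, seq: Sequence) -> float:
        hits = self.merged_hits(seq)
        if not self.gate_open(hits):
            return self.config.b0
        total = self.config.b0 + sum(
            self.config.booster_weights.get(h.tf, 0.0) * h.norm_affinity for h in hits
        )
        return min(self.config.c_max, total)


class AdditiveOracle:
    """Strictly additive, gate-free variant: b0 + sum of booster terms,
    no ceiling. Used to validate greedy-vs-sorted equivalence."""

    def __init__(self, surrogate: SurrogateOracle):
        self._s = surrogate
        self.name = "additive-surrogate"

    def score(self, seq: Sequence) -> float:
        hits = self._s.merged_hits(seq)
        return self._s.config.b0 + sum(
            self._s.config.booster_weights.get(h.tf, 0.0) * h.norm_affinity
            for h in hits
        )


class ExternalOracle:
    """Batch plug-in contract for external accessibility models.

    Runs ``command input.fasta output.tsv`` in a temp directory; the
    command must write a two-column TSV (id, score). Scores are cached per
    sequence content within the oracle's lifetime.
    """

    def __init__(self, command: list[str], name: str = "external"):
        self.command = list(command)
        self.name = name
        self._cache: dict[str, float] = {}

    def score_batch(self, seqs: TypingSequence[Sequence]) -> list[float]:
        missing = [s for s in seqs if s.residues not in self._cache]
        if missing:
            with tempfile.TemporaryDirectory() as tmp:
                fa = Path(tmp) / "input.fasta"
                out = Path(tmp) / "output.tsv"
                uniq = {s.residues: i for i, s in enumerate(missing)}
                write_fasta(
                    [Sequence(id=f"q{i}", residues=r) for r, i in uniq.items()], fa
                )
                try:
                    subprocess.run(
                        self.command + [str(fa), str(out)],
                        check=True, capture_output=True,
                    )
                except subprocess.CalledProcessError as exc:
                    raise OracleError(
                        f"external oracle failed: {exc.stderr.decode()[:500]}"
                    ) from exc
                scores = {}
                for line in out.read_text().splitlines():
                    sid, val = line.split("\t")
                    scores[sid] = float(val)
                for residues, i in uniq.items():
                    self._cache[residues] = scores[f"q{i}"]
        return [self._cache[s.residues] for s in seqs]

    def score(self, seq: Sequence) -> float:
        return self.score_batch([seq])[0]


def make_backgrounds(
    n: int, length: int, seed: int, gc: float = 0.5
) -> list[Sequence]:
    """Seeded i.i.d. (Markov-0) background sequences."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for i in range(n):
        idx = rng.choice(4, size=length, p=p)
        out.append(
            Sequence(id=f"bg{i:04d}", residues="".join(ALPHABET[j] for j in idx))
        )
    return out


def embed_center(candidate: Sequence, background: Sequence) -> Sequence:
    """Replace the central len(candidate) bases of the background."""
    L, l = len(background), len(candidate)
    if l > L:
        raise OracleError(
            f"candidate ({l} bp) longer than background ({L} bp)"
        )
    start = (L - l) // 2
    residues = (
        background.residues[:start] + candidate.residues + background.residues[start + l:]
    )
    return Sequence(id=f"{background.id}|{candidate.id}", residues=residues)


@dataclass(frozen=True)
class FootprintResult:
    mean_embedded: float
    null: float
    ratio: float


def marginal_footprint(
    oracle: ScoringOracle,
    candidate: Sequence,
    backgrounds: TypingSequence[Sequence],
    mode: str = "ratio_of_means",
) -> FootprintResult:
    """Marginal footprint of a candidate over background sequences.

    Each background is scored with the candidate replacing its center and
    alone (the null). ``ratio_of_means`` (default) divides the mean
    embedded score by the pooled mean null score; ``mean_of_ratios``
    averages per-background embedded/null ratios.
    """
    if not backgrounds:
        raise OracleError("need at least one background sequence")
    embedded = np.array([oracle.score(embed_center(candidate, bg)) for bg in backgrounds])
    nulls = np.array([oracle.score(bg) for bg in backgrounds])
    if mode == "ratio_of_means":
        null = float(nulls.mean())
        if null <= 0:
            raise OracleError("null score is zero; footprint undefined")
        ratio = float(embedded.mean()) / null
        return FootprintResult(float(embedded.mean()), null, ratio)
    if mode == "mean_of_ratios":
        if (nulls <= 0).any():
            raise OracleError("a background has zero null score")
        ratios = embedded / nulls
        return FootprintResult(float(embedded.mean()), float(nulls.mean()), float(ratios.mean()))
    raise OracleError(f"unknown footprint mode {mode!r}")
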