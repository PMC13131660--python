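"""PSAM-based TFBS affinity scanning and hit calling.

A position-specific affinity matrix (PSAM) assigns each base at each motif
position a nonnegative relative affinity; the raw affinity of a k-mer is the
product over positions of the observed base's weight. At load, each position
row is max-normalized to 1 so the consensus k-mer scores 1 before
normalization. Raw affinities are made comparable across TFs by dividing by
a normalizer: by default the q99.99 quantile of raw affinities over one
million uniformly random k-mers (an exhaustive enumeration over all 4^k
k-mers is available for small k). Sites are called where the normalized
affinity strictly exceeds a threshold (default 0.05), with strand assigned
forward when the forward-orientation affinity is greater than or equal to
the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import MotifError
from .seqmut import ALPHABET, GAP_SENTINEL, Sequence, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: sentinel fold change for a site deleted in one of the two sequences
LOST = "lost"


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class MotifModel:
    """A PSAM: ``weights[i, j]`` is the relative affinity of base j
    (ACGT order) at motif position i. Rows are max-normalized to 1."""

    tf_name: str
    weights: np.ndarray
    paralog_group: Optional[str] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4:
            raise MotifError(f"{self.tf_name}: weights must be k x 4")
        if (w < 0).any():
            raise MotifError(f"{self.tf_name}: negative affinity weight")
        rowmax = w.max(axis=1)
        if (rowmax <= 0).any():
            raise MotifError(f"{self.tf_name}: position with no positive weight")
        object.__setattr__(self, "weights", w / rowmax[:, None])

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.weights.argmax(axis=1))


def score_kmer(motif: MotifModel, kmer: str) -> float:
    """Raw affinity of a single k-mer: product of per-position weights."""
    if len(kmer) != motif.k:
        raise MotifError(
            f"k-mer length {len(kmer)} != motif width {motif.k} for {motif.tf_name}"
        )
    idx = _encode(kmer)
    return float(np.prod(motif.weights[np.arange(motif.k), idx]))


def _scan_forward(encoded: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Raw affinities for every window start (vectorized product)."""
    k = weights.shape[0]
    L = encoded.size
    n = L - k + 1
    if n <= 0:
        return np.empty(0)
    # windows[i, p] = encoded[i + p]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, k)
    per_pos = weights[np.arange(k)[None, :], windows]
    return per_pos.prod(axis=1)


@dataclass(frozen=True)
class AffinityProfile:
    """Per-start raw affinities of one motif over one sequence, both strands.

    ``rev[i]`` is the raw affinity of the reverse complement of the window
    starting at i (i.e. the motif on the minus strand at that window).
    """

    sequence_id: str
    tf_name: str
    k: int
    fwd: np.ndarray
    rev: np.ndarray

    def __len__(self) -> int:
        return self.fwd.size


def scan(seq: Sequence, motif: MotifModel) -> AffinityProfile:
    """Slide the motif over every window of ``seq`` in both orientations."""
    if len(seq) < motif.k:
        import warnings

        warnings.warn(
            f"sequence {seq.id} shorter than motif {motif.tf_name} "
            f"({len(seq)} < {motif.k}); empty profile"
        )
        return AffinityProfile(seq.id, motif.tf_name, motif.k, np.empty(0), np.empty(0))
    enc = _encode(seq.residues)
    fwd = _scan_forward(enc, motif.weights)
    enc_rc = _encode(revcomp(seq.residues))
    rev = _scan_forward(enc_rc, motif.weights)[::-1].copy()
    return AffinityProfile(seq.id, motif.tf_name, motif.k, fwd, rev)


@dataclass(frozen=True)
class NormalizationReference:
    """Normalization constant for one TF's raw affinities."""

    tf_name: str
    normalizer: float
    n_samples: int
    quantile: float
    seed: int
    method: str = "quantile"

    def __post_init__(self) -> None:
        if self.normalizer <= 0:
            raise MotifError(f"{self.tf_name}: normalizer must be positive")


def compute_normalizer(
    motif: MotifModel,
    n: int = 1_000_000,
    quantile: float = 0.9999,
    seed: int = 0,
    method: str = "quantile",
) -> NormalizationReference:
    """Estimate the affinity normalizer from uniformly random k-mers.

    ``method="quantile"`` (default) takes the given quantile of the raw
    affinities over ``n`` random k-mers; ``method="max"`` takes their
    maximum. Deterministic under a fixed seed.
    """
    if n < 1 or not (0 < quantile < 1):
        raise MotifError("need n >= 1 and 0 < quantile < 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=(n, motif.k))
    scores = motif.weights[np.arange(motif.k)[None, :], idx].prod(axis=1)
    if scores.max() <= 0:
        raise MotifError(f"{motif.tf_name}: all sampled affinities are zero")
    if method == "quantile":
        norm = float(np.quantile(scores, quantile))
    elif method == "max":
        norm = float(scores.max())
    else:
        raise MotifError(f"unknown normalization method {method!r}")
    if norm <= 0:
        # extremely sparse motifs: fall back to the max so the reference is usable
        norm = float(scores.max())
    return NormalizationReference(motif.tf_name, norm, n, quantile, seed, method)


def exhaustive_normalizer(motif: MotifModel, quantile: float = 0.9999) -> float:
    """Exact quantile of raw affinity over all 4^k k-mers (small k only).

    Uses the inverse-CDF definition (smallest value whose cumulative
    probability reaches the quantile), which is what the sampled estimator
    converges to; interpolated definitions disagree in the extreme tail
    where the affinity distribution has large atoms (consensus k-mers).
    """
    k = motif.k
    if 4**k > 4**9:
        raise MotifError("exhaustive enumeration limited to k <= 9")
    grids = np.indices((4,) * k).reshape(k, -1).T
    scores = motif.weights[np.arange(k)[None, :], grids].prod(axis=1)
    return float(np.quantile(scores, quantile, method="inverted_cdf"))


@dataclass(frozen=True)
class TFBSHit:
    """A called binding site with strand and normalized affinity."""

    tf: str
    sequence_id: str
    start: int
    width: int
    strand: str
    norm_affinity: float

    @property
    def end(self) -> int:
        return self.start + self.width


def call_hits(
    profile: AffinityProfile,
    normref: NormalizationReference,
    threshold: float = 0.05,
) -> list[TFBSHit]:
    """Call TFBS where normalized affinity strictly exceeds ``threshold``.

    Strand is forward iff fwd >= rev (ties forward); the reported affinity
    is the higher of the two orientations divided by the normalizer.
    """
    if profile.tf_name != normref.tf_name:
        raise MotifError(
            f"profile TF {profile.tf_name!r} != normalizer TF {normref.tf_name!r}"
        )
    fwd = profile.fwd / normref.normalizer
    rev = profile.rev / normref.normalizer
    best = np.maximum(fwd, rev)
    hits: list[TFBSHit] = []
    for i in np.nonzero(best > threshold)[0]:
        strand = "+" if fwd[i] >= rev[i] else "-"
        hits.append(
            TFBSHit(
                tf=profile.tf_name,
                sequence_id=profile.sequence_id,
                start=int(i),
                width=profile.k,
                strand=strand,
                norm_affinity=float(best[i]),
            )
        )
    return hits


def merge_paralogs(
    hits_by_tf: Mapping[str, list[TFBSHit]],
    groups: Mapping[str, str],
) -> list[TFBSHit]:
    """Merge paralogous TFs' hits, keeping the maximal normalized affinity.

    ``groups`` maps tf_name -> group label (e.g. Gata4 and Gata6 ->
    "Gata4/6"); TFs absent from ``groups`` keep their own name. At each
    (sequence, start), grouped TFs contribute one hit labeled with the
    group, carrying the maximum affinity; strand follows the winning TF.
    """
    best: dict[tuple[str, str, int], TFBSHit] = {}
    for tf, hits in sorted(hits_by_tf.items()):
        label = groups.get(tf, tf)
        for h in hits:
            key = (label, h.sequence_id, h.start)
            cur = best.get(key)
            if cur is None or h.norm_affinity > cur.norm_affinity:
                best[key] = TFBSHit(
                    tf=label,
                    sequence_id=h.sequence_id,
                    start=h.start,
                    width=h.width,
                    strand=h.strand,
                    norm_affinity=h.norm_affinity,
                )
    return sorted(best.values(), key=lambda h: (h.sequence_id, h.start, h.tf))


def overlap_with_reference(
    hits: Iterable[TFBSHit],
    reference_sites: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Assign hits to reference functional sites by interval overlap.

    Hits and reference sites must share a coordinate system (typically MSA
    columns). A hit is assigned to the site with which it shares at least
    one position; with several overlapping sites the largest overlap wins
    (leftmost site on ties). Unassigned hits are labeled ``novel``.
    Returns a table (tf, start, end, strand, norm_affinity, assigned_site).
    """
    rows = []
    for h in hits:
        best_site, best_ov = "novel", 0
        for name, (s0, s1) in reference_sites.items():
            ov = min(h.end, s1) - max(h.start, s0)
            if ov > best_ov:
                best_site, best_ov = name, ov
        rows.append(
            {
                "tf": h.tf, "sequence_id": h.sequence_id, "start": h.start,
                "end": h.end, "strand": h.strand,
                "norm_affinity": h.norm_affinity, "assigned_site": best_site,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tf", "sequence_id", "start", "end", "strand",
            "norm_affinity", "assigned_site",
        ],
    )


def best_affinity_in_window(
    seq: Sequence,
    motif: MotifModel,
    normref: NormalizationReference,
    window: tuple[int, int],
) -> float:
    """Maximal normalized affinity of windows overlapping ``[start, end)``.

    A motif placement counts if its k-mer overlaps the window by at least
    one base. Returns 0.0 if the sequence is shorter than the motif or no
    placement overlaps.
    """
    prof = scan(seq, motif)
    if len(prof) == 0:
        return 0.0
    start, end = window
    lo = max(0, start - motif.k + 1)
    hi = min(len(prof), end)
    if hi <= lo:
        return 0.0
    best = np.maximum(prof.fwd[lo:hi], prof.rev[lo:hi]).max()
    return float(best / normref.normalizer)


def affinity_fold_change(
    seq_a: Sequence,
    seq_b: Sequence,
    site: tuple[int, int],
    motif: MotifModel,
    normref: NormalizationReference,
    pos_map_a: Optional[Mapping[int, int]] = None,
    pos_map_b: Optional[Mapping[int, int]] = None,
):
    """Fold change of a site's best normalized affinity in ``b`` vs ``a``.

    ``site`` is an interval on a shared coordinate system (MSA columns when
    the ``pos_map`` arguments translate columns to each sequence's
    positions, else direct sequence coordinates). Values > 1 are fold
    gains, < 1 fold losses. If the site is deleted in either sequence the
    sentinel :data:`LOST` is returned; if the ancestral affinity is zero
    but the derived is not, ``inf`` is returned.
    """

    def mapped(site_, pmap, seq):
        if pmap is None:
            return site_
        cols = [pmap[c] for c in range(site_[0], site_[1]) if c in pmap]
        if not cols:
            return None
        return (min(cols), max(cols) + 1)

    wa = mapped(site, pos_map_a, seq_a)
    wb = mapped(site, pos_map_b, seq_b)
    if wa is None or wb is None:
        return LOST
    aff_a = best_affinity_in_window(seq_a, motif, normref, wa)
    aff_b = best_affinity_in_window(seq_b, motif, normref, wb)
    if aff_a == 0.0:
        return float("inf") if aff_b > 0 else 1.0
    return aff_b / aff_a


# ---------------------------------------------------------------------------
# PSAM / hit / normalizer serialization

def read_psams(path: str | Path) -> dict[str, MotifModel]:
    """Read PSAMs from TSV with columns (tf, position, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"tf", "position", "A", "C", "G", "T"}
    if not needed.issubset(df.columns):
        raise MotifError(f"PSAM TSV must have columns {sorted(needed)}")
    out = {}
    group_col = "paralog_group" if "paralog_group" in df.columns else None
    for tf, sub in df.groupby("tf", sort=True):
        sub = sub.sort_values("position")
        weights = sub[["A", "C", "G", "T"]].to_numpy(dtype=float)
        group = None
        if group_col:
            vals = sub[group_col].dropna().unique()
            group = str(vals[0]) if len(vals) else None
        out[str(tf)] = MotifModel(tf_name=str(tf), weights=weights, paralog_group=group)
    return out


def write_psams(motifs: Iterable[MotifModel], path: str | Path) -> None:
    rows = []
    for m in motifs:
        for pos in range(m.k):
            row = {"tf": m.tf_name, "position": pos}
            row.update({b: m.weights[pos, j] for j, b in enumerate(ALPHABET)})
            if m.paralog_group:
                row["paralog_group"] = m.paralog_group
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hits_to_bed(hits: Iterable[TFBSHit], path: str | Path) -> None:
    """Write hits as BED-like TSV (seq_id, start, end, tf, norm_affinity, strand)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.sequence_id, h.start, h.tf)):
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.tf}\t"
                f"{h.norm_affinity:.6g}\t{h.strand}\n"
            )


def normalizers_to_tsv(refs: Iterable[NormalizationReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tnormalizer\tn\tquantile\tseed\tmethod\n")
        for r in refs:
            fh.write(
                f"{r.tf_name}\t{r.normalizer:.10g}\t{r.n_samples}\t"
                f"{r.quantile}\t{r.seed}\t{r.method}\n"
            )


def normalizers_from_tsv(path: str | Path) -> dict[str, NormalizationReference]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.tf): NormalizationReference(
            str(r.tf), float(r.normalizer), int(r.n), float(r.quantile),
            int(r.seed), str(r.method),
        )
        for r in df.itertuples()
    }
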