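"""Barcode-level MPRA quantification.

Each reporter element is represented by many barcodes; per replicate, each
barcode's RNA and DNA UMI counts are normalized by their sample totals and
the element's activity is the ratio of (within-element winsorized) summed
normalized RNA to summed normalized DNA. Replicate-level activities are
summarized as mean and standard error; activities are reported both
absolutely and as fold change over negative controls (e.g. minimal-promoter
constructs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .errors import MPRAError

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Long-form UMI counts: one row per (barcode, replicate, molecule).

    ``molecule`` is "DNA" or "RNA"; counts are nonnegative integers.
    """

    df: pd.DataFrame

    REQUIRED = ("barcode", "replicate", "molecule", "umi_count")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise MPRAError(f"count table missing columns {sorted(missing)}")
        counts = self.df["umi_count"]
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise MPRAError("umi_count must be nonnegative integers")
        bad = set(self.df["molecule"].unique()) - {"DNA", "RNA"}
        if bad:
            raise MPRAError(f"unknown molecule labels {sorted(bad)}")
        dup = self.df.duplicated(["barcode", "replicate", "molecule"])
        if dup.any():
            raise MPRAError("duplicate (barcode, replicate, molecule) rows")

    @property
    def replicates(self) -> list:
        return sorted(self.df["replicate"].unique())

    def sample(self, replicate, molecule: str) -> pd.Series:
        sub = self.df[(self.df["replicate"] == replicate) & (self.df["molecule"] == molecule)]
        return sub.set_index("barcode")["umi_count"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "CountTable":
        """Wide matrix alternative: index barcode, columns '<rep>:<mol>'."""
        rows = []
        for col in wide.columns:
            rep, mol = str(col).rsplit(":", 1)
            for bc, v in wide[col].items():
                rows.append((bc, rep, mol, int(v)))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))


@dataclass
class BarcodeMap:
    """barcode -> element assignment with subassembly read support."""

    df: pd.DataFrame  # columns: barcode, element, reads

    def __post_init__(self) -> None:
        missing = {"barcode", "element", "reads"} - set(self.df.columns)
        if missing:
            raise MPRAError(f"barcode map missing columns {sorted(missing)}")
        if self.df["barcode"].duplicated().any():
            raise MPRAError("a barcode maps to more than one element")

    def element_of(self) -> pd.Series:
        return self.df.set_index("barcode")["element"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def filter_barcodes(bmap: BarcodeMap, min_reads: int = 2) -> BarcodeMap:
    """Drop barcodes with subassembly read support below ``min_reads``."""
    if min_reads < 0:
        raise MPRAError("min_reads must be >= 0")
    keep = bmap.df["reads"] >= min_reads
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_barcodes: removed %d low-abundance barcodes", n_removed)
    if keep.sum() == 0:
        warnings.warn("all barcodes removed by read-count filter")
    return BarcodeMap(bmap.df[keep].reset_index(drop=True))


def barcode_expression(table: CountTable, replicate) -> pd.Series:
    """Per-barcode normalized RNA/DNA ratio for one replicate.

    Each barcode's count is first normalized by its sample total (RNA and
    DNA separately); the expression estimate is the ratio of the normalized
    counts. Barcodes with zero DNA are excluded.
    """
    dna = table.sample(replicate, "DNA")
    rna = table.sample(replicate, "RNA")
    if dna.sum() <= 0 or rna.sum() <= 0:
        raise MPRAError(f"replicate {replicate!r}: zero total DNA or RNA")
    barcodes = dna.index.intersection(rna.index)
    dna, rna = dna.loc[barcodes], rna.loc[barcodes]
    covered = dna > 0
    norm_rna = rna[covered] / rna.sum()
    norm_dna = dna[covered] / dna.sum()
    return norm_rna / norm_dna


def winsorize(values: np.ndarray, frac: float) -> np.ndarray:
    """Clip values at the [frac, 1-frac] quantiles (linear interpolation)."""
    if frac == 0 or values.size == 0:
        return values.astype(float)
    lo, hi = np.quantile(values, [frac, 1 - frac])
    return np.clip(values.astype(float), lo, hi)


@dataclass(frozen=True)
class ElementActivity:
    """Per-element activity across replicates."""

    element: str
    per_replicate: tuple[float, ...]
    mu: float
    sigma: Optional[float]  # standard error; None for a single replicate
    n_barcodes: int


def element_activity_one(
    table: CountTable,
    bmap: BarcodeMap,
    replicate,
    winsor_frac: float = 0.01,
    method: str = "sum_ratio",
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-element activity for one replicate.

    ``method="sum_ratio"`` (default): within each element, winsorize the
    barcodes' normalized RNA and normalized DNA values at
    [winsor_frac, 1 - winsor_frac], sum each, and report the ratio of sums
    — the winsorized summed-RNA-over-DNA estimator. With ``winsor_frac=0``
    this is the plain summed-ratio estimator.
    ``method="ratio_mean"``: winsorize the per-barcode RNA/DNA ratios and
    report their mean. Elements with zero summed DNA get NaN.
    """
    if not (0 <= winsor_frac < 0.5):
        raise MPRAError("winsor_frac must be in [0, 0.5)")
    dna = table.sample(replicate, "DNA").astype(float) + pseudocount
    rna = table.sample(replicate, "RNA").astype(float) + pseudocount
    if dna.sum() <= 0 or rna.sum() <= 0:
        raise MPRAError(f"replicate {replicate!r}: zero total DNA or RNA")
    barcodes = dna.index.intersection(rna.index)
    dna, rna = dna.loc[barcodes], rna.loc[barcodes]
    norm_dna = dna / dna.sum()
    norm_rna = rna / rna.sum()
    element_of = bmap.element_of()
    common = barcodes.intersection(element_of.index)
    groups = element_of.loc[common]
    out = {}
    for element, bcs in groups.groupby(groups).groups.items():
        nd = norm_dna.loc[bcs].to_numpy()
        nr = norm_rna.loc[bcs].to_numpy()
        covered = nd > 0
        if method == "sum_ratio":
            wd = winsorize(nd[covered], winsor_frac)
            wr = winsorize(nr[covered], winsor_frac)
            out[element] = float(wr.sum() / wd.sum()) if wd.sum() > 0 else float("nan")
        elif method == "ratio_mean":
            if covered.sum() == 0:
                out[element] = float("nan")
            else:
                ratios = winsorize(nr[covered] / nd[covered], winsor_frac)
                out[element] = float(ratios.mean())
        else:
            raise MPRAError(f"unknown method {method!r}")
    return pd.Series(out).sort_index()


def element_activity(
    table: CountTable,
    bmap: BarcodeMap,
    winsor_frac: float = 0.01,
    method: str = "sum_ratio",
    pseudocount: float = 0.0,
) -> dict[str, ElementActivity]:
    """Activity per element across all replicates (mean and standard error)."""
    per_rep = {
        rep: element_activity_one(table, bmap, rep, winsor_frac, method, pseudocount)
        for rep in table.replicates
    }
    n_bc = bmap.df.groupby("element")["barcode"].count()
    elements = sorted(set().union(*[set(s.index) for s in per_rep.values()]))
    out = {}
    for el in elements:
        vals = [per_rep[rep].get(el, float("nan")) for rep in table.replicates]
        vals = [v for v in vals if not np.isnan(v)]
        mu, sigma = replicate_stats(vals)
        out[el] = ElementActivity(
            element=el, per_replicate=tuple(vals), mu=mu, sigma=sigma,
            n_barcodes=int(n_bc.get(el, 0)),
        )
    return out


def replicate_stats(values: TypingSequence[float]) -> tuple[float, Optional[float]]:
    """Mean and standard error across replicates (sigma None if n < 2)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), None
    mu = float(arr.mean())
    if arr.size < 2:
        return mu, None
    return mu, float(arr.std(ddof=1) / np.sqrt(arr.size))


def fold_vs_controls(
    activities: Mapping[str, ElementActivity],
    negatives: TypingSequence[str],
) -> pd.DataFrame:
    """Per-element fold change (and log2) over the negative-control mean."""
    if not negatives:
        raise MPRAError("need at least one negative-control element")
    neg = [activities[n].mu for n in negatives if n in activities]
    if not neg:
        raise MPRAError("no negative-control element has a defined activity")
    neg_mean = float(np.mean(neg))
    if neg_mean <= 0:
        raise MPRAError("negative-control mean activity is zero")
    rows = []
    for el in sorted(activities):
        a = activities[el]
        fold = a.mu / neg_mean
        rows.append(
            {
                "element": el, "mu": a.mu,
                "sigma": float("nan") if a.sigma is None else a.sigma,
                "n_barcodes": a.n_barcodes, "fold_vs_neg": fold,
                "log2_fold_vs_neg": np.log2(fold) if fold > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    table: CountTable,
    bmap: BarcodeMap,
    element: str,
    replicate,
    n_boot: int = 200,
    winsor_frac: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI over an element's barcodes (convenience only;
    not a differential-activity test)."""
    rng = np.random.default_rng(seed)
    element_of = bmap.element_of()
    bcs = element_of[element_of == element].index
    dna = table.sample(replicate, "DNA").astype(float)
    rna = table.sample(replicate, "RNA").astype(float)
    bcs = bcs.intersection(dna.index).intersection(rna.index)
    if len(bcs) == 0:
        raise MPRAError(f"element {element!r} has no barcodes in replicate {replicate!r}")
    nd = (dna.loc[bcs] / dna.sum()).to_numpy()
    nr = (rna.loc[bcs] / rna.sum()).to_numpy()
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(bcs), size=len(bcs))
        wd = winsorize(nd[idx], winsor_frac)
        wr = winsorize(nr[idx], winsor_frac)
        if wd.sum() > 0:
            stats.append(wr.sum() / wd.sum())
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def activities_to_tsv(
    activities: Mapping[str, ElementActivity], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("element\tmu\tsigma\tn_replicates\tn_barcodes\tper_replicate\n")
        for el in sorted(activities):
            a = activities[el]
            sig = "NA" if a.sigma is None else f"{a.sigma:.6g}"
            per = ",".join(f"{v:.6g}" for v in a.per_replicate)
            fh.write(
                f"{a.element}\t{a.mu:.6g}\t{sig}\t{len(a.per_replicate)}\t"
                f"{a.n_barcodes}\t{per}\n"
            )
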