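"""Sort-seq read processing and enrichment scoring.

A displayed variant library is sorted by FACS into an unsorted reference
population ``u``, a display-only population ``d`` and an IgG-binding
population ``b`` (optionally low/wt-like/high binding bins ``l``/``w``/``h``),
and each population is sequenced.  Per-design proportions ``p_{x,i}``
(design count divided by the population's total reads) yield log10
enrichment scores, each normalized so the wild type scores exactly zero:

* binding:  ``e_bind,i = log10(p_b,i / p_d,i) - log10(p_b,wt / p_d,wt)``
* display:  ``e_disp,i = log10((w_b p_b,i + w_d p_d,i) / p_u,i) - (wt term)``
* any bin:  ``e_x,i    = log10(p_x,i / p_u,i) - log10(p_x,wt / p_u,wt)``

``(w_b, w_d)`` are the relative sizes of the binding and display-only
populations in the sorting experiment (defaults 0.6/0.4); they are
experiment-specific configuration, not constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.optimize import curve_fit

POPULATIONS = ("u", "d", "b", "l", "w", "h")


@dataclass
class SortSeqCounts:
    """Per-design read counts per sorted population.

    ``frame`` is indexed by design id with columns ``count_u``, ``count_d``,
    ``count_b`` and optionally ``count_l``/``count_w``/``count_h``.
    """

    frame: pd.DataFrame
    wt_id: str
    w_b: float = 0.6
    w_d: float = 0.4

    def __post_init__(self) -> None:
        required = {"count_u", "count_d", "count_b"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing count columns: {sorted(missing)}")
        if (self.frame[list(self.frame.columns)] < 0).any().any():
            raise ValueError("counts must be non-negative")
        if self.wt_id not in self.frame.index:
            raise ValueError(f"wild-type id {self.wt_id!r} not present")
        if abs(self.w_b + self.w_d - 1.0) > 1e-9:
            raise ValueError("w_b + w_d must equal 1")

    @property
    def totals(self) -> pd.Series:
        return self.frame.sum(axis=0)

    def has_population(self, pop: str) -> bool:
        return f"count_{pop}" in self.frame.columns

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, wt_id: str, **kwargs) -> "SortSeqCounts":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame, wt_id, **kwargs)


@dataclass
class EnrichmentTable:
    """Per-design log10 enrichment scores, wild-type normalized.

    ``frame`` carries ``e_bind``, ``e_disp``, a boolean ``pseudocount``
    column flagging designs rescued from zero counts, and optionally
    per-bin ``e_l``/``e_w``/``e_h`` columns.
    """

    frame: pd.DataFrame
    wt_id: str

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Read processing
# ---------------------------------------------------------------------------

def _as_phred(quals: str | Sequence[int]) -> np.ndarray:
    if isinstance(quals, str):
        return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(int) - 33
    return np.asarray(quals, dtype=int)


def merge_read_pair(
    fwd: str,
    fwd_qual: str | Sequence[int],
    rev: str,
    rev_qual: str | Sequence[int],
    offset: int,
) -> str:
    """Merge a forward read with an (already reverse-complemented) reverse read.

    ``offset`` is the 0-based position of the reverse read's first base on
    the merged coordinate system (a predetermined alignment offset).  Bases
    outside the overlap are copied verbatim; inside the overlap the base
    with the higher Phred quality wins, with ties going to the forward read.
    """
    if offset < 0 or offset > len(fwd):
        raise ValueError(
            f"offset {offset} leaves a gap or negative overlap beyond read lengths"
        )
    fq = _as_phred(fwd_qual)
    rq = _as_phred(rev_qual)
    if len(fq) != len(fwd) or len(rq) != len(rev):
        raise ValueError("quality length does not match read length")
    merged_len = max(len(fwd), offset + len(rev))
    out = []
    for pos in range(merged_len):
        in_fwd = pos < len(fwd)
        j = pos - offset
        in_rev = 0 <= j < len(rev)
        if in_fwd and in_rev:
            out.append(rev[j] if rq[j] > fq[pos] else fwd[pos])
        elif in_fwd:
            out.append(fwd[pos])
        else:
            out.append(rev[j])
    return "".join(out)


def merge_fastq_pair(
    fwd_path: str | Path, rev_path: str | Path, offset: int
) -> list[str]:
    """Merge paired FASTQ files; reverse reads are reverse-complemented first."""
    merged = []
    for f, r in zip(
        SeqIO.parse(str(fwd_path), "fastq"), SeqIO.parse(str(rev_path), "fastq")
    ):
        rseq = str(Seq(str(r.seq)).reverse_complement())
        rqual = list(reversed(r.letter_annotations["phred_quality"]))
        merged.append(
            merge_read_pair(
                str(f.seq), f.letter_annotations["phred_quality"], rseq, rqual, offset
            )
        )
    return merged


def count_exact_matches(
    reads: Iterable[str], design_library: Mapping[str, str]
) -> tuple[pd.Series, int]:
    """Count reads exactly matching each design's nucleotide sequence.

    Only exact string equality counts (no fuzzy matching); reads matching no
    design are tallied as unassigned.  Synonymous controls must be distinct
    ids with distinct nucleotide sequences.
    """
    seq_to_id: dict[str, str] = {}
    for design_id, seq in design_library.items():
        if seq in seq_to_id:
            raise ValueError(
                f"designs {seq_to_id[seq]!r} and {design_id!r} share a nucleotide sequence"
            )
        seq_to_id[seq] = design_id
    tally = Counter()
    unassigned = 0
    for read in reads:
        design_id = seq_to_id.get(read)
        if design_id is None:
            unassigned += 1
        else:
            tally[design_id] += 1
    counts = pd.Series(
        {design_id: tally.get(design_id, 0) for design_id in design_library},
        dtype=np.int64,
    )
    return counts, unassigned


def filter_min_count(counts: SortSeqCounts, min_count: int = 10) -> SortSeqCounts:
    """Drop designs with fewer than ``min_count`` unsorted reads.

    The wild type is the normalization anchor and may never be dropped; a
    wild type below threshold is a hard error.
    """
    keep = counts.frame["count_u"] >= min_count
    if not keep.loc[counts.wt_id]:
        raise ValueError(
            f"wild type {counts.wt_id!r} has fewer than {min_count} unsorted reads"
        )
    return replace(counts, frame=counts.frame[keep].copy())


# ---------------------------------------------------------------------------
# Enrichment scores
# ---------------------------------------------------------------------------

def _rescue_zero_pairs(frame: pd.DataFrame, num: str, den: str) -> pd.Series:
    """+1 pseudocount to *both* columns of a design whose pair has a zero.

    Applied in place; returns the boolean rescue flag.  Adding the
    pseudocount to numerator and paired denominator together keeps scores
    finite without moving the wild-type normalization when the wild type
    itself has nonzero counts.
    """
    flag = (frame[num] == 0) | (frame[den] == 0)
    frame.loc[flag, num] += 1
    frame.loc[flag, den] += 1
    return flag


def enrichment_scores(counts: SortSeqCounts) -> EnrichmentTable:
    """Binding and display enrichment scores for every design.

    Designs with a zero count in the binding or display-only population get
    a +1 pseudocount in both (flagged); proportions are recomputed from the
    adjusted columns.  Wild-type scores are exactly zero by construction.
    """
    frame = counts.frame[["count_u", "count_d", "count_b"]].astype(np.int64).copy()
    if frame.loc[counts.wt_id, ["count_u", "count_d", "count_b"]].eq(0).any():
        raise ValueError("wild type must have nonzero counts in u, d and b")
    flag = _rescue_zero_pairs(frame, "count_b", "count_d")
    p = frame / frame.sum(axis=0)
    pu, pd_, pb = p["count_u"], p["count_d"], p["count_b"]
    wt = counts.wt_id
    e_bind = np.log10(pb / pd_) - np.log10(pb[wt] / pd_[wt])
    disp_num = counts.w_b * pb + counts.w_d * pd_
    e_disp = np.log10(disp_num / pu) - np.log10(disp_num[wt] / pu[wt])
    out = pd.DataFrame(
        {"e_bind": e_bind, "e_disp": e_disp, "pseudocount": flag},
        index=counts.frame.index,
    )
    return EnrichmentTable(out, wt)


def population_enrichment(counts: SortSeqCounts, population: str) -> pd.Series:
    """Enrichment of each design in one sorted population vs unsorted.

    ``e_x,i = log10(p_x,i / p_u,i) - log10(p_x,wt / p_u,wt)`` for
    ``x`` in l/w/h/d/b.  Zero counts in ``x`` or ``u`` for a design are
    rescued with a paired +1 pseudocount.
    """
    if population not in POPULATIONS[1:]:
        raise ValueError(f"unknown population {population!r}")
    col = f"count_{population}"
    if col not in counts.frame.columns:
        raise ValueError(f"population {population!r} not present")
    frame = counts.frame[["count_u", col]].astype(np.int64).copy()
    wt = counts.wt_id
    if frame.loc[wt].eq(0).any():
        raise ValueError(f"wild type must have nonzero counts in u and {population}")
    _rescue_zero_pairs(frame, col, "count_u")
    p = frame / frame.sum(axis=0)
    e_x = np.log10(p[col] / p["count_u"]) - np.log10(
        p.loc[wt, col] / p.loc[wt, "count_u"]
    )
    return e_x.rename(f"e_{population}")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def derive_threshold(
    negative_scores: Sequence[float], positive_scores: Sequence[float]
) -> float:
    """Decision boundary halfway between two calibration groups' means."""
    return float((np.mean(negative_scores) + np.mean(positive_scores)) / 2.0)


def classify_designs(
    table: EnrichmentTable,
    display_threshold: float | None = None,
    bind_threshold: float | None = None,
    calibration: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Quadrant call (displays/not x binds/not) from (e_disp, e_bind).

    Thresholds may be given directly or derived from ``calibration``, a
    frame with columns ``design_id``, ``displays`` and ``binds`` naming
    designs of known phenotype: each threshold is the midpoint between the
    negative and positive calibration groups' mean scores.  A score greater
    than or equal to its threshold counts as positive.
    """
    scores = table.frame
    if display_threshold is None or bind_threshold is None:
        if calibration is None:
            raise ValueError("supply thresholds or calibration records")
        cal = calibration.set_index("design_id")
        joined = cal.join(scores[["e_bind", "e_disp"]], how="inner")
        if display_threshold is None:
            display_threshold = derive_threshold(
                joined.loc[~joined["displays"], "e_disp"],
                joined.loc[joined["displays"], "e_disp"],
            )
        if bind_threshold is None:
            bind_threshold = derive_threshold(
                joined.loc[~joined["binds"], "e_bind"],
                joined.loc[joined["binds"], "e_bind"],
            )
    displays = scores["e_disp"] >= display_threshold
    binds = scores["e_bind"] >= bind_threshold
    category = np.select(
        [displays & binds, displays & ~binds, ~displays & binds],
        ["bind+display", "display-only", "bind-no-display"],
        default="inactive",
    )
    return pd.DataFrame(
        {"displays": displays, "binds": binds, "category": category},
        index=scores.index,
    )


def classify_bins(
    scores: pd.Series,
    calibration_scores: Mapping[str, Sequence[float]],
    bin_order: Sequence[str] = ("display_only", "low_bind", "wt_like", "high_bind"),
) -> pd.Series:
    """Assign each design to an ordered bin from a scalar enrichment score.

    Boundaries are the midpoints between the mean calibration score of each
    adjacent pair of bins (bins ordered from weakest to strongest).
    """
    means = [float(np.mean(calibration_scores[b])) for b in bin_order]
    if any(b <= a for a, b in zip(means, means[1:])):
        raise ValueError("calibration group means must increase with bin order")
    boundaries = [(a + b) / 2.0 for a, b in zip(means, means[1:])]
    idx = np.searchsorted(boundaries, scores.to_numpy(), side="right")
    return pd.Series(
        [bin_order[i] for i in idx], index=scores.index, name="bin"
    )


# ---------------------------------------------------------------------------
# Titration fitting
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    """Saturation-binding fit ``s = Bmax * c / (KD + c)`` (Hill coefficient 1)."""

    kd: float
    bmax: float
    residual_norm: float
    kd_defined: bool = True


def fit_hill(concentrations: Sequence[float], signals: Sequence[float]) -> HillFit:
    """Least-squares fit of a one-site binding isotherm.

    With all-zero signals the fit degenerates: Bmax is 0 and KD is reported
    as NaN with ``kd_defined=False``.
    """
    c = np.asarray(concentrations, dtype=np.float64)
    s = np.asarray(signals, dtype=np.float64)
    if len(c) < 3:
        raise ValueError("need at least 3 concentration points")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")
    if np.all(s == 0):
        return HillFit(kd=np.nan, bmax=0.0, residual_norm=0.0, kd_defined=False)

    def isotherm(conc, bmax, kd):
        return bmax * conc / (kd + conc)

    p0 = (float(s.max()), float(np.median(c[c > 0])) if np.any(c > 0) else 1.0)
    popt, _ = curve_fit(
        isotherm, c, s, p0=p0, bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20_000
    )
    resid = s - isotherm(c, *popt)
    return HillFit(
        kd=float(popt[1]),
        bmax=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)),
    )
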