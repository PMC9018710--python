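"""The 5' end definition score: windowed cleavage-site competition along clusters.

For each transcript position x, the score is

    s(x) = f(x) / sum_{i = x-10}^{x+20} f(i)

where f(x) counts read 5' ends at x (or, in the 3' variant, positions
immediately downstream of read 3' ends). The window is transcript-oriented
and includes x itself (31 positions by default); positions with at least
``min_local_reads`` reads in the window are "covered" and feed the downstream
statistics. Covered positions split into bin 0 (s = 0) plus ``n_bins``
equally sized bins of increasing score, which anchor the composition, motif,
conservation, and ORF analyses.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import revcomp
from .io_formats import Interval, IntervalSet, ReadRecord, SequenceSet

__all__ = [
    "ScoreConfig",
    "compute_scores",
    "bin_positions",
    "score_by_context",
    "bin_composition",
    "motif_around",
    "correlate_five_three",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ScoreConfig:
    """Window, coverage gate, and binning parameters of the definition score."""

    upstream_window: int = 10
    downstream_window: int = 20
    min_local_reads: int = 100
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.upstream_window < 0 or self.downstream_window < 0:
            raise ValueError("window sizes must be >= 0")
        if self.min_local_reads < 1:
            raise ValueError("min_local_reads must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def compute_scores(
    reads: Iterable[ReadRecord],
    regions: IntervalSet | Iterable[Interval],
    config: ScoreConfig | None = None,
    end: str = "five_prime",
) -> pd.DataFrame:
    """Score every position of every region by its local 5'-end competition.

    ``end='five_prime'`` counts read 5' ends at each position;
    ``end='downstream_of_three_prime'`` counts positions one base past read
    3' ends (the next expected 5' end under phased processing). Only reads
    matching the region's strand contribute; the window is oriented along the
    transcript (upstream = toward the transcript 5' end). Positions whose
    window is truncated by a region edge are scored anyway and flagged.

    Returns a DataFrame with one row per region position: contig, position
    (genomic), strand, region, offset (transcript-relative), f, local_total,
    s, covered, truncated.
    """
    if end not in ("five_prime", "downstream_of_three_prime"):
        raise ValueError(f"unknown end mode {end!r}")
    config = config or ScoreConfig()
    up, down = config.upstream_window, config.downstream_window

    by_contig: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        by_contig[r.contig].append(r)

    frames = []
    for iv in regions:
        L = iv.length
        f = np.zeros(L, dtype=float)
        for r in by_contig.get(iv.contig, ()):
            if r.strand != iv.strand:
                continue
            g = r.five_prime if end == "five_prime" else r.downstream_of_three_prime
            if not iv.start <= g < iv.end:
                continue
            off = g - iv.start if iv.strand == "+" else iv.end - 1 - g
            f[off] += r.count
        cs = np.concatenate([[0.0], np.cumsum(f)])
        idx = np.arange(L)
        lo = np.clip(idx - up, 0, L)
        hi = np.clip(idx + down + 1, 0, L)
        local = cs[hi] - cs[lo]
        truncated = (idx < up) | (idx > L - down - 1)
        if truncated.all():
            warnings.warn(
                f"region {iv.name} ({L} nt) is shorter than the score window; "
                "all positions use truncated windows",
                stacklevel=2,
            )
        s = np.divide(f, local, out=np.zeros_like(f), where=local > 0)
        genomic = iv.start + idx if iv.strand == "+" else iv.end - 1 - idx
        frames.append(
            pd.DataFrame(
                {
                    "contig": iv.contig,
                    "position": genomic,
                    "strand": iv.strand,
                    "region": iv.name,
                    "offset": idx,
                    "f": f,
                    "local_total": local,
                    "s": s,
                    "covered": local >= config.min_local_reads,
                    "truncated": truncated,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "contig", "position", "strand", "region", "offset",
                "f", "local_total", "s", "covered", "truncated",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def bin_positions(scored: pd.DataFrame, config: ScoreConfig | None = None) -> pd.DataFrame:
    """Assign covered positions to bin 0 (s = 0) plus n_bins equal-size score bins.

    Positions with positive score are stable-sorted by (s, contig, position)
    and split into ``n_bins`` contiguous groups whose sizes differ by at most
    one, ordered from lowest to highest score; equal sizes take precedence
    over keeping tied scores together, and the stable sort makes the
    assignment deterministic and permutation-invariant.
    """
    config = config or ScoreConfig()
    cov = scored[scored["covered"]].copy()
    cov["bin"] = 0
    positive = cov[cov["s"] > 0]
    n_pos = len(positive)
    n_bins = config.n_bins
    if n_pos == 0:
        return cov
    if n_pos < n_bins:
        warnings.warn(
            f"only {n_pos} positive-score positions for {n_bins} bins; "
            "producing fewer, smaller bins",
            stacklevel=2,
        )
        n_bins = n_pos
    order = positive.sort_values(
        ["s", "contig", "position"], kind="mergesort"
    ).index.to_numpy()
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        cov.loc[chunk, "bin"] = b
    return cov


def _context_at(
    seqs: SequenceSet, contig: str, position: int, strand: str, k: int
) -> str | None:
    """Transcript-oriented k-mer starting at a genomic position (strand-aware)."""
    seq = seqs[contig]
    if strand == "+":
        kmer = seq[position : position + k]
    else:
        lo = position - k + 1
        if lo < 0:
            return None
        kmer = revcomp(seq[lo : position + 1])
    if len(kmer) != k or "N" in kmer:
        return None
    return kmer


def attach_context(
    scored: pd.DataFrame, seqs: SequenceSet, k: int = 3, column: str = "context"
) -> pd.DataFrame:
    """Add the transcript-oriented k-mer starting at each position (None-dropped)."""
    out = scored.copy()
    out[column] = [
        _context_at(seqs, c, int(p), st, k)
        for c, p, st in zip(out["contig"], out["position"], out["strand"])
    ]
    return out[out[column].notna()]

def score_by_context(
    scored: pd.DataFrame,
    seqs: SequenceSet,
    context: str = "trinucleotide",
) -> pd.DataFrame:
    """Per-context summaries of definition scores at covered positions.

    Groups covered positions by the nucleotide (or trinucleotide starting) at
    the position, transcript-oriented, and reports n, mean, median, and
    quartiles of s per group.
    """
    if context not in ("nucleotide", "trinucleotide"):
        raise ValueError(f"unknown context {context!r}")
    k = 1 if context == "nucleotide" else 3
    cov = attach_context(scored[scored["covered"]], seqs, k=k)
    grouped = cov.groupby("context")["s"]
    out = grouped.agg(
        n="size",
        mean="mean",
        median="median",
        q25=lambda x: x.quantile(0.25),
        q75=lambda x: x.quantile(0.75),
    )
    out.index.name = context
    return out


def bin_composition(
    binned: pd.DataFrame, seqs: SequenceSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin frequency of each starting trinucleotide and of each single base.

    Returns ``(trinucleotide_freqs, base_freqs)``: DataFrames whose columns
    are bin indices and whose columns each sum to 1 over represented
    sequences.
    """
    ctx = attach_context(binned, seqs, k=3)
    ctx["base"] = ctx["context"].str[0]
    tri = (
        ctx.groupby("bin")["context"].value_counts(normalize=True).unstack(0).fillna(0.0)
    )
    base = ctx.groupby("bin")["base"].value_counts(normalize=True).unstack(0).fillna(0.0)
    return tri, base


@dataclass
class MotifResult:
    """Position-wise base frequencies around selected positions, with enrichment."""

    foreground: pd.DataFrame  # 4 x offsets base frequencies at bin positions
    background: pd.DataFrame  # 4 x offsets frequencies at background positions
    enrichment: pd.DataFrame  # foreground / background
    n_foreground: int
    n_background: int


def motif_around(
    binned: pd.DataFrame,
    seqs: SequenceSet,
    bin_index: int,
    flank: int = 10,
    background: str = "all_scored",
) -> MotifResult:
    """Base frequencies and enrichments at offsets -flank..+flank around bin positions.

    The enrichment at each offset is the base frequency among the selected
    bin's positions divided by the frequency among the background positions
    (all covered positions by default, or the selected set itself with
    ``background='self'``, in which case every enrichment is 1).
    """
    if background not in ("all_scored", "self"):
        raise ValueError(f"unknown background {background!r}")
    fg_rows = binned[binned["bin"] == bin_index]
    bg_rows = fg_rows if background == "self" else binned

    def freq_matrix(rows: pd.DataFrame) -> pd.DataFrame:
        offsets = range(-flank, flank + 1)
        counts = pd.DataFrame(0.0, index=list(_BASES), columns=list(offsets))
        for contig, pos, strand in zip(rows["contig"], rows["position"], rows["strand"]):
            seq = seqs[contig]
            for d in offsets:
                g = pos + d if strand == "+" else pos - d
                if not 0 <= g < len(seq):
                    continue
                base = seq[g] if strand == "+" else revcomp(seq[g])
                if base in counts.index:
                    counts.loc[base, d] += 1
        sums = counts.sum(axis=0)
        return counts.div(sums.where(sums > 0, 1.0), axis=1)

    fg = freq_matrix(fg_rows)
    bg = freq_matrix(bg_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = fg / bg
    return MotifResult(fg, bg, enr, len(fg_rows), len(bg_rows))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


def correlate_five_three(
    scored5: pd.DataFrame, scored3: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation between 5'-end and 3'-downstream scores.

    Computed over positions covered in both score sets; with fewer than 3
    shared positions the correlation is undefined and flagged.
    """
    keys = ["contig", "position", "strand"]
    a = scored5[scored5["covered"]][keys + ["s"]]
    b = scored3[scored3["covered"]][keys + ["s"]]
    merged = a.merge(b, on=keys, suffixes=("_5", "_3"))
    n = len(merged)
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, defined=False)
    r, p = stats.pearsonr(merged["s_5"], merged["s_3"])
    return CorrelationResult(float(r), float(p), n)
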