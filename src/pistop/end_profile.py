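"""5' end and 3'-downstream sequence composition statistics for piRNA libraries.

This module tabulates the trinucleotide found at each read 5' end (or
immediately downstream of each 3' end), applies the standard read filters
(length windows, 10A ping-pong exclusion, per-position duplicate caps), and
computes the stop-codon enrichment statistics: the stop-codon ratio (mean 5'
frequency of UAA/UAG/UGA over the mean frequency of the 13 other Unn
trinucleotides) and a one-sample t test of per-replicate ratios against 1.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import OTHER_UNN, STOP_CODONS, TRINUCLEOTIDES, revcomp, to_rna
from .io_formats import (
    ReadRecord,
    SequenceSet,
    extract_downstream_sequence,
    extract_five_prime_trinucleotide,
)

__all__ = [
    "EndCountTable",
    "LengthWindow",
    "StopRatioResult",
    "FoldEnrichmentResult",
    "tabulate_five_prime",
    "positional_codon_frequency",
    "exclude_tenA",
    "stop_codon_ratio",
    "fold_enrichment_test",
    "downstream_profile",
    "length_distribution",
]

#: Baseline fractions assuming all trinucleotides are equally abundant.
EXPECTED_ONE_U_FRACTION = 1 / 4
EXPECTED_STOP_FRACTION = 3 / 64


@dataclass(frozen=True)
class LengthWindow:
    """Inclusive read-length filter in nucleotides (e.g. 26-32 for adult mouse)."""

    min_length: int = 15
    max_length: int = 70

    def __post_init__(self) -> None:
        if not 15 <= self.min_length <= self.max_length <= 70:
            raise ValueError(
                f"need 15 <= min <= max <= 70, got {self.min_length}-{self.max_length}"
            )

    def __contains__(self, length: int) -> bool:
        return self.min_length <= length <= self.max_length


@dataclass
class EndCountTable:
    """Counts of the 64 trinucleotides observed at read ends.

    ``counts`` is indexed by all 64 DNA trinucleotides in fixed order;
    ``metadata`` carries library id, the length window used, filter flags,
    and, for simulated tables, species/tissue/class labels.
    """

    counts: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.counts.reindex(list(TRINUCLEOTIDES)).fillna(0.0).astype(float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts

    @classmethod
    def from_counts(cls, counts: dict[str, float], **metadata) -> "EndCountTable":
        return cls(counts=pd.Series(counts, dtype=float), metadata=metadata)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, kmer: str) -> float:
        return float(self.counts[kmer])

    def __add__(self, other: "EndCountTable") -> "EndCountTable":
        return EndCountTable(counts=self.counts + other.counts)

    def frequencies(self, within: str = "all") -> pd.Series:
        """Relative frequencies, normalised over all 64 cells or within Unn only."""
        if within == "all":
            denom = self.counts.sum()
            sub = self.counts
        elif within == "unn":
            sub = self.counts[self.counts.index.str.startswith("T")]
            denom = sub.sum()
        else:
            raise ValueError(f"within must be 'all' or 'unn', got {within!r}")
        if denom == 0:
            return sub * 0.0
        return sub / denom

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        idx = [to_rna(k) for k in self.counts.index] if rna else list(self.counts.index)
        return pd.DataFrame({"trinucleotide": idx, "count": self.counts.to_numpy()})

    def to_tsv(self, path: str | Path, rna: bool = True) -> None:
        with open(path, "w") as handle:
            for key, value in sorted(self.metadata.items()):
                handle.write(f"# {key}={value}\n")
            self.to_frame(rna=rna).to_csv(handle, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EndCountTable":
        metadata: dict = {}
        rows = []
        with open(path) as handle:
            for line in handle:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    metadata[key.strip()] = value.strip()
                else:
                    rows.append(line)
        df = pd.read_csv(pd.io.common.StringIO("".join(rows)), sep="\t")
        counts = pd.Series(
            df["count"].to_numpy(float),
            index=[k.replace("U", "T").replace("u", "t") for k in df["trinucleotide"]],
        )
        return cls(counts=counts, metadata=metadata)


@dataclass
class StopRatioResult:
    """Stop-codon ratio of one library: mean stop frequency / mean other-Unn frequency."""

    mean_stop: float
    mean_other_unn: float
    ratio: float
    defined: bool = True
    per_replicate: list[float] | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None


@dataclass
class FoldEnrichmentResult:
    mean: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    df: int
    zero_variance: bool = False
    log_scale: bool = False


def _cap_duplicates(
    reads: Iterable[ReadRecord], cap: int | None, seed: int
) -> list[ReadRecord]:
    """Cap the total multiplicity contributed by identical coordinate tuples.

    Identical (contig, start, end, strand) records are interchangeable for
    every statistic downstream, so removing surplus copies uniformly at
    random reduces to truncating the pooled count at the cap; the seed is
    accepted for interface stability.
    """
    if cap is None:
        return list(reads)
    pooled: dict[tuple, int] = defaultdict(int)
    order: list[tuple] = []
    for r in reads:
        key = (r.contig, r.start, r.end, r.strand)
        if key not in pooled:
            order.append(key)
        pooled[key] += r.count
    del seed  # uniform removal of identical records is count truncation
    return [
        ReadRecord(contig, start, end, strand, min(count, cap))
        for (contig, start, end, strand), count in ((k, pooled[k]) for k in order)
    ]


def tabulate_five_prime(
    reads: Iterable[ReadRecord],
    seqs: SequenceSet,
    window: LengthWindow | None = None,
    dedup_cap: int | None = None,
    seed: int = 0,
    **metadata,
) -> EndCountTable:
    """Tabulate the trinucleotide at each read's 5' end into a 64-cell table.

    Reads outside the length window are dropped; with ``dedup_cap`` set,
    identical coordinate tuples contribute at most ``cap`` counts. Reads
    whose 5' trinucleotide leaves the sequence or contains N are excluded
    from this table only. An empty result is returned as a zero-total table
    flagged in metadata, not as an error.
    """
    window = window or LengthWindow()
    kept = [r for r in reads if r.length in window]
    kept = _cap_duplicates(kept, dedup_cap, seed)
    counts: Counter = Counter()
    for r in kept:
        kmer = extract_five_prime_trinucleotide(r, seqs)
        if kmer is not None:
            counts[kmer] += r.count
    meta = {
        "length_window": f"{window.min_length}-{window.max_length}",
        "dedup_cap": dedup_cap,
        **metadata,
    }
    table = EndCountTable(counts=pd.Series(counts, dtype=float), metadata=meta)
    if table.total == 0:
        table.metadata["empty"] = True
    return table


def _relative_kmer(read: ReadRecord, seq: str, offset: int, k: int = 3) -> str | None:
    """k-mer starting at 1-based 5'-relative position ``offset`` (strand-aware)."""
    if read.strand == "+":
        lo = read.start + offset - 1
        kmer = seq[lo : lo + k]
    else:
        hi = read.end - offset + 1
        lo = hi - k
        if lo < 0:
            return None
        kmer = revcomp(seq[lo:hi])
    if len(kmer) != k or "N" in kmer:
        return None
    return kmer


def positional_codon_frequency(
    reads: Iterable[ReadRecord],
    seqs: SequenceSet,
    positions: int = 20,
) -> pd.DataFrame:
    """64 x P matrix of trinucleotide frequencies at each 5'-relative position.

    Column ``p`` holds the frequency of each trinucleotide beginning at read
    position ``p`` (1-based from the 5' end); each column sums to 1 over the
    trinucleotides represented there.
    """
    mat = pd.DataFrame(
        0.0, index=list(TRINUCLEOTIDES), columns=range(1, positions + 1)
    )
    for r in reads:
        seq = seqs[r.contig]
        max_p = min(positions, r.length - 2)
        for p in range(1, max_p + 1):
            kmer = _relative_kmer(r, seq, p)
            if kmer is not None:
                mat.loc[kmer, p] += r.count
    sums = mat.sum(axis=0)
    mat = mat.div(sums.where(sums > 0, 1.0), axis=1)
    return mat


def exclude_tenA(reads: Iterable[ReadRecord], seqs: SequenceSet) -> list[ReadRecord]:
    """Drop reads with an A at 5'-relative position 10 (ping-pong signature).

    Position 10 is 1-based from the 5' end, matching the position-10/11
    cleavage register of the ping-pong cycle.
    """
    kept = []
    for r in reads:
        if r.length < 10:
            continue
        base = _relative_kmer(r, seqs[r.contig], 10, k=1)
        if base != "A":
            kept.append(r)
    return kept


def stop_codon_ratio(table: EndCountTable) -> StopRatioResult:
    """Stop-codon ratio: mean stop-codon frequency over mean other-Unn frequency.

    The ratio is scale-invariant (counts in non-U cells are irrelevant) and is
    undefined, flagged rather than raised, when the other-Unn mean is zero.
    """
    if table.total <= 0:
        raise ValueError("cannot compute a stop-codon ratio from an empty table")
    freqs = table.frequencies(within="all")
    mean_stop = float(freqs[list(STOP_CODONS)].mean())
    mean_other = float(freqs[list(OTHER_UNN)].mean())
    if mean_other == 0:
        return StopRatioResult(mean_stop, mean_other, float("nan"), defined=False)
    return StopRatioResult(mean_stop, mean_other, mean_stop / mean_other)


def fold_enrichment_test(
    per_replicate_ratios: Sequence[float],
    log_scale: bool = False,
    ci_level: float = 0.95,
) -> FoldEnrichmentResult:
    """Two-sided one-sample t test of per-replicate stop-codon ratios against 1.

    With ``log_scale`` the test is performed on log-ratios against 0 (the CI
    is reported back on the ratio scale). Zero-variance inputs are flagged and
    reported with a p value at the machine floor (or exactly 1 when every
    ratio equals the null).
    """
    x = np.asarray(per_replicate_ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates for the t test")
    null = 1.0
    if log_scale:
        x = np.log(x)
        null = 0.0
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    dof = n - 1
    if sd == 0:
        p = 1.0 if mean == null else float(np.finfo(float).tiny)
        t_stat = 0.0 if mean == null else float("inf") * np.sign(mean - null)
        lo = hi = mean
        if log_scale:
            mean, lo, hi = np.exp(mean), np.exp(lo), np.exp(hi)
        return FoldEnrichmentResult(mean, lo, hi, t_stat, p, dof, True, log_scale)
    t_stat, p = stats.ttest_1samp(x, null)
    half = stats.t.ppf(0.5 + ci_level / 2, dof) * sd / np.sqrt(n)
    lo, hi = mean - half, mean + half
    if log_scale:
        mean, lo, hi = float(np.exp(mean)), float(np.exp(lo)), float(np.exp(hi))
    return FoldEnrichmentResult(mean, lo, hi, float(t_stat), float(p), dof, False, log_scale)


def downstream_profile(
    reads: Iterable[ReadRecord],
    seqs: SequenceSet,
    by_length: bool = True,
) -> pd.DataFrame:
    """1U and stop-codon fractions immediately downstream of read 3' ends.

    In a phased (untrimmed) library the position just past each 3' end is the
    next fragment's 5' end, so both fractions rise above the equal-abundance
    baselines (1/4 for 1U, 3/64 for stop codons); trimming erases the signal.
    Returns one row per read length (or a single pooled row), with the
    baselines attached as DataFrame attrs.
    """
    rows: dict[int | str, Counter] = defaultdict(Counter)
    for r in reads:
        kmer = extract_downstream_sequence(r, seqs, 3)
        if kmer is None:
            continue
        key = r.length if by_length else "all"
        c = rows[key]
        c["n"] += r.count
        if kmer[0] == "T":
            c["one_u"] += r.count
        if kmer in STOP_CODONS:
            c["stop"] += r.count
    records = []
    for key in sorted(rows, key=str):
        c = rows[key]
        n = c["n"]
        records.append(
            {
                "length": key,
                "n": n,
                "one_u_fraction": c["one_u"] / n if n else float("nan"),
                "stop_fraction": c["stop"] / n if n else float("nan"),
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["expected_one_u"] = EXPECTED_ONE_U_FRACTION
    df.attrs["expected_stop"] = EXPECTED_STOP_FRACTION
    return df


def length_distribution(reads: Iterable[ReadRecord]) -> pd.Series:
    """Histogram of read lengths weighted by multiplicity (sums to total count)."""
    counts: Counter = Counter()
    for r in reads:
        counts[r.length] += r.count
    return pd.Series(dict(sorted(counts.items())), dtype=int)
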