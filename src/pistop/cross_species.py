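"""Stop-codon enrichment across species: QC, robustness classes, and normalization.

Per-library 5'-end trinucleotide tables are filtered (expressed-cluster
calling, length window, per-position caps, library-level read thresholds),
classified by how decisively the three stop codons dominate the 5'-end
sequence ranking (robust: each stop codon more frequent than every non-stop
sequence; near-robust: all three within the top five), normalised by the
cluster's own 3-mer composition, and compared between taxonomic groups with
Fisher's exact test. The analytic null gives the chance that all three stop
codons top a uniform random ranking of the 16 Unn sequences: 3!/(16*15*14)
= 0.18%.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import STOP_CODONS, TRINUCLEOTIDES, UNN
from .end_profile import EndCountTable, StopRatioResult, stop_codon_ratio
from .io_formats import SequenceSet

__all__ = [
    "ClusterFilterConfig",
    "LibraryQcConfig",
    "LibrarySummary",
    "call_expressed_clusters",
    "classify_robustness",
    "expected_composition",
    "normalize_composition",
    "summarize_library",
    "species_group_summary",
    "group_enrichment_fisher",
    "null_robust_fraction",
]


@dataclass(frozen=True)
class ClusterFilterConfig:
    """Thresholds for calling a piRNA cluster 'expressed' in one library."""

    min_unique_reads: int = 100
    min_strand_fraction: float = 0.80
    min_1u_fraction: float = 0.40

    def __post_init__(self) -> None:
        if not 0 < self.min_strand_fraction <= 1 or not 0 < self.min_1u_fraction <= 1:
            raise ValueError("fractions must be in (0, 1]")


@dataclass(frozen=True)
class LibraryQcConfig:
    """Library-level thresholds and read filters for the cross-species analysis."""

    min_cluster_reads: int = 10_000  # refined analysis
    min_total_reads: int = 100_000  # global analysis
    min_length: int = 24
    max_length: int = 31
    per_position_cap: int = 100


@dataclass
class LibrarySummary:
    """Per-library stop-codon enrichment summary."""

    species: str
    tissue: str
    taxon_class: str
    table: EndCountTable
    one_u_fraction: float
    stop_ratio: StopRatioResult
    normalized_stop_ratio: float | None = None
    robustness: str = "none"
    qc: dict = field(default_factory=dict)


def call_expressed_clusters(
    cluster_stats: pd.DataFrame, config: ClusterFilterConfig | None = None
) -> set[str]:
    """Clusters passing the expression thresholds (all inclusive, >= semantics).

    ``cluster_stats`` needs columns ``cluster``, ``unique_reads``,
    ``plus_reads``, ``minus_reads``, ``one_u_reads``; the strand fraction is
    taken on the preferred (majority) strand.
    """
    config = config or ClusterFilterConfig()
    expressed = set()
    for row in cluster_stats.itertuples(index=False):
        n = row.unique_reads
        if n < config.min_unique_reads or n <= 0:
            continue
        strand_frac = max(row.plus_reads, row.minus_reads) / n
        if strand_frac < config.min_strand_fraction:
            continue
        if row.one_u_reads / n < config.min_1u_fraction:
            continue
        expressed.add(row.cluster)
    return expressed


def classify_robustness(table: EndCountTable) -> str:
    """Robustness class of one library's stop-codon enrichment.

    ``'robust'``: every stop codon's 5'-end frequency strictly exceeds every
    non-stop sequence's (ties demote). ``'near_robust'``: all three stop
    codons rank within the five most abundant sequences. Otherwise
    ``'none'``. Robust implies near-robust.
    """
    if table.total <= 0:
        raise ValueError("cannot classify an empty table")
    freqs = table.frequencies(within="all")
    stop = freqs[list(STOP_CODONS)]
    non_stop = freqs.drop(list(STOP_CODONS))
    if float(stop.min()) > float(non_stop.max()):
        return "robust"
    # max-rank makes ties count against the stop codons, consistent with the
    # strict inequality of the robust class
    ranks = freqs.rank(ascending=False, method="max")
    if (ranks[list(STOP_CODONS)] <= 5).all():
        return "near_robust"
    return "none"


def expected_composition(seqs: SequenceSet | Iterable[str]) -> pd.Series:
    """Sliding-window 3-mer frequencies over sense-strand cluster sequences.

    Windows containing N are skipped; windows never cross record boundaries.
    """
    counts = pd.Series(0.0, index=list(TRINUCLEOTIDES))
    sequences = seqs.values() if isinstance(seqs, SequenceSet) else seqs
    any_window = False
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - 2):
            kmer = seq[i : i + 3]
            if "N" in kmer:
                continue
            counts[kmer] += 1
            any_window = True
    if not any_window:
        raise ValueError("no valid 3-mer windows in the input sequences")
    return counts / counts.sum()


def normalize_composition(
    observed: EndCountTable, expected: pd.Series
) -> tuple[pd.Series, StopRatioResult]:
    """Observed/expected ratios per Unn sequence and the normalized stop ratio.

    Each Unn cell's observed 5'-end frequency is divided by the expected
    3-mer frequency from the cluster composition; cells with expected 0 but
    positive observed counts are excluded and flagged (NaN in the ratios).
    The normalized stop ratio is the mean of the stop-codon ratios over the
    mean of the other-Unn ratios.
    """
    freqs = observed.frequencies(within="all")
    expected = expected.reindex(list(TRINUCLEOTIDES)).fillna(0.0)
    ratios = pd.Series(index=list(UNN), dtype=float)
    for kmer in UNN:
        e = float(expected[kmer])
        o = float(freqs[kmer])
        if e > 0:
            ratios[kmer] = o / e
        else:
            ratios[kmer] = float("nan") if o > 0 else 0.0
    normalized = EndCountTable(
        counts=ratios.reindex(list(TRINUCLEOTIDES)).fillna(0.0),
        metadata={**observed.metadata, "normalized": True},
    )
    result = stop_codon_ratio(normalized)
    return ratios, result


def summarize_library(
    table: EndCountTable, expected: pd.Series | None = None
) -> LibrarySummary:
    """Full per-library summary: 1U fraction, stop ratio, robustness, normalization."""
    freqs = table.frequencies(within="all")
    one_u = float(freqs[freqs.index.str.startswith("T")].sum())
    ratio = stop_codon_ratio(table)
    normalized = None
    if expected is not None:
        _, norm = normalize_composition(table, expected)
        normalized = norm.ratio
    meta = table.metadata
    return LibrarySummary(
        species=str(meta.get("species", "unknown")),
        tissue=str(meta.get("tissue", "unknown")),
        taxon_class=str(meta.get("class", "unknown")),
        table=table,
        one_u_fraction=one_u,
        stop_ratio=ratio,
        normalized_stop_ratio=normalized,
        robustness=classify_robustness(table),
    )


def species_group_summary(summaries: Sequence[LibrarySummary]) -> pd.DataFrame:
    """Per class x tissue Unn frequency distributions with species equal-weighted.

    Trinucleotide frequencies are first averaged across libraries of the same
    (species, tissue) pair, then each species contributes one equal-weight
    point to its class x tissue group. Returns a long DataFrame with columns
    class, tissue, species, trinucleotide, frequency.
    """
    per_species: dict[tuple[str, str, str], list[pd.Series]] = {}
    for s in summaries:
        key = (s.taxon_class, s.tissue, s.species)
        per_species.setdefault(key, []).append(s.table.frequencies(within="all"))
    rows = []
    for (taxon_class, tissue, species), freq_list in sorted(per_species.items()):
        mean_freq = pd.concat(freq_list, axis=1).mean(axis=1)
        for kmer in UNN:
            rows.append(
                {
                    "class": taxon_class,
                    "tissue": tissue,
                    "species": species,
                    "trinucleotide": kmer,
                    "frequency": float(mean_freq[kmer]),
                }
            )
    return pd.DataFrame.from_records(rows)


def group_enrichment_fisher(
    a_success: int, a_total: int, b_success: int, b_total: int
) -> float:
    """Two-sided Fisher exact p for robust-library counts between two groups."""
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be positive")
    if a_success > a_total or b_success > b_total:
        raise ValueError("successes cannot exceed totals")
    table = [[a_success, a_total - a_success], [b_success, b_total - b_success]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def null_robust_fraction(n_unn: int = 16, n_stop: int = 3) -> float:
    """Probability that the stop codons occupy the top ranks by pure chance.

    Under a uniform random ranking of ``n_unn`` Unn sequences, the chance that
    the ``n_stop`` stop codons take the ``n_stop`` top ranks is
    prod_{i=0}^{n_stop-1} (n_stop - i) / (n_unn - i); for 16 and 3 this is
    (3/16)(2/15)(1/14) = 0.18%.
    """
    if n_stop > n_unn:
        raise ValueError("n_stop cannot exceed n_unn")
    prob = 1.0
    for i in range(n_stop):
        prob *= (n_stop - i) / (n_unn - i)
    return prob
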