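"""Stop codons, ORF membership, and score comparisons on precursor transcripts.

Every occurrence of TAA/TAG/TGA on a transcript's sense strand is a candidate
cleavage-preferred site. A stop codon belongs to an ORF when an in-frame ATG
is met upstream before any in-frame stop; ORF length counts codons from that
ATG up to, but excluding, the stop, and only lengths of 3-100 amino acids are
accepted. The module compares definition scores between groups of stop
codons with a Wilcoxon rank-sum test and with a size-matched empirical
resampling test.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import START_CODON, STOP_CODONS
from .io_formats import SequenceSet

__all__ = [
    "StopCodonSite",
    "EmpiricalTestConfig",
    "EmpiricalTestResult",
    "find_stop_codons",
    "classify_in_orf",
    "stop_codon_sites",
    "attach_scores",
    "compare_orf_scores",
    "empirical_size_matched_test",
    "SIZE_STRATA",
]

#: ORF-size strata (amino acids, inclusive) used for matching and grouping.
SIZE_STRATA: tuple[tuple[int, int], ...] = ((3, 8), (9, 19), (20, 100))


@dataclass
class StopCodonSite:
    """One stop-codon occurrence on a transcript's sense strand."""

    transcript: str
    position: int  # 0-based position of the stop 3-mer's first base
    codon: str
    in_orf: bool = False
    orf_length_aa: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.codon not in STOP_CODONS:
            raise ValueError(f"{self.codon!r} is not a stop codon")
        if self.in_orf != (self.orf_length_aa is not None):
            raise ValueError("orf_length_aa must be present iff in_orf")


@dataclass(frozen=True)
class EmpiricalTestConfig:
    n_resamples: int = 10_000
    strata: tuple[tuple[int, int], ...] = SIZE_STRATA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class EmpiricalTestResult:
    observed_mean: float
    control_means: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float


def find_stop_codons(transcript: str, sequence: str) -> list[StopCodonSite]:
    """Every TAA/TAG/TGA occurrence on the sense strand, any frame, overlaps allowed."""
    sequence = sequence.upper()
    sites = []
    for i in range(len(sequence) - 2):
        codon = sequence[i : i + 3]
        if codon in STOP_CODONS:
            sites.append(StopCodonSite(transcript, i, codon))
    return sites


def classify_in_orf(
    site: StopCodonSite,
    sequence: str,
    min_aa: int = 3,
    max_aa: int = 100,
) -> StopCodonSite:
    """Decide ORF membership of a stop codon by an in-frame upstream scan.

    Walking upstream codon-by-codon in the stop's frame, the first in-frame
    ATG met before any in-frame stop defines the ORF; its length is the
    number of codons from that ATG up to but excluding the stop. The site is
    in an ORF only when ``min_aa <= length <= max_aa``.
    """
    sequence = sequence.upper()
    j = site.position - 3
    while j >= 0:
        codon = sequence[j : j + 3]
        if codon in STOP_CODONS:
            break
        if codon == START_CODON:
            length = (site.position - j) // 3
            if min_aa <= length <= max_aa:
                return StopCodonSite(
                    site.transcript, site.position, site.codon,
                    in_orf=True, orf_length_aa=length, score=site.score,
                )
            break
        j -= 3
    return StopCodonSite(
        site.transcript, site.position, site.codon,
        in_orf=False, orf_length_aa=None, score=site.score,
    )


def stop_codon_sites(
    seqs: SequenceSet, min_aa: int = 3, max_aa: int = 100
) -> pd.DataFrame:
    """Find and ORF-classify every stop codon in a set of transcripts."""
    rows = []
    for name, seq in seqs.items():
        for site in find_stop_codons(name, seq):
            site = classify_in_orf(site, seq, min_aa=min_aa, max_aa=max_aa)
            rows.append(
                {
                    "transcript": site.transcript,
                    "position": site.position,
                    "codon": site.codon,
                    "in_orf": site.in_orf,
                    "orf_length_aa": site.orf_length_aa,
                }
            )
    return pd.DataFrame.from_records(
        rows, columns=["transcript", "position", "codon", "in_orf", "orf_length_aa"]
    )


def attach_scores(sites: pd.DataFrame, scored: pd.DataFrame) -> pd.DataFrame:
    """Join definition scores onto stop-codon sites (covered positions only).

    ``scored`` must come from :func:`pistop.definition_score.compute_scores`
    over regions whose contig names are the transcript identifiers. Sites at
    uncovered positions are dropped, mirroring the coverage gate.
    """
    cov = scored[scored["covered"]][["contig", "position", "s"]]
    merged = sites.merge(
        cov, left_on=["transcript", "position"], right_on=["contig", "position"]
    )
    return merged.drop(columns="contig").rename(columns={"s": "score"})


def compare_orf_scores(
    scores_in_orf: Sequence[float], scores_not_in_orf: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of scores between two stop-codon groups."""
    a = np.asarray(scores_in_orf, dtype=float)
    b = np.asarray(scores_not_in_orf, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)


def _stratum_of(size_aa: int, strata: tuple[tuple[int, int], ...]) -> int:
    for i, (lo, hi) in enumerate(strata):
        if lo <= size_aa <= hi:
            return i
    raise ValueError(f"ORF size {size_aa} aa falls outside every stratum")


def empirical_size_matched_test(
    confirmed: pd.DataFrame,
    controls: pd.DataFrame,
    config: EmpiricalTestConfig | None = None,
) -> EmpiricalTestResult:
    """One-sided empirical test of the observed mean score vs size-matched controls.

    Both inputs need ``orf_length_aa`` and ``score`` columns. Each resample
    draws, for every confirmed site, one control score from the same ORF-size
    stratum (with replacement), giving a null distribution of control means.
    The p value is the fraction of resampled control means at or below the
    observed mean, and the CI spans the central 95% of control means.
    """
    config = config or EmpiricalTestConfig()
    if confirmed.empty:
        raise ValueError("no confirmed sites to test")
    rng = np.random.default_rng(config.seed)

    control_strata = {
        i: controls.loc[
            [(_stratum_of(s, config.strata) == i) for s in controls["orf_length_aa"]],
            "score",
        ].to_numpy(float)
        for i in range(len(config.strata))
    }
    needed: dict[int, int] = {}
    for s in confirmed["orf_length_aa"]:
        i = _stratum_of(int(s), config.strata)
        needed[i] = needed.get(i, 0) + 1
    for i, k in needed.items():
        pool = control_strata.get(i, np.empty(0))
        if pool.size == 0:
            lo, hi = config.strata[i]
            raise ValueError(f"no control sites in stratum {lo}-{hi} aa")

    n_total = int(sum(needed.values()))
    sums = np.zeros(config.n_resamples)
    for i, k in sorted(needed.items()):
        draws = rng.choice(control_strata[i], size=(config.n_resamples, k), replace=True)
        sums += draws.sum(axis=1)
    control_means = sums / n_total
    observed = float(confirmed["score"].mean())
    p = float(np.mean(control_means <= observed))
    lo, hi = np.quantile(control_means, [0.025, 0.975])
    return EmpiricalTestResult(observed, control_means, float(lo), float(hi), p)
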