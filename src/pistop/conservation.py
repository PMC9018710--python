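"""Per-base conservation and variant analyses across definition-score bins.

Joins a per-base conservation track (e.g. phyloP) and a set of SNP positions
to binned cluster positions, then summarises each bin: mean with a t-based
95% confidence interval, the fraction of positions with significant
acceleration (score strictly below -1.30103, i.e. -log10(0.05)), and the SNP
frequency. Bins can first be restricted to U positions or to U positions in
stop-codon context.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .alphabet import STOP_CODONS
from .definition_score import attach_context
from .io_formats import SequenceSet, Track

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationConfig",
    "join_track",
    "subset_positions",
    "bin_mean_ci",
    "accelerated_fraction",
    "snp_frequency",
]


@dataclass(frozen=True)
class ConservationConfig:
    """Acceleration threshold (phyloP convention: -log10(0.05)) and CI level."""

    acceleration_threshold: float = -1.30103
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.acceleration_threshold >= 0:
            raise ValueError("acceleration threshold must be negative")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def join_track(binned: pd.DataFrame, track: Track) -> pd.DataFrame:
    """Inner-join track values onto binned positions; missing positions are dropped.

    The number of positions without a track value is logged and stored in
    the result's ``attrs['n_missing']``.
    """
    values = [track.get(c, int(p)) for c, p in zip(binned["contig"], binned["position"])]
    out = binned.copy()
    out["value"] = values
    missing = out["value"].isna().sum()
    if missing:
        logger.info("join_track: %d positions missing from the track", missing)
    out = out[out["value"].notna()].copy()
    out.attrs["n_missing"] = int(missing)
    return out


def subset_positions(
    binned: pd.DataFrame, seqs: SequenceSet, mode: str = "all"
) -> pd.DataFrame:
    """Restrict binned positions to U positions or U-in-stop-codon-context positions.

    ``mode='U'`` keeps positions whose transcript-oriented base is U;
    ``'stopU'`` keeps positions whose starting trinucleotide is a stop codon.
    Subsetting never increases n.
    """
    if mode == "all":
        return binned
    if mode == "U":
        ctx = attach_context(binned, seqs, k=1)
        return ctx[ctx["context"] == "T"].drop(columns="context")
    if mode == "stopU":
        ctx = attach_context(binned, seqs, k=3)
        return ctx[ctx["context"].isin(STOP_CODONS)].drop(columns="context")
    raise ValueError(f"unknown subset mode {mode!r}")


def bin_mean_ci(
    pairs: pd.DataFrame, config: ConservationConfig | None = None
) -> pd.DataFrame:
    """Per-bin mean track value with a t-based confidence interval.

    Bins with fewer than 2 positions report the mean without a CI.
    """
    config = config or ConservationConfig()
    rows = []
    for b, grp in pairs.groupby("bin"):
        vals = grp["value"].to_numpy(float)
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            half = stats.t.ppf(0.5 + config.ci_level / 2, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        rows.append({"bin": b, "n": n, "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame.from_records(rows).set_index("bin")


def accelerated_fraction(
    pairs: pd.DataFrame, config: ConservationConfig | None = None
) -> pd.DataFrame:
    """Per-bin fraction of significantly accelerated positions, with Z tests.

    A position counts as accelerated when its value is strictly below the
    threshold. Each bin is compared against the pooled remaining bins with a
    two-sided two-proportion Z test; a pooled rate of 0 (or 1) leaves the Z
    statistic undefined and flagged.
    """
    config = config or ConservationConfig()
    acc = pairs["value"].to_numpy(float) < config.acceleration_threshold
    total_acc = int(acc.sum())
    total_n = len(pairs)
    rows = []
    for b, grp in pairs.groupby("bin"):
        sub = grp["value"].to_numpy(float) < config.acceleration_threshold
        n, k = sub.size, int(sub.sum())
        rest_n, rest_k = total_n - n, total_acc - k
        frac = k / n if n else float("nan")
        if rest_n > 0 and 0 < (k + rest_k) < (n + rest_n):
            z, p = proportions_ztest([k, rest_k], [n, rest_n], alternative="two-sided")
            z, p, defined = float(z), float(p), True
        else:
            z = p = float("nan")
            defined = False
        rows.append(
            {"bin": b, "n": n, "accelerated": k, "fraction": frac,
             "z": z, "p_value": p, "test_defined": defined}
        )
    return pd.DataFrame.from_records(rows).set_index("bin")


def snp_frequency(
    binned: pd.DataFrame, snp_positions: Iterable[tuple[str, int]]
) -> pd.DataFrame:
    """Per-bin fraction of positions listed in the SNP set."""
    snps = set(snp_positions)
    hit = [
        (c, int(p)) in snps for c, p in zip(binned["contig"], binned["position"])
    ]
    df = binned.copy()
    df["snp"] = hit
    out = df.groupby("bin")["snp"].agg(n="size", snps="sum")
    out["frequency"] = out["snps"] / out["n"]
    return out
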