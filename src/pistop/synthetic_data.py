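"""Synthetic piRNA clusters, phased reads, conservation tracks, and count tables.

The generator emulates Zuc/PLD6-style phased piRNA biogenesis so that every
downstream statistic in the package can be exercised with known ground truth:

* cluster sequences with tunable base composition and CpG depletion,
* tail-to-head pre-piRNA chains whose cut sites are drawn with
  per-trinucleotide cleavage weights, a -1G penalty, and an upstream-GC bonus,
* a 3' trimming toggle (mature 26-27 nt vs untrimmed pre-piRNAs),
* per-base conservation/SNP-like tracks, and
* multinomial 5'-end trinucleotide count tables for many libraries/species.

Everything is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import STOP_CODONS, TRINUCLEOTIDES, UNN
from .end_profile import EndCountTable
from .io_formats import ReadRecord, SequenceSet, Track

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionModel",
    "CleavageModel",
    "SimulationTruth",
    "generate_cluster",
    "position_weights",
    "simulate_phased_reads",
    "simulate_track",
    "simulate_library_tables",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: The four trinucleotides preferred by in vivo Zuc-dependent cleavage.
PREFERRED_CUT_SITES: tuple[str, ...] = ("TAA", "TAG", "TGA", "TAC")


@dataclass(frozen=True)
class CompositionModel:
    """First-order background model for piRNA cluster sequences.

    ``base_probs`` are the marginal A/C/G/T probabilities; the defaults are
    mildly AT-rich, as piRNA clusters typically are. ``cpg_depletion`` scales
    the C->G transition probability before renormalisation, mimicking the
    genome-wide CpG depletion of non-coding DNA (1.0 disables it). If
    ``trinucleotide_targets`` is given, sequences are instead produced by a
    second-order chain whose conditional probabilities derive from those
    3-mer frequencies.
    """

    base_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    cpg_depletion: float = 0.25
    trinucleotide_targets: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probs, dtype=float)
        if p.min() < 0 or p.sum() <= 0:
            raise ValueError("base probabilities must be non-negative with positive sum")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("base probabilities must sum to 1")
        if not 0 < self.cpg_depletion <= 1:
            raise ValueError("cpg_depletion must be in (0, 1]")

    def transition_matrix(self) -> np.ndarray:
        """4x4 row-stochastic matrix P[prev, next] with the CpG row renormalised."""
        p = np.asarray(self.base_probs, dtype=float)
        mat = np.tile(p, (4, 1))
        c, g = _BASE_INDEX["C"], _BASE_INDEX["G"]
        mat[c, g] *= self.cpg_depletion
        mat /= mat.sum(axis=1, keepdims=True)
        return mat

    def stationary_distribution(self) -> np.ndarray:
        """Stationary base distribution of the first-order chain."""
        mat = self.transition_matrix()
        vals, vecs = np.linalg.eig(mat.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def trinucleotide_probs(self) -> pd.Series:
        """Analytic stationary 3-mer probabilities of the generating chain.

        This is the closed-form oracle for the empirical 3-mer content of
        long generated clusters: pi(a) * P(b|a) * P(c|b).
        """
        if self.trinucleotide_targets is not None:
            s = pd.Series(
                {k: float(self.trinucleotide_targets.get(k, 0.0)) for k in TRINUCLEOTIDES}
            )
            total = s.sum()
            if total <= 0:
                raise ValueError("trinucleotide targets must have positive total")
            return s / total
        mat = self.transition_matrix()
        pi = self.stationary_distribution()
        probs = {}
        for kmer in TRINUCLEOTIDES:
            a, b, c = (_BASE_INDEX[x] for x in kmer)
            probs[kmer] = pi[a] * mat[a, b] * mat[b, c]
        return pd.Series(probs)


@dataclass(frozen=True)
class CleavageModel:
    """In vivo cleavage preference of the phasing endonuclease.

    ``weights`` assigns each trinucleotide the relative propensity that a cut
    creates a new 5' end starting with it (keyed by the 3-mer beginning at the
    cut's downstream side). ``minus1_g_penalty`` multiplies the weight when the
    base immediately upstream of the cut is G (values < 1 reproduce the
    observed -1G depletion). ``upstream_gc_bonus`` rewards a GC-rich region
    20-10 nt upstream of the cut: the weight is multiplied by
    ``1 + (bonus - 1) * gc_fraction``. ``initiation_rate`` is the expected
    number of processing chains per nucleotide when the caller does not fix
    the chain count.
    """

    weights: Mapping[str, float]
    minus1_g_penalty: float = 1.0
    upstream_gc_bonus: float = 1.0
    initiation_rate: float = 0.01

    def __post_init__(self) -> None:
        w = {k: float(v) for k, v in self.weights.items()}
        unknown = set(w) - set(TRINUCLEOTIDES)
        if unknown:
            raise ValueError(f"unknown trinucleotides in weights: {sorted(unknown)}")
        if any(v < 0 for v in w.values()):
            raise ValueError("cleavage weights must be non-negative")
        if not any(v > 0 for v in w.values()):
            raise ValueError("at least one cleavage weight must be positive")
        if self.minus1_g_penalty <= 0 or self.upstream_gc_bonus <= 0:
            raise ValueError("multipliers must be positive")
        object.__setattr__(self, "weights", w)

    def weight_vector(self) -> pd.Series:
        return pd.Series({k: self.weights.get(k, 0.0) for k in TRINUCLEOTIDES})

    @classmethod
    def uniform_u(cls, **kwargs) -> "CleavageModel":
        """Equal weight on all 16 Unn trinucleotides, zero elsewhere (1U-only null)."""
        return cls(weights={k: 1.0 for k in UNN}, **kwargs)

    @classmethod
    def stop_preference(
        cls,
        fold: float = 4.0,
        background: float = 0.0,
        minus1_g_penalty: float = 0.25,
        upstream_gc_bonus: float = 2.0,
        **kwargs,
    ) -> "CleavageModel":
        """The in vivo-like model: ``fold``-boosted weights on UAA/UAG/UGA/UAC.

        Other Unn trinucleotides get weight 1 and non-U trinucleotides get
        ``background`` (default 0: strictly 1U cleavage).
        """
        weights = {k: background for k in TRINUCLEOTIDES}
        weights.update({k: 1.0 for k in UNN})
        weights.update({k: float(fold) for k in PREFERRED_CUT_SITES})
        return cls(
            weights=weights,
            minus1_g_penalty=minus1_g_penalty,
            upstream_gc_bonus=upstream_gc_bonus,
            **kwargs,
        )


@dataclass
class SimulationTruth:
    """Ground truth of one phased-read simulation, for parameter-recovery tests."""

    cleavage_model: CleavageModel
    seed: int
    trimming: str
    expected_cut_probability: np.ndarray
    n_chains: int = 0
    n_terminated: int = 0
    extra: dict = field(default_factory=dict)


def generate_cluster(
    length: int,
    model: CompositionModel | None = None,
    seed: int = 0,
    name: str = "cluster",
) -> SequenceSet:
    """Sample one cluster sequence of ``length`` nt from ``model``.

    Returns a single-entry :class:`SequenceSet` keyed by ``name``. The
    sequence is sampled base-by-base; with CpG depletion the C->G transition
    is down-weighted and renormalised, so the analytic
    :meth:`CompositionModel.trinucleotide_probs` describes long-run content.
    """
    if length < 100:
        raise ValueError("cluster length must be >= 100 nt")
    model = model or CompositionModel()
    rng = np.random.default_rng(seed)
    if model.trinucleotide_targets is not None:
        return SequenceSet({name: _generate_second_order(length, model, rng)})
    mat = model.transition_matrix()
    start_probs = model.stationary_distribution()
    bases = np.empty(length, dtype=np.int64)
    bases[0] = rng.choice(4, p=start_probs)
    # sample transitions with one uniform draw per base via CDF lookup
    cdf = np.cumsum(mat, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        bases[i] = np.searchsorted(cdf[bases[i - 1]], u[i], side="right")
    seq = "".join(_BASES[b] for b in bases)
    return SequenceSet({name: seq})


def _generate_second_order(length: int, model: CompositionModel, rng) -> str:
    probs = model.trinucleotide_probs()
    arr = probs.to_numpy().reshape(4, 4, 4)
    dimer = arr.sum(axis=2)
    if dimer.sum() <= 0:
        raise ValueError("degenerate trinucleotide target distribution")
    flat = dimer.ravel() / dimer.sum()
    first = rng.choice(16, p=flat)
    bases = [first // 4, first % 4]
    for _ in range(length - 2):
        cond = arr[bases[-2], bases[-1]]
        total = cond.sum()
        if total <= 0:  # dead end: restart from the dimer marginal
            nxt = rng.choice(16, p=flat)
            bases.extend([nxt // 4, nxt % 4])
            continue
        bases.append(rng.choice(4, p=cond / total))
    return "".join(_BASES[b] for b in bases[:length])


def position_weights(seq: str, model: CleavageModel) -> np.ndarray:
    """Per-position relative cut propensity along a cluster's sense strand.

    ``w[i]`` is the propensity that a cut places a new 5' end at position
    ``i``: the trinucleotide weight at ``i``, times the -1G penalty if
    ``seq[i-1]`` is G, times the upstream-GC bonus scaled by the GC fraction
    of ``seq[i-20:i-10]``. The last two positions (incomplete trinucleotide)
    get weight 0.
    """
    L = len(seq)
    w = np.zeros(L, dtype=float)
    weights = model.weights
    for i in range(L - 2):
        w[i] = weights.get(seq[i : i + 3], 0.0)
    if model.minus1_g_penalty != 1.0:
        is_g_prev = np.zeros(L, dtype=bool)
        for i in range(1, L):
            is_g_prev[i] = seq[i - 1] == "G"
        w[is_g_prev] *= model.minus1_g_penalty
    if model.upstream_gc_bonus != 1.0:
        gc = np.fromiter((1.0 if b in "GC" else 0.0 for b in seq), float, count=L)
        cs = np.concatenate([[0.0], np.cumsum(gc)])
        idx = np.arange(L)
        lo = idx - 20
        hi = idx - 10  # window [i-20, i-10): 10 bases
        valid = lo >= 0
        frac = np.zeros(L)
        frac[valid] = (cs[hi[valid]] - cs[lo[valid]]) / 10.0
        w *= 1.0 + (model.upstream_gc_bonus - 1.0) * frac
    return w


def simulate_phased_reads(
    cluster: SequenceSet,
    model: CleavageModel,
    n_initiations: int | None = None,
    trimming: str = "untrimmed",
    seed: int = 0,
    min_step: int = 28,
    max_step: int = 50,
    max_fragments_per_chain: int = 25,
    mature_lengths: tuple[int, int] = (26, 27),
) -> tuple[list[ReadRecord], SimulationTruth]:
    """Simulate tail-to-head phased pre-piRNA production from one cluster.

    Each chain starts at an initiation site drawn proportionally to the
    position weights, then repeatedly picks the next cut among candidate
    positions ``min_step``-``max_step`` nt downstream with probability
    proportional to the position weight, emitting fragments tail-to-head
    (``next.start == prev.end``). ``trimming='trimmed'`` truncates each
    fragment from its 3' side to a mature length (26 or 27 nt, 5' end kept);
    ``'untrimmed'`` leaves pre-piRNA fragments intact. The default fragment
    window (28-50 nt) keeps every pre-piRNA longer than mature length, so the
    trimming toggle cleanly creates or destroys 3'-end/5'-end adjacency. A
    chain with no positively weighted candidate in its window terminates
    (counted in the returned truth).
    """
    if trimming not in ("trimmed", "untrimmed"):
        raise ValueError(f"trimming must be 'trimmed' or 'untrimmed', got {trimming!r}")
    if len(cluster) != 1:
        raise ValueError("simulate_phased_reads expects a single-sequence cluster")
    (name,) = cluster.keys()
    seq = cluster[name]
    L = len(seq)
    if L <= max_step + 3:
        raise ValueError("cluster must be longer than the maximum fragment length")
    # independent streams for cut choice and trim length, so the same seed
    # yields identical pre-piRNA chains whether or not trimming is applied
    cut_ss, trim_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(cut_ss)
    trim_rng = np.random.default_rng(trim_ss)
    w = position_weights(seq, model)
    if n_initiations is None:
        n_initiations = max(1, int(round(model.initiation_rate * L)))

    init_hi = L - max_step  # leave room for at least one fragment
    init_w = w[:init_hi]
    if init_w.sum() <= 0:
        raise ValueError("no positively weighted initiation site in the cluster")
    init_p = init_w / init_w.sum()

    reads: list[ReadRecord] = []
    n_terminated = 0
    starts = rng.choice(init_hi, size=n_initiations, p=init_p)
    for pos in starts:
        pos = int(pos)
        for _ in range(max_fragments_per_chain):
            lo = pos + min_step
            hi = min(pos + max_step, L - 3)
            if lo > hi:
                n_terminated += 1
                break
            cand_w = w[lo : hi + 1]
            total = cand_w.sum()
            if total <= 0:
                n_terminated += 1
                logger.debug("chain at %d terminated: no positive-weight candidate", pos)
                break
            cut = lo + int(rng.choice(hi + 1 - lo, p=cand_w / total))
            end = cut
            if trimming == "trimmed":
                target = int(trim_rng.choice(mature_lengths))
                end = min(cut, pos + target)
            reads.append(ReadRecord(name, pos, end, "+", 1))
            pos = cut

    truth = SimulationTruth(
        cleavage_model=model,
        seed=seed,
        trimming=trimming,
        expected_cut_probability=w / w.sum(),
        n_chains=n_initiations,
        n_terminated=n_terminated,
    )
    return reads, truth


def simulate_track(
    cluster: SequenceSet,
    mode: str = "noisy",
    seed: int = 0,
    value: float = 0.0,
    sd: float = 1.0,
    offset: float = 0.5,
    offset_positions: Sequence[int] = (),
) -> Track:
    """Per-base score track over a cluster: flat, i.i.d. noisy, or bin-correlated.

    ``flat`` sets every position to ``value``; ``noisy`` adds N(0, sd) noise;
    ``bin-correlated`` additionally shifts the positions in
    ``offset_positions`` by ``offset`` (fixture for binned conservation
    analyses).
    """
    if mode not in ("flat", "noisy", "bin-correlated"):
        raise ValueError(f"unknown track mode {mode!r}")
    (name,) = cluster.keys()
    L = len(cluster[name])
    rng = np.random.default_rng(seed)
    vals = np.full(L, float(value))
    if mode in ("noisy", "bin-correlated"):
        vals = vals + rng.normal(0.0, sd, size=L)
    if mode == "bin-correlated":
        for pos in offset_positions:
            vals[pos] += offset
    return Track({(name, i): float(v) for i, v in enumerate(vals)})


def _default_table_distribution(effect: float) -> np.ndarray:
    # 1U-biased base distribution: Unn cells 4x the others, stops scaled by `effect`
    probs = pd.Series(1.0, index=TRINUCLEOTIDES)
    probs[list(UNN)] = 4.0
    probs[list(STOP_CODONS)] *= effect
    p = probs.to_numpy()
    return p / p.sum()


def simulate_library_tables(
    n_species: int = 5,
    libraries_per_species: int = 2,
    effect: float = 1.0,
    depth: int = 100_000,
    seed: int = 0,
    tissue: str = "testis",
    taxon_class: str = "mammals",
    base_distribution: Sequence[float] | None = None,
) -> list[EndCountTable]:
    """Multinomial 5'-end trinucleotide tables for a grid of species/libraries.

    Each table draws ``depth`` reads from a 1U-biased trinucleotide
    distribution whose three stop-codon cells are multiplied by ``effect``
    and renormalised. Metadata (species, tissue, class, library) is attached
    to every table.
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    if base_distribution is None:
        p = _default_table_distribution(effect)
    else:
        p = np.asarray(base_distribution, dtype=float)
        if p.shape != (64,):
            raise ValueError("base_distribution must have 64 cells")
        p = p.copy()
        stop_idx = [TRINUCLEOTIDES.index(k) for k in STOP_CODONS]
        p[stop_idx] *= effect
        p = p / p.sum()
    rng = np.random.default_rng(seed)
    tables = []
    for s in range(n_species):
        species = f"species{s + 1:02d}"
        for lib in range(libraries_per_species):
            counts = rng.multinomial(depth, p)
            tables.append(
                EndCountTable(
                    counts=pd.Series(counts, index=list(TRINUCLEOTIDES)),
                    metadata={
                        "species": species,
                        "tissue": tissue,
                        "class": taxon_class,
                        "library": f"{species}_{tissue}_{lib + 1}",
                    },
                )
            )
    return tables
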