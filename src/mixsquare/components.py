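"""The Mix² probability model for a genomic locus.

A fragment r from transcript t=i is modelled as

    p(r | t=i) = p(l(r) | t=i, s(r)) * sum_j beta_ij p(s(r) | t=i, b=j)

where the M positional components p(s | t=i, b=j) are Gaussians placed
equidistantly along the transcript, evaluated at the integer start
positions s = 1..l(t) and renormalized to sum to one.  The locus-level
fragment probability is the superposition over the N isoforms weighted by
their relative abundances alpha_i.

Means and standard deviations of the positional Gaussians:

    mu_ij    = j * l / M - l / (2M),   j = 1..M
    sigma_ij = l / (2M)

For paired-end data the fragment length factor is a Gaussian (default mean
200 bp, sd 80 bp) truncated and renormalized over the lengths admissible at
the given start; for single-end data the length is unknown and summed out,
setting the factor to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "PositionMixture",
    "FragmentLengthModel",
    "FragmentObservation",
    "Mix2Parameters",
    "build_position_components",
    "start_probability",
    "fragment_probability",
    "locus_probability",
]


@dataclass(frozen=True)
class PositionMixture:
    """The M normalized Gaussian start-position components of one transcript."""

    transcript_length: int
    n_components: int
    means: np.ndarray
    sd: float
    tables: np.ndarray  # shape (M, L); each row sums to 1

    def render(self, beta_row: np.ndarray) -> np.ndarray:
        """The mixture start distribution p(s|t) for component weights beta."""
        beta_row = np.asarray(beta_row, dtype=float)
        if beta_row.shape != (self.n_components,):
            raise ValueError("beta_row has wrong number of components")
        return beta_row @ self.tables


def build_position_components(length: int, n_components: int) -> PositionMixture:
    """Place M Gaussian components equidistantly along a transcript.

    Each component is the Gaussian density evaluated at the integer start
    positions 1..length and renormalized so that it sums to one.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    M = n_components
    j = np.arange(1, M + 1, dtype=float)
    means = j * length / M - length / (2.0 * M)
    sd = length / (2.0 * M)
    s = np.arange(1, length + 1, dtype=float)
    z = (s[None, :] - means[:, None]) / sd
    tables = np.exp(-0.5 * z * z)
    tables /= tables.sum(axis=1, keepdims=True)
    return PositionMixture(length, M, means, sd, tables)


def start_probability(mix: PositionMixture, beta_row, s: int) -> float:
    """p(s|t) = sum_j beta_j * component_j(s) at start position s."""
    if not 1 <= s <= mix.transcript_length:
        raise ValueError(f"start {s} outside 1..{mix.transcript_length}")
    beta_row = np.asarray(beta_row, dtype=float)
    return float(beta_row @ mix.tables[:, s - 1])


@dataclass
class FragmentLengthModel:
    """Fragment length distribution: Gaussian for paired-end data, or the
    degenerate unit factor for single-end data where length is summed out."""

    mean: float = 200.0
    sd: float = 80.0
    mode: str = "gaussian"  # or "single_end_unit"
    _pdf_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("mean and sd must be positive")
        if self.mode not in ("gaussian", "single_end_unit"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def single_end(self) -> bool:
        return self.mode == "single_end_unit"

    def _density_cumsum(self, max_len: int) -> np.ndarray:
        """Cumulative sum of the Gaussian density at integer lengths 1..max_len."""
        key = max_len
        cached = self._pdf_cache.get(key)
        if cached is None:
            dens = norm.pdf(np.arange(1, max_len + 1), loc=self.mean, scale=self.sd)
            cached = np.cumsum(dens)
            self._pdf_cache[key] = cached
        return cached

    def probability(self, length: int, max_length: int) -> float:
        """p(l | t, s): density at integer l renormalized over 1..max_length."""
        if self.single_end:
            return 1.0
        if length < 1 or length > max_length:
            return 0.0
        cs = self._density_cumsum(max_length)
        total = cs[max_length - 1]
        dens = cs[length - 1] - (cs[length - 2] if length >= 2 else 0.0)
        return float(dens / total) if total > 0 else 0.0

    def probabilities(self, lengths: np.ndarray, max_lengths: np.ndarray) -> np.ndarray:
        """Vectorized ``probability``; zero where length is inadmissible."""
        if self.single_end:
            return np.ones(len(lengths), dtype=float)
        lengths = np.asarray(lengths, dtype=np.int64)
        max_lengths = np.asarray(max_lengths, dtype=np.int64)
        top = int(max_lengths.max()) if len(max_lengths) else 1
        cs = self._density_cumsum(max(top, 1))
        ok = (lengths >= 1) & (lengths <= max_lengths)
        li = np.clip(lengths, 1, top)
        dens = cs[li - 1] - np.where(li >= 2, cs[np.maximum(li - 2, 0)], 0.0)
        total = cs[np.clip(max_lengths, 1, top) - 1]
        out = np.zeros(len(lengths), dtype=float)
        nz = ok & (total > 0)
        out[nz] = dens[nz] / total[nz]
        return out


@dataclass
class FragmentObservation:
    """One sequenced fragment and its per-isoform placement.

    ``compatibility`` maps transcript id -> (start, length); length is None
    for single-end reads, where only the fragment start (the read's
    downstream end in transcript orientation) is known.
    """

    id: str
    compatibility: dict[str, tuple[int, int | None]]


@dataclass
class Mix2Parameters:
    """Model parameters: abundances alpha over N isoforms and component
    weights beta, one row per tying group."""

    alpha: np.ndarray  # (N,), sums to 1
    beta: np.ndarray  # (G, M), rows sum to 1
    group_of: np.ndarray  # (N,) -> group index

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.group_of = np.asarray(self.group_of, dtype=np.int64)
        if np.any(self.alpha < -1e-12) or abs(self.alpha.sum() - 1) > 1e-6:
            raise ValueError("alpha must be a probability vector")
        if np.any(self.beta < -1e-12) or np.any(
            np.abs(self.beta.sum(axis=1) - 1) > 1e-6
        ):
            raise ValueError("every beta row must sum to 1")

    @property
    def n_components(self) -> int:
        return self.beta.shape[1]

    def beta_of_transcript(self, i: int) -> np.ndarray:
        return self.beta[self.group_of[i]]


def fragment_probability(
    fragment: FragmentObservation,
    transcript,
    mixtures: dict,
    params: Mix2Parameters,
    transcript_index: dict,
    length_model: FragmentLengthModel,
) -> float:
    """p(r | t=i) per the start/length factorization; 0 if incompatible."""
    entry = fragment.compatibility.get(transcript.id)
    if entry is None:
        return 0.0
    s, l = entry
    mix = mixtures[transcript.id]
    i = transcript_index[transcript.id]
    beta_row = params.beta_of_transcript(i)
    p_start = start_probability(mix, beta_row, s)
    if length_model.single_end or l is None:
        return p_start
    p_len = length_model.probability(l, transcript.length - s + 1)
    return p_len * p_start


def locus_probability(
    fragment: FragmentObservation,
    locus,
    mixtures: dict,
    params: Mix2Parameters,
    length_model: FragmentLengthModel,
) -> float:
    """p(r) = sum_i alpha_i p(r | t=i); 0 when r matches no isoform."""
    tindex = {t.id: i for i, t in enumerate(locus.transcripts)}
    total = 0.0
    for i, t in enumerate(locus.transcripts):
        total += params.alpha[i] * fragment_probability(
            fragment, t, mixtures, params, tindex, length_model
        )
    return total
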