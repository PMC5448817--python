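"""EM estimation of the Mix² model: Model/Results objects plus the
underlying update-rule functions.

``Mix2Model`` holds one gene locus and its fragment observations together
with the tying configuration; ``fit()`` runs EM and returns a
``Mix2Results`` with abundance estimates, component weights, rendered
fragment-start distributions, expected counts and diagnostics.

Parameter tying
---------------
The component weights beta determine the shape of a transcript's fragment
start distribution.  Transcripts with similar distributions can share one
beta row:

* ``none``   — every transcript has its own beta row (M=3 by default);
* ``global`` — all transcripts of the gene share one row (M=4);
* ``group``  — transcripts are binned by length (7 boundaries equidistant
  on the log scale between 300 and 5000 bp) and bins are merged until every
  group has at least 20 valid reads and at most one group is a singleton
  (M=4).

Updates:  alpha_i <- (1/R) sum_r p(t=i|r);  for group k,
beta_kj <- sum_r p(g=k, b=j|r) / sum_r p(g=k|r), where the group posteriors
sum the transcript posteriors over the group members.  Initialization is
uniform (alpha_i = 1/N, beta_kj = 1/M), which renders near-uniform initial
start distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .components import (
    FragmentLengthModel,
    FragmentObservation,
    Mix2Parameters,
    build_position_components,
)
from .transcripts import GeneLocus

logger = logging.getLogger(__name__)

__all__ = [
    "TyingScheme",
    "EMConfig",
    "GroupAssignment",
    "FragmentTable",
    "Mix2Model",
    "Mix2Results",
    "initialize_parameters",
    "e_step",
    "update_alpha",
    "update_beta",
    "build_length_groups",
    "merge_groups",
    "group_distance",
    "fpkm_from_result",
    "DegenerateInputError",
]

#: transcript-length bin boundaries for group tying: 7 values equidistant
#: on the log scale between 300 and 5000 bp
GROUP_BOUNDARIES = 300.0 * (5000.0 / 300.0) ** (np.arange(7) / 6.0)

DEFAULT_COMPONENTS = {"none": 3, "global": 4, "group": 4}


class DegenerateInputError(ValueError):
    """No usable fragments remain for estimation."""


@dataclass
class TyingScheme:
    """How beta rows are shared across the transcripts of a locus."""

    mode: str = "group"
    n_components: int | None = None

    def __post_init__(self):
        if self.mode not in ("none", "global", "group"):
            raise ValueError(f"unknown tying mode {self.mode!r}")
        if self.n_components is None:
            self.n_components = DEFAULT_COMPONENTS[self.mode]
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class EMConfig:
    max_iterations: int = 1000
    param_tol: float = 1e-4
    loglik_tol: float = 1e-6
    seed: int | None = None  # logged for provenance; EM itself is deterministic

    def __post_init__(self):
        if self.param_tol <= 0 or self.loglik_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class GroupAssignment:
    """A partition of the locus transcripts into tying groups."""

    groups: list[list[int]]  # transcript indices per group
    mean_length: list[float]
    valid_read_count: list[int]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of_array(self, n_transcripts: int) -> np.ndarray:
        out = np.full(n_transcripts, -1, dtype=np.int64)
        for k, members in enumerate(self.groups):
            out[members] = k
        if np.any(out < 0):
            raise ValueError("groups do not cover all transcripts")
        return out


class FragmentTable:
    """Columnar fragment store: per-isoform compatibility, start and length.

    ``lengths`` is 0 where the fragment length is unknown (single-end data).
    """

    def __init__(self, compat, starts, lengths, single_end=False, ids=None):
        self.compat = np.asarray(compat, dtype=bool)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.single_end = bool(single_end)
        self.ids = ids
        if not (self.compat.shape == self.starts.shape == self.lengths.shape):
            raise ValueError("compat/starts/lengths shapes differ")

    def __len__(self):
        return self.compat.shape[0]

    @property
    def n_transcripts(self):
        return self.compat.shape[1]

    @classmethod
    def from_observations(
        cls,
        locus: GeneLocus,
        observations: list[FragmentObservation],
        single_end: bool = False,
    ) -> "FragmentTable":
        tindex = {t.id: i for i, t in enumerate(locus.transcripts)}
        R, N = len(observations), locus.n_transcripts
        compat = np.zeros((R, N), dtype=bool)
        starts = np.zeros((R, N), dtype=np.int64)
        lengths = np.zeros((R, N), dtype=np.int64)
        ids = []
        for r, obs in enumerate(observations):
            ids.append(obs.id)
            for tid, (s, l) in obs.compatibility.items():
                i = tindex.get(tid)
                if i is None:
                    continue
                compat[r, i] = True
                starts[r, i] = s
                lengths[r, i] = 0 if l is None else l
        return cls(compat, starts, lengths, single_end=single_end, ids=ids)

    def to_observations(self, locus: GeneLocus) -> list[FragmentObservation]:
        out = []
        for r in range(len(self)):
            comp = {}
            for i in np.nonzero(self.compat[r])[0]:
                l = int(self.lengths[r, i])
                comp[locus.transcripts[i].id] = (
                    int(self.starts[r, i]),
                    None if (self.single_end or l == 0) else l,
                )
            out.append(FragmentObservation(id=str(r) if self.ids is None else self.ids[r], compatibility=comp))
        return out


# ---------------------------------------------------------------------------
# update rules


def initialize_parameters(n_transcripts: int, group_of, n_components: int) -> Mix2Parameters:
    """Uniform start: alpha_i = 1/N, beta_kj = 1/M."""
    if n_transcripts < 1 or n_components < 1:
        raise ValueError("need at least one transcript and one component")
    group_of = np.asarray(group_of, dtype=np.int64)
    n_groups = int(group_of.max()) + 1
    alpha = np.full(n_transcripts, 1.0 / n_transcripts)
    beta = np.full((n_groups, n_components), 1.0 / n_components)
    return Mix2Parameters(alpha=alpha, beta=beta, group_of=group_of)


def _component_likelihoods(
    locus: GeneLocus,
    table: FragmentTable,
    n_components: int,
    length_model: FragmentLengthModel,
) -> np.ndarray:
    """W[r, i, j] = p(l(r)|t=i, s(r)) * p(s(r)|t=i, b=j); 0 if incompatible."""
    R, N = len(table), locus.n_transcripts
    W = np.zeros((R, N, n_components))
    for i, t in enumerate(locus.transcripts):
        rows = np.nonzero(table.compat[:, i])[0]
        if len(rows) == 0:
            continue
        mix = build_position_components(t.length, n_components)
        s = table.starts[rows, i]
        comp = mix.tables[:, s - 1].T  # (Ri, M)
        if length_model.single_end or table.single_end:
            lf = 1.0
        else:
            lf = length_model.probabilities(
                table.lengths[rows, i], t.length - s + 1
            )[:, None]
        W[rows, i, :] = comp * lf
    return W


def _posteriors(W: np.ndarray, params: Mix2Parameters):
    """E-step kernel: joint posteriors p(t=i, b=j | r) and log-likelihood."""
    numer = W * params.alpha[None, :, None] * params.beta[params.group_of][None, :, :]
    p_r = numer.sum(axis=(1, 2))
    ok = p_r > 0
    post = np.zeros_like(numer)
    post[ok] = numer[ok] / p_r[ok, None, None]
    loglik = float(np.log(p_r[ok]).sum())
    return post, p_r, loglik


@dataclass
class EStepResult:
    posteriors: np.ndarray  # (R', N, M) over retained fragments
    retained: np.ndarray  # indices of retained fragments
    n_dropped: int
    log_likelihood: float


def e_step(
    locus: GeneLocus,
    fragments,
    params: Mix2Parameters,
    length_model: FragmentLengthModel | None = None,
) -> EStepResult:
    """Posterior table p(t=i, b=j | r) for every retained fragment.

    Fragments with p(r)=0 (compatible with nothing, or of impossible
    length) are dropped with a logged count.
    """
    length_model = length_model or FragmentLengthModel()
    table = (
        fragments
        if isinstance(fragments, FragmentTable)
        else FragmentTable.from_observations(locus, fragments)
    )
    W = _component_likelihoods(locus, table, params.n_components, length_model)
    post, p_r, loglik = _posteriors(W, params)
    keep = p_r > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d fragments with zero locus probability", n_dropped)
    if not keep.any():
        raise DegenerateInputError("all fragments have zero locus probability")
    return EStepResult(post[keep], np.nonzero(keep)[0], n_dropped, loglik)


def update_alpha(posteriors: np.ndarray) -> np.ndarray:
    """alpha_i <- (1/R) sum_r p(t=i | r)."""
    if len(posteriors) == 0:
        raise ValueError("empty posterior table")
    return posteriors.sum(axis=2).mean(axis=0)


def update_beta(
    posteriors: np.ndarray,
    group_of,
    previous_beta: np.ndarray | None = None,
) -> np.ndarray:
    """beta_kj <- sum_r p(g=k, b=j | r) / sum_r p(g=k | r).

    A group with zero posterior mass keeps its previous row (uniform if no
    previous beta is supplied); the event is logged.
    """
    if len(posteriors) == 0:
        raise ValueError("empty posterior table")
    group_of = np.asarray(group_of, dtype=np.int64)
    n_groups = int(group_of.max()) + 1
    M = posteriors.shape[2]
    per_transcript = posteriors.sum(axis=0)  # (N, M)
    num = np.zeros((n_groups, M))
    np.add.at(num, group_of, per_transcript)
    denom = num.sum(axis=1, keepdims=True)
    beta = np.empty_like(num)
    zero = denom[:, 0] <= 0
    nz = ~zero
    beta[nz] = num[nz] / denom[nz]
    if zero.any():
        logger.info("%d tying groups with zero posterior mass keep previous beta", int(zero.sum()))
        if previous_beta is not None:
            beta[zero] = previous_beta[zero]
        else:
            beta[zero] = 1.0 / M
    return beta


# ---------------------------------------------------------------------------
# group tying


def build_length_groups(locus: GeneLocus) -> GroupAssignment:
    """Bin transcripts by length into the 7-boundary log-equidistant bins
    between 300 and 5000 bp; lengths below 300 fall in the first bin and
    lengths of 5000 or more in the last; empty bins are removed."""
    lengths = np.array([t.length for t in locus.transcripts], dtype=float)
    # bin k covers [b_k, b_{k+1}); 6 bins for 7 boundaries
    bins = np.clip(np.searchsorted(GROUP_BOUNDARIES, lengths, side="right") - 1, 0, 5)
    groups, means = [], []
    for b in range(6):
        members = list(np.nonzero(bins == b)[0])
        if members:
            groups.append(members)
            means.append(float(lengths[members].mean()))
    return GroupAssignment(groups=groups, mean_length=means, valid_read_count=[0] * len(groups))


def group_distance(mean1: float, mean2: float) -> float:
    """Percent relative difference of group mean lengths:
    |m1 - m2| / min(m1, m2) * 100."""
    return abs(mean1 - mean2) / min(mean1, mean2) * 100.0


def _valid_read_counts(assignment: GroupAssignment, compat: np.ndarray) -> list[int]:
    # a read is valid for a group if compatible with >= 1 member transcript
    return [int(compat[:, members].any(axis=1).sum()) for members in assignment.groups]


def merge_groups(
    assignment: GroupAssignment,
    fragments,
    locus: GeneLocus | None = None,
    min_valid_reads: int = 20,
) -> GroupAssignment:
    """Merge the closest groups until every group has >= ``min_valid_reads``
    valid reads and at most one group is a singleton.  Ties break toward the
    lowest pair of group indices.  A locus may collapse to a single group."""
    if isinstance(fragments, FragmentTable):
        compat = fragments.compat
    else:
        if locus is None:
            raise ValueError("locus required to interpret fragment observations")
        compat = FragmentTable.from_observations(locus, fragments).compat
    groups = [list(g) for g in assignment.groups]
    means = list(assignment.mean_length)

    def constraints_ok(counts):
        if any(c < min_valid_reads for c in counts):
            return False
        return sum(1 for g in groups if len(g) == 1) <= 1

    counts = _valid_read_counts(GroupAssignment(groups, means, [0] * len(groups)), compat)
    while len(groups) > 1 and not constraints_ok(counts):
        best, best_d = None, np.inf
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                d = group_distance(means[a], means[b])
                if d < best_d - 1e-12:
                    best, best_d = (a, b), d
        a, b = best
        # mean of member lengths = size-weighted mean of the two group means
        na, nb = len(groups[a]), len(groups[b])
        merged_mean = (na * means[a] + nb * means[b]) / (na + nb)
        merged = groups[a] + groups[b]
        groups = [g for i, g in enumerate(groups) if i not in (a, b)]
        means = [m for i, m in enumerate(means) if i not in (a, b)]
        groups.insert(a, merged)
        means.insert(a, merged_mean)
        counts = _valid_read_counts(GroupAssignment(groups, means, [0] * len(groups)), compat)
    return GroupAssignment(groups=groups, mean_length=means, valid_read_count=counts)


# ---------------------------------------------------------------------------
# the fitted-model surface


def fpkm_from_result(result: "Mix2Results", total_mapped_fragments: int) -> np.ndarray:
    """FPKM_i = c_i * 1e9 / (l_i * total_mapped_fragments)."""
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    lengths = np.array([t.length for t in result.locus.transcripts], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("zero transcript length")
    if total_mapped_fragments < round(result.expected_counts.sum()) - 1:
        raise ValueError("total mapped fragments below locus fragment count")
    return result.expected_counts * 1e9 / (lengths * total_mapped_fragments)


class Mix2Model:
    """The Mix² mixture-of-mixtures model for one gene locus.

    Parameters
    ----------
    locus : GeneLocus
        The gene and its N isoforms.
    fragments : list[FragmentObservation] | FragmentTable
        Aligned fragments with per-isoform placements.
    tying : str or TyingScheme
        ``none``, ``global`` or ``group`` (default) beta sharing.
    n_components : int, optional
        Positional mixture size M; defaults to 3 (no tying) or 4 (tying).
    length_model : FragmentLengthModel, optional
        Gaussian(200, 80) paired-end model by default; pass
        ``mode="single_end_unit"`` for single-end data.
    config : EMConfig, optional
        Convergence control.
    """

    def __init__(
        self,
        locus: GeneLocus,
        fragments,
        tying="group",
        n_components: int | None = None,
        length_model: FragmentLengthModel | None = None,
        config: EMConfig | None = None,
        min_valid_reads: int = 20,
    ):
        self.locus = locus
        self.tying = tying if isinstance(tying, TyingScheme) else TyingScheme(tying, n_components)
        self.length_model = length_model or FragmentLengthModel()
        self.config = config or EMConfig()
        self.min_valid_reads = min_valid_reads
        self.table = (
            fragments
            if isinstance(fragments, FragmentTable)
            else FragmentTable.from_observations(
                locus, fragments, single_end=self.length_model.single_end
            )
        )
        if self.table.n_transcripts != locus.n_transcripts:
            raise ValueError("fragment table does not match locus")

    @classmethod
    def from_alignments(
        cls, gtf_path, sam_path, gene_id, single_end=False, **kwargs
    ) -> "Mix2Model":
        """Build a model for one gene straight from a GTF and a SAM/BAM."""
        from . import io as _io

        index = _io.read_annotation(gtf_path)
        locus = index.loci[gene_id]
        cfg = _io.FragmentExtractionConfig(mode="single" if single_end else "paired")
        per_locus = _io.extract_fragments(sam_path, index, cfg)
        frags = per_locus.get(gene_id, [])
        if single_end:
            kwargs.setdefault("length_model", FragmentLengthModel(mode="single_end_unit"))
        return cls(locus, frags, **kwargs)

    def build_groups(self) -> GroupAssignment:
        """The tying partition implied by the scheme (after merging for
        ``group`` mode)."""
        N = self.locus.n_transcripts
        lengths = [float(t.length) for t in self.locus.transcripts]
        if self.tying.mode == "none":
            groups = [[i] for i in range(N)]
            means = lengths
        elif self.tying.mode == "global":
            groups = [list(range(N))]
            means = [float(np.mean(lengths))]
        else:
            initial = build_length_groups(self.locus)
            merged = merge_groups(
                initial, self.table, locus=self.locus, min_valid_reads=self.min_valid_reads
            )
            groups, means = merged.groups, merged.mean_length
        ga = GroupAssignment(groups=groups, mean_length=means, valid_read_count=[0] * len(groups))
        ga.valid_read_count = _valid_read_counts(ga, self.table.compat)
        return ga

    def fit(self) -> "Mix2Results":
        if len(self.table) == 0:
            raise DegenerateInputError("no fragments to fit")
        groups = self.build_groups()
        group_of = groups.group_of_array(self.locus.n_transcripts)
        M = self.tying.n_components
        params = initialize_parameters(self.locus.n_transcripts, group_of, M)

        W = _component_likelihoods(self.locus, self.table, M, self.length_model)
        keep = W.sum(axis=(1, 2)) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("locus %s: dropped %d unusable fragments", self.locus.gene_id, n_dropped)
        W = W[keep]
        if len(W) == 0:
            raise DegenerateInputError("all fragments have zero locus probability")

        loglik_path = []
        converged = False
        alpha, beta = params.alpha, params.beta
        for it in range(1, self.config.max_iterations + 1):
            post, _, loglik = _posteriors(
                W, Mix2Parameters(alpha=alpha, beta=beta, group_of=group_of)
            )
            loglik_path.append(loglik)
            new_alpha = update_alpha(post)
            new_beta = update_beta(post, group_of, previous_beta=beta)
            d_param = max(
                float(np.abs(new_alpha - alpha).max()),
                float(np.abs(new_beta - beta).max()),
            )
            d_ll = (
                abs(loglik - loglik_path[-2]) / (abs(loglik_path[-2]) + 1e-300)
                if len(loglik_path) > 1
                else np.inf
            )
            alpha, beta = new_alpha, new_beta
            if d_param < self.config.param_tol or d_ll < self.config.loglik_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.config.max_iterations} iterations "
                f"for locus {self.locus.gene_id}",
                RuntimeWarning,
            )
        params = Mix2Parameters(alpha=alpha, beta=beta, group_of=group_of)
        return Mix2Results(
            model=self,
            params=params,
            groups=groups,
            n_fragments=len(W),
            n_dropped=n_dropped,
            loglik_path=np.array(loglik_path),
            n_iter=len(loglik_path),
            converged=converged,
        )


class Mix2Results:
    """Fitted Mix² parameters for one locus, with derived quantities."""

    def __init__(self, model, params, groups, n_fragments, n_dropped, loglik_path, n_iter, converged):
        self.model = model
        self.locus = model.locus
        self.params = params
        self.groups = groups
        self.n_fragments = n_fragments
        self.n_dropped = n_dropped
        self.loglik_path = loglik_path
        self.n_iter = n_iter
        self.converged = converged

    @property
    def alpha(self) -> np.ndarray:
        """Relative isoform abundances (sum to 1)."""
        return self.params.alpha

    @property
    def beta(self) -> np.ndarray:
        """Component weights, one row per tying group (rows sum to 1)."""
        return self.params.beta

    @property
    def log_likelihood(self) -> float:
        return float(self.loglik_path[-1])

    @property
    def expected_counts(self) -> np.ndarray:
        """c_i = R * alpha_i over retained fragments."""
        return self.n_fragments * self.alpha

    def start_distribution(self, i: int) -> np.ndarray:
        """Estimated fragment-start distribution p(s | t=i), s = 1..l(t)."""
        t = self.locus.transcripts[i]
        mix = build_position_components(t.length, self.params.n_components)
        return mix.render(self.params.beta_of_transcript(i))

    def start_distributions(self) -> list[np.ndarray]:
        return [self.start_distribution(i) for i in range(self.locus.n_transcripts)]

    def fpkm(self, total_mapped_fragments: int) -> np.ndarray:
        return fpkm_from_result(self, total_mapped_fragments)

    def summary(self) -> str:
        lines = [
            f"Mix2 quantification: locus {self.locus.gene_id}",
            f"  tying={self.model.tying.mode}  M={self.params.n_components}  "
            f"groups={self.groups.n_groups}",
            f"  fragments={self.n_fragments} (dropped {self.n_dropped})  "
            f"iterations={self.n_iter}  converged={self.converged}",
            f"  log-likelihood={self.log_likelihood:.4f}",
            "",
            f"  {'transcript':<20}{'length':>8}{'group':>7}{'alpha':>10}{'count':>10}",
        ]
        for i, t in enumerate(self.locus.transcripts):
            lines.append(
                f"  {t.id:<20}{t.length:>8}{self.params.group_of[i]:>7}"
                f"{self.alpha[i]:>10.4f}{self.expected_counts[i]:>10.1f}"
            )
        return "\n".join(lines)
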