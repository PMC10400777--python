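"""Synthetic cohorts with known, score-coupled covariance structure.

The generator plants a latent shared factor on designated region pairs so
that a subject's contribution to those edges' group correlation — exactly
what the jackknife pseudovalue measures — is monotone in the subject's
severity score. That is the minimal structure CPM on individualized SCNs
assumes, which makes parameter recovery quantifiable end to end.

Generative model (one RNG stream, fixed draw order; reordering draws is a
breaking change):

1. scores ``s_i ~ Normal(6, 2.5)`` clipped to the FTND range [0, 10], then
   standardized within the sample to ``z_i``;
2. baselines ``x_ij = mu_j + eps_ij`` with region means ``mu_j ~
   Normal(500, 50)`` drawn once and ``eps_ij ~ Normal(0, noise_sd)``;
3. for each signal edge (a, b), in sorted order (positive set first), a
   shared factor ``u_i ~ Normal(0, 1)`` is added to both regions with
   loading ``lam_i = max(0, base_load + coupling * z_i)`` for positive
   edges and ``max(0, base_load - coupling * z_i)`` for negative edges;
4. covariates TIV ``~ Normal(1.5e6, 1.5e5)`` mm^3, IQR ``~ Normal(2.06,
   0.11)`` and age ``~ Normal(35, 7.3)`` years, all independent of score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from scn_cpm.atlas_io import CohortGMV

Edge = tuple[int, int]


def _normalize_edges(edges) -> tuple[Edge, ...]:
    out = []
    for e in edges:
        i, j = int(e[0]), int(e[1])
        if not i < j:
            raise ValueError(f"edge ({i}, {j}) must have i < j")
        out.append((i, j))
    if len(set(out)) != len(out):
        raise ValueError("duplicate signal edges")
    return tuple(sorted(out))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth signal structure of a synthetic cohort.

    ``coupling`` (beta) scales how strongly an edge's loading follows the
    standardized score; ``base_load`` (lambda0) is the score-independent
    co-deviation; loadings are clamped at zero. ``noise_sd`` is the
    independent per-region noise standard deviation, on the same scale as
    the loadings.
    """

    pos_edges: tuple[Edge, ...] = ()
    neg_edges: tuple[Edge, ...] = ()
    coupling: float = 0.8
    base_load: float = 1.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_edges", _normalize_edges(self.pos_edges))
        object.__setattr__(self, "neg_edges", _normalize_edges(self.neg_edges))
        if set(self.pos_edges) & set(self.neg_edges):
            raise ValueError("pos_edges and neg_edges must be disjoint")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.base_load <= 0:
            raise ValueError("base_load must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_cohort(
    n_subjects: int, n_regions: int, truth: SyntheticTruth
) -> tuple[CohortGMV, SyntheticTruth]:
    """Draw one cohort under the generative model; echoes the truth back.

    Fully deterministic given ``truth.seed``: two calls with identical
    arguments return identical cohorts.
    """
    if n_subjects < 4:
        raise ValueError("n_subjects must be >= 4")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    for i, j in truth.pos_edges + truth.neg_edges:
        if j >= n_regions:
            raise ValueError(f"edge ({i}, {j}) outside the {n_regions}-region atlas")

    rng = np.random.default_rng(truth.seed)

    score = np.clip(rng.normal(6.0, 2.5, n_subjects), 0.0, 10.0)
    sd = score.std()
    if sd == 0.0:
        raise ValueError("degenerate draw: constant score")
    z = (score - score.mean()) / sd

    mu = rng.normal(500.0, 50.0, n_regions)
    gmv = mu[None, :] + rng.normal(0.0, truth.noise_sd, (n_subjects, n_regions))

    for (a, b), sign in [(e, +1.0) for e in truth.pos_edges] + [
        (e, -1.0) for e in truth.neg_edges
    ]:
        u = rng.normal(0.0, 1.0, n_subjects)
        lam = np.maximum(0.0, truth.base_load + sign * truth.coupling * z)
        gmv[:, a] += lam * u
        gmv[:, b] += lam * u

    covariates = {
        "TIV": rng.normal(1.5e6, 1.5e5, n_subjects),
        "IQR": rng.normal(2.06, 0.11, n_subjects),
        "age": rng.normal(35.0, 7.3, n_subjects),
    }
    cohort = CohortGMV(
        subject_ids=[f"S{i + 1:04d}" for i in range(n_subjects)],
        gmv=gmv,
        score=score,
        covariates=covariates,
    )
    return cohort, truth


def null_cohort(n_subjects: int, n_regions: int, seed: int) -> CohortGMV:
    """A cohort with no signal edges: score independent of GMV by construction."""
    truth = SyntheticTruth(pos_edges=(), neg_edges=(), coupling=0.0, seed=seed)
    cohort, _ = generate_cohort(n_subjects, n_regions, truth)
    return cohort


def random_signal_edges(
    n_regions: int, n_pos: int, n_neg: int, seed: int
) -> tuple[tuple[Edge, ...], tuple[Edge, ...]]:
    """Sample disjoint positive/negative edge sets uniformly without replacement."""
    E = n_regions * (n_regions - 1) // 2
    if n_pos + n_neg > E:
        raise ValueError("more signal edges requested than pairs available")
    iu = np.triu_indices(n_regions, k=1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(E, size=n_pos + n_neg, replace=False)
    pairs = [(int(iu[0][k]), int(iu[1][k])) for k in chosen]
    return tuple(sorted(pairs[:n_pos])), tuple(sorted(pairs[n_pos:]))
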