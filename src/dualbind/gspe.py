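"""Global stochastic projection embedding (GSPE).

Variable-length residue-embedding matrices are turned into fixed-width,
permutation-invariant global signatures by projecting every residue vector
onto random unit directions, sorting the projections, and summarizing each
sorted vector by fixed quantiles.  Antibody/antigen signatures from ``n``
independent projection sets are compared by trainable scaled squared
distances, mapped through a softplus to a strictly positive pair feature.

The projection bases are frozen at construction (saved, never trained); only
the per-coordinate scales sigma are learnable.  Sorting is what buys exact
permutation invariance: reordering residues reorders the raw projections but
not their sorted vector.  Because protein lengths vary, each sorted
projection is summarized by ``q`` linearly interpolated quantiles, giving a
fixed ``m * q`` signature per projection set; with uniform lengths, ``q = L``
reproduces the sorted vector exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import softplus


class GspeConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ProjectionBasis:
    """One frozen set of ``m`` random unit projection directions in R^d."""

    vectors: np.ndarray   # (m, d), rows unit-norm
    seed: int
    set_index: int

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise GspeConfigurationError("basis rows must have unit Euclidean norm")


@dataclass(frozen=True)
class GspeSignature:
    """Sorted-projection quantile signature for one protein and one basis set."""

    per_projection: np.ndarray   # (m, q), each row non-decreasing

    @property
    def flat(self) -> np.ndarray:
        return self.per_projection.reshape(-1)


@dataclass(frozen=True)
class PairFeature:
    """Scaled squared signature distances and their softplus, one per basis set."""

    distances: np.ndarray   # (n_sets,), >= 0
    h_pair: np.ndarray      # (n_sets,), > 0
    sigma: np.ndarray       # (m*q,), > 0


def build_basis(m: int, d: int, n_sets: int, seed: int) -> list[ProjectionBasis]:
    """Draw ``n_sets`` independent bases of ``m`` unit directions in R^d.

    Rows are sampled i.i.d. from N(0, I_d) and normalized to the unit
    hypersphere.  Reproducible: identical (m, d, n_sets, seed) gives
    bit-identical bases; distinct set indices use independently spawned
    streams.
    """
    if m < 1 or d < 1 or n_sets < 1:
        raise GspeConfigurationError("m, d, and n_sets must all be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_sets)
    bases = []
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        vecs = rng.standard_normal((m, d))
        vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        bases.append(ProjectionBasis(vectors=vecs, seed=seed, set_index=idx))
    return bases


def project_sort(x: np.ndarray, basis: ProjectionBasis, q: int) -> GspeSignature:
    """Project residues onto each basis direction, sort, summarize by quantiles.

    For projection ``i``: compute ``X @ r_i`` (length L), sort ascending, and
    take ``q`` quantiles at probabilities linspace(0, 1, q) with linear
    interpolation.  ``q = L`` reproduces the sorted vector itself.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError(f"expected non-empty L x d matrix, got shape {x.shape}")
    m, d = basis.vectors.shape
    if x.shape[1] != d:
        raise ValueError(f"embedding width {x.shape[1]} != basis width {d}")
    if q < 1:
        raise GspeConfigurationError("q must be >= 1")
    # einsum (not BLAS matmul): each projection is an independent fixed-order
    # sum, so the result is bit-identical under any row permutation of x
    proj = np.einsum("ld,md->lm", x, basis.vectors)   # (L, m)
    probs = np.linspace(0.0, 1.0, q) if q > 1 else np.array([0.5])
    sig = np.quantile(proj, probs, axis=0, method="linear").T   # (m, q)
    return GspeSignature(per_projection=sig)


def compute_signatures(
    x: np.ndarray, bases: list[ProjectionBasis], q: int
) -> list[GspeSignature]:
    """Signature per projection set for one protein's embedding matrix."""
    return [project_sort(x, basis, q) for basis in bases]


def pair_feature(
    sigs_a: list[GspeSignature] | GspeSignature,
    sigs_b: list[GspeSignature] | GspeSignature,
    sigma: np.ndarray,
) -> PairFeature:
    """Aggregate two proteins' signatures into the pair feature.

    ``distances[i] = sum_j ((a_ij - b_ij) / sigma_j)^2`` over the flat
    signature of projection set ``i``; ``h_pair = log(1 + exp(distances))``,
    strictly positive.  Symmetric in (a, b).
    """
    if isinstance(sigs_a, GspeSignature):
        sigs_a = [sigs_a]
    if isinstance(sigs_b, GspeSignature):
        sigs_b = [sigs_b]
    if len(sigs_a) != len(sigs_b):
        raise ValueError(f"signature set counts differ: {len(sigs_a)} vs {len(sigs_b)}")
    sigma = np.asarray(sigma, dtype=np.float64).reshape(-1)
    if np.any(sigma <= 0):
        raise ValueError("sigma entries must be strictly positive")
    dists = np.empty(len(sigs_a))
    for i, (sa, sb) in enumerate(zip(sigs_a, sigs_b)):
        fa, fb = sa.flat, sb.flat
        if fa.shape != fb.shape:
            raise ValueError(f"set {i}: signature shapes differ: {fa.shape} vs {fb.shape}")
        if fa.size != sigma.size:
            raise ValueError(
                f"set {i}: signature length {fa.size} != sigma length {sigma.size}"
            )
        dists[i] = np.sum(((fa - fb) / sigma) ** 2)
    return PairFeature(distances=dists, h_pair=np.asarray(softplus(dists)), sigma=sigma)
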