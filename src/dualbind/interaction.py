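"""Residue-to-residue interaction module.

Per-residue embeddings are compressed position-wise to scalar interaction
potentials by a shared KAN stack; the outer product of the antibody and
antigen potential vectors forms a parameter-free pairwise interaction map
(rank <= 1 by construction, a complete "contact grid" over all residue
pairs).  The map, concatenated with the antibody potentials, is refined by a
second KAN stack into an interaction-aware per-antibody-residue
representation.

Because the refinement stack has a fixed input width while antigens vary in
length, the antigen axis is padded to a configured maximum with a boolean
mask; masked columns are excluded from the refinement entirely (their edge
contributions are zeroed, see :mod:`dualbind.kan`), so extending the padding
never changes the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kan import KanStack


@dataclass(frozen=True)
class CompressedPotentials:
    """Scalar interaction potentials, one per residue of each chain."""

    v_ab: np.ndarray
    v_ag: np.ndarray


@dataclass(frozen=True)
class InteractionMap:
    """Pairwise antibody x antigen interaction matrix and its refinement."""

    m_inter: np.ndarray       # (L_ab, L_ag)
    m_concat: np.ndarray      # (L_ab, L_ag_max + 1), padded antigen cols zero
    h_aa: np.ndarray          # (L_ab,)
    mask_ag: np.ndarray       # (L_ag_max,) bool, True at valid antigen columns


def compress(x: np.ndarray, stack: KanStack) -> np.ndarray:
    """Compress an ``L x D`` embedding matrix to one scalar per residue.

    The stack is applied position-wise with shared parameters, so identical
    embedding rows always map to identical scalars.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected L x D matrix, got shape {x.shape}")
    if stack.out_width not in (None, 1):
        raise ValueError(f"compression stack must end in width 1, got {stack.out_width}")
    out = stack.forward(x)
    return out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out.reshape(len(x))


def outer_interaction(v_ab: np.ndarray, v_ag: np.ndarray) -> np.ndarray:
    """Pairwise interaction matrix ``M[i, j] = v_ab[i] * v_ag[j]``."""
    v_ab = np.asarray(v_ab, dtype=np.float64).reshape(-1)
    v_ag = np.asarray(v_ag, dtype=np.float64).reshape(-1)
    if v_ab.size == 0 or v_ag.size == 0:
        raise ValueError("potential vectors must be non-empty")
    if not (np.all(np.isfinite(v_ab)) and np.all(np.isfinite(v_ag))):
        raise ValueError("potential vectors must be finite")
    return np.outer(v_ab, v_ag)


def pad_interaction(
    m_inter: np.ndarray, v_ab: np.ndarray, l_ag_max: int,
    mask_ag: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pad the antigen axis to ``l_ag_max`` and append the antibody potentials.

    Returns ``(m_concat, full_mask)`` where ``m_concat`` is
    (L_ab, l_ag_max + 1) with antigen columns first and the antibody column
    last, and ``full_mask`` marks valid inputs for the refinement stack.
    """
    m_inter = np.asarray(m_inter, dtype=np.float64)
    v_ab = np.asarray(v_ab, dtype=np.float64).reshape(-1)
    l_ab, l_ag = m_inter.shape
    if l_ab != v_ab.size:
        raise ValueError(f"row count {l_ab} != antibody length {v_ab.size}")
    if mask_ag is None:
        mask_ag = np.zeros(l_ag_max, dtype=bool)
        mask_ag[:l_ag] = True
    else:
        mask_ag = np.asarray(mask_ag, dtype=bool)
        if mask_ag.size != l_ag_max:
            raise ValueError(f"mask length {mask_ag.size} != padded width {l_ag_max}")
    if l_ag > l_ag_max:
        raise ValueError(f"antigen length {l_ag} exceeds padded width {l_ag_max}")
    m_concat = np.zeros((l_ab, l_ag_max + 1))
    m_concat[:, :l_ag] = m_inter
    m_concat[:, -1] = v_ab
    full_mask = np.concatenate([mask_ag, [True]]).astype(bool)
    return m_concat, full_mask


def concat_refine(
    m_inter: np.ndarray,
    v_ab: np.ndarray,
    refine_stack: KanStack,
    mask_ag: np.ndarray | None = None,
    l_ag_max: int | None = None,
) -> np.ndarray:
    """Refine the padded interaction map row-wise into ``h_aa`` (length L_ab)."""
    m_inter = np.asarray(m_inter, dtype=np.float64)
    if l_ag_max is None:
        l_ag_max = (refine_stack.in_width - 1) if refine_stack.in_width else m_inter.shape[1]
    m_concat, full_mask = pad_interaction(m_inter, v_ab, l_ag_max, mask_ag)
    if refine_stack.in_width is not None and refine_stack.in_width != m_concat.shape[1]:
        raise ValueError(
            f"refinement stack expects width {refine_stack.in_width}, "
            f"got {m_concat.shape[1]}"
        )
    mask_rows = np.broadcast_to(full_mask, m_concat.shape)
    out = refine_stack.forward(m_concat, input_mask=np.asarray(mask_rows, dtype=np.float64))
    h_aa = out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out.reshape(len(m_concat))
    if not np.all(np.isfinite(h_aa)):
        raise ValueError("refinement produced non-finite values")
    return h_aa


def build_interaction_map(
    x_ab: np.ndarray,
    x_ag: np.ndarray,
    compress_stack: KanStack,
    refine_stack: KanStack,
    l_ag_max: int | None = None,
) -> InteractionMap:
    """Full single-pair pipeline: compress, outer product, pad, refine."""
    v_ab = compress(x_ab, compress_stack)
    v_ag = compress(x_ag, compress_stack)
    m_inter = outer_interaction(v_ab, v_ag)
    if l_ag_max is None:
        l_ag_max = (refine_stack.in_width - 1) if refine_stack.in_width else m_inter.shape[1]
    m_concat, full_mask = pad_interaction(m_inter, v_ab, l_ag_max)
    h_aa = concat_refine(m_inter, v_ab, refine_stack, mask_ag=full_mask[:-1], l_ag_max=l_ag_max)
    return InteractionMap(m_inter=m_inter, m_concat=m_concat, h_aa=h_aa, mask_ag=full_mask[:-1])
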