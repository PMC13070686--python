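"""Dual-level affinity model: interaction module + global projection embedding
fused into a feed-forward head, with training, evaluation, and checkpointing.

The model predicts pK_D for an antibody-antigen pair from per-residue
embeddings.  Two parallel representations are fused:

* the residue-to-residue branch compresses embeddings to scalar potentials,
  forms the pairwise outer-product interaction map, and refines it into a
  per-antibody-residue vector ``h_aa`` which is mean- and max-pooled;
* the global branch compares sorted-random-projection signatures of the two
  chains through trainable scaled squared distances (``h_pair``).

The pooled local block and the global block are concatenated and passed to a
small feed-forward head; ablation variants drop one block.  Everything is
plain NumPy with hand-derived gradients; training uses AdamW with early
stopping on validation MAE and is bit-reproducible for a fixed seed on one
device.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingProvider, MockEmbeddingProvider, embed
from .gspe import build_basis, compute_signatures
from .kan import KanStack
from .metrics import EvalReport, evaluate, mae, mse_loss
from .nn import MLP, AdamW, sigmoid, softplus, softplus_inverse
from .sequences import AffinityRecord

SCHEMA_VERSION = 1

VARIANTS = ("full", "no_r2r", "no_gspe")


class TrainingDivergedError(RuntimeError):
    pass


class IncompatibleProviderError(RuntimeError):
    pass


class SequenceTooLongError(ValueError):
    """Raised instead of silently truncating an over-long chain."""


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    ``l_ag_max`` fixes the refinement-stack input width (antigen axis padded
    to this length); ``l_ab_max`` only bounds antibody length validation.
    """

    variant: str = "full"
    embed_dim: int = 32
    compress_hidden: tuple[int, ...] = ()
    refine_hidden: tuple[int, ...] = ()
    share_compress: bool = False
    num_harmonics: int = 2
    l_ab_max: int = 256
    l_ag_max: int = 96
    gspe_m: int = 64
    gspe_q: int = 16
    gspe_n_sets: int = 8
    basis_seed: int = 0
    head_hidden: tuple[int, ...] = (32, 32)
    compute_dtype: str = "float32"
    spectral_init: bool = True      # warm-start compression from the label cross-moment
    lr_schedule: str = "cosine"     # "cosine" (decay to lr/10) or "constant"
    lr: float = 1e-2
    weight_decay: float = 1e-3
    clip_norm: float = 5.0
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.compress_hidden = tuple(self.compress_hidden)
        self.refine_hidden = tuple(self.refine_hidden)
        self.head_hidden = tuple(self.head_hidden)

    @property
    def uses_r2r(self) -> bool:
        return self.variant in ("full", "no_gspe")

    @property
    def uses_gspe(self) -> bool:
        return self.variant in ("full", "no_r2r")

    @property
    def head_in_width(self) -> int:
        width = 0
        if self.uses_r2r:
            width += 2                      # mean- and max-pooled h_aa
        if self.uses_gspe:
            width += self.gspe_n_sets       # h_pair block
        return width

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class TrainResult:
    log: list[dict]
    best_epoch: int
    best_val_mae: float


class AffinityModel:
    """The assembled dual-level predictor (see module docstring)."""

    def __init__(self, config: ModelConfig, provider: EmbeddingProvider):
        if provider.dim != config.embed_dim:
            raise IncompatibleProviderError(
                f"provider dim {provider.dim} != configured embed_dim {config.embed_dim}"
            )
        self.config = config
        self.provider = provider
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
        cfg = config
        dtype = np.dtype(cfg.compute_dtype)
        self._dtype = dtype
        if cfg.uses_r2r:
            widths = (cfg.embed_dim, *cfg.compress_hidden, 1)
            self.compress_ab = KanStack.from_widths(widths, cfg.num_harmonics, rng, dtype=dtype)
            self.compress_ag = (
                self.compress_ab if cfg.share_compress
                else KanStack.from_widths(widths, cfg.num_harmonics, rng, dtype=dtype)
            )
            self.refine_stack = KanStack.from_widths(
                (cfg.l_ag_max + 1, *cfg.refine_hidden, 1), cfg.num_harmonics, rng,
                dtype=dtype,
            )
            # aggregation prior: start the refinement as a near-uniform sum over
            # antigen columns so gradient signal reaches the antigen potentials
            # from the first step (a random init tends to silence that pathway)
            first = self.refine_stack.layers[0]
            scale = 1.0 / np.sqrt(first.spec.in_width)
            first.weight[...] = scale * (1.0 + 0.1 * rng.standard_normal(first.weight.shape))
        else:
            self.compress_ab = None
            self.compress_ag = None
            self.refine_stack = None
        if cfg.uses_gspe:
            self.bases = build_basis(cfg.gspe_m, cfg.embed_dim, cfg.gspe_n_sets, cfg.basis_seed)
            self.rho = np.full(cfg.gspe_m * cfg.gspe_q, float(softplus_inverse(1.0)))
            self._sigma_initialized = False
        else:
            self.bases = None
            self.rho = None
            self._sigma_initialized = True
        self.head = MLP((cfg.head_in_width, *cfg.head_hidden, 1), rng)
        # linear bypass around the head: gives every fused feature a direct,
        # init-independent gradient path to the output (the nonlinear head
        # alone can gate a branch off before it has learned anything)
        self.skip = np.zeros(cfg.head_in_width)
        self.label_mean = 0.0
        # frozen affine feature normalization fitted at train start (identity
        # until then); keeps the head input scale stable as branches train
        self.feature_loc = np.zeros(cfg.head_in_width)
        self.feature_scale = np.ones(cfg.head_in_width)
        self._embed_cache: dict[str, np.ndarray] = {}
        self._sig_cache: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ data

    def _embedding(self, seq) -> np.ndarray:
        m = self._embed_cache.get(seq.residues)
        if m is None:
            m = embed(seq, self.provider)
            self._embed_cache[seq.residues] = m
        return m

    def _signature(self, seq) -> np.ndarray:
        s = self._sig_cache.get(seq.residues)
        if s is None:
            sigs = compute_signatures(self._embedding(seq), self.bases, self.config.gspe_q)
            s = np.stack([sg.flat for sg in sigs])     # (n_sets, m*q)
            self._sig_cache[seq.residues] = s
        return s

    def prepare_batch(self, records: Sequence[AffinityRecord]) -> dict:
        """Pad a record list into batch tensors (embeddings, masks, signature
        differences, labels)."""
        cfg = self.config
        b = len(records)
        for r in records:
            if len(r.antibody) > cfg.l_ab_max:
                raise SequenceTooLongError(
                    f"antibody {r.antibody.id!r} length {len(r.antibody)} exceeds "
                    f"l_ab_max={cfg.l_ab_max}; refusing to truncate"
                )
            if len(r.antigen) > cfg.l_ag_max:
                raise SequenceTooLongError(
                    f"antigen {r.antigen.id!r} length {len(r.antigen)} exceeds "
                    f"l_ag_max={cfg.l_ag_max}; refusing to truncate"
                )
        batch: dict = {"n": b, "y": np.array([r.pkd for r in records], dtype=np.float64)}
        if cfg.uses_r2r:
            lab = max(len(r.antibody) for r in records)
            lag = cfg.l_ag_max
            d = cfg.embed_dim
            xab = np.zeros((b, lab, d), dtype=self._dtype)
            xag = np.zeros((b, lag, d), dtype=self._dtype)
            mab = np.zeros((b, lab), dtype=bool)
            mag = np.zeros((b, lag), dtype=bool)
            for i, r in enumerate(records):
                ea, eg = self._embedding(r.antibody), self._embedding(r.antigen)
                xab[i, : len(ea)] = ea
                mab[i, : len(ea)] = True
                xag[i, : len(eg)] = eg
                mag[i, : len(eg)] = True
            batch.update(xab=xab, xag=xag, mask_ab=mab, mask_ag=mag)
        if cfg.uses_gspe:
            delta = np.stack(
                [self._signature(r.antibody) - self._signature(r.antigen) for r in records]
            )                                           # (b, n_sets, m*q)
            batch["delta"] = delta
        return batch

    # --------------------------------------------------------- forward pass

    def forward_batch(self, batch: dict) -> tuple[np.ndarray, dict]:
        cfg = self.config
        cache: dict = {}
        blocks = []
        if cfg.uses_r2r:
            mab, mag = batch["mask_ab"], batch["mask_ag"]
            nab = int(mab.sum())
            if self.config.share_compress:
                rows = np.concatenate([batch["xab"][mab], batch["xag"][mag]])
                v_flat = self.compress_ab.forward(rows)[:, 0]
                v_ab_flat, v_ag_flat = v_flat[:nab], v_flat[nab:]
            else:
                v_ab_flat = self.compress_ab.forward(batch["xab"][mab])[:, 0]
                v_ag_flat = self.compress_ag.forward(batch["xag"][mag])[:, 0]
            vab = np.zeros(mab.shape, dtype=self._dtype)
            vag = np.zeros(mag.shape, dtype=self._dtype)
            vab[mab] = v_ab_flat
            vag[mag] = v_ag_flat
            m_inter = vab[:, :, None] * vag[:, None, :]          # (b, lab, lag)
            r_in = np.concatenate([m_inter, vab[:, :, None]], axis=2)
            col_mask = np.concatenate(
                [mag, np.ones((mag.shape[0], 1), dtype=bool)], axis=1
            )                                                    # (b, lag+1)
            row_mask = np.broadcast_to(col_mask[:, None, :], r_in.shape)
            rin_flat = np.ascontiguousarray(r_in[mab])
            rmask_flat = np.ascontiguousarray(row_mask[mab]).astype(self._dtype)
            h_flat = self.refine_stack.forward(rin_flat, input_mask=rmask_flat)[:, 0]
            h_aa = np.zeros(mab.shape, dtype=np.float64)
            h_aa[mab] = h_flat
            counts = mab.sum(axis=1)
            pooled_mean = (h_aa * mab).sum(axis=1) / counts
            masked = np.where(mab, h_aa, -np.inf)
            argmax = masked.argmax(axis=1)
            pooled_max = masked[np.arange(len(argmax)), argmax]
            blocks.append(np.stack([pooled_mean, pooled_max], axis=1))
            cache.update(nab=nab, vab=vab, vag=vag, counts=counts, argmax=argmax,
                         mab=mab, mag=mag)
        if cfg.uses_gspe:
            sig = np.asarray(softplus(self.rho))
            dists = ((batch["delta"] / sig) ** 2).sum(axis=2)    # (b, n_sets)
            h_pair = np.asarray(softplus(dists))
            blocks.append(h_pair)
            cache.update(sigma=sig, dists=dists)
        z = np.concatenate(blocks, axis=1)
        z_std = (z - self.feature_loc) / self.feature_scale
        out = self.head.forward(z_std)
        preds = self.label_mean + out[:, 0] + z_std @ self.skip
        cache["z"] = z
        cache["z_std"] = z_std
        return preds, cache

    def backward_batch(self, batch: dict, cache: dict, dpred: np.ndarray) -> None:
        cfg = self.config
        self._skip_grad = cache["z_std"].T @ dpred
        dz = (self.head.backward(dpred[:, None]) + np.outer(dpred, self.skip)) / self.feature_scale
        offset = 0
        if cfg.uses_r2r:
            d_mean, d_max = dz[:, 0], dz[:, 1]
            offset = 2
            mab, mag = cache["mab"], cache["mag"]
            vab, vag = cache["vab"], cache["vag"]
            dh = mab * (d_mean / cache["counts"])[:, None]
            dh[np.arange(len(d_max)), cache["argmax"]] += d_max
            drows = self.refine_stack.backward(dh[mab][:, None])
            dr = np.zeros((*mab.shape, cfg.l_ag_max + 1), dtype=drows.dtype)
            dr[mab] = drows
            dm = dr[:, :, :-1]
            dvab = (dm * vag[:, None, :]).sum(axis=2) + dr[:, :, -1]
            dvag = (dm * vab[:, :, None]).sum(axis=1)
            if self.config.share_compress:
                dv_flat = np.concatenate([dvab[mab], dvag[mag]])
                self.compress_ab.backward(dv_flat[:, None], need_input_grad=False)
            else:
                self.compress_ab.backward(dvab[mab][:, None], need_input_grad=False)
                self.compress_ag.backward(dvag[mag][:, None], need_input_grad=False)
        if cfg.uses_gspe:
            d_hp = dz[:, offset : offset + cfg.gspe_n_sets]
            ddist = d_hp * np.asarray(sigmoid(cache["dists"]))
            sig = cache["sigma"]
            dsigma = np.einsum(
                "bn,bnj->j", ddist, -2.0 * batch["delta"] ** 2 / sig**3
            )
            drho = dsigma * np.asarray(sigmoid(self.rho))
            self._rho_grad = self._rho_grad + drho if hasattr(self, "_rho_grad") else drho

    # ----------------------------------------------------------- parameters

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.config.uses_r2r:
            out.update({f"compress_ab.{k}": v for k, v in self.compress_ab.params().items()})
            if not self.config.share_compress:
                out.update({f"compress_ag.{k}": v for k, v in self.compress_ag.params().items()})
            out.update({f"refine.{k}": v for k, v in self.refine_stack.params().items()})
        if self.config.uses_gspe:
            out["rho"] = self.rho
        out.update({f"head.{k}": v for k, v in self.head.params().items()})
        out["skip"] = self.skip
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.config.uses_r2r:
            out.update({f"compress_ab.{k}": v for k, v in self.compress_ab.grads().items()})
            if not self.config.share_compress:
                out.update({f"compress_ag.{k}": v for k, v in self.compress_ag.grads().items()})
            out.update({f"refine.{k}": v for k, v in self.refine_stack.grads().items()})
        if self.config.uses_gspe and hasattr(self, "_rho_grad"):
            out["rho"] = self._rho_grad
        out.update({f"head.{k}": v for k, v in self.head.grads().items()})
        if hasattr(self, "_skip_grad"):
            out["skip"] = self._skip_grad
        return out

    def zero_grads(self) -> None:
        if self.config.uses_r2r:
            self.compress_ab.zero_grads()
            self.compress_ag.zero_grads()
            self.refine_stack.zero_grads()
        self.head.zero_grads()
        for attr in ("_rho_grad", "_skip_grad"):
            if hasattr(self, attr):
                delattr(self, attr)

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for key, arr in self.params().items():
            arr[...] = values[key]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    # ------------------------------------------------------------- inference

    def predict(self, records: Sequence[AffinityRecord], batch_size: int = 128) -> np.ndarray:
        preds = []
        for start in range(0, len(records), batch_size):
            batch = self.prepare_batch(records[start : start + batch_size])
            p, _ = self.forward_batch(batch)
            preds.append(p)
        return np.concatenate(preds) if preds else np.empty(0)

    def forward(self, record: AffinityRecord) -> float:
        """Predict pK_D for a single pair (deterministic in eval mode)."""
        return float(self.predict([record])[0])

    def evaluate_records(self, records: Sequence[AffinityRecord]) -> EvalReport:
        preds = self.predict(records)
        targets = np.array([r.pkd for r in records])
        return evaluate(preds, targets)

    # -------------------------------------------------------------- training

    def _spectral_init(self, batch: dict) -> None:
        """Warm-start the linear part of the two compression maps.

        The interaction branch is bilinear at its core: the pooled map
        behaves like (w_a . mean antibody embedding) * (w_g . summed antigen
        embedding).  Gradient descent from a random (w_a, w_g) must bootstrap
        both directions through each other, which fails from unlucky draws.
        The top singular pair of the label-weighted cross-moment
        C = sum_c (y_c - mean y) a_c g_c^T gives the directions a bilinear
        fit would choose, so training starts inside the recoverable basin.
        Deterministic given the training set.
        """
        mab, mag = batch["mask_ab"], batch["mask_ag"]
        y = batch["y"] - batch["y"].mean()
        if len(y) < 8 or not np.all(np.isfinite(y)) or y.std() == 0:
            return   # not enough usable label variation to estimate a direction
        a_bar = (batch["xab"] * mab[:, :, None]).sum(axis=1) / mab.sum(axis=1)[:, None]
        g_bar = (batch["xag"] * mag[:, :, None]).sum(axis=1)
        a_bar = a_bar.astype(np.float64)
        g_bar = g_bar.astype(np.float64)
        cross = np.einsum("c,ci,cj->ij", y, a_bar, g_bar)
        u, _, vt = np.linalg.svd(cross)
        w_a, w_g = u[:, 0], vt[0]
        # alternating ridge refinement of the rank-one fit y ~ (a.w_a)(g.w_g);
        # the raw cross-moment direction is biased by whatever else in the
        # labels covaries with chain composition
        dim = a_bar.shape[1]
        for _ in range(8):
            s_g = g_bar @ w_g
            design = a_bar * s_g[:, None]
            reg = 1e-3 * np.trace(design.T @ design) / dim * np.eye(dim)
            w_a = np.linalg.solve(design.T @ design + reg, design.T @ y)
            s_a = a_bar @ w_a
            design = g_bar * s_a[:, None]
            reg = 1e-3 * np.trace(design.T @ design) / dim * np.eye(dim)
            w_g = np.linalg.solve(design.T @ design + reg, design.T @ y)
        # sign: make the bilinear feature positively correlated with labels
        feat = (a_bar @ w_a) * (g_bar @ w_g)
        if float(np.dot(feat - feat.mean(), y)) < 0:
            w_g = -w_g
        rows_a = batch["xab"][mab].astype(np.float64)
        rows_g = batch["xag"][mag].astype(np.float64)
        scale_a = max(float((rows_a @ w_a).std()), 1e-6)
        scale_g = max(float((rows_g @ w_g).std()), 1e-6)
        self.compress_ab.layers[0].weight[0, :] = (w_a / scale_a).astype(self._dtype)
        if not self.config.share_compress:
            self.compress_ag.layers[0].weight[0, :] = (w_g / scale_g).astype(self._dtype)

    def _init_sigma(self, delta: np.ndarray) -> None:
        """Scale sigma so the initial mean squared distance is ~1 (stable head
        input scale); deterministic given the training set."""
        mq = delta.shape[2]
        per_coord_rms = np.sqrt((delta**2).mean(axis=(0, 1)) + 1e-8)
        sigma0 = np.sqrt(mq) * np.maximum(per_coord_rms, 1e-4)
        self.rho[...] = softplus_inverse(sigma0)
        self._sigma_initialized = True

    def train(
        self,
        train_records: Sequence[AffinityRecord],
        val_records: Sequence[AffinityRecord] | None = None,
        optimizer: AdamW | None = None,
        max_epochs: int | None = None,
        start_epoch: int = 0,
    ) -> TrainResult:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 41]))
        batch_all = self.prepare_batch(train_records)
        y = batch_all["y"]
        resuming = optimizer is not None and getattr(optimizer, "t", 0) > 0
        if start_epoch == 0 and not resuming:
            self.label_mean = float(y.mean())
            if cfg.uses_gspe and not self._sigma_initialized:
                self._init_sigma(batch_all["delta"])
            if cfg.uses_r2r and cfg.spectral_init:
                self._spectral_init(batch_all)
            _, cache0 = self.forward_batch(batch_all)
            z0 = cache0["z"]
            self.feature_loc = z0.mean(axis=0)
            z0_std = z0.std(axis=0)
            # a (near-)constant feature gets unit scale, not a huge gain
            self.feature_scale = np.where(z0_std < 1e-6, 1.0, z0_std)
        val_batch = self.prepare_batch(val_records) if val_records else None
        opt = optimizer or AdamW(lr=cfg.lr, weight_decay=cfg.weight_decay)
        n = len(train_records)
        max_epochs = cfg.max_epochs if max_epochs is None else max_epochs
        log: list[dict] = []
        eval_batch0 = val_batch if val_batch is not None else batch_all
        preds0, _ = self.forward_batch(eval_batch0)
        best = {"val_mae": float(mae(preds0, eval_batch0["y"])), "epoch": start_epoch - 1,
                "params": self.snapshot(), "label_mean": self.label_mean}
        stale = 0
        for epoch in range(start_epoch, start_epoch + max_epochs):
            if cfg.lr_schedule == "cosine":
                frac = (epoch - start_epoch) / max(1, max_epochs - 1)
                opt.lr = cfg.lr * (0.1 + 0.45 * (1.0 + np.cos(np.pi * frac)))
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                sub = self._slice_batch(batch_all, idx)
                preds, cache = self.forward_batch(sub)
                loss = mse_loss(preds, sub["y"])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, batch indices {idx.tolist()}"
                    )
                losses.append(loss)
                self.zero_grads()
                dpred = 2.0 * (preds - sub["y"]) / len(idx)
                self.backward_batch(sub, cache, dpred)
                grads = self.grads()
                if cfg.clip_norm > 0:
                    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                    if total > cfg.clip_norm:
                        grads = {k: g * (cfg.clip_norm / total) for k, g in grads.items()}
                opt.step(self.params(), grads)
            eval_batch = val_batch if val_batch is not None else batch_all
            val_preds, _ = self.forward_batch(eval_batch)
            val_mae = mae(val_preds, eval_batch["y"])
            val_rmse = float(np.sqrt(mse_loss(val_preds, eval_batch["y"])))
            entry = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_mae": float(val_mae),
                "val_rmse": val_rmse,
            }
            log.append(entry)
            if val_mae < best["val_mae"] - 1e-9:
                best = {"val_mae": float(val_mae), "epoch": epoch,
                        "params": self.snapshot(), "label_mean": self.label_mean}
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        self.set_params(best["params"])
        self.label_mean = best["label_mean"]
        self._last_optimizer = opt
        return TrainResult(log=log, best_epoch=best["epoch"], best_val_mae=best["val_mae"])

    @staticmethod
    def _slice_batch(batch: dict, idx: np.ndarray) -> dict:
        out = {"n": len(idx), "y": batch["y"][idx]}
        for key in ("xab", "xag", "mask_ab", "mask_ag", "delta"):
            if key in batch:
                out[key] = batch[key][idx]
        return out

    # ---------------------------------------------------------- persistence

    def save(self, path: str | Path, optimizer: AdamW | None = None) -> None:
        """Write a single-file checkpoint (parameters, frozen bases, config)."""
        arrays: dict[str, np.ndarray] = {f"param::{k}": v for k, v in self.params().items()}
        if self.bases is not None:
            arrays["bases"] = np.stack([b.vectors for b in self.bases])
        arrays["feature_loc"] = self.feature_loc
        arrays["feature_scale"] = self.feature_scale
        meta = {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "provider": {"name": self.provider.name, "version": self.provider.version,
                         "dim": self.provider.dim},
            "label_mean": self.label_mean,
            "sigma_initialized": bool(self._sigma_initialized),
        }
        opt = optimizer or getattr(self, "_last_optimizer", None)
        if opt is not None:
            meta["optimizer"] = {"lr": opt.lr, "weight_decay": opt.weight_decay, "t": opt.t}
            for k, v in opt.m.items():
                arrays[f"opt_m::{k}"] = v
            for k, v in opt.v.items():
                arrays[f"opt_v::{k}"] = v
        arrays["meta_json"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, provider: EmbeddingProvider | None = None
             ) -> tuple["AffinityModel", AdamW | None]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            if meta["schema_version"] != SCHEMA_VERSION:
                raise RuntimeError(f"unsupported checkpoint schema {meta['schema_version']}")
            cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in meta["config"].items()})
            if provider is None:
                p = meta["provider"]
                if p["name"] != "mock":
                    raise IncompatibleProviderError(
                        f"checkpoint needs provider {p['name']!r}; pass one explicitly"
                    )
                provider = MockEmbeddingProvider(dim=int(p["dim"]), version=p["version"])
            stored = meta["provider"]
            if provider.dim != int(stored["dim"]):
                raise IncompatibleProviderError(
                    f"checkpoint embedding dim {stored['dim']} != provider dim {provider.dim}"
                )
            model = cls(cfg, provider)
            model.set_params({k.split("::", 1)[1]: data[k] for k in data.files
                              if k.startswith("param::")})
            model.label_mean = float(meta["label_mean"])
            model._sigma_initialized = bool(meta.get("sigma_initialized", True))
            if "feature_loc" in data.files:
                model.feature_loc = np.array(data["feature_loc"])
                model.feature_scale = np.array(data["feature_scale"])
            opt = None
            if "optimizer" in meta:
                o = meta["optimizer"]
                opt = AdamW(lr=o["lr"], weight_decay=o["weight_decay"])
                opt.t = int(o["t"])
                opt.m = {k.split("::", 1)[1]: np.array(data[k]) for k in data.files
                         if k.startswith("opt_m::")}
                opt.v = {k.split("::", 1)[1]: np.array(data[k]) for k in data.files
                         if k.startswith("opt_v::")}
        return model, opt


def train_val_test_split(
    records: Sequence[AffinityRecord],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    group_by_antibody: bool = False,
) -> tuple[list[AffinityRecord], list[AffinityRecord], list[AffinityRecord]]:
    """Seeded split; with ``group_by_antibody`` identical antibody sequences
    never straddle splits (guards against near-duplicate leakage)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if group_by_antibody:
        groups: dict[str, list[AffinityRecord]] = {}
        for r in records:
            groups.setdefault(r.antibody.residues, []).append(r)
        keys = list(groups)
        rng.shuffle(keys)
        pools: tuple[list, list, list] = ([], [], [])
        targets = [f * len(records) for f in fractions]
        for key in keys:
            deficit = [t - len(p) for t, p in zip(targets, pools)]
            pools[int(np.argmax(deficit))].extend(groups[key])
        return pools
    idx = rng.permutation(len(records))
    n_train = int(round(fractions[0] * len(records)))
    n_val = int(round(fractions[1] * len(records)))
    picked = [records[i] for i in idx]
    return (picked[:n_train], picked[n_train : n_train + n_val], picked[n_train + n_val :])
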