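"""Deep embedded clustering of pooled multi-species single-presynapse data.

The model follows the IDEC recipe: two parallel fully-connected
autoencoders are pretrained on the pooled (balanced, arcsinh-transformed)
event matrix under mean-squared-error reconstruction loss; their
bottleneck codes are concatenated into the shared latent representation;
a clustering layer of K centres sits on top of that code and assigns each
event a Student-t soft membership

    q_ij = (1 + ||z_i - mu_j||^2 / alpha)^(-(alpha+1)/2)  (row-normalised),

fine-tuned by minimising  L = MSE + gamma * KL(P || Q)  where P is the
sharpened target distribution  p_ij ∝ q_ij^2 / f_j,  f_j = Σ_i q_ij.
Training uses Adagrad (initial learning rate 0.1, batch size 1024),
Glorot initialisation, seeded shuffling and early stopping; the whole
procedure is repeated over an ensemble of seeds and the run labelings are
merged downstream by consensus meta-clustering.

Usage follows the model/results idiom::

    model = SynTofDEC(table, TrainConfig())
    res = model.fit(k="auto", seed=7)
    res.labels, res.consensus.mean_nmi, res.summary()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .consensus import ConsensusResult, RunSet, greedy_consensus
from .events import EventTable
from .nn import DTYPE, Adagrad, Autoencoder

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the embedding/clustering model.

    Defaults follow the training protocol: Adagrad with initial learning
    rate 0.1, batch size 1024, Glorot initialisation, early stopping, and
    a 10-run ensemble.  ``gamma`` weights the clustering loss against the
    reconstruction loss; ``alpha`` is the Student-t degrees of freedom.
    """

    latent_dim: int = 8                 # per autoencoder; shared code is 2x
    hidden_layers: tuple[int, ...] = (64, 32)
    learning_rate: float = 0.1
    batch_size: int = 1024
    gamma: float = 0.1
    alpha: float = 1.0
    target_update_interval: int = 140   # batches between P refreshes
    patience: int = 10
    min_delta: float = 1e-4
    max_epochs_pretrain: int = 60
    max_epochs_finetune: int = 40
    n_runs: int = 10
    kmeans_restarts: int = 4

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


# ---------------------------------------------------------------------------
# DEC mathematics (pure functions, exercised directly by the test oracles)

def soft_assign(latent: np.ndarray, centers: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignments Q of events to cluster centres.

    ``q_ij = (1 + ||z_i - mu_j||^2/alpha)^(-(alpha+1)/2)``, rows normalised
    to sum to 1.  Distinct centres guarantee a nonzero row sum.
    """
    z = np.asarray(latent, dtype=np.float64)
    mu = np.asarray(centers, dtype=np.float64)
    d2 = ((z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    q = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def _soft_assign_blocked(z, mu, alpha, block=8192):
    out = np.empty((len(z), len(mu)), dtype=np.float64)
    for s in range(0, len(z), block):
        out[s : s + block] = soft_assign(z[s : s + block], mu, alpha)
    return out


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target P with ``p_ij ∝ q_ij^2 / f_j``, ``f_j = Σ_i q_ij``."""
    Q = np.asarray(Q, dtype=np.float64)
    if Q.size == 0:
        raise ValueError("empty Q")
    f = Q.sum(axis=0)
    weight = Q**2 / f
    return weight / weight.sum(axis=1, keepdims=True)


def elbow_from_sse(k_values, sse) -> tuple[int, float, bool]:
    """Pick K from an SSE curve by maximal normalised second difference.

    Returns ``(k, strength, has_elbow)``.  The curvature at interior point
    i is ``(sse[i-1] - 2 sse[i] + sse[i+1]) / sse[i]`` — the drop in
    marginal SSE relative to the SSE still unexplained, which is large at
    a genuine elbow and small on the smooth decay of structureless data.
    Strength below 0.1 means "no elbow": the smallest k is returned with a
    warning.  Ties break toward smaller k.
    """
    k_values = list(k_values)
    sse = np.asarray(sse, dtype=float)
    if len(k_values) < 3:
        raise ValueError("k range must contain at least 3 values")
    eps = 1e-12
    curv = (sse[:-2] - 2.0 * sse[1:-1] + sse[2:]) / np.maximum(sse[1:-1], eps)
    best = int(np.argmax(curv))  # argmax takes the first (smallest-k) maximum
    strength = float(curv[best])
    if not np.isfinite(strength) or strength < 0.1:
        warnings.warn("no elbow detected in SSE curve; returning smallest k",
                      stacklevel=2)
        return k_values[0], max(strength, 0.0), False
    return k_values[best + 1], strength, True


# ---------------------------------------------------------------------------

@dataclass
class PretrainedModel:
    """Two pretrained autoencoders plus their optimiser state."""

    nets: tuple[Autoencoder, Autoencoder]
    loss_history: list[float]
    seed: int
    optimizers: tuple[Adagrad, Adagrad] | None = None

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Shared representation: concatenated bottleneck codes."""
        return np.concatenate([net.encode(x) for net in self.nets], axis=1)


@dataclass
class SingleRun:
    """One pretrain+fine-tune execution."""

    labels: np.ndarray
    latent: np.ndarray
    centers: np.ndarray
    Q: np.ndarray
    pretrain_loss: list[float]
    finetune_loss: list[float]
    kl_initial: float
    kl_final: float
    seed: int


class SynTofDEC:
    """Joint embedding + clustering model over an event table.

    Parameters
    ----------
    table : EventTable or ndarray
        Transformed (arcsinh-scale) intensities.  An array is accepted for
        benchmark data without metadata.
    config : TrainConfig
    """

    def __init__(self, table, config: TrainConfig | None = None):
        if isinstance(table, EventTable):
            self.table = table
            self.X = np.ascontiguousarray(table.intensities, dtype=DTYPE)
        else:
            self.table = None
            self.X = np.ascontiguousarray(np.asarray(table), dtype=DTYPE)
        if self.X.ndim != 2 or self.X.size == 0:
            raise ValueError("need a nonempty events x markers matrix")
        self.config = config or TrainConfig()

    # -- training stages ---------------------------------------------------
    def pretrain(self, seed: int = 0) -> PretrainedModel:
        """Train the two autoencoders under MSE reconstruction loss."""
        cfg = self.config
        nets = (
            Autoencoder(self.X.shape[1], cfg.hidden_layers, cfg.latent_dim, seed=seed * 2 + 1),
            Autoencoder(self.X.shape[1], cfg.hidden_layers, cfg.latent_dim, seed=seed * 2 + 2),
        )
        opts = [Adagrad(net.params, cfg.learning_rate) for net in nets]
        rng = np.random.default_rng(seed)
        history: list[float] = []
        best, wait = np.inf, 0
        n = len(self.X)
        for _epoch in range(cfg.max_epochs_pretrain):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                xb = self.X[order[start : start + cfg.batch_size]]
                m = len(xb)
                for net, opt in zip(nets, opts):
                    _, recon, cache = net.forward(xb)
                    err = recon - xb
                    total += float((err.astype(np.float64) ** 2).mean()) * m
                    grads = net.backward(cache, (2.0 / (m * xb.shape[1])) * err)
                    opt.step(grads)
            epoch_loss = total / (2 * n)
            history.append(epoch_loss)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("non-finite pretraining loss; aborting run")
            if epoch_loss < best - cfg.min_delta:
                best, wait = epoch_loss, 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        return PretrainedModel(nets=nets, loss_history=history, seed=seed,
                               optimizers=tuple(opts))

    def _kmeans(self, Z: np.ndarray, k: int, seed: int) -> KMeans:
        for attempt in range(5):
            km = KMeans(n_clusters=k, n_init=self.config.kmeans_restarts,
                        random_state=(seed + 7919 * attempt) % (2**31 - 1))
            labels = km.fit_predict(Z)
            if len(np.unique(labels)) == k:
                return km
            logger.warning("K-means produced an empty cluster; retrying")
        raise RuntimeError(f"K-means failed to produce {k} non-empty clusters")

    def select_k(self, k_range=range(2, 21), seed: int = 0,
                 pretrained: PretrainedModel | None = None):
        """Elbow selection of K from the K-means SSE curve on the latent codes."""
        k_range = list(k_range)
        if len(k_range) < 3:
            raise ValueError("k range must contain at least 3 values")
        if pretrained is None:
            pretrained = self.pretrain(seed=seed)
        Z = pretrained.encode(self.X).astype(np.float64)
        sse = []
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=self.config.kmeans_restarts,
                        random_state=seed % (2**31 - 1)).fit(Z)
            sse.append(float(km.inertia_))
        k, strength, has_elbow = elbow_from_sse(k_range, sse)
        return KSelection(k=k, k_range=k_range, sse=sse, strength=strength,
                          has_elbow=has_elbow)

    def finetune(self, pretrained: PretrainedModel, k: int,
                 seed: int = 0) -> SingleRun:
        """IDEC fine-tuning: MSE + gamma*KL(P||Q), centres from K-means."""
        if k < 2:
            raise ValueError("K must be >= 2")
        cfg = self.config
        nets = pretrained.nets
        X, n = self.X, len(self.X)
        Z = pretrained.encode(X).astype(np.float64)
        km = self._kmeans(Z, k, seed)
        centers = km.cluster_centers_.astype(np.float64)

        Q = _soft_assign_blocked(Z, centers, cfg.alpha)
        P = target_distribution(Q)
        kl_initial = _kl(P, Q)
        params = [p for net in nets for p in net.params] + [centers]
        opt = Adagrad(params, cfg.learning_rate)
        if pretrained.optimizers is not None:
            # fine-tuning continues pretraining: carry the Adagrad
            # accumulators so the first updates are not a large jolt
            carried = [a for o in pretrained.optimizers for a in o.accum]
            for i, a in enumerate(carried):
                opt.accum[i] = a
        rng = np.random.default_rng(seed + 10_007)
        history: list[float] = []
        best, wait = np.inf, 0
        batches_since_update = 0
        half_latent = cfg.latent_dim
        for _epoch in range(cfg.max_epochs_finetune):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = X[idx]
                m = len(xb)
                if batches_since_update >= cfg.target_update_interval:
                    Z = np.concatenate([net.encode(X) for net in nets], axis=1).astype(np.float64)
                    Q = _soft_assign_blocked(Z, centers, cfg.alpha)
                    P = target_distribution(Q)
                    batches_since_update = 0
                batches_since_update += 1

                lat1, rec1, cache1 = nets[0].forward(xb)
                lat2, rec2, cache2 = nets[1].forward(xb)
                zb = np.concatenate([lat1, lat2], axis=1).astype(np.float64)
                diff = zb[:, None, :] - centers[None, :, :]
                d2 = (diff**2).sum(axis=2)
                w = 1.0 / (1.0 + d2 / cfg.alpha)            # (1+d2/a)^-1
                qb = w ** ((cfg.alpha + 1.0) / 2.0)
                qb = qb / qb.sum(axis=1, keepdims=True)
                pb = P[idx]

                err1 = rec1 - xb
                err2 = rec2 - xb
                mse = float((err1.astype(np.float64) ** 2).mean()
                            + (err2.astype(np.float64) ** 2).mean()) / 2.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    kl = float(np.where(pb > 0, pb * np.log(pb / np.maximum(qb, 1e-12)), 0.0).sum() / m)
                total += (mse + cfg.gamma * kl) * m

                grads: list[np.ndarray] = []
                if cfg.gamma > 0:
                    # d KL / d z_i = (a+1)/a * sum_j w_ij (p_ij - q_ij)(z_i - mu_j)
                    coef = ((cfg.alpha + 1.0) / cfg.alpha) * w * (pb - qb)  # (m, k)
                    dz = (cfg.gamma / m) * np.einsum("ik,ikl->il", coef, diff)
                    dmu = -(cfg.gamma / m) * np.einsum("ik,ikl->kl", coef, diff)
                else:
                    dz = np.zeros_like(zb)
                    dmu = np.zeros_like(centers)
                g1 = nets[0].backward(cache1, (2.0 / (m * xb.shape[1])) * err1,
                                      d_latent=dz[:, :half_latent])
                g2 = nets[1].backward(cache2, (2.0 / (m * xb.shape[1])) * err2,
                                      d_latent=dz[:, half_latent:])
                grads = [*g1, *g2, dmu]
                opt.step(grads)
            epoch_loss = total / n
            history.append(epoch_loss)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("non-finite fine-tuning loss; aborting run")
            if epoch_loss < best - cfg.min_delta:
                best, wait = epoch_loss, 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

        Z = np.concatenate([net.encode(X) for net in nets], axis=1).astype(np.float64)
        Q = _soft_assign_blocked(Z, centers, cfg.alpha)
        P = target_distribution(Q)
        return SingleRun(
            labels=np.argmax(Q, axis=1),
            latent=Z.astype(np.float32),
            centers=centers,
            Q=Q,
            pretrain_loss=pretrained.loss_history,
            finetune_loss=history,
            kl_initial=kl_initial,
            kl_final=_kl(P, Q),
            seed=seed,
        )

    def fit_single(self, k: int, seed: int = 0) -> SingleRun:
        return self.finetune(self.pretrain(seed=seed), k, seed=seed)

    def run_ensemble(self, k: int, seeds) -> tuple[RunSet, list[SingleRun]]:
        """Independent pretrain+fine-tune runs, one per seed."""
        seeds = list(seeds)
        if len(set(seeds)) != len(seeds):
            raise ValueError("ensemble seeds must be distinct")
        runs: list[SingleRun] = []
        for s in seeds:
            try:
                runs.append(self.fit_single(k, seed=s))
            except (FloatingPointError, RuntimeError) as exc:  # pragma: no cover
                fallback = (s + 99_991) % (2**31 - 1)
                logger.warning("run with seed %d failed (%s); retrying with %d",
                               s, exc, fallback)
                runs.append(self.fit_single(k, seed=fallback))
        labelings = np.stack([r.labels for r in runs])
        return RunSet(labelings=labelings, run_seeds=[r.seed for r in runs]), runs

    def fit(self, k="auto", seed: int = 0, n_runs: int | None = None,
            k_range=range(8, 25)) -> "DECResults":
        """Full procedure: pretrain, select K, run the ensemble, form consensus."""
        n_runs = self.config.n_runs if n_runs is None else n_runs
        selection = None
        if k == "auto":
            selection = self.select_k(k_range=k_range, seed=seed)
            k = selection.k
        seeds = [(seed + 1000 * i) % (2**31 - 1) for i in range(n_runs)]
        runset, runs = self.run_ensemble(int(k), seeds)
        consensus = greedy_consensus(runset)
        return DECResults(model=self, k=int(k), runs=runs, runset=runset,
                          consensus=consensus, k_selection=selection)


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / np.maximum(Q, 1e-300)), 0.0)
    return float(terms.sum() / len(P))


@dataclass
class KSelection:
    k: int
    k_range: list[int]
    sse: list[float]
    strength: float
    has_elbow: bool


@dataclass
class DECResults:
    """Fitted clustering: consensus labels, per-run diagnostics, embedding."""

    model: SynTofDEC
    k: int
    runs: list[SingleRun]
    runset: RunSet
    consensus: ConsensusResult
    k_selection: KSelection | None = None

    @property
    def labels(self) -> np.ndarray:
        """Consensus hard labels, one per event."""
        return self.consensus.consensus_labels

    @property
    def latent(self) -> np.ndarray:
        """Latent embedding of the consensus reference run."""
        return self.runs[self.consensus.reference_run].latent

    @property
    def n_clusters(self) -> int:
        return self.consensus.n_clusters

    def summary(self) -> str:
        rows = []
        for i, r in enumerate(self.runs):
            rows.append(
                f"  run {i:>2d} seed={r.seed:<10d} epochs={len(r.finetune_loss):>3d} "
                f"KL {r.kl_initial:.4f}->{r.kl_final:.4f} "
                f"F={self.consensus.per_run_fscore[i]:.3f} "
                f"NMI={self.consensus.per_run_nmi[i]:.3f}"
            )
        sizes = pd.Series(self.labels).value_counts().sort_index()
        lines = [
            "Deep embedded clustering results",
            "================================",
            f"events: {len(self.labels)}   latent dim: {self.latent.shape[1]}   K: {self.k}",
            f"consensus clusters: {self.n_clusters}   "
            f"mean F-score: {self.consensus.mean_fscore:.3f}   "
            f"mean NMI: {self.consensus.mean_nmi:.3f}",
        ]
        if self.k_selection is not None:
            lines.append(
                f"elbow: k={self.k_selection.k} strength={self.k_selection.strength:.3f}"
                f" ({'elbow' if self.k_selection.has_elbow else 'no elbow'})"
            )
        lines.append("per-run agreement with consensus:")
        lines.extend(rows)
        lines.append("consensus cluster sizes: "
                     + ", ".join(f"{c}:{n}" for c, n in sizes.items()))
        return "\n".join(lines)
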