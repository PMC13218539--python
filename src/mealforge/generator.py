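"""Conditional VAE over binary food-presence vectors.

The model generates food *combinations* (which foods appear together in a
meal), conditioned on (archetype cluster, meal type) through FiLM
(feature-wise linear modulation) of every hidden block. Portions are
assigned downstream by :mod:`mealforge.portioning`; separating the two is
a deliberate architecture choice.

Architecture: 64-d Gaussian latent; encoder and decoder each 3 Dense(512)
GELU blocks, FiLM-conditioned by a linear map of the concatenated cluster
and meal-type embeddings (8 dimensions each). Decoding adds a
pair-specific prior (log-odds of within-pair food prevalence) to the
output logits, and sampling applies a hard allowed-foods gate: the top-k
foods by within-pair prevalence, k = the pair's median item count, with
logits of disallowed foods penalised by the mask strength (12).

Training: Adam (lr 5e-4) with global-norm gradient clipping (0.5);
weighted BCE with a dynamic positive-class weight, free-bits KL with a
cyclically annealed beta (linear warmup to beta_max, then a descending
ramp from beta_max to beta_min each cycle), and a count-matching term
penalising the squared difference between the summed presence
probabilities and the true item count.

The implementation is pure numpy with hand-written backpropagation; runs
are deterministic given the config seed (single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf, expit

from mealforge.containers import MEAL_TYPES, MealCorpus

# ---------------------------------------------------------------- config


@dataclass
class CVAEConfig:
    latent_dim: int = 64
    hidden_dim: int = 512
    n_blocks: int = 3
    embed_dim: int = 8
    mask_strength: float = 12.0
    lr: float = 5e-4
    clipnorm: float = 0.5
    free_bits: float = 0.05  # nats per latent dim
    beta_max: float = 1.0
    beta_min_frac: float = 0.1  # beta_min = frac * beta_max
    warmup_epochs: int = 5
    cycle_epochs: int = 10
    pos_weight_clip: tuple[float, float] = (1.0, 50.0)
    count_loss_weight: float = 1.0
    epochs: int = 80
    batch_size: int = 128
    seed: int = 0
    conditioning: bool = True  # ablation switch: zero conditioning + pooled gate/prior
    joint_portioning: bool = False  # ablation: decoder also regresses log grams
    gram_loss_weight: float = 1.0
    decode: str = "topk"  # or "bernoulli"
    min_pair_size: int = 5

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.hidden_dim, self.embed_dim, self.n_blocks) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be > 0")


# ------------------------------------------------------------ primitives


def gelu(x: np.ndarray) -> np.ndarray:
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def film(h: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Feature-wise linear modulation: gamma * h + beta, elementwise."""
    h, gamma, beta = np.asarray(h), np.asarray(gamma), np.asarray(beta)
    if not (h.shape[-1] == gamma.shape[-1] == beta.shape[-1]):
        raise ValueError(
            f"FiLM length mismatch: h {h.shape[-1]}, gamma {gamma.shape[-1]}, beta {beta.shape[-1]}"
        )
    return gamma * h + beta


def beta_schedule(step: int, config: CVAEConfig, steps_per_epoch: int = 1) -> float:
    """Annealed beta: linear 0 -> beta_max over warmup, then cyclic ramp
    beta_max -> beta_min each cycle (restarting at beta_max)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    t = step / max(steps_per_epoch, 1)  # epochs, fractional
    w = config.warmup_epochs
    if w > 0 and t < w:
        return config.beta_max * t / w
    beta_min = config.beta_min_frac * config.beta_max
    cycle = max(config.cycle_epochs, 1e-9)
    phase = ((t - w) % cycle) / cycle
    return config.beta_max - (config.beta_max - beta_min) * phase


# -------------------------------------------------------- gate and prior


@dataclass
class PairStats:
    """Per-(cluster, meal type) prevalence statistics fitted from data."""

    prevalence: np.ndarray  # fraction of the pair's meals containing each food
    n_meals: int
    median_items: int

    @property
    def allowed(self) -> np.ndarray:
        """Top-k food indices by prevalence, k = median item count.

        Ties broken by food index (ascending) for determinism.
        """
        k = max(1, self.median_items)
        order = np.lexsort((np.arange(len(self.prevalence)), -self.prevalence))
        return np.sort(order[:k])

    @property
    def prior_logits(self) -> np.ndarray:
        """Log-odds of within-pair prevalence, clipped to stay finite."""
        n = self.n_meals
        p = np.clip(self.prevalence, 1.0 / (n + 2), (n + 1.0) / (n + 2))
        return np.log(p / (1.0 - p))


def fit_pair_stats(
    X: np.ndarray, clusters: np.ndarray, meal_type_ids: np.ndarray
) -> dict[tuple[int, int], PairStats]:
    stats: dict[tuple[int, int], PairStats] = {}
    for key in sorted({(int(c), int(m)) for c, m in zip(clusters, meal_type_ids)}):
        mask = (clusters == key[0]) & (meal_type_ids == key[1])
        rows = X[mask]
        stats[key] = PairStats(
            prevalence=rows.mean(axis=0),
            n_meals=int(mask.sum()),
            median_items=int(round(float(np.median(rows.sum(axis=1))))),
        )
    return stats


# ----------------------------------------------------------------- model


class MealCVAE:
    """FiLM-conditioned VAE over food-presence vectors (numpy backprop)."""

    def __init__(
        self,
        food_codes: list[str],
        cluster_ids: list[int],
        config: CVAEConfig,
    ) -> None:
        self.food_codes = list(food_codes)
        self.cluster_ids = list(cluster_ids)
        self.cluster_index = {c: i for i, c in enumerate(self.cluster_ids)}
        self.config = config
        self.pair_stats: dict[tuple[int, int], PairStats] = {}
        self._rng = np.random.default_rng(config.seed)
        self._init_params()

    # -- parameters

    def _init_params(self) -> None:
        cfg = self.config
        rng = self._rng
        F, H, L = len(self.food_codes), cfg.hidden_dim, cfg.latent_dim
        C = 2 * cfg.embed_dim  # conditioning vector length
        p: dict[str, np.ndarray] = {}

        def dense(name, fan_in, fan_out, scale=None):
            s = scale if scale is not None else np.sqrt(2.0 / fan_in)
            p[f"W_{name}"] = rng.normal(0.0, s, size=(fan_in, fan_out))
            p[f"b_{name}"] = np.zeros(fan_out)

        p["E_cluster"] = rng.normal(0.0, 0.1, size=(max(len(self.cluster_ids), 1), cfg.embed_dim))
        p["E_meal"] = rng.normal(0.0, 0.1, size=(len(MEAL_TYPES), cfg.embed_dim))
        dims_in = [F] + [H] * (cfg.n_blocks - 1)
        for i, d in enumerate(dims_in):
            dense(f"enc{i}", d, H)
            dense(f"film_enc{i}", C, 2 * H, scale=0.0)  # identity FiLM at init
        dense("mu", H, L)
        dense("logvar", H, L)
        dims_in = [L] + [H] * (cfg.n_blocks - 1)
        for i, d in enumerate(dims_in):
            dense(f"dec{i}", d, H)
            dense(f"film_dec{i}", C, 2 * H, scale=0.0)
        dense("out", H, F)
        if cfg.joint_portioning:
            dense("gram", H, F)
        self.params = p
        self._adam_m_flat: np.ndarray | None = None
        self._adam_v_flat: np.ndarray | None = None
        self._adam_t = 0

    # -- conditioning

    def _cond(self, clusters: np.ndarray, meal_type_ids: np.ndarray) -> np.ndarray:
        if not self.config.conditioning:
            return np.zeros((len(clusters), 2 * self.config.embed_dim))
        c_rows = np.array([self.cluster_index[int(c)] for c in clusters])
        return np.concatenate(
            [self.params["E_cluster"][c_rows], self.params["E_meal"][meal_type_ids]], axis=1
        )

    def _pair_key(self, cluster: int, meal_type_id: int) -> tuple[int, int]:
        if not self.config.conditioning:
            return (-1, int(meal_type_id))  # pooled per meal type
        return (int(cluster), int(meal_type_id))

    # -- forward

    def _mlp_forward(self, x: np.ndarray, cond: np.ndarray, prefix: str) -> dict:
        """Shared FiLM-MLP forward, caching intermediates for backprop."""
        p = self.params
        cache = {"inputs": [], "pre_film": [], "film_go": [], "pre_act": [], "cdf": []}
        a = x
        for i in range(self.config.n_blocks):
            h = a @ p[f"W_{prefix}{i}"] + p[f"b_{prefix}{i}"]
            fg = cond @ p[f"W_film_{prefix}{i}"] + p[f"b_film_{prefix}{i}"]
            go, be = np.split(fg, 2, axis=1)
            f = film(h, 1.0 + go, be)
            cdf = 0.5 * (1.0 + erf(f / np.sqrt(2.0)))  # cached for backprop
            cache["inputs"].append(a)
            cache["pre_film"].append(h)
            cache["film_go"].append(go)
            cache["pre_act"].append(f)
            cache["cdf"].append(cdf)
            a = f * cdf
        cache["out"] = a
        return cache

    def _mlp_backward(self, d_out: np.ndarray, cond: np.ndarray, cache: dict,
                      prefix: str, grads: dict) -> tuple[np.ndarray, np.ndarray]:
        """Returns (grad wrt mlp input, grad wrt cond)."""
        p = self.params
        d_cond = np.zeros_like(cond)
        da = d_out
        for i in reversed(range(self.config.n_blocks)):
            f = cache["pre_act"][i]
            pdf = np.exp(-0.5 * f * f) / np.sqrt(2.0 * np.pi)
            df = da * (cache["cdf"][i] + f * pdf)
            go = cache["film_go"][i]
            h = cache["pre_film"][i]
            dh = df * (1.0 + go)
            dgo = df * h
            dbe = df
            dfg = np.concatenate([dgo, dbe], axis=1)
            grads[f"W_film_{prefix}{i}"] += cond.T @ dfg
            grads[f"b_film_{prefix}{i}"] += dfg.sum(axis=0)
            d_cond += dfg @ p[f"W_film_{prefix}{i}"].T
            a_in = cache["inputs"][i]
            grads[f"W_{prefix}{i}"] += a_in.T @ dh
            grads[f"b_{prefix}{i}"] += dh.sum(axis=0)
            da = dh @ p[f"W_{prefix}{i}"].T
        return da, d_cond

    def encode(self, X: np.ndarray, clusters: np.ndarray, meal_type_ids: np.ndarray):
        cond = self._cond(clusters, meal_type_ids)
        cache = self._mlp_forward(X, cond, "enc")
        p = self.params
        mu = cache["out"] @ p["W_mu"] + p["b_mu"]
        logvar = np.clip(cache["out"] @ p["W_logvar"] + p["b_logvar"], -10.0, 10.0)
        return mu, logvar, cond, cache

    def decode_logits(self, z: np.ndarray, cond: np.ndarray,
                      pairs: list[tuple[int, int]] | None = None):
        cache = self._mlp_forward(z, cond, "dec")
        logits = cache["out"] @ self.params["W_out"] + self.params["b_out"]
        if pairs is not None:
            prior = np.stack([self.pair_stats[k].prior_logits for k in pairs])
            logits = logits + prior
        return logits, cache

    # -- losses

    def loss_components(self, X, clusters, meal_type_ids, beta, eps=None, log_grams=None):
        """Forward pass returning (bce, kl_term, count_loss, total) and caches.

        bce: weighted binary cross-entropy, positive-class weight
        #neg/#pos per batch clipped to the configured range, summed over
        foods, averaged over the batch. kl_term: per-dim KL floored at the
        free-bits value, summed over dims, scaled by beta. count_loss:
        mean squared error between summed probabilities and item counts.
        In joint-portioning mode a gram-regression term over present
        foods is added to the total (weighted by gram_loss_weight).
        """
        cfg = self.config
        mu, logvar, cond, enc_cache = self.encode(X, clusters, meal_type_ids)
        if eps is None:
            eps = self._rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * logvar)
        z = mu + eps * sigma
        pairs = [self._pair_key(c, m) for c, m in zip(clusters, meal_type_ids)]
        known = [k for k in pairs if k in self.pair_stats]
        logits, dec_cache = self.decode_logits(z, cond, pairs if len(known) == len(pairs) else None)

        B = X.shape[0]
        n_pos = X.sum()
        n_neg = X.size - n_pos
        lo, hi = cfg.pos_weight_clip
        w = float(np.clip(n_neg / max(n_pos, 1.0), lo, hi))

        probs = expit(logits)
        eps_p = 1e-12
        bce = float(
            np.sum(-w * X * np.log(probs + eps_p) - (1 - X) * np.log(1 - probs + eps_p)) / B
        )
        kl_dim = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).mean(axis=0)
        kl_floored = np.maximum(cfg.free_bits, kl_dim)
        kl_term = float(beta * kl_floored.sum())

        counts = X.sum(axis=1)
        s = probs.sum(axis=1)
        count_loss = float(np.mean((s - counts) ** 2))
        total = bce + kl_term + cfg.count_loss_weight * count_loss
        gram_pred = None
        gram_loss = 0.0
        if cfg.joint_portioning and log_grams is not None:
            gram_pred = dec_cache["out"] @ self.params["W_gram"] + self.params["b_gram"]
            n_present = max(X.sum(), 1.0)
            gram_loss = float(np.sum(X * (gram_pred - log_grams) ** 2) / n_present)
            total = total + cfg.gram_loss_weight * gram_loss
        caches = dict(
            gram_pred=gram_pred, log_grams=log_grams, gram_loss=gram_loss,
            mu=mu, logvar=logvar, sigma=sigma, eps=eps, z=z, cond=cond,
            enc=enc_cache, dec=dec_cache, logits=logits, probs=probs,
            pos_weight=w, kl_dim=kl_dim, counts=counts, beta=beta,
        )
        return (bce, kl_term, count_loss, total), caches

    def _backward(self, X, clusters, meal_type_ids, caches) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        B = X.shape[0]
        probs, w = caches["probs"], caches["pos_weight"]

        # BCE + count loss -> logits
        d_logits = (probs * ((1 - X) + w * X) - w * X) / B
        s = probs.sum(axis=1)
        d_logits += (
            cfg.count_loss_weight * (2.0 * (s - caches["counts"]) / B)[:, None] * probs * (1 - probs)
        )

        d_dec_out = d_logits @ p["W_out"].T
        if cfg.joint_portioning and caches.get("gram_pred") is not None:
            n_present = max(X.sum(), 1.0)
            d_gram = cfg.gram_loss_weight * 2.0 * X * (
                caches["gram_pred"] - caches["log_grams"]
            ) / n_present
            grads["W_gram"] += caches["dec"]["out"].T @ d_gram
            grads["b_gram"] += d_gram.sum(axis=0)
            d_dec_out = d_dec_out + d_gram @ p["W_gram"].T
        dz, d_cond_dec = self._mlp_backward(
            d_dec_out, caches["cond"], caches["dec"], "dec", grads
        )
        grads["W_out"] += caches["dec"]["out"].T @ d_logits
        grads["b_out"] += d_logits.sum(axis=0)

        # KL (free bits: zero gradient on floored dims)
        active = (caches["kl_dim"] > cfg.free_bits).astype(float)
        beta = caches["beta"]
        d_mu_kl = beta * active * caches["mu"] / B
        d_logvar_kl = beta * active * 0.5 * (np.exp(caches["logvar"]) - 1.0) / B

        # reparameterisation
        d_mu = dz + d_mu_kl
        d_logvar = dz * caches["eps"] * 0.5 * caches["sigma"] + d_logvar_kl

        enc_out = caches["enc"]["out"]
        grads["W_mu"] += enc_out.T @ d_mu
        grads["b_mu"] += d_mu.sum(axis=0)
        grads["W_logvar"] += enc_out.T @ d_logvar
        grads["b_logvar"] += d_logvar.sum(axis=0)
        d_enc_out = d_mu @ p["W_mu"].T + d_logvar @ p["W_logvar"].T
        _, d_cond_enc = self._mlp_backward(d_enc_out, caches["cond"], caches["enc"], "enc", grads)

        if cfg.conditioning:
            d_cond = d_cond_enc + d_cond_dec
            e = cfg.embed_dim
            c_rows = np.array([self.cluster_index[int(c)] for c in clusters])
            np.add.at(grads["E_cluster"], c_rows, d_cond[:, :e])
            np.add.at(grads["E_meal"], meal_type_ids, d_cond[:, e:])
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        keys = sorted(self.params)
        g = np.concatenate([np.ravel(grads[k]) for k in keys])
        norm = float(np.sqrt(g @ g))
        if norm > cfg.clipnorm:
            g *= cfg.clipnorm / norm
        if self._adam_m_flat is None or len(self._adam_m_flat) != len(g):
            self._adam_m_flat = np.zeros_like(g)
            self._adam_v_flat = np.zeros_like(g)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        self._adam_m_flat = b1 * self._adam_m_flat + (1 - b1) * g
        self._adam_v_flat = b2 * self._adam_v_flat + (1 - b2) * g * g
        step = (
            cfg.lr
            * (self._adam_m_flat / (1 - b1**t))
            / (np.sqrt(self._adam_v_flat / (1 - b2**t)) + eps)
        )
        offset = 0
        for k in keys:
            size = self.params[k].size
            self.params[k] -= step[offset:offset + size].reshape(self.params[k].shape)
            offset += size

    # -- training

    def fit(
        self,
        X: np.ndarray,
        clusters: np.ndarray,
        meal_type_ids: np.ndarray,
        log_grams: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Train on binary presence rows; returns per-epoch loss history.

        ``log_grams`` (standardised log gram amounts, 0 where absent) is
        only consumed in joint-portioning mode.
        """
        cfg = self.config
        X = np.asarray(X, dtype=float)
        clusters = np.asarray(clusters, dtype=int)
        meal_type_ids = np.asarray(meal_type_ids, dtype=int)
        self.pair_stats = fit_pair_stats(
            X, np.array([self._pair_key(c, m)[0] for c, m in zip(clusters, meal_type_ids)]),
            meal_type_ids,
        )
        n = X.shape[0]
        steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
        history = []
        step = 0
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            ep = np.zeros(4)
            for b in range(steps_per_epoch):
                idx = order[b * cfg.batch_size: (b + 1) * cfg.batch_size]
                beta = beta_schedule(step, cfg, steps_per_epoch)
                comps, caches = self.loss_components(
                    X[idx], clusters[idx], meal_type_ids[idx], beta,
                    log_grams=None if log_grams is None else log_grams[idx],
                )
                if not np.isfinite(comps[3]):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch} step {step}: "
                        f"bce={comps[0]:.3g} kl={comps[1]:.3g} count={comps[2]:.3g}"
                    )
                grads = self._backward(X[idx], clusters[idx], meal_type_ids[idx], caches)
                self._adam_step(grads)
                ep += np.array(comps)
                step += 1
            ep /= steps_per_epoch
            history.append(
                {"epoch": epoch, "bce": ep[0], "kl": ep[1], "count": ep[2], "total": ep[3]}
            )
        return pd.DataFrame(history)

    # -- inference

    def reconstruct(self, X, clusters, meal_type_ids) -> np.ndarray:
        """Deterministic reconstruction (z = posterior mean): binary matrix.

        Decoded with the count-calibrated top-m rule, m = round(sum of
        probabilities) clamped to [1, n_foods]; the sampling-time gate is
        not applied, so reconstruction measures encoder/decoder capacity.
        """
        X = np.asarray(X, dtype=float)
        mu, _, cond, _ = self.encode(X, np.asarray(clusters), np.asarray(meal_type_ids))
        pairs = [self._pair_key(c, m) for c, m in zip(clusters, meal_type_ids)]
        if all(k in self.pair_stats for k in pairs):
            logits, _ = self.decode_logits(mu, cond, pairs)
        else:
            logits, _ = self.decode_logits(mu, cond, None)
        probs = expit(logits)
        out = np.zeros_like(probs, dtype=np.int8)
        for i, row in enumerate(probs):
            m = int(np.clip(round(float(row.sum())), 1, len(row)))
            top = np.argpartition(-row, m - 1)[:m]
            out[i, top] = 1
        return out

    def sample_meals(self, cluster: int, meal_type: str, n: int, seed: int = 0) -> list[list[str]]:
        """Sample n food sets for a (cluster, meal type) pair.

        z ~ N(0, I); decoder logits plus the pair prior; foods outside the
        pair's allowed set are penalised by the mask strength before the
        sigmoid; the decoded set is the top-m gated foods with
        m = round(sum of gated probabilities) clamped to [1, k].
        """
        if meal_type not in MEAL_TYPES:
            raise ValueError(f"unknown meal type {meal_type!r}")
        mt = MEAL_TYPES.index(meal_type)
        key = self._pair_key(cluster, mt)
        if key not in self.pair_stats:
            raise KeyError(
                f"no gate for pair (cluster={cluster}, meal_type={meal_type}); "
                f"known pairs: {sorted(self.pair_stats)}"
            )
        if n == 0:
            return []
        stats = self.pair_stats[key]
        allowed = stats.allowed
        k = len(allowed)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.latent_dim))
        cond = self._cond(np.full(n, cluster), np.full(n, mt))
        logits, _ = self.decode_logits(z, cond, [key] * n)
        mask = np.full(logits.shape[1], -self.config.mask_strength)
        mask[allowed] = 0.0
        gated = expit(logits + mask)
        meals = []
        for row in gated:
            if self.config.decode == "bernoulli":
                sel = np.flatnonzero((rng.random(len(row)) < row) & np.isin(
                    np.arange(len(row)), allowed))
                if sel.size == 0:
                    sel = np.array([allowed[int(np.argmax(row[allowed]))]])
            else:
                m = int(np.clip(round(float(row.sum())), 1, k))
                order = np.argsort(-row[allowed], kind="stable")
                sel = allowed[order[:m]]
            meals.append([self.food_codes[i] for i in np.sort(sel)])
        return meals


# ------------------------------------------------------------- train API


def micro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(((y_true == 1) & (y_pred == 1)).sum())
    fp = float(((y_true == 0) & (y_pred == 1)).sum())
    fn = float(((y_true == 1) & (y_pred == 0)).sum())
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def build_training_arrays(
    corpus: MealCorpus, labels: pd.Series, food_codes: list[str] | None = None
):
    """Corpus + cluster labels -> (X, clusters, meal_type_ids, food_codes, meal_ids).

    Noise meals (label -1) are excluded.
    """
    keep = labels.index[labels != -1]
    sub = corpus.subset(keep)
    foods = food_codes or sorted(sub.df["food_code"].unique())
    f_index = {f: i for i, f in enumerate(foods)}
    ids = sub.meal_ids
    X = np.zeros((len(ids), len(foods)), dtype=np.int8)
    m_index = {m: i for i, m in enumerate(ids)}
    for r in sub.df.itertuples():
        j = f_index.get(r.food_code)
        if j is not None:
            X[m_index[r.meal_id], j] = 1
    types = sub.meal_types().loc[ids].map(MEAL_TYPES.index).to_numpy()
    return X, labels.loc[ids].to_numpy(), types, foods, ids


def build_log_gram_matrix(corpus: MealCorpus, meal_ids, food_codes: list[str]) -> np.ndarray:
    """Standardised log grams (0 where absent), aligned with the presence
    matrix; used by the joint-portioning ablation."""
    f_index = {f: i for i, f in enumerate(food_codes)}
    m_index = {m: i for i, m in enumerate(meal_ids)}
    G = np.zeros((len(meal_ids), len(food_codes)))
    for r in corpus.df.itertuples():
        i, j = m_index.get(r.meal_id), f_index.get(r.food_code)
        if i is not None and j is not None:
            G[i, j] = np.log(r.grams)
    present = G != 0
    if present.any():
        vals = G[present]
        G[present] = (vals - vals.mean()) / max(vals.std(), 1e-9)
    return G


def train_cvae(
    corpus: MealCorpus,
    labels: pd.Series,
    config: CVAEConfig,
    holdout_frac: float = 0.1,
) -> tuple[MealCVAE, pd.DataFrame, dict]:
    """Train on non-noise meals; returns (model, history, report).

    The report carries train/held-out reconstruction micro-F1. Pairs with
    fewer than ``min_pair_size`` meals are dropped before training.
    """
    X, cl, mt, foods, ids = build_training_arrays(corpus, labels)
    G = build_log_gram_matrix(corpus, ids, foods) if config.joint_portioning else None
    pair_key = pd.Series(list(zip(cl, mt)))
    sizes = pair_key.map(pair_key.value_counts())
    keep = (sizes >= config.min_pair_size).to_numpy()
    X, cl, mt = X[keep], cl[keep], mt[keep]
    if G is not None:
        G = G[keep]
    if len({(c, m) for c, m in zip(cl, mt)}) < 2:
        raise ValueError("need at least 2 (cluster, meal type) pairs with enough meals")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_hold = int(round(holdout_frac * n))
    hold, train = perm[:n_hold], perm[n_hold:]

    model = MealCVAE(foods, sorted(set(int(c) for c in cl)), config)
    history = model.fit(X[train], cl[train], mt[train],
                        None if G is None else G[train])

    report = {
        "n_train": int(len(train)),
        "n_holdout": int(len(hold)),
        "train_micro_f1": micro_f1(X[train], model.reconstruct(X[train], cl[train], mt[train])),
    }
    if n_hold > 0:
        report["holdout_micro_f1"] = micro_f1(
            X[hold], model.reconstruct(X[hold], cl[hold], mt[hold])
        )
    return model, history, report


# ------------------------------------------------------------ persistence


def save_model(model: MealCVAE, out_dir) -> None:
    import json
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **model.params)
    cfg = asdict(model.config)
    cfg["pos_weight_clip"] = list(cfg["pos_weight_clip"])
    meta = {
        "config": cfg,
        "food_codes": model.food_codes,
        "cluster_ids": model.cluster_ids,
        "pairs": [
            {
                "cluster": k[0],
                "meal_type_id": k[1],
                "n_meals": v.n_meals,
                "median_items": v.median_items,
                "prevalence": v.prevalence.tolist(),
            }
            for k, v in model.pair_stats.items()
        ],
    }
    (out / "model.json").write_text(json.dumps(meta))


def load_model(model_dir) -> MealCVAE:
    import json
    import pathlib

    path = pathlib.Path(model_dir)
    meta = json.loads((path / "model.json").read_text())
    cfg_d = meta["config"]
    cfg_d["pos_weight_clip"] = tuple(cfg_d["pos_weight_clip"])
    config = CVAEConfig(**cfg_d)
    model = MealCVAE(meta["food_codes"], meta["cluster_ids"], config)
    weights = np.load(path / "weights.npz")
    model.params = {k: weights[k] for k in weights.files}
    model.pair_stats = {
        (p["cluster"], p["meal_type_id"]): PairStats(
            prevalence=np.asarray(p["prevalence"]),
            n_meals=p["n_meals"],
            median_items=p["median_items"],
        )
        for p in meta["pairs"]
    }
    return model
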