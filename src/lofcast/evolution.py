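"""Generative modelling of the MCT8 alignment and the evolutionary index.

A variational autoencoder is trained on the one-hot-encoded, phylogeny-
reweighted multiple sequence alignment (gap is a 21st category).  The
evolutionary index of a missense variant is the ensemble-mean difference
in approximate sequence log-probability (ELBO) between the wild-type and
mutated sequence:

    index(v) = mean_m [ ELBO_m(x_wt) - ELBO_m(x_mut) ]

so a positive index means the model prefers the wild type — a stronger
evolutionary constraint against the substitution.  Ten independently
initialised models are ensembled by default.

The VAE is implemented directly in numpy (encoder MLP -> diagonal
Gaussian latent -> symmetric decoder with per-column categorical output),
trained with Adam on the weighted ELBO.  All randomness flows from
explicit seeds; training and scoring are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import ALPHABET, Alignment, VariantSpec

N_SYMBOLS = len(ALPHABET)  # 20 amino acids + gap
GAP_CODE = N_SYMBOLS - 1


# ---------------------------------------------------------------------------
# Sequence reweighting
# ---------------------------------------------------------------------------

@dataclass
class SequenceWeights:
    """Per-row phylogenetic down-weighting of redundant sequences.

    Each row's weight is 1 / (number of rows, itself included, whose
    normalized pairwise identity to it is at least 1 - theta).  Neff is
    the resulting effective number of sequences.
    """

    weights: np.ndarray
    theta: float

    @property
    def neff(self) -> float:
        return float(self.weights.sum())


def compute_sequence_weights(alignment: Alignment, theta: float = 0.2) -> SequenceWeights:
    """Cluster-based reweighting at identity threshold 1 - theta.

    Pairwise identity counts matching residues over columns where both
    rows are non-gap ('X' counts as gap).  Deterministic.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    idx = alignment.to_indices()
    nongap = idx != GAP_CODE
    if not nongap.any(axis=1).all():
        bad = [alignment.ids[i] for i in np.where(~nongap.any(axis=1))[0]]
        raise ValueError(f"all-gap rows in alignment: {bad}")
    n = idx.shape[0]
    if n == 1:
        import warnings

        warnings.warn("single-sequence alignment: weight 1, Neff 1", stacklevel=2)
        return SequenceWeights(weights=np.ones(1), theta=theta)

    counts = np.zeros(n, dtype=int)
    for i in range(n):
        both = nongap[i] & nongap
        denom = both.sum(axis=1)
        matches = ((idx[i] == idx) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        counts[i] = int((identity >= 1.0 - theta).sum())
    return SequenceWeights(weights=1.0 / counts, theta=theta)


# ---------------------------------------------------------------------------
# The VAE
# ---------------------------------------------------------------------------

@dataclass
class VAEConfig:
    """Architecture and training settings (all sizes are free knobs).

    Defaults target desk-scale CPU training; shrink ``epochs`` and the
    layer sizes for tests.
    """

    latent_dim: int = 16
    hidden: tuple[int, int] = (64, 32)
    epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 128
    n_elbo_samples: int = 200

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(d["hidden"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VAEConfig":
        d = dict(d)
        d["hidden"] = tuple(d["hidden"])
        return cls(**d)

    @classmethod
    def reduced(cls) -> "VAEConfig":
        """Desk-scale configuration for small synthetic alignments:
        seconds per model on one CPU, still enough capacity to resolve
        per-column conservation structure."""
        return cls(
            latent_dim=8, hidden=(48, 24), epochs=120,
            batch_size=64, n_elbo_samples=50,
        )


class TrainingError(RuntimeError):
    pass


def _one_hot(idx: np.ndarray) -> np.ndarray:
    """(n, L) integer codes -> (n, L * 21) flat one-hot."""
    n, length = idx.shape
    out = np.zeros((n, length, N_SYMBOLS))
    out[np.arange(n)[:, None], np.arange(length)[None, :], idx] = 1.0
    return out.reshape(n, length * N_SYMBOLS)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


class SequenceVAE:
    """One numpy VAE over flattened one-hot sequences.

    Encoder: x -> tanh -> tanh -> (mu, log var); decoder mirrors the
    encoder and emits per-column 21-way categorical logits.  Trained by
    Adam on the (sequence-weighted) negative ELBO.
    """

    def __init__(self, seq_length: int, config: VAEConfig, seed: int):
        self.seq_length = seq_length
        self.config = config
        self.seed = int(seed)
        self.loss_history: list[float] = []
        rng = np.random.default_rng(self.seed)
        d = seq_length * N_SYMBOLS
        h1, h2 = config.hidden
        z = config.latent_dim

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        self.params = {
            "W1": glorot(d, h1), "b1": np.zeros(h1),
            "W2": glorot(h1, h2), "b2": np.zeros(h2),
            "Wm": glorot(h2, z), "bm": np.zeros(z),
            "Wv": glorot(h2, z), "bv": np.zeros(z),
            "V1": glorot(z, h2), "c1": np.zeros(h2),
            "V2": glorot(h2, h1), "c2": np.zeros(h1),
            "V3": glorot(h1, d), "c3": np.zeros(d),
        }

    # -- forward pieces ----------------------------------------------------
    def _encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        p = self.params
        a1 = x @ p["W1"] + p["b1"]
        h1 = np.tanh(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = np.tanh(a2)
        mu = h2 @ p["Wm"] + p["bm"]
        logvar = np.clip(h2 @ p["Wv"] + p["bv"], -10.0, 10.0)
        return mu, logvar, {"h1": h1, "h2": h2}

    def _decode(self, z: np.ndarray) -> tuple[np.ndarray, dict]:
        p = self.params
        g1 = np.tanh(z @ p["V1"] + p["c1"])
        g2 = np.tanh(g1 @ p["V2"] + p["c2"])
        logits = g2 @ p["V3"] + p["c3"]
        return logits, {"g1": g1, "g2": g2}

    def _recon_nll(self, logits: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Per-sequence categorical cross-entropy, summed over columns."""
        b = logits.shape[0]
        lp = _log_softmax(logits.reshape(b, self.seq_length, N_SYMBOLS))
        xr = x.reshape(b, self.seq_length, N_SYMBOLS)
        return -(xr * lp).sum(axis=(1, 2))

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, weights: np.ndarray) -> "SequenceVAE":
        cfg = self.config
        n = x.shape[0]
        w = np.asarray(weights, dtype=float)
        rng = np.random.default_rng(self.seed + 1)
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                xb, wb = x[batch], w[batch]
                loss, grads = self._loss_and_grads(xb, wb, rng)
                epoch_loss += loss * wb.sum()
                t += 1
                for k in self.params:
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = adam_m[k] / (1 - beta1 ** t)
                    vhat = adam_v[k] / (1 - beta2 ** t)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
            epoch_loss /= w.sum()
            if not np.isfinite(epoch_loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} (seed {self.seed})"
                )
            self.loss_history.append(float(epoch_loss))
        return self

    def _loss_and_grads(
        self, x: np.ndarray, w: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict]:
        p = self.params
        b = x.shape[0]
        wn = w / w.sum()

        mu, logvar, enc = self._encode(x)
        eps = rng.standard_normal(mu.shape)
        sd = np.exp(0.5 * logvar)
        z = mu + eps * sd
        logits, dec = self._decode(z)

        blk = logits.reshape(b, self.seq_length, N_SYMBOLS)
        lp = _log_softmax(blk)
        probs = np.exp(lp)
        xr = x.reshape(b, self.seq_length, N_SYMBOLS)
        recon = -(xr * lp).sum(axis=(1, 2))
        kl = 0.5 * (np.exp(logvar) + mu ** 2 - 1.0 - logvar).sum(axis=1)
        loss = float((wn * (recon + kl)).sum())

        # backward
        dlogits = ((probs - xr) * wn[:, None, None]).reshape(b, -1)
        g1, g2 = dec["g1"], dec["g2"]
        grads = {
            "V3": g2.T @ dlogits, "c3": dlogits.sum(axis=0),
        }
        dg2 = (dlogits @ p["V3"].T) * (1 - g2 ** 2)
        grads["V2"] = g1.T @ dg2
        grads["c2"] = dg2.sum(axis=0)
        dg1 = (dg2 @ p["V2"].T) * (1 - g1 ** 2)
        grads["V1"] = z.T @ dg1
        grads["c1"] = dg1.sum(axis=0)
        dz = dg1 @ p["V1"].T

        dmu = dz + wn[:, None] * mu
        dlogvar = dz * eps * 0.5 * sd + wn[:, None] * 0.5 * (np.exp(logvar) - 1.0)

        h1, h2 = enc["h1"], enc["h2"]
        grads["Wm"] = h2.T @ dmu
        grads["bm"] = dmu.sum(axis=0)
        grads["Wv"] = h2.T @ dlogvar
        grads["bv"] = dlogvar.sum(axis=0)
        dh2 = (dmu @ p["Wm"].T + dlogvar @ p["Wv"].T) * (1 - h2 ** 2)
        grads["W2"] = h1.T @ dh2
        grads["b2"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["W2"].T) * (1 - h1 ** 2)
        grads["W1"] = x.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        return loss, grads

    # -- scoring -----------------------------------------------------------
    def elbo(self, x: np.ndarray, n_samples: int, eps: np.ndarray | None = None,
             rng: np.random.Generator | None = None) -> float:
        """ELBO of a single flattened one-hot sequence, averaged over
        ``n_samples`` latent draws (shared ``eps`` enables common random
        numbers across wild-type/mutant scoring)."""
        x = x.reshape(1, -1)
        mu, logvar, _ = self._encode(x)
        if eps is None:
            if rng is None:
                raise ValueError("either eps or rng is required")
            eps = rng.standard_normal((n_samples, mu.shape[1]))
        z = mu + eps * np.exp(0.5 * logvar)
        logits, _ = self._decode(z)
        recon = self._recon_nll(logits, np.repeat(x, n_samples, axis=0))
        kl = 0.5 * (np.exp(logvar) + mu ** 2 - 1.0 - logvar).sum()
        return float(-recon.mean() - kl)


class SiteIndependentModel:
    """Degenerate, latent-free limit: per-column categorical frequencies.

    The sequence log-probability is the sum of weighted column
    log-frequencies (with a Laplace pseudocount), so a substitution's
    index reduces exactly to the column log-frequency ratio
    log f(wt) - log f(mut).  Serves as a closed-form reference point for
    the VAE scoring contract.
    """

    def __init__(self, pseudocount: float = 0.1):
        self.pseudocount = pseudocount
        self.log_freqs: np.ndarray | None = None  # (L, 21)

    def fit(self, x_idx: np.ndarray, weights: np.ndarray) -> "SiteIndependentModel":
        n, length = x_idx.shape
        counts = np.full((length, N_SYMBOLS), self.pseudocount)
        for j in range(length):
            np.add.at(counts[j], x_idx[:, j], weights)
        freqs = counts / counts.sum(axis=1, keepdims=True)
        self.log_freqs = np.log(freqs)
        return self

    def log_prob(self, seq_idx: np.ndarray) -> float:
        assert self.log_freqs is not None, "model not fitted"
        return float(self.log_freqs[np.arange(len(seq_idx)), seq_idx].sum())

    def elbo(self, x: np.ndarray, n_samples: int = 0, eps=None, rng=None) -> float:
        seq_idx = x.reshape(-1, N_SYMBOLS).argmax(axis=1)
        return self.log_prob(seq_idx)


# ---------------------------------------------------------------------------
# Ensemble: statsmodels-style model / results pair
# ---------------------------------------------------------------------------

def _alignment_fingerprint(alignment: Alignment) -> str:
    h = hashlib.sha256()
    for s in alignment.seqs:
        h.update(s.encode())
    return h.hexdigest()[:16]


def _variant_seed(variant: VariantSpec, base_seed: int) -> int:
    key = f"{variant.position}:{variant.wt}:{variant.mut}:{base_seed}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


class AlignmentVAE:
    """Model object: a VAE ensemble specification over an alignment.

    ``fit`` trains ``n_models`` independently seeded VAEs on the
    reweighted alignment and returns a :class:`VAEEnsembleResults`.

    ``ref_offset`` is the reference-protein position of alignment
    column 1 (default 1, i.e. the alignment covers the full protein).
    """

    def __init__(
        self,
        alignment: Alignment,
        weights: SequenceWeights | None = None,
        config: VAEConfig | None = None,
        ref_offset: int = 1,
    ):
        self.alignment = alignment
        self.weights = weights or compute_sequence_weights(alignment)
        self.config = config or VAEConfig()
        self.ref_offset = ref_offset

    def fit(self, n_models: int = 10, base_seed: int = 0) -> "VAEEnsembleResults":
        if n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.weights.neff < 2:
            raise ValueError(
                f"alignment has effective sample size {self.weights.neff:.2f} "
                "< 2; a generative model cannot be trained on it"
            )
        idx = self.alignment.to_indices()
        x = _one_hot(idx)
        seeds = [
            int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(base_seed).spawn(n_models)
        ]
        models = [
            SequenceVAE(self.alignment.length, self.config, seed).fit(
                x, self.weights.weights
            )
            for seed in seeds
        ]
        return VAEEnsembleResults(
            models=models,
            config=self.config,
            base_seed=base_seed,
            reference=self.alignment.reference,
            ref_offset=self.ref_offset,
            alignment_fingerprint=_alignment_fingerprint(self.alignment),
        )


@dataclass
class VAEEnsembleResults:
    """A fitted VAE ensemble plus everything needed to score variants."""

    models: list
    config: VAEConfig
    base_seed: int
    reference: str
    ref_offset: int
    alignment_fingerprint: str
    seeds: list[int] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def _check_position(self, variant: VariantSpec) -> int:
        col = variant.position - self.ref_offset
        if not 0 <= col < len(self.reference):
            raise IndexError(
                f"position {variant.position} outside the alignment's "
                f"reference span {self.ref_offset}.."
                f"{self.ref_offset + len(self.reference) - 1}"
            )
        if self.reference[col] != variant.wt:
            raise ValueError(
                f"wild-type mismatch at {variant.position}: reference has "
                f"{self.reference[col]}, variant says {variant.wt}"
            )
        return col

    def evolutionary_index(self, variant: VariantSpec) -> float:
        """Ensemble-mean ELBO(wt) - ELBO(mut); > 0 means constrained.

        A wt == wt substitution scores exactly 0.  Latent sampling uses a
        per-variant seed derived from (variant, base_seed) and common
        random numbers across the wild-type/mutant pair.
        """
        col = self._check_position(variant)
        if variant.wt == variant.mut:
            return 0.0
        from .io import AA_TO_INDEX

        wt_idx = np.array([AA_TO_INDEX[c] for c in self.reference], dtype=np.int8)
        mut_idx = wt_idx.copy()
        mut_idx[col] = AA_TO_INDEX[variant.mut]
        x_wt = _one_hot(wt_idx[None, :])[0]
        x_mut = _one_hot(mut_idx[None, :])[0]

        seed = _variant_seed(variant, self.base_seed)
        k = self.config.n_elbo_samples
        deltas = []
        for m, model in enumerate(self.models):
            rng = np.random.default_rng(seed + m)
            zdim = getattr(self.config, "latent_dim", 1)
            eps = rng.standard_normal((k, zdim))
            deltas.append(model.elbo(x_wt, k, eps=eps) - model.elbo(x_mut, k, eps=eps))
        return float(np.mean(deltas))

    def indices(self, variants: list[VariantSpec]) -> np.ndarray:
        return np.array([self.evolutionary_index(v) for v in variants])

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, m in enumerate(self.models):
            for k, v in m.params.items():
                arrays[f"model{i}_{k}"] = v
        meta = {
            "config": self.config.to_dict(),
            "base_seed": self.base_seed,
            "reference": self.reference,
            "ref_offset": self.ref_offset,
            "alignment_fingerprint": self.alignment_fingerprint,
            "model_seeds": [m.seed for m in self.models],
            "seq_length": len(self.reference),
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "VAEEnsembleResults":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            config = VAEConfig.from_dict(meta["config"])
            models = []
            for i, seed in enumerate(meta["model_seeds"]):
                m = SequenceVAE(meta["seq_length"], config, seed)
                m.params = {
                    k.split("_", 1)[1]: data[k]
                    for k in data.files
                    if k.startswith(f"model{i}_")
                }
                models.append(m)
        return cls(
            models=models,
            config=config,
            base_seed=meta["base_seed"],
            reference=meta["reference"],
            ref_offset=meta["ref_offset"],
            alignment_fingerprint=meta["alignment_fingerprint"],
        )


def train_vae_ensemble(
    alignment: Alignment,
    weights: SequenceWeights | None = None,
    n_models: int = 10,
    base_seed: int = 0,
    config: VAEConfig | None = None,
    ref_offset: int = 1,
) -> VAEEnsembleResults:
    """Functional wrapper over :class:`AlignmentVAE`.fit."""
    return AlignmentVAE(
        alignment, weights=weights, config=config, ref_offset=ref_offset
    ).fit(n_models=n_models, base_seed=base_seed)


def evolutionary_index(ensemble: VAEEnsembleResults, variant: VariantSpec) -> float:
    return ensemble.evolutionary_index(variant)


def site_independent_results(
    alignment: Alignment,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.1,
    ref_offset: int = 1,
) -> VAEEnsembleResults:
    """The latent-free closed-form limit packaged as a results object.

    Its evolutionary index equals the per-column weighted log-frequency
    ratio log f(wt) - log f(mut) exactly.
    """
    weights = weights or compute_sequence_weights(alignment)
    model = SiteIndependentModel(pseudocount=pseudocount).fit(
        alignment.to_indices(), weights.weights
    )
    return VAEEnsembleResults(
        models=[model],
        config=VAEConfig(n_elbo_samples=1, latent_dim=1),
        base_seed=0,
        reference=alignment.reference,
        ref_offset=ref_offset,
        alignment_fingerprint=_alignment_fingerprint(alignment),
    )
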